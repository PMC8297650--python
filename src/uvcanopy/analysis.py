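"""Aggregate trace tallies into position summaries, vertical profiles,
leaf area index and per-leaf cumulative absorbed UV.

A leaf's height is the area-weighted centroid z of its triangles; class
summaries are means over leaves with the standard error across leaves in
the class. Percent differences follow the "(upper - other)/other x 100"
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dosimetry import ExposureSchedule
from .raytracer import InterceptionResult
from .synthetic import PlantModel

__all__ = [
    "PositionSummary",
    "summarize_by_position",
    "vertical_profile",
    "leaf_area_index",
    "cumulative_absorbed_uv",
    "photon_flux_column",
]

_CLASS_ORDER = ["upper", "middle", "lower"]


@dataclass
class PositionSummary:
    """Per-position-class flux summary plus pairwise percent differences."""

    band: str
    by_class: pd.DataFrame  # position_class, mean_flux_W_m2, se, n
    percent_difference: pd.DataFrame  # reference, other, percent

    def mean_flux(self, position_class: str) -> float:
        row = self.by_class[self.by_class["position_class"] == position_class]
        if row.empty:
            raise KeyError(position_class)
        return float(row["mean_flux_W_m2"].iloc[0])


def _leaf_table(result: InterceptionResult, plants: Sequence[PlantModel]) -> pd.DataFrame:
    leaves = result.leaves().copy()
    heights = {
        (p.plant_id, l.leaf_id): l.centroid_height()
        for p in plants
        for l in p.leaves
    }
    leaves["height_m"] = [
        heights[(pid, lid)] for pid, lid in zip(leaves["plant_id"], leaves["leaf_id"])
    ]
    return leaves


def summarize_by_position(
    result: InterceptionResult, plants: Sequence[PlantModel]
) -> PositionSummary:
    """Mean and SE of absorbed flux density per leaf-position class."""
    leaves = result.leaves()
    if leaves["position_class"].eq("").any():
        raise ValueError("every leaf needs a position class")
    rows = []
    for cls, grp in leaves.groupby("position_class"):
        flux = grp["flux_W_m2"].to_numpy()
        rows.append(
            {
                "position_class": cls,
                "mean_flux_W_m2": float(flux.mean()),
                "se_flux_W_m2": float(flux.std(ddof=1) / np.sqrt(len(flux)))
                if len(flux) > 1
                else 0.0,
                "n_leaves": int(len(flux)),
            }
        )
    order = {c: i for i, c in enumerate(_CLASS_ORDER)}
    by_class = (
        pd.DataFrame(rows)
        .sort_values("position_class", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )

    diffs = []
    means = dict(zip(by_class["position_class"], by_class["mean_flux_W_m2"]))
    for ref in by_class["position_class"]:
        for other in by_class["position_class"]:
            if ref == other or means[other] == 0:
                continue
            diffs.append(
                {
                    "reference": ref,
                    "other": other,
                    "percent": (means[ref] - means[other]) / means[other] * 100.0,
                }
            )
    return PositionSummary(
        band=result.band,
        by_class=by_class,
        percent_difference=pd.DataFrame(diffs, columns=["reference", "other", "percent"]),
    )


def vertical_profile(
    result: InterceptionResult,
    plants: Sequence[PlantModel],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean absorbed flux density per height bin (leaf centroid height).

    Returns bin_center_m, mean_flux_W_m2, n_leaves; empty bins are dropped.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    leaves = _leaf_table(result, plants)
    lo = leaves["height_m"].min()
    hi = leaves["height_m"].max()
    if hi <= lo:
        edges = np.array([lo - 1e-9, lo + 1e-9])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(leaves["height_m"], edges) - 1, 0, n_bins - 1)
    leaves = leaves.assign(bin=idx)
    rows = []
    for b, grp in leaves.groupby("bin"):
        rows.append(
            {
                "bin_center_m": float((edges[b] + edges[b + 1]) / 2),
                "mean_flux_W_m2": float(grp["flux_W_m2"].mean()),
                "n_leaves": int(len(grp)),
            }
        )
    return pd.DataFrame(rows).sort_values("bin_center_m").reset_index(drop=True)


def canopy_mean_flux(result: InterceptionResult) -> float:
    """Area-weighted mean absorbed flux density over all leaves."""
    leaves = result.leaves()
    return float(
        np.average(leaves["flux_W_m2"], weights=leaves["area_m2"])
    )


def leaf_area_index(plants: Sequence[PlantModel], bed_area_m2: float) -> float:
    """Total one-sided leaf area per bed area, m^2 m^-2."""
    if bed_area_m2 <= 0:
        raise ValueError("bed area must be positive")
    return sum(p.total_leaf_area for p in plants) / bed_area_m2


def cumulative_absorbed_uv(
    result: InterceptionResult, schedule: ExposureSchedule
) -> pd.DataFrame:
    """Per-leaf cumulative absorbed UV over a schedule, kJ m^-2.

    dUV = absorbed flux density x hours/day x 3600 x days / 1000; linear in
    exposure time, zero for a zero-day schedule.
    """
    leaves = result.leaves().copy()
    leaves["cumulative_absorbed_uv_kJ_m2"] = (
        leaves["flux_W_m2"] * schedule.total_seconds / 1000.0
    )
    return leaves[
        ["plant_id", "leaf_id", "position_class", "cumulative_absorbed_uv_kJ_m2"]
    ]


def photon_flux_column(flux_W_m2, umol_per_J: float) -> np.ndarray:
    """Convert an energy flux column to photon flux with a band-averaged
    conversion factor (umol per J, e.g. from the source spectrum)."""
    return np.asarray(flux_W_m2, dtype=float) * umol_per_J
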