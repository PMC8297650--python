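"""Synthetic rosette plants and per-leaf assay tables.

Real canopies in this workflow come from 3D scans; this module generates
stand-in rosettes with spiral phyllotaxis (137.5 deg divergence) so every
downstream stage — scene assembly, ray tracing, dose integration, yield
regression — runs end to end without any external data. Assay tables are
drawn from an explicit response curve plus Gaussian noise, which makes
parameter-recovery tests possible: the generating curve is the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PositionClass",
    "LeafMesh",
    "PlantModel",
    "RosetteParams",
    "generate_rosette",
    "assign_position_classes",
    "generate_assay_data",
    "preset_params",
    "PRESET_CLASS_COUNTS",
    "ASSAY_COLUMNS",
]


class PositionClass(str, Enum):
    UPPER = "upper"
    MIDDLE = "middle"
    LOWER = "lower"


def _triangle_areas(triangles: np.ndarray) -> np.ndarray:
    a = triangles[:, 1] - triangles[:, 0]
    b = triangles[:, 2] - triangles[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


@dataclass
class LeafMesh:
    """Triangulated one-sided leaf surface with rank and position metadata.

    Rank 1 is the oldest (lowest) leaf; position classes partition ranks so
    the youngest leaves are 'upper'. ``triangles`` has shape (n, 3, 3) in
    metres; ``one_sided_area`` is always the sum of triangle areas.
    """

    leaf_id: int
    rank: int
    triangles: np.ndarray
    position_class: PositionClass | None = None
    one_sided_area: float = field(init=False)

    def __post_init__(self) -> None:
        tri = np.asarray(self.triangles, dtype=float)
        if tri.ndim != 3 or tri.shape[1:] != (3, 3):
            raise ValueError("triangles must have shape (n, 3, 3)")
        areas = _triangle_areas(tri)
        if np.any(areas <= 0):
            raise ValueError("degenerate triangle (zero area) in leaf mesh")
        self.triangles = tri
        self.one_sided_area = float(areas.sum())

    def centroid_height(self) -> float:
        """Area-weighted centroid z of the leaf's triangles, metres."""
        areas = _triangle_areas(self.triangles)
        cz = self.triangles[:, :, 2].mean(axis=1)
        return float(np.average(cz, weights=areas))


@dataclass
class PlantModel:
    plant_id: int
    leaves: list[LeafMesh]
    total_leaf_area: float = field(init=False)
    height: float = field(init=False)

    def __post_init__(self) -> None:
        ranks = sorted(leaf.rank for leaf in self.leaves)
        if ranks != list(range(1, len(self.leaves) + 1)):
            raise ValueError("leaf ranks must be unique and contiguous from 1")
        self.total_leaf_area = float(sum(l.one_sided_area for l in self.leaves))
        self.height = float(
            max(l.triangles[:, :, 2].max() for l in self.leaves)
        )

    def leaf_by_rank(self, rank: int) -> LeafMesh:
        for leaf in self.leaves:
            if leaf.rank == rank:
                return leaf
        raise KeyError(rank)

    def translated(self, dx: float, dy: float, plant_id: int | None = None) -> "PlantModel":
        """Copy of the plant shifted in the bed plane."""
        shift = np.array([dx, dy, 0.0])
        leaves = [
            LeafMesh(
                leaf_id=l.leaf_id,
                rank=l.rank,
                triangles=l.triangles + shift,
                position_class=l.position_class,
            )
            for l in self.leaves
        ]
        return PlantModel(self.plant_id if plant_id is None else plant_id, leaves)


@dataclass(frozen=True)
class RosetteParams:
    """Geometry controls for a synthetic spiral-phyllotaxis rosette.

    Blade dimensions and elevation may be scalar (every leaf identical) or
    one value per rank (rank 1 first). Jitter standard deviations add
    seed-controlled variation in azimuth/elevation so canopies differ
    between replicates; with zero jitter the plant is a pure deterministic
    function of the shape parameters.
    """

    n_leaves: int
    divergence_angle_deg: float = 137.5
    blade_length_m: float | Sequence[float] = 0.05
    blade_width_m: float | Sequence[float] = 0.03
    elevation_deg: float | Sequence[float] = 30.0
    internode_rise_m: float = 0.01
    petiole_length_m: float = 0.01
    bend: float = 0.3
    azimuth_jitter_deg: float = 0.0
    elevation_jitter_deg: float = 0.0
    n_rings: int = 4
    n_sectors: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        for name in ("blade_length_m", "blade_width_m"):
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(vals <= 0):
                raise ValueError(f"{name} must be positive")
        elev = np.atleast_1d(np.asarray(self.elevation_deg, dtype=float))
        if np.any((elev < 0) | (elev > 90)):
            raise ValueError("elevation must lie in [0, 90] degrees")

    def per_leaf(self, name: str) -> np.ndarray:
        vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
        if vals.size == 1:
            return np.full(self.n_leaves, vals[0])
        if vals.size != self.n_leaves:
            raise ValueError(f"{name} must be scalar or length n_leaves")
        return vals


#: Leaf-position class counts (upper, middle, lower) for the two growth-stage
#: presets: 7 leaves split 3/2/2 at 14 DAT and 10 leaves split 4/3/3 at 28 DAT.
PRESET_CLASS_COUNTS: dict[str, tuple[int, int, int]] = {
    "14DAT": (3, 2, 2),
    "28DAT": (4, 3, 3),
}


def preset_params(stage: str, rng_seed: int = 0) -> RosetteParams:
    """Rosette parameters for the '14DAT' and '28DAT' growth-stage presets.

    Blade dimensions are calibrated so a full bed (24 or 12 plants on a
    0.40 m^2 module) lands near leaf area index 0.40 and 1.60 respectively;
    older leaves are larger, younger upper leaves smaller and steeper.
    """
    if stage == "14DAT":
        n = 7
        ramp = np.linspace(1.0, 0.55, n)  # rank 1 (oldest, largest) -> youngest
        return RosetteParams(
            n_leaves=n,
            blade_length_m=0.055 * ramp,
            blade_width_m=0.036 * ramp,
            elevation_deg=np.linspace(15.0, 25.0, n),
            internode_rise_m=0.012,
            petiole_length_m=0.012,
            bend=0.5,
            azimuth_jitter_deg=8.0,
            elevation_jitter_deg=5.0,
            rng_seed=rng_seed,
        )
    if stage == "28DAT":
        n = 10
        ramp = np.linspace(1.0, 0.5, n)
        return RosetteParams(
            n_leaves=n,
            blade_length_m=0.135 * ramp,
            blade_width_m=0.088 * ramp,
            elevation_deg=np.linspace(15.0, 45.0, n),
            internode_rise_m=0.012,
            petiole_length_m=0.02,
            azimuth_jitter_deg=8.0,
            elevation_jitter_deg=5.0,
            rng_seed=rng_seed,
        )
    raise ValueError(f"unknown preset {stage!r}; expected '14DAT' or '28DAT'")


def _ellipse_blade(
    half_length: float,
    half_width: float,
    n_rings: int,
    n_sectors: int,
) -> np.ndarray:
    """Triangulated planar ellipse in local (u, v) blade coordinates.

    u runs along the midrib from -half_length to +half_length, v across.
    Returns triangles of shape (m, 3, 2).
    """
    rings = np.linspace(0.0, 1.0, n_rings + 1)[1:]
    thetas = np.linspace(0.0, 2 * np.pi, n_sectors, endpoint=False)
    pts = [np.array([0.0, 0.0])]
    for r in rings:
        for t in thetas:
            pts.append(np.array([half_length * r * np.cos(t), half_width * r * np.sin(t)]))
    pts = np.asarray(pts)

    tris: list[tuple[int, int, int]] = []
    # innermost fan
    for j in range(n_sectors):
        tris.append((0, 1 + j, 1 + (j + 1) % n_sectors))
    # ring bands
    for i in range(1, len(rings)):
        base0 = 1 + (i - 1) * n_sectors
        base1 = 1 + i * n_sectors
        for j in range(n_sectors):
            jn = (j + 1) % n_sectors
            tris.append((base0 + j, base1 + j, base1 + jn))
            tris.append((base0 + j, base1 + jn, base0 + jn))
    return pts[np.asarray(tris)]


def generate_rosette(params: RosetteParams, plant_id: int = 0) -> PlantModel:
    """Build a spiral-phyllotaxis rosette plant.

    Leaf of rank k sits at azimuth (k-1) x divergence angle (mod 360) and
    attaches at height (k-1) x internode rise; the blade is a triangulated
    ellipse tilted by its elevation angle, with an optional quadratic droop
    (``bend``) of the outer blade. Deterministic for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    lengths = params.per_leaf("blade_length_m")
    widths = params.per_leaf("blade_width_m")
    elevs = params.per_leaf("elevation_deg")

    leaves: list[LeafMesh] = []
    for k in range(1, params.n_leaves + 1):
        az = np.deg2rad(
            (k - 1) * params.divergence_angle_deg
            + rng.normal(0.0, params.azimuth_jitter_deg)
        )
        elev = np.deg2rad(
            np.clip(elevs[k - 1] + rng.normal(0.0, params.elevation_jitter_deg), 0.0, 90.0)
        )
        z0 = (k - 1) * params.internode_rise_m

        blade2d = _ellipse_blade(
            lengths[k - 1] / 2, widths[k - 1] / 2, params.n_rings, params.n_sectors
        )
        # local frame: midrib direction tilted up by elev, cross horizontal
        u_hat = np.array(
            [np.cos(elev) * np.cos(az), np.cos(elev) * np.sin(az), np.sin(elev)]
        )
        v_hat = np.array([-np.sin(az), np.cos(az), 0.0])
        n_hat = np.cross(u_hat, v_hat)
        origin = (
            np.array([np.cos(az), np.sin(az), 0.0]) * params.petiole_length_m
            + np.array([0.0, 0.0, z0])
            + u_hat * lengths[k - 1] / 2
        )
        u = blade2d[..., 0]
        v = blade2d[..., 1]
        # quadratic droop of the blade tip, as a fraction of half-length
        droop = params.bend * (np.maximum(u, 0.0) / (lengths[k - 1] / 2)) ** 2
        tri = (
            origin
            + u[..., None] * u_hat
            + v[..., None] * v_hat
            - (droop * lengths[k - 1] / 2)[..., None] * n_hat * np.sign(n_hat[2])
        )
        tri[..., 2] = np.maximum(tri[..., 2], 1e-4)  # stay above the bed
        leaves.append(LeafMesh(leaf_id=k, rank=k, triangles=tri))
    return PlantModel(plant_id, leaves)


def assign_position_classes(
    plant: PlantModel, counts: tuple[int, int, int] | Mapping[str, int]
) -> PlantModel:
    """Label leaves upper/middle/lower from youngest (highest rank) down.

    ``counts`` is (upper, middle, lower) and must sum to the leaf count.
    Returns the same plant with position_class set on each leaf.
    """
    if isinstance(counts, Mapping):
        counts = (counts["upper"], counts["middle"], counts["lower"])
    n_upper, n_middle, n_lower = counts
    if n_upper + n_middle + n_lower != len(plant.leaves):
        raise ValueError(
            f"class counts {counts} do not sum to leaf count {len(plant.leaves)}"
        )
    by_rank = sorted(plant.leaves, key=lambda l: -l.rank)  # youngest first
    for i, leaf in enumerate(by_rank):
        if i < n_upper:
            leaf.position_class = PositionClass.UPPER
        elif i < n_upper + n_middle:
            leaf.position_class = PositionClass.MIDDLE
        else:
            leaf.position_class = PositionClass.LOWER
    return plant


ASSAY_COLUMNS = [
    "plant_id",
    "leaf_id",
    "position_class",
    "treatment",
    "cumulative_absorbed_uv_kJ_m2",
    "tpc_mg_gae_g",
    "tfc_mg_ce_g",
    "rsa_pct",
]

_COMPOUND_COLUMNS = ["tpc_mg_gae_g", "tfc_mg_ce_g", "rsa_pct"]


def generate_assay_data(
    interception: pd.DataFrame,
    yield_models: Mapping[str, object],
    control_concentration: Mapping[str, float | Mapping[str, float]],
    noise_sd: float | Mapping[str, float] = 0.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Synthesize a per-leaf assay table from absorbed-UV values.

    ``interception`` needs columns plant_id, leaf_id, position_class,
    treatment and cumulative_absorbed_uv_kJ_m2; control rows carry 0
    absorbed UV. For each compound column named in ``yield_models`` the
    concentration is control x (1 + f(dUV)/100) + Gaussian noise, truncated
    at zero (and capped at 100 for the radical-scavenging percentage).
    ``control_concentration[col]`` is a scalar or a per-position-class map.
    Deterministic for a fixed seed.
    """

    def _noise_for(col: str) -> float:
        sd = noise_sd[col] if isinstance(noise_sd, Mapping) else noise_sd
        if sd < 0:
            raise ValueError("noise_sd must be non-negative")
        return float(sd)

    duv = interception["cumulative_absorbed_uv_kJ_m2"].to_numpy(dtype=float)
    if np.any(duv < 0):
        raise ValueError("cumulative absorbed UV must be non-negative")

    rng = np.random.default_rng(rng_seed)
    out = interception.copy()
    for col, model in yield_models.items():
        ctrl = control_concentration[col]
        if isinstance(ctrl, Mapping):
            base = out["position_class"].map(
                lambda c: ctrl[c.value if isinstance(c, PositionClass) else str(c)]
            ).to_numpy(dtype=float)
        else:
            base = np.full(len(out), float(ctrl))
        pct = np.where(duv > 0, model.percent_increase(np.where(duv > 0, duv, 1.0)), 0.0)
        conc = base * (1.0 + pct / 100.0)
        sd = _noise_for(col)
        if sd > 0:
            conc = conc + rng.normal(0.0, sd, size=len(out))
        conc = np.maximum(conc, 0.0)
        if col == "rsa_pct":
            conc = np.minimum(conc, 100.0)
        out[col] = conc
    missing = [c for c in ASSAY_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"assay table missing columns {missing}")
    return out[ASSAY_COLUMNS + [c for c in out.columns if c not in ASSAY_COLUMNS]]
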