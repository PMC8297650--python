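"""Bioactive-compound response statistics.

Implements the assay arithmetic (DPPH radical scavenging activity, Fv/Fm),
the "UV energy yield" linear regression of compound concentration on
cumulative absorbed UV (the slope is the yield, in concentration units per
kJ m^-2 — the UV analogue of radiation use efficiency), and the nonlinear
increase-rate model against absorbed UV.

The typeset increase-rate equation "a/dUV + b" admits three readings, all
provided:

* F1: rate = a / (dUV + b)        (decaying hyperbola)
* F2: rate = a dUV / (dUV + b)    (saturating rectangular hyperbola, default)
* F3: rate = a / dUV + b          (literal reading; undefined at dUV = 0)

F2 is the default because a rectangular hyperbola through the origin is the
conventional saturating dose-response and matches monotone dose-dependent
increases; the form used is always recorded in the fit result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

__all__ = [
    "AssayAbsorbance",
    "FluorescenceRecord",
    "YieldFit",
    "Eq2Fit",
    "LinearYield",
    "HyperbolicYield",
    "rsa",
    "fv_fm",
    "fv_fm_is_normal",
    "increase_rate",
    "fit_linear_yield",
    "fit_hyperbolic",
    "yield_report",
    "HYPERBOLIC_FORMS",
]


@dataclass(frozen=True)
class AssayAbsorbance:
    """Absorbances at 517 nm without (control) and with leaf extract."""

    a_control: float
    a_sample: float

    def __post_init__(self) -> None:
        if self.a_control <= 0:
            raise ValueError("control absorbance must be positive")
        if self.a_sample < 0:
            raise ValueError("sample absorbance must be non-negative")


@dataclass(frozen=True)
class FluorescenceRecord:
    """Dark-adapted minimal (F0) and maximal (Fm) chlorophyll fluorescence."""

    f0: float
    fm: float

    def __post_init__(self) -> None:
        if self.fm <= 0:
            raise ValueError("Fm must be positive")
        if not 0 <= self.f0 <= self.fm:
            raise ValueError("need 0 <= F0 <= Fm")


def rsa(x: AssayAbsorbance) -> float:
    """DPPH radical scavenging activity, %: (Ac - As) / Ac x 100."""
    return (x.a_control - x.a_sample) / x.a_control * 100.0


def fv_fm(x: FluorescenceRecord) -> float:
    """Maximal photochemical efficiency of PSII: (Fm - F0) / Fm."""
    return (x.fm - x.f0) / x.fm


def fv_fm_is_normal(value: float, lo: float = 0.78, hi: float = 0.85) -> bool:
    """Whether an Fv/Fm value falls in the unstressed range for healthy leaves.

    Values near 0.82-0.83 indicate no photoinhibition; the default band is a
    conventional healthy range for dark-adapted leaves.
    """
    return lo <= value <= hi


def increase_rate(conc_treated: float, conc_control: float) -> float:
    """Percent change of a treated concentration relative to its control."""
    if conc_control <= 0:
        raise ValueError("control concentration must be positive")
    return (conc_treated - conc_control) / conc_control * 100.0


# ---------------------------------------------------------------------------
# response curves (also used by the synthetic assay generator)


@dataclass(frozen=True)
class LinearYield:
    """Percent increase linear in absorbed UV: f(dUV) = slope_pct * dUV."""

    slope_pct_per_kJ: float

    def percent_increase(self, duv) -> np.ndarray:
        return self.slope_pct_per_kJ * np.asarray(duv, dtype=float)


def _f1(duv, a, b):
    return a / (duv + b)


def _f2(duv, a, b):
    return a * duv / (duv + b)


def _f3(duv, a, b):
    return a / duv + b


HYPERBOLIC_FORMS = {"F1": _f1, "F2": _f2, "F3": _f3}


@dataclass(frozen=True)
class HyperbolicYield:
    """Percent increase following one of the hyperbolic forms above."""

    a: float
    b: float
    form: str = "F2"

    def percent_increase(self, duv) -> np.ndarray:
        return HYPERBOLIC_FORMS[self.form](np.asarray(duv, dtype=float), self.a, self.b)


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class YieldFit:
    """OLS fit of concentration on cumulative absorbed UV.

    ``slope`` is the cumulative UV energy yield (concentration units per
    kJ m^-2 absorbed).
    """

    slope: float
    intercept: float
    slope_se: float
    r2: float
    n: int
    position_class: str = ""
    stage: str = ""
    compound: str = ""


@dataclass(frozen=True)
class Eq2Fit:
    a: float
    b: float
    form: str
    r2: float
    n: int
    converged: bool
    position_class: str = ""
    stage: str = ""
    compound: str = ""


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 0.0 if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def fit_linear_yield(
    duv: Sequence[float],
    conc: Sequence[float],
    position_class: str = "",
    stage: str = "",
    compound: str = "",
) -> YieldFit:
    """Ordinary least squares of concentration against absorbed UV."""
    x = np.asarray(duv, dtype=float)
    y = np.asarray(conc, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a yield regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all dUV values equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    yhat = model.predict(sm.add_constant(x))
    r2 = _r_squared(y, yhat)
    if np.ptp(y) == 0:  # constant response: define R^2 = 0, slope exactly 0
        r2 = 0.0
    return YieldFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        r2=r2,
        n=int(x.size),
        position_class=position_class,
        stage=stage,
        compound=compound,
    )


def fit_hyperbolic(
    duv: Sequence[float],
    rate_pct: Sequence[float],
    form: str = "F2",
    position_class: str = "",
    stage: str = "",
    compound: str = "",
    n_starts: int = 5,
    seed: int = 0,
) -> Eq2Fit:
    """Nonlinear least squares of increase rate (%) on absorbed UV.

    Multi-start Levenberg-Marquardt-style fitting over (a, b); starts are
    spread over data-scaled magnitudes. Ties between converged starts break
    on lowest residual sum of squares, then lowest |b|. Non-convergence is
    reported in the result, never silently ignored.
    """
    if form not in HYPERBOLIC_FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {list(HYPERBOLIC_FORMS)}")
    x = np.asarray(duv, dtype=float)
    y = np.asarray(rate_pct, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if form in ("F1", "F3") and np.any(x <= 0):
        raise ValueError(f"form {form} requires strictly positive dUV")
    fn = HYPERBOLIC_FORMS[form]

    xscale = float(np.median(x[x > 0])) if np.any(x > 0) else 1.0
    yscale = float(np.max(np.abs(y))) or 1.0
    rng = np.random.default_rng(seed)
    starts = [(yscale, xscale)]
    for _ in range(n_starts - 1):
        starts.append(
            (yscale * rng.uniform(0.2, 5.0), xscale * rng.uniform(0.2, 5.0))
        )

    best = None
    for a0, b0 in starts:
        try:
            res = least_squares(
                lambda p: fn(x, p[0], p[1]) - y,
                x0=np.array([a0, b0]),
                method="lm",
                max_nfev=2000,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(res.fun)):
            continue
        ssr = float(np.sum(res.fun**2))
        key = (not res.success, ssr, abs(float(res.x[1])))
        if best is None or key < best[0]:
            best = (key, res, ssr)
    if best is None:
        raise RuntimeError("hyperbolic fit failed from every start")
    _, res, ssr = best
    yhat = fn(x, *res.x)
    return Eq2Fit(
        a=float(res.x[0]),
        b=float(res.x[1]),
        form=form,
        r2=_r_squared(y, yhat),
        n=int(x.size),
        converged=bool(res.success),
        position_class=position_class,
        stage=stage,
        compound=compound,
    )


def fit_yields_by_group(
    table: pd.DataFrame,
    compound_columns: Sequence[str] = ("tfc_mg_ce_g", "tpc_mg_gae_g"),
    duv_column: str = "cumulative_absorbed_uv_kJ_m2",
    stage: str = "",
    form: str = "F2",
    include_controls: bool = True,
) -> tuple[list[YieldFit], list[Eq2Fit]]:
    """Per-position-class linear and nonlinear fits for each compound.

    Linear fits regress raw concentration on dUV (controls pooled in by
    default). Nonlinear fits regress the percent increase over the
    class-matched control mean, using treated rows only.
    """
    linear: list[YieldFit] = []
    nonlinear: list[Eq2Fit] = []
    for pos, grp in table.groupby("position_class", sort=False, observed=True):
        pos = pos.value if hasattr(pos, "value") else str(pos)
        duv = grp[duv_column].to_numpy(dtype=float)
        is_ctrl = duv == 0
        for col in compound_columns:
            y = grp[col].to_numpy(dtype=float)
            sel = slice(None) if include_controls else ~is_ctrl
            linear.append(
                fit_linear_yield(
                    duv[sel], y[sel], position_class=pos, stage=stage, compound=col
                )
            )
            if is_ctrl.any() and (~is_ctrl).any():
                ctrl_mean = float(y[is_ctrl].mean())
                rates = (y[~is_ctrl] - ctrl_mean) / ctrl_mean * 100.0
                nonlinear.append(
                    fit_hyperbolic(
                        duv[~is_ctrl], rates, form=form,
                        position_class=pos, stage=stage, compound=col,
                    )
                )
    return linear, nonlinear


def yield_report(
    linear_fits: Sequence[YieldFit],
    nonlinear_fits: Sequence[Eq2Fit] = (),
    compound_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """R^2 summary by growth stage and leaf position.

    One row per (stage, position); columns pair each compound with the
    regression kind ("Linear regression" / "Nonlinear regression").
    """
    if not linear_fits and not nonlinear_fits:
        raise ValueError("no fits to report")
    labels = compound_labels or {"tfc_mg_ce_g": "TFC", "tpc_mg_gae_g": "TPC"}

    rows: dict[tuple[str, str], dict[str, float]] = {}
    for fit, kind in [(f, "Linear regression") for f in linear_fits] + [
        (f, "Nonlinear regression") for f in nonlinear_fits
    ]:
        key = (fit.stage, fit.position_class)
        name = labels.get(fit.compound, fit.compound)
        rows.setdefault(key, {})[f"{kind} {name} R2"] = round(fit.r2, 4)
    order = {"upper": 0, "middle": 1, "lower": 2}
    records = [
        {"Growth stage": stage, "Leaf position": pos, **vals}
        for (stage, pos), vals in sorted(
            rows.items(), key=lambda kv: (kv[0][0], order.get(kv[0][1], 9))
        )
    ]
    return pd.DataFrame.from_records(records)
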