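"""Monte Carlo forward ray tracing of LED light through the canopy.

Rays start on the emitting faces with cosine-weighted (Lambertian)
directions and random-walk through the scene: at every surface hit one
outcome — absorb, diffuse-reflect, diffuse-transmit — is sampled with the
surface's (alpha, rho, tau). Every ray carries the same power
P_total / n_rays, so emitted power equals absorbed plus escaped power
exactly, by construction of the estimator. Tallies are binomial counts;
the reported Monte Carlo standard error is the binomial one and shrinks as
1/sqrt(n_rays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import build_bvh, trace_rays
from .scene import Scene, TraceGeometry

__all__ = [
    "TraceConfig",
    "InterceptionResult",
    "trace",
    "analytic_plate_irradiance",
    "check_conservation",
]


@dataclass(frozen=True)
class TraceConfig:
    """Engine parameters for one band's trace.

    One interaction outcome is sampled per hit (an absorbed ray terminates,
    which plays the role of Russian roulette), so ``max_bounces`` is the
    only termination control; rays exceeding it count as escaped.
    """

    n_rays: int = 200_000
    max_bounces: int = 10
    rng_seed: int = 0
    band: str = "UV"

    def __post_init__(self) -> None:
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if self.max_bounces < 0:
            raise ValueError("max_bounces must be >= 0")


@dataclass
class InterceptionResult:
    """Per-surface absorbed power from one trace.

    ``surfaces`` carries one row per detector (bed and every leaf) with
    absorbed_W, its binomial standard error, and for leaves the absorbed
    flux density flux_W_m2 = absorbed_W / one-sided area.
    """

    band: str
    n_rays: int
    rng_seed: int
    emitted_W: float
    escaped_W: float
    surfaces: pd.DataFrame

    @property
    def absorbed_total_W(self) -> float:
        return float(self.surfaces["absorbed_W"].sum())

    @property
    def balance_residual_W(self) -> float:
        return self.emitted_W - self.absorbed_total_W - self.escaped_W

    def leaves(self) -> pd.DataFrame:
        return self.surfaces[self.surfaces["kind"] == "leaf"].reset_index(drop=True)

    def to_csv(self, path) -> None:
        cols = [
            "kind", "plant_id", "leaf_id", "position_class", "band",
            "absorbed_W", "area_m2", "flux_W_m2", "mc_se_W",
        ]
        out = self.surfaces.copy()
        out["band"] = self.band
        out[cols].to_csv(path, index=False)


def trace(scene: Scene | TraceGeometry, config: TraceConfig) -> InterceptionResult:
    """Run the Monte Carlo transport for one band.

    Accepts a Scene (flattened internally for ``config.band``) or an
    already flattened TraceGeometry. Bit-reproducible for a fixed seed.
    """
    geom = scene.flatten(config.band) if isinstance(scene, Scene) else scene
    tri = np.ascontiguousarray(geom.triangles, dtype=np.float64)
    if len(tri) == 0:
        raise ValueError("scene has no geometry")
    v0 = tri[:, 0].copy()
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    nrm = np.cross(e1, e2)
    norms = np.linalg.norm(nrm, axis=1)
    if np.any(norms <= 0):
        raise ValueError("degenerate triangle in scene")
    nrm /= norms[:, None]

    surf = geom.surfaces
    alpha = surf["alpha"].to_numpy(dtype=np.float64)
    rho = surf["rho"].to_numpy(dtype=np.float64)

    powers = np.array(
        [s.power_W.get(config.band, 0.0) for s in geom.sources], dtype=np.float64
    )
    total = float(powers.sum())
    if total <= 0:
        raise ValueError(f"no source power in band {config.band!r}")
    src_cum = np.cumsum(powers) / total
    src_center = np.array([s.center for s in geom.sources], dtype=np.float64)
    src_size = np.array([s.size for s in geom.sources], dtype=np.float64)

    bvh = build_bvh(tri)
    counts, escaped = trace_rays(
        v0, np.ascontiguousarray(e1), np.ascontiguousarray(e2),
        np.ascontiguousarray(nrm), geom.tri_surface.astype(np.int64),
        *bvh, alpha, rho, src_cum, src_center, src_size,
        config.n_rays, config.max_bounces, config.rng_seed,
    )

    p = counts / config.n_rays
    out = surf.copy()
    out["absorbed_W"] = total * p
    out["mc_se_W"] = total * np.sqrt(p * (1.0 - p) / config.n_rays)
    out["flux_W_m2"] = out["absorbed_W"] / out["area_m2"]
    return InterceptionResult(
        band=config.band,
        n_rays=config.n_rays,
        rng_seed=config.rng_seed,
        emitted_W=total,
        escaped_W=total * escaped / config.n_rays,
        surfaces=out,
    )


def analytic_plate_irradiance(
    source_center: tuple[float, float, float],
    source_size: tuple[float, float],
    source_power_W: float,
    receiver_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    receiver_size: tuple[float, float] | None = None,
    n_quad: int = 64,
) -> float:
    """Irradiance from a downward-facing Lambertian rectangle, W m^-2.

    Deterministic Gauss-Legendre integration of L cos(t1) cos(t2) / d^2 over
    the source (and over the receiver, when ``receiver_size`` requests a
    plate average rather than a point value). Source and receiver must be
    horizontal and parallel — the configuration the tracer oracle needs.
    Radiance L = P / (pi A) for a diffuse emitter of power P and area A.
    """
    sx, sy = source_size
    h = source_center[2] - receiver_center[2]
    if h <= 0:
        raise ValueError("source must lie above the receiver")
    area_src = sx * sy
    radiance = source_power_W / (np.pi * area_src)

    xg, wg = np.polynomial.legendre.leggauss(n_quad)

    def point_irradiance(px: np.ndarray, py: np.ndarray) -> np.ndarray:
        # integrate over the source for receiver points (px, py)
        ux = source_center[0] + xg * sx / 2
        uy = source_center[1] + xg * sy / 2
        wx = wg * sx / 2
        wy = wg * sy / 2
        X = ux[:, None, None] - px[None, None, :]
        Y = uy[None, :, None] - py[None, None, :]
        d2 = X**2 + Y**2 + h**2
        # cos(t1) = cos(t2) = h / d for parallel horizontal faces
        integrand = h**2 / d2**2
        w2 = wx[:, None] * wy[None, :]
        return radiance * np.einsum("ij,ijk->k", w2, integrand)

    if receiver_size is None:
        return float(point_irradiance(
            np.array([receiver_center[0]]), np.array([receiver_center[1]])
        )[0])

    rx, ry = receiver_size
    px = receiver_center[0] + xg * rx / 2
    py = receiver_center[1] + xg * ry / 2
    wx = wg / 2  # normalised: average, not integral
    wy = wg / 2
    P = np.stack(np.meshgrid(px, py, indexing="ij"), axis=-1).reshape(-1, 2)
    vals = point_irradiance(P[:, 0], P[:, 1]).reshape(n_quad, n_quad)
    return float(wx @ vals @ wy)


def check_conservation(result: InterceptionResult) -> dict:
    """Energy-balance report for a trace: residual and any negative tally."""
    negatives = int((result.surfaces["absorbed_W"] < 0).sum())
    report = {
        "emitted_W": result.emitted_W,
        "absorbed_total_W": result.absorbed_total_W,
        "escaped_W": result.escaped_W,
        "balance_residual_W": result.balance_residual_W,
        "n_negative_tallies": negatives,
        "ok": negatives == 0
        and abs(result.balance_residual_W) <= 1e-12 * max(result.emitted_W, 1.0),
    }
    return report
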