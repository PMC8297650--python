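"""Virtual plant-factory scenes: growth bed, LED bars, placed plants.

Coordinates are metres, z-up, with the bed top surface at z = 0 and the bed
rectangle centred on the origin. LED bars hang above the bed as rectangular
Lambertian emitters facing down. Optical properties are band-level
(reflectance / transmittance / absorptance summing to 1), one set per
surface class and band.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh

from .synthetic import LeafMesh, PlantModel, PositionClass

log = logging.getLogger(__name__)

__all__ = [
    "OpticalProperties",
    "LightSource",
    "Scene",
    "TraceGeometry",
    "build_scene",
    "grid_layout",
    "default_bar_sources",
    "DEFAULT_LEAF_OPTICS",
    "DEFAULT_BED_OPTICS",
    "save_plant",
    "load_mesh",
    "save_scene",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Diffuse band-level surface optics: rho + tau + alpha = 1."""

    reflectance: float
    transmittance: float
    absorptance: float

    def __post_init__(self) -> None:
        for name in ("reflectance", "transmittance", "absorptance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.reflectance + self.transmittance + self.absorptance - 1.0) > 1e-9:
            raise ValueError("rho + tau + alpha must equal 1")

    @classmethod
    def from_rho_tau(cls, rho: float, tau: float) -> "OpticalProperties":
        return cls(rho, tau, 1.0 - rho - tau)


#: Default leaf optics per band. The measured per-position values belong to
#: an unavailable supplement, so these are typical green-leaf values: modest
#: PAR reflectance/transmittance, and strong UV absorption by the epidermis.
DEFAULT_LEAF_OPTICS: dict[str, OpticalProperties] = {
    "PAR": OpticalProperties.from_rho_tau(0.10, 0.07),
    "UV": OpticalProperties.from_rho_tau(0.05, 0.01),
}

#: Default bed optics: white module material, diffuse, opaque.
DEFAULT_BED_OPTICS: dict[str, OpticalProperties] = {
    "PAR": OpticalProperties.from_rho_tau(0.50, 0.0),
    "UV": OpticalProperties.from_rho_tau(0.50, 0.0),
}


@dataclass(frozen=True)
class LightSource:
    """Rectangular Lambertian emitter facing straight down.

    ``center`` is the face centre (m); ``size`` the (x, y) extent; power is
    per band, in W, emitted diffusely (cosine-weighted) from the face.
    """

    center: tuple[float, float, float]
    size: tuple[float, float]
    power_W: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.power_W.values()):
            raise ValueError("source power must be non-negative")
        if self.size[0] <= 0 or self.size[1] <= 0:
            raise ValueError("source size must be positive")
        if self.center[2] <= 0:
            raise ValueError("source must sit above the bed (z > 0)")


@dataclass
class Scene:
    bed_size: tuple[float, float]
    plants: list[PlantModel]
    sources: list[LightSource]
    leaf_optics: Mapping[str, Mapping[str, OpticalProperties]] = field(
        default_factory=lambda: {
            c.value: dict(DEFAULT_LEAF_OPTICS) for c in PositionClass
        }
    )
    bed_optics: Mapping[str, OpticalProperties] = field(
        default_factory=lambda: dict(DEFAULT_BED_OPTICS)
    )

    @property
    def bed_area(self) -> float:
        return self.bed_size[0] * self.bed_size[1]

    def total_power(self, band: str) -> float:
        return sum(s.power_W.get(band, 0.0) for s in self.sources)

    def flatten(self, band: str) -> "TraceGeometry":
        """Triangle soup plus per-surface optics for one band's trace."""
        tris: list[np.ndarray] = []
        tri_surface: list[np.ndarray] = []
        surfaces: list[dict] = []

        w, l = self.bed_size
        bed = np.array(
            [
                [[-w / 2, -l / 2, 0.0], [w / 2, -l / 2, 0.0], [w / 2, l / 2, 0.0]],
                [[-w / 2, -l / 2, 0.0], [w / 2, l / 2, 0.0], [-w / 2, l / 2, 0.0]],
            ]
        )
        bo = self.bed_optics[band]
        surfaces.append(
            {
                "kind": "bed",
                "plant_id": -1,
                "leaf_id": -1,
                "position_class": "",
                "area_m2": w * l,
                "rho": bo.reflectance,
                "tau": bo.transmittance,
                "alpha": bo.absorptance,
            }
        )
        tris.append(bed)
        tri_surface.append(np.zeros(len(bed), dtype=np.int64))

        for plant in self.plants:
            for leaf in plant.leaves:
                if leaf.position_class is None:
                    raise ValueError(
                        f"leaf {leaf.leaf_id} of plant {plant.plant_id} has no "
                        "position class; run assign_position_classes first"
                    )
                opt = self.leaf_optics[leaf.position_class.value][band]
                sid = len(surfaces)
                surfaces.append(
                    {
                        "kind": "leaf",
                        "plant_id": plant.plant_id,
                        "leaf_id": leaf.leaf_id,
                        "position_class": leaf.position_class.value,
                        "area_m2": leaf.one_sided_area,
                        "rho": opt.reflectance,
                        "tau": opt.transmittance,
                        "alpha": opt.absorptance,
                    }
                )
                tris.append(leaf.triangles)
                tri_surface.append(np.full(len(leaf.triangles), sid, dtype=np.int64))

        return TraceGeometry(
            triangles=np.concatenate(tris, axis=0),
            tri_surface=np.concatenate(tri_surface),
            surfaces=pd.DataFrame(surfaces),
            sources=list(self.sources),
            band=band,
        )


@dataclass
class TraceGeometry:
    """Flattened, band-resolved scene ready for the Monte Carlo tracer."""

    triangles: np.ndarray  # (n, 3, 3)
    tri_surface: np.ndarray  # (n,)
    surfaces: pd.DataFrame
    sources: list[LightSource]
    band: str


def grid_layout(n_plants: int, bed_size: tuple[float, float]) -> list[tuple[float, float]]:
    """Evenly spaced grid of n placements centred on the bed.

    Chooses the most nearly square grid whose cell aspect follows the bed.
    """
    w, l = bed_size
    best = None
    for nx in range(1, n_plants + 1):
        ny = int(np.ceil(n_plants / nx))
        waste = nx * ny - n_plants
        aspect = abs((w / nx) / (l / ny) - 1.0)
        key = (waste, aspect)
        if best is None or key < best[0]:
            best = (key, (nx, ny))
    nx, ny = best[1]
    xs = (np.arange(nx) + 0.5) / nx * w - w / 2
    ys = (np.arange(ny) + 0.5) / ny * l - l / 2
    spots = [(float(x), float(y)) for y in ys for x in xs]
    return spots[:n_plants]


def default_bar_sources(
    bed_size: tuple[float, float],
    height: float = 0.45,
    n_bars: int = 4,
    bar_width: float = 0.04,
    irradiance_W_m2: Mapping[str, float] | None = None,
    power_W: Mapping[str, float] | None = None,
) -> list[LightSource]:
    """Parallel LED bars spanning the bed length, evenly spaced across width.

    Power is either given directly (split equally across bars) or derived
    from a target irradiance as irradiance x bed area.
    """
    if (irradiance_W_m2 is None) == (power_W is None):
        raise ValueError("specify exactly one of irradiance_W_m2 or power_W")
    w, l = bed_size
    if power_W is None:
        power_W = {b: e * w * l for b, e in irradiance_W_m2.items()}
    per_bar = {b: p / n_bars for b, p in power_W.items()}
    xs = (np.arange(n_bars) + 0.5) / n_bars * w - w / 2
    return [
        LightSource(center=(float(x), 0.0, height), size=(bar_width, l), power_W=per_bar)
        for x in xs
    ]


def build_scene(
    plants: Sequence[PlantModel],
    placements: Sequence[tuple[float, float]] | None,
    bed_size: tuple[float, float],
    sources: Sequence[LightSource],
    leaf_optics: Mapping[str, Mapping[str, OpticalProperties]] | None = None,
    bed_optics: Mapping[str, OpticalProperties] | None = None,
    overlap_tolerance: float = 0.0,
) -> Scene:
    """Place plants on the bed and assemble a ray-traceable scene.

    ``placements`` gives one (x, y) bed-plane position per plant (None
    defaults to a grid). Placements must be unique and on the bed; pairs
    closer than ``overlap_tolerance`` are rejected.
    """
    plants = list(plants)
    if placements is None:
        placements = grid_layout(len(plants), bed_size)
    if len(placements) != len(plants):
        raise ValueError("one placement per plant required")
    w, l = bed_size
    pts = np.asarray(placements, dtype=float)
    if len(pts):
        if np.any(np.abs(pts[:, 0]) > w / 2) or np.any(np.abs(pts[:, 1]) > l / 2):
            raise ValueError("placement outside bed bounds")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("two plants share a placement")
        if overlap_tolerance > 0 and len(pts) > 1:
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < overlap_tolerance:
                raise ValueError("plant placements closer than overlap tolerance")
    placed = [
        p.translated(x, y, plant_id=i) for i, (p, (x, y)) in enumerate(zip(plants, pts))
    ]
    kwargs = {}
    if leaf_optics is not None:
        kwargs["leaf_optics"] = leaf_optics
    if bed_optics is not None:
        kwargs["bed_optics"] = bed_optics
    return Scene(bed_size=tuple(bed_size), plants=placed, sources=list(sources), **kwargs)


# ---------------------------------------------------------------------------
# mesh I/O

_SIDECAR_COLUMNS = ["leaf_id", "rank", "position_class", "area_m2", "face_start", "face_end"]


def _sidecar_path(mesh_path: Path) -> Path:
    return mesh_path.with_suffix(mesh_path.suffix + ".leaves.csv")


def save_plant(plant: PlantModel, path: str | Path) -> Path:
    """Write a plant as OBJ (named group per leaf) or PLY (single mesh).

    A sidecar CSV `<mesh>.leaves.csv` always carries leaf_id, rank,
    position class, area and the face range of each leaf (faces are written
    in leaf order, which is what makes PLY — a format without named groups —
    round-trippable). Returns the sidecar path.
    """
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unknown mesh format {fmt!r}; expected obj or ply")

    rows = []
    face_start = 0
    meshes: dict[str, trimesh.Trimesh] = {}
    leaves = sorted(plant.leaves, key=lambda l: l.leaf_id)
    for leaf in leaves:
        tri = leaf.triangles
        verts = tri.reshape(-1, 3)
        faces = np.arange(len(verts)).reshape(-1, 3)
        meshes[f"leaf_{leaf.leaf_id}"] = trimesh.Trimesh(
            vertices=verts, faces=faces, process=False
        )
        rows.append(
            {
                "leaf_id": leaf.leaf_id,
                "rank": leaf.rank,
                "position_class": leaf.position_class.value if leaf.position_class else "",
                "area_m2": leaf.one_sided_area,
                "face_start": face_start,
                "face_end": face_start + len(tri),
            }
        )
        face_start += len(tri)

    if fmt == "obj":
        scene = trimesh.Scene(meshes)
        path.write_text(trimesh.exchange.obj.export_obj(scene))
    else:
        combined = trimesh.util.concatenate(list(meshes.values()))
        combined.export(path, encoding="ascii")

    sidecar = _sidecar_path(path)
    pd.DataFrame(rows, columns=_SIDECAR_COLUMNS).to_csv(sidecar, index=False)
    return sidecar


def load_mesh(path: str | Path, plant_id: int = 0) -> PlantModel:
    """Load a plant mesh written by :func:`save_plant`.

    OBJ leaves are recovered from named groups; PLY leaves from the sidecar
    face ranges. The sidecar CSV must sit next to the mesh.
    """
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"leaf metadata sidecar {sidecar.name} not found next to {path.name}"
        )
    meta = pd.read_csv(sidecar)

    leaves: list[LeafMesh] = []
    if fmt == "obj":
        loaded = trimesh.load(
            path, process=False, split_objects=True, group_material=False,
            maintain_order=True,
        )
        if not isinstance(loaded, trimesh.Scene) or not any(
            name.startswith("leaf_") for name in loaded.geometry
        ):
            raise ValueError("leaf segmentation missing: OBJ has no leaf_* groups")
        geoms = {name: g for name, g in loaded.geometry.items()}
        for row in meta.itertuples():
            g = geoms[f"leaf_{row.leaf_id}"]
            tri = np.asarray(g.vertices, dtype=float)[np.asarray(g.faces)]
            leaves.append(_make_leaf(row, tri))
    elif fmt == "ply":
        mesh = trimesh.load(path, process=False, maintain_order=True)
        tri_all = np.asarray(mesh.vertices, dtype=float)[np.asarray(mesh.faces)]
        for row in meta.itertuples():
            leaves.append(_make_leaf(row, tri_all[row.face_start : row.face_end]))
    else:
        raise ValueError(f"unknown mesh format {fmt!r}; expected obj or ply")
    return PlantModel(plant_id, leaves)


def _make_leaf(row, tri: np.ndarray) -> LeafMesh:
    cls = PositionClass(row.position_class) if row.position_class else None
    leaf = LeafMesh(leaf_id=int(row.leaf_id), rank=int(row.rank), triangles=tri,
                    position_class=cls)
    if abs(leaf.one_sided_area - row.area_m2) > 1e-6 * max(row.area_m2, 1e-12):
        warnings.warn(
            f"leaf {row.leaf_id}: mesh area {leaf.one_sided_area:.3e} differs "
            f"from sidecar {row.area_m2:.3e}",
            stacklevel=3,
        )
    return leaf


def save_scene(scene: Scene, path: str | Path, mesh_dir: str | Path | None = None) -> None:
    """Serialize a scene to JSON (plants as mesh files in ``mesh_dir``)."""
    path = Path(path)
    mesh_dir = Path(mesh_dir) if mesh_dir else path.parent
    mesh_dir.mkdir(parents=True, exist_ok=True)
    plant_files = []
    for plant in scene.plants:
        mesh_path = mesh_dir / f"plant_{plant.plant_id}.obj"
        save_plant(plant, mesh_path)
        plant_files.append(str(mesh_path))
    doc = {
        "bed_size": list(scene.bed_size),
        "plants": plant_files,
        "sources": [
            {"center": list(s.center), "size": list(s.size), "power_W": dict(s.power_W)}
            for s in scene.sources
        ],
        "leaf_optics": {
            cls: {b: [o.reflectance, o.transmittance, o.absorptance] for b, o in bands.items()}
            for cls, bands in scene.leaf_optics.items()
        },
        "bed_optics": {
            b: [o.reflectance, o.transmittance, o.absorptance]
            for b, o in scene.bed_optics.items()
        },
    }
    path.write_text(json.dumps(doc, indent=2))


def load_scene(path: str | Path) -> Scene:
    doc = json.loads(Path(path).read_text())
    plants = [load_mesh(p, plant_id=i) for i, p in enumerate(doc["plants"])]
    sources = [
        LightSource(tuple(s["center"]), tuple(s["size"]), s["power_W"])
        for s in doc["sources"]
    ]
    leaf_optics = {
        cls: {b: OpticalProperties(*vals) for b, vals in bands.items()}
        for cls, bands in doc["leaf_optics"].items()
    }
    bed_optics = {b: OpticalProperties(*vals) for b, vals in doc["bed_optics"].items()}
    return Scene(
        bed_size=tuple(doc["bed_size"]),
        plants=plants,
        sources=sources,
        leaf_optics=leaf_optics,
        bed_optics=bed_optics,
    )
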