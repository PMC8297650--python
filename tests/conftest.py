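import numpy as np
import pytest

import uvcanopy as uc
from uvcanopy.scene import LightSource, OpticalProperties, Scene
from uvcanopy.synthetic import LeafMesh, PlantModel, PositionClass

ABSORB = OpticalProperties(0.0, 0.0, 1.0)


def horizontal_plate(z, half=0.05, center=(0.0, 0.0), leaf_id=1, rank=None):
    """Square horizontal leaf (two triangles) at height z."""
    cx, cy = center
    v = np.array(
        [
            [cx - half, cy - half, z],
            [cx + half, cy - half, z],
            [cx + half, cy + half, z],
            [cx - half, cy + half, z],
        ]
    )
    tri = np.array([[v[0], v[1], v[2]], [v[0], v[2], v[3]]])
    return LeafMesh(
        leaf_id=leaf_id,
        rank=rank if rank is not None else leaf_id,
        triangles=tri,
        position_class=PositionClass.UPPER,
    )


def plate_scene(
    leaves,
    source_power=1.0,
    source_center=(0.0, 0.0, 0.5),
    source_size=(0.02, 0.02),
    leaf_optics=ABSORB,
    bed_optics=ABSORB,
    bed_size=(2.0, 2.0),
    band="UV",
):
    """Scene with explicit leaf plates under a single emitter."""
    if leaves:
        ranks = {l.leaf_id: i + 1 for i, l in enumerate(sorted(leaves, key=lambda x: x.leaf_id))}
        leaves = [
            LeafMesh(l.leaf_id, ranks[l.leaf_id], l.triangles, l.position_class)
            for l in leaves
        ]
        plants = [PlantModel(0, leaves)]
    else:
        plants = []
    optics = {c.value: {band: leaf_optics} for c in PositionClass}
    return Scene(
        bed_size=bed_size,
        plants=plants,
        sources=[LightSource(source_center, source_size, {band: source_power})],
        leaf_optics=optics,
        bed_optics={band: bed_optics},
    )


def build_canopy(preset, n_plants, seed, bed=(0.8, 0.5), uv_irradiance=1.0):
    rng = np.random.default_rng(seed)
    plants = []
    for i in range(n_plants):
        params = uc.preset_params(preset, rng_seed=int(rng.integers(2**31)))
        plant = uc.generate_rosette(params, plant_id=i)
        plants.append(uc.assign_position_classes(plant, uc.PRESET_CLASS_COUNTS[preset]))
    sources = uc.default_bar_sources(bed, irradiance_W_m2={"UV": uv_irradiance})
    return uc.build_scene(plants, None, bed, sources)


@pytest.fixture(scope="session")
def plant_14dat():
    plant = uc.generate_rosette(uc.preset_params("14DAT", rng_seed=11))
    return uc.assign_position_classes(plant, (3, 2, 2))
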