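import numpy as np
import pandas as pd
import pytest

import uvcanopy as uc
from uvcanopy.response import HyperbolicYield, LinearYield, fit_hyperbolic, fit_linear_yield
from uvcanopy.synthetic import (
    PRESET_CLASS_COUNTS,
    PositionClass,
    RosetteParams,
    assign_position_classes,
    generate_assay_data,
    generate_rosette,
    preset_params,
)


def leaf_azimuth_deg(plant, rank):
    leaf = plant.leaf_by_rank(rank)
    c = leaf.triangles.mean(axis=(0, 1))
    return np.degrees(np.arctan2(c[1], c[0])) % 360.0


class TestGenerateRosette:
    def test_spiral_phyllotaxis_azimuths(self):
        params = RosetteParams(n_leaves=7)  # no jitter by default
        plant = generate_rosette(params)
        expected = [(k - 1) * 137.5 % 360 for k in range(1, 8)]
        got = [leaf_azimuth_deg(plant, k) for k in range(1, 8)]
        delta = (np.asarray(got) - np.asarray(expected) + 180.0) % 360.0 - 180.0
        np.testing.assert_allclose(delta, 0.0, atol=1e-6)

    def test_leaf_areas_sum_to_total(self):
        plant = generate_rosette(preset_params("28DAT", rng_seed=4))
        assert plant.total_leaf_area == pytest.approx(
            sum(l.one_sided_area for l in plant.leaves), rel=1e-9
        )

    def test_one_sided_area_matches_triangle_sum(self):
        plant = generate_rosette(RosetteParams(n_leaves=3))
        for leaf in plant.leaves:
            a = leaf.triangles[:, 1] - leaf.triangles[:, 0]
            b = leaf.triangles[:, 2] - leaf.triangles[:, 0]
            areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
            assert leaf.one_sided_area == pytest.approx(areas.sum(), rel=1e-9)
            assert np.all(areas > 0)

    def test_attachment_heights_increase_with_rank(self):
        plant = generate_rosette(RosetteParams(n_leaves=5, internode_rise_m=0.02))
        mins = [plant.leaf_by_rank(k).triangles[:, :, 2].min() for k in range(1, 6)]
        assert np.all(np.diff(mins) > 0)

    def test_bit_reproducible_for_fixed_seed(self):
        params = preset_params("14DAT", rng_seed=9)
        a = generate_rosette(params)
        b = generate_rosette(params)
        for la, lb in zip(a.leaves, b.leaves):
            np.testing.assert_array_equal(la.triangles, lb.triangles)

    def test_seed_changes_geometry_when_jittered(self):
        a = generate_rosette(preset_params("14DAT", rng_seed=1))
        b = generate_rosette(preset_params("14DAT", rng_seed=2))
        assert not np.array_equal(a.leaves[0].triangles, b.leaves[0].triangles)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_leaves=0),
            dict(n_leaves=3, blade_length_m=-0.1),
            dict(n_leaves=3, blade_width_m=0.0),
            dict(n_leaves=3, elevation_deg=120.0),
        ],
    )
    def test_rejects_invalid_params(self, bad):
        with pytest.raises(ValueError):
            RosetteParams(**bad)


class TestPositionClasses:
    def test_14dat_preset_class_sizes(self):
        plant = generate_rosette(preset_params("14DAT", rng_seed=0))
        assign_position_classes(plant, PRESET_CLASS_COUNTS["14DAT"])
        sizes = {c: sum(l.position_class == c for l in plant.leaves) for c in PositionClass}
        assert sizes == {PositionClass.UPPER: 3, PositionClass.MIDDLE: 2, PositionClass.LOWER: 2}

    def test_28dat_counts_match_ten_leaves(self):
        plant = generate_rosette(preset_params("28DAT", rng_seed=0))
        assign_position_classes(plant, (4, 3, 3))
        sizes = {c: sum(l.position_class == c for l in plant.leaves) for c in PositionClass}
        assert sizes == {PositionClass.UPPER: 4, PositionClass.MIDDLE: 3, PositionClass.LOWER: 3}

    def test_youngest_leaves_are_upper(self):
        plant = generate_rosette(RosetteParams(n_leaves=7))
        assign_position_classes(plant, (3, 2, 2))
        ranks_by_class = {
            c: sorted(l.rank for l in plant.leaves if l.position_class == c)
            for c in PositionClass
        }
        assert ranks_by_class[PositionClass.UPPER] == [5, 6, 7]
        assert ranks_by_class[PositionClass.MIDDLE] == [3, 4]
        assert ranks_by_class[PositionClass.LOWER] == [1, 2]

    def test_all_upper_degenerate_split(self):
        plant = generate_rosette(RosetteParams(n_leaves=7))
        assign_position_classes(plant, (7, 0, 0))
        assert all(l.position_class == PositionClass.UPPER for l in plant.leaves)

    def test_count_mismatch_rejected(self):
        plant = generate_rosette(RosetteParams(n_leaves=7))
        with pytest.raises(ValueError):
            assign_position_classes(plant, (3, 2, 3))


def _duv_table(duv_values, with_control=True):
    rows = [
        {
            "plant_id": 0,
            "leaf_id": i + 1,
            "position_class": "upper",
            "treatment": "3 d 12 h",
            "cumulative_absorbed_uv_kJ_m2": v,
        }
        for i, v in enumerate(duv_values)
    ]
    if with_control:
        rows += [
            {
                "plant_id": 1,
                "leaf_id": i + 1,
                "position_class": "upper",
                "treatment": "control",
                "cumulative_absorbed_uv_kJ_m2": 0.0,
            }
            for i in range(len(duv_values))
        ]
    return pd.DataFrame(rows)


class TestGenerateAssayData:
    def test_zero_noise_zero_response_returns_controls(self):
        table = _duv_table([10.0, 50.0, 120.0])
        out = generate_assay_data(
            table,
            yield_models={"tpc_mg_gae_g": LinearYield(0.0),
                          "tfc_mg_ce_g": LinearYield(0.0),
                          "rsa_pct": LinearYield(0.0)},
            control_concentration={"tpc_mg_gae_g": 10.0, "tfc_mg_ce_g": 5.0, "rsa_pct": 40.0},
            noise_sd=0.0,
        )
        assert np.allclose(out["tpc_mg_gae_g"], 10.0)
        assert np.allclose(out["rsa_pct"], 40.0)

    def test_noiseless_linear_slope_recovered_exactly(self):
        g = 0.8  # percent increase per kJ m^-2
        c0 = 10.0
        table = _duv_table(np.linspace(5, 130, 20))
        out = generate_assay_data(
            table,
            yield_models={"tpc_mg_gae_g": LinearYield(g),
                          "tfc_mg_ce_g": LinearYield(g),
                          "rsa_pct": LinearYield(0.0)},
            control_concentration={"tpc_mg_gae_g": c0, "tfc_mg_ce_g": 5.0, "rsa_pct": 40.0},
            noise_sd=0.0,
        )
        fit = fit_linear_yield(out["cumulative_absorbed_uv_kJ_m2"], out["tpc_mg_gae_g"])
        # conc = c0 (1 + g dUV / 100): slope in concentration units is c0 g / 100
        assert fit.slope * 100.0 / c0 == pytest.approx(g, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_stochastic_hyperbolic_parameter_recovery(self):
        a, b = 60.0, 20.0
        recovered = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            table = _duv_table(rng.uniform(5, 130, 200), with_control=False)
            out = generate_assay_data(
                table,
                yield_models={"tpc_mg_gae_g": HyperbolicYield(a, b, "F2"),
                              "tfc_mg_ce_g": LinearYield(0.0),
                              "rsa_pct": LinearYield(0.0)},
                control_concentration={"tpc_mg_gae_g": 10.0, "tfc_mg_ce_g": 5.0,
                                       "rsa_pct": 40.0},
                noise_sd={"tpc_mg_gae_g": 0.3, "tfc_mg_ce_g": 0.0, "rsa_pct": 0.0},
                rng_seed=seed,
            )
            duv = out["cumulative_absorbed_uv_kJ_m2"].to_numpy()
            rate = (out["tpc_mg_gae_g"].to_numpy() / 10.0 - 1.0) * 100.0
            fit = fit_hyperbolic(duv, rate, "F2")
            recovered.append((fit.a, fit.b))
        med_a = np.median([r[0] for r in recovered])
        med_b = np.median([r[1] for r in recovered])
        assert med_a == pytest.approx(a, rel=0.10)
        assert med_b == pytest.approx(b, rel=0.10)

    def test_concentrations_truncated_at_zero_and_rsa_capped(self):
        table = _duv_table([10.0] * 200)
        out = generate_assay_data(
            table,
            yield_models={"tpc_mg_gae_g": LinearYield(0.0),
                          "tfc_mg_ce_g": LinearYield(0.0),
                          "rsa_pct": LinearYield(50.0)},
            control_concentration={"tpc_mg_gae_g": 0.1, "tfc_mg_ce_g": 0.1, "rsa_pct": 90.0},
            noise_sd=5.0,
            rng_seed=3,
        )
        assert (out["tpc_mg_gae_g"] >= 0).all()
        assert (out["rsa_pct"] <= 100).all()

    def test_deterministic_for_fixed_seed_and_negative_sd_rejected(self):
        table = _duv_table([10.0, 20.0])
        kwargs = dict(
            yield_models={"tpc_mg_gae_g": LinearYield(0.5),
                          "tfc_mg_ce_g": LinearYield(0.5),
                          "rsa_pct": LinearYield(0.0)},
            control_concentration={"tpc_mg_gae_g": 10.0, "tfc_mg_ce_g": 5.0, "rsa_pct": 40.0},
            noise_sd=1.0,
            rng_seed=7,
        )
        a = generate_assay_data(table, **kwargs)
        b = generate_assay_data(table, **kwargs)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            generate_assay_data(table, **{**kwargs, "noise_sd": -1.0})


class TestPresets:
    @pytest.mark.parametrize("stage,n_plants,lai", [("14DAT", 24, 0.40), ("28DAT", 12, 1.60)])
    def test_preset_canopy_leaf_area_index_near_target(self, stage, n_plants, lai):
        # LAI on the 0.40 m^2 module footprint, averaged over seeds
        areas = [
            generate_rosette(preset_params(stage, rng_seed=s)).total_leaf_area
            for s in range(5)
        ]
        got = n_plants * float(np.mean(areas)) / 0.40
        assert got == pytest.approx(lai, rel=0.15)
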