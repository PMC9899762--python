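"""Phantom generator: determinism, feasibility, and ground-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from sahquant.morphometry import measure_profile
from sahquant.synthetic import (
    GROUP_PARAMETERS,
    ColocSimConfig,
    PhantomConfig,
    draw_record_table,
    make_capillary_phantom,
    make_coloc_volume,
    make_ct_table,
    make_grade_sheet,
    make_group_dataset,
)


class TestConfigValidation:
    def test_sham_hole_mean_is_zero(self):
        assert GROUP_PARAMETERS["SHAM"]["hole_area"] == (0.0, 0.0)
        assert GROUP_PARAMETERS["SAH+Mino"]["hole_area"] == (0.0, 0.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(group_label="SHAM", parameters={"capillary_area": (30.0, -1.0)})

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            PhantomConfig(group_label="SHAM", parameters={"lumen_volume_fraction": (1.5, 0.1)})


class TestSinglePhantom:
    def test_sham_has_no_holes(self):
        cfg = PhantomConfig(group_label="SHAM", seed=5)
        profile, truth = make_capillary_phantom(cfg, 0, 0)
        assert truth["hole_area"] == 0.0
        # no perivascular pixel anywhere near the hole intensity
        assert profile.intensity_image.max() < cfg.hole_intensity / 2

    def test_degenerate_lumen_fraction_is_exact(self):
        cfg = PhantomConfig(
            group_label="SHAM", seed=5, parameters={"lumen_volume_fraction": (0.5, 0.0)}
        )
        profile, truth = make_capillary_phantom(cfg, 0, 0, with_image=False)
        ratio = profile.luminal_contour.area / profile.abluminal_contour.area
        assert ratio == pytest.approx(0.5, abs=1e-9)

    def test_profiles_satisfy_invariants(self):
        # CapillaryProfile.__post_init__ re-validates every invariant
        for g in ("SHAM", "SAH", "SAH+Mino"):
            cfg = PhantomConfig(group_label=g, seed=9)
            for i in range(3):
                profile, _ = make_capillary_phantom(cfg, 0, i, with_image=False)
                profile.validate()

    def test_sham_capillary_area_mean_within_two_se(self):
        cfg = PhantomConfig(group_label="SHAM", n_animals=1, profiles_per_animal=100, seed=1)
        truths = [make_capillary_phantom(cfg, 0, i, with_image=False)[1] for i in range(100)]
        mean = np.mean([t["capillary_area"] for t in truths])
        se = 8.67 / np.sqrt(100)
        assert abs(mean - 34.45) < 2 * se


class TestGroupDataset:
    def test_counting_and_unique_keys(self):
        cfgs = [
            PhantomConfig(group_label=g, n_animals=3, profiles_per_animal=5)
            for g in ("SHAM", "SAH", "SAH+Mino")
        ]
        profiles, truth = make_group_dataset(cfgs, seed=1, with_images=False)
        assert len(profiles) == 45
        keys = {(p.group, p.animal, p.profile) for p in profiles}
        assert len(keys) == 45
        assert len(truth) == 45

    def test_same_seed_identical_ground_truth(self):
        cfgs = [PhantomConfig(group_label="SAH", n_animals=2, profiles_per_animal=3)]
        _, t1 = make_group_dataset(cfgs, seed=4, with_images=False)
        _, t2 = make_group_dataset(cfgs, seed=4, with_images=False)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sah_hole_mean_within_two_se(self):
        cfgs = [PhantomConfig(group_label="SAH", n_animals=4, profiles_per_animal=25)]
        _, truth = make_group_dataset(cfgs, seed=21)
        se = 4.18 / np.sqrt(100)
        assert abs(truth["hole_area"].mean() - 22.29) < 2 * se


class TestRoundTrip:
    """Every ground-truth value is recovered by the matching measurement."""

    TOLERANCES = {
        "capillary_area": 1e-6,
        "lumen_volume_fraction": 1e-9,
        "bl_thickness": 1e-3,
        "tj_tortuosity": 1e-6,
        "pericyte_area": 1e-6,
        "pericyte_adhesion": 1e-6,
        "astrocyte_adhesion": 1e-6,
        "hole_area": 1e-9,
        "vesicle_density": 1e-9,
        "pericyte_coverage": 1e-9,
        "astrocyte_coverage": 1e-9,
    }

    @pytest.mark.parametrize("group", ["SHAM", "SAH", "SAH+Mino"])
    def test_recovery_per_group(self, group):
        cfg = PhantomConfig(group_label=group, seed=33)
        for i in range(5):
            profile, truth = make_capillary_phantom(cfg, 0, i)
            rec = measure_profile(profile)
            for key, tol in self.TOLERANCES.items():
                assert abs(getattr(rec, key) - truth[key]) < tol, key

    def test_record_fast_path_matches_geometry_draws(self):
        # the record-level fast path reproduces exactly the values the
        # geometric phantoms are built from (same seed stream)
        cfg = PhantomConfig(group_label="SAH", n_animals=1, profiles_per_animal=4, seed=8)
        table = draw_record_table(cfg)
        for i in range(4):
            _, truth = make_capillary_phantom(cfg, 0, i, with_image=False)
            row = table.iloc[i]
            assert row["capillary_area"] == pytest.approx(truth["capillary_area"], rel=1e-12)
            assert row["lumen_volume_fraction"] == pytest.approx(
                truth["lumen_volume_fraction"], rel=1e-12
            )


class TestColocVolumes:
    def test_perfect_correlation_no_noise(self):
        from sahquant.coloc import pearson

        v = make_coloc_volume(ColocSimConfig(rho=1.0, noise_scale=0.0, seed=0))
        assert pearson(v.channel_a, v.channel_b) == pytest.approx(1.0, abs=1e-9)

    def test_zero_correlation_monte_carlo(self):
        from sahquant.coloc import pearson

        rs = []
        for seed in range(20):
            v = make_coloc_volume(ColocSimConfig(rho=0.0, shape=(64, 64, 64), seed=seed))
            rs.append(pearson(v.channel_a, v.channel_b))
        assert max(abs(r) for r in rs) < 0.05

    def test_target_rho_hit_within_tolerance(self):
        from sahquant.coloc import pearson

        v = make_coloc_volume(ColocSimConfig(rho=0.9, seed=2))
        assert 0.85 <= pearson(v.channel_a, v.channel_b) <= 0.95

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            ColocSimConfig(rho=1.5)


class TestTables:
    def test_fold_two_shifts_delta_ct_by_one_cycle(self):
        ct = make_ct_table(["mmp9"], {"SHAM": {}, "SAH": {"mmp9": 2.0}}, 3, noise_sd=0.0)
        ref = ct[ct["gene"] == "GAPDH"].set_index("sample")["ct"]
        targets = ct[ct["gene"] == "mmp9"].copy()
        targets["dct"] = targets["ct"] - targets["sample"].map(ref)
        sham = targets.loc[targets["group"] == "SHAM", "dct"].mean()
        sah = targets.loc[targets["group"] == "SAH", "dct"].mean()
        assert sham - sah == pytest.approx(1.0, abs=1e-12)

    def test_all_threes_grade_sheet_totals_eighteen(self):
        from sahquant.groupstats import grade_sheet_totals

        sheets = make_grade_sheet(6, distribution=(0, 0, 0, 1.0), seed=0)
        assert (grade_sheet_totals(sheets) == 18).all()

    def test_empty_table_no_error(self):
        assert make_grade_sheet(0).empty
        ct = make_ct_table(["x"], {"SHAM": {}}, 0)
        assert ct.empty
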