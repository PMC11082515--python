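"""Synthetic two-cohort generator: determinism, structure, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from heartwoodkit import datagen
from heartwoodkit.anatomy import N_RADII
from heartwoodkit.datagen import CohortConfig, default_study_config, generate_cohort


def test_same_config_and_seed_is_byte_identical(tmp_path, study):
    cfg = default_study_config()["shaded"]
    ds1, tr1 = generate_cohort(cfg, seed=42)
    ds2, tr2 = generate_cohort(cfg, seed=42)
    for name in datagen.DATASET_TABLES:
        pd.testing.assert_frame_equal(ds1[name], ds2[name])
    datagen.write_dataset(ds1, tr1, tmp_path / "a")
    datagen.write_dataset(ds2, tr2, tmp_path / "b")
    for name in datagen.DATASET_TABLES:
        assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
            tmp_path / "b" / f"{name}.csv"
        ).read_bytes()
    ds3, _ = generate_cohort(cfg, seed=43)
    assert not ds3["discs"].equals(ds1["discs"])


def test_roundtrip_read_write(tmp_path, study):
    dataset, truth = study
    datagen.write_dataset(dataset, truth, tmp_path)
    back = datagen.read_dataset(tmp_path)
    assert set(back) == set(datagen.DATASET_TABLES)
    assert len(back["discs"]) == len(dataset["discs"])
    assert (tmp_path / "truth.json").exists()


def test_default_configs_match_study_conditions():
    cfgs = default_study_config()
    shaded, sun = cfgs["shaded"], cfgs["sun_exposed"]
    assert shaded.diameter_growth_rate_mean == pytest.approx(0.30)
    assert sun.diameter_growth_rate_mean == pytest.approx(1.02)
    assert shaded.leaf_area_mean == pytest.approx(33.82)
    assert shaded.hw_ring_rate > 1.0 > sun.hw_ring_rate
    assert shaded.disc_interval == 1.0 and sun.disc_interval == 2.0
    assert sun.n_trees == 10 and shaded.n_trees == 7


@pytest.mark.parametrize(
    "override",
    [
        {"n_trees": 0},
        {"diameter_growth_rate_mean": -0.1},
        {"vessel_ellipticity": 1.5},
        {"age_range": (1, 1)},
        {"disc_interval": 50.0},  # too coarse for the smallest tree
    ],
)
def test_invalid_configs_rejected(override):
    base = dataclasses.asdict(default_study_config()["shaded"])
    base.update(override)
    with pytest.raises(ValueError):
        CohortConfig(**base)


def test_disc_structural_invariants(study):
    dataset, _ = study
    discs = dataset["discs"]
    assert (discs["hw_rings"] + discs["sw_rings"] == discs["cambial_age"]).all()
    assert (discs["hw_present"] == (discs["hw_rings"] >= 1)).all()
    assert (discs["distance_from_top"] >= 0).all()
    for i in range(1, N_RADII + 1):
        assert (discs[f"hw_r{i}"] <= discs[f"stem_r{i}"] + 1e-9).all()
        assert (discs[f"stem_r{i}"] > 0).all()


def test_trees_have_consistent_geometry(study):
    dataset, _ = study
    trees = dataset["trees"]
    assert (trees["total_height"] >= trees["trunk_height"]).all()
    assert (trees["dbh"] > 0).all()
    assert trees["tree_id"].is_unique


def test_vessel_table_structure(study):
    dataset, _ = study
    vessels = dataset["vessels"]
    assert (vessels["major_um"] >= vessels["minor_um"]).all()
    assert (vessels["minor_um"] > 0).all()
    assert (vessels["vessel_density_per_mm2"] > 0).all()
    # one shared density per disc
    per_disc = vessels.groupby("disc_id")["vessel_density_per_mm2"].nunique()
    assert (per_disc == 1).all()
    # vessels exist exactly for trunk discs
    trunk_ids = set(
        dataset["discs"].loc[dataset["discs"]["disc_type"] == "trunk", "disc_id"]
    )
    assert set(vessels["disc_id"]) == trunk_ids


def test_leaf_area_consistency(study):
    dataset, _ = study
    leaves = dataset["leaves"]
    implied = leaves["n_leaves"] * leaves["mean_leaf_area_cm2"] / 1e4
    np.testing.assert_allclose(implied, leaves["total_leaf_area_m2"], rtol=0.05)
    assert (leaves["green_mass_g"] > leaves["dry_mass_g"]).all()


@pytest.fixture(scope="module")
def big_sun():
    cfg = dataclasses.replace(default_study_config()["sun_exposed"], n_trees=50)
    ds, _ = generate_cohort(cfg, seed=11)
    return cfg, ds


class TestCalibration:
    """Empirical moments of large generated cohorts match configured truth."""

    def test_growth_rate_mean(self, big_sun):
        cfg, ds = big_sun
        discs = ds["discs"]
        trunk = discs[discs["disc_type"] == "trunk"]
        rms = np.sqrt(
            np.mean(
                trunk[[f"stem_r{i}" for i in range(1, 9)]].to_numpy() ** 2, axis=1
            )
        )
        gr = 2 * rms / trunk["cambial_age"].to_numpy()
        se = gr.std(ddof=1) / np.sqrt(len(gr))
        assert abs(gr.mean() - cfg.diameter_growth_rate_mean) < 3 * se

    def test_vessel_diameter_mean_table_value(self, big_sun):
        """Per-disc hydraulic diameters centre on the configured 123.55 µm."""
        from heartwoodkit.anatomy import hydraulic_diameter

        _, ds = big_sun
        dh = [
            hydraulic_diameter(g[["major_um", "minor_um"]].to_numpy())
            for _, g in ds["vessels"].groupby("disc_id")
        ]
        dh = np.asarray(dh)
        se = dh.std(ddof=1) / np.sqrt(len(dh))
        assert abs(dh.mean() - 123.55) < 3 * se

    def test_vessel_density_and_leaf_size_means(self, big_sun):
        cfg, ds = big_sun
        dens = ds["vessels"].groupby("disc_id")["vessel_density_per_mm2"].first()
        se = dens.std(ddof=1) / np.sqrt(len(dens))
        assert abs(dens.mean() - cfg.vessel_density_mean) < 3 * se
        al = ds["leaves"]["mean_leaf_area_cm2"]
        se = al.std(ddof=1) / np.sqrt(len(al))
        assert abs(al.mean() - cfg.leaf_area_mean) < 3 * se

    def test_table_example_two_se_on_default_size(self):
        """The 10-tree default sun cohort reproduces D_H 123.55 within 2 SE."""
        from heartwoodkit.anatomy import hydraulic_diameter

        cfg = default_study_config()["sun_exposed"]
        ds, _ = generate_cohort(cfg, seed=5)
        dh = np.array(
            [
                hydraulic_diameter(g[["major_um", "minor_um"]].to_numpy())
                for _, g in ds["vessels"].groupby("disc_id")
            ]
        )
        se = dh.std(ddof=1) / np.sqrt(len(dh))
        assert abs(dh.mean() - 123.55) < 2 * se


def test_ring_rate_recovered_by_regression():
    """Slope of heartwood rings vs cambial age recovers the configured
    conversion rate (0.96) within 0.05 on a large cohort."""
    cfg = dataclasses.replace(default_study_config()["sun_exposed"], n_trees=30)
    ds, _ = generate_cohort(cfg, seed=2)
    discs = ds["discs"]
    hw = discs[discs["hw_present"]]
    assert len(hw) >= 200
    slope = np.polyfit(hw["cambial_age"], hw["hw_rings"], 1)[0]
    assert abs(slope - cfg.hw_ring_rate) < 0.05


def test_onset_age_helper_matches_logistic_inflection():
    cfg = default_study_config()["shaded"]
    age = datagen.onset_age_from_truth(cfg, 0.30)
    # at the inflection age the truth probability is exactly 0.5
    eta = (
        cfg.onset_logistic_a
        + cfg.onset_logistic_b * np.log(age)
        + cfg.onset_logistic_c * np.log(0.30)
    )
    assert eta == pytest.approx(0.0, abs=1e-9)
    assert age == pytest.approx(15.8, rel=0.01)
    assert datagen.onset_age_from_truth(cfg, 1.02) == pytest.approx(12.0, rel=0.01)
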