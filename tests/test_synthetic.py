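"""Cohort generator: structure, determinism, generative identities, clinical draws."""

import io

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from ponsmrsi.config import CohortConfig, GroupEffect
from ponsmrsi.metrics import measure_lesion_volume
from ponsmrsi.synthetic import (
    DEFAULT_LESION_THRESHOLD,
    simulate_cohort,
    simulate_fss,
    simulate_lesion_map,
)
from ponsmrsi.voxels import ALL_VOXELS, BANDS


def test_cohort_shape_and_voxel_vocabulary(cohort):
    assert len(cohort) == 32 * 16 == 512
    assert cohort["subject_id"].nunique() == 32
    counts = cohort["group"].value_counts()
    assert counts["control"] == 15 * 16
    assert counts["low_fatigue"] == 7 * 16
    assert counts["high_fatigue"] == 10 * 16
    for _, sub in cohort.groupby("subject_id"):
        assert sorted(sub["voxel"]) == sorted(ALL_VOXELS)
    assert set(cohort.loc[cohort["voxel"].str.startswith("C"), "region"]) == {"cerebellum"}


def test_identical_config_and_seed_is_byte_identical(default_config):
    a, _ = simulate_cohort(default_config)
    b, _ = simulate_cohort(default_config)
    buf_a, buf_b = io.StringIO(), io.StringIO()
    a.to_csv(buf_a, index=False)
    b.to_csv(buf_b, index=False)
    assert buf_a.getvalue() == buf_b.getvalue()
    c, _ = simulate_cohort(default_config.model_copy(update={"seed": 2}))
    assert not c["naa"].equals(a["naa"])


def test_fractions_sum_to_one(cohort_truth):
    total = cohort_truth.frame[["f_gm", "f_wm", "f_csf"]].sum(axis=1)
    assert np.allclose(total, 1.0, atol=1e-9)


def test_noiseless_amplitudes_are_tissue_mixtures(noiseless_config):
    frame, truth = simulate_cohort(noiseless_config)
    g = truth.frame["pct_gm_true"].to_numpy() / 100.0
    w = 1.0 - g
    dil = 1.0 - truth.frame["f_csf"].to_numpy()
    cfg = noiseless_config
    expect_naa = (g * cfg.gm_conc["NAA"] + w * cfg.wm_conc["NAA"]) * dil
    expect_tcr = (g * cfg.gm_conc["tCr"] + w * cfg.wm_conc["tCr"]) * dil
    assert np.allclose(frame["naa"], expect_naa, rtol=1e-12)
    assert np.allclose(frame["tcr"], expect_tcr, rtol=1e-12)
    # voxel ratio equals the CSF-free mixture ratio exactly
    ratio = frame["naa"] / frame["tcr"]
    assert np.allclose(ratio, expect_naa / expect_tcr, rtol=1e-12)


def test_voxel_effect_scales_amplitude_exactly():
    effect = GroupEffect(group="high_fatigue", voxel="L4", metabolite="tCr", factor=1.25)
    cfg = CohortConfig(seed=5, noise_sd=0.0, effect_map=(effect,),
                       crlb_model={"inflate_prob": 0.0})
    frame, truth = simulate_cohort(cfg)
    g = truth.frame["pct_gm_true"].to_numpy() / 100.0
    base = (g * cfg.gm_conc["tCr"] + (1 - g) * cfg.wm_conc["tCr"]) * (
        1.0 - truth.frame["f_csf"].to_numpy()
    )
    factor = frame["tcr"].to_numpy() / base
    hit = (frame["group"] == "high_fatigue") & (frame["voxel"] == "L4")
    assert np.allclose(factor[hit.to_numpy()], 1.25, rtol=1e-12)
    assert np.allclose(factor[~hit.to_numpy()], 1.0, rtol=1e-12)


def test_gm_gradient_monotone_across_bands(cohort):
    corr = cohort.assign(pct_gm=100 * cohort["f_gm"] / (cohort["f_gm"] + cohort["f_wm"]))
    band_means = [corr[corr["voxel"].isin(band)]["pct_gm"].mean() for band in BANDS]
    assert all(a < b for a, b in zip(band_means, band_means[1:]))
    # pattern runs from WM-rich pons (~12 %GM) to GM-rich cerebellum (~90 %GM)
    assert band_means[0] < 20 and band_means[-1] > 80


@pytest.mark.parametrize(
    "group,low,high",
    [("high", 42, 59), ("control", 13, 26), ("low", 11, 34)],
)
def test_fss_draws_respect_group_ranges(default_config, group, low, high):
    rng = np.random.default_rng(0)
    scores = [simulate_fss(group, default_config, rng) for _ in range(200)]
    assert all(low <= s <= high for s in scores)
    if group == "high":
        assert all(s > 36 for s in scores)
    else:
        assert all(s <= 36 for s in scores)


def test_fss_degenerate_sd_returns_mean():
    cfg = CohortConfig(
        clinical_params={
            **CohortConfig().clinical_params,
            "control": {
                "age": {"mean": 38, "sd": 7, "low": 26, "high": 49},
                "fss": {"mean": 18, "sd": 0, "low": 13, "high": 26},
            },
        }
    )
    assert simulate_fss("control", cfg, 0) == 18.0


def test_fss_unknown_group_raises(default_config):
    with pytest.raises(ValueError, match="unknown group"):
        simulate_fss("medium", default_config)


def test_clinical_fields_by_group(cohort):
    per_subject = cohort.drop_duplicates("subject_id")
    controls = per_subject[per_subject["group"] == "control"]
    patients = per_subject[per_subject["group"] != "control"]
    assert controls["edss"].isna().all() and controls["lesion_volume_cm3"].isna().all()
    assert patients["edss"].notna().all() and patients["lesion_volume_cm3"].notna().all()
    assert ((patients["edss"] * 2) % 1 == 0).all()
    hf = per_subject[per_subject["group"] == "high_fatigue"]
    assert hf["lesion_volume_cm3"].between(0.44, 37.17).all()


def test_config_validation_reports_offending_fields():
    with pytest.raises(ValidationError) as err:
        CohortConfig(n_control=0, noise_sd=-1)
    msg = str(err.value)
    assert "n_control" in msg and "noise_sd" in msg
    with pytest.raises(ValidationError, match="outside"):
        CohortConfig(tissue_profile={**CohortConfig().tissue_profile, "R6": (120.0, 5.0)})


def test_lesion_map_volume_by_construction():
    img = simulate_lesion_map(0.0, shape=(20, 20, 20), seed=1)
    assert measure_lesion_volume(img) == 0.0
    img = simulate_lesion_map(2.0, shape=(20, 20, 20), seed=1)
    assert int((img >= DEFAULT_LESION_THRESHOLD).sum()) == 2000
    assert measure_lesion_volume(img) == pytest.approx(2.0, abs=1e-3)


def test_lesion_map_roundtrip_and_capacity():
    for vol in (0.123, 1.5, 5.0):
        img = simulate_lesion_map(vol, shape=(30, 30, 30), seed=3)
        assert abs(measure_lesion_volume(img) - vol) <= 1e-3  # one 1 mm^3 voxel
    with pytest.raises(ValueError, match="grid holds only"):
        simulate_lesion_map(10.0, shape=(10, 10, 10), seed=0)
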