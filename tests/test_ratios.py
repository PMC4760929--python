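"""Ratios, cerebellar normalization and pure-tissue composition projection."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from ponsmrsi.config import CohortConfig, GroupEffect
from ponsmrsi.metrics import add_composition, qc_filter
from ponsmrsi.ratios import (
    build_ratio_table,
    cerebellar_normalize,
    composition_fit,
    fit_composition_group,
    naa_tcr_ratio,
    percent_change,
    report_percent_change,
)
from ponsmrsi.synthetic import simulate_cohort
from ponsmrsi.voxels import GROUPS


def test_naa_tcr_ratio_basics():
    assert naa_tcr_ratio(1.3, 1.3) == 1.0
    assert math.isnan(naa_tcr_ratio(1.0, 0.0))
    assert math.isnan(naa_tcr_ratio(1.0, float("nan")))


def test_voxel_ratios_match_generator_calibration(ratio_table):
    """WM-rich pons voxels sit near 2.5, cerebellar voxels near 1.2."""
    ctrl = ratio_table[ratio_table["group"] == "control"]
    r6 = ctrl[ctrl["voxel"] == "R6"]["naa_tcr"].mean()
    c1 = ctrl[ctrl["voxel"] == "C1"]["naa_tcr"].mean()
    assert r6 == pytest.approx(2.5, abs=0.35)
    assert c1 == pytest.approx(1.2, abs=0.2)


def _subject(values_cb, tcr_pons=0.6, naa_pons=1.2):
    rows = [
        {"subject_id": "s1", "voxel": f"C{i+1}", "region": "cerebellum",
         "naa": v, "tcr": v} for i, v in enumerate(values_cb)
    ]
    rows.append({"subject_id": "s1", "voxel": "R1", "region": "pons",
                 "naa": naa_pons, "tcr": tcr_pons})
    return pd.DataFrame(rows)


def test_cerebellar_normalization_examples():
    out = cerebellar_normalize(_subject([1.0, 1.0, 1.0, 1.0], tcr_pons=0.6))
    assert out.loc[out["voxel"] == "R1", "tcr_over_tcr_cb"].iloc[0] == pytest.approx(0.6)
    out = cerebellar_normalize(_subject([1.0, 1.0, 1.4, 1.4], tcr_pons=1.2))
    assert out.loc[out["voxel"] == "R1", "tcr_over_tcr_cb"].iloc[0] == pytest.approx(1.0)
    # cerebellar voxels themselves carry no normalized ratio
    assert out.loc[out["voxel"] == "C1", "tcr_over_tcr_cb"].isna().all()


def test_cerebellar_normalization_scale_invariance():
    df = _subject([0.9, 1.0, 1.1, 1.2], tcr_pons=0.7, naa_pons=1.5)
    base = cerebellar_normalize(df)
    scaled = cerebellar_normalize(df.assign(naa=df["naa"] * 3.7, tcr=df["tcr"] * 3.7))
    for col in ("naa_over_naa_cb", "tcr_over_tcr_cb"):
        assert np.allclose(
            base.loc[base["region"] == "pons", col],
            scaled.loc[scaled["region"] == "pons", col],
        )


def test_all_cerebellar_rejected_yields_missing_and_logs(caplog):
    df = _subject([np.nan] * 4)
    with caplog.at_level(logging.WARNING, logger="ponsmrsi.ratios"):
        out = cerebellar_normalize(df)
    assert out["tcr_over_tcr_cb"].isna().all()
    assert any("cerebellar" in r.message for r in caplog.records)


def test_percent_change_examples():
    assert report_percent_change(0.75, 0.60) == 25
    assert report_percent_change(0.67, 0.53) == 26
    assert percent_change(1.0, 1.0) == 0.0
    with pytest.raises(ValueError):
        percent_change(1.0, 0.0)


def test_ratio_strictly_decreasing_in_gm_on_noiseless_data(noiseless_ratio_table):
    """NAA/tCr falls with %GM whenever the WM pool ratio exceeds the GM one."""
    df = noiseless_ratio_table.dropna(subset=["naa_tcr"]).sort_values("f_wm_tissue")
    # on noiseless data the ratio is an exact function of composition
    assert df["naa_tcr"].is_monotonic_increasing  # increasing in fWM = decreasing in %GM


def test_noiseless_projection_closure(noiseless_ratio_table, noiseless_config):
    truth_gm = noiseless_config.gm_conc["NAA"] / noiseless_config.gm_conc["tCr"]
    truth_wm = noiseless_config.wm_conc["NAA"] / noiseless_config.wm_conc["tCr"]
    for g in GROUPS:
        fit = fit_composition_group(noiseless_ratio_table, g)
        assert fit.endpoint_gm == pytest.approx(truth_gm, rel=1e-6)
        assert fit.endpoint_wm == pytest.approx(truth_wm, rel=1e-6)


def test_wm_pool_effect_shifts_wm_endpoint():
    """A 1.25x WM-tCr elevation divides the pure-WM NAA/tCr endpoint by 1.25."""
    effect = GroupEffect(group="high_fatigue", voxel="*", metabolite="tCr",
                         factor=1.25, mode="wm_pool")
    cfg = CohortConfig(seed=11, noise_sd=0.0, effect_map=(effect,),
                       crlb_model={"inflate_prob": 0.0})
    frame, truth = simulate_cohort(cfg)
    table = build_ratio_table(qc_filter(add_composition(frame))[0])
    ctrl = fit_composition_group(table, "control")
    hf = fit_composition_group(table, "high_fatigue")
    assert hf.endpoint_wm == pytest.approx(ctrl.endpoint_wm / 1.25, rel=1e-6)
    assert truth.pure_tissue_ratios["high_fatigue"]["naa_tcr_wm"] == pytest.approx(
        hf.endpoint_wm, rel=1e-6
    )
    # shared GM pools: the group curves converge toward 100% GM
    assert hf.endpoint_gm == pytest.approx(ctrl.endpoint_gm, rel=1e-6)
    f = np.array([0.02, 0.5, 0.95])
    gap = np.abs(hf.predict(f) - ctrl.predict(f))
    assert gap[0] < gap[1] < gap[2]


def test_composition_fit_requires_spread():
    df = pd.DataFrame(
        {
            "subject_id": ["a"] * 4,
            "group": ["control"] * 4,
            "f_wm_tissue": [0.5] * 4,
            "naa_tcr": [2.0, 2.1, 1.9, 2.0],
        }
    )
    with pytest.raises(ValueError, match="distinct composition"):
        fit_composition_group(df, "control")


def test_bootstrap_contrasts_structure(ratio_table):
    fits, contrasts = composition_fit(ratio_table, n_bootstrap=50, seed=0)
    assert set(fits) == set(GROUPS)
    eps = {(c.endpoint, c.group_a, c.group_b) for c in contrasts}
    assert ("wm", "control", "high_fatigue") in eps
    for c in contrasts:
        assert 0 < c.p_value <= 1
        assert c.ci_low <= c.ci_high
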