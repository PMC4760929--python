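"""Metabolite ratios, cerebellar normalization and pure-tissue projection.

Three ratio families are computed per subject and voxel:

* ``NAA/tCr`` — the within-voxel ratio (CSF-correction cancels in it);
* ``NAA/NAA_Cb`` and ``tCr/tCr_Cb`` — each pons metabolite normalized to the
  subject's mean value over the surviving cerebellar reference voxels C1-C4,
  which disentangles whether NAA or tCr drives a change in NAA/tCr.

Because both NAA and tCr are (to first order) linear in the white-matter
fraction fWM of the tissue sampled, their ratio is a rational linear/linear
function of fWM,

    r(f) = (alpha + beta * f) / (1 + gamma * f),

which explains the curvature and between-group convergence of the ratio
toward GM-rich compositions that a straight line cannot.  Fitting this curve
per group and evaluating it at f = 0 and f = 1 projects the observed voxel
ratios to hypothetical pure-GM and pure-WM compositions; endpoint contrasts
between groups are assessed by a subject-level nonparametric bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .voxels import GROUPS

logger = logging.getLogger(__name__)


def naa_tcr_ratio(naa: float, tcr: float) -> float:
    """NAA/tCr for one voxel; NaN when tCr is missing or non-positive."""
    if naa is None or tcr is None or not np.isfinite(naa) or not np.isfinite(tcr) or tcr <= 0:
        return float("nan")
    return naa / tcr


def cerebellar_normalize(subject_voxels: pd.DataFrame) -> pd.DataFrame:
    """Normalize one subject's pons metabolites to their mean cerebellar value.

    Input: that subject's voxel rows with columns ``voxel``, ``region`` and
    metabolite amplitudes (QC-masked values as NaN).  CSF-corrected columns
    (``naa_corr``/``tcr_corr``) are used when present — unlike the
    within-voxel NAA/tCr ratio, a cross-voxel ratio does not cancel the CSF
    partial-volume factor, so the correction matters here.  Output adds
    ``naa_over_naa_cb`` and ``tcr_over_tcr_cb`` for pons voxels (NaN in the
    cerebellum).  If all four cerebellar values of a metabolite were rejected,
    that metabolite's normalized ratios are missing for the subject (logged).

    The reference is the per-subject mean of surviving C1-C4 values, so any
    global per-subject scaling (e.g. coil loading) cancels exactly.
    """
    df = subject_voxels.copy()
    cb = df[df["region"] == "cerebellum"]
    pons = df["region"] == "pons"
    for met, base in (("NAA", "naa"), ("tCr", "tcr")):
        col = f"{base}_corr" if f"{base}_corr" in df.columns else base
        ref_vals = cb[col].dropna()
        out_col = f"{base}_over_{base}_cb"
        if ref_vals.empty:
            sid = df["subject_id"].iloc[0] if "subject_id" in df and len(df) else "?"
            logger.warning(
                "subject %s: all cerebellar %s values rejected; normalized %s ratios missing",
                sid, met, met,
            )
            df[out_col] = np.nan
            continue
        ref = float(ref_vals.mean())
        df[out_col] = np.where(pons, df[col] / ref, np.nan)
    return df


def build_ratio_table(corrected: pd.DataFrame) -> pd.DataFrame:
    """Per subject x voxel ratio table from a composition-annotated cohort.

    Expects the output of :func:`ponsmrsi.metrics.add_composition` (and
    usually :func:`ponsmrsi.metrics.qc_filter`).  Returns columns
    ``naa_tcr``, ``naa_over_naa_cb``, ``tcr_over_tcr_cb`` alongside
    composition and grouping columns; ``f_wm_tissue`` is the white-matter
    fraction of brain tissue on the [0, 1] scale used by the projection.
    """
    parts = []
    for _, sub in corrected.groupby("subject_id", sort=False):
        parts.append(cerebellar_normalize(sub))
    df = pd.concat(parts, ignore_index=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = df["naa"] / df["tcr"]
    df["naa_tcr"] = ratio.where(df["tcr"] > 0)
    df["f_wm_tissue"] = df["pct_wm"] / 100.0
    keep = [
        "subject_id", "group", "age", "fss", "voxel", "region",
        "pct_gm", "pct_wm", "f_wm_tissue",
        "naa_tcr", "naa_over_naa_cb", "tcr_over_tcr_cb",
    ]
    return df[[c for c in keep if c in df.columns]]


def percent_change(mean_case: float, mean_control: float) -> float:
    """Percent change of a case-group mean relative to the control mean."""
    if not np.isfinite(mean_control) or mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_case - mean_control) / mean_control


def report_percent_change(mean_case: float, mean_control: float) -> int:
    """Percent change rounded to the nearest integer, as reported in tables."""
    return int(round(percent_change(mean_case, mean_control)))


@dataclass
class CompositionFit:
    """Per-group rational fit of a ratio against white-matter fraction."""

    group: str
    alpha: float
    beta: float
    gamma: float
    endpoint_gm: float  # fitted ratio at fWM = 0
    endpoint_wm: float  # fitted ratio at fWM = 1
    se_gm: float
    se_wm: float
    n_points: int
    n_subjects: int
    method: str = "rational"

    def predict(self, f_wm: np.ndarray) -> np.ndarray:
        f = np.asarray(f_wm, dtype=float)
        if self.method == "linear":
            return self.alpha + self.beta * f
        return (self.alpha + self.beta * f) / (1.0 + self.gamma * f)


@dataclass
class EndpointContrast:
    """Bootstrap contrast of two groups' fitted endpoints."""

    endpoint: str  # "gm" or "wm"
    group_a: str
    group_b: str
    difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n_bootstrap: int


def _fit_rational(f: np.ndarray, r: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of r(f); returns (params, covariance)."""
    A = np.column_stack([np.ones_like(f), f])
    lin, *_ = np.linalg.lstsq(A, r, rcond=None)
    if method == "linear":
        resid = r - A @ lin
        dof = max(len(f) - 2, 1)
        cov = np.linalg.inv(A.T @ A) * (resid @ resid / dof)
        return np.array([lin[0], lin[1], 0.0]), cov

    def residuals(p):
        a, b, g = p
        return (a + b * f) / (1.0 + g * f) - r

    sol = least_squares(
        residuals,
        x0=np.array([lin[0], lin[1], 0.0]),
        bounds=([-np.inf, -np.inf, -0.95], [np.inf, np.inf, 20.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    J = sol.jac
    dof = max(len(f) - 3, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ) * s2
    except np.linalg.LinAlgError:  # flat directions at (near-)zero residual
        cov = np.linalg.pinv(JtJ) * s2
    return sol.x, cov


def _endpoints(params: np.ndarray, cov: np.ndarray, method: str):
    a, b, g = params
    if method == "linear":
        gm, wm = a, a + b
        grad_gm = np.array([1.0, 0.0, 0.0])
        grad_wm = np.array([1.0, 1.0, 0.0])
    else:
        gm = a
        wm = (a + b) / (1.0 + g)
        grad_gm = np.array([1.0, 0.0, 0.0])
        grad_wm = np.array([1.0 / (1.0 + g), 1.0 / (1.0 + g), -(a + b) / (1.0 + g) ** 2])
    se_gm = float(np.sqrt(max(grad_gm @ cov @ grad_gm, 0.0)))
    se_wm = float(np.sqrt(max(grad_wm @ cov @ grad_wm, 0.0)))
    return float(gm), float(wm), se_gm, se_wm


def fit_composition_group(
    ratio_table: pd.DataFrame,
    group: str,
    outcome: str = "naa_tcr",
    method: str = "rational",
) -> CompositionFit:
    """Fit one group's ratio-versus-composition curve over all 16 voxels."""
    sub = ratio_table[(ratio_table["group"] == group)][["subject_id", "f_wm_tissue", outcome]]
    sub = sub.dropna()
    f = sub["f_wm_tissue"].to_numpy(dtype=float)
    r = sub[outcome].to_numpy(dtype=float)
    if len(np.unique(np.round(f, 6))) < 3:
        raise ValueError(
            f"group {group!r}: need >= 3 distinct composition values spanning the "
            "pons-cerebellum range to fit the projection"
        )
    params, cov = _fit_rational(f, r, method)
    gm, wm, se_gm, se_wm = _endpoints(params, cov, method)
    return CompositionFit(
        group=group,
        alpha=float(params[0]), beta=float(params[1]), gamma=float(params[2]),
        endpoint_gm=gm, endpoint_wm=wm, se_gm=se_gm, se_wm=se_wm,
        n_points=len(f), n_subjects=sub["subject_id"].nunique(),
        method=method,
    )


def composition_fit(
    ratio_table: pd.DataFrame,
    outcome: str = "naa_tcr",
    groups: tuple[str, ...] = GROUPS,
    method: str = "rational",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> tuple[dict[str, CompositionFit], list[EndpointContrast]]:
    """Per-group composition fits plus bootstrap endpoint contrasts.

    Contrasts compare each patient group against the first group listed
    (conventionally the controls) and the two patient groups against each
    other, at both the pure-GM and pure-WM endpoints.  The bootstrap
    resamples subjects (not voxels) within each group, respecting the
    within-subject correlation of the 16 voxel measurements.
    """
    fits = {g: fit_composition_group(ratio_table, g, outcome, method) for g in groups}
    contrasts: list[EndpointContrast] = []
    if n_bootstrap <= 0 or len(groups) < 2:
        return fits, contrasts

    rng = np.random.default_rng(seed)
    boot: dict[str, dict[str, np.ndarray]] = {}
    for g in groups:
        sub = ratio_table[ratio_table["group"] == g][["subject_id", "f_wm_tissue", outcome]].dropna()
        arrays = [
            (d["f_wm_tissue"].to_numpy(dtype=float), d[outcome].to_numpy(dtype=float))
            for _, d in sub.groupby("subject_id")
        ]
        n_subj = len(arrays)
        gm_s = np.empty(n_bootstrap)
        wm_s = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            take = rng.integers(0, n_subj, size=n_subj)
            f = np.concatenate([arrays[i][0] for i in take])
            r = np.concatenate([arrays[i][1] for i in take])
            try:
                p, cov = _fit_rational(f, r, method)
                gm_b, wm_b, *_ = _endpoints(p, cov, method)
            except Exception:  # degenerate resample; record as missing
                gm_b = wm_b = np.nan
            gm_s[b], wm_s[b] = gm_b, wm_b
        boot[g] = {"gm": gm_s, "wm": wm_s}

    pairs = [(groups[0], g) for g in groups[1:]]
    if len(groups) >= 3:
        pairs.append((groups[1], groups[2]))
    for ga, gb in pairs:
        for ep in ("gm", "wm"):
            point = getattr(fits[gb], f"endpoint_{ep}") - getattr(fits[ga], f"endpoint_{ep}")
            diffs = boot[gb][ep] - boot[ga][ep]
            diffs = diffs[np.isfinite(diffs)]
            n = len(diffs)
            if n == 0:
                continue
            p_lo = (np.sum(diffs <= 0) + 1) / (n + 1)
            p_hi = (np.sum(diffs >= 0) + 1) / (n + 1)
            contrasts.append(
                EndpointContrast(
                    endpoint=ep, group_a=ga, group_b=gb,
                    difference=float(point),
                    ci_low=float(np.percentile(diffs, 2.5)),
                    ci_high=float(np.percentile(diffs, 97.5)),
                    p_value=float(min(1.0, 2.0 * min(p_lo, p_hi))),
                    n_bootstrap=n,
                )
            )
    return fits, contrasts


def group_voxel_percent_change(
    ratio_table: pd.DataFrame,
    outcome: str,
    voxel: str,
    case_group: str,
    control_group: str = "control",
) -> float:
    """Percent change of a voxel's mean outcome in a case group vs control."""
    sel = ratio_table["voxel"] == voxel
    case = ratio_table.loc[sel & (ratio_table["group"] == case_group), outcome].dropna()
    ctrl = ratio_table.loc[sel & (ratio_table["group"] == control_group), outcome].dropna()
    if case.empty or ctrl.empty:
        raise ValueError(f"no surviving {outcome} values in voxel {voxel} for the contrast")
    return percent_change(float(case.mean()), float(ctrl.mean()))
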