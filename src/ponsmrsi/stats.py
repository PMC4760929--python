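"""Covariate-adjusted group comparisons, FDR control and clinical statistics.

The per-voxel comparison is an analysis of covariance: the ratio outcome is
regressed on group membership with the voxel's %GM as covariate (optionally
age as a second covariate), and pairwise group contrasts are taken from the
full three-group model so that all contrasts share one covariate-adjusted
error term.  Raw contrast p-values are corrected per outcome and contrast
across the 12 pons voxels with the Benjamini-Hochberg step-up procedure
(the cerebellar voxels serve only as the normalization reference).

Clinical comparisons between the patient groups use the Mann-Whitney test
(exact by enumeration for small samples) and Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

from .voxels import GROUPS, PONS_VOXELS

logger = logging.getLogger(__name__)

FSS_MIN, FSS_MAX = 9, 63
FATIGUE_CUTOFF = 36.0
#: Exact Mann-Whitney enumeration is used when both groups have at most this many.
MW_EXACT_MAX_N = 8

CONTRAST_PAIRS = (
    ("control", "low_fatigue"),
    ("control", "high_fatigue"),
    ("low_fatigue", "high_fatigue"),
)


def classify_fatigue(fss: float) -> str:
    """Fatigue dichotomy on the FSS sum scale: ``"high"`` iff the score exceeds 36."""
    if not (FSS_MIN <= fss <= FSS_MAX):
        raise ValueError(f"FSS score {fss} outside the [{FSS_MIN}, {FSS_MAX}] sum scale")
    return "high" if fss > FATIGUE_CUTOFF else "low"


@dataclass
class GroupComparison:
    """One covariate-adjusted contrast for one voxel and outcome."""

    voxel: str
    outcome: str
    group_a: str
    group_b: str
    adjusted_mean_a: float
    adjusted_mean_b: float
    estimate: float  # adjusted difference b - a
    p_raw: float
    p_fdr: float = float("nan")
    significant: bool = False


def ancova_voxel(
    data: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("pct_gm",),
    group_col: str = "group",
) -> tuple[float, list[GroupComparison]]:
    """ANCOVA for one voxel: omnibus group p and pairwise contrasts.

    ``data`` holds one row per subject with the outcome, group label and
    covariate columns.  Returns the omnibus F-test p-value for the group
    factor and the pairwise contrasts (each patient group vs control, and
    low vs high fatigue) from the full model, with group means adjusted to
    the grand mean of each covariate.  A covariate with no variance is
    dropped with a warning, falling back to a plain one-way comparison.
    """
    df = data.dropna(subset=[outcome, group_col, *covariates]).copy()
    groups = [g for g in GROUPS if g in set(df[group_col])]
    if len(groups) < 2 or any((df[group_col] == g).sum() < 3 for g in groups):
        raise ValueError("need >= 2 groups with >= 3 subjects each")
    used = []
    for cov in covariates:
        if np.ptp(df[cov].to_numpy(dtype=float)) == 0:
            logger.warning("covariate %r is constant; dropping it from the model", cov)
        else:
            used.append(cov)
    rhs = " + ".join([f"C({group_col}, Treatment('{groups[0]}'))"] + list(used))
    model = ols(f"{outcome} ~ {rhs}", data=df).fit()

    # omnibus group test: joint Wald F on the group dummies
    group_terms = [n for n in model.params.index if n.startswith(f"C({group_col}")]
    omnibus_p = float(model.f_test([f"{t} = 0" for t in group_terms]).pvalue)

    cov_means = {c: float(df[c].mean()) for c in used}
    adj_means = {}
    for g in groups:
        row = {group_col: g, **cov_means}
        adj_means[g] = float(model.predict(pd.DataFrame([row])).iloc[0])

    voxel = str(df["voxel"].iloc[0]) if "voxel" in df else ""
    out = []
    for ga, gb in CONTRAST_PAIRS:
        if ga not in groups or gb not in groups:
            continue

        def term(g):
            return f"C({group_col}, Treatment('{groups[0]}'))[T.{g}]"

        if ga == groups[0]:
            hyp = f"{term(gb)} = 0"
        else:
            hyp = f"{term(gb)} - {term(ga)} = 0"
        t_res = model.t_test(hyp)
        out.append(
            GroupComparison(
                voxel=voxel,
                outcome=outcome,
                group_a=ga,
                group_b=gb,
                adjusted_mean_a=adj_means[ga],
                adjusted_mean_b=adj_means[gb],
                estimate=float(np.squeeze(t_res.effect)),
                p_raw=float(np.squeeze(t_res.pvalue)),
            )
        )
    return omnibus_p, out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_voxels(
    ratio_table: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = ("pct_gm",),
    fdr_level: float = 0.05,
    voxels: tuple[str, ...] = PONS_VOXELS,
) -> pd.DataFrame:
    """Run the per-voxel ANCOVA over the pons and FDR-correct each contrast family.

    The correction family is the set of voxels within one outcome and one
    group contrast.  Returns one row per voxel x contrast with raw and
    adjusted p-values; ``significant`` derives from the adjusted value only.
    """
    rows: list[GroupComparison] = []
    for voxel in voxels:
        sub = ratio_table[ratio_table["voxel"] == voxel]
        try:
            _, contrasts = ancova_voxel(sub, outcome, covariates)
        except ValueError as exc:
            logger.warning("voxel %s: %s; skipped", voxel, exc)
            continue
        rows.extend(contrasts)
    if not rows:
        return pd.DataFrame(
            columns=["voxel", "outcome", "group_a", "group_b", "adjusted_mean_a",
                     "adjusted_mean_b", "estimate", "p_raw", "p_fdr", "significant"]
        )
    df = pd.DataFrame([vars(r) for r in rows])
    df["p_fdr"] = np.nan
    for (_, _), idx in df.groupby(["group_a", "group_b"]).groups.items():
        df.loc[idx, "p_fdr"] = fdr_adjust(df.loc[idx, "p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < fdr_level
    return df


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; exact by enumeration for small samples.

    For groups of at most :data:`MW_EXACT_MAX_N` each, the null distribution
    of U is enumerated over all assignments of the pooled (mid-ranked)
    observations, so ties are handled without approximation and identical
    samples give p = 1 exactly.  Larger samples use the tie-corrected normal
    approximation.  Returns (U of sample_a, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    if n <= MW_EXACT_MAX_N and m <= MW_EXACT_MAX_N:
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        total = math.comb(n + m, n)
        count = 0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
        return u_obs, count / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def clinical_comparisons(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney comparisons of age, EDSS and lesion load between fatigue groups."""
    per_subject = cohort.drop_duplicates("subject_id")
    lf = per_subject[per_subject["group"] == "low_fatigue"]
    hf = per_subject[per_subject["group"] == "high_fatigue"]
    rows = []
    for label, col in (("age", "age"), ("edss", "edss"), ("lesion_load", "lesion_volume_cm3")):
        x = lf[col].dropna().to_numpy()
        y = hf[col].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            continue
        u, p = mann_whitney(x, y)
        rows.append({"measure": label, "u_statistic": u, "p_value": p,
                     "n_low": len(x), "n_high": len(y)})
    return pd.DataFrame(rows)
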