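"""Per-voxel tissue composition, CSF partial-volume correction and quality control.

The composition quantities are

    %GM  = 100 * GM / (GM + WM)          (gray matter share of brain tissue)
    %CSF = 100 * CSF / (GM + WM + CSF)   (CSF share of the whole voxel)

and the CSF partial-volume correction rescales a metabolite amplitude for the
signal-free CSF fraction of the voxel,

    S = S0 / (1 - %CSF/100).

Only relative and ratio quantities are used downstream, so the correction is
implemented without any global scale constant; its defining property is that
it exactly inverts a CSF dilution and cancels in within-voxel ratios.

Quality control excludes a metabolite value when its reported relative
Cramér-Rao lower bound strictly exceeds the threshold (default 20%); the
voxel's other metabolite and the subject's other voxels are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_LESION_THRESHOLD

DEFAULT_CRLB_MAX_PCT = 20.0


def pct_gm(gm: float, wm: float) -> float:
    """Gray matter percentage of the voxel's brain tissue."""
    if gm < 0 or wm < 0:
        raise ValueError("tissue volumes must be >= 0")
    if gm + wm == 0:
        raise ValueError("no brain tissue in voxel (GM + WM = 0)")
    return 100.0 * gm / (gm + wm)


def pct_csf(gm: float, wm: float, csf: float) -> float:
    """CSF percentage of the whole voxel volume."""
    if min(gm, wm, csf) < 0:
        raise ValueError("tissue volumes must be >= 0")
    if gm + wm + csf == 0:
        raise ValueError("voxel has zero total volume")
    return 100.0 * csf / (gm + wm + csf)


def csf_correct(s0: float, pct_csf_value: float) -> float:
    """Partial-volume-corrected amplitude; inverse of CSF dilution.

    Ratios of two corrected metabolites from the same voxel equal the ratios
    of their uncorrected values, since the factor is per-voxel.
    """
    if not (0 <= pct_csf_value < 100):
        raise ValueError("%CSF must lie in [0, 100): a pure-CSF voxel has no tissue signal")
    return s0 / (1.0 - pct_csf_value / 100.0)


def add_composition(cohort: pd.DataFrame, tol: float = 0.01) -> pd.DataFrame:
    """Derive pct_gm / pct_wm / pct_csf and CSF-corrected amplitudes.

    ``f_gm``/``f_wm``/``f_csf`` may be volumes in any common unit or fractions;
    fractions summing to 1 within ``tol`` are accepted and renormalized, and
    the composition formulas (being scale-free) apply to both cases.
    """
    df = cohort.copy()
    total = df["f_gm"] + df["f_wm"] + df["f_csf"]
    if (total <= 0).any():
        bad = df.loc[total <= 0, "voxel"].tolist()
        raise ValueError(f"voxels with zero total tissue volume: {bad}")
    near_one = (total - 1.0).abs() <= tol
    frac_like = near_one | (total > 0)
    if not frac_like.all():  # pragma: no cover - defensive
        raise ValueError("inconsistent tissue volumes")
    for col in ("f_gm", "f_wm", "f_csf"):
        df[col] = df[col] / total
    tissue = df["f_gm"] + df["f_wm"]
    if (tissue <= 0).any():
        bad = df.loc[tissue <= 0, "voxel"].tolist()
        raise ValueError(f"voxels with no brain tissue (GM + WM = 0): {bad}")
    df["pct_gm"] = 100.0 * df["f_gm"] / tissue
    df["pct_wm"] = 100.0 - df["pct_gm"]
    df["pct_csf"] = 100.0 * df["f_csf"]
    corr = 1.0 - df["pct_csf"] / 100.0
    df["naa_corr"] = df["naa"] / corr
    df["tcr_corr"] = df["tcr"] / corr
    return df


@dataclass
class RejectionReport:
    """Per-group, per-metabolite QC rejection percentages and counts."""

    threshold_pct: float
    counts: pd.DataFrame  # columns: group, metabolite, n_total, n_rejected, pct_rejected

    def rate(self, group: str, metabolite: str) -> float:
        sel = self.counts[
            (self.counts["group"] == group) & (self.counts["metabolite"] == metabolite)
        ]
        if sel.empty:
            raise KeyError(f"no QC entry for {group}/{metabolite}")
        return float(sel["pct_rejected"].iloc[0])

    def __str__(self) -> str:
        lines = [f"CRLB > {self.threshold_pct:g}% exclusions:"]
        for _, r in self.counts.iterrows():
            lines.append(
                f"  {r['group']:>13s} {r['metabolite']:>4s}: "
                f"{int(r['n_rejected'])}/{int(r['n_total'])} voxels ({r['pct_rejected']:.1f}%)"
            )
        return "\n".join(lines)


def qc_filter(
    cohort: pd.DataFrame, crlb_max_pct: float = DEFAULT_CRLB_MAX_PCT
) -> tuple[pd.DataFrame, RejectionReport]:
    """Mask metabolite values whose relative CRLB strictly exceeds the threshold.

    A value with CRLB exactly at the threshold is retained.  Rejection voids
    only that metabolite in that voxel (its amplitude columns become NaN);
    the subject and their other voxels stay in the table.
    """
    df = cohort.copy()
    rows = []
    for met, amp_col, crlb_col in (("NAA", "naa", "naa_crlb_pct"), ("tCr", "tcr", "tcr_crlb_pct")):
        reject = df[crlb_col] > crlb_max_pct
        df.loc[reject, amp_col] = np.nan
        corr_col = amp_col + "_corr"
        if corr_col in df.columns:
            df.loc[reject, corr_col] = np.nan
        if len(df):
            for group, sub in df.groupby("group", sort=False):
                n = len(sub)
                k = int((sub[crlb_col] > crlb_max_pct).sum())
                rows.append(
                    {
                        "group": group,
                        "metabolite": met,
                        "n_total": n,
                        "n_rejected": k,
                        "pct_rejected": 100.0 * k / n,
                    }
                )
    report = RejectionReport(
        threshold_pct=crlb_max_pct,
        counts=pd.DataFrame(
            rows, columns=["group", "metabolite", "n_total", "n_rejected", "pct_rejected"]
        ),
    )
    return df, report


def measure_lesion_volume(
    image: np.ndarray,
    threshold: float = DEFAULT_LESION_THRESHOLD,
    voxel_volume_mm3: float = 1.0,
) -> float:
    """Supra-threshold volume of an intensity image, in cm^3.

    Counts voxels with intensity >= ``threshold`` and multiplies by the voxel
    volume.  The default threshold matches the synthetic lesion generator's
    background mean + 3 SD convention.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel volume must be > 0")
    return float((arr >= threshold).sum()) * voxel_volume_mm3 / 1000.0


def measure_lesion_volume_nifti(path, threshold: float = DEFAULT_LESION_THRESHOLD) -> float:
    """Lesion volume from a NIfTI image, voxel volume taken from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    voxel_volume = float(np.prod(img.header.get_zooms()[:3]))
    return measure_lesion_volume(np.asanyarray(img.dataobj), threshold, voxel_volume)


def fractions_from_probability_maps(
    gm_map: np.ndarray,
    wm_map: np.ndarray,
    csf_map: np.ndarray,
    boxes: dict[str, tuple[slice, slice, slice]],
) -> pd.DataFrame:
    """Mean tissue-probability fractions over index boxes of aligned 3D maps.

    ``boxes`` maps voxel labels to index slices of the CSI voxel footprint in
    the segmentation grid.  Returns one row per label with renormalized
    f_gm / f_wm / f_csf; feeding these into :func:`add_composition` yields the
    composition percentages of the tabular path.
    """
    gm, wm, csf = (np.asarray(a, dtype=float) for a in (gm_map, wm_map, csf_map))
    if not (gm.shape == wm.shape == csf.shape):
        raise ValueError("tissue probability maps must share a grid")
    rows = []
    for label, box in boxes.items():
        g, w, c = float(gm[box].sum()), float(wm[box].sum()), float(csf[box].sum())
        total = g + w + c
        if total <= 0:
            raise ValueError(f"box {label!r} contains no tissue probability mass")
        rows.append({"voxel": label, "f_gm": g / total, "f_wm": w / total, "f_csf": c / total})
    return pd.DataFrame(rows)
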