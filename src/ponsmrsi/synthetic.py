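"""Synthetic cohort generation for the pontine CSI analysis.

The generator draws, for each subject, clinical covariates (age, fatigue
severity, EDSS, lesion load) and 16 voxel measurements on the pons/cerebellum
grid.  Voxel metabolite amplitudes follow the partial-volume mixture model

    S0 = (fGM * C_GM + fWM * C_WM) * (1 - fCSF) + noise

with fGM + fWM = 1 the brain-tissue fractions within the voxel, so that the
CSF partial-volume correction downstream is the exact inverse of the CSF
dilution in expectation.  Group effects are multiplicative, either on a
voxel's amplitude wholesale or on the WM-compartment contribution only.
Reported CRLBs follow ``100 * noise_sd * k / amplitude`` with occasional
inflated draws that exercise the quality filter.

Reproducibility: a single global seed fans out to per-subject substreams via
``numpy.random.SeedSequence.spawn``, so identical (config, seed) pairs give
byte-identical cohorts and subsetting subjects does not perturb the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .config import CohortConfig, GroupEffect, TruncatedNormal
from .voxels import ALL_VOXELS, GROUPS, region_of

#: Canonical voxel order of a subject's 16 rows.
VOXEL_ORDER = tuple(ALL_VOXELS)

#: Default intensity model for synthetic lesion images.
LESION_BACKGROUND_MEAN = 100.0
LESION_BACKGROUND_SD = 10.0
#: Default supra-threshold cutoff (= background mean + 3 SD).
DEFAULT_LESION_THRESHOLD = LESION_BACKGROUND_MEAN + 3.0 * LESION_BACKGROUND_SD

_AMP_EPS = 1e-12


@dataclass
class GroundTruth:
    """Noise-free generative state recorded alongside a simulated cohort.

    ``frame`` holds one row per subject x voxel with the true tissue fractions
    and pre-noise amplitudes; ``pure_tissue_ratios`` the per-group NAA/tCr at
    100% GM and 100% WM implied by the configured concentrations and WM-pool
    effects; ``effect_sizes`` the expected percent change of each configured
    voxel-level effect.
    """

    frame: pd.DataFrame
    pure_tissue_ratios: dict[str, dict[str, float]]
    effect_sizes: list[dict]
    seed: int

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "pure_tissue_ratios": self.pure_tissue_ratios,
            "effect_sizes": self.effect_sizes,
            "frame": self.frame.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            frame=pd.DataFrame(payload["frame"]),
            pure_tissue_ratios=payload["pure_tissue_ratios"],
            effect_sizes=payload["effect_sizes"],
            seed=payload["seed"],
        )


def _draw_truncnorm(spec: TruncatedNormal, rng: np.random.Generator) -> float:
    """Inverse-CDF truncated-normal draw (one uniform per value)."""
    if spec.sd == 0:
        return float(spec.mean)
    a = (spec.low - spec.mean) / spec.sd
    b = (spec.high - spec.mean) / spec.sd
    fa, fb = special.ndtr(a), special.ndtr(b)
    u = rng.uniform()
    z = special.ndtri(fa + u * (fb - fa))
    return float(np.clip(spec.mean + spec.sd * z, spec.low, spec.high))


def simulate_fss(group: str, config: CohortConfig, rng: np.random.Generator | int = 0) -> float:
    """Draw a Fatigue Severity Scale score (sum scale, 9-63) for one subject.

    High-fatigue draws always exceed the >36 fatigue cutoff and low-fatigue /
    control draws never do, because the truncation bounds of each group's
    score distribution lie entirely on one side of the cutoff.
    """
    key = {"control": "control", "low": "low_fatigue", "high": "high_fatigue"}.get(group, group)
    if key not in GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {GROUPS}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _draw_truncnorm(config.clinical_params[key].fss, rng)


def _effect_factor(
    effects: tuple[GroupEffect, ...], group: str, voxel: str, metabolite: str, mode: str
) -> float:
    f = 1.0
    for e in effects:
        if (
            e.mode == mode
            and e.group == group
            and e.metabolite == metabolite
            and (e.voxel == "*" or e.voxel == voxel)
        ):
            f *= e.factor
    return f


def _pure_tissue_ratios(config: CohortConfig) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for g in GROUPS:
        # wm_pool effects move the pure-WM endpoint only when they span all voxels
        wm = {
            m: config.wm_conc[m] * _effect_factor(config.effect_map, g, "*", m, "wm_pool")
            for m in ("NAA", "tCr")
        }
        gm = config.gm_conc
        out[g] = {
            "naa_tcr_gm": gm["NAA"] / gm["tCr"],
            "naa_tcr_wm": wm["NAA"] / wm["tCr"],
        }
    return out


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a full cohort; returns the tidy voxel table and its ground truth.

    The returned frame has one row per subject x voxel, in subject order
    control, low fatigue, high fatigue and voxel order R1-R6, L1-L6, C1-C4,
    with the columns of the tidy cohort schema (see :mod:`ponsmrsi.io`).
    """
    root = np.random.SeedSequence(config.seed)
    subjects: list[tuple[str, str]] = []
    for group in GROUPS:
        n = config.group_sizes[group]
        for i in range(n):
            subjects.append((f"{group[:4]}{i + 1:03d}", group))
    streams = root.spawn(len(subjects))

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for (subject_id, group), seq in zip(subjects, streams):
        rng = np.random.default_rng(seq)
        clin = config.clinical_params[group]
        age = round(_draw_truncnorm(clin.age, rng), 1)
        fss = round(simulate_fss(group, config, rng), 1)
        if clin.edss_choices:
            edss = float(rng.choice(np.asarray(clin.edss_choices)))
        else:
            edss = np.nan
        if clin.lesion_range_cm3 is not None:
            lo, hi = clin.lesion_range_cm3
            lesion = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            lesion = np.nan

        for voxel in VOXEL_ORDER:
            region = region_of(voxel)
            mean_gm, sd_gm = config.tissue_profile[voxel]
            pct_gm = _draw_truncnorm(
                TruncatedNormal(mean=mean_gm, sd=sd_gm, low=0.0, high=100.0), rng
            )
            lo_csf, hi_csf = config.csf_fraction_range[region]
            f_csf = float(rng.uniform(lo_csf, hi_csf))
            g = pct_gm / 100.0
            w = 1.0 - g
            f_gm = g * (1.0 - f_csf)
            f_wm = w * (1.0 - f_csf)

            amps: dict[str, float] = {}
            crlbs: dict[str, float] = {}
            true_amps: dict[str, float] = {}
            for met in ("NAA", "tCr"):
                wm_c = config.wm_conc[met] * _effect_factor(
                    config.effect_map, group, voxel, met, "wm_pool"
                )
                tissue = g * config.gm_conc[met] + w * wm_c
                tissue *= _effect_factor(config.effect_map, group, voxel, met, "voxel")
                s0 = tissue * (1.0 - f_csf)
                true_amps[met] = s0
                noisy = max(s0 + config.noise_sd * float(rng.standard_normal()), 0.0)
                amps[met] = noisy

                cm = config.crlb_model
                if float(rng.uniform()) < cm.inflate_prob:
                    crlb = float(rng.uniform(*cm.inflate_range))
                elif config.noise_sd == 0:
                    crlb = 0.0 if noisy > _AMP_EPS else cm.cap_pct
                else:
                    crlb = min(100.0 * config.noise_sd * cm.k / max(noisy, _AMP_EPS), cm.cap_pct)
                crlbs[met] = crlb

            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "age": age,
                    "fss": fss,
                    "edss": edss,
                    "lesion_volume_cm3": lesion,
                    "voxel": voxel,
                    "region": region,
                    "f_gm": f_gm,
                    "f_wm": f_wm,
                    "f_csf": f_csf,
                    "naa": amps["NAA"],
                    "naa_crlb_pct": crlbs["NAA"],
                    "tcr": amps["tCr"],
                    "tcr_crlb_pct": crlbs["tCr"],
                }
            )
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "voxel": voxel,
                    "pct_gm_true": pct_gm,
                    "f_gm": f_gm,
                    "f_wm": f_wm,
                    "f_csf": f_csf,
                    "naa_true": true_amps["NAA"],
                    "tcr_true": true_amps["tCr"],
                }
            )

    cohort = pd.DataFrame(rows)
    effect_sizes = [
        {
            "group": e.group,
            "voxel": e.voxel,
            "metabolite": e.metabolite,
            "factor": e.factor,
            "mode": e.mode,
            "expected_percent_change": 100.0 * (e.factor - 1.0),
        }
        for e in config.effect_map
    ]
    truth = GroundTruth(
        frame=pd.DataFrame(truth_rows),
        pure_tissue_ratios=_pure_tissue_ratios(config),
        effect_sizes=effect_sizes,
        seed=config.seed,
    )
    return cohort, truth


def simulate_lesion_map(
    volume_cm3: float,
    shape: tuple[int, int, int] = (40, 40, 40),
    seed: int = 0,
    voxel_volume_mm3: float = 1.0,
    threshold: float = DEFAULT_LESION_THRESHOLD,
) -> np.ndarray:
    """Synthesize an intensity image whose supra-threshold volume is ``volume_cm3``.

    Background intensities are drawn strictly below ``threshold``; a compact
    lesion blob of ``round(volume_cm3 * 1000 / voxel_volume_mm3)`` voxels is
    set strictly above it, so thresholding recovers the target volume to
    within one voxel's volume (the rounding error).
    """
    if volume_cm3 < 0:
        raise ValueError("target lesion volume must be >= 0")
    n_total = int(np.prod(shape))
    n_lesion = int(round(volume_cm3 * 1000.0 / voxel_volume_mm3))
    if n_lesion > n_total:
        raise ValueError(
            f"target volume {volume_cm3} cm^3 needs {n_lesion} voxels but the "
            f"grid holds only {n_total}"
        )
    rng = np.random.default_rng(seed)
    b = (threshold - LESION_BACKGROUND_MEAN) / LESION_BACKGROUND_SD
    image = stats.truncnorm.rvs(
        -np.inf, b, loc=LESION_BACKGROUND_MEAN, scale=LESION_BACKGROUND_SD,
        size=shape, random_state=rng,
    )
    # truncnorm is open at the upper bound in theory but guard float round-off
    image = np.minimum(image, np.nextafter(threshold, -np.inf))
    if n_lesion > 0:
        center = np.array([rng.uniform(0, s) for s in shape])
        grid = np.indices(shape).reshape(3, -1).T
        d2 = ((grid - center) ** 2).sum(axis=1) + rng.uniform(0, 1e-6, size=n_total)
        blob = np.argsort(d2)[:n_lesion]
        lesion_vals = stats.truncnorm.rvs(
            0.0, np.inf, loc=threshold + 3 * LESION_BACKGROUND_SD, scale=LESION_BACKGROUND_SD,
            size=n_lesion, random_state=rng,
        )
        flat = image.reshape(-1)
        flat[blob] = np.maximum(lesion_vals, threshold)
        image = flat.reshape(shape)
    return image
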