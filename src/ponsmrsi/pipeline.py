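"""End-to-end orchestration: simulate -> metrics -> ratios -> projection -> compare.

Each stage reads and writes the tidy interchange CSV so the pipeline can be
restarted from any intermediate artifact.  A run log (stderr + file) records
versions, seeds, parameter values and the QC rejection percentages per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import config_hash, read_cohort, read_table, write_cohort, write_json, write_table
from .metrics import add_composition, qc_filter
from .ratios import build_ratio_table, composition_fit
from .stats import clinical_comparisons, compare_voxels
from .synthetic import simulate_cohort

logger = logging.getLogger(__name__)

#: Outcomes compared per voxel: the within-voxel ratio and the two
#: cerebellar-referenced single-metabolite ratios.
OUTCOMES = ("naa_tcr", "naa_over_naa_cb", "tcr_over_tcr_cb")

_MARK = {"low_fatigue": "☆", "high_fatigue": "★"}  # LF ☆ / HF ★


class PipelineError(RuntimeError):
    """A stage failed; partial outputs up to that stage are preserved."""


@dataclass
class PipelineResult:
    """Paths of the primary artifacts a full run emits."""

    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    rejection_report: object = None
    log_path: Path | None = None


def _setup_logging(out_dir: Path) -> Path:
    log_path = out_dir / "pipeline.log"
    root = logging.getLogger("ponsmrsi")
    for h in list(root.handlers):  # drop handlers from previous runs
        if getattr(h, "_ponsmrsi_run_log", False):
            root.removeHandler(h)
            h.close()
    handler = logging.FileHandler(log_path, mode="w")
    handler._ponsmrsi_run_log = True
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return log_path


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the enabled stages in order, writing every intermediate artifact."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = _setup_logging(out_dir)
    cfg_hash = config_hash(config)
    result = PipelineResult(out_dir=out_dir, log_path=log_path)
    logger.info("ponsmrsi %s | seed=%d config_hash=%s", __version__, config.seed, cfg_hash)
    logger.info("parameters: %s", config.model_dump_json())

    stage = "simulate"
    try:
        if config.run_simulate:
            cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
            cohort, truth = simulate_cohort(cohort_cfg)
            p = write_cohort(cohort, out_dir / "cohort.csv", config.seed, cfg_hash)
            (out_dir / "ground_truth.json").write_text(truth.to_json())
            result.artifacts["cohort"] = p
            logger.info("simulate: %d subjects, %d rows", cohort["subject_id"].nunique(), len(cohort))
        elif config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
            result.artifacts["cohort"] = Path(config.cohort_csv)
        else:
            raise ValueError("run_simulate is off and no cohort_csv was provided")

        stage = "metrics"
        if config.run_metrics:
            corrected = add_composition(cohort)
            corrected, report = qc_filter(corrected, config.crlb_max_pct)
            result.rejection_report = report
            for line in str(report).splitlines():
                logger.info("metrics: %s", line)
            p = write_table(corrected, out_dir / "corrected.csv", config.seed, cfg_hash)
            result.artifacts["corrected"] = p
        else:
            corrected = add_composition(cohort)

        stage = "ratios"
        if config.run_ratios:
            ratio_table = build_ratio_table(corrected)
            n_missing = int(ratio_table["naa_tcr"].isna().sum())
            logger.info("ratios: %d rows, %d missing NAA/tCr values", len(ratio_table), n_missing)
            p = write_table(ratio_table, out_dir / "ratios.csv", config.seed, cfg_hash)
            result.artifacts["ratios"] = p
        else:
            ratio_table = build_ratio_table(corrected)

        stage = "projection"
        if config.run_projection:
            fits, contrasts = composition_fit(
                ratio_table, outcome="naa_tcr",
                n_bootstrap=config.n_bootstrap, seed=config.seed,
            )
            payload = {
                "outcome": "naa_tcr",
                "fits": {g: vars(f) for g, f in fits.items()},
                "contrasts": [vars(c) for c in contrasts],
            }
            p = write_json(payload, out_dir / "projection.json", config.seed, cfg_hash)
            result.artifacts["projection"] = p
            for c in contrasts:
                logger.info(
                    "projection: %s endpoint %s vs %s diff=%.3f p=%.4f",
                    c.endpoint, c.group_b, c.group_a, c.difference, c.p_value,
                )

        stage = "compare"
        if config.run_compare:
            frames = []
            for outcome in OUTCOMES:
                frames.append(
                    compare_voxels(
                        ratio_table, outcome,
                        covariates=config.covariates, fdr_level=config.fdr_level,
                    )
                )
            comparisons = pd.concat(frames, ignore_index=True)
            p = write_table(comparisons, out_dir / "comparisons.csv", config.seed, cfg_hash)
            result.artifacts["comparisons"] = p
            clin = clinical_comparisons(cohort)
            if not clin.empty:
                write_table(clin, out_dir / "clinical.csv", config.seed, cfg_hash)
            _write_report(comparisons, out_dir / "report.txt")
            n_sig = int(comparisons["significant"].sum())
            logger.info("compare: %d contrasts, %d FDR-significant", len(comparisons), n_sig)
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return result


def _write_report(comparisons: pd.DataFrame, path: Path) -> None:
    """Human-readable summary marking FDR-significant voxels (LF ☆, HF ★)."""
    lines = ["Per-voxel covariate-adjusted group comparisons (FDR-corrected)", ""]
    for outcome, sub in comparisons.groupby("outcome", sort=False):
        lines.append(f"[{outcome}]")
        sig = sub[sub["significant"]]
        if sig.empty:
            lines.append("  no significant voxels")
        for _, r in sig.iterrows():
            mark = _MARK.get(r["group_b"], "*")
            lines.append(
                f"  {r['voxel']} {mark} {r['group_b']} vs {r['group_a']}: "
                f"adj. means {r['adjusted_mean_b']:.3f} vs {r['adjusted_mean_a']:.3f}, "
                f"p_FDR={r['p_fdr']:.4f}"
            )
        lines.append("")
    Path(path).write_text("\n".join(lines))
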