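"""End-to-end orchestration: QC-filter -> normalize -> predict -> compare.

The pipeline consumes a paired cohort (simulated, or loaded from GCT/TSV
files), runs each arm through detection/%P-call QC and the %P-call
exclusion rule, spline-normalizes the survivors, predicts classes per
sample with resampling confidence, and compares the two arms' calls on
the samples retained in both.  Every artifact is written to the output
directory along with a machine-readable run log (parameters, seed,
per-stage sample counts) sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from . import io as fio
from . import qc as fqc
from .concordance import confident_subset
from .matrix import ExpressionMatrix, ValidationError, RAW
from .normalize import SplineNormalizationParams, qspline_normalize
from .ntp import (
    DEFAULT_CONFIDENCE_ALPHA,
    DEFAULT_N_RESAMPLES,
    Signature,
    predict_cohort,
    predictions_to_frame,
)
from .simulate import SimulationConfig, simulate_cohort


@dataclass
class PipelineConfig:
    """Parameters and paths for one pipeline run.

    Either ``simulate`` holds a :class:`SimulationConfig` mapping (the
    cohort is generated) or ``fc_path``/``as_path`` point at expression
    files with ``signature_path`` naming the marker list.
    """

    outdir: str = "ffpesig_run"
    seed: int = 0
    detection_alpha: float = fqc.DEFAULT_DETECTION_ALPHA
    pcall_threshold: float = fqc.DEFAULT_PCALL_THRESHOLD
    normalization: str = "qspline"
    n_anchors: int = 14
    n_resamples: int = DEFAULT_N_RESAMPLES
    alpha: float = DEFAULT_CONFIDENCE_ALPHA
    simulate: Optional[dict] = None
    fc_path: Optional[str] = None
    as_path: Optional[str] = None
    signature_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_alpha < 1.0:
            raise ValidationError("detection_alpha must be in (0, 1)")
        if not 0.0 <= self.pcall_threshold <= 1.0:
            raise ValidationError("pcall_threshold must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_resamples < 100:
            raise ValidationError("n_resamples must be >= 100")
        if self.normalization not in ("qspline", "none"):
            raise ValidationError("normalization must be 'qspline' or 'none'")
        if self.simulate is None and not (
            self.fc_path and self.as_path and self.signature_path
        ):
            raise ValidationError(
                "config needs either a 'simulate' block or fc/as/signature paths"
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _prepare_arm(
    matrix: ExpressionMatrix, name: str, cfg: PipelineConfig, outdir: Path, log: dict
):
    if matrix.scale == RAW and matrix.detection_p is None:
        matrix = fqc.detection_pvalues(matrix)
    report = fqc.qc_report(
        matrix,
        detection_alpha=cfg.detection_alpha,
        pcall_threshold=cfg.pcall_threshold,
    )
    report.to_tsv(outdir / f"qc_{name}.tsv")
    kept, report = fqc.filter_by_pcall(matrix, report)
    log[f"{name}_samples_in"] = int(matrix.n_samples)
    log[f"{name}_samples_passed"] = int(kept.n_samples)
    if cfg.normalization == "qspline" and kept.scale == RAW:
        kept.values = kept.values.clip(lower=np.nextafter(0, 1))
        kept = qspline_normalize(
            kept, SplineNormalizationParams(n_anchors=cfg.n_anchors)
        )
    logm = kept.to_log2() if kept.scale == RAW else kept
    return logm, report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the run log (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if config.simulate is not None:
        sim_cfg = SimulationConfig.from_dict({**config.simulate, "seed": config.seed})
        cohort = simulate_cohort(sim_cfg)
        fc, as_, signature = cohort.fc, cohort.as_, cohort.signature
        fio.write_truth(cohort.truth, outdir / "truth.tsv")
        fio.write_signature_tsv(signature, outdir / "signature.tsv")
    else:
        fc = fio.read_expression(config.fc_path)
        as_ = fio.read_expression(config.as_path)
        signature = fio.read_signature(config.signature_path)

    fc_log, _ = _prepare_arm(fc, "fc", config, outdir, log)
    as_log, _ = _prepare_arm(as_, "as", config, outdir, log)

    preds_fc = predict_cohort(
        fc_log, signature, n_resamples=config.n_resamples,
        seed=config.seed, alpha=config.alpha,
    )
    preds_as = predict_cohort(
        as_log, signature, n_resamples=config.n_resamples,
        seed=config.seed, alpha=config.alpha,
    )
    predictions_to_frame(preds_fc).to_csv(outdir / "predictions_fc.tsv", sep="\t")
    predictions_to_frame(preds_as).to_csv(outdir / "predictions_as.tsv", sep="\t")

    common = [p.sample_id for p in preds_fc
              if p.sample_id in {q.sample_id for q in preds_as}]
    log["paired_samples"] = len(common)
    if len(common) >= 1:
        sub_fc = [p for p in preds_fc if p.sample_id in set(common)]
        sub_as = [p for p in preds_as if p.sample_id in set(common)]
        conf_tab, report = confident_subset(
            sub_fc, sub_as, labels=signature.class_labels
        )
        report.overall_table.counts.to_csv(outdir / "contingency.tsv", sep="\t")
        conf_tab.counts.to_csv(outdir / "contingency_confident.tsv", sep="\t")
        fio.write_json(report.to_dict(), outdir / "concordance.json")
        log["concordance"] = report.to_dict()
    fio.write_json(log, outdir / "run_log.json")
    return log
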