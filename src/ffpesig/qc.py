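"""Profile-quality statistics for degraded FFPE expression data.

Archived FFPE sections carry heavily fragmented RNA, and the first question
for any retrospective study is which profiles are still analyzable.  The
statistics here mirror standard bead-array practice:

* **detection p-values** rank every gene-probe signal against the built-in
  negative-control probes of the same sample;
* **%P-call** (percent present call) is the fraction of gene probes detected
  at a given alpha;
* the **median array** is a hypothetical representative profile (per-gene
  median over the cohort), and a sample's Pearson correlation to it flags
  outlier / poor-quality profiles;
* profiles with %P-call below a threshold (default 20%) are excluded.

The detection p-value is the add-one empirical rank

    p = (1 + #{control signals in the sample >= cell signal}) / (1 + n_controls)

one-sided with the negative controls as the null, so it is in (0, 1],
monotone non-increasing in signal within a sample, and depends only on
ranks (any monotone per-sample transform leaves %P-call unchanged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError, LOG2, RAW

DEFAULT_DETECTION_ALPHA = 0.05
DEFAULT_PCALL_THRESHOLD = 0.20
MIN_CONTROL_PROBES = 20


@dataclass
class QCReport:
    """Per-sample quality summary plus the thresholds that produced it.

    ``samples`` has one row per sample with columns ``pcall`` (fraction of
    gene probes detected), ``median_corr`` (Pearson r to the median array,
    NaN when undefined) and ``passed`` (pcall >= pcall_threshold).
    """

    samples: pd.DataFrame
    pcall_threshold: float = DEFAULT_PCALL_THRESHOLD
    detection_alpha: float = DEFAULT_DETECTION_ALPHA
    median_profile: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        required = {"pcall", "median_corr", "passed"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"QCReport missing columns: {sorted(missing)}")

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index_label="sample")

    def summary(self) -> dict:
        s = self.samples
        return {
            "n_samples": int(len(s)),
            "n_passed": int(s["passed"].sum()),
            "pcall_threshold": self.pcall_threshold,
            "detection_alpha": self.detection_alpha,
            "pcall_mean": float(s["pcall"].mean()),
            "pcall_range": [float(s["pcall"].min()), float(s["pcall"].max())],
            "median_corr_mean": float(s["median_corr"].mean()),
            "median_corr_range": [
                float(s["median_corr"].min()),
                float(s["median_corr"].max()),
            ],
        }


def detection_pvalues(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Populate per-cell detection p-values against negative controls.

    For each cell the p-value is the add-one fraction of that sample's
    negative-control signals at or above the cell's signal.  Requires
    raw-scale input (control ranks are meaningless after an affine log
    shift only if controls were transformed differently; we insist on raw
    for a single well-defined convention) and at least 20 flagged controls.
    """
    matrix.require_scale(RAW, "detection_pvalues")
    n_ctrl = matrix.n_controls
    if n_ctrl == 0:
        raise ValidationError("no negative-control probes flagged")
    if n_ctrl < MIN_CONTROL_PROBES:
        raise ValidationError(
            f"need >= {MIN_CONTROL_PROBES} negative-control probes, got {n_ctrl}"
        )
    vals = matrix.values.to_numpy()
    ctrl = matrix.control_values().to_numpy()
    pmat = np.empty_like(vals, dtype=float)
    for j in range(vals.shape[1]):
        c = np.sort(ctrl[:, j])
        # count of controls >= x is n_ctrl - searchsorted(c, x, 'left')
        ge = n_ctrl - np.searchsorted(c, vals[:, j], side="left")
        pmat[:, j] = (1.0 + ge) / (1.0 + n_ctrl)
    out = matrix.copy()
    out.detection_p = pd.DataFrame(
        pmat, index=matrix.gene_ids, columns=matrix.sample_ids
    )
    return out


def percent_present(
    matrix: ExpressionMatrix, detection_alpha: float = DEFAULT_DETECTION_ALPHA
) -> pd.Series:
    """Per-sample fraction of non-control genes detected at ``detection_alpha``."""
    if matrix.detection_p is None:
        raise ValidationError(
            "detection_p not populated; run detection_pvalues first"
        )
    if not 0.0 < detection_alpha < 1.0:
        raise ValidationError("detection_alpha must be in (0, 1)")
    gene_p = matrix.detection_p.loc[~matrix.control_flags]
    return (gene_p < detection_alpha).mean(axis=0)


def median_profile(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene median over samples: the hypothetical representative array.

    For an even number of samples the convention is the mean of the two
    central order statistics.  Undefined for a single sample (there is
    nothing to compare against).
    """
    if matrix.n_samples < 2:
        raise ValidationError("median profile needs >= 2 samples")
    return matrix.values.median(axis=1)


def intersample_correlation(
    matrix: ExpressionMatrix, profile: pd.Series
) -> pd.Series:
    """Pearson correlation of each sample to a reference (median) profile.

    Computed over non-control genes on the log2 scale.  A zero-variance
    sample or profile yields NaN with a warning rather than an error: a
    flat profile is a data pathology worth reporting, not a crash.
    """
    if len(profile) != matrix.n_genes:
        raise ValidationError(
            f"profile length {len(profile)} != gene count {matrix.n_genes}"
        )
    logm = matrix if matrix.scale == LOG2 else matrix.to_log2()
    keep = ~matrix.control_flags.to_numpy()
    x = logm.values.to_numpy()[keep]
    prof = np.asarray(profile, dtype=float)[keep]
    if matrix.scale == RAW:
        prof = np.log2(prof + 1.0)
    pc = prof - prof.mean()
    pnorm = np.sqrt((pc**2).sum())
    out = np.full(matrix.n_samples, np.nan)
    if pnorm == 0.0:
        warnings.warn("reference profile has zero variance; correlations undefined")
        return pd.Series(out, index=matrix.sample_ids)
    xc = x - x.mean(axis=0)
    xnorm = np.sqrt((xc**2).sum(axis=0))
    ok = xnorm > 0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} sample(s) with zero variance; correlation set to NaN"
        )
    out[ok] = (xc[:, ok] * pc[:, None]).sum(axis=0) / (xnorm[ok] * pnorm)
    return pd.Series(np.clip(out, -1.0, 1.0), index=matrix.sample_ids)


def qc_report(
    matrix: ExpressionMatrix,
    detection_alpha: float = DEFAULT_DETECTION_ALPHA,
    pcall_threshold: float = DEFAULT_PCALL_THRESHOLD,
) -> QCReport:
    """Run the full per-sample QC: detection, %P-call, median-array correlation."""
    if matrix.detection_p is None:
        matrix = detection_pvalues(matrix)
    pcall = percent_present(matrix, detection_alpha)
    prof = median_profile(matrix)
    corr = intersample_correlation(matrix, prof)
    samples = pd.DataFrame(
        {
            "pcall": pcall,
            "median_corr": corr,
            "passed": pcall >= pcall_threshold,
        }
    )
    return QCReport(
        samples=samples,
        pcall_threshold=pcall_threshold,
        detection_alpha=detection_alpha,
        median_profile=prof,
    )


def filter_by_pcall(
    matrix: ExpressionMatrix, report: QCReport
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop samples whose %P-call falls below the report's threshold.

    The exclusion rule is strict-below: a sample at exactly the threshold
    passes.  Sample order is preserved; the returned report is restricted
    to the retained samples.
    """
    missing = [s for s in matrix.sample_ids if s not in report.samples.index]
    if missing:
        raise ValidationError(f"QC report does not cover samples: {missing[:10]}")
    pcall = report.samples.loc[matrix.sample_ids, "pcall"]
    keep = matrix.sample_ids[(pcall >= report.pcall_threshold).to_numpy()]
    if len(keep) == 0:
        diag = report.samples["pcall"].round(4).to_dict()
        raise ValidationError(
            f"all samples fail the %P-call threshold "
            f"{report.pcall_threshold}; per-sample %P-call: {diag}"
        )
    sub = matrix.subset_samples(keep)
    new_report = QCReport(
        samples=report.samples.loc[keep].copy(),
        pcall_threshold=report.pcall_threshold,
        detection_alpha=report.detection_alpha,
        median_profile=report.median_profile,
    )
    return sub, new_report


def replicate_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two (log2-scale) replicate profiles.

    Affine-invariant; returns NaN with a warning if either profile has
    zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("replicate profiles must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        warnings.warn("zero-variance replicate profile; R^2 undefined")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def suggest_pcall_threshold(
    pcalls: pd.Series,
    corrs: pd.Series,
    default: float = DEFAULT_PCALL_THRESHOLD,
    min_group: int = 3,
) -> float:
    """Locate the %P-call value where inter-sample correlation sharply drops.

    Scans candidate cuts over the observed %P-call values and returns the
    cut maximizing mean(corr above) - mean(corr below).  Purely advisory:
    the pipeline default stays at ``default``.  If no change-point stands
    out after removing a linear trend (drop < 2 pooled standard errors),
    the default is returned with a warning.
    """
    pcalls = pd.Series(pcalls).astype(float)
    corrs = pd.Series(corrs).astype(float).reindex(pcalls.index)
    if len(pcalls) < 10:
        raise ValidationError("need >= 10 samples to suggest a threshold")
    if pcalls.nunique() < 3 or corrs.nunique() < 2:
        warnings.warn("degenerate inputs; returning default threshold")
        return default

    order = np.argsort(pcalls.to_numpy(), kind="stable")
    p = pcalls.to_numpy()[order]
    c = corrs.to_numpy()[order]
    n = len(p)
    # detrend to distinguish a genuine step from a smooth monotone rise
    slope, intercept = np.polyfit(p, c, 1)
    resid = c - (slope * p + intercept)

    best_cut, best_drop, best_resid_drop, best_se = None, -np.inf, -np.inf, np.nan
    for k in range(min_group, n - min_group + 1):
        drop = c[k:].mean() - c[:k].mean()
        rdrop = resid[k:].mean() - resid[:k].mean()
        if rdrop > best_resid_drop:
            se = np.sqrt(
                np.var(resid[k:], ddof=1) / (n - k) + np.var(resid[:k], ddof=1) / k
            )
            best_cut, best_drop, best_resid_drop, best_se = p[k], drop, rdrop, se
    if best_cut is None or not np.isfinite(best_se) or best_resid_drop <= 2.0 * best_se:
        warnings.warn(
            "no sharp correlation drop detected; returning default threshold"
        )
        return default
    return float(best_cut)
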