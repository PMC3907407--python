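"""Synthetic paired FFPE cohorts with a tunable RNA-degradation model.

Archived-section (AS) FFPE tissue yields RNA that is far more fragmented
than freshly cut (FC) sections of the same block.  This module generates
paired FC/AS expression cohorts — plus focused digital-count panels —
with planted class structure and known ground truth, so the whole QC /
normalization / prediction / concordance pipeline can be exercised and
validated without any external download.

Degradation model
-----------------
Degradation sites are scattered essentially at random along a transcript,
so the chance that the probe-spanning region of a transcript of effective
length ``L`` (kilobases) remains intact under per-sample degradation rate
``severity`` is ``exp(-severity * L)`` — an exponential fragment-survival
model.  Measured intensity aggregates many molecules, so each cell's
surviving fraction is drawn as ``Binomial(m, exp(-severity*L)) / m``
(``m`` effective fragments per probe).  On top of fragmentation, archived
sections lose assayable material overall: signal is divided by a global
``attenuation`` factor (default 40).  Degraded signal cannot fall below
the optical background, so it is floored at draws from the sample's own
negative-control distribution.  Between-sample heterogeneity of RNA
quality — the hallmark of archived material — enters through per-sample
severities drawn from a gamma distribution.

Defaults emulate a desk-scale archival cohort: 100 samples x 8000 gene
probes + 200 negative controls, mean FC %P-call in the 70-90% band and
mean AS %P-call in the 10-60% band, with visibly more heterogeneous AS
quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ExpressionMatrix, ValidationError, RAW
from .ntp import Signature, SignatureEntry
from . import qc

# internal generator constants (documented in the methods note)
BASELINE_LOG2_MEAN = 11.0  # mean of per-gene baseline log2 intensity
BASELINE_LOG2_SD = 4.0  # gene-to-gene spread of baseline log2 intensity
FRAGMENT_LENGTH_MEDIAN_KB = 1.0  # median effective transcript length
FRAGMENT_LENGTH_SIGMA = 0.5  # log-sd of effective lengths
FRAGMENTS_PER_PROBE = 200  # effective molecules behind one intensity

# fixed seed-substream offsets so each arm is independently reproducible
_SUB_STRUCTURE = 0
_SUB_FC = 1
_SUB_DEGRADE = 2
_SUB_NCOUNTER = 3


@dataclass
class SimulationConfig:
    """Parameters of the paired-cohort generator.

    attenuation is the fold reduction of assayable signal in the archived
    arm (>= 1; default 40); severity is the mean per-sample degradation
    rate (per kilobase) and severity_spread its between-sample standard
    deviation; effect_size is the mean log2 shift of a class's up-markers
    in members of that class; background_mean / background_sd describe the
    raw-scale negative-control distribution.
    """

    n_genes: int = 8000
    n_controls: int = 200
    n_samples: int = 100
    class_labels: Sequence[str] = ("S1", "S2", "S3")
    class_proportions: Optional[Sequence[float]] = None
    markers_per_class: int = 30
    effect_size: float = 1.5
    noise_sd: float = 0.5
    attenuation: float = 40.0
    severity: float = 2.4
    severity_spread: float = 1.2
    background_mean: float = 100.0
    background_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_controls < 1 or self.n_samples < 1:
            raise ValidationError("n_genes, n_controls, n_samples must be positive")
        self.class_labels = list(self.class_labels)
        if not self.class_labels:
            raise ValidationError("class_labels must be non-empty")
        if self.class_proportions is None:
            k = len(self.class_labels)
            self.class_proportions = [1.0 / k] * k
        self.class_proportions = [float(p) for p in self.class_proportions]
        if len(self.class_proportions) != len(self.class_labels):
            raise ValidationError(
                "class_proportions length must match class_labels"
            )
        if abs(sum(self.class_proportions) - 1.0) > 1e-6:
            raise ValidationError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValidationError("class_proportions must be nonnegative")
        if self.markers_per_class < 2:
            raise ValidationError("markers_per_class must be >= 2")
        if self.markers_per_class * len(self.class_labels) > self.n_genes:
            raise ValidationError(
                "markers_per_class x number of classes exceeds n_genes"
            )
        if self.effect_size < 0:
            raise ValidationError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.attenuation < 1:
            raise ValidationError("attenuation must be >= 1")
        if self.severity < 0 or self.severity_spread < 0:
            raise ValidationError("severity and severity_spread must be >= 0")
        if self.background_mean <= 0 or self.background_sd <= 0:
            raise ValidationError("background_mean and background_sd must be > 0")

    def to_dict(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_controls": self.n_controls,
            "n_samples": self.n_samples,
            "class_labels": list(self.class_labels),
            "class_proportions": list(self.class_proportions),
            "markers_per_class": self.markers_per_class,
            "effect_size": self.effect_size,
            "noise_sd": self.noise_sd,
            "attenuation": self.attenuation,
            "severity": self.severity,
            "severity_spread": self.severity_spread,
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    sample_labels: dict
    marker_assignment: dict  # gene -> (class label, "up"/"down")
    severity_per_sample: dict


@dataclass
class PairedCohort:
    """Paired freshly-cut / archived-section arms of the same samples."""

    fc: ExpressionMatrix
    as_: ExpressionMatrix
    truth: CohortTruth
    signature: Signature

    def __post_init__(self) -> None:
        if not self.fc.gene_ids.equals(self.as_.gene_ids):
            raise ValidationError("FC and AS arms must share gene ids and order")
        if not self.fc.sample_ids.equals(self.as_.sample_ids):
            raise ValidationError("FC and AS arms must share sample ids and order")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a raw-scale mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def default_fragment_lengths(n_genes: int, seed: int) -> np.ndarray:
    """Per-gene effective intact lengths (kb), log-normal with median 1 kb."""
    rng = np.random.default_rng(seed)
    return np.exp(
        rng.normal(np.log(FRAGMENT_LENGTH_MEDIAN_KB), FRAGMENT_LENGTH_SIGMA, n_genes)
    )


def simulate_degradation(
    matrix: ExpressionMatrix,
    severity,
    attenuation: float = 40.0,
    fragment_lengths: Optional[np.ndarray] = None,
    seed: int = 0,
    fragments_per_probe: int = FRAGMENTS_PER_PROBE,
) -> ExpressionMatrix:
    """Degrade a raw-scale expression matrix in place of an archived arm.

    Gene-probe signal in sample ``s`` is multiplied by a surviving
    fraction (Binomial(m, exp(-severity_s * length_g)) / m) and divided by
    ``attenuation``, then floored at background draws resampled from that
    sample's own negative-control values.  Control probes are background
    and pass through unchanged.  Detection p-values are recomputed.

    With ``severity == 0`` and ``attenuation == 1`` nothing is degraded
    and the input is returned unchanged (the undegraded aliquot is the
    same measurement, so no new background is drawn).
    """
    matrix.require_scale(RAW, "simulate_degradation")
    sev = np.broadcast_to(
        np.asarray(severity, dtype=float), (matrix.n_samples,)
    ).copy()
    if (sev < 0).any():
        raise ValidationError("severity must be nonnegative")
    if attenuation < 1:
        raise ValidationError("attenuation must be >= 1")
    gene_mask = ~matrix.control_flags.to_numpy()
    n_genes = int(gene_mask.sum())
    if fragment_lengths is None:
        fragment_lengths = default_fragment_lengths(n_genes, seed)
    lengths = np.asarray(fragment_lengths, dtype=float)
    if lengths.shape != (n_genes,):
        raise ValidationError(
            f"fragment_lengths must have one entry per non-control gene ({n_genes})"
        )
    if (lengths <= 0).any():
        raise ValidationError("fragment lengths must be positive")

    if attenuation == 1.0 and (sev == 0).all():
        out = matrix.copy()
        if out.detection_p is None and matrix.n_controls >= qc.MIN_CONTROL_PROBES:
            out = qc.detection_pvalues(out)
        return out

    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy(dtype=float).copy()
    gene_vals = vals[gene_mask]
    p_survive = np.exp(-np.outer(lengths, sev))  # (genes, samples)
    frac = (
        rng.binomial(fragments_per_probe, p_survive) / float(fragments_per_probe)
    )
    degraded = gene_vals * frac / attenuation
    ctrl_vals = vals[~gene_mask]
    floor = np.empty_like(degraded)
    for j in range(vals.shape[1]):
        floor[:, j] = rng.choice(ctrl_vals[:, j], size=n_genes, replace=True)
    vals[gene_mask] = np.maximum(degraded, floor)
    out = ExpressionMatrix(
        values=pd.DataFrame(vals, index=matrix.gene_ids, columns=matrix.sample_ids),
        control_flags=matrix.control_flags.copy(),
        scale=RAW,
    )
    if matrix.n_controls >= qc.MIN_CONTROL_PROBES:
        out = qc.detection_pvalues(out)
    return out


def simulate_technical_replicates(
    matrix: ExpressionMatrix,
    tech_sd: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two technical replicate measurements of the same RNA.

    Technical replicates re-assay one extract: the biological signal —
    including whatever degradation it already carries — is shared, and
    the replicates differ only by multiplicative measurement noise
    (``2**Normal(0, tech_sd)`` per cell, ``tech_sd`` on the log2 scale).
    Detection p-values are recomputed per replicate.
    """
    matrix.require_scale(RAW, "simulate_technical_replicates")
    if tech_sd <= 0:
        raise ValidationError("tech_sd must be positive")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(2):
        noise = np.power(2.0, rng.normal(0.0, tech_sd, matrix.values.shape))
        rep = ExpressionMatrix(
            values=matrix.values * noise,
            control_flags=matrix.control_flags.copy(),
            scale=RAW,
        )
        if matrix.n_controls >= qc.MIN_CONTROL_PROBES:
            rep = qc.detection_pvalues(rep)
        reps.append(rep)
    return reps[0], reps[1]


def _draw_severities(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.severity == 0:
        return np.zeros(config.n_samples)
    if config.severity_spread == 0:
        return np.full(config.n_samples, config.severity)
    shape = (config.severity / config.severity_spread) ** 2
    scale = config.severity_spread**2 / config.severity
    return rng.gamma(shape, scale, config.n_samples)


def simulate_cohort(config: SimulationConfig) -> PairedCohort:
    """Generate a paired FC/AS cohort with planted class structure.

    The FC arm is baseline log2 expression (per-gene means, class effects
    on marker genes, Gaussian noise) exponentiated to the raw scale and
    floored at background; negative-control probes carry pure background.
    The AS arm applies :func:`simulate_degradation` to the FC arm with
    per-sample severities drawn from the configured gamma distribution.
    Deterministic for a fixed ``config.seed``.
    """
    rng_struct = np.random.default_rng(config.seed + _SUB_STRUCTURE)
    rng_fc = np.random.default_rng(config.seed + _SUB_FC)

    classes = list(config.class_labels)
    gene_ids = [f"GENE_{i:05d}" for i in range(config.n_genes)]
    ctrl_ids = [f"NEG_{i:04d}" for i in range(config.n_controls)]
    sample_ids = [f"sample_{i:03d}" for i in range(config.n_samples)]

    # class membership and marker assignment
    labels = rng_struct.choice(
        classes, size=config.n_samples, p=config.class_proportions
    )
    marker_idx = rng_struct.choice(
        config.n_genes,
        size=config.markers_per_class * len(classes),
        replace=False,
    )
    marker_assignment: dict = {}
    entries = []
    it = iter(marker_idx)
    for label in classes:
        for k in range(config.markers_per_class):
            g = gene_ids[next(it)]
            direction = "up" if k % 2 == 0 else "down"
            marker_assignment[g] = (label, direction)
            entries.append(
                SignatureEntry(
                    gene=g, label=label, weight=1.0,
                    direction=1 if direction == "up" else -1,
                )
            )
    signature = Signature(entries=entries, name="planted")

    # baseline expression and class effects on the log2 scale
    base = rng_fc.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, config.n_genes)
    log2expr = np.tile(base[:, None], (1, config.n_samples))
    gi = {g: i for i, g in enumerate(gene_ids)}
    for g, (label, direction) in marker_assignment.items():
        shift = config.effect_size if direction == "up" else -config.effect_size
        member = labels == label
        log2expr[gi[g], member] += shift
    log2expr += rng_fc.normal(0.0, config.noise_sd, log2expr.shape)
    signal = np.power(2.0, log2expr)

    # background: negative controls and per-cell floors
    mu, sigma = _lognormal_params(config.background_mean, config.background_sd)
    bg_genes = rng_fc.lognormal(mu, sigma, signal.shape)
    ctrl = rng_fc.lognormal(mu, sigma, (config.n_controls, config.n_samples))
    fc_vals = np.vstack([np.maximum(signal, bg_genes), ctrl])

    flags = pd.Series(
        [False] * config.n_genes + [True] * config.n_controls,
        index=gene_ids + ctrl_ids,
    )
    fc = ExpressionMatrix(
        values=pd.DataFrame(
            fc_vals, index=gene_ids + ctrl_ids, columns=sample_ids
        ),
        control_flags=flags,
        scale=RAW,
    )
    fc = qc.detection_pvalues(fc)

    severities = _draw_severities(config, rng_struct)
    lengths = default_fragment_lengths(config.n_genes, config.seed + _SUB_DEGRADE)
    as_ = simulate_degradation(
        fc,
        severities,
        attenuation=config.attenuation,
        fragment_lengths=lengths,
        seed=config.seed + _SUB_DEGRADE,
    )

    truth = CohortTruth(
        sample_labels=dict(zip(sample_ids, labels.tolist())),
        marker_assignment=marker_assignment,
        severity_per_sample=dict(zip(sample_ids, severities.tolist())),
    )
    return PairedCohort(fc=fc, as_=as_, truth=truth, signature=signature)


def simulate_ncounter(
    truth: CohortTruth,
    signature: Signature,
    config: SimulationConfig,
    n_filler: int = 400,
    n_panel_controls: int = 20,
    control_log2_mean: float = 10.0,
    base_log2_mean: float = 7.0,
    base_log2_sd: float = 1.5,
    scaling_sd: float = 0.25,
    dispersion: float = 20.0,
) -> CountMatrix:
    """Digital transcript counts for a focused signature panel.

    The panel holds the signature genes, ``n_filler`` unrelated panel
    genes (so resampling-based confidence has a background to draw from)
    and built-in control probes.  Counts are negative-binomial around
    ``scaling_factor(sample) * 2**(base + class effect)``; control probes
    are Poisson around ``scaling_factor * 2**control_log2_mean``.  Sample
    scaling factors are log-normal (library-size analogue, log2-sd
    ``scaling_sd``; 0 means all equal).  Deterministic for a fixed
    ``config.seed``.
    """
    if not signature.entries:
        raise ValidationError("empty signature")
    rng = np.random.default_rng(config.seed + _SUB_NCOUNTER)
    sample_ids = list(truth.sample_labels)
    n_samples = len(sample_ids)
    sig_genes = signature.genes
    filler = [f"PANEL_{i:04d}" for i in range(n_filler)]
    ctrl = [f"NEG_CTRL_{i:02d}" for i in range(n_panel_controls)]
    genes = sig_genes + filler

    base = rng.normal(base_log2_mean, base_log2_sd, len(genes))
    if scaling_sd > 0:
        scal = np.power(2.0, rng.normal(0.0, scaling_sd, n_samples))
    else:
        scal = np.ones(n_samples)

    log2mu = np.tile(base[:, None], (1, n_samples))
    by_class: dict = {}
    for e in signature.entries:
        by_class.setdefault(e.label, []).append(e)
    gidx = {g: i for i, g in enumerate(genes)}
    labels = np.asarray([truth.sample_labels[s] for s in sample_ids])
    for label, es in by_class.items():
        member = labels == label
        for e in es:
            log2mu[gidx[e.gene], member] += e.direction * config.effect_size
    mu = scal[None, :] * np.power(2.0, log2mu)
    p_nb = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p_nb)

    ctrl_mu = scal[None, :] * (2.0**control_log2_mean)
    ctrl_counts = rng.poisson(np.tile(ctrl_mu, (n_panel_controls, 1)))

    all_counts = np.vstack([counts, ctrl_counts])
    flags = pd.Series(
        [False] * len(genes) + [True] * n_panel_controls, index=genes + ctrl
    )
    return CountMatrix(
        counts=pd.DataFrame(all_counts, index=genes + ctrl, columns=sample_ids),
        control_flags=flags,
    )
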