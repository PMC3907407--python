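"""Nearest template prediction (NTP) with resampling confidence p-values.

NTP is a single-sample classifier for signed gene signatures.  Each class
is represented by a *template* vector over the union of signature genes:
+w on that class's up-markers, -w on its down-markers, 0 on the other
classes' markers.  A sample is assigned the class whose template is
nearest in cosine distance

    d(x, t) = 1 - x.t / (|x| |t|)            (range [0, 2])

computed on the sample's signature-gene values after within-sample
standardization of the full profile (subtract the sample mean, divide by
the sample standard deviation over non-control genes — a single-sample
operation requiring no cohort).

Confidence comes from random resampling: ``n_resamples`` gene sets of the
same size are drawn uniformly without replacement from the assayed
(non-control) panel, the template sign/weight pattern is applied to each
random set, and the same min-over-templates distance is computed.  The
confidence p-value is the add-one fraction of null distances at or below
the observed one,

    p = (1 + #{null <= observed}) / (1 + n_resamples),

so p is in (0, 1] and super-uniform under exchangeable genes.  A
prediction with p below the confidence threshold (default 0.05) is
flagged "statistically more confident".  Benjamini-Hochberg FDR across a
cohort accompanies the per-sample p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix, ValidationError, LOG2

DEFAULT_N_RESAMPLES = 1000
DEFAULT_CONFIDENCE_ALPHA = 0.05
MAX_MISSING_FRACTION = 0.10


@dataclass(frozen=True)
class SignatureEntry:
    gene: str
    label: str
    weight: float = 1.0
    direction: int = 1  # +1 up-marker, -1 down-marker


@dataclass
class Signature:
    """Signed marker-gene list assigning genes to classes."""

    entries: list
    name: str = "signature"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if e.direction not in (1, -1):
                raise ValidationError(f"direction must be +1/-1, got {e.direction}")
            if e.gene in seen:
                raise ValidationError(
                    f"gene {e.gene!r} assigned to multiple classes "
                    f"({seen[e.gene]!r} and {e.label!r})"
                )
            seen[e.gene] = e.label
        for label in self.class_labels:
            if sum(1 for e in self.entries if e.label == label) < 2:
                raise ValidationError(f"class {label!r} has < 2 marker genes")

    @property
    def class_labels(self) -> list:
        out: list = []
        for e in self.entries:
            if e.label not in out:
                out.append(e.label)
        return out

    @property
    def genes(self) -> list:
        return [e.gene for e in self.entries]

    def subset(self, genes: Iterable[str]) -> "Signature":
        genes = set(genes)
        return Signature(
            entries=[e for e in self.entries if e.gene in genes], name=self.name
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene, e.label, e.weight, e.direction) for e in self.entries],
            columns=["gene", "class", "weight", "direction"],
        )


@dataclass
class TemplateSet:
    """One signed template per class over the union of signature genes."""

    classes: list
    genes: list
    matrix: np.ndarray  # (n_genes, n_classes)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genes), len(self.classes)):
            raise ValidationError("template matrix shape mismatch")
        if (np.abs(self.matrix).sum(axis=0) == 0).any():
            raise ValidationError("all-zero template")


@dataclass
class Prediction:
    """A single sample's class call with resampling confidence."""

    sample_id: str
    label: str
    distance: float
    p_confidence: float
    fdr: float
    confident: bool
    n_resamples: int
    tie_flag: bool = False


def cosine_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - cosine similarity; 0 for parallel, 1 orthogonal, 2 anti-parallel."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValidationError("cosine distance undefined for a zero vector")
    return float(np.clip(1.0 - x.dot(y) / (nx * ny), 0.0, 2.0))


def build_templates(signature: Signature) -> TemplateSet:
    """Construct the signed class templates from a signature.

    Deterministic and invariant to the order of signature entries: class
    labels are sorted lexicographically and genes laid out sorted within
    class, a canonical layout independent of input order.
    """
    classes = sorted(signature.class_labels)
    genes: list = []
    for label in classes:
        genes.extend(
            sorted(e.gene for e in signature.entries if e.label == label)
        )
    gi = {g: i for i, g in enumerate(genes)}
    ci = {c: j for j, c in enumerate(classes)}
    mat = np.zeros((len(genes), len(classes)))
    for e in signature.entries:
        mat[gi[e.gene], ci[e.label]] = e.direction * e.weight
    return TemplateSet(classes=classes, genes=genes, matrix=mat)


def _min_template_distances(V: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min cosine distance over templates for each row of V.

    V: (n_vectors, n_genes); T: (n_genes, n_classes).  Returns (min
    distance per row, argmin class index per row); ties resolve to the
    first class in order.
    """
    vnorm = np.linalg.norm(V, axis=1)
    if (vnorm == 0).any():
        raise ValidationError("zero vector in distance computation")
    tnorm = np.linalg.norm(T, axis=0)
    sim = (V @ T) / (vnorm[:, None] * tnorm[None, :])
    dist = 1.0 - sim
    idx = np.argmin(dist, axis=1)
    return dist[np.arange(len(dist)), idx], idx


def _standardize(profile: np.ndarray) -> np.ndarray:
    sd = profile.std()
    if sd == 0.0:
        raise ValidationError("flat expression profile cannot be standardized")
    return (profile - profile.mean()) / sd


def _resample_indices(
    rng: np.random.Generator, n_panel: int, m: int, n_resamples: int
) -> np.ndarray:
    """n_resamples index sets of size m, uniform without replacement."""
    keys = rng.random((n_resamples, n_panel))
    return np.argpartition(keys, m - 1, axis=1)[:, :m]


def ntp_predict(
    sample: pd.Series,
    templates: TemplateSet,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    alpha: float = DEFAULT_CONFIDENCE_ALPHA,
    sample_id: str = "sample",
    standardize: bool = True,
) -> Prediction:
    """Classify one sample against the templates, with a resampling p-value.

    ``sample`` is the full assayed panel (gene id -> value, non-control
    genes), not just the signature genes: the null distribution draws
    random gene sets from this panel.  Signature genes absent from the
    panel are dropped with a warning up to a 10% missing fraction; beyond
    that the prediction is considered unreliable and an error is raised.
    """
    if n_resamples < 100:
        raise ValidationError("n_resamples must be >= 100")
    panel = sample.index
    present = [g in panel for g in templates.genes]
    n_missing = present.count(False)
    if len(panel) < len(templates.genes):
        raise ValidationError("panel smaller than the signature")
    if n_missing:
        frac = n_missing / len(templates.genes)
        if frac > MAX_MISSING_FRACTION:
            raise ValidationError(
                f"{n_missing}/{len(templates.genes)} signature genes missing "
                f"({frac:.0%} > {MAX_MISSING_FRACTION:.0%}); prediction unreliable"
            )
        import warnings

        warnings.warn(
            f"dropping {n_missing} signature gene(s) absent from the panel"
        )
        keep = np.asarray(present)
        templates = TemplateSet(
            classes=templates.classes,
            genes=[g for g, k in zip(templates.genes, keep) if k],
            matrix=templates.matrix[keep],
        )
    values = np.asarray(sample, dtype=float)
    if standardize:
        values = _standardize(values)
    pos = pd.Index(panel).get_indexer(templates.genes)
    obs_vec = values[pos]
    T = templates.matrix
    dist, idx = _min_template_distances(obs_vec[None, :], T)
    observed = float(dist[0])
    # distances per class for tie detection
    all_d = 1.0 - (obs_vec @ T) / (np.linalg.norm(obs_vec) * np.linalg.norm(T, axis=0))
    tie = bool((np.isclose(all_d, observed, rtol=0, atol=1e-12)).sum() > 1)

    rng = np.random.default_rng(seed)
    m = len(templates.genes)
    null_idx = _resample_indices(rng, len(values), m, n_resamples)
    V = values[null_idx]
    null_dist, _ = _min_template_distances(V, T)
    p = (1.0 + int((null_dist <= observed).sum())) / (1.0 + n_resamples)
    return Prediction(
        sample_id=str(sample_id),
        label=templates.classes[int(idx[0])],
        distance=observed,
        p_confidence=float(p),
        fdr=float(p),  # per-sample call: FDR defaults to p until cohort adjust
        confident=bool(p < alpha),
        n_resamples=int(n_resamples),
        tie_flag=tie,
    )


def fdr_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, clipped to 1."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if ((arr <= 0) | (arr > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def predict_cohort(
    matrix: ExpressionMatrix,
    signature: Signature,
    n_resamples: int = DEFAULT_N_RESAMPLES,
    seed: int = 0,
    alpha: float = DEFAULT_CONFIDENCE_ALPHA,
) -> list[Prediction]:
    """Per-sample NTP over a QC-passed, normalized, log2-scale cohort.

    Each sample gets its own derived seed (``seed + sample index``) so any
    single sample's call can be reproduced in isolation; BH FDR is applied
    across the cohort afterwards.
    """
    matrix.require_scale(LOG2, "predict_cohort")
    templates = build_templates(signature)
    genes = matrix.gene_values()
    preds: list[Prediction] = []
    for i, sid in enumerate(matrix.sample_ids):
        try:
            preds.append(
                ntp_predict(
                    genes[sid],
                    templates,
                    n_resamples=n_resamples,
                    seed=seed + i,
                    alpha=alpha,
                    sample_id=sid,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"sample {sid!r}: {err}") from err
    fdrs = fdr_adjust([p.p_confidence for p in preds])
    for p, f in zip(preds, fdrs):
        p.fdr = float(min(max(f, np.nextafter(0, 1)), 1.0))
    return preds


def predictions_to_frame(preds: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.sample_id,
                p.label,
                p.distance,
                p.p_confidence,
                p.fdr,
                p.confident,
                p.tie_flag,
            )
            for p in preds
        ],
        columns=["sample", "label", "distance", "p", "fdr", "confident", "tie"],
    ).set_index("sample")
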