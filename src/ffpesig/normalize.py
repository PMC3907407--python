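"""Between-sample normalization.

Two procedures are provided, matching the two assay families the pipeline
serves:

* :func:`qspline_normalize` — cubic-spline quantile normalization of raw
  array intensities.  A reference profile (per-gene geometric mean across
  samples by default) is summarized at a small set of anchor quantiles;
  each sample is mapped onto the reference scale through a monotone cubic
  interpolant fitted to the (sample quantile, reference quantile) anchor
  pairs.  Compared to classical full-quantile normalization this smooths
  rather than forces the entire distribution, but agrees with it at the
  anchors.

* :func:`ncounter_normalize` — digital-count normalization: log2(count+1),
  then per-sample scaling so that every sample's built-in control probes
  share the same (grand-mean) log2 level, i.e. control geometric means are
  equalized exactly on the offset scale.

Anchor quantiles are taken at the *nearest order statistic* (no
interpolation between data points), so that "anchored output quantiles
equal reference quantiles" holds to machine precision: the anchor value is
an actual data point, its image is an actual output point, and the fitted
map is monotone so ranks — and hence order-statistic positions — are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .matrix import ExpressionMatrix, ValidationError, RAW, LOG2


@dataclass
class SplineNormalizationParams:
    """Tuning for the quantile-anchored spline normalization.

    n_anchors : number of anchor quantile probabilities (>= 4); the default
        14 is small enough to smooth noise yet dense enough to track the
        curvature of typical array intensity distributions.
    exclude_extremes : fraction of each tail excluded from the anchor grid
        (anchors span [exclude_extremes, 1 - exclude_extremes]).
    reference : "geometric_mean" to build the reference from the data, or
        an explicit per-gene reference vector.
    """

    n_anchors: int = 14
    exclude_extremes: float = 0.02
    reference: object = "geometric_mean"

    def __post_init__(self) -> None:
        if self.n_anchors < 4:
            raise ValidationError("n_anchors must be >= 4")
        if not 0.0 <= self.exclude_extremes <= 0.1:
            raise ValidationError("exclude_extremes must lie in [0, 0.1]")

    def probabilities(self) -> np.ndarray:
        return np.linspace(
            self.exclude_extremes, 1.0 - self.exclude_extremes, self.n_anchors
        )


def _anchor_quantiles(x: np.ndarray, probs: np.ndarray) -> np.ndarray:
    # nearest order statistic: anchors are actual data values
    return np.quantile(x, probs, method="nearest")


def _monotone_map(xa: np.ndarray, ya: np.ndarray):
    """Monotone cubic interpolant through anchor pairs.

    Duplicate/non-increasing abscissae are collapsed and the anchor images
    are projected onto the nearest nondecreasing sequence (isotonic pool-
    adjacent-violators) so the fitted map — a monotone piecewise-cubic
    Hermite — can never locally invert, guaranteeing rank preservation.
    Outside the anchor range the map continues linearly with the boundary
    slope.
    """
    keep = np.concatenate(([True], np.diff(xa) > 0))
    xa, ya = xa[keep], ya[keep]
    ya = _isotonic(ya)
    # strictly increasing images are needed for a strictly monotone map;
    # break exact ties by an epsilon ramp (relative to data span)
    span = max(ya[-1] - ya[0], 1.0)
    eps = 1e-12 * span
    for i in range(1, len(ya)):
        if ya[i] <= ya[i - 1]:
            ya[i] = ya[i - 1] + eps
    if len(xa) < 2:
        raise ValidationError("degenerate sample: fewer than 2 distinct anchor values")
    interp = PchipInterpolator(xa, ya, extrapolate=False)
    d0 = float(interp.derivative()(xa[0]))
    d1 = float(interp.derivative()(xa[-1]))
    d0 = d0 if np.isfinite(d0) and d0 > 0 else 1.0
    d1 = d1 if np.isfinite(d1) and d1 > 0 else 1.0

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = interp(x)
        lo = x < xa[0]
        hi = x > xa[-1]
        out[lo] = ya[0] + d0 * (x[lo] - xa[0])
        out[hi] = ya[-1] + d1 * (x[hi] - xa[-1])
        return out

    return f


def _isotonic(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto nondecreasing sequences."""
    y = y.astype(float).copy()
    n = len(y)
    w = np.ones(n)
    # blocks as (value, weight) with merging
    vals, wts, sizes = [], [], []
    for v in y:
        vals.append(v)
        wts.append(1.0)
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, s2 = vals.pop(), wts.pop(), sizes.pop()
            v1, w1, s1 = vals.pop(), wts.pop(), sizes.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            sizes.append(s1 + s2)
    out = np.empty(n)
    i = 0
    for v, s in zip(vals, sizes):
        out[i : i + s] = v
        i += s
    return out


def qspline_normalize(
    matrix: ExpressionMatrix,
    params: SplineNormalizationParams | None = None,
) -> ExpressionMatrix:
    """Map every sample onto a common reference scale via anchored splines.

    Requires strictly positive raw-scale values (the geometric-mean
    reference needs logs) and at least two samples.  Identical input
    arrays come back unchanged (the fitted map is the identity), and
    within-sample rank order is preserved exactly.
    """
    if params is None:
        params = SplineNormalizationParams()
    matrix.require_scale(RAW, "qspline_normalize")
    if matrix.n_samples < 2 and not isinstance(params.reference, (np.ndarray, pd.Series, list)):
        raise ValidationError("qspline needs >= 2 samples (or an explicit reference)")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValidationError(
            "qspline requires strictly positive values; floor the matrix first"
        )
    if matrix.n_genes < params.n_anchors:
        raise ValidationError(
            f"fewer genes ({matrix.n_genes}) than anchors ({params.n_anchors})"
        )
    if isinstance(params.reference, str):
        if params.reference not in ("geometric_mean", "geometric_mean_array"):
            raise ValidationError(f"unknown reference {params.reference!r}")
        ref = np.exp(np.log(vals).mean(axis=1))
    else:
        ref = np.asarray(params.reference, dtype=float)
        if ref.shape != (matrix.n_genes,):
            raise ValidationError("explicit reference length must equal gene count")
        if (ref <= 0).any():
            raise ValidationError("explicit reference must be strictly positive")
    probs = params.probabilities()
    ref_anchors = _anchor_quantiles(ref, probs)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        x = vals[:, j]
        xa = _anchor_quantiles(x, probs)
        f = _monotone_map(xa, ref_anchors.copy())
        out[:, j] = f(x)
    res = matrix.copy()
    res.values = pd.DataFrame(out, index=matrix.gene_ids, columns=matrix.sample_ids)
    return res


def ncounter_normalize(counts) -> ExpressionMatrix:
    """Normalize digital counts by control-probe geometric-mean scaling.

    ``log2(count + 1)`` (the +1 offset admits zero counts), then each
    sample is shifted by (grand mean of per-sample control log2 means) -
    (that sample's control log2 mean).  By construction every sample's
    control-probe log2 mean equals the grand mean afterwards — i.e. the
    control geometric means are identical across samples on the offset
    scale.  Re-centering to the grand mean (rather than zero) keeps
    absolute expression levels interpretable.
    """
    from .matrix import CountMatrix

    if not isinstance(counts, CountMatrix):
        counts = CountMatrix(counts)
    if int(counts.control_flags.sum()) < 1:
        raise ValidationError("nCounter normalization needs >= 1 control probe")
    log2v = np.log2(counts.counts.to_numpy(dtype=float) + 1.0)
    ctrl = log2v[counts.control_flags.to_numpy()]
    sample_ctrl_mean = ctrl.mean(axis=0)
    grand = sample_ctrl_mean.mean()
    normed = log2v + (grand - sample_ctrl_mean)[None, :]
    return ExpressionMatrix(
        values=pd.DataFrame(
            normed, index=counts.gene_ids, columns=counts.sample_ids
        ),
        control_flags=counts.control_flags.copy(),
        scale=LOG2,
    )
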