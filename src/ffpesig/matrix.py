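"""Core in-memory containers for expression and digital-count data.

The central currency of the pipeline is the :class:`ExpressionMatrix`:
a genes x samples table of signal values, an optional parallel table of
per-cell detection p-values, and a per-gene flag marking built-in
negative-control probes.  Values live either on the raw scanner scale
(nonnegative intensities) or on the log2 scale; the ``scale`` attribute
records which, and operations that care (detection p-values, correlation)
check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"

#: Reserved identifier prefix marking built-in negative-control probes in
#: files that carry no explicit flag column.
CONTROL_PREFIX = "NEG_"


class ValidationError(ValueError):
    """An input violated a documented invariant; the message names it."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with optional detection p-values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    control_flags
        Boolean Series over the same gene index; True marks a built-in
        negative-control probe.  If omitted, genes whose id starts with
        ``NEG_`` are flagged.
    detection_p
        Optional DataFrame of per-cell detection p-values in [0, 1],
        aligned with ``values``.
    scale
        ``"raw"`` (nonnegative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    control_flags: Optional[pd.Series] = None
    detection_p: Optional[pd.DataFrame] = None
    scale: str = RAW

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        if self.control_flags is None:
            self.control_flags = pd.Series(
                self.values.index.astype(str).str.startswith(CONTROL_PREFIX),
                index=self.values.index,
            )
        else:
            self.control_flags = pd.Series(self.control_flags).reindex(
                self.values.index
            )
            if self.control_flags.isna().any():
                raise ValidationError("control_flags do not cover every gene id")
            self.control_flags = self.control_flags.astype(bool)
        if self.scale not in (RAW, LOG2):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("values contain non-finite entries")
        if self.scale == RAW and (vals < 0).any():
            raise ValidationError("raw-scale values must be >= 0")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValidationError(
                    "detection_p shape does not match values "
                    f"({self.detection_p.shape} vs {self.values.shape})"
                )
            self.detection_p = self.detection_p.reindex(
                index=self.values.index, columns=self.values.columns
            )
            dp = self.detection_p.to_numpy()
            if np.isnan(dp).any() or (dp < 0).any() or (dp > 1).any():
                raise ValidationError("detection_p entries must lie in [0, 1]")

    # -- basic geometry -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_controls(self) -> int:
        return int(self.control_flags.sum())

    # -- views ----------------------------------------------------------
    def gene_values(self) -> pd.DataFrame:
        """Values restricted to non-control (assayed gene) probes."""
        return self.values.loc[~self.control_flags]

    def control_values(self) -> pd.DataFrame:
        """Values of the negative-control probes."""
        return self.values.loc[self.control_flags]

    def subset_samples(self, sample_ids: Sequence) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:10]}")
        return ExpressionMatrix(
            values=self.values[list(sample_ids)].copy(),
            control_flags=self.control_flags.copy(),
            detection_p=None
            if self.detection_p is None
            else self.detection_p[list(sample_ids)].copy(),
            scale=self.scale,
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            control_flags=self.control_flags.copy(),
            detection_p=None if self.detection_p is None else self.detection_p.copy(),
            scale=self.scale,
        )

    # -- scale conversion ----------------------------------------------
    def to_log2(self, offset: float = 1.0) -> "ExpressionMatrix":
        """Return a log2-scale copy, ``log2(value + offset)``.

        Detection p-values are carried over unchanged (they are rank
        statistics of the raw signal and unaffected by a monotone
        transform).
        """
        if self.scale == LOG2:
            return self.copy()
        out = self.copy()
        out.values = np.log2(self.values + offset)
        out.scale = LOG2
        return out

    def require_scale(self, scale: str, op: str) -> None:
        if self.scale != scale:
            hint = (
                "call .to_log2() first"
                if scale == LOG2
                else "this operation needs raw-scale signal; do not log-transform first"
            )
            raise ValidationError(f"{op} requires {scale}-scale values ({hint})")


@dataclass
class CountMatrix:
    """Digital transcript counts (genes x samples) with control-probe flags."""

    counts: pd.DataFrame
    control_flags: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "gene ids")
        _check_unique(self.counts.columns, "sample ids")
        if self.control_flags is None:
            self.control_flags = pd.Series(
                self.counts.index.astype(str).str.startswith(CONTROL_PREFIX),
                index=self.counts.index,
            )
        else:
            self.control_flags = (
                pd.Series(self.control_flags).reindex(self.counts.index).astype(bool)
            )
        cnts = self.counts.to_numpy()
        if (cnts < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns
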