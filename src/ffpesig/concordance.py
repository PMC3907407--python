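"""Paired-prediction concordance between two assay arms.

Given per-sample class predictions from two profiling arms of the same
specimens (e.g. freshly cut vs archived-section FFPE), this module builds
the arm-A x arm-B contingency table, the overall percent agreement
(diagonal fraction, reported half-up-rounded to the integer percent as in
clinical summaries), and the same statistics restricted to pairs called
"statistically more confident" (confidence p < alpha) in *both* arms.
Cohen's kappa is offered as an auxiliary chance-corrected statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import ValidationError
from .ntp import Prediction


@dataclass
class ContingencyTable:
    """Cross-tabulation of paired class calls (rows arm A, columns arm B)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_labels(self) -> list:
        return list(self.counts.index)

    @property
    def col_labels(self) -> list:
        return list(self.counts.columns)

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy())


@dataclass
class ConcordanceReport:
    overall_agreement_percent: int
    overall_agreement_raw: float
    confident_pair_count: int
    confident_agreement_percent: Optional[int]
    confident_agreement_raw: Optional[float]
    overall_table: ContingencyTable
    confident_table: ContingencyTable
    kappa: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n": self.overall_table.n,
            "overall_agreement_percent": self.overall_agreement_percent,
            "overall_agreement_raw": self.overall_agreement_raw,
            "confident_pair_count": self.confident_pair_count,
            "confident_agreement_percent": self.confident_agreement_percent,
            "confident_agreement_raw": self.confident_agreement_raw,
            "kappa": self.kappa,
        }


def _pair(a: Sequence[Prediction], b: Sequence[Prediction]):
    a_by = {p.sample_id: p for p in a}
    b_by = {p.sample_id: p for p in b}
    if len(a_by) != len(a) or len(b_by) != len(b):
        raise ValidationError("duplicate sample ids within an arm")
    only_a = sorted(set(a_by) - set(b_by))
    only_b = sorted(set(b_by) - set(a_by))
    if only_a or only_b:
        raise ValidationError(
            f"unpaired samples (A only: {only_a[:5]}, B only: {only_b[:5]})"
        )
    ids = [p.sample_id for p in a]  # preserve arm-A order
    return ids, a_by, b_by


def contingency(
    a: Sequence[Prediction],
    b: Sequence[Prediction],
    labels: Optional[Sequence[str]] = None,
) -> ContingencyTable:
    """Cross-tabulate paired predictions, matched by sample id (not order).

    ``labels`` fixes the row/column order (e.g. signature class order) and
    pads absent classes with zeros; by default the union of observed
    labels in first-appearance order is used.
    """
    ids, a_by, b_by = _pair(a, b)
    if labels is None:
        labels = []
        for sid in ids:
            for lab in (a_by[sid].label, b_by[sid].label):
                if lab not in labels:
                    labels.append(lab)
    labels = list(labels)
    tab = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for sid in ids:
        tab.loc[a_by[sid].label, b_by[sid].label] += 1
    return ContingencyTable(tab)


def percent_agreement(table: ContingencyTable) -> tuple[int, float]:
    """Diagonal fraction of a square table, as (integer percent, raw percent).

    The integer percent uses half-up rounding (55/64 -> 86, 36/37 -> 97),
    the convention of clinical concordance reporting.
    """
    if table.n == 0:
        raise ValidationError("percent agreement undefined for an empty table")
    if table.row_labels != table.col_labels:
        raise ValidationError("percent agreement needs a square table with matching labels")
    diag = int(np.trace(table.counts.to_numpy()))
    raw = 100.0 * diag / table.n
    return int(math.floor(raw + 0.5)), raw


def cohens_kappa(table: ContingencyTable) -> float:
    """Chance-corrected agreement; auxiliary to percent agreement."""
    c = table.counts.to_numpy(dtype=float)
    n = c.sum()
    if n == 0:
        raise ValidationError("kappa undefined for an empty table")
    po = np.trace(c) / n
    pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def confident_subset(
    a: Sequence[Prediction],
    b: Sequence[Prediction],
    labels: Optional[Sequence[str]] = None,
) -> tuple[ContingencyTable, ConcordanceReport]:
    """Concordance overall and restricted to pairs confident in both arms."""
    ids, a_by, b_by = _pair(a, b)
    overall = contingency(a, b, labels=labels)
    conf_ids = [sid for sid in ids if a_by[sid].confident and b_by[sid].confident]
    use_labels = labels if labels is not None else overall.row_labels
    conf_tab = pd.DataFrame(0, index=list(use_labels), columns=list(use_labels), dtype=int)
    for sid in conf_ids:
        conf_tab.loc[a_by[sid].label, b_by[sid].label] += 1
    conf_table = ContingencyTable(conf_tab)
    ov_pct, ov_raw = percent_agreement(overall)
    if conf_ids:
        cf_pct, cf_raw = percent_agreement(conf_table)
    else:
        cf_pct, cf_raw = None, None
    report = ConcordanceReport(
        overall_agreement_percent=ov_pct,
        overall_agreement_raw=ov_raw,
        confident_pair_count=len(conf_ids),
        confident_agreement_percent=cf_pct,
        confident_agreement_raw=cf_raw,
        overall_table=overall,
        confident_table=conf_table,
        kappa=cohens_kappa(overall),
    )
    return conf_table, report
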