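"""Readers and writers for the interchange formats the pipeline speaks.

Expression matrices travel as GCT (version line ``#1.2``, dimensions
line, ``Name``/``Description`` columns) or plain TSV; signatures as GMT
(one line per class gene set, with an optional ``_up``/``_dn`` suffix
convention marking direction) or a 4-column TSV (gene, class, weight,
direction); generator and pipeline configuration as YAML.

Control probes are recognized by the reserved id prefix ``NEG_`` in all
generated and example files; foreign data can supply an explicit sidecar
list of control ids instead.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .matrix import CountMatrix, ExpressionMatrix, ValidationError, RAW
from .ntp import Signature, SignatureEntry


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line."""


# --------------------------------------------------------------------------
# expression matrices
# --------------------------------------------------------------------------

def _parse_body(
    lines: list[str], start: int, n_value_cols: int, id_col: int, skip_cols: int
) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[list[float]] = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != skip_cols + n_value_cols:
            raise ParseError(
                f"line {ln}: expected {skip_cols + n_value_cols} columns, "
                f"got {len(parts)}"
            )
        ids.append(parts[id_col])
        try:
            rows.append([float(x) for x in parts[skip_cols:]])
        except ValueError as err:
            raise ParseError(f"line {ln}: non-numeric cell ({err})") from None
    return ids, np.asarray(rows, dtype=float)


def _finish_matrix(
    ids: list[str],
    values: np.ndarray,
    samples: list[str],
    controls: Optional[Sequence[str]],
    scale: str,
) -> ExpressionMatrix:
    seen: set = set()
    for g in ids:
        if g in seen:
            raise ParseError(f"duplicated gene id {g!r}")
        seen.add(g)
    df = pd.DataFrame(values, index=ids, columns=samples)
    flags = None
    if controls is not None:
        cset = set(controls)
        flags = pd.Series([g in cset for g in ids], index=df.index)
    return ExpressionMatrix(values=df, control_flags=flags, scale=scale)


def read_gct(
    path, controls: Optional[Sequence[str]] = None, scale: str = RAW
) -> ExpressionMatrix:
    """Read a GCT-dialect expression matrix.

    ``controls`` optionally lists control-probe ids; otherwise the
    ``NEG_`` prefix convention applies.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#1.2"):
        raise ParseError("line 1: missing GCT version line '#1.2'")
    try:
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError):
        raise ParseError("line 2: malformed GCT dimensions line") from None
    header = lines[2].rstrip("\n").split("\t")
    if header[:2] != ["Name", "Description"]:
        raise ParseError("line 3: GCT header must start with Name\\tDescription")
    samples = header[2:]
    if len(samples) != n_samples:
        raise ParseError(
            f"line 3: header lists {len(samples)} samples but the dimensions "
            f"line declares {n_samples}"
        )
    ids, values = _parse_body(lines, 3, n_samples, id_col=0, skip_cols=2)
    if len(ids) != n_genes:
        raise ParseError(
            f"line 2: dimensions line declares {n_genes} rows but the body "
            f"has {len(ids)}"
        )
    return _finish_matrix(ids, values, samples, controls, scale)


def write_gct(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for gene, row in matrix.values.iterrows():
            desc = "control" if matrix.control_flags[gene] else "na"
            fh.write(
                f"{gene}\t{desc}\t" + "\t".join(repr(float(v)) for v in row) + "\n"
            )


def read_tsv_matrix(
    path, controls: Optional[Sequence[str]] = None, scale: str = RAW
) -> ExpressionMatrix:
    """Read a plain TSV matrix (first column gene id, header row samples)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("line 1: empty file")
    header = lines[0].rstrip("\n").split("\t")
    samples = header[1:]
    ids, values = _parse_body(lines, 1, len(samples), id_col=0, skip_cols=1)
    return _finish_matrix(ids, values, samples, controls, scale)


def write_tsv_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(map(str, matrix.sample_ids)) + "\n")
        for gene, row in matrix.values.iterrows():
            fh.write(f"{gene}\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_expression(
    path, format: Optional[str] = None, controls=None, scale: str = RAW
) -> ExpressionMatrix:
    """Dispatch on ``format`` ('gct' or 'tsv'; inferred from the suffix)."""
    if format is None:
        format = "gct" if str(path).lower().endswith(".gct") else "tsv"
    if format == "gct":
        return read_gct(path, controls=controls, scale=scale)
    if format == "tsv":
        return read_tsv_matrix(path, controls=controls, scale=scale)
    raise ValidationError(f"unknown expression format {format!r}")


def write_expression(matrix: ExpressionMatrix, path, format: Optional[str] = None) -> None:
    if format is None:
        format = "gct" if str(path).lower().endswith(".gct") else "tsv"
    if format == "gct":
        write_gct(matrix, path)
    elif format == "tsv":
        write_tsv_matrix(matrix, path)
    else:
        raise ValidationError(f"unknown expression format {format!r}")


def read_counts(path, controls=None) -> CountMatrix:
    m = read_tsv_matrix(path, controls=controls)
    return CountMatrix(counts=m.values, control_flags=m.control_flags)


# --------------------------------------------------------------------------
# signatures
# --------------------------------------------------------------------------

_DN_SUFFIXES = ("_dn", "_down", "_DN")
_UP_SUFFIXES = ("_up", "_UP")


def read_gmt(path, name: Optional[str] = None) -> Signature:
    """Read a GMT-dialect signature: one line per class gene set.

    A set named ``<class>_dn`` (or ``_down``) contributes down-markers of
    ``<class>``; ``<class>_up`` or a bare name contributes up-markers.
    """
    entries: list[SignatureEntry] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(
                f"line {ln}: GMT line needs name, description and >= 1 gene"
            )
        set_name, genes = parts[0], parts[2:]
        direction = 1
        label = set_name
        for suf in _DN_SUFFIXES:
            if set_name.endswith(suf):
                direction, label = -1, set_name[: -len(suf)]
                break
        else:
            for suf in _UP_SUFFIXES:
                if set_name.endswith(suf):
                    label = set_name[: -len(suf)]
                    break
        for g in genes:
            if g:
                entries.append(
                    SignatureEntry(gene=g, label=label, weight=1.0, direction=direction)
                )
    return Signature(entries=entries, name=name or Path(path).stem)


def read_signature_tsv(path, name: Optional[str] = None) -> Signature:
    """Read a 4-column signature TSV: gene, class, weight, direction."""
    entries: list[SignatureEntry] = []
    lines = Path(path).read_text().splitlines()
    start = 0
    if lines and lines[0].lower().startswith("gene\t"):
        start = 1
    for ln, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ParseError(f"line {ln}: expected 4 columns, got {len(parts)}")
        try:
            entries.append(
                SignatureEntry(
                    gene=parts[0],
                    label=parts[1],
                    weight=float(parts[2]),
                    direction=int(parts[3]),
                )
            )
        except ValueError as err:
            raise ParseError(f"line {ln}: {err}") from None
    return Signature(entries=entries, name=name or Path(path).stem)


def read_signature(path, format: Optional[str] = None) -> Signature:
    if format is None:
        format = "gmt" if str(path).lower().endswith(".gmt") else "tsv4"
    if format == "gmt":
        return read_gmt(path)
    if format == "tsv4":
        return read_signature_tsv(path)
    raise ValidationError(f"unknown signature format {format!r}")


def write_signature_tsv(signature: Signature, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tclass\tweight\tdirection\n")
        for e in signature.entries:
            fh.write(f"{e.gene}\t{e.label}\t{e.weight!r}\t{e.direction}\n")


# --------------------------------------------------------------------------
# configuration / reports
# --------------------------------------------------------------------------

def read_yaml_config(path, cls):
    """Load a YAML mapping into a config dataclass, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError("config file must hold a YAML mapping")
    return cls.from_dict(data)


def write_yaml_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlabel\tseverity\n")
        for sid, lab in truth.sample_labels.items():
            fh.write(f"{sid}\t{lab}\t{truth.severity_per_sample[sid]!r}\n")
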