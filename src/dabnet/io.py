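"""Readers, writers and expression binarization.

Matrices travel as delimited text with element rows and sample columns, a
header row of sample labels and a leading column of element labels.  The
delimiter is sniffed (tab or comma) unless given.  Expression matrices hold
real log2 red/green ratios with explicit missing markers; the published
convention binarizes at zero (positive log-ratio = on) and drops whole
arrays that contain missing values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BinaryMatrix, NetworkModel, RelationshipKind

log = logging.getLogger("dabnet")

__all__ = [
    "ExpressionMatrix",
    "read_binary_matrix",
    "write_binary_matrix",
    "read_expression_matrix",
    "binarize_expression",
    "write_network",
]


@dataclass
class ExpressionMatrix:
    """Real-valued log-ratio expression with explicit missing values."""

    element_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float array, NaN marks missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.element_ids), len(self.sample_ids)):
            raise ValueError("label lengths do not match the value grid")


def _sniff_delimiter(path: str, override: str | None) -> str:
    if override:
        return override
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_binary_matrix(path: str, delimiter: str | None = None) -> BinaryMatrix:
    """Read and validate an element-by-sample 0/1 matrix."""
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-binary cell {values[i, j]!r} at element {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate element or sample labels")
    return BinaryMatrix([str(x) for x in df.index],
                        [str(c) for c in df.columns],
                        values.astype(np.int8))


def write_binary_matrix(matrix: BinaryMatrix, path: str,
                        delimiter: str = "\t") -> None:
    df = pd.DataFrame(matrix.values, index=matrix.element_ids,
                      columns=matrix.sample_ids)
    df.to_csv(path, sep=delimiter)


def read_expression_matrix(path: str, delimiter: str | None = None,
                           na_values=("", "NA", "NaN")) -> ExpressionMatrix:
    sep = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na_values))
    return ExpressionMatrix([str(x) for x in df.index],
                            [str(c) for c in df.columns],
                            df.to_numpy(dtype=float))


def binarize_expression(
    matrix: ExpressionMatrix,
    zero_is_on: bool = False,
    missing: str = "drop-sample",
) -> BinaryMatrix:
    """Binarize log-ratios at zero.

    Entries above zero become on (1), below zero off (0); an exact zero is
    off unless ``zero_is_on``.  Samples containing missing values are dropped
    (``missing="drop-sample"``, the published treatment) or the call fails
    (``missing="error"``).
    """
    values = matrix.values
    keep = ~np.isnan(values).any(axis=0)
    if not keep.all():
        dropped = [s for s, k in zip(matrix.sample_ids, keep) if not k]
        if missing == "error":
            raise ValueError(f"missing values in samples {dropped}")
        log.info("dropping %d sample(s) with missing values: %s",
                 len(dropped), dropped)
    values = values[:, keep]
    samples = [s for s, k in zip(matrix.sample_ids, keep) if k]
    if zero_is_on:
        binary = (values >= 0).astype(np.int8)
    else:
        binary = (values > 0).astype(np.int8)
    return BinaryMatrix(list(matrix.element_ids), samples, binary)


def write_network(model: NetworkModel, path: str, fmt: str = "tsv",
                  report: pd.DataFrame | None = None) -> None:
    """Write a called network as a TSV edge list, SIF, or DOT.

    SIF and DOT render the covering edges, with similarity as undirected
    edges; TSV lists every called relation.
    """
    rels = sorted(model.relations, key=lambda r: (r.a, r.b, r.kind.value))
    if fmt == "tsv":
        rows = []
        for r in rels:
            row = {"a": r.a, "b": r.b, "kind": r.kind.value}
            rows.append(row)
        pd.DataFrame(rows, columns=["a", "b", "kind"]).to_csv(
            path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for r in sorted(model.covering | _sim_edges(model),
                            key=lambda r: (r.a, r.b, r.kind.value)):
                fh.write(f"{r.a}\t{r.kind.value}\t{r.b}\n")
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("digraph dab {\n")
            for e in model.elements:
                fh.write(f'  "{e}";\n')
            for r in sorted(model.covering, key=lambda r: (r.a, r.b, r.kind.value)):
                style = "" if r.kind is RelationshipKind.F01 else \
                    f' [label="{r.kind.value}"]'
                # F01: a prerequisite of b, drawn a -> b
                a, b = (r.a, r.b) if r.kind is not RelationshipKind.F10 else (r.b, r.a)
                fh.write(f'  "{a}" -> "{b}"{style};\n')
            for r in sorted(_sim_edges(model), key=lambda r: (r.a, r.b)):
                fh.write(f'  "{r.a}" -> "{r.b}" [dir=none, style=dashed];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def _sim_edges(model: NetworkModel):
    return {r for r in model.relations if r.kind is RelationshipKind.SIM}
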