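"""Plain delimited-text I/O for expression matrices, gold standards and networks.

Everything is desk-scale and inspectable: TSV by default (comma accepted
by file extension or explicit ``sep``), one header row and one identifier
column for expression matrices, two-column edge lists for gold standards,
and networks as a weighted edge list plus a JSON metadata sidecar.  Gene
matching across files is always by identifier; positional matching is
refused.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GoldStandard, Network
from .exceptions import FormatError

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gold_standard",
    "write_gold_standard",
    "write_network",
    "read_network",
]

ORIENTATIONS = ("samples_by_genes", "genes_by_samples")


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_header_duplicates(path: Path, sep: str) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen, dup = set(), set()
    for h in header:
        if h in seen:
            dup.add(h)
        seen.add(h)
    if dup:
        raise FormatError(f"{path}: duplicate identifiers in header: {sorted(dup)}")


def read_expression_matrix(path, orientation: str = "samples_by_genes",
                           sep: str | None = None) -> ExpressionMatrix:
    """Load a delimited expression matrix, normalizing to samples x genes.

    ``orientation`` declares the layout of the FILE; the returned matrix
    is always samples x genes with gene identifiers preserved verbatim.
    Duplicate gene identifiers, non-numeric cells and missing values are
    format errors (with a row/column report for bad cells).
    """
    path = Path(path)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_sep(path, sep)
    _check_header_duplicates(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate identifiers in first column: {dup}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise FormatError(
            f"{path}: non-numeric cell at row '{df.index[r]}', column "
            f"'{df.columns[c]}': {df.iat[r, c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise FormatError(
            f"{path}: missing value at row '{df.index[r]}', column '{df.columns[c]}'"
        )
    if orientation == "genes_by_samples":
        numeric = numeric.T
    return ExpressionMatrix(
        values=numeric.values.astype(float),
        sample_ids=[str(s) for s in numeric.index],
        gene_ids=[str(g) for g in numeric.columns],
    )


def write_expression_matrix(em: ExpressionMatrix, path, sep: str | None = None) -> None:
    path = Path(path)
    sep = _infer_sep(path, sep)
    df = pd.DataFrame(em.values, index=em.sample_ids, columns=em.gene_ids)
    df.to_csv(path, sep=sep, index_label="sample")


def read_gold_standard(path, gene_universe: list[str],
                       sep: str | None = None) -> GoldStandard:
    """Load a two-column (tf, target) edge list restricted to known genes.

    Edges touching genes outside ``gene_universe`` are dropped and
    counted (``.n_dropped``); self-edges are dropped with a warning.  An
    optional ``tf<sep>target`` header line is tolerated.
    """
    path = Path(path)
    sep = _infer_sep(path, sep)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            if lineno == 1 and [p.lower() for p in parts] == ["tf", "target"]:
                continue
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise FormatError(f"{path}: empty gold-standard file")
    universe = set(gene_universe)
    edges: set[tuple[str, str]] = set()
    dropped = 0
    for tf, target in rows:
        if tf == target:
            warnings.warn(f"dropping self-edge ({tf}, {target})", stacklevel=2)
            dropped += 1
            continue
        if tf not in universe or target not in universe:
            dropped += 1
            continue
        edges.add((tf, target))
    tf_ids = sorted({tf for tf, _ in edges})
    return GoldStandard(tf_ids=tf_ids, edges=edges,
                        gene_universe=list(gene_universe), n_dropped=dropped)


def write_gold_standard(gold: GoldStandard, path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"tf{sep}target\n")
        for tf, target in sorted(gold.edges):
            fh.write(f"{tf}{sep}{target}\n")


def write_network(net: Network, path, sep: str = "\t") -> None:
    """Write retained edges plus a JSON metadata sidecar.

    The edge list has columns gene_a, gene_b, partial_correlation with
    gene_a < gene_b lexicographically and rows sorted, so output is
    byte-stable across runs.  The sidecar ``<path>.meta.json`` carries
    threshold, rho, edge count and the full gene list (needed to rebuild
    the matrices on read).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"gene_a{sep}gene_b{sep}partial_correlation\n")
        for a, b, w in net.edge_list():
            fh.write(f"{a}{sep}{b}{sep}{w!r}\n")
    meta = {
        "threshold_value": net.threshold_value,
        "rho": net.rho,
        "n_edges": net.n_edges,
        "gene_ids": net.gene_ids,
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_network(path, sep: str = "\t") -> Network:
    """Rebuild a Network from an edge list and its metadata sidecar.

    Only retained edges carry weights in the file, so the reconstructed
    weight matrix is zero off the retained support; adjacency round-trips
    exactly.
    """
    path = Path(path)
    with open(str(path) + ".meta.json") as fh:
        meta = json.load(fh)
    gene_ids = [str(g) for g in meta["gene_ids"]]
    index = {g: i for i, g in enumerate(gene_ids)}
    p = len(gene_ids)
    weights = np.zeros((p, p))
    adjacency = np.zeros((p, p), dtype=int)
    df = pd.read_csv(path, sep=sep)
    for _, row in df.iterrows():
        i, j = index[str(row["gene_a"])], index[str(row["gene_b"])]
        w = float(row["partial_correlation"])
        weights[i, j] = weights[j, i] = w
        adjacency[i, j] = adjacency[j, i] = 1
    return Network(gene_ids=gene_ids, weights=weights, adjacency=adjacency,
                   threshold_value=float(meta["threshold_value"]),
                   rho=meta.get("rho"))
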