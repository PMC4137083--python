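"""Readers and writers for the plain-text formats the pipeline speaks.

Everything is tab-separated text: evidence tables, 0/1 experiment matrices,
GMT gene-set collections, BED6 intervals, expression matrices and one-gene-
per-line curated lists.  Readers validate and raise :class:`DataError` with
enough context to find the offending line.
"""

from __future__ import annotations

import os
import tempfile
from collections.abc import Iterable, Mapping

import pandas as pd

from .errors import DataError

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def atomic_write(path: str, text: str) -> None:
    """Write *text* to *path* via a temp file + rename (no partial files)."""
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    atomic_write(path, df.to_csv(sep="\t", index=index))


# ---------------------------------------------------------------------------
# evidence table

def read_evidence(path: str) -> pd.DataFrame:
    """Read a per-pair evidence table (gene_a, gene_b, channel columns).

    Enforces canonical pair order (gene_a < gene_b), no self-pairs and no
    duplicate pairs; violations are data errors, not silently merged.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    except FileNotFoundError:
        raise DataError(f"evidence file not found: {path}") from None
    if list(df.columns[:2]) != ["gene_a", "gene_b"]:
        raise DataError(f"{path}: first columns must be gene_a, gene_b")
    if (df["gene_a"] == df["gene_b"]).any():
        g = df.loc[df["gene_a"] == df["gene_b"], "gene_a"].iloc[0]
        raise DataError(f"{path}: self-pair for gene {g}")
    bad = df["gene_a"] >= df["gene_b"]
    if bad.any():
        i = int(bad.idxmax())
        raise DataError(
            f"{path}: row {i + 2} not in canonical order "
            f"({df.at[i, 'gene_a']!r} >= {df.at[i, 'gene_b']!r})"
        )
    dup = df.duplicated(subset=["gene_a", "gene_b"])
    if dup.any():
        i = int(dup.idxmax())
        raise DataError(
            f"{path}: duplicate pair ({df.at[i, 'gene_a']}, {df.at[i, 'gene_b']})"
        )
    for c in df.columns[2:]:
        col = df[c].astype(float)
        if ((col < 0) | (col > 1)).any():
            raise DataError(f"{path}: channel {c!r} has scores outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into ``{term: (description, genes)}``."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT rows need term, desc, ≥1 gene")
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in sets:
                raise DataError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = (desc, frozenset(g for g in genes if g))
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str) -> None:
    lines = []
    for term in sorted(sets):
        desc, genes = sets[term]
        lines.append("\t".join([term, desc, *sorted(genes)]))
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED6

def read_bed6(path: str) -> pd.DataFrame:
    """Read BED6 (0-based half-open) with per-line validation."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise DataError(f"{path}:{lineno}: BED6 needs 6 fields")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
            if e <= s or s < 0:
                raise DataError(f"{path}:{lineno}: bad interval [{s}, {e})")
            if strand not in "+-":
                raise DataError(f"{path}:{lineno}: strand must be + or -")
            rows.append((chrom, s, e, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed6(df: pd.DataFrame, path: str) -> None:
    atomic_write(path, df[BED6_COLUMNS].to_csv(sep="\t", index=False, header=False))


# ---------------------------------------------------------------------------
# matrices and lists

def read_experiments(path: str) -> pd.DataFrame:
    """Read the gene × experiment 0/1 membership matrix (index = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise DataError(f"{path}: experiment flags must be 0/1")
    return df.astype(int)


def read_expression(path: str) -> pd.DataFrame:
    """Read a genes × conditions expression matrix (index = gene)."""
    return pd.read_csv(path, sep="\t", index_col=0).astype(float)


def read_gene_list(path: str) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_gene_list(genes: Iterable[str], path: str) -> None:
    atomic_write(path, "\n".join(sorted(genes)) + "\n")
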