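"""File dialects and pipeline configuration.

All genomic coordinates are 1-based inclusive on disk (GFF3 convention) and
are kept 1-based inclusive in memory; nothing in the toolkit needs half-open
arithmetic except interval-overlap tests, which handle it locally.

Readers validate eagerly and raise :class:`InputError` with the offending
line number; writers are atomic (temp file in the target directory, then
rename), so a failed run never leaves a partial output behind.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import pandas as pd
import yaml


class InputError(ValueError):
    """Malformed input file (bad column, coordinate, strand or Newick)."""


@dataclass
class PipelineConfig:
    """Every numeric threshold used by the pipeline, in one place.

    Defaults are the operating points of the analysis protocol this toolkit
    implements: profile hits are kept at PSI-BLAST e-value <= 1e-4; abundance
    counting requires >= 0.75 query coverage; protein clustering runs at a
    strict (0.9 identity / 0.9 coverage) and a permissive (0.5 / 0.33) level;
    profile footprints cluster at 0.7 identity; the profile dendrogram is cut
    at depth 0.8; profile merges must retain > 98% of member sequences and
    gain <= 10 new false positives; locus assembly takes 10 flanking genes
    per side; CRISPR arrays need a >= 20 bp direct repeat.
    """

    evalue_max: float = 1e-4
    abundance_min_cov: float = 0.75
    strict_id: float = 0.9
    strict_cov: float = 0.9
    permissive_id: float = 0.5
    permissive_cov: float = 0.33
    footprint_cluster_id: float = 0.7
    tree_depth_cut: float = 0.8
    merge_retention_min: float = 0.98
    merge_new_fp_max: int = 10
    flank_genes: int = 10
    min_repeat_len_bp: int = 20
    overlap_tolerance: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("abundance_min_cov", "strict_id", "strict_cov",
                     "permissive_id", "permissive_cov", "footprint_cluster_id",
                     "merge_retention_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("merge_new_fp_max", "flank_genes", "min_repeat_len_bp",
                     "overlap_tolerance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# atomic writing

def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write *text* to *path* via a temp file + rename in the same directory."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp_", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# gene tables (GFF3 subset)

GENE_COLUMNS = ["protein_id", "genome_id", "contig", "start", "end", "strand", "rank"]


def read_genes(path: str | os.PathLike, genome_id: str | None = None) -> pd.DataFrame:
    """Read a GFF3 subset (type=CDS rows; ID=... attribute) or a gene TSV.

    Returns a frame with GENE_COLUMNS, ranks assigned by start position per
    contig if the file does not carry them.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("protein_id"):
        df = pd.read_csv(path, sep="\t", dtype={"contig": str, "genome_id": str})
        missing = set(GENE_COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"{path}: missing columns {sorted(missing)}")
        _check_genes(df, path)
        return df[GENE_COLUMNS]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "CDS":
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise InputError(f"{path}:{lineno}: start > end")
            if strand not in "+-":
                raise InputError(f"{path}:{lineno}: strand must be + or -")
            attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if "ID" not in attr_map:
                raise InputError(f"{path}:{lineno}: CDS row lacks ID attribute")
            rows.append((attr_map["ID"], attr_map.get("genome_id", genome_id or ""),
                         seqid, start_i, end_i, strand))
    df = pd.DataFrame(rows, columns=["protein_id", "genome_id", "contig",
                                     "start", "end", "strand"])
    df = df.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
    df["rank"] = df.groupby("contig").cumcount() + 1
    return df[GENE_COLUMNS]


def _check_genes(df: pd.DataFrame, path: str) -> None:
    bad = df[df["start"] > df["end"]]
    if len(bad):
        raise InputError(f"{path}: start > end for protein {bad.iloc[0]['protein_id']}")
    if not df["strand"].isin(["+", "-"]).all():
        raise InputError(f"{path}: strand must be + or -")
    dup = df.duplicated(subset=["genome_id", "contig", "rank"])
    if dup.any():
        raise InputError(f"{path}: duplicate gene rank on a contig")


# ---------------------------------------------------------------------------
# profile-hit tables

HIT_COLUMNS = ["protein_id", "profile_id", "evalue", "bitscore", "qcov",
               "pstart", "pend"]


def read_hits(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(os.fspath(path), sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if (df["evalue"] < 0).any():
        raise InputError(f"{path}: negative e-value")
    if ((df["qcov"] < 0) | (df["qcov"] > 1)).any():
        raise InputError(f"{path}: qcov outside [0, 1]")
    if (df["pstart"] > df["pend"]).any():
        raise InputError(f"{path}: pstart > pend")
    return df[HIT_COLUMNS + [c for c in df.columns if c not in HIT_COLUMNS]]


# ---------------------------------------------------------------------------
# CRISPR array tables

ARRAY_COLUMNS = ["genome_id", "contig", "start", "end", "repeat_len", "n_spacers"]


def read_arrays(path: str | os.PathLike, min_repeat_len: int = 20) -> pd.DataFrame:
    """Read an array-call table, dropping repeats shorter than *min_repeat_len*."""
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={"contig": str, "genome_id": str})
    missing = set(ARRAY_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise InputError(f"{path}: array start > end")
    if (df["n_spacers"] < 1).any():
        raise InputError(f"{path}: array with no spacers")
    return df[df["repeat_len"] >= min_repeat_len].reset_index(drop=True)


# ---------------------------------------------------------------------------
# trees and matrices

def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=os.fspath(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise InputError(f"{path}: unparseable Newick ({exc})") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise InputError(f"{path}: duplicate leaf labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise InputError(f"{path}: negative branch length")
    return tree


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    atomic_write_text(path, tree.as_string(schema="newick",
                                           suppress_rooting=True))


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a labelled square matrix TSV (labels in first column and header)."""
    df = pd.read_csv(os.fspath(path), sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InputError(f"{path}: matrix rows and columns differ")
    return df


def write_matrix(df: pd.DataFrame, path: str | os.PathLike) -> None:
    atomic_write_text(path, df.to_csv(sep="\t"))


# ---------------------------------------------------------------------------
# locus / census reports

def write_loci(rows: Iterable[dict], path: str | os.PathLike) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    atomic_write_table(df, path)
    return df


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={"genome_id": str})
    if "genome_id" not in df.columns:
        raise InputError(f"{path}: metadata table needs a genome_id column")
    return df
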