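"""Annotation ingest and summary tables.

Consumes standard tabular artifacts produced upstream — protein-vs-COG
alignment hits (BLAST outfmt-6 style), ortholog pair lists from two
independent callers — and builds the per-category and per-length summaries
of CIB used downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: one-letter COG functional categories (2014 scheme)
COG_ALPHABET = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")


@dataclass(frozen=True)
class CategoryAssignment:
    """Gene to COG functional category letters (possibly several)."""

    gene_id: str
    categories: frozenset[str]

    def __post_init__(self):
        if not self.categories:
            raise ValueError(f"gene {self.gene_id!r}: empty category set")
        bad = set(self.categories) - COG_ALPHABET
        if bad:
            raise ValueError(f"gene {self.gene_id!r}: invalid COG letters {sorted(bad)}")


@dataclass
class OrthologPartition:
    """Genes split into conserved (paired) and strain-unique sets."""

    conserved_pairs: set[tuple[str, str]]
    unique_a: set[str]
    unique_b: set[str]


def _parse_hit_row(fields: Sequence[str], row_num: int) -> dict:
    """Parse one outfmt-6 row (12 columns, or 14 with qlen/slen appended)."""
    if len(fields) not in (12, 14):
        raise ValueError(
            f"row {row_num}: expected 12 or 14 tab-separated columns, got {len(fields)}"
        )
    try:
        rec = {
            "query": fields[0],
            "subject": fields[1],
            "identity": float(fields[2]),
            "evalue": float(fields[10]),
        }
        if len(fields) == 14:
            rec["qlen"] = float(fields[12])
            rec["slen"] = float(fields[13])
    except ValueError as exc:
        raise ValueError(f"row {row_num}: malformed numeric field ({exc})") from None
    return rec


def filter_cog_hits(hits: Iterable[Sequence[str] | str],
                    max_evalue: float = 1e-5,
                    min_identity: float = 40.0,
                    min_length_fraction: float | None = None,
                    cog_categories: Mapping[str, str] | None = None,
                    ) -> list[CategoryAssignment]:
    """Assign COG categories from tabular alignment hits with cutoffs.

    Keeps rows with e-value <= ``max_evalue`` and percent identity >=
    ``min_identity``; when ``min_length_fraction`` is set (metagenome mode,
    0.90 in the study design) additionally requires
    query length >= fraction * hit length, which needs the 14-column input.
    Surviving hits are mapped to category letters via ``cog_categories``
    (subject id -> letters such as ``"O,C"``); without a map the subject
    field itself is taken as the letters. Categories are unioned per gene
    across surviving hits.
    """
    per_gene: dict[str, set[str]] = {}
    for row_num, row in enumerate(hits, start=1):
        if isinstance(row, str):
            row = row.rstrip("\n")
            if not row or row.startswith("#"):
                continue
            fields = row.split("\t")
        else:
            fields = list(row)
        rec = _parse_hit_row(fields, row_num)
        if rec["evalue"] > max_evalue or rec["identity"] < min_identity:
            continue
        if min_length_fraction is not None:
            if "qlen" not in rec:
                raise ValueError(
                    f"row {row_num}: length filter requires the 14-column "
                    "format with query/subject lengths"
                )
            if rec["qlen"] < min_length_fraction * rec["slen"]:
                continue
        letters_src = (
            cog_categories.get(rec["subject"], "") if cog_categories is not None
            else rec["subject"]
        )
        letters = {ch for ch in letters_src if ch.isalpha()}
        if not letters:
            logger.warning("row %d: no category letters for subject %s",
                           row_num, rec["subject"])
            continue
        per_gene.setdefault(rec["query"], set()).update(letters)
    return [
        CategoryAssignment(gene_id=g, categories=frozenset(cats))
        for g, cats in sorted(per_gene.items())
    ]


def _norm_pair(pair: Sequence[str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def intersect_ortholog_calls(pairs_tool1: Iterable[Sequence[str]],
                             pairs_tool2: Iterable[Sequence[str]],
                             ) -> list[tuple[str, str]]:
    """Keep only gene pairs called orthologous by both tools.

    Pairs are unordered; the result is order-normalized and sorted.
    """
    s1 = {_norm_pair(p) for p in pairs_tool1}
    s2 = {_norm_pair(p) for p in pairs_tool2}
    return sorted(s1 & s2)


def partition_conserved_unique(genes_a: Iterable[str], genes_b: Iterable[str],
                               pairs: Iterable[Sequence[str]],
                               ) -> OrthologPartition:
    """Split two strains' genes into conserved (in any ortholog pair) and unique."""
    genes_a = set(genes_a)
    genes_b = set(genes_b)
    kept = set()
    in_pair_a: set[str] = set()
    in_pair_b: set[str] = set()
    for p in pairs:
        a, b = p
        if a in genes_b and b in genes_a and not (a in genes_a and b in genes_b):
            a, b = b, a
        if a not in genes_a or b not in genes_b:
            raise ValueError(f"pair ({a}, {b}) references unknown gene ids")
        kept.add((a, b))
        in_pair_a.add(a)
        in_pair_b.add(b)
    return OrthologPartition(
        conserved_pairs=kept,
        unique_a=genes_a - in_pair_a,
        unique_b=genes_b - in_pair_b,
    )


def category_means(cib_table: pd.DataFrame,
                   assignments: Sequence[CategoryAssignment],
                   groups: Mapping[str, str],
                   per_species: Mapping[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean CIB per (group, COG category) with gene counts.

    A gene assigned several category letters contributes its CIB to each.
    By default the mean is pooled over all genes of the group; passing
    ``per_species`` (gene id -> species) instead averages per-species means
    within each group. Cells with no genes are NaN (empty), never 0. Genes
    in ``assignments`` missing from ``cib_table`` or with undefined CIB are
    logged and skipped.

    Returns ``(means, counts)`` DataFrames indexed by group with category
    columns.
    """
    cib_by_gene = cib_table.set_index("gene_id")["cib"]
    records = []
    n_missing = n_undefined = 0
    for a in assignments:
        if a.gene_id not in cib_by_gene.index:
            n_missing += 1
            continue
        value = cib_by_gene[a.gene_id]
        if isinstance(value, pd.Series):  # duplicated gene id
            value = value.iloc[0]
        if math.isnan(value):
            n_undefined += 1
            continue
        group = groups.get(a.gene_id)
        if group is None:
            n_missing += 1
            continue
        for cat in a.categories:
            rec = {"group": group, "category": cat, "cib": value}
            if per_species is not None:
                rec["species"] = per_species.get(a.gene_id, group)
            records.append(rec)
    if n_missing:
        logger.info("category_means: %d assignments without CIB/group skipped", n_missing)
    if n_undefined:
        logger.info("category_means: %d genes with undefined CIB skipped", n_undefined)
    if not records:
        empty = pd.DataFrame()
        return empty, empty
    df = pd.DataFrame(records)
    if per_species is None:
        means = df.pivot_table(index="group", columns="category", values="cib",
                               aggfunc="mean")
    else:
        by_species = df.groupby(["group", "species", "category"])["cib"].mean().reset_index()
        means = by_species.pivot_table(index="group", columns="category",
                                       values="cib", aggfunc="mean")
    counts = df.pivot_table(index="group", columns="category", values="cib",
                            aggfunc="count").fillna(0).astype(int)
    means.columns.name = None
    counts.columns.name = None
    return means, counts


def bin_by_length(cib_table: pd.DataFrame, width: int = 500,
                  group: str = "all") -> pd.DataFrame:
    """Mean CIB per gene-length bin.

    A gene of length L bases falls in the half-open bin (l - width, l]
    with l = width * ceil(L / width); genes with undefined CIB are
    excluded. Returns columns ``bin_upper, mean_cib, n_genes, group``,
    only for non-empty bins.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    defined = cib_table.dropna(subset=["cib"])
    if defined.empty:
        return pd.DataFrame(columns=["bin_upper", "mean_cib", "n_genes", "group"])
    upper = (np.ceil(defined["length_nt"] / width) * width).astype(int)
    out = (
        defined.assign(bin_upper=upper)
        .groupby("bin_upper")["cib"]
        .agg(mean_cib="mean", n_genes="count")
        .reset_index()
    )
    out["group"] = group
    return out


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV of gene-id pairs (``#`` lines skipped)."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path} row {i}: expected 2 columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_mapping_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV as an ordered gene -> label mapping."""
    mapping = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path} row {i}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping
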