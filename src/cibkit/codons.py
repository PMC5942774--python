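"""Genetic-code bookkeeping and in-frame codon counting for CDS input.

Sequences are treated as given in reading frame (CDS convention, frame
starting at the first base); no ORF detection is attempted. Counting is
strand-naive and case-insensitive.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

SUPPORTED_TABLES = frozenset({1, 11})

#: warning flags attached to CodonCounts
W_PARTIAL = "partial-codon-dropped"
W_AMBIGUOUS = "ambiguous-codon-skipped"
W_INTERNAL_STOP = "internal-stop"


class UnsupportedTableError(ValueError):
    """Raised for a translation-table id outside the supported set."""


@dataclass(frozen=True)
class GeneticCode:
    """A complete DNA codon table with synonymous-family bookkeeping.

    Attributes
    ----------
    table_id : int
        NCBI translation-table identifier.
    codon_to_aa : dict
        Maps each of the 64 DNA triplets to a one-letter amino acid, or
        ``"*"`` for stops.
    degeneracy : dict
        ``n(a)``: number of sense codons per amino acid.
    stops : frozenset
        The stop triplets.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    degeneracy: dict[str, int]
    stops: frozenset[str]

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in sorted(self.codon_to_aa) if c not in self.stops)

    def family(self, aa: str) -> tuple[str, ...]:
        """Sense codons coding for amino acid ``aa``, sorted."""
        return tuple(
            c for c in sorted(self.codon_to_aa)
            if c not in self.stops and self.codon_to_aa[c] == aa
        )

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.degeneracy))


def load_genetic_code(table_id: int = 11) -> GeneticCode:
    """Load a validated genetic code by NCBI translation-table id.

    Only tables 1 (standard) and 11 (bacterial/archaeal/plastid) are
    supported; their sense-codon degeneracy structure is identical, so CIB
    is the same under either.
    """
    if table_id not in SUPPORTED_TABLES:
        raise UnsupportedTableError(
            f"translation table {table_id} not supported; choose one of "
            f"{sorted(SUPPORTED_TABLES)}"
        )
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    for stop in stops:
        codon_to_aa[stop] = "*"
    if len(codon_to_aa) != 64:
        raise AssertionError("incomplete codon table")
    degeneracy = Counter(aa for c, aa in codon_to_aa.items() if c not in stops)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        degeneracy=dict(degeneracy),
        stops=stops,
    )


@dataclass
class CodonCounts:
    """Per-gene sense-codon counts with derived amino-acid counts."""

    gene_id: str
    counts: dict[str, int]
    aa_counts: dict[str, int]
    n_codons: int
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_codon_counts(cls, gene_id: str, counts: dict[str, int],
                          code: GeneticCode, warnings: list[str] | None = None
                          ) -> "CodonCounts":
        """Build from a raw codon->count map, deriving aa_counts."""
        aa_counts: Counter[str] = Counter()
        for codon, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for codon {codon}")
            aa = code.codon_to_aa.get(codon)
            if aa is None or codon in code.stops:
                raise ValueError(f"{codon!r} is not a sense codon of table {code.table_id}")
            aa_counts[aa] += n
        return cls(
            gene_id=gene_id,
            counts={c: n for c, n in counts.items() if n > 0},
            aa_counts=dict(aa_counts),
            n_codons=sum(counts.values()),
            warnings=list(warnings or []),
        )


_VALID_BASES = frozenset("ACGT")


def count_codons(sequence: str, code: GeneticCode,
                 drop_terminal_stop: bool = True,
                 gene_id: str = "") -> CodonCounts:
    """Count every complete in-frame sense codon of a CDS.

    A terminal stop codon is excluded when ``drop_terminal_stop`` is set;
    internal stops are flagged but not counted (draft genomes contain
    pseudogenes and we do not abort on them). Codons containing non-ACGT
    characters are skipped and flagged rather than imputed, so codon
    frequencies stay true empirical frequencies. A trailing partial codon
    is dropped and flagged.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("U", "T")
    warnings: list[str] = []
    n_full = len(seq) // 3
    if len(seq) % 3 != 0:
        warnings.append(W_PARTIAL)
    codons = [seq[3 * i:3 * i + 3] for i in range(n_full)]
    if drop_terminal_stop and codons and codons[-1] in code.stops:
        codons.pop()
    counts: Counter[str] = Counter()
    for i, codon in enumerate(codons):
        if not _VALID_BASES.issuperset(codon):
            if W_AMBIGUOUS not in warnings:
                warnings.append(W_AMBIGUOUS)
            continue
        if codon in code.stops:
            if W_INTERNAL_STOP not in warnings:
                warnings.append(W_INTERNAL_STOP)
            continue
        counts[codon] += 1
    return CodonCounts.from_codon_counts(gene_id, dict(counts), code, warnings)


def read_cds_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream ``(gene_id, sequence)`` pairs from a FASTA file (plain or gzip).

    The gene id is the first whitespace-delimited token of the header.
    Raises ``ValueError`` on malformed input (content before the first
    header); an empty file yields an empty stream with a logged warning.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        first = handle.read(1)
        if first == "":
            logger.warning("empty FASTA file: %s", path)
            return
        if first != ">":
            raise ValueError(f"malformed FASTA {path}: does not start with '>'")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            if not record.id:
                raise ValueError(f"malformed FASTA {path}: record with empty header")
            yield record.id, str(record.seq)


def iter_counts(records: Iterable[tuple[str, str]], code: GeneticCode,
                drop_terminal_stop: bool = True) -> Iterator[tuple[CodonCounts, int]]:
    """Yield ``(CodonCounts, raw length in nt)`` for each record."""
    for gene_id, seq in records:
        yield count_codons(seq, code, drop_terminal_stop, gene_id=gene_id), len(seq)
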