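"""The codon information bias (CIB) statistic.

CIB is a rescaled Kullback-Leibler divergence of the observed synonymous
codon usage from equal usage within each amino acid's codon family:

    numerator   = sum_a p(a) * (log n(a) - H_a)
    denominator = sum_a p(a) * log n(a)
    CIB         = numerator / denominator

with p(a) the amino-acid relative frequency among counted codons, n(a) the
synonymous-family size and H_a = -sum_{c in a} q(c|a) log q(c|a) the
conditional entropy of codon usage within family a. Natural logarithms are
used internally; the log base cancels in the ratio.

CIB = 0 iff codons within every family are used equally often; CIB = 1 iff
every amino acid present uses exactly one codon (and at least one present
amino acid is degenerate). Genes composed only of single-codon amino acids
(Met/Trp in the standard and bacterial codes) have denominator 0 and an
undefined CIB, flagged rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from cibkit.codons import CodonCounts, GeneticCode, count_codons

UNDEFINED_FLAG = "undefined-cib"


@dataclass
class CibValue:
    """Per-gene CIB with its components.

    ``cib`` is NaN when the denominator is zero (gene contains only
    non-degenerate amino acids); such rows carry ``undefined-cib`` in
    ``flags``.
    """

    gene_id: str
    cib: float
    numerator: float
    denominator: float
    length_nt: int
    n_codons: int
    flags: list[str]

    @property
    def defined(self) -> bool:
        return not math.isnan(self.cib)


def cib_components(counts: CodonCounts, code: GeneticCode) -> tuple[float, float]:
    """Return ``(numerator, denominator)`` of CIB for one gene.

    Amino acids absent from the gene contribute nothing (their p(a) = 0);
    0*log 0 is taken as 0; single-codon families contribute 0 to both sums.
    """
    if counts.n_codons == 0:
        raise ValueError(f"gene {counts.gene_id!r}: no sense codons counted")
    total = counts.n_codons
    numerator = 0.0
    denominator = 0.0
    for aa, aa_count in counts.aa_counts.items():
        if aa_count == 0:
            continue
        n_a = code.degeneracy[aa]
        if n_a == 1:
            continue
        p_a = aa_count / total
        h_a = 0.0
        for codon in code.family(aa):
            c = counts.counts.get(codon, 0)
            if c > 0:
                q = c / aa_count
                h_a -= q * math.log(q)
        log_n = math.log(n_a)
        numerator += p_a * (log_n - h_a)
        denominator += p_a * log_n
    # clamp tiny negative rounding residue from the entropy sum
    return max(numerator, 0.0), denominator


def cib(counts: CodonCounts, code: GeneticCode, length_nt: int | None = None) -> CibValue:
    """Compute the rescaled CIB in [0, 1] for one gene."""
    numerator, denominator = cib_components(counts, code)
    flags = list(counts.warnings)
    if denominator > 0.0:
        value = numerator / denominator
    else:
        value = float("nan")
        flags.append(UNDEFINED_FLAG)
    return CibValue(
        gene_id=counts.gene_id,
        cib=value,
        numerator=numerator,
        denominator=denominator,
        length_nt=length_nt if length_nt is not None else 3 * counts.n_codons,
        n_codons=counts.n_codons,
        flags=flags,
    )


def cib_table(records: Iterable[tuple[str, str]], code: GeneticCode,
              drop_terminal_stop: bool = True) -> pd.DataFrame:
    """Compute CIB for a stream of ``(gene_id, sequence)`` records.

    Returns one row per gene in input order with columns
    ``gene_id, cib, numerator, denominator, length_nt, n_codons, flags``.
    Undefined-CIB rows are retained (cib = NaN) and flagged.
    """
    rows = []
    for gene_id, seq in records:
        counts = count_codons(seq, code, drop_terminal_stop, gene_id=gene_id)
        value = cib(counts, code, length_nt=len(seq))
        rows.append(
            (value.gene_id, value.cib, value.numerator, value.denominator,
             value.length_nt, value.n_codons, ",".join(value.flags))
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cib", "numerator", "denominator",
                 "length_nt", "n_codons", "flags"],
    )


def population_cib(p_aa: Mapping[str, float],
                   q_cond: Mapping[str, Mapping[str, float]],
                   code: GeneticCode,
                   tol: float = 1e-9) -> float:
    """CIB of a population model (exact distributions, not counts).

    ``p_aa`` is an amino-acid distribution and ``q_cond[a]`` a distribution
    over a's codons. This equals the large-sample limit of the per-gene CIB
    on sequences drawn from the model. Returns NaN when no degenerate amino
    acid has positive probability.
    """
    s = sum(p_aa.values())
    if abs(s - 1.0) > tol:
        raise ValueError(f"p_aa sums to {s}, expected 1")
    numerator = 0.0
    denominator = 0.0
    for aa, p_a in p_aa.items():
        if p_a < 0:
            raise ValueError(f"negative probability for amino acid {aa}")
        if p_a == 0:
            continue
        n_a = code.degeneracy[aa]
        if n_a == 1:
            continue
        q = q_cond[aa]
        family = code.family(aa)
        sq = sum(q.get(c, 0.0) for c in family)
        if abs(sq - 1.0) > tol:
            raise ValueError(f"q_cond[{aa}] sums to {sq}, expected 1")
        h_a = -sum(
            q[c] * math.log(q[c]) for c in family if q.get(c, 0.0) > 0.0
        )
        log_n = math.log(n_a)
        numerator += p_a * (log_n - h_a)
        denominator += p_a * log_n
    if denominator == 0.0:
        return float("nan")
    return max(numerator, 0.0) / denominator


def write_cib_tsv(table: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    """Write a CIB table as TSV with fixed 6-decimal formatting.

    ``header_lines`` are emitted first, each prefixed with ``#``.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out = table.copy()
        for col in ("cib", "numerator", "denominator"):
            out[col] = out[col].map(lambda v: f"{v:.6f}")
        out.to_csv(fh, sep="\t", index=False)
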