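"""Within-pool diversity statistics: per-gene π, Nei–Gojobori πN/πS,
Ts/Tv and SNP-count correlates.

Synonymous and nonsynonymous *site* counts follow the Nei–Gojobori
convention: every codon position contributes fractional synonymous sites
equal to the fraction of its three possible single-base changes that
preserve the amino acid; mutations creating stop codons count as
nonsynonymous, and reference stop codons are excluded from gene totals.
Per-site diversity uses the pooled unbiased estimator
2·p̂·(1−p̂)·n/(n−1) on the estimated minor-allele frequency p̂ with
n pool chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .caller import CallSet, SnpCall
from .io import BASES, GeneModel

__all__ = [
    "DiversityStats",
    "ng_site_counts",
    "classify_snp_effect",
    "substitution_effect",
    "site_pi",
    "gene_diversity",
    "ts_tv",
    "snp_count_correlates",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)


def _aa(codon: str) -> str | None:
    """Amino acid for a codon under the standard code; None for stops."""
    if codon in _STOPS:
        return None
    return _STANDARD.forward_table[codon]


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori (nonsynonymous, synonymous) site counts for one codon.

    Each of the nine single-base mutants contributes 1/3 of a site to the
    synonymous total if it preserves the amino acid, otherwise to the
    nonsynonymous total; changes to stop codons are nonsynonymous.
    Raises for ambiguous bases; stop codons raise and must be excluded
    upstream.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"codon must be 3 unambiguous bases, got {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon} has no Nei-Gojobori site counts")
    aa = _aa(codon)
    s_sites = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if _aa(mutant) == aa:  # stops give None, never equal
                s_sites += 1.0 / 3.0
    return 3.0 - s_sites, s_sites


def substitution_effect(cds_seq: str, cds_index: int, new_base: str) -> str:
    """Effect of replacing the base at a 0-based CDS index: ``synonymous``
    or ``nonsynonymous`` (stop gain/loss counts as nonsynonymous)."""
    codon_start = (cds_index // 3) * 3
    codon = cds_seq[codon_start : codon_start + 3].upper()
    if len(codon) != 3:
        raise ValueError("CDS index beyond the last complete codon")
    offset = cds_index - codon_start
    mutant = codon[:offset] + new_base.upper() + codon[offset + 1 :]
    if codon == mutant:
        raise ValueError("substitution does not change the base")
    if codon in _STOPS or mutant in _STOPS:
        if codon in _STOPS and mutant in _STOPS:
            return "synonymous"
        return "nonsynonymous"
    return "synonymous" if _aa(codon) == _aa(mutant) else "nonsynonymous"


def classify_snp_effect(
    call: SnpCall, gene: GeneModel, reference: Mapping[str, str]
) -> str:
    """Classify a call as synonymous / nonsynonymous / non-coding against
    a gene model.

    Positions outside the CDS are non-coding.  Minus-strand genes are
    evaluated on the reverse complement; the codon context is the
    reference codon with the single substituted base.  If two SNPs fall
    in one codon each is classified against the reference background
    (and the caller of this function sees a warning from
    :func:`gene_diversity`).
    """
    idx = gene.genomic_to_cds(call.pos)
    if idx is None:
        return "non-coding"
    if not gene.usable_for_codons:
        raise ValueError(f"gene {gene.gene_id}: CDS frame broken, cannot classify")
    cds = gene.cds_sequence(reference[gene.contig])
    alt = call.alt_allele
    if gene.strand == "-":
        alt = _COMPLEMENT[alt]
    idx -= gene.phase
    if idx < 0:
        return "non-coding"  # within the phase overhang, no complete codon
    return substitution_effect(cds[gene.phase :], idx, alt)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def site_pi(p_hat: float, pool_n: int, unbiased: bool = True) -> float:
    """Per-site nucleotide diversity from a pooled allele frequency:
    2·p̂·(1−p̂), with the n/(n−1) small-pool correction by default."""
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if pool_n < 2:
        raise ValueError("pool_n must be >= 2")
    pi = 2.0 * p_hat * (1.0 - p_hat)
    if unbiased:
        pi *= pool_n / (pool_n - 1)
    return pi


@dataclass(frozen=True)
class DiversityStats:
    """Per-gene diversity summary (one row of the per-gene report)."""

    gene_id: str
    n_snps: int
    pi_per_gene: float
    piN: float
    piS: float
    N_sites: float
    S_sites: float
    n_nonsyn: int
    n_syn: int
    ts: int
    tv: int

    @property
    def piN_piS(self) -> float | None:
        """πN/πS; 0 when πN = 0 with πS > 0; None (undefined) when πS = 0."""
        if self.piS == 0.0:
            return None
        return self.piN / self.piS


def gene_diversity(
    gene: GeneModel,
    calls: CallSet | Iterable[SnpCall],
    reference: Mapping[str, str],
    pool_n: int = 20,
    unbiased: bool = True,
) -> DiversityStats:
    """π, πN and πS for one gene from a call set.

    πN and πS sum per-site diversity over nonsynonymous / synonymous
    SNPs and divide by the Nei–Gojobori nonsynonymous / synonymous site
    totals of the CDS; π per gene divides the sum over all CDS SNPs by
    the CDS length.  Non-coding calls on the gene's contig are ignored.
    """
    if gene.cds_length == 0:
        raise ValueError(f"gene {gene.gene_id} has zero-length CDS")
    if not gene.usable_for_codons:
        raise ValueError(f"gene {gene.gene_id}: CDS frame broken")
    cds = gene.cds_sequence(reference[gene.contig])[gene.phase :]
    n_sites = s_sites = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            continue  # reference stop codons excluded from totals
        n, s = ng_site_counts(codon)
        n_sites += n
        s_sites += s

    gene_calls = [
        c for c in calls if c.contig == gene.contig and gene.genomic_to_cds(c.pos) is not None
    ]
    codon_seen: dict[int, int] = {}
    pi_sum = piN_sum = piS_sum = 0.0
    n_nonsyn = n_syn = ts = tv = 0
    for c in gene_calls:
        idx = gene.genomic_to_cds(c.pos) - gene.phase
        if idx < 0:
            continue
        ci = idx // 3
        codon_seen[ci] = codon_seen.get(ci, 0) + 1
        effect = classify_snp_effect(c, gene, reference)
        pi = site_pi(c.p_hat, pool_n, unbiased)
        pi_sum += pi
        if effect == "nonsynonymous":
            piN_sum += pi
            n_nonsyn += 1
        elif effect == "synonymous":
            piS_sum += pi
            n_syn += 1
        if _is_transition(c.ref_base, c.alt_allele):
            ts += 1
        else:
            tv += 1
    multi = [ci for ci, n in codon_seen.items() if n > 1]
    if multi:
        warnings.warn(
            f"gene {gene.gene_id}: {len(multi)} codon(s) carry more than one SNP; "
            "each classified against the reference codon background",
            stacklevel=2,
        )
    return DiversityStats(
        gene_id=gene.gene_id,
        n_snps=len(gene_calls),
        pi_per_gene=pi_sum / gene.cds_length,
        piN=piN_sum / n_sites if n_sites else 0.0,
        piS=piS_sum / s_sites if s_sites else 0.0,
        N_sites=n_sites,
        S_sites=s_sites,
        n_nonsyn=n_nonsyn,
        n_syn=n_syn,
        ts=ts,
        tv=tv,
    )


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def ts_tv(calls: CallSet | Iterable[SnpCall]) -> float | None:
    """Transition/transversion ratio over reference→alternate pairs;
    None (undefined) when there are no transversions."""
    ts = tv = 0
    for c in calls:
        if _is_transition(c.ref_base, c.alt_allele):
            ts += 1
        else:
            tv += 1
    return ts / tv if tv else None


def snp_count_correlates(
    n_snps: Sequence[int],
    lengths: Sequence[int],
    mean_depths: Sequence[float],
) -> tuple[float | None, float | None]:
    """Pearson r of per-gene SNP count against gene length and against
    mean coverage depth; None where an input vector has zero variance."""
    n_snps = np.asarray(n_snps, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    mean_depths = np.asarray(mean_depths, dtype=float)
    if len(n_snps) < 3:
        raise ValueError("need at least 3 genes")

    def r(x, y) -> float | None:
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            return None
        return float(stats.pearsonr(x, y).statistic)

    return r(n_snps, lengths), r(n_snps, mean_depths)
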