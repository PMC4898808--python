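"""Folded site-frequency spectra from pooled minor-allele frequencies.

With ancestral states unknown, each SNP is binned by its minor-allele
copy number out of the pool's chromosomes and the spectrum is folded
onto classes 1..n/2 (for a pool of 20 chromosomes, class 10 is a
frequency of one half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .caller import SnpCall, copy_class

__all__ = ["FoldedSFS", "assign_frequency_class", "build_folded_sfs", "compare_sfs"]


def assign_frequency_class(p_hat: float, pool_n: int) -> int:
    """Folded copy class of a pooled frequency: the raw class
    clamp(round(p̂·n), 1, n−1) folded to min(k, n−k)."""
    if not 0.0 < p_hat < 1.0:
        raise ValueError(f"p_hat must lie strictly in (0, 1), got {p_hat}")
    k0 = copy_class(p_hat, pool_n)
    return min(k0, pool_n - k0)


@dataclass(frozen=True)
class FoldedSFS:
    """Absolute counts per folded minor-allele copy class 1..pool_n/2."""

    pool_n: int
    counts: tuple[int, ...]  # index 0 ↔ class 1

    def __post_init__(self) -> None:
        if self.pool_n < 2 or self.pool_n % 2:
            raise ValueError("pool_n must be an even number >= 2")
        if len(self.counts) != self.pool_n // 2:
            raise ValueError(
                f"need {self.pool_n // 2} classes, got {len(self.counts)}"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def classes(self) -> range:
        return range(1, self.pool_n // 2 + 1)

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def relative(self) -> tuple[float, ...] | None:
        """Counts normalised to sum 1; None (undefined) for an empty
        spectrum."""
        t = self.total
        if t == 0:
            return None
        return tuple(c / t for c in self.counts)

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self.classes, self.counts))


def build_folded_sfs(
    calls: Iterable[SnpCall], pool_n: int = 20, per_gene: bool = False
) -> FoldedSFS | tuple[FoldedSFS, Mapping[str, FoldedSFS]]:
    """Fold a call set into a spectrum over classes 1..pool_n/2.

    With ``per_gene=True`` also returns one spectrum per contig (the
    synthetic references place one gene per contig, so contig stands for
    gene).
    """
    half = pool_n // 2
    counts = [0] * half
    per: dict[str, list[int]] = {}
    for c in calls:
        k = assign_frequency_class(c.p_hat, pool_n)
        counts[k - 1] += 1
        if per_gene:
            per.setdefault(c.contig, [0] * half)[k - 1] += 1
    sfs = FoldedSFS(pool_n=pool_n, counts=tuple(counts))
    if per_gene:
        return sfs, {g: FoldedSFS(pool_n=pool_n, counts=tuple(v)) for g, v in per.items()}
    return sfs


def compare_sfs(a: FoldedSFS, b: FoldedSFS) -> float | None:
    """Pearson correlation of two relative spectra over classes
    1..pool_n/2; None (undefined) when either spectrum has zero
    variance or no SNPs."""
    if a.pool_n != b.pool_n:
        raise ValueError("spectra have different pool sizes")
    ra, rb = a.relative, b.relative
    if ra is None or rb is None:
        return None
    ra, rb = np.asarray(ra), np.asarray(rb)
    if np.std(ra) == 0.0 or np.std(rb) == 0.0:
        return None
    return float(stats.pearsonr(ra, rb).statistic)
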