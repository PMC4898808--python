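"""SNP detection from pooled per-site counts.

A site is called polymorphic when its depth reaches ``min_cov`` and the
second-most-frequent base is seen at least ``min_count`` times — the
count/coverage rule under which, at depth 30 and minimum count 6, minor
alleles at 4 of 20 pool chromosomes are still detectable in expectation.
Sites close to indel evidence and sites in the extreme upper tail of the
per-contig depth distribution (enrichment/PCR artefacts) are masked
before calling.  Independent call sets can be intersected, and any call
set scored against a truth table restricted to a validated region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .io import SiteCounts

__all__ = [
    "CallerParams",
    "SnpCall",
    "CallSet",
    "NoCall",
    "call_site",
    "call_pileup",
    "copy_class",
    "detectability_threshold",
    "DetectabilityResult",
    "filter_fixed_differences",
    "intersect_callsets",
    "validate_against_truth",
    "ValidationReport",
]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the pooled caller.

    min_cov: minimum depth for a site to be considered.
    min_count: minimum read count of the second-most-frequent base.
    pool_n: chromosomes in the pool (10 diploid plants → 20).
    indel_window: bp radius around indel evidence to exclude.
    max_cov_quantile: per-contig depth quantile above which sites are
        excluded (likely PCR/enrichment bias).
    """

    min_cov: int = 30
    min_count: int = 6
    pool_n: int = 20
    indel_window: int = 5
    max_cov_quantile: float = 0.98

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.pool_n < 2 or self.pool_n % 2:
            raise ValueError("pool_n must be an even number >= 2")
        if not 0.0 < self.max_cov_quantile <= 1.0:
            raise ValueError("max_cov_quantile must lie in (0, 1]")
        if self.indel_window < 0:
            raise ValueError("indel_window must be >= 0")


def copy_class(p_hat: float, pool_n: int) -> int:
    """Minor-allele copy number out of ``pool_n`` chromosomes implied by a
    pooled frequency: round half-up, clamped to 1..pool_n−1 (a called SNP
    is segregating by definition, so class 0 promotes to 1)."""
    k0 = int(math.floor(p_hat * pool_n + 0.5))
    return max(1, min(pool_n - 1, k0))


@dataclass(frozen=True)
class SnpCall:
    """A detected polymorphism with its pooled minor-allele frequency.

    The minor allele is the second-most-frequent base at the site; the
    alternate allele (vs the reference) is whichever of major/minor
    differs from the reference base.
    """

    contig: str
    pos: int
    ref_base: str
    major_allele: str
    minor_allele: str
    minor_count: int
    depth: int
    pool_n: int = 20

    @property
    def p_hat(self) -> float:
        return self.minor_count / self.depth

    @property
    def k(self) -> int:
        return copy_class(self.p_hat, self.pool_n)

    @property
    def alt_allele(self) -> str:
        return self.minor_allele if self.minor_allele != self.ref_base else self.major_allele

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.minor_allele)


class NoCall(NamedTuple):
    """Reason-coded absence of a call at a site."""

    contig: str
    pos: int
    reason: str  # low_coverage | low_count | multiallelic | indel_proximal
    #              | excess_coverage | monomorphic


class CallSet:
    """Collection of :class:`SnpCall` keyed by (contig, pos, minor allele)."""

    def __init__(self, calls: Iterable[SnpCall] = ()) -> None:
        self._calls: dict[tuple[str, int, str], SnpCall] = {}
        for c in calls:
            self.add(c)

    def add(self, call: SnpCall) -> None:
        self._calls[call.key] = call

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[SnpCall]:
        return iter(sorted(self._calls.values(), key=lambda c: c.key))

    def __contains__(self, key) -> bool:
        if isinstance(key, SnpCall):
            key = key.key
        return key in self._calls

    def keys(self):
        return set(self._calls)

    def get(self, key) -> SnpCall | None:
        return self._calls.get(key)

    def by_contig(self, contig: str) -> list[SnpCall]:
        return [c for c in self if c.contig == contig]

    def __eq__(self, other) -> bool:
        return isinstance(other, CallSet) and self._calls == other._calls

    def __repr__(self) -> str:
        return f"CallSet({len(self)} calls)"


def call_site(
    site: SiteCounts, params: CallerParams = CallerParams()
) -> SnpCall | NoCall:
    """Apply the count/coverage rules to a single site.

    Masking (indel proximity, excess coverage) is the responsibility of
    :func:`call_pileup`; this function sees only the thresholds.  A
    no-call is a value carrying a reason code, not an error.
    """
    if site.depth < params.min_cov:
        return NoCall(site.contig, site.pos, "low_coverage")
    ranked = site.ranked_alleles()
    (major, _), (minor, c2), (_, c3) = ranked[0], ranked[1], ranked[2]
    if c2 == 0:
        return NoCall(site.contig, site.pos, "monomorphic")
    if c2 < params.min_count:
        return NoCall(site.contig, site.pos, "low_count")
    if c3 >= params.min_count:
        return NoCall(site.contig, site.pos, "multiallelic")
    return SnpCall(
        contig=site.contig,
        pos=site.pos,
        ref_base=site.ref_base,
        major_allele=major,
        minor_allele=minor,
        minor_count=c2,
        depth=site.depth,
        pool_n=params.pool_n,
    )


def call_pileup(
    sites: Sequence[SiteCounts], params: CallerParams = CallerParams()
) -> tuple[CallSet, list[NoCall]]:
    """Call SNPs over a sorted pileup, applying the indel-proximity and
    excess-coverage masks before the per-site thresholds.

    Returns the call set and the per-site reason log for every site that
    was not called.  Input must be sorted by (contig, pos).
    """
    order = [(s.contig, s.pos) for s in sites]
    if order != sorted(order):
        raise ValueError("call_pileup requires input sorted by (contig, pos)")

    # per-contig excess-coverage threshold (empirical quantile)
    by_contig: dict[str, list[int]] = {}
    for s in sites:
        by_contig.setdefault(s.contig, []).append(s.depth)
    cov_cut = {
        contig: float(np.quantile(np.asarray(d), params.max_cov_quantile))
        for contig, d in by_contig.items()
    }

    # indel mask: positions within +/- indel_window of any indel evidence
    indel_pos: dict[str, set[int]] = {}
    for s in sites:
        if s.indel_evidence > 0:
            indel_pos.setdefault(s.contig, set()).update(
                range(s.pos - params.indel_window, s.pos + params.indel_window + 1)
            )

    calls = CallSet()
    log: list[NoCall] = []
    for s in sites:
        if s.pos in indel_pos.get(s.contig, ()):
            log.append(NoCall(s.contig, s.pos, "indel_proximal"))
            continue
        if s.depth > cov_cut[s.contig]:
            log.append(NoCall(s.contig, s.pos, "excess_coverage"))
            continue
        result = call_site(s, params)
        if isinstance(result, SnpCall):
            calls.add(result)
        else:
            log.append(result)
    return calls, log


class DetectabilityResult(NamedTuple):
    k: int
    feasible: bool  # False when even pool_n/2 copies fall short in expectation


def detectability_threshold(
    depth: int, params: CallerParams = CallerParams()
) -> DetectabilityResult:
    """Smallest minor-allele copy class detectable in expectation at a
    given depth: the smallest k with depth · k / pool_n >= min_count,
    i.e. ceil(min_count · pool_n / depth), capped at pool_n/2."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    k = math.ceil(params.min_count * params.pool_n / depth)
    half = params.pool_n // 2
    if k > half:
        return DetectabilityResult(k=half, feasible=False)
    return DetectabilityResult(k=k, feasible=True)


def filter_fixed_differences(
    calls_vs_reference: CallSet,
    sites: Sequence[SiteCounts],
    params: CallerParams = CallerParams(),
) -> CallSet:
    """Drop variants that merely differ from the reference without being
    polymorphic within the pool.

    A call (typically imported from a reference-based caller) is removed
    when the pooled counts at its position show fewer than ``min_count``
    reads for the second allele — one effective allele, a fixed
    difference to the reference rather than a within-population SNP.
    """
    site_index = {(s.contig, s.pos): s for s in sites}
    kept = CallSet()
    for call in calls_vs_reference:
        site = site_index.get((call.contig, call.pos))
        if site is None:
            raise KeyError(f"no pileup site for call at {call.contig}:{call.pos}")
        second = site.ranked_alleles()[1][1]
        if second >= params.min_count:
            kept.add(call)
    return kept


def intersect_callsets(
    a: CallSet, b: CallSet, match_on: str = "pos_allele"
) -> tuple[CallSet, CallSet, CallSet]:
    """Split two call sets into (both, only_a, only_b).

    Matching is on (contig, pos, minor allele) by default, or on
    position alone with ``match_on="pos"``.  Calls present in both keep
    the first argument's frequency estimates.  The three outputs
    partition the union of the inputs.
    """
    if match_on not in ("pos_allele", "pos"):
        raise ValueError("match_on must be 'pos_allele' or 'pos'")

    def key(c: SnpCall):
        return c.key if match_on == "pos_allele" else (c.contig, c.pos)

    b_keys = {key(c) for c in b}
    a_keys = {key(c) for c in a}
    both = CallSet(c for c in a if key(c) in b_keys)
    only_a = CallSet(c for c in a if key(c) not in b_keys)
    only_b = CallSet(c for c in b if key(c) not in a_keys)
    return both, only_a, only_b


@dataclass(frozen=True)
class ValidationReport:
    """True/false positive and negative counts of a call set against a
    truth set, restricted to a validated region (the Sanger-sequenced
    analogue).  Rates are None when their denominator is zero."""

    tp: int
    fp: int
    fn: int
    restricted_to_region: bool = True

    @property
    def fp_rate(self) -> float | None:
        d = self.tp + self.fp
        return self.fp / d if d else None

    @property
    def fn_rate(self) -> float | None:
        d = self.tp + self.fn
        return self.fn / d if d else None

    @property
    def recall(self) -> float | None:
        r = self.fn_rate
        return None if r is None else 1.0 - r


def _in_region(contig: str, pos: int, region) -> bool:
    return any(c == contig and s <= pos <= e for c, s, e in region)


def validate_against_truth(
    calls: CallSet,
    truth,
    region: Sequence[tuple[str, int, int]],
) -> ValidationReport:
    """Score calls against known segregating sites inside a region.

    ``truth`` is any iterable of objects with contig/pos/alt attributes
    (e.g. :class:`~nlrpool.simulate.TruthSite`) or (contig, pos, alt)
    tuples; matching is on position and alternate allele.  ``region`` is
    a sequence of (contig, start, end) 1-based inclusive intervals.
    """
    if not region:
        raise ValueError("validation region must be non-empty")
    truth_keys = set()
    for t in truth:
        if hasattr(t, "alt"):
            contig, pos, alt = t.contig, t.pos, t.alt
        else:
            contig, pos, alt = t[0], t[1], t[2]
        if _in_region(contig, pos, region):
            truth_keys.add((contig, pos, alt))
    call_keys = {
        (c.contig, c.pos, c.alt_allele)
        for c in calls
        if _in_region(c.contig, c.pos, region)
    }
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    return ValidationReport(tp=tp, fp=fp, fn=fn)
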