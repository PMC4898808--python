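"""Readers, writers and coordinate utilities for the formats the pipeline touches.

On-disk coordinates are 1-based inclusive throughout (pileup, GFF3, VCF
convention).  The native per-site count dialect is a tab-separated table

    contig  pos  ref  A  C  G  T  indel_count

with depth implied by the sum of the four base counts.  A reader for
PoPoolation2-style ``sync`` count tables (the standard mpileup-derived
count intermediate for pool-seq) is provided alongside.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

BASES = ("A", "C", "G", "T")


class PileupFormatError(ValueError):
    """Raised for malformed rows in a per-site count table."""


@dataclass(frozen=True)
class SiteCounts:
    """Per-site nucleotide counts from the pooled alignment.

    ``depth`` may exceed the sum of the four base counts when ambiguous
    bases (N) were observed: they contribute to depth but are never
    candidate alleles.  ``indel_evidence`` counts reads with an inserted
    or deleted base starting or spanning the site.
    """

    contig: str
    pos: int
    ref_base: str
    counts: Mapping[str, int]
    depth: int = -1
    indel_evidence: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in ("A", "C", "G", "T", "N"):
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        total = 0
        for b in BASES:
            c = int(self.counts.get(b, 0))
            if c < 0:
                raise ValueError(f"negative count for {b} at {self.contig}:{self.pos}")
            total += c
        if self.depth == -1:
            object.__setattr__(self, "depth", total)
        elif self.depth < total:
            raise ValueError(
                f"depth {self.depth} < sum of base counts {total} "
                f"at {self.contig}:{self.pos}"
            )
        if self.indel_evidence < 0:
            raise ValueError("indel_evidence must be non-negative")

    def count(self, base: str) -> int:
        return int(self.counts.get(base, 0))

    def ranked_alleles(self) -> list[tuple[str, int]]:
        """Bases with their counts, most frequent first.

        Ties are broken in favour of the reference base, then
        alphabetically, so ranking is deterministic.
        """
        return sorted(
            ((b, self.count(b)) for b in BASES),
            key=lambda bc: (-bc[1], bc[0] != self.ref_base, bc[0]),
        )


@dataclass
class GeneModel:
    """CDS structure of one gene.

    ``segments`` are (start, end) pairs, 1-based inclusive, ordered 5'→3'
    in transcript orientation: ascending genomic coordinates on the plus
    strand, descending on the minus strand.  ``phase`` is the phase of
    the first segment (bases to skip before the first complete codon).
    """

    gene_id: str
    contig: str
    segments: tuple[tuple[int, int], ...]
    strand: str = "+"
    phase: int = 0
    usable_for_codons: bool = True
    _pos_index: dict[int, int] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.segments:
            raise ValueError(f"gene {self.gene_id} has no CDS segments")
        segs = sorted(self.segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"gene {self.gene_id}: overlapping CDS segments "
                    f"({s1}-{e1}, {s2}-{e2})"
                )
        expected = tuple(segs if self.strand == "+" else segs[::-1])
        self.segments = expected
        if (self.cds_length - self.phase) % 3 != 0:
            self.usable_for_codons = False

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.segments]
        ends = [e for _, e in self.segments]
        return min(starts), max(ends)

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of the CDS in transcript (5'→3') order."""
        out: list[int] = []
        for s, e in self.segments:
            rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
            out.extend(rng)
        return out

    def genomic_to_cds(self, pos: int) -> int | None:
        """Transcript-orientation CDS index (0-based) of a genomic position,
        or None for positions outside the CDS."""
        if self._pos_index is None:
            self._pos_index = {
                p: i for i, p in enumerate(self.cds_genomic_positions())
            }
        return self._pos_index.get(pos)

    def cds_sequence(self, contig_seq: str) -> str:
        """Spliced CDS in transcript orientation (reverse-complemented on
        the minus strand)."""
        parts = []
        for s, e in sorted(self.segments):
            parts.append(contig_seq[s - 1 : e])
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# ---------------------------------------------------------------------------
# native pileup dialect
# ---------------------------------------------------------------------------

_PILEUP_COLS = 8


def read_pileup(stream: IO[str] | Iterable[str]) -> Iterator[SiteCounts]:
    """Parse the native tab/space-separated per-site count table.

    Yields one :class:`SiteCounts` per row, in file order.  Malformed rows
    raise :class:`PileupFormatError` naming the line number.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != _PILEUP_COLS:
            raise PileupFormatError(
                f"line {lineno}: expected {_PILEUP_COLS} fields, got {len(fields)}"
            )
        contig, pos_s, ref = fields[0], fields[1], fields[2].upper()
        try:
            pos = int(pos_s)
            nums = [int(x) for x in fields[3:8]]
        except ValueError as exc:
            raise PileupFormatError(f"line {lineno}: non-integer field ({exc})") from None
        if any(n < 0 for n in nums):
            raise PileupFormatError(f"line {lineno}: negative count")
        try:
            yield SiteCounts(
                contig=contig,
                pos=pos,
                ref_base=ref,
                counts=dict(zip(BASES, nums[:4])),
                indel_evidence=nums[4],
            )
        except ValueError as exc:
            raise PileupFormatError(f"line {lineno}: {exc}") from None


def write_pileup(sites: Iterable[SiteCounts], stream: IO[str]) -> None:
    """Write the native dialect; round-trips byte-identically with
    :func:`read_pileup` for well-formed input."""
    for s in sites:
        stream.write(
            f"{s.contig}\t{s.pos}\t{s.ref_base}\t"
            f"{s.count('A')}\t{s.count('C')}\t{s.count('G')}\t{s.count('T')}\t"
            f"{s.indel_evidence}\n"
        )


def read_sync(stream: IO[str] | Iterable[str], pool_column: int = 0) -> Iterator[SiteCounts]:
    """Parse a PoPoolation2-style sync table (``contig pos ref A:T:C:G:N:del``).

    N reads count toward depth but not toward any allele; the deletion
    field feeds ``indel_evidence``.
    """
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4 + pool_column:
            raise PileupFormatError(f"line {lineno}: too few columns for sync format")
        contig, pos_s, ref = fields[0], fields[1], fields[2].upper()
        parts = fields[3 + pool_column].split(":")
        if len(parts) != 6:
            raise PileupFormatError(f"line {lineno}: sync column needs 6 ':' fields")
        try:
            pos = int(pos_s)
            a, t, c, g, n, dels = (int(x) for x in parts)
        except ValueError:
            raise PileupFormatError(f"line {lineno}: non-integer count") from None
        if min(a, t, c, g, n, dels) < 0:
            raise PileupFormatError(f"line {lineno}: negative count")
        yield SiteCounts(
            contig=contig,
            pos=pos,
            ref_base=ref,
            counts={"A": a, "C": c, "G": g, "T": t},
            depth=a + t + c + g + n,
            indel_evidence=dels,
        )


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------


def read_fasta(path_or_stream) -> dict[str, str]:
    """Reference sequences keyed by contig name (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path_or_stream, "fasta")
    }


def write_fasta(seqs: Mapping[str, str], stream: IO[str], width: int = 70) -> None:
    for name, seq in seqs.items():
        stream.write(f">{name}\n")
        for i in range(0, len(seq), width):
            stream.write(seq[i : i + width] + "\n")


def read_gff_cds(source) -> list[GeneModel]:
    """Assemble :class:`GeneModel` objects from the CDS features of a GFF3
    file (path, file object or string content).

    Grouping follows the ``Parent`` attribute (falling back to ``ID`` /
    ``gene_id``).  A gene whose CDS length minus phase is not a multiple
    of three is flagged unusable for codon analysis with a warning rather
    than rejected.
    """
    import gffutils

    if hasattr(source, "read"):
        data, from_string = source.read(), True
    elif isinstance(source, str) and "\n" in source:
        data, from_string = source, True
    else:
        data, from_string = str(source), False
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, list] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parent = (
            feat.attributes.get("Parent")
            or feat.attributes.get("ID")
            or feat.attributes.get("gene_id")
            or [feat.seqid]
        )[0]
        if parent not in grouped:
            order.append(parent)
        grouped.setdefault(parent, []).append(feat)
    models = []
    for gene_id in order:
        feats = grouped[gene_id]
        strand = feats[0].strand if feats[0].strand in ("+", "-") else "+"
        segs = tuple((f.start, f.end) for f in feats)
        # phase belongs to the transcript-first segment
        first = min(feats, key=lambda f: f.start) if strand == "+" else max(
            feats, key=lambda f: f.end
        )
        try:
            phase = int(first.frame)
        except (TypeError, ValueError):
            phase = 0
        model = GeneModel(
            gene_id=gene_id,
            contig=feats[0].seqid,
            segments=segs,
            strand=strand,
            phase=phase,
        )
        if not model.usable_for_codons:
            warnings.warn(
                f"gene {gene_id}: CDS length {model.cds_length} (phase {phase}) "
                "not a multiple of 3; excluded from codon analysis",
                stacklevel=2,
            )
        models.append(model)
    return models


def write_gff_cds(genes: Sequence[GeneModel], stream: IO[str]) -> None:
    stream.write("##gff-version 3\n")
    for g in genes:
        # phases accumulate along the transcript: the next segment skips
        # whatever is left of the codon straddling the junction
        phases: dict[tuple[int, int], int] = {}
        phase = g.phase
        for s, e in g.segments:  # transcript order
            phases[(s, e)] = phase
            phase = (3 - ((e - s + 1) - phase) % 3) % 3
        for s, e in sorted(g.segments):
            stream.write(
                f"{g.contig}\tnlrpool\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phases[(s, e)]}\t"
                f"Parent={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# coverage utilities
# ---------------------------------------------------------------------------


def coverage_cdf(
    depths: Sequence[int] | np.ndarray, thresholds: Sequence[int]
) -> dict[int, float]:
    """Fraction of sites with depth >= d for each threshold d.

    This is the complementary CDF used for target-enrichment coverage
    plots; it is non-increasing in d and valued in [0, 1].
    """
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("coverage_cdf requires at least one depth value")
    arr = np.sort(arr)
    n = arr.size
    out = {}
    for d in thresholds:
        out[int(d)] = float(n - np.searchsorted(arr, d, side="left")) / n
    return out


def quartile_coverage(depths: Sequence[int] | np.ndarray, q: float = 0.75) -> int:
    """Largest depth d such that at least a fraction ``q`` of sites have
    coverage >= d (e.g. q=0.75 gives the first-quartile coverage)."""
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("empty depths")
    arr = np.sort(arr)
    n = arr.size
    best = 0
    for d in np.unique(arr):
        frac = (n - np.searchsorted(arr, d, side="left")) / n
        if frac >= q:
            best = int(d)
    return best


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------


def write_vcf(calls, contig_lengths: Mapping[str, int], path: str) -> None:
    """Write a call set as a minimal VCF 4.2 with INFO keys MC (minor-allele
    count), DP (depth), AF (pooled minor-allele frequency) and MA (minor
    allele base, for lossless round-trip when the minor allele is REF)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##source=nlrpool')
    header.add_line(
        '##INFO=<ID=MC,Number=1,Type=Integer,Description="Minor allele read count">'
    )
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Pooled minor allele frequency">'
    )
    header.add_line('##INFO=<ID=MA,Number=1,Type=String,Description="Minor allele base">')
    for contig, length in contig_lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    with pysam.VariantFile(path, "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: (c.contig, c.pos, c.minor_allele)):
            rec = vf.new_record(
                contig=call.contig,
                start=call.pos - 1,
                stop=call.pos,
                alleles=(call.ref_base, call.alt_allele),
            )
            rec.info["MC"] = int(call.minor_count)
            rec.info["DP"] = int(call.depth)
            rec.info["AF"] = float(call.p_hat)
            rec.info["MA"] = call.minor_allele
            vf.write(rec)


def read_vcf(path: str, pool_n: int = 20):
    """Read a VCF-subset call set back into a :class:`~nlrpool.caller.CallSet`.

    Records missing the MC/DP annotations (e.g. imported from another
    caller) fall back to the AF field alone; AF above one half is
    interpreted as the alternate-allele frequency and folded.
    """
    import pysam

    from .caller import CallSet, SnpCall

    cs = CallSet()
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            ref = rec.ref.upper()
            alt = rec.alts[0].upper() if rec.alts else ref
            info = dict(rec.info)
            af = info.get("AF", 0.0)
            if isinstance(af, (tuple, list)):
                af = af[0]
            af = float(af)
            dp = int(info.get("DP", 0))
            if af > 0.5:
                af = 1.0 - af
                minor = ref
            else:
                minor = str(info.get("MA", alt))
            mc = int(info.get("MC", round(af * dp)))
            major = alt if minor == ref else ref
            cs.add(
                SnpCall(
                    contig=rec.contig,
                    pos=rec.pos,
                    ref_base=ref,
                    major_allele=major,
                    minor_allele=minor,
                    minor_count=mc,
                    depth=dp,
                    pool_n=pool_n,
                )
            )
    return cs


def open_maybe_stdin(path: str) -> IO[str]:
    if path == "-":
        return sys.stdin
    return open(path)
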