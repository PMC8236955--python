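"""Rearrangement and gene-fusion detection from discordant read evidence.

Discordant read pairs (mates on separate chromosomes, or more than 2 kb
apart) are selected, clustered by single linkage on both ends, classified as
translocation / inversion / long deletion / duplication, and — when both
breakpoints fall inside annotated genes — annotated as a fusion with the
joined exons and the protein domains retained on each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Optional, Sequence

__all__ = [
    "DiscordantRead",
    "RearrangementCall",
    "FusionAnnotation",
    "select_discordant",
    "cluster_breakpoints",
    "classify_rearrangement",
    "annotate_fusion",
    "call_svs",
    "rearrangements_to_table",
]

#: Minimum same-chromosome mate distance (strict) for a read pair to count
#: as discordant.
DISCORDANT_DISTANCE_BP = 2000


@dataclass(frozen=True)
class Breakend:
    chrom: str
    pos: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class DiscordantRead:
    """A read pair whose two ends map discordantly."""

    read_id: str
    end1: Breakend
    end2: Breakend
    clip_length: int = 0

    def __post_init__(self) -> None:
        if self.end1.pos < 0 or self.end2.pos < 0:
            raise ValueError("read end positions must be nonnegative")

    @property
    def interchromosomal(self) -> bool:
        return self.end1.chrom != self.end2.chrom

    @property
    def mapped_distance(self) -> Optional[int]:
        """Distance between ends on the same chromosome, None across chromosomes."""
        if self.interchromosomal:
            return None
        return abs(self.end2.pos - self.end1.pos)

    def canonical(self) -> "DiscordantRead":
        """Order the two ends by (chrom, pos) so clustering is orientation-free."""
        if (self.end1.chrom, self.end1.pos) <= (self.end2.chrom, self.end2.pos):
            return self
        return DiscordantRead(self.read_id, self.end2, self.end1, self.clip_length)


@dataclass(frozen=True)
class RearrangementCall:
    breakpoint1: Breakend
    breakpoint2: Breakend
    supporting_reads: int
    svclass: str  # translocation | inversion | long_deletion | duplication
    passed: bool = True


@dataclass(frozen=True)
class FusionAnnotation:
    gene5: str
    gene3: str
    exon5_last: int  # last retained exon of the 5' partner (1-based)
    exon3_first: int  # first retained exon of the 3' partner (1-based)
    n_exons5: int
    n_exons3: int
    domains5: tuple[str, ...]
    domains3: tuple[str, ...]
    in_frame: Optional[bool]  # None = unknown
    direction_known: bool = True
    supporting_reads: int = 0

    @property
    def join_string(self) -> str:
        return (
            f"{self.gene5} exon 1-{self.exon5_last} joined "
            f"{self.gene3} exon {self.exon3_first}-{self.n_exons3}"
        )


def select_discordant(
    reads: Iterable[DiscordantRead],
    min_distance: int = DISCORDANT_DISTANCE_BP,
) -> list[DiscordantRead]:
    """Keep reads mapped to separate chromosomes or > ``min_distance`` apart.

    The distance rule is a strict inequality: exactly 2000 bp is dropped.
    Idempotent and order-preserving.
    """
    out = []
    for read in reads:
        if read.interchromosomal or read.mapped_distance > min_distance:
            out.append(read)
    return out


def cluster_breakpoints(
    reads: Sequence[DiscordantRead],
    window: int = 500,
    min_support: int = 5,
) -> list[RearrangementCall]:
    """Single-linkage clustering of read ends into rearrangement calls.

    Two reads join a cluster when both their (canonically ordered) ends lie
    within ``window`` bp on the same chromosome pair. A call is emitted iff
    the cluster holds at least ``min_support`` reads; each breakpoint is the
    median member position with the majority strand.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    canon = [r.canonical() for r in reads]
    n = len(canon)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = canon[i], canon[j]
            if a.end1.chrom != b.end1.chrom or a.end2.chrom != b.end2.chrom:
                continue
            if abs(a.end1.pos - b.end1.pos) <= window and abs(a.end2.pos - b.end2.pos) <= window:
                union(i, j)

    clusters: dict[int, list[DiscordantRead]] = {}
    for i, read in enumerate(canon):
        clusters.setdefault(find(i), []).append(read)

    calls = []
    for members in clusters.values():
        if len(members) < min_support:
            continue
        bp1 = _consensus_breakend([m.end1 for m in members])
        bp2 = _consensus_breakend([m.end2 for m in members])
        call = RearrangementCall(
            breakpoint1=bp1,
            breakpoint2=bp2,
            supporting_reads=len(members),
            svclass="",
        )
        call = RearrangementCall(
            bp1, bp2, len(members), classify_rearrangement(call), True
        )
        calls.append(call)
    calls.sort(
        key=lambda c: (c.breakpoint1.chrom, c.breakpoint1.pos,
                       c.breakpoint2.chrom, c.breakpoint2.pos)
    )
    return calls


def _consensus_breakend(ends: Sequence[Breakend]) -> Breakend:
    pos = int(median(e.pos for e in ends))
    fwd = sum(1 for e in ends if e.strand == "+")
    strand = "+" if fwd * 2 >= len(ends) else "-"
    return Breakend(ends[0].chrom, pos, strand)


def classify_rearrangement(call: RearrangementCall) -> str:
    """Classify by chromosome and strand pattern.

    Interchromosomal pairs are translocations; same-chromosome pairs with
    equal strands are inversions; +/- orientation over more than 2 kb is a
    long deletion and -/+ a (tandem) duplication.
    """
    b1, b2 = call.breakpoint1, call.breakpoint2
    if b1.chrom != b2.chrom:
        return "translocation"
    if b1.strand == b2.strand:
        return "inversion"
    first, second = (b1, b2) if b1.pos <= b2.pos else (b2, b1)
    if first.strand == "+" and second.strand == "-":
        return "long_deletion"
    return "duplication"


def _exon_number(gene, idx: int) -> int:
    """1-based exon number of genomic exon index ``idx`` respecting strand."""
    if gene.strand == "+":
        return idx + 1
    return len(gene.exons) - idx


def _retained_region_5p(gene, bp: int) -> tuple[int, int]:
    """Genomic interval retained in a 5' partner broken at ``bp``."""
    return (gene.start, bp) if gene.strand == "+" else (bp, gene.end)


def _retained_region_3p(gene, bp: int) -> tuple[int, int]:
    return (bp, gene.end) if gene.strand == "+" else (gene.start, bp)


def _domains_within(gene, region: tuple[int, int]) -> tuple[str, ...]:
    lo, hi = region
    return tuple(name for name, s, e in gene.domains if lo <= s and e <= hi)


def _last_exon_5p(gene, bp: int) -> Optional[int]:
    """Last retained exon number of a 5' partner; None when nothing retained."""
    if gene.strand == "+":
        retained = [i for i, (s, e) in enumerate(gene.exons) if s < bp]
    else:
        retained = [i for i, (s, e) in enumerate(gene.exons) if e > bp]
    if not retained:
        return None
    idx = max(retained) if gene.strand == "+" else min(retained)
    return _exon_number(gene, idx)


def _first_exon_3p(gene, bp: int) -> Optional[int]:
    if gene.strand == "+":
        kept = [i for i, (s, e) in enumerate(gene.exons) if e > bp]
    else:
        kept = [i for i, (s, e) in enumerate(gene.exons) if s < bp]
    if not kept:
        return None
    idx = min(kept) if gene.strand == "+" else max(kept)
    return _exon_number(gene, idx)


def _breakpoint_in_exon(gene, bp: int) -> bool:
    return any(s <= bp < e for s, e in gene.exons)


def annotate_fusion(call: RearrangementCall, genes: Sequence) -> Optional[FusionAnnotation]:
    """Annotate a rearrangement joining two genes as a fusion.

    Each breakpoint maps to the flanking exon in transcription direction
    (intronic breakpoints map to the adjacent exon). Retained domains are
    those lying wholly inside the retained genomic region of the partner.
    The fusion is in frame when the donor coding phase equals the acceptor
    phase (cumulative exon lengths mod 3); mid-exon breakpoints yield
    in_frame=None. Returns None for intergenic or intragenic calls.
    """
    gene1 = _gene_at(genes, call.breakpoint1)
    gene2 = _gene_at(genes, call.breakpoint2)
    if gene1 is None or gene2 is None or gene1.name == gene2.name:
        return None
    # Decide which partner contributes its 5' part: the end whose read strand
    # matches the gene strand donates its upstream (transcription-wise) exons.
    m1 = call.breakpoint1.strand == gene1.strand
    m2 = call.breakpoint2.strand == gene2.strand
    direction_known = m1 != m2
    if m1 or not direction_known:
        g5, bp5 = gene1, call.breakpoint1.pos
        g3, bp3 = gene2, call.breakpoint2.pos
    else:
        g5, bp5 = gene2, call.breakpoint2.pos
        g3, bp3 = gene1, call.breakpoint1.pos

    exon5 = _last_exon_5p(g5, bp5)
    exon3 = _first_exon_3p(g3, bp3)
    if exon5 is None or exon3 is None:
        return None

    exonic_break = _breakpoint_in_exon(g5, bp5) or _breakpoint_in_exon(g3, bp3)
    in_frame: Optional[bool] = None
    if direction_known and not exonic_break:
        lens5 = [e - s for s, e in _exons_tx_order(g5)]
        lens3 = [e - s for s, e in _exons_tx_order(g3)]
        phase5 = sum(lens5[:exon5]) % 3
        phase3 = sum(lens3[: exon3 - 1]) % 3
        in_frame = phase5 == phase3

    return FusionAnnotation(
        gene5=g5.name,
        gene3=g3.name,
        exon5_last=exon5,
        exon3_first=exon3,
        n_exons5=len(g5.exons),
        n_exons3=len(g3.exons),
        domains5=_domains_within(g5, _retained_region_5p(g5, bp5)),
        domains3=_domains_within(g3, _retained_region_3p(g3, bp3)),
        in_frame=in_frame,
        direction_known=direction_known,
        supporting_reads=call.supporting_reads,
    )


def _exons_tx_order(gene) -> list[tuple[int, int]]:
    return list(gene.exons) if gene.strand == "+" else list(gene.exons)[::-1]


def _gene_at(genes: Sequence, bp: Breakend):
    for gene in genes:
        if gene.chromosome == bp.chrom and gene.start <= bp.pos < gene.end:
            return gene
    return None


def call_svs(
    evidence,
    panel,
    *,
    window: int = 500,
    min_support: int = 5,
) -> tuple[list[RearrangementCall], list[FusionAnnotation]]:
    """End-to-end rearrangement + fusion calling for one sample."""
    selected = select_discordant(evidence.discordant_reads)
    calls = cluster_breakpoints(selected, window=window, min_support=min_support)
    fusions = []
    for call in calls:
        ann = annotate_fusion(call, panel.genes)
        if ann is not None:
            fusions.append(ann)
    return calls, fusions


def rearrangements_to_table(sample_id: str, calls: Sequence[RearrangementCall]):
    import pandas as pd

    rows = [
        {
            "sample_id": sample_id,
            "chrom1": c.breakpoint1.chrom,
            "pos1": c.breakpoint1.pos,
            "strand1": c.breakpoint1.strand,
            "chrom2": c.breakpoint2.chrom,
            "pos2": c.breakpoint2.pos,
            "strand2": c.breakpoint2.strand,
            "supporting_reads": c.supporting_reads,
            "class": c.svclass,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom1", "pos1", "strand1", "chrom2", "pos2",
                 "strand2", "supporting_reads", "class"],
    )
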