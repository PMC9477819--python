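"""Partition of assembly contigs against the reference and pan-genome build.

A kept contig is *reference* when it aligns with at least 95% identity
over at least 95% of its length; otherwise it is *fully unaligned* (no
alignment at all) or *partially unaligned*, in which case each maximal
unaligned segment long enough to matter is extracted as a candidate
non-reference sequence, placed by its aligned flanks (two-end when both
flanks land concordantly on the same chromosome, one-end when exactly one
does). Redundant non-reference sequences are absorbed greedily
longest-first, and the survivors are appended to the reference to form
the pan-genome.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .alignment import (
    AlignmentBlock,
    QuerySummary,
    SeedIndex,
    align,
    build_index,
    summarize_query,
)
from .config import Thresholds
from .pav import GeneModel, merge_intervals

__all__ = [
    "ContigClass",
    "NonRefSequence",
    "PanGenome",
    "filter_contigs",
    "classify_contig",
    "extract_nonref",
    "remove_redundancy",
    "build_pangenome",
    "mapping_rate",
]

#: a two-end placement is rejected when the reference gap exceeds this
#: multiple of the novel segment length (chimeric-join guard)
TWO_END_MAX_GAP_FACTOR = 10


class ContigClass(enum.Enum):
    REFERENCE = "REFERENCE"
    PARTIAL_ONE_END = "PARTIAL_ONE_END"
    PARTIAL_TWO_END = "PARTIAL_TWO_END"
    FULLY_UNALIGNED = "FULLY_UNALIGNED"


@dataclass(frozen=True)
class Placement:
    """Reference placement of a non-reference segment by its flanks."""

    kind: str  # "two_end" | "one_end"
    chrom: str
    left: int | None  # reference boundary of the left flank (half-open)
    right: int | None
    side: str | None = None  # for one_end: which side the flank is on


@dataclass
class NonRefSequence:
    seq_id: str
    sequence: str
    origin_contigs: list[str]
    placement: Placement | None = None
    absorbed: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PanGenome:
    reference: dict[str, str]
    nonref: list[NonRefSequence]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        ids = list(self.reference) + [n.seq_id for n in self.nonref]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence id between reference and non-ref set")
        hosts = set(ids)
        for g in self.genes:
            if g.host not in hosts:
                raise ValueError(f"gene {g.gene_id}: host {g.host} not in pan-genome")

    def sequences(self) -> dict[str, str]:
        out = dict(self.reference)
        out.update({n.seq_id: n.sequence for n in self.nonref})
        return out

    def totals(self) -> dict[str, int]:
        full = sum(len(n) for n in self.nonref if n.placement is None)
        partial = sum(len(n) for n in self.nonref if n.placement is not None)
        return {
            "n_nonref": len(self.nonref),
            "fully_unaligned_bp": full,
            "partially_unaligned_bp": partial,
            "total_nonref_bp": full + partial,
        }


def filter_contigs(contigs: list, t: Thresholds) -> list:
    """Keep contigs strictly longer than the minimum length, in order."""
    return [c for c in contigs if len(c.seq) > t.min_contig_len]


def _unaligned_segments(blocks: list[AlignmentBlock], contig_len: int) -> list[tuple[int, int]]:
    aligned = merge_intervals([(b.q_start, b.q_end) for b in blocks])
    out = []
    cur = 0
    for s, e in aligned:
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < contig_len:
        out.append((cur, contig_len))
    return out


def _flank_for(blocks: list[AlignmentBlock], pos: int, side: str) -> AlignmentBlock | None:
    """The aligned block abutting an unaligned segment boundary."""
    if side == "left":
        cands = [b for b in blocks if b.q_end <= pos]
        return max(cands, key=lambda b: b.q_end) if cands else None
    cands = [b for b in blocks if b.q_start >= pos]
    return min(cands, key=lambda b: b.q_start) if cands else None


def _segment_placement(
    seg: tuple[int, int], blocks: list[AlignmentBlock]
) -> Placement | None:
    s, e = seg
    left = _flank_for(blocks, s, "left")
    right = _flank_for(blocks, e, "right")
    seg_len = e - s
    if left is not None and right is not None:
        # reference boundary adjacent to the gap, on either flank
        l_bound = left.t_end if left.strand == "+" else left.t_start
        r_bound = right.t_start if right.strand == "+" else right.t_end
        gap = abs(r_bound - l_bound)
        if (
            left.target_id == right.target_id
            and left.strand == right.strand
            and gap < TWO_END_MAX_GAP_FACTOR * seg_len
        ):
            lo, hi = sorted((l_bound, r_bound))
            return Placement("two_end", left.target_id, lo, hi)
        # discordant flanks degrade to a one-end placement on the left flank
    if left is not None:
        bound = left.t_end if left.strand == "+" else left.t_start
        return Placement("one_end", left.target_id, bound, None, side="left")
    if right is not None:
        bound = right.t_start if right.strand == "+" else right.t_end
        return Placement("one_end", right.target_id, None, bound, side="right")
    return None


def classify_contig(
    summary: QuerySummary,
    blocks: list[AlignmentBlock],
    contig_len: int,
    t: Thresholds,
) -> ContigClass:
    """Apply the 95/95 reference rule, then the flanking rules.

    REFERENCE when identity >= 95% over >= 95% of the contig;
    FULLY_UNALIGNED with no alignment at all; otherwise partial, two-end
    when any unaligned segment is flanked concordantly on both sides.
    """
    for b in blocks:
        if b.q_end > contig_len:
            raise ValueError(
                f"block [{b.q_start},{b.q_end}) exceeds contig length {contig_len}"
            )
    if (
        summary.weighted_identity >= t.ref_identity
        and summary.covered_fraction >= t.ref_query_coverage
    ):
        return ContigClass.REFERENCE
    if summary.covered_fraction == 0.0 or not blocks:
        return ContigClass.FULLY_UNALIGNED
    segments = _unaligned_segments(blocks, contig_len)
    placements = [_segment_placement(seg, blocks) for seg in segments]
    if any(p is not None and p.kind == "two_end" for p in placements):
        return ContigClass.PARTIAL_TWO_END
    return ContigClass.PARTIAL_ONE_END


def extract_nonref(contig, blocks: list[AlignmentBlock], t: Thresholds) -> list[NonRefSequence]:
    """Extract candidate non-reference sequences from one contig.

    Fully unaligned contigs are emitted whole with no placement; partial
    contigs contribute each maximal unaligned segment at least
    ``min_contig_len`` long, placed by its flanks.
    """
    contig_len = len(contig.seq)
    summary = summarize_query(blocks, contig_len)
    cls = classify_contig(summary, blocks, contig_len, t)
    if cls == ContigClass.REFERENCE:
        return []
    if cls == ContigClass.FULLY_UNALIGNED:
        return [
            NonRefSequence(
                seq_id=f"{contig.contig_id}_full",
                sequence=contig.seq,
                origin_contigs=[contig.contig_id],
                placement=None,
            )
        ]
    out = []
    for i, (s, e) in enumerate(_unaligned_segments(blocks, contig_len)):
        if e - s < t.min_contig_len:
            continue
        out.append(
            NonRefSequence(
                seq_id=f"{contig.contig_id}_nr{i}",
                sequence=contig.seq[s:e],
                origin_contigs=[contig.contig_id],
                placement=_segment_placement((s, e), blocks),
            )
        )
    return out


def remove_redundancy(seqs: list[NonRefSequence], t: Thresholds, k: int = 15) -> list[NonRefSequence]:
    """Greedy longest-first absorption of redundant sequences.

    A candidate is absorbed by the kept set when it aligns to one kept
    sequence with at least the redundancy identity over at least the
    redundancy coverage of its own length.
    """
    order = sorted(seqs, key=lambda s: (-len(s), s.seq_id))
    kept: list[NonRefSequence] = []
    index: SeedIndex | None = None
    stale = True
    for cand in order:
        absorbed = False
        if kept:
            if stale:
                index = build_index({s.seq_id: s.sequence for s in kept}, k=k)
                stale = False
            blocks = align(cand.sequence, index, min_block_len=k)
            by_target: dict[str, list[AlignmentBlock]] = {}
            for b in blocks:
                by_target.setdefault(b.target_id, []).append(b)
            for target_id, tblocks in by_target.items():
                s = summarize_query(tblocks, len(cand.sequence))
                if (
                    s.covered_fraction >= t.redundancy_coverage
                    and s.weighted_identity >= t.redundancy_identity
                ):
                    keeper = next(x for x in kept if x.seq_id == target_id)
                    keeper.absorbed.append(cand.seq_id)
                    keeper.origin_contigs = sorted(
                        set(keeper.origin_contigs) | set(cand.origin_contigs)
                    )
                    absorbed = True
                    break
        if not absorbed:
            kept.append(cand)
            stale = True
    return kept


def build_pangenome(
    reference: dict[str, str],
    nonref: list[NonRefSequence],
    novel_genes: list[GeneModel],
    ref_genes: list[GeneModel] | None = None,
) -> PanGenome:
    """Reference chromosomes plus the non-redundant non-reference set."""
    return PanGenome(
        reference=dict(reference),
        nonref=list(nonref),
        genes=list(ref_genes or []) + list(novel_genes),
    )


def mapping_rate(
    reads: list[str],
    target: PanGenome | dict[str, str],
    t: Thresholds,
    k: int = 15,
    min_read_cover: float = 0.9,
    index: SeedIndex | None = None,
) -> float:
    """Fraction of reads with one alignment block covering >=90% of the read.

    The cover threshold is loose enough that substitution noise up to a
    couple of percent never unmaps a read; the contract is the comparison
    of rates between targets, not the absolute value.
    """
    if not reads:
        return 0.0
    if index is None:
        seqs = target.sequences() if isinstance(target, PanGenome) else dict(target)
        index = build_index(seqs, k=k)
    mapped = 0
    for read in reads:
        need = int(min_read_cover * len(read))
        blocks = align(read, index, min_block_len=need)
        if blocks:
            mapped += 1
    return mapped / len(reads)
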