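"""Anchor-based chromosomal placement of non-reference genes.

A predicted gene is located on the reference through long-read contigs:
the gene's coding sequence is matched to a contig (identity over the
coding length must exceed 80%), the 3000 bp immediately flanking the hit
become left/right anchor sequences, each anchor is placed on the
reference (accepted only when its best alignment exceeds 1500 bp at more
than 80% identity), and the reference gap between concordant anchors
becomes the gene's locus when it is shorter than twice the gene length.
Loci from independent contigs are clustered by overlap and the
best-supported cluster is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import SeedIndex, align, build_index, summarize_query
from .config import Thresholds
from .synthetic_data import LongReadContig

__all__ = [
    "AnchorPlacement",
    "GenePlacement",
    "match_gene_to_contig",
    "extract_anchors",
    "place_anchor",
    "assign_locus",
    "place_gene",
]


@dataclass(frozen=True)
class AnchorPlacement:
    chrom: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    chrom: str
    start: int
    end: int
    support: int
    contig_ids: tuple[str, ...]


def match_gene_to_contig(
    gene_seq: str, contig: LongReadContig, t: Thresholds, contig_index: SeedIndex | None = None
) -> tuple[int, int] | None:
    """Interval on the contig carrying the gene's coding sequence, or None.

    The gene is matched when its aligned matching columns exceed the
    identity cut-off as a fraction of the full coding length (so partial
    or diverged hits fail even if locally clean).
    """
    if contig_index is None:
        contig_index = build_index({contig.contig_id: contig.seq})
    blocks = align(gene_seq, contig_index, min_block_len=contig_index.k, query_id="gene")
    if not blocks:
        return None
    summary = summarize_query(blocks, len(gene_seq))
    global_identity = summary.covered_fraction * summary.weighted_identity
    if global_identity <= t.gene_contig_min_identity:
        return None
    best = max(blocks, key=lambda b: (b.block_len, b.identity))
    span = [b for b in blocks if b.strand == best.strand and b.target_id == best.target_id]
    return (min(b.t_start for b in span), max(b.t_end for b in span))


def extract_anchors(
    contig: LongReadContig, hit: tuple[int, int], t: Thresholds
) -> tuple[str | None, str | None]:
    """The anchor-flank-length bases on each side of the hit.

    A side with less than a full flank available yields None: a truncated
    anchor would make the minimum-alignment-length acceptance rule
    meaningless.
    """
    s, e = hit
    left = contig.seq[s - t.anchor_flank_len : s] if s >= t.anchor_flank_len else None
    right = (
        contig.seq[e : e + t.anchor_flank_len]
        if len(contig.seq) - e >= t.anchor_flank_len
        else None
    )
    return left, right


def place_anchor(
    anchor: str, ref_index: SeedIndex, t: Thresholds
) -> AnchorPlacement | None:
    """Best reference placement of an anchor, or None if it fails the rules.

    Best block by (length, identity) lexicographic order; accepted only
    when longer than the minimum anchor alignment length with identity
    above the minimum.
    """
    blocks = align(anchor, ref_index, min_block_len=ref_index.k, query_id="anchor")
    if not blocks:
        return None
    best = max(blocks, key=lambda b: (b.block_len, b.identity))
    if best.block_len <= t.anchor_min_aln_len or best.identity <= t.anchor_min_identity:
        return None
    return AnchorPlacement(
        chrom=best.target_id,
        start=best.t_start,
        end=best.t_end,
        strand=best.strand,
        identity=best.identity,
    )


def assign_locus(
    gene_len: int,
    left: AnchorPlacement | None,
    right: AnchorPlacement | None,
    t: Thresholds,
) -> tuple[str, int, int] | None:
    """The reference gap between two concordant anchors, if small enough.

    Requires both anchors on the same chromosome and strand; the locus is
    the interval between the inner anchor boundaries, accepted when its
    span is under the span factor times the gene length. Overlapping or
    abutting anchors give a zero-length insertion point, accepted.
    """
    if left is None or right is None:
        return None
    if left.chrom != right.chrom or left.strand != right.strand:
        return None
    # inner boundaries regardless of which anchor sits first on the reference
    if left.start <= right.start:
        lo, hi = left.end, right.start
    else:
        lo, hi = right.end, left.start
    if hi < lo:  # overlapping anchors: zero-length insertion point
        lo = hi = (lo + hi) // 2
    if (hi - lo) >= t.placement_span_factor * gene_len:
        return None
    return (left.chrom, lo, hi)


def _cluster_loci(
    loci: list[tuple[str, int, int, str]]
) -> list[tuple[str, int, int, list[str]]]:
    """Single-linkage overlap clustering of (chrom, start, end, contig)."""
    clusters: list[tuple[str, int, int, list[str]]] = []
    for chrom, s, e, cid in sorted(loci):
        merged = False
        for i, (c2, s2, e2, cids) in enumerate(clusters):
            if c2 == chrom and s <= e2 and s2 <= e:
                clusters[i] = (c2, min(s, s2), max(e, e2), cids + [cid])
                merged = True
                break
        if not merged:
            clusters.append((chrom, s, e, [cid]))
    return clusters


def place_gene(
    gene_id: str,
    gene_seq: str,
    contigs: list[LongReadContig],
    ref_index: SeedIndex,
    t: Thresholds,
) -> GenePlacement | None:
    """Run the full per-contig chain and aggregate loci across contigs.

    For each contig: match the coding sequence, extract anchors, place
    both anchors on the reference, and accept the inter-anchor gap when
    concordant and short enough. Accepted loci are clustered by overlap;
    the cluster with the most distinct supporting contigs wins (ties go
    to the leftmost).
    """
    loci = []
    for contig in contigs:
        hit = match_gene_to_contig(gene_seq, contig, t)
        if hit is None:
            continue
        left_seq, right_seq = extract_anchors(contig, hit, t)
        left = place_anchor(left_seq, ref_index, t) if left_seq else None
        right = place_anchor(right_seq, ref_index, t) if right_seq else None
        locus = assign_locus(len(gene_seq), left, right, t)
        if locus is not None:
            loci.append((locus[0], locus[1], locus[2], contig.contig_id))
    if not loci:
        return None
    clusters = _cluster_loci(loci)
    best = max(
        clusters, key=lambda c: (len(set(c[3])), (-c[1], c[0]))
    )
    # tie-break toward leftmost: sort key above prefers more support, then
    # smaller start (negated)
    chrom, s, e, cids = best
    uniq = tuple(sorted(set(cids)))
    return GenePlacement(
        gene_id=gene_id, chrom=chrom, start=s, end=e, support=len(uniq), contig_ids=uniq
    )
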