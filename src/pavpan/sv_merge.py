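"""Multi-caller SV merging and SV-based cross-validation of gene PAVs.

Merging follows the SURVIVOR-style rule set: calls below a minimum size
are dropped, calls of the same type (and strand, when required) whose
start and end breakpoints each lie within a maximum distance are chained
by single linkage, each caller contributes at most one call per cluster,
and only clusters supported by at least the minimum number of distinct
callers are kept, with median consensus breakpoints.

Deletion clusters can then re-derive gene presence/absence through the
exact same CDS-coverage machinery used for read depth, and insertion
clusters (after a tandem-repeat content filter) can be traced back to
pan-genome non-reference sequences by best-hit alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AlignmentBlock, SeedIndex, align, build_index
from .config import Thresholds
from .pav import DepthTrack, GeneModel, call_presence, cds_coverage

__all__ = [
    "SVCall",
    "MergedSV",
    "merge_svs",
    "del_sv_pav",
    "repeat_fraction",
    "filter_ins",
    "map_ins_to_pangenome",
    "read_sv_tsv",
    "write_sv_tsv",
]

SV_TYPES = {"DEL", "INS", "DUP", "INV", "TRA"}


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call from one caller on one sample.

    ``pos``/``end`` are 0-based half-open; for INS, ``end == pos + 1``.
    ``svlen`` is signed (negative for DEL).
    """

    caller: str
    call_id: str
    sample_id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    strands: str = "+-"
    genotype: str = "unknown"
    ins_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.end < self.pos:
            raise ValueError(f"end < pos for {self.call_id}")
        if abs(self.svlen) < 1:
            raise ValueError(f"|svlen| must be >= 1 for {self.call_id}")
        if self.genotype not in ("het", "hom", "unknown"):
            raise ValueError(f"bad genotype {self.genotype!r}")


@dataclass(frozen=True)
class MergedSV:
    """A cluster of concordant calls with its consensus breakpoints."""

    members: tuple[SVCall, ...]
    support: int
    chrom: str
    pos: int
    end: int
    svtype: str
    sample_id: str

    @property
    def genotype(self) -> str:
        gts = {m.genotype for m in self.members if m.genotype != "unknown"}
        return gts.pop() if len(gts) == 1 else "unknown"

    @property
    def svlen(self) -> int:
        return int(np.median([m.svlen for m in self.members]))

    @property
    def ins_sequence(self) -> str | None:
        seqs = [m.ins_sequence for m in self.members if m.ins_sequence]
        return max(seqs, key=len) if seqs else None


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_svs(callsets: dict[str, list[SVCall]], t: Thresholds) -> list[MergedSV]:
    """Single-linkage merge of concordant calls across callers.

    Calls merge only within the same sample and chromosome, with matching
    type (and strands, when required), when both breakpoints agree within
    the maximum distance. The closest call per caller to the cluster
    median wins when a caller reports several.
    """
    seen: set[tuple[str, str]] = set()
    calls: list[SVCall] = []
    for caller, cs in callsets.items():
        for c in cs:
            key = (c.caller, c.call_id)
            if key in seen:
                raise ValueError(f"duplicate call id {key}")
            seen.add(key)
            if abs(c.svlen) >= t.sv_min_size:
                calls.append(c)

    def group_key(c: SVCall):
        key = [c.sample_id, c.chrom]
        if t.sv_merge_type_match:
            key.append(c.svtype)
        if t.sv_merge_strand_match:
            key.append(c.strands)
        return tuple(key)

    groups: dict[tuple, list[SVCall]] = {}
    for c in calls:
        groups.setdefault(group_key(c), []).append(c)

    merged: list[MergedSV] = []
    for group in groups.values():
        group.sort(key=lambda c: (c.pos, c.end, c.caller, c.call_id))
        uf = _UnionFind(len(group))
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if b.pos - a.pos > t.sv_merge_max_dist:
                    break
                if abs(b.end - a.end) <= t.sv_merge_max_dist:
                    uf.union(i, j)
        clusters: dict[int, list[SVCall]] = {}
        for i in range(len(group)):
            clusters.setdefault(uf.find(i), []).append(group[i])
        for members in clusters.values():
            med_pos = float(np.median([m.pos for m in members]))
            med_end = float(np.median([m.end for m in members]))
            by_caller: dict[str, SVCall] = {}
            for m in members:
                cur = by_caller.get(m.caller)
                if cur is None or (
                    abs(m.pos - med_pos) + abs(m.end - med_end)
                    < abs(cur.pos - med_pos) + abs(cur.end - med_end)
                ):
                    by_caller[m.caller] = m
            kept = tuple(sorted(by_caller.values(), key=lambda m: (m.caller, m.call_id)))
            if len(kept) < t.sv_merge_min_support:
                continue
            merged.append(
                MergedSV(
                    members=kept,
                    support=len(kept),
                    chrom=kept[0].chrom,
                    pos=int(np.median([m.pos for m in kept])),
                    end=int(np.median([m.end for m in kept])),
                    svtype=kept[0].svtype,
                    sample_id=kept[0].sample_id,
                )
            )
    merged.sort(key=lambda m: (m.sample_id, m.chrom, m.pos, m.end, m.svtype))
    return merged


def _subtract(full: tuple[int, int], holes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    cur = full[0]
    for s, e in sorted(holes):
        s, e = max(s, full[0]), min(e, full[1])
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < full[1]:
        out.append((cur, full[1]))
    return out


def del_sv_pav(
    merged: list[MergedSV],
    genes: list[GeneModel],
    sample_id: str,
    host_lengths: dict[str, int],
    t: Thresholds,
    homozygous_only: bool = False,
) -> dict[str, bool]:
    """Re-derive per-gene presence from merged deletion SVs.

    Deleted intervals are subtracted from an all-covered track and the
    standard CDS-coverage presence rule is applied verbatim. With
    ``homozygous_only``, only clusters whose members agree on a hom
    genotype count as deletions.
    """
    dels: dict[str, list[tuple[int, int]]] = {}
    for m in merged:
        if m.sample_id != sample_id or m.svtype != "DEL":
            continue
        if homozygous_only and m.genotype != "hom":
            continue
        dels.setdefault(m.chrom, []).append((m.pos, m.end))
    track = DepthTrack()
    for host, L in host_lengths.items():
        track.add(host, _subtract((0, L), dels.get(host, [])))
    return {
        g.gene_id: call_presence(cds_coverage(g, track), t)
        for g in genes
        if g.host in host_lengths
    }


def repeat_fraction(seq: str, max_period: int = 6, min_tract: int = 20) -> float:
    """Fraction of bases inside perfect tandem tracts.

    A tract of period p is a maximal segment where every base equals the
    base p positions before it; tracts shorter than ``min_tract`` are
    ignored. This is an explicit simplification of full tandem-repeat
    masking (no mismatches, period <= ``max_period``); a mask produced by
    a dedicated tool can be supplied instead via :func:`filter_ins`.
    """
    L = len(seq)
    if L == 0:
        return 0.0
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    mask = np.zeros(L, dtype=bool)
    for p in range(1, min(max_period, L - 1) + 1):
        m = arr[p:] == arr[:-p]
        if not m.any():
            continue
        padded = np.concatenate([[False], m, [False]])
        edges = np.diff(padded.astype(np.int8))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        for s, e in zip(starts, ends):
            tract_len = (e - s) + p
            if tract_len >= min_tract:
                mask[s : e + p] = True
    return float(mask.sum()) / L


def filter_ins(
    ins_calls: list[SVCall],
    t: Thresholds,
    repeat_mask: dict[str, float] | None = None,
) -> list[SVCall]:
    """Drop insertion calls whose sequence is more than half tandem repeat.

    ``repeat_mask`` optionally supplies externally computed per-call repeat
    fractions (keyed by call id), e.g. from a dedicated repeat masker.
    """
    kept = []
    for c in ins_calls:
        if c.svtype != "INS":
            continue
        if repeat_mask is not None and c.call_id in repeat_mask:
            frac = repeat_mask[c.call_id]
        elif c.ins_sequence:
            frac = repeat_fraction(c.ins_sequence)
        else:
            frac = 0.0
        if frac <= t.ins_max_repeat_fraction:
            kept.append(c)
    return kept


def map_ins_to_pangenome(
    ins: SVCall,
    index: SeedIndex,
    t: Thresholds,
) -> tuple[str, tuple[int, int], float] | None:
    """Best hit of an insertion sequence on the pan-genome.

    The index should cover the pan-genome sequences (reference plus
    non-reference). Best hit by (aligned length, identity), None when
    nothing aligns or the call carries no sequence.
    """
    if not ins.ins_sequence:
        return None
    blocks = align(ins.ins_sequence, index, min_block_len=index.k, query_id=ins.call_id)
    if not blocks:
        return None
    best = max(blocks, key=lambda b: (b.block_len, b.identity))
    return (best.target_id, (best.t_start, best.t_end), best.identity)


_TSV_HEADER = ["CHROM", "POS", "ID", "TYPE", "END", "SVLEN", "STRANDS", "SAMPLE", "GT"]


def write_sv_tsv(calls: list[SVCall], path: str | Path) -> None:
    """Write the minimal per-caller TSV dialect (POS/END 1-based)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_HEADER) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        c.chrom,
                        c.pos + 1,
                        c.call_id,
                        c.svtype,
                        c.end,
                        c.svlen,
                        c.strands,
                        c.sample_id,
                        c.genotype,
                    )
                )
                + "\n"
            )


def read_sv_tsv(path: str | Path, caller: str) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ValueError(f"SV TSV line {lineno}: expected >=8 columns")
            gt = cols[8] if len(cols) > 8 else "unknown"
            calls.append(
                SVCall(
                    caller=caller,
                    call_id=cols[2],
                    sample_id=cols[7],
                    chrom=cols[0],
                    pos=int(cols[1]) - 1,
                    end=int(cols[4]),
                    svtype=cols[3],
                    svlen=int(cols[5]),
                    strands=cols[6],
                    genotype=gt,
                )
            )
    return calls
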