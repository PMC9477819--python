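"""Exact-seed chaining aligner and alignment I/O.

This is the single provider of :class:`AlignmentBlock` for the whole
package. It is a deliberately small aligner: exact k-mer seeds, chained by
diagonal collinearity, merged into ungapped blocks with X-drop extension.
That is adequate for substitution-only sequence (the synthetic cohorts)
and cheap to audit; real-data users supply PAF from an external aligner
(minimap2, MUMmer) through :func:`read_paf` instead.

All coordinates are 0-based half-open. Conversions to 1-based formats
happen only inside readers/writers elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AlignmentBlock",
    "QuerySummary",
    "SeedIndex",
    "build_index",
    "align",
    "summarize_query",
    "read_paf",
    "write_paf",
    "revcomp",
]

DEFAULT_K = 15
#: maximum query-position gap (bp) between consecutive seeds of a chain
MAX_SEED_GAP = 500
_XDROP = 12
_MISMATCH_PENALTY = 3

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers plus a validity mask (no N inside)."""
    n = enc.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    x = enc.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + x[j : j + n]
    bad = x >= 4
    if bad.any():
        run = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid")
        valid = run == 0
    else:
        valid = np.ones(n, dtype=bool)
    return codes, valid


@dataclass(frozen=True)
class AlignmentBlock:
    """One ungapped local alignment between a query and a target segment."""

    query_id: str
    q_start: int
    q_end: int
    target_id: str
    t_start: int
    t_end: int
    strand: str
    identity: float
    q_len: int = 0
    t_len: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start},{self.q_end})")
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(f"bad target interval [{self.t_start},{self.t_end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity must lie in [0,1], got {self.identity!r}")

    @property
    def block_len(self) -> int:
        return self.q_end - self.q_start


@dataclass(frozen=True)
class QuerySummary:
    """Coverage and identity of one query over all its alignment blocks.

    ``covered_fraction`` is the unioned fraction of query bases inside at
    least one block; ``weighted_identity`` is the block-length-weighted
    mean identity over a best non-overlapping chain of blocks (maximal
    total aligned length, ties broken toward higher identity).
    """

    query_id: str
    covered_fraction: float
    weighted_identity: float


class SeedIndex:
    """Exact k-mer position index over a set of named target sequences."""

    def __init__(self, targets: dict[str, str], k: int = DEFAULT_K):
        if k < 8:
            raise ValueError(f"k must be >= 8, got {k}")
        if not targets:
            raise ValueError("empty target set")
        self.k = k
        self.target_ids = list(targets)
        self.target_seqs = {tid: seq.upper() for tid, seq in targets.items()}
        self._enc = {tid: _encode(s) for tid, s in self.target_seqs.items()}

        all_codes, all_tidx, all_pos = [], [], []
        for tidx, tid in enumerate(self.target_ids):
            codes, valid = _kmer_codes(self._enc[tid], k)
            pos = np.nonzero(valid)[0]
            all_codes.append(codes[pos])
            all_pos.append(pos)
            all_tidx.append(np.full(pos.shape[0], tidx, dtype=np.int64))
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.int64)
        self.n_positions = int(codes.shape[0])
        order = np.argsort(codes, kind="stable")
        self._codes_sorted = codes[order]
        self._tidx_sorted = np.concatenate(all_tidx)[order] if all_tidx else np.empty(0, np.int64)
        self._pos_sorted = np.concatenate(all_pos)[order] if all_pos else np.empty(0, np.int64)

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (query_kmer_index, target_index, target_pos) for all hits."""
        lo = np.searchsorted(self._codes_sorted, codes, side="left")
        hi = np.searchsorted(self._codes_sorted, codes, side="right")
        counts = hi - lo
        qidx = np.repeat(np.arange(codes.shape[0]), counts)
        if qidx.shape[0] == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        flat = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        return qidx, self._tidx_sorted[flat], self._pos_sorted[flat]


def build_index(target_sequences: dict[str, str], k: int = DEFAULT_K) -> SeedIndex:
    """Build an exact k-mer index; k-mers containing N are skipped."""
    return SeedIndex(target_sequences, k)


def _extend_xdrop(qenc: np.ndarray, tenc: np.ndarray, qs: int, qe: int, diag: int) -> tuple[int, int]:
    """Extend [qs,qe) outward along a fixed diagonal with an X-drop stop."""
    qlen, tlen = qenc.shape[0], tenc.shape[0]
    # rightward
    score = best = 0
    best_q = qe
    q = qe
    while q < qlen and q + diag < tlen:
        score += 1 if qenc[q] == tenc[q + diag] else -_MISMATCH_PENALTY
        q += 1
        if score > best:
            best, best_q = score, q
        elif best - score > _XDROP:
            break
    qe = best_q
    # leftward
    score = best = 0
    best_q = qs
    q = qs
    while q > 0 and q + diag > 0:
        q -= 1
        score += 1 if qenc[q] == tenc[q + diag] else -_MISMATCH_PENALTY
        if score > best:
            best, best_q = score, q
        elif best - score > _XDROP:
            break
    return best_q, qe


def _align_one_strand(
    qenc: np.ndarray, index: SeedIndex, min_block_len: int
) -> list[tuple[int, int, int, int, float]]:
    """Blocks (tidx, qs, qe, ts, identity) for one query orientation."""
    codes, valid = _kmer_codes(qenc, index.k)
    qpos_all = np.nonzero(valid)[0]
    if qpos_all.shape[0] == 0:
        return []
    qidx, tidx, tpos = index.lookup(codes[qpos_all])
    if qidx.shape[0] == 0:
        return []
    qpos = qpos_all[qidx]
    diag = tpos - qpos
    order = np.lexsort((qpos, diag, tidx))
    tidx, qpos, diag = tidx[order], qpos[order], diag[order]

    # blocks are ungapped, so a chain lives on one exact diagonal; break
    # wherever target, diagonal, or seed spacing jumps
    brk = np.ones(tidx.shape[0], dtype=bool)
    if tidx.shape[0] > 1:
        brk[1:] = (
            (np.diff(tidx) != 0)
            | (np.diff(diag) != 0)
            | (np.diff(qpos) > MAX_SEED_GAP)
        )
    starts = np.nonzero(brk)[0]
    ends = np.append(starts[1:], tidx.shape[0])

    blocks = []
    k = index.k
    for s, e in zip(starts, ends):
        ti = int(tidx[s])
        d = int(diag[s])
        qs = int(qpos[s:e].min())
        qe = int(qpos[s:e].max()) + k
        tenc = index._enc[index.target_ids[ti]]
        qs = max(qs, -d)
        qe = min(qe, tenc.shape[0] - d, qenc.shape[0])
        if qe <= qs:
            continue
        qs, qe = _extend_xdrop(qenc, tenc, qs, qe, d)
        if qe - qs < max(min_block_len, k):
            continue
        matches = int(np.count_nonzero(qenc[qs:qe] == tenc[qs + d : qe + d]))
        blocks.append((ti, qs, qe, qs + d, matches / (qe - qs)))
    return blocks


def align(
    query: str,
    index: SeedIndex,
    min_block_len: int = 50,
    query_id: str = "query",
) -> list[AlignmentBlock]:
    """Align a query against the index on both strands.

    Overlapping chains are all reported; uniqueness pressure is applied
    only in :func:`summarize_query`, because downstream classification
    rules operate on coverage, not on a unique alignment.
    """
    qseq = query.upper()
    qlen = len(qseq)
    if qlen < index.k:
        return []
    out: list[AlignmentBlock] = []
    for strand, seq in (("+", qseq), ("-", revcomp(qseq))):
        qenc = _encode(seq)
        for ti, qs, qe, ts, ident in _align_one_strand(qenc, index, min_block_len):
            tid = index.target_ids[ti]
            if strand == "-":
                qs, qe = qlen - qe, qlen - qs
            out.append(
                AlignmentBlock(
                    query_id=query_id,
                    q_start=qs,
                    q_end=qe,
                    target_id=tid,
                    t_start=ts,
                    t_end=ts + (qe - qs),
                    strand=strand,
                    identity=ident,
                    q_len=qlen,
                    t_len=len(index.target_seqs[tid]),
                )
            )
    out.sort(key=lambda b: (b.query_id, b.q_start, b.q_end, b.target_id, b.t_start))
    return out


def _best_nonoverlapping(blocks: list[AlignmentBlock]) -> list[AlignmentBlock]:
    """Weighted interval scheduling: maximal total aligned length, ties
    resolved toward higher summed identity mass."""
    bl = sorted(blocks, key=lambda b: b.q_end)
    n = len(bl)
    if n == 0:
        return []
    ends = [b.q_end for b in bl]
    import bisect

    # value = (total length, total identity*length)
    best: list[tuple[float, float]] = [(0.0, 0.0)] * (n + 1)
    choice: list[bool] = [False] * (n + 1)
    pred: list[int] = [0] * (n + 1)
    for i in range(1, n + 1):
        b = bl[i - 1]
        j = bisect.bisect_right(ends, b.q_start, 0, i - 1)
        pred[i] = j
        take = (best[j][0] + b.block_len, best[j][1] + b.identity * b.block_len)
        skip = best[i - 1]
        if take > skip:
            best[i], choice[i] = take, True
        else:
            best[i], choice[i] = skip, False
    chosen = []
    i = n
    while i > 0:
        if choice[i]:
            chosen.append(bl[i - 1])
            i = pred[i]
        else:
            i -= 1
    chosen.reverse()
    return chosen


def summarize_query(blocks: list[AlignmentBlock], query_len: int, query_id: str = "query") -> QuerySummary:
    """Unioned query coverage and chained length-weighted identity."""
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    if not blocks:
        return QuerySummary(query_id=query_id, covered_fraction=0.0, weighted_identity=0.0)
    ivs = sorted((b.q_start, b.q_end) for b in blocks)
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    chain = _best_nonoverlapping(blocks)
    total = sum(b.block_len for b in chain)
    wid = sum(b.identity * b.block_len for b in chain) / total if total else 0.0
    return QuerySummary(
        query_id=blocks[0].query_id if blocks else query_id,
        covered_fraction=min(1.0, covered / query_len),
        weighted_identity=wid,
    )


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    """Read minimap2-dialect PAF (columns 1-12) into AlignmentBlocks."""
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
            try:
                qlen, qs, qe = int(cols[1]), int(cols[2]), int(cols[3])
                tlen, ts, te = int(cols[6]), int(cols[7]), int(cols[8])
                matches, alnlen = int(cols[9]), int(cols[10])
            except ValueError as exc:
                raise ValueError(f"PAF line {lineno}: non-numeric coordinate field") from exc
            blocks.append(
                AlignmentBlock(
                    query_id=cols[0],
                    q_start=qs,
                    q_end=qe,
                    target_id=cols[5],
                    t_start=ts,
                    t_end=te,
                    strand=cols[4],
                    identity=matches / alnlen if alnlen else 0.0,
                    q_len=qlen,
                    t_len=tlen,
                )
            )
    return blocks


def write_paf(blocks: list[AlignmentBlock], path: str | Path) -> None:
    """Write blocks as PAF columns 1-12 (mapq fixed at 60)."""
    with open(path, "w") as fh:
        for b in blocks:
            alnlen = b.block_len
            matches = round(b.identity * alnlen)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_id,
                        b.q_len or b.q_end,
                        b.q_start,
                        b.q_end,
                        b.strand,
                        b.target_id,
                        b.t_len or b.t_end,
                        b.t_start,
                        b.t_end,
                        matches,
                        alnlen,
                        60,
                    )
                )
                + "\n"
            )
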