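"""Gene presence-absence (PAV) calling from CDS read coverage.

The presence statistic is the fraction of a gene's coding bases covered by
mapped reads, evaluated on the representative transcript (the one with the
longest open reading frame). A gene is *present* in a sample when strictly
more than 80% of its CDS is covered, otherwise *absent*. Genes present in
every evaluable individual are *core*; the rest are *distributed*. Genes on
chromosome Y are evaluated over male samples only, since females carry no
Y sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Thresholds

__all__ = [
    "GeneModel",
    "DepthTrack",
    "SampleMeta",
    "PAVMatrix",
    "CORE",
    "DISTRIBUTED",
    "UNEVALUABLE",
    "representative_transcript",
    "cds_coverage",
    "call_presence",
    "build_pav_matrix",
    "classify_core_distributed",
    "genes_per_sample",
    "read_depth_tsv",
    "merge_intervals",
    "CHRY",
]

CORE = "CORE"
DISTRIBUTED = "DISTRIBUTED"
UNEVALUABLE = "UNEVALUABLE"
#: name of the male-specific chromosome in reference/simulated genomes
CHRY = "chrY"

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge possibly-overlapping 0-based half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect_len(a: list[Interval], b: list[Interval]) -> int:
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts of sorted, disjoint CDS intervals.

    ``host`` is a chromosome name or a non-reference sequence id. CDS
    intervals are 0-based half-open on the host.
    """

    gene_id: str
    host: str
    strand: str
    transcripts: tuple[tuple[Interval, ...], ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            if not tx:
                raise ValueError(f"gene {self.gene_id} has an empty transcript")
            for (s1, e1), (s2, e2) in zip(tx, tx[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise ValueError(
                        f"gene {self.gene_id}: CDS intervals must be sorted and disjoint"
                    )

    @property
    def representative_index(self) -> int:
        totals = [sum(e - s for s, e in tx) for tx in self.transcripts]
        return int(np.argmax(totals))  # argmax takes the first maximum: declared tie-break

    @property
    def span(self) -> Interval:
        tx = self.transcripts[self.representative_index]
        return (tx[0][0], tx[-1][1])

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.transcripts[self.representative_index])


def representative_transcript(gene: GeneModel) -> tuple[Interval, ...]:
    """CDS intervals of the transcript with the longest total CDS.

    Ties go to the lowest transcript index.
    """
    return gene.transcripts[gene.representative_index]


@dataclass
class DepthTrack:
    """Per-host covered positions, stored as sorted disjoint intervals.

    A position is covered when its read depth reaches the configured
    minimum (default: one read).
    """

    covered: dict[str, list[Interval]] = field(default_factory=dict)

    def add(self, host: str, intervals: list[Interval]) -> None:
        self.covered[host] = merge_intervals(self.covered.get(host, []) + list(intervals))

    def covered_length(self, host: str) -> int:
        return sum(e - s for s, e in self.covered.get(host, []))


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cohort: str
    sex: str
    phenotypes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")

    def phenotype(self, name: str) -> str | None:
        return dict(self.phenotypes).get(name)


@dataclass
class PAVMatrix:
    """Samples x genes CDS-coverage matrix with derived presence calls."""

    coverage: pd.DataFrame
    presence: pd.DataFrame
    genes: dict[str, GeneModel]
    meta: dict[str, SampleMeta]
    labels: pd.Series | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.coverage.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coverage.columns)


def cds_coverage(gene: GeneModel, depth: DepthTrack) -> float:
    """Fraction of representative-transcript CDS bases that are covered.

    A host absent from the track (e.g. chrY in a female) yields 0.
    """
    cds = list(representative_transcript(gene))
    total = sum(e - s for s, e in cds)
    cov = depth.covered.get(gene.host)
    if not cov:
        return 0.0
    return _intersect_len(cds, cov) / total


def call_presence(coverage: float, t: Thresholds) -> bool:
    """Present iff coverage is strictly greater than the presence cut-off."""
    return coverage > t.presence_cds_coverage


def build_pav_matrix(
    genes: list[GeneModel],
    tracks: dict[str, DepthTrack],
    meta: list[SampleMeta],
    t: Thresholds,
) -> PAVMatrix:
    """Coverage and presence for every (sample, gene) pair.

    Ordering is deterministic: genes by (host, start position), samples by
    id. Every sample with a depth track must appear in the metadata.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    missing = sorted(set(tracks) - set(meta_by_id))
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    gene_order = sorted(genes, key=lambda g: (g.host, g.span[0], g.gene_id))
    sample_order = sorted(tracks)
    cov = np.zeros((len(sample_order), len(gene_order)))
    for i, sid in enumerate(sample_order):
        track = tracks[sid]
        for j, g in enumerate(gene_order):
            cov[i, j] = cds_coverage(g, track)
    coverage = pd.DataFrame(
        cov, index=sample_order, columns=[g.gene_id for g in gene_order]
    )
    presence = coverage > t.presence_cds_coverage
    matrix = PAVMatrix(
        coverage=coverage,
        presence=presence,
        genes={g.gene_id: g for g in gene_order},
        meta={sid: meta_by_id[sid] for sid in sample_order},
    )
    matrix.labels = classify_core_distributed(matrix, meta)
    return matrix


def classify_core_distributed(matrix: PAVMatrix, meta: list[SampleMeta]) -> pd.Series:
    """Label each gene CORE, DISTRIBUTED, or UNEVALUABLE.

    A non-chrY gene is core iff present in all samples. A chrY gene is
    core iff present in all *male* samples (females are excluded from its
    evaluation); with no males at all it is unevaluable.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    males = [s for s in matrix.samples if meta_by_id[s].sex == "male"]
    labels = {}
    for gid in matrix.gene_ids:
        gene = matrix.genes[gid]
        if gene.host == CHRY:
            if not males:
                labels[gid] = UNEVALUABLE
                continue
            col = matrix.presence.loc[males, gid]
        else:
            col = matrix.presence[gid]
        labels[gid] = CORE if bool(col.all()) else DISTRIBUTED
    out = pd.Series(labels, name="label")
    matrix.labels = out
    return out


def genes_per_sample(
    matrix: PAVMatrix, reference_hosts: set[str] | None = None
) -> dict[str, tuple[int, int]]:
    """Per-sample counts of present genes, split reference vs non-reference.

    ``reference_hosts`` defaults to hosts that look like chromosomes
    (names starting with 'chr'); anything else counts as non-reference.
    """
    if reference_hosts is None:
        reference_hosts = {
            g.host for g in matrix.genes.values() if g.host.startswith("chr")
        }
    ref_cols = [gid for gid in matrix.gene_ids if matrix.genes[gid].host in reference_hosts]
    nov_cols = [gid for gid in matrix.gene_ids if gid not in set(ref_cols)]
    out = {}
    for sid in matrix.samples:
        out[sid] = (
            int(matrix.presence.loc[sid, ref_cols].sum()),
            int(matrix.presence.loc[sid, nov_cols].sum()),
        )
    return out


def read_depth_tsv(path: str | Path, t: Thresholds) -> DepthTrack:
    """Read a samtools-depth style TSV (target, 1-based pos, depth).

    Positions with depth below the presence minimum are dropped; adjacent
    kept positions are merged into 0-based half-open intervals.
    """
    track = DepthTrack()
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["host", "pos", "depth"],
            dtype={"host": str, "pos": np.int64, "depth": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return track
    df = df[df["depth"] >= t.depth_presence_min]
    for host, sub in df.groupby("host", sort=False):
        pos = np.sort(sub["pos"].to_numpy()) - 1  # to 0-based
        if pos.size == 0:
            continue
        brk = np.nonzero(np.diff(pos) > 1)[0]
        starts = np.concatenate([[0], brk + 1])
        ends = np.concatenate([brk, [pos.size - 1]])
        track.add(str(host), [(int(pos[s]), int(pos[e]) + 1) for s, e in zip(starts, ends)])
    return track
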