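"""Synthetic mini-study generator with machine-readable ground truth.

Emulates, at desk scale, a cohort WGS pan-genome study: a small
multi-chromosome reference with annotated genes (one chromosome is chrY),
two cohorts of individuals carrying planted gene deletions at
cohort-specific frequencies and planted novel-gene insertions, fragmentary
per-sample assembly contigs, uniform read depth with dropout over deleted
regions, long-read contigs spanning the novel insertions with reference
flanks, and several noisy SV callsets per sample.

Everything is deterministic given the seed: the global seed plus a stable
CRC32 hash of each sample id seeds a per-sample stream, so adding or
removing samples never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .config import Thresholds
from .pav import CHRY, DepthTrack, GeneModel, SampleMeta, merge_intervals
from .sv_merge import SVCall

__all__ = [
    "CohortSpec",
    "SimulationParams",
    "ReferenceGenome",
    "IndividualGenome",
    "Segment",
    "Contig",
    "LongReadContig",
    "ReadPlacement",
    "NovelGeneSpec",
    "TrueSV",
    "TruthSet",
    "Study",
    "simulate_reference",
    "insertion_loci",
    "simulate_population",
    "simulate_contigs",
    "simulate_depth",
    "simulate_long_reads",
    "simulate_sv_callsets",
    "simulate_study",
    "write_study",
    "simulate_presence_matrix",
    "default_params",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# layout constants for gene packing (bp)
_EDGE_MARGIN = 500
_MIN_GAP = 100
_DELETION_PAD = 50
_CASSETTE_PAD = 200
#: half-width of the intergenic window reserved around each insertion
#: locus, keeping it clear of gene deletion spans (pad 50) on either side
_INSERTION_CLEARANCE = 600


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_samples: int
    absence_freqs: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationParams:
    seed: int = 0
    n_chromosomes: int = 3
    chrom_len: int = 100_000
    n_ref_genes: int = 120
    n_novel_genes: int = 6
    cds_exons_per_gene: tuple[int, int] = (1, 3)
    gene_len: tuple[int, int] = (600, 2000)
    cohorts: tuple[CohortSpec, ...] = ()
    chry_gene_fraction: float = 0.1
    novel_carrier_freq: float = 0.5
    sex_ratio: float = 0.5
    read_len: int = 150
    depth: float = 30.0
    contig_break_rate: float = 1.0  # expected breaks per 10 kb
    base_error_rate: float = 0.0
    long_reads_per_insertion: int = 3
    sv_caller_jitter_sd: float = 50.0
    sv_caller_fn_rate: float = 0.1
    sv_caller_fp_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_len", "n_novel_genes", "read_len"):
            if getattr(self, name) < 0 or (name != "n_novel_genes" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        for name in (
            "chry_gene_fraction",
            "novel_carrier_freq",
            "sex_ratio",
            "base_error_rate",
            "sv_caller_fn_rate",
            "sv_caller_fp_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v!r}")
        for spec in self.cohorts:
            for f in spec.absence_freqs.values():
                if not (0.0 <= f <= 1.0):
                    raise ValueError("absence frequencies must lie in [0,1]")


def default_params(seed: int = 0, n_per_cohort: int = 25) -> SimulationParams:
    """The standard toy study: two cohorts, five differentially absent
    genes (0.6 vs 0.05) and ten genes distributed equally in both (0.2)."""
    differential = {f"G{i:04d}": 0.6 for i in range(1, 6)}
    shared = {f"G{i:04d}": 0.2 for i in range(6, 16)}
    case = {**differential, **shared}
    control = {**{g: 0.05 for g in differential}, **shared}
    return SimulationParams(
        seed=seed,
        cohorts=(
            CohortSpec("case", n_per_cohort, case),
            CohortSpec("control", n_per_cohort, control),
        ),
    )


@dataclass(frozen=True)
class ReferenceGenome:
    chromosomes: dict[str, str]

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]


@dataclass(frozen=True)
class NovelGeneSpec:
    """A novel gene cassette with a fixed insertion locus on the reference."""

    gene: GeneModel  # host = cassette id
    cassette_id: str
    cassette_seq: str
    chrom: str
    locus: int  # 0-based insertion point on the reference chromosome

    @property
    def gene_seq(self) -> str:
        cds = self.gene.transcripts[self.gene.representative_index]
        return "".join(self.cassette_seq[s:e] for s, e in cds)


@dataclass(frozen=True)
class Segment:
    """One piece of an individual chromosome, mapped back to its source
    (a reference interval or a novel cassette)."""

    source_id: str
    src_start: int
    src_end: int
    seq: str


@dataclass
class IndividualGenome:
    sample_id: str
    sex: str
    chromosomes: dict[str, list[Segment]]

    def sequence(self, chrom: str) -> str:
        return "".join(seg.seq for seg in self.chromosomes[chrom])

    def length(self, chrom: str) -> int:
        return sum(len(seg.seq) for seg in self.chromosomes[chrom])


@dataclass(frozen=True)
class Contig:
    contig_id: str
    seq: str
    sample_id: str
    source_chrom: str
    source_start: int  # individual-genome coordinates
    source_end: int


@dataclass(frozen=True)
class LongReadContig:
    contig_id: str
    seq: str
    dataset: str = "synthetic-longread"


@dataclass(frozen=True)
class ReadPlacement:
    chrom: str  # individual chromosome
    start: int
    end: int
    seq: str


@dataclass(frozen=True)
class TrueSV:
    sample_id: str
    svtype: str  # DEL | INS
    chrom: str
    pos: int  # 0-based on reference
    end: int
    length: int
    gene_id: str


@dataclass
class TruthSet:
    pav_truth: dict[tuple[str, str], bool]
    novel_gene_loci: dict[str, tuple[str, int]]
    sv_truth: list[TrueSV]


@dataclass
class Study:
    params: SimulationParams
    reference: ReferenceGenome
    ref_genes: list[GeneModel]
    novel_genes: list[NovelGeneSpec]
    individuals: list[IndividualGenome]
    meta: list[SampleMeta]
    truth: TruthSet


def _rng_for(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _make_transcripts(
    rng: np.random.Generator, start: int, glen: int, exon_range: tuple[int, int]
) -> tuple[tuple[tuple[int, int], ...], ...]:
    """Exon/intron structure inside [start, start+glen); an optional second
    transcript drops the last exon, so the first is always representative."""
    n_ex = int(rng.integers(exon_range[0], exon_range[1] + 1))
    cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_ex - 2, replace=False)) if n_ex > 1 else np.empty(0, int)
    bounds = [0, *cuts.tolist(), glen]
    exons = tuple(
        (start + bounds[2 * i], start + bounds[2 * i + 1]) for i in range(n_ex)
    )
    transcripts = [exons]
    if n_ex > 1 and rng.random() < 0.3:
        transcripts.append(exons[:-1])
    return tuple(transcripts)


def simulate_reference(
    params: SimulationParams,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Random chromosomes with non-overlapping annotated genes.

    A `chry_gene_fraction` of genes goes on chrY; room for the novel-gene
    insertion loci is reserved on the autosomes so that anchor flanks stay
    gene-free. Raises if the requested genes cannot be packed.
    """
    ref, genes, _ = _simulate_reference_full(params)
    return ref, genes


def _simulate_reference_full(
    params: SimulationParams,
) -> tuple[ReferenceGenome, list[GeneModel], list[tuple[str, int]]]:
    rng = _rng_for(params.seed, "reference")
    names = [f"chr{i + 1}" for i in range(params.n_chromosomes - 1)] + [CHRY]
    chroms = {name: _random_dna(rng, params.chrom_len) for name in names}

    n_y = int(round(params.chry_gene_fraction * params.n_ref_genes))
    autosomes = names[:-1] if len(names) > 1 else names
    per_auto = (params.n_ref_genes - n_y) // len(autosomes)
    counts = {name: per_auto for name in autosomes}
    counts[autosomes[0]] += (params.n_ref_genes - n_y) - per_auto * len(autosomes)
    counts[CHRY] = counts.get(CHRY, 0) + n_y

    # round-robin novel loci over autosomes
    reservations: dict[str, int] = {name: 0 for name in names}
    for i in range(params.n_novel_genes):
        reservations[autosomes[i % len(autosomes)]] += 1

    genes: list[GeneModel] = []
    loci: list[tuple[str, int]] = []
    gid = 0
    # a locus must sit at least an anchor flank (plus margin) from the
    # chromosome ends so long-read contigs can carry full true flanks;
    # guarantee that by keeping this many gene items on each side of it
    min_edge_bp = 3600
    j_min = -(-(min_edge_bp - _EDGE_MARGIN) // (_MIN_GAP + params.gene_len[0]))
    for name in names:
        n_genes = counts.get(name, 0)
        lens = rng.integers(params.gene_len[0], params.gene_len[1] + 1, size=n_genes)
        items = [("gene", int(L)) for L in lens]
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        n_res = reservations[name]
        if n_res:
            if n_genes < 2 * j_min + n_res:
                raise ValueError(
                    f"cannot pack {n_genes} genes plus {n_res} insertion "
                    f"loci into {name}: too few genes to keep loci away "
                    f"from chromosome ends"
                )
            span = n_genes - 2 * j_min
            for i in range(n_res):
                at = j_min + (i + 1) * span // (n_res + 1) + i
                items.insert(at, ("locus", 2 * _INSERTION_CLEARANCE))
        used = sum(L for _, L in items)
        slack = params.chrom_len - 2 * _EDGE_MARGIN - used - (len(items) + 1) * _MIN_GAP
        if slack < 0:
            raise ValueError(
                f"cannot pack {n_genes} genes plus {reservations[name]} insertion "
                f"loci into {name} of length {params.chrom_len}"
            )
        extra = rng.multinomial(slack, np.ones(len(items) + 1) / (len(items) + 1)) if items else []
        pos = _EDGE_MARGIN
        for (kind, L), pad in zip(items, extra):
            pos += _MIN_GAP + int(pad)
            if kind == "gene":
                gid += 1
                genes.append(
                    GeneModel(
                        gene_id=f"G{gid:04d}",
                        host=name,
                        strand="+" if rng.random() < 0.5 else "-",
                        transcripts=_make_transcripts(
                            rng, pos, L, params.cds_exons_per_gene
                        ),
                    )
                )
            else:
                loci.append((name, pos + L // 2))
            pos += L
    genes.sort(key=lambda g: (g.host, g.span[0]))
    # renumber in positional order so ids are stable and readable
    renamed = [
        replace(g, gene_id=f"G{i + 1:04d}") for i, g in enumerate(genes)
    ]
    return ReferenceGenome(chromosomes=chroms), renamed, loci


def insertion_loci(params: SimulationParams) -> list[tuple[str, int]]:
    """The fixed per-gene insertion loci implied by the seed."""
    return _simulate_reference_full(params)[2]


def _make_novel_genes(
    params: SimulationParams, loci: list[tuple[str, int]]
) -> list[NovelGeneSpec]:
    rng = _rng_for(params.seed, "novel-genes")
    specs = []
    for i in range(params.n_novel_genes):
        glen = int(rng.integers(params.gene_len[0], params.gene_len[1] + 1))
        cassette_id = f"NG{i + 1:02d}_cassette"
        seq = _random_dna(rng, glen + 2 * _CASSETTE_PAD)
        gene = GeneModel(
            gene_id=f"NG{i + 1:02d}",
            host=cassette_id,
            strand="+",
            transcripts=_make_transcripts(
                rng, _CASSETTE_PAD, glen, params.cds_exons_per_gene
            ),
        )
        chrom, locus = loci[i % len(loci)] if loci else ("chr1", params.chrom_len // 2)
        specs.append(
            NovelGeneSpec(
                gene=gene, cassette_id=cassette_id, cassette_seq=seq, chrom=chrom, locus=locus
            )
        )
    return specs


def _gene_deletion_span(gene: GeneModel) -> tuple[int, int]:
    start = min(tx[0][0] for tx in gene.transcripts)
    end = max(tx[-1][1] for tx in gene.transcripts)
    return (max(0, start - _DELETION_PAD), end + _DELETION_PAD)


def simulate_population(
    ref: ReferenceGenome,
    genes: list[GeneModel],
    params: SimulationParams,
    novel: list[NovelGeneSpec] | None = None,
) -> tuple[list[IndividualGenome], TruthSet, list[SampleMeta]]:
    """Draw individuals: per-cohort gene deletions, novel-gene insertions,
    sexes; returns genomes, the ground truth, and sample metadata."""
    if novel is None:
        novel = _make_novel_genes(params, insertion_loci(params))
    by_id = {g.gene_id: g for g in genes}
    for spec in params.cohorts:
        unknown = set(spec.absence_freqs) - set(by_id)
        if unknown:
            raise KeyError(f"absence frequencies for unknown genes: {sorted(unknown)}")

    individuals, meta = [], []
    pav: dict[tuple[str, str], bool] = {}
    svs: list[TrueSV] = []
    loci = {n.gene.gene_id: (n.chrom, n.locus) for n in novel}

    for spec in params.cohorts:
        for i in range(spec.n_samples):
            sid = f"{spec.name}{i + 1:03d}"
            rng = _rng_for(params.seed, f"sample:{sid}")
            sex = "male" if rng.random() < params.sex_ratio else "female"
            deleted: dict[str, list[tuple[int, int, str]]] = {c: [] for c in ref.chromosomes}
            for g in genes:
                if g.host == CHRY and sex == "female":
                    pav[(sid, g.gene_id)] = False
                    continue
                freq = spec.absence_freqs.get(g.gene_id, 0.0)
                absent = bool(rng.random() < freq)
                pav[(sid, g.gene_id)] = not absent
                if absent:
                    s, e = _gene_deletion_span(g)
                    deleted[g.host].append((s, e, g.gene_id))
                    svs.append(
                        TrueSV(sid, "DEL", g.host, s, e, e - s, g.gene_id)
                    )
            inserted: dict[str, list[NovelGeneSpec]] = {c: [] for c in ref.chromosomes}
            for n in novel:
                carries = bool(rng.random() < params.novel_carrier_freq)
                pav[(sid, n.gene.gene_id)] = carries
                if carries:
                    inserted[n.chrom].append(n)
                    svs.append(
                        TrueSV(
                            sid,
                            "INS",
                            n.chrom,
                            n.locus,
                            n.locus + 1,
                            len(n.cassette_seq),
                            n.gene.gene_id,
                        )
                    )
            chrom_segs: dict[str, list[Segment]] = {}
            for chrom, seq in ref.chromosomes.items():
                if chrom == CHRY and sex == "female":
                    continue
                events: list[tuple[int, int, str, NovelGeneSpec | None]] = [
                    (s, e, "del", None) for s, e, _ in deleted[chrom]
                ] + [(n.locus, n.locus, "ins", n) for n in inserted[chrom]]
                events.sort()
                segs: list[Segment] = []
                cur = 0
                for s, e, kind, n in events:
                    if s > cur:
                        segs.append(Segment(chrom, cur, s, seq[cur:s]))
                    if kind == "ins" and n is not None:
                        segs.append(
                            Segment(n.cassette_id, 0, len(n.cassette_seq), n.cassette_seq)
                        )
                    cur = max(cur, e)
                if cur < len(seq):
                    segs.append(Segment(chrom, cur, len(seq), seq[cur:]))
                chrom_segs[chrom] = segs
            individuals.append(IndividualGenome(sid, sex, chrom_segs))
            meta.append(SampleMeta(sample_id=sid, cohort=spec.name, sex=sex))
    truth = TruthSet(pav_truth=pav, novel_gene_loci=loci, sv_truth=svs)
    return individuals, truth, meta


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hits.size:
        # substitute with a uniformly different base
        cur = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(cur + rng.integers(1, 4, size=hits.size)) % 4]
    return arr.tobytes().decode("ascii")


def simulate_contigs(ind: IndividualGenome, params: SimulationParams) -> list[Contig]:
    """Fragment each individual chromosome at Poisson breakpoints and apply
    substitution errors; each contig remembers its true source interval."""
    rng = _rng_for(params.seed, f"contigs:{ind.sample_id}")
    out = []
    for chrom in ind.chromosomes:
        seq = ind.sequence(chrom)
        L = len(seq)
        n_breaks = rng.poisson(params.contig_break_rate * L / 10_000)
        cuts = np.sort(rng.integers(1, L, size=n_breaks)) if n_breaks else np.empty(0, int)
        bounds = [0, *np.unique(cuts).tolist(), L]
        for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
            if e <= s:
                continue
            out.append(
                Contig(
                    contig_id=f"{ind.sample_id}_{chrom}_c{i}",
                    seq=_mutate(seq[s:e], params.base_error_rate, rng),
                    sample_id=ind.sample_id,
                    source_chrom=chrom,
                    source_start=s,
                    source_end=e,
                )
            )
    return out


def _lift_intervals(
    segs: list[Segment], intervals: list[tuple[int, int]]
) -> dict[str, list[tuple[int, int]]]:
    """Map individual-coordinate intervals back to source coordinates."""
    out: dict[str, list[tuple[int, int]]] = {}
    offsets = []
    pos = 0
    for seg in segs:
        offsets.append((pos, pos + len(seg.seq), seg))
        pos += len(seg.seq)
    si = 0
    for s, e in intervals:
        while si < len(offsets) and offsets[si][1] <= s:
            si += 1
        j = si
        while j < len(offsets) and offsets[j][0] < e:
            o_s, o_e, seg = offsets[j]
            lo, hi = max(s, o_s), min(e, o_e)
            if lo < hi:
                out.setdefault(seg.source_id, []).append(
                    (seg.src_start + (lo - o_s), seg.src_start + (hi - o_s))
                )
            j += 1
    return {k: merge_intervals(v) for k, v in out.items()}


def simulate_depth(
    ind: IndividualGenome,
    params: SimulationParams,
    t: Thresholds | None = None,
    keep_reads: bool = False,
    counts_out: dict[str, np.ndarray] | None = None,
) -> tuple[DepthTrack, list[ReadPlacement]]:
    """Place uniform reads over the individual's actual sequence and lift
    the pileup to reference / cassette coordinates.

    Deleted regions receive zero depth by construction (the individual
    simply lacks them). With ``keep_reads`` the placements (with their
    sequences, mutated at the base error rate) are returned too. If a
    dict is passed as ``counts_out`` it is filled with per-base depth
    arrays in source coordinates (for writing depth TSVs).
    """
    t = t or Thresholds()
    rng = _rng_for(params.seed, f"depth:{ind.sample_id}")
    track = DepthTrack()
    reads: list[ReadPlacement] = []
    for chrom, segs in ind.chromosomes.items():
        seq = ind.sequence(chrom)
        L = len(seq)
        if L < params.read_len or params.depth <= 0:
            continue
        n_reads = rng.poisson(params.depth * L / params.read_len)
        starts = np.sort(rng.integers(0, L - params.read_len + 1, size=n_reads))
        # exact pileup via a difference array
        diff = np.zeros(L + 1, dtype=np.int32)
        np.add.at(diff, starts, 1)
        np.add.at(diff, starts + params.read_len, -1)
        depth_arr = np.cumsum(diff[:-1])
        covered = depth_arr >= t.depth_presence_min
        edges = np.diff(covered.astype(np.int8))
        iv_starts = np.nonzero(edges == 1)[0] + 1
        iv_ends = np.nonzero(edges == -1)[0] + 1
        if covered[0]:
            iv_starts = np.concatenate([[0], iv_starts])
        if covered[-1]:
            iv_ends = np.concatenate([iv_ends, [L]])
        intervals = list(zip(iv_starts.tolist(), iv_ends.tolist()))
        for host, ivs in _lift_intervals(segs, intervals).items():
            track.add(host, ivs)
        if counts_out is not None:
            pos = 0
            for seg in segs:
                sl = depth_arr[pos : pos + len(seg.seq)]
                arr = counts_out.setdefault(
                    seg.source_id, np.zeros(0, dtype=np.int32)
                )
                if arr.shape[0] < seg.src_end:
                    arr = np.concatenate(
                        [arr, np.zeros(seg.src_end - arr.shape[0], dtype=np.int32)]
                    )
                    counts_out[seg.source_id] = arr
                arr[seg.src_start : seg.src_end] += sl
                pos += len(seg.seq)
        if keep_reads:
            for s in starts.tolist():
                reads.append(
                    ReadPlacement(
                        chrom,
                        s,
                        s + params.read_len,
                        _mutate(seq[s : s + params.read_len], params.base_error_rate, rng),
                    )
                )
    return track, reads


def simulate_long_reads(
    ind: IndividualGenome,
    params: SimulationParams,
    novel: list[NovelGeneSpec],
    ref: ReferenceGenome,
    t: Thresholds | None = None,
) -> list[LongReadContig]:
    """Error-free long-read contigs spanning each insertion the individual
    carries, with at least anchor-flank-length of true reference flank."""
    t = t or Thresholds()
    flank = t.anchor_flank_len + 500
    out = []
    carried = {
        seg.source_id
        for segs in ind.chromosomes.values()
        for seg in segs
        if not seg.source_id.startswith("chr")
    }
    for n in novel:
        if n.cassette_id not in carried:
            continue
        chrom_seq = ref[n.chrom]
        lo = max(0, n.locus - flank)
        hi = min(len(chrom_seq), n.locus + flank)
        for j in range(params.long_reads_per_insertion):
            out.append(
                LongReadContig(
                    contig_id=f"{ind.sample_id}_{n.gene.gene_id}_lr{j}",
                    seq=chrom_seq[lo : n.locus] + n.cassette_seq + chrom_seq[n.locus : hi],
                )
            )
    return out


def simulate_sv_callsets(
    truth: TruthSet,
    params: SimulationParams,
    n_callers: int = 3,
    novel: list[NovelGeneSpec] | None = None,
    chrom_names: list[str] | None = None,
) -> dict[str, list[SVCall]]:
    """Per-caller noisy views of the true SVs.

    Each caller misses a true event with the false-negative rate, jitters
    breakpoints with rounded Gaussian noise, and adds Poisson false
    positives proportional to the number of true events.
    """
    cassette_seq = {n.gene.gene_id: n.cassette_seq for n in (novel or [])}
    callsets: dict[str, list[SVCall]] = {}
    chroms = chrom_names or sorted({sv.chrom for sv in truth.sv_truth}) or ["chr1"]
    for c in range(n_callers):
        caller = f"caller{c + 1}"
        rng = _rng_for(params.seed, f"svcaller:{caller}")
        calls: list[SVCall] = []
        k = 0
        by_sample: dict[str, int] = {}
        for sv in truth.sv_truth:
            by_sample[sv.sample_id] = by_sample.get(sv.sample_id, 0) + 1
            if rng.random() < params.sv_caller_fn_rate:
                continue
            jp = int(round(rng.normal(0, params.sv_caller_jitter_sd))) if params.sv_caller_jitter_sd else 0
            je = int(round(rng.normal(0, params.sv_caller_jitter_sd))) if params.sv_caller_jitter_sd else 0
            pos = max(0, sv.pos + jp)
            if sv.svtype == "INS":
                end = pos + 1
            else:
                end = max(pos + 1, sv.end + je)
            k += 1
            calls.append(
                SVCall(
                    caller=caller,
                    call_id=f"{caller}_{k}",
                    sample_id=sv.sample_id,
                    chrom=sv.chrom,
                    pos=pos,
                    end=end,
                    svtype=sv.svtype,
                    svlen=-(end - pos) if sv.svtype == "DEL" else sv.length,
                    strands="+-",
                    genotype="hom",
                    ins_sequence=cassette_seq.get(sv.gene_id) if sv.svtype == "INS" else None,
                )
            )
        for sid, n_true in sorted(by_sample.items()):
            for _ in range(rng.poisson(params.sv_caller_fp_rate * n_true)):
                svtype = "DEL" if rng.random() < 0.5 else "INS"
                length = int(rng.integers(50, 5000))
                pos = int(rng.integers(0, max(1, params.chrom_len - length)))
                k += 1
                calls.append(
                    SVCall(
                        caller=caller,
                        call_id=f"{caller}_{k}",
                        sample_id=sid,
                        chrom=str(rng.choice(chroms)),
                        pos=pos,
                        end=pos + 1 if svtype == "INS" else pos + length,
                        svtype=svtype,
                        svlen=length if svtype == "INS" else -length,
                        strands="+-",
                        genotype="het" if rng.random() < 0.5 else "hom",
                        ins_sequence=_random_dna(rng, length) if svtype == "INS" else None,
                    )
                )
        callsets[caller] = calls
    return callsets


def simulate_study(params: SimulationParams) -> Study:
    """Run the full generator: reference, novel genes, population, truth."""
    ref, genes, loci = _simulate_reference_full(params)
    novel = _make_novel_genes(params, loci)
    individuals, truth, meta = simulate_population(ref, genes, params, novel)
    return Study(
        params=params,
        reference=ref,
        ref_genes=genes,
        novel_genes=novel,
        individuals=individuals,
        meta=meta,
        truth=truth,
    )


def write_study(
    study: Study,
    outdir,
    t: Thresholds | None = None,
    n_callers: int = 3,
) -> None:
    """Write the whole study to disk: reference FASTA + GFF3, cassette
    FASTA + novel-gene GFF3, per-sample contigs / depth TSV / long-read
    FASTA, per-caller SV TSVs, sample metadata, and the truth tables."""
    from pathlib import Path

    import pandas as pd

    from . import io as pio
    from .sv_merge import write_sv_tsv

    t = t or Thresholds()
    out = Path(outdir)
    for sub in ("contigs", "depth", "longreads", "sv", "truth"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    pio.write_fasta(study.reference.chromosomes, out / "reference.fa")
    pio.write_gff3(study.ref_genes, out / "genes.gff3")
    pio.write_fasta(
        {n.cassette_id: n.cassette_seq for n in study.novel_genes}, out / "cassettes.fa"
    )
    pio.write_gff3([n.gene for n in study.novel_genes], out / "novel_genes.gff3")
    pio.write_sample_meta(study.meta, out / "meta.tsv")

    for ind in study.individuals:
        contigs = simulate_contigs(ind, study.params)
        pio.write_fasta(
            {c.contig_id: c.seq for c in contigs}, out / "contigs" / f"{ind.sample_id}.fa"
        )
        counts: dict[str, np.ndarray] = {}
        simulate_depth(ind, study.params, t, counts_out=counts)
        pio.write_depth_tsv(
            {h: arr.tolist() for h, arr in counts.items()},
            out / "depth" / f"{ind.sample_id}.tsv",
        )
        lr = simulate_long_reads(ind, study.params, study.novel_genes, study.reference, t)
        pio.write_fasta({c.contig_id: c.seq for c in lr}, out / "longreads" / f"{ind.sample_id}.fa")

    callsets = simulate_sv_callsets(study.truth, study.params, n_callers, study.novel_genes)
    for caller, calls in callsets.items():
        write_sv_tsv(calls, out / "sv" / f"{caller}.tsv")

    pd.DataFrame(
        [
            {"sample": s, "gene": g, "present": int(v)}
            for (s, g), v in sorted(study.truth.pav_truth.items())
        ]
    ).to_csv(out / "truth" / "pav_truth.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene": g, "chrom": c, "locus": p}
            for g, (c, p) in sorted(study.truth.novel_gene_loci.items())
        ]
    ).to_csv(out / "truth" / "novel_loci.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample": sv.sample_id,
                "type": sv.svtype,
                "chrom": sv.chrom,
                "pos": sv.pos,
                "end": sv.end,
                "length": sv.length,
                "gene": sv.gene_id,
            }
            for sv in study.truth.sv_truth
        ]
    ).to_csv(out / "truth" / "sv_truth.tsv", sep="\t", index=False)


def simulate_presence_matrix(
    gene_freqs_case: dict[str, float],
    gene_freqs_control: dict[str, float],
    n_case: int,
    n_control: int,
    rng: np.random.Generator,
):
    """Bernoulli draw of two cohort PAV matrices from absence frequencies.

    A lightweight emulator for statistical calibration (null and power
    studies) that skips genome simulation entirely: coverage is 1.0 for
    present calls and 0.0 for absent calls.
    """
    import pandas as pd

    from .pav import PAVMatrix

    def one(freqs: dict[str, float], n: int, cohort: str) -> "PAVMatrix":
        gene_ids = sorted(freqs)
        samples = [f"{cohort}{i + 1:03d}" for i in range(n)]
        absent = rng.random((n, len(gene_ids))) < np.array([freqs[g] for g in gene_ids])
        coverage = pd.DataFrame(
            np.where(absent, 0.0, 1.0), index=samples, columns=gene_ids
        )
        genes = {
            g: GeneModel(gene_id=g, host="chr1", strand="+", transcripts=(((0, 100),),))
            for g in gene_ids
        }
        meta = {
            s: SampleMeta(sample_id=s, cohort=cohort, sex="male") for s in samples
        }
        return PAVMatrix(
            coverage=coverage, presence=coverage > 0.8, genes=genes, meta=meta
        )

    return (
        one(gene_freqs_case, n_case, "case"),
        one(gene_freqs_control, n_control, "control"),
    )
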