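import dataclasses

import numpy as np
import pytest

from pavpan.config import Thresholds
from pavpan.pav import CHRY, cds_coverage
from pavpan.synthetic_data import (
    CohortSpec,
    SimulationParams,
    default_params,
    simulate_contigs,
    simulate_depth,
    simulate_long_reads,
    simulate_population,
    simulate_reference,
    simulate_study,
    simulate_sv_callsets,
)


class TestReference:
    def test_deterministic(self, small_params):
        r1, g1 = simulate_reference(small_params)
        r2, g2 = simulate_reference(small_params)
        assert r1.chromosomes == r2.chromosomes
        assert g1 == g2

    def test_zero_genes(self):
        params = SimulationParams(seed=0, n_ref_genes=0, n_novel_genes=0)
        _, genes = simulate_reference(params)
        assert genes == []

    def test_infeasible_packing_raises(self):
        params = SimulationParams(seed=0, chrom_len=1000, n_ref_genes=120)
        with pytest.raises(ValueError, match="pack"):
            simulate_reference(params)

    def test_genes_non_overlapping_and_on_chry(self, small_study):
        genes = small_study.ref_genes
        by_host = {}
        for g in genes:
            by_host.setdefault(g.host, []).append(g.span)
        for spans in by_host.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2
        n_y = sum(1 for g in genes if g.host == CHRY)
        assert n_y == round(0.1 * len(genes))


class TestPopulation:
    def test_unknown_gene_in_freq_map(self, small_params):
        ref, genes = simulate_reference(small_params)
        bad = dataclasses.replace(
            small_params,
            cohorts=(CohortSpec("case", 2, {"NOPE": 0.5}),),
        )
        with pytest.raises(KeyError, match="NOPE"):
            simulate_population(ref, genes, bad)

    def test_degenerate_frequencies(self):
        params = SimulationParams(
            seed=5,
            n_novel_genes=0,
            cohorts=(
                CohortSpec("a", 6, {"G0001": 1.0}),
                CohortSpec("b", 6, {}),
            ),
        )
        study_ref, genes = simulate_reference(params)
        _, truth, meta = simulate_population(study_ref, genes, params)
        for m in meta:
            expected = m.cohort == "b"
            assert truth.pav_truth[(m.sample_id, "G0001")] is expected
        # frequency 0 everywhere else: all present except female chrY
        sexes = {m.sample_id: m.sex for m in meta}
        for (sid, gid), present in truth.pav_truth.items():
            if gid == "G0001":
                continue
            host = next(g.host for g in genes if g.gene_id == gid)
            if host == CHRY and sexes[sid] == "female":
                assert not present
            else:
                assert present

    def test_absence_count_within_binomial_99(self):
        """Empirical absences at freq 0.6, n=50, inside the 99% interval."""
        params = SimulationParams(
            seed=7,
            n_novel_genes=0,
            cohorts=(CohortSpec("a", 50, {"G0020": 0.6}),),
        )
        ref, genes = simulate_reference(params)
        _, truth, _ = simulate_population(ref, genes, params)
        absences = sum(
            1 for (s, g), present in truth.pav_truth.items() if g == "G0020" and not present
        )
        # Binomial(50, 0.6): mean 30, sd 3.46; z(0.995)=2.576 -> [22, 38]
        assert 21 <= absences <= 39

    def test_truth_consistency_pav_vs_sv(self, small_study):
        sexes = {m.sample_id: m.sex for m in small_study.meta}
        hosts = {g.gene_id: g.host for g in small_study.ref_genes}
        dels = {(sv.sample_id, sv.gene_id) for sv in small_study.truth.sv_truth if sv.svtype == "DEL"}
        for (sid, gid), present in small_study.truth.pav_truth.items():
            if gid not in hosts:
                continue  # novel genes correspond to INS events
            female_y = hosts[gid] == CHRY and sexes[sid] == "female"
            if not present and not female_y:
                assert (sid, gid) in dels
            if present:
                assert (sid, gid) not in dels


class TestContigs:
    def test_no_breaks_no_error_identity(self, small_study):
        params = dataclasses.replace(small_study.params, contig_break_rate=0.0)
        ind = small_study.individuals[0]
        contigs = simulate_contigs(ind, params)
        per_chrom = {c.source_chrom: c for c in contigs}
        assert len(contigs) == len(ind.chromosomes)
        for chrom in ind.chromosomes:
            assert per_chrom[chrom].seq == ind.sequence(chrom)

    def test_conservation_under_fragmentation(self, small_study):
        ind = small_study.individuals[1]
        contigs = simulate_contigs(ind, small_study.params)
        by_chrom = {}
        for c in sorted(contigs, key=lambda c: (c.source_chrom, c.source_start)):
            by_chrom.setdefault(c.source_chrom, []).append(c.seq)
        for chrom in ind.chromosomes:
            assert "".join(by_chrom[chrom]) == ind.sequence(chrom)

    def test_n50_matches_independent_resimulation(self, small_study):
        """N50 of emitted contigs vs a re-simulation of the same Poisson
        fragmentation written independently here."""

        def n50(lengths):
            lengths = sorted(lengths, reverse=True)
            half = sum(lengths) / 2
            acc = 0
            for L in lengths:
                acc += L
                if acc >= half:
                    return L

        got = [
            len(c.seq)
            for ind in small_study.individuals
            for c in simulate_contigs(ind, small_study.params)
        ]
        rng = np.random.default_rng(12345)
        resim = []
        for ind in small_study.individuals:
            for chrom in ind.chromosomes:
                L = ind.length(chrom)
                cuts = np.sort(rng.integers(1, L, size=rng.poisson(L / 10_000)))
                bounds = [0, *np.unique(cuts).tolist(), L]
                resim += [e - s for s, e in zip(bounds, bounds[1:])]
        ratio = n50(got) / n50(resim)
        assert 0.8 <= ratio <= 1.25


class TestDepth:
    def test_zero_depth_empty_track(self, small_study):
        params = dataclasses.replace(small_study.params, depth=0.0)
        track, _ = simulate_depth(small_study.individuals[0], params)
        assert track.covered == {}

    def test_deleted_gene_cds_has_zero_depth(self, small_study, thresholds):
        truth = small_study.truth.pav_truth
        genes = {g.gene_id: g for g in small_study.ref_genes}
        for ind in small_study.individuals:
            absent = [
                g
                for gid, g in genes.items()
                if not truth[(ind.sample_id, gid)] and not (g.host == CHRY and ind.sex == "female")
            ]
            if not absent:
                continue
            track, _ = simulate_depth(ind, small_study.params, thresholds)
            assert cds_coverage(absent[0], track) == 0.0
            return
        pytest.skip("no sample with a planted deletion")

    def test_present_gene_cds_nearly_fully_covered(self, small_study, thresholds):
        ind = small_study.individuals[0]
        track, _ = simulate_depth(ind, small_study.params, thresholds)
        present = [
            g
            for g in small_study.ref_genes
            if small_study.truth.pav_truth[(ind.sample_id, g.gene_id)]
            and not (g.host == CHRY and ind.sex == "female")
        ]
        covs = [cds_coverage(g, track) for g in present[:20]]
        assert min(covs) >= 0.999  # 1 - e^-30 per-base coverage


class TestLongReads:
    def test_no_insertions_empty(self, small_params, thresholds):
        params = dataclasses.replace(small_params, novel_carrier_freq=0.0)
        study = simulate_study(params)
        for ind in study.individuals:
            assert (
                simulate_long_reads(ind, params, study.novel_genes, study.reference, thresholds)
                == []
            )

    def test_length_additivity_and_exact_flanks(self, small_study, thresholds):
        t = thresholds
        for ind in small_study.individuals:
            lrs = simulate_long_reads(
                ind, small_study.params, small_study.novel_genes, small_study.reference, t
            )
            for c in lrs:
                gid = c.contig_id.split("_")[1]
                n = next(x for x in small_study.novel_genes if x.gene.gene_id == gid)
                assert len(c.seq) >= len(n.cassette_seq) + 2 * t.anchor_flank_len
                flank = t.anchor_flank_len + 500
                ref_seq = small_study.reference[n.chrom]
                assert c.seq.startswith(ref_seq[max(0, n.locus - flank) : n.locus][:100])
                assert c.seq.endswith(ref_seq[n.locus : n.locus + flank][-100:])
            if lrs:
                return


class TestSVCallsets:
    def test_noise_free_callers_emit_truth(self, small_study):
        params = dataclasses.replace(
            small_study.params,
            sv_caller_jitter_sd=0.0,
            sv_caller_fn_rate=0.0,
            sv_caller_fp_rate=0.0,
        )
        callsets = simulate_sv_callsets(small_study.truth, params, 3, small_study.novel_genes)
        truth = [(sv.sample_id, sv.chrom, sv.pos, sv.svtype) for sv in small_study.truth.sv_truth]
        for calls in callsets.values():
            got = [(c.sample_id, c.chrom, c.pos, c.svtype) for c in calls]
            assert got == truth

    def test_fn_one_empties_all(self, small_study):
        params = dataclasses.replace(
            small_study.params, sv_caller_fn_rate=1.0, sv_caller_fp_rate=0.0
        )
        callsets = simulate_sv_callsets(small_study.truth, params, 3)
        assert all(calls == [] for calls in callsets.values())

    def test_jitter_mean_is_half_normal(self):
        """Mean |reported - true| ~ sd * sqrt(2/pi) for Gaussian jitter."""
        params = default_params(seed=3, n_per_cohort=25)
        study = simulate_study(params)
        noiseless = dataclasses.replace(
            params, sv_caller_fn_rate=0.0, sv_caller_fp_rate=0.0
        )
        callsets = simulate_sv_callsets(study.truth, noiseless, 3, study.novel_genes)
        offsets = []
        for calls in callsets.values():
            for call, sv in zip(calls, study.truth.sv_truth):
                offsets.append(abs(call.pos - sv.pos))
        expected = 50 * np.sqrt(2 / np.pi)
        assert len(offsets) > 500
        assert np.mean(offsets) == pytest.approx(expected, rel=0.10)


class TestStudyDeterminism:
    def test_identical_params_identical_outputs(self, small_params, small_study):
        other = simulate_study(small_params)
        assert other.reference.chromosomes == small_study.reference.chromosomes
        assert other.truth.pav_truth == small_study.truth.pav_truth
        assert other.truth.sv_truth == small_study.truth.sv_truth
        ind_a = small_study.individuals[0]
        ind_b = other.individuals[0]
        for chrom in ind_a.chromosomes:
            assert ind_a.sequence(chrom) == ind_b.sequence(chrom)
        ca = simulate_contigs(ind_a, small_params)
        cb = simulate_contigs(ind_b, small_params)
        assert [c.seq for c in ca] == [c.seq for c in cb]
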