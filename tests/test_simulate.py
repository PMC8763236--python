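"""Synthetic-data generators: planted-copy truth, GC targets, transposition
mechanics, Wright-Fisher dynamics, read simulation, growth curves."""

from __future__ import annotations

import numpy as np
import pytest

from isburst._util import gc_fraction, revcomp
from isburst.census import flag_pseudogenes
from isburst.simulate import (
    EvolutionParams,
    Genotype,
    ISFamilySpec,
    calibrate_target_bias,
    generate_genome,
    simulate_growth_curve,
    simulate_reads,
    simulate_serial_transfer,
    simulate_transposition,
)
from isburst.simulate.genome import CapacityError
from isburst.simulate.reads import flatten_pairs
from isburst.simulate.rnaseq import simulate_rnaseq
from isburst.simulate.transposition import apply_events, expected_tsd_gc


class TestGenerateGenome:
    def test_nine_copies_one_intact(self, nine_copy_genome):
        genome, planted, spec = nine_copy_genome
        assert len(planted) == 9
        assert sum(p.intact for p in planted) == 1
        # the 8 non-intact copies all carry a frameshift
        for p in planted:
            gene = next(g for g in genome.genes if g.gene_id == p.gene_id)
            call = flag_pseudogenes(genome.gene_seq(gene))
            assert call.intact == p.intact
            if not p.intact:
                assert "frameshift" in call.reasons

    def test_no_families_means_no_transposases(self):
        genome, planted = generate_genome(1, [5000], family_specs=[], seed=0)
        assert planted == []
        assert not any(g.is_transposase for g in genome.genes)

    def test_realized_coding_gc_near_target(self):
        genome, _ = generate_genome(
            1, [150_000], gc_coding=0.475, gc_noncoding=0.415,
            gene_density=0.7, family_specs=[], seed=7,
        )
        coding = "".join(genome.gene_seq(g) for g in genome.genes)
        assert len(coding) > 80_000
        assert gc_fraction(coding) == pytest.approx(0.475, abs=0.01)
        mask = genome.coding_mask("contig_0")
        noncoding = "".join(
            c for c, m in zip(genome.contigs["contig_0"], mask) if not m
        )
        assert gc_fraction(noncoding) == pytest.approx(0.415, abs=0.015)

    def test_capacity_error(self):
        spec = ISFamilySpec("big", element_length=2000, copy_number=3)
        with pytest.raises(CapacityError):
            generate_genome(1, [1000], family_specs=[spec], seed=0)

    def test_deterministic_under_seed(self):
        spec = ISFamilySpec("fam", element_length=600, copy_number=2)
        g1, p1 = generate_genome(1, [10_000], family_specs=[spec], seed=3)
        g2, p2 = generate_genome(1, [10_000], family_specs=[spec], seed=3)
        assert g1.contigs == g2.contigs
        assert [vars(a) for a in p1] == [vars(b) for b in p2]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ISFamilySpec("x", copy_number=1, intact_copies=2)
        with pytest.raises(ValueError):
            ISFamilySpec("x", element_length=20, itr_length=14)


class TestTransposition:
    def test_single_event_string_structure(self, caller_genome):
        """Inserted locus reads flank + TSD + element + TSD + flank."""
        genome, planted, elem = caller_genome
        muts, events = simulate_transposition(
            genome, planted, "ISAm1", 1, beta=0.0, seed=21, tsd_length=8
        )
        ev = events[0]
        ref = genome.contigs[ev.contig]
        s, k = ev.site, len(ev.tsd_seq)
        assert k == 8
        assert ev.tsd_seq == ref[s:s + k]
        assert muts[0][ev.contig] == ref[:s + k] + ev.element_seq + ref[s:]

    def test_copy_and_paste_preserves_donor(self, caller_genome):
        genome, planted, elem = caller_genome
        donor = next(p for p in planted if p.intact)
        muts, events = simulate_transposition(genome, planted, "ISAm1", 3, seed=2)
        for mut in muts:
            donor_region = genome.contigs[donor.contig][donor.start:donor.end]
            assert donor_region in mut[donor.contig]

    def test_unbiased_sampling_matches_genome_gc(self):
        genome, planted = generate_genome(
            1, [40_000], gc_coding=0.5, gc_noncoding=0.5, gene_density=0.5,
            family_specs=[ISFamilySpec("f", element_length=300, copy_number=1)],
            seed=13,
        )
        _, events = simulate_transposition(
            genome, planted, "f", 10_000, beta=0.0, seed=4, tsd_length=8,
        )
        mean_gc = np.mean([gc_fraction(e.tsd_seq) for e in events])
        assert mean_gc == pytest.approx(0.50, abs=0.02)

    def test_calibrated_bias_hits_27_percent(self, nine_copy_genome):
        genome, planted, _ = nine_copy_genome
        beta = calibrate_target_bias(genome, 8, 0.27)
        assert expected_tsd_gc(genome, 8, beta) == pytest.approx(0.27, abs=1e-4)
        _, events = simulate_transposition(
            genome, planted, "ISAm1", 3000, beta=beta, seed=6, tsd_length=8
        )
        mean_gc = np.mean([gc_fraction(e.tsd_seq) for e in events])
        assert mean_gc == pytest.approx(0.27, abs=0.02)

    def test_no_intact_donor_raises(self):
        spec = ISFamilySpec("dead", element_length=400, copy_number=2, intact_copies=0)
        genome, planted = generate_genome(1, [10_000], family_specs=[spec], seed=1)
        with pytest.raises(ValueError, match="intact donor"):
            simulate_transposition(genome, planted, "dead", 1, seed=0)

    def test_apply_events_right_to_left(self, caller_genome):
        genome, planted, _ = caller_genome
        _, events = simulate_transposition(genome, planted, "ISAm1", 2, seed=33)
        merged = apply_events(genome.contigs, events)
        extra = sum(len(e.element_seq) + len(e.tsd_seq) for e in events)
        assert sum(map(len, merged.values())) == sum(map(len, genome.contigs.values())) + extra


class TestSerialTransfer:
    def test_generations_per_cycle(self):
        p = EvolutionParams(dilution_factor=150.0)
        assert p.generations_per_cycle == pytest.approx(np.log2(150), abs=1e-9)

    def test_neutral_drift_bounded_at_large_n(self):
        founder = [
            (Genotype("anc", frozenset()), 0.5),
            (Genotype("mut", frozenset({"A"})), 0.5),
        ]
        params = EvolutionParams(bottleneck_size=1_000_000, n_cycles=10)
        res = simulate_serial_transfer(founder, params, seed=8)
        freqs = res.allele_frequencies["A"].to_numpy()
        assert np.abs(np.diff(freqs)).max() < 0.01

    def test_frequencies_conserved(self):
        founder = [
            (Genotype("anc", frozenset()), 0.7),
            (Genotype("mut", frozenset({"A"})), 0.3),
        ]
        params = EvolutionParams(bottleneck_size=500, n_cycles=20, transposition_rate=1e-4)
        res = simulate_serial_transfer(founder, params, seed=9)
        sums = res.genotype_frequencies.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_neutral_fixation_proportion(self):
        """Diffusion prediction: fixation probability of a neutral allele
        equals its initial frequency (Monte-Carlo check at 0.1)."""
        params = EvolutionParams(bottleneck_size=100, n_cycles=400)
        fixed = 0
        n_rep = 400
        for rep in range(n_rep):
            founder = [
                (Genotype("anc", frozenset()), 0.9),
                (Genotype("mut", frozenset({"A"})), 0.1),
            ]
            res = simulate_serial_transfer(founder, params, seed=10_000 + rep)
            fixed += res.allele_frequencies["A"].iloc[-1] >= 0.999
        # 95% MC interval at n=400 is ~±0.03
        assert fixed / n_rep == pytest.approx(0.10, abs=0.045)

    def test_clonal_interference_with_equal_benefits(self):
        """Two beneficial alleles in distinct backgrounds segregate
        simultaneously at intermediate cycles in most replicates."""
        both = 0
        n_rep = 30
        for rep in range(n_rep):
            founder = [
                (Genotype("anc", frozenset()), 0.98),
                (Genotype("g1", frozenset({"A"}), 1.08, 1.0), 0.01),
                (Genotype("g2", frozenset({"B"}), 1.08, 1.0), 0.01),
            ]
            params = EvolutionParams(bottleneck_size=2000, n_cycles=30)
            res = simulate_serial_transfer(founder, params, seed=500 + rep)
            af = res.allele_frequencies
            co = ((af["A"] > 0.05) & (af["A"] < 0.95) & (af["B"] > 0.05) & (af["B"] < 0.95))
            both += co.any()
        assert both / n_rep > 0.5


class TestSimulateReads:
    def test_coverage_and_exactness_without_errors(self, caller_genome):
        genome, _, _ = caller_genome
        pairs, truth = simulate_reads(
            [(genome.contigs, 1.0)], depth=30, read_length=100,
            insert_size=300, error_rate=0.0, seed=3,
        )
        L = sum(len(s) for s in genome.contigs.values())
        cov = len(pairs) * 200 / L
        assert cov == pytest.approx(30, abs=2)
        joined = genome.contigs["contig_0"]
        for r1, r2 in pairs[:200]:
            assert r1.seq in joined or revcomp(r1.seq) in joined
            assert r2.seq in joined or revcomp(r2.seq) in joined

    def test_mixture_proportions(self, caller_genome):
        genome, planted, _ = caller_genome
        muts, _ = simulate_transposition(genome, planted, "ISAm1", 1, seed=70)
        pairs, truth = simulate_reads(
            [(genome.contigs, 0.6), (muts[0], 0.4)], depth=80,
            read_length=100, insert_size=300, seed=5,
        )
        frac_mut = (truth.genome_index == 1).mean()
        # weight x length sampling: mutant genome is slightly longer
        assert frac_mut == pytest.approx(0.4, abs=0.05)

    def test_error_rate_realized(self, caller_genome):
        genome, _, _ = caller_genome
        pairs, truth = simulate_reads(
            [(genome.contigs, 1.0)], depth=40, read_length=100,
            insert_size=250, error_rate=0.01, seed=6,
        )
        ref = genome.contigs["contig_0"]
        mism = total = 0
        for (r1, _), row in zip(pairs, truth.itertuples()):
            frag = ref[row.frag_start:row.frag_end]
            expect = frag[:100] if row.r1_strand == "+" else revcomp(frag[-100:])
            mism += sum(1 for a, b in zip(r1.seq, expect) if a != b)
            total += 100
        assert mism / total == pytest.approx(0.01, abs=0.001)

    def test_insert_shorter_than_read_rejected(self, caller_genome):
        genome, _, _ = caller_genome
        with pytest.raises(ValueError):
            simulate_reads([(genome.contigs, 1.0)], depth=1, read_length=100, insert_size=50)


class TestSimulateRnaseq:
    GENES = None

    def _genes(self):
        rng = np.random.default_rng(17)
        from isburst._util import random_seq

        return {f"g{i}": random_seq(rng, 900, 0.5) for i in range(4)}

    def test_zero_antisense(self):
        genes = self._genes()
        _, truth, _ = simulate_rnaseq(genes, {g: 1.0 for g in genes}, antisense_fraction=0.0,
                                      depth=2000, seed=1)
        assert truth.antisense.sum() == 0

    def test_identical_paralogs_split_in_truth(self):
        from isburst._util import random_seq

        seq = random_seq(np.random.default_rng(23), 800, 0.5)
        genes = {"copyA": seq, "copyB": seq}
        _, truth, _ = simulate_rnaseq(genes, {"copyA": 3.0, "copyB": 1.0},
                                      depth=20_000, seed=2)
        share = truth.set_index("gene_id").sense / truth.sense.sum()
        assert share["copyA"] == pytest.approx(0.75, abs=0.02)
        assert share["copyB"] == pytest.approx(0.25, abs=0.02)

    def test_antisense_fraction_realized(self):
        genes = self._genes()
        _, truth, _ = simulate_rnaseq(genes, {g: 1.0 for g in genes},
                                      antisense_fraction=0.2, depth=10_000, seed=3)
        frac = truth.antisense.sum() / (truth.sense.sum() + truth.antisense.sum())
        assert frac == pytest.approx(0.2, abs=0.01)

    def test_invalid_weights(self):
        genes = self._genes()
        with pytest.raises(ValueError):
            simulate_rnaseq(genes, {g: 0.0 for g in genes}, depth=10)


class TestSimulateGrowthCurve:
    def test_zero_noise_continuity_and_shape(self):
        df = simulate_growth_curve(a=0.001, r=0.0163, m=0.00135, t_break=400,
                                   noise_sd=0.0, seed=0)
        od = df.od.to_numpy()
        t = df.time_h.to_numpy()
        pre = t <= 400
        assert np.allclose(od[pre], 0.001 * np.exp(0.0163 * t[pre]))
        d = np.diff(od[~pre])
        assert np.allclose(d, 0.00135 * 48, atol=1e-12)

    def test_flat_after_break_when_m_zero(self):
        df = simulate_growth_curve(m=0.0, t_break=384, noise_sd=0.0)
        post = df[df.time_h > 384].od.to_numpy()
        assert np.allclose(post, post[0])

    def test_negative_od_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clip"):
            df = simulate_growth_curve(a=1e-6, r=0.0, m=0.0, t_break=0.0,
                                       noise_sd=0.5, seed=12)
        assert (df.od >= 0).all()
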