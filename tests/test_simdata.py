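"""Simulator behavior: determinism, planted-truth statistics, cut/stop
geometry, conservation, and spike-in pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmseq.core import MethylationTruth, MotifRule
from mmseq.simdata import (
    SimConfig,
    find_motif_adenines,
    mix_spikein,
    plant_methylation,
    simulate_fragments_endo,
    simulate_fragments_exo,
    simulate_genome,
    simulate_wga,
)
from mmseq.annotate import partition_by_namespace


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        assert simulate_genome(1, 1000, 0.5, 7) == simulate_genome(1, 1000, 0.5, 7)

    def test_gc_content_matches_request(self):
        g = simulate_genome(1, 10_000, 0.64, 1)
        seq = g["contig1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.64) < 0.03  # binomial CI on 10,000 draws

    def test_multiple_contigs_distinct_names(self):
        g = simulate_genome(2, 100, 0.5, 1)
        assert len(g.names()) == 2 and len(set(g.names())) == 2

    @pytest.mark.parametrize("bad", [dict(length=50), dict(gc=0.0), dict(n_contigs=0)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(n_contigs=1, length=1000, gc=0.5, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            simulate_genome(kwargs["n_contigs"], kwargs["length"], kwargs["gc"], 0)


class TestPlantMethylation:
    def test_fraction_one_includes_every_motif_adenine(self, toy_genome, gatc_rule):
        truth = plant_methylation(toy_genome, gatc_rule, 1.0, 3)
        expected = set(find_motif_adenines(toy_genome, gatc_rule))
        assert truth.positions() == expected
        # GATC: plus A at offset 1, minus A opposite offset 2
        for contig, pos, strand in truth.positions():
            assert toy_genome.base(contig, pos, strand) == "A"

    def test_fraction_zero_is_empty(self, toy_genome, gatc_rule):
        assert len(plant_methylation(toy_genome, gatc_rule, 0.0, 3)) == 0

    def test_half_fraction_within_binomial_ci(self, toy_genome, gatc_rule):
        truth = plant_methylation(toy_genome, gatc_rule, 0.5, 3)
        total = len(find_motif_adenines(toy_genome, gatc_rule))
        assert abs(len(truth) / total - 0.5) < 0.1

    def test_joint_duplex_planting_pairs_strand_adenines(self, toy_genome, gatc_rule):
        truth = plant_methylation(toy_genome, gatc_rule, 0.5, 3)
        keys = truth.positions()
        for contig, pos, strand in keys:
            partner = (contig, pos + 1, "-") if strand == "+" else (contig, pos - 1, "+")
            assert partner in keys

    def test_rule_without_adenine_rejected(self):
        with pytest.raises(ValueError):
            MotifRule("bad", "GGTC", 1)


class TestEndoSimulator:
    def test_oligo_cleaved_into_25_and_34(self, oligo, full_length_cfg):
        genome, truth = oligo
        frags = simulate_fragments_endo(genome, truth, full_length_cfg)
        assert sorted(f.length for f in frags) == [25, 34]
        up = next(f for f in frags if f.source_tag == "endo_up")
        assert (up.start, up.end) == (0, 25)

    def test_capture_zero_equals_pure_shear(self, toy_genome, toy_truth):
        cfg0 = SimConfig(n_fragments=500, capture_prob=0.0, seed=9)
        sheared = simulate_fragments_endo(toy_genome, toy_truth, cfg0)
        null = simulate_fragments_endo(toy_genome, MethylationTruth(), cfg0)
        assert sheared == null

    def test_cut_count_binomial(self, oligo):
        genome, truth = oligo
        cfg = SimConfig(
            n_fragments=100, capture_prob=0.5, frag_len_mean=59, frag_len_sd=0, seed=0
        )
        frags = simulate_fragments_endo(genome, truth, cfg)
        n_cut = sum(f.source_tag == "endo_up" for f in frags)
        assert 35 <= n_cut <= 65  # 50 +/- 15, binomial CI

    def test_determinism(self, toy_genome, toy_truth):
        cfg = SimConfig(n_fragments=300, capture_prob=0.4, seed=21)
        a = simulate_fragments_endo(toy_genome, toy_truth, cfg)
        b = simulate_fragments_endo(toy_genome, toy_truth, cfg)
        assert a == b

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), capture=st.floats(0.0, 1.0))
    def test_cut_pieces_partition_fragment_spans(self, toy_genome, toy_truth, seed, capture):
        """Conservation: cutting only splits spans, never loses bases."""
        cfg = SimConfig(n_fragments=50, capture_prob=capture, seed=seed)
        frags = simulate_fragments_endo(toy_genome, toy_truth, cfg)
        null = simulate_fragments_endo(toy_genome, MethylationTruth(), cfg)
        covered = sum(f.length for f in frags)
        assert covered == sum(f.length for f in null)
        assert len(frags) >= len(null)


class TestExoSimulator:
    def test_oligo_stop_alignment(self, oligo, full_length_cfg):
        genome, truth = oligo
        frags = simulate_fragments_exo(genome, truth, full_length_cfg)
        plus = next(f for f in frags if f.strand == "+")
        assert (plus.start, plus.end, plus.length) == (24, 59, 35)
        assert genome.base("oligo", plus.five_prime(), "+") == "A"
        assert plus.source_tag == "exo_stop"

    def test_semi_methylated_duplex_leaves_minus_strand_untrimmed(self, oligo, full_length_cfg):
        genome, truth = oligo  # 6mA on the plus strand only
        frags = simulate_fragments_exo(genome, truth, full_length_cfg)
        minus = next(f for f in frags if f.strand == "-")
        assert (minus.start, minus.end) == (0, 59)
        assert minus.source_tag == "shear"

    def test_stop_alignments_always_start_with_adenine(self, toy_genome, toy_truth):
        cfg = SimConfig(n_fragments=2000, capture_prob=0.5, seed=4)
        for f in simulate_fragments_exo(toy_genome, toy_truth, cfg):
            if f.source_tag == "exo_stop":
                assert toy_genome.base(f.contig, f.five_prime(), f.strand) == "A"

    def test_adenine_bias_increases_with_capture_prob(self, toy_genome, toy_truth):
        """5'-terminal adenine fraction rises monotonically with capture."""
        fracs = []
        for capture in (0.0, 0.3, 0.8):
            cfg = SimConfig(n_fragments=3000, capture_prob=capture, seed=13)
            frags = simulate_fragments_exo(toy_genome, toy_truth, cfg)
            a = sum(
                toy_genome.base(f.contig, f.five_prime(), f.strand) == "A" for f in frags
            )
            fracs.append(a / len(frags))
        assert fracs[0] < fracs[1] < fracs[2]

    def test_empty_truth_5prime_composition_matches_genome(self, toy_genome):
        cfg = SimConfig(n_fragments=5000, capture_prob=1.0, seed=6)
        frags = simulate_fragments_exo(toy_genome, MethylationTruth(), cfg)
        a_frac = np.mean(
            [toy_genome.base(f.contig, f.five_prime(), f.strand) == "A" for f in frags]
        )
        seq = toy_genome["contig1"]
        genome_a = (seq.count("A") + seq.count("T")) / (2 * len(seq))
        assert abs(a_frac - genome_a) < 0.05


class TestWga:
    def test_equals_endo_with_empty_truth(self, toy_genome):
        cfg = SimConfig(n_fragments=400, seed=17)
        wga = simulate_wga(toy_genome, cfg)
        endo = simulate_fragments_endo(toy_genome, MethylationTruth(), cfg)
        assert [(f.contig, f.start, f.end, f.strand) for f in wga] == [
            (f.contig, f.start, f.end, f.strand) for f in endo
        ]
        assert all(f.source_tag == "wga" for f in wga)

    def test_terminal_positions_uniform(self):
        """Chi-square goodness of fit of 5' termini over 1-kb bins."""
        from scipy import stats

        genome = simulate_genome(1, 50_000, 0.5, 3)
        cfg = SimConfig(n_fragments=50_000, seed=8)
        frags = simulate_wga(genome, cfg)
        termini = np.array([f.five_prime() for f in frags])
        # avoid edge bins where fragment placement is constrained
        core = termini[(termini >= 1000) & (termini < 49_000)]
        counts, _ = np.histogram(core, bins=48, range=(1000, 49_000))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, len(counts) - 1) > 0.001


class TestSpikeIn:
    def _alignments(self, n, contig):
        from mmseq.core import ReadAlignment

        return [ReadAlignment(contig, i, i + 50, "+") for i in range(n)]

    def test_mix_preserves_counts_and_partitions(self):
        host = self._alignments(200, "c1")
        spike = self._alignments(10, "c1")
        mixed = mix_spikein(host, spike, "host_", "spike_")
        assert len(mixed) == 210
        h, s = partition_by_namespace(mixed, "spike_", host_prefix="host_", strip=True)
        assert h == host and s == spike

    def test_empty_spike(self):
        host = self._alignments(5, "c1")
        mixed = mix_spikein(host, [], "host_", "spike_")
        assert [a.contig for a in mixed] == ["host_c1"] * 5

    def test_prefix_collision_rejected(self):
        host = self._alignments(1, "c1")
        with pytest.raises(ValueError):
            mix_spikein(host, host, "ho", "host")

    def test_unprefixed_contig_reported(self):
        from mmseq.core import ReadAlignment

        mixed = [ReadAlignment("stray", 0, 10, "+")]
        with pytest.raises(ValueError, match="stray"):
            partition_by_namespace(mixed, "spike_", host_prefix="host_")

    def test_empty_prefix_matches_nothing(self):
        host = self._alignments(3, "c1")
        h, s = partition_by_namespace(host, "")
        assert h == host and s == []
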