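"""Terminal counting conventions, conservation, and background estimation."""

import numpy as np
import pytest

from mmseq.core import Genome, MethylationTruth, ReadAlignment
from mmseq.simdata import SimConfig, simulate_fragments_endo, simulate_wga
from mmseq.terminal_model import (
    count_terminals,
    dedup_alignments,
    estimate_background,
    read_counts_tsv,
)


class TestDedup:
    def test_exact_duplicates_collapsed(self):
        a = ReadAlignment("c1", 0, 50, "+")
        assert dedup_alignments([a, a]) == [a]

    def test_strand_distinguishes(self):
        a = ReadAlignment("c1", 0, 50, "+")
        b = ReadAlignment("c1", 0, 50, "-")
        assert dedup_alignments([a, b]) == [a, b]

    def test_idempotent_and_order_stable(self):
        alns = [
            ReadAlignment("c1", 10, 60, "+"),
            ReadAlignment("c1", 0, 50, "+"),
            ReadAlignment("c1", 10, 60, "+"),
        ]
        once = dedup_alignments(alns)
        assert once == dedup_alignments(once) == alns[:2]


class TestCountingConventions:
    @pytest.fixture
    def genome(self):
        return Genome({"c1": "ACGT" * 100})

    def test_exo_plus_five_prime(self, genome):
        counts = count_terminals([ReadAlignment("c1", 100, 160, "+")], "exo", genome)
        assert counts.get("c1", 100, "+") == (1, 1)
        c = counts.contigs["c1"]
        assert c.n_plus[100:160].tolist() == [1] * 60
        assert c.n_plus[99] == 0 and c.n_plus[160] == 0

    def test_exo_minus_five_prime_is_rightmost(self, genome):
        counts = count_terminals([ReadAlignment("c1", 100, 160, "-")], "exo", genome)
        assert counts.get("c1", 159, "-") == (1, 1)
        assert counts.get("c1", 100, "-")[0] == 0

    def test_endo_cut_pair_maps_to_single_site(self, genome):
        """Cut 3' of a plus-strand A at p: upstream 3' end at p and
        downstream 5' end at p+1 both register candidate p."""
        p = 200  # 'A' in the repeating ACGT pattern
        pair = [
            ReadAlignment("c1", 150, p + 1, "+", "endo_up"),
            ReadAlignment("c1", p + 1, 260, "+", "endo_down"),
        ]
        counts = count_terminals(pair, "endo", genome)
        k, n = counts.get("c1", p, "+")
        assert k == 2 and n == 2

    def test_endo_minus_cut_pair(self, genome):
        """Minus-strand cut at site p (plus coord): breakpoint b = p."""
        p = 203  # plus base 'T' -> minus-strand adenine
        pair = [
            ReadAlignment("c1", 150, p, "-", "endo_up"),
            ReadAlignment("c1", p, 260, "-", "endo_down"),
        ]
        counts = count_terminals(pair, "endo", genome)
        assert counts.get("c1", p, "-")[0] == 2

    def test_unknown_mode_rejected(self, genome):
        with pytest.raises(ValueError, match="mode"):
            count_terminals([], "both", genome)

    def test_counts_tsv_round_trip(self, genome, tmp_path):
        alns = [ReadAlignment("c1", 10, 70, "+"), ReadAlignment("c1", 30, 90, "-")]
        counts = count_terminals(alns, "endo", genome)
        p = tmp_path / "counts.tsv"
        counts.write_tsv(str(p))
        loaded = read_counts_tsv(str(p), genome)
        assert loaded.mode == "endo"
        for c, l in zip(counts.contigs.values(), loaded.contigs.values()):
            assert (c.k_plus == l.k_plus).all() and (c.n_minus == l.n_minus).all()


class TestConservationInvariants:
    def test_exo_total_k_equals_alignments(self, toy_genome, toy_truth):
        from mmseq.simdata import simulate_fragments_exo

        cfg = SimConfig(n_fragments=1000, capture_prob=0.5, seed=3)
        frags = simulate_fragments_exo(toy_genome, toy_truth, cfg)
        counts = count_terminals(frags, "exo", toy_genome)
        assert counts.total_k() == len(frags)

    def test_endo_total_k_is_twice_alignments_up_to_edges(self, toy_genome, toy_truth):
        cfg = SimConfig(n_fragments=1000, capture_prob=0.5, seed=3)
        frags = simulate_fragments_endo(toy_genome, toy_truth, cfg)
        counts = count_terminals(frags, "endo", toy_genome)
        # candidates mapped off the contig ends are dropped
        edge_losses = sum(f.start == 0 and f.strand == "+" for f in frags) + sum(
            f.end == toy_genome.length(f.contig) and f.strand == "-" for f in frags
        )
        assert counts.total_k() == 2 * len(frags) - edge_losses
        assert counts.total_k() <= 2 * len(frags)

    def test_k_never_exceeds_n(self, toy_genome, toy_truth):
        for mode, sim in (("endo", simulate_fragments_endo),):
            cfg = SimConfig(n_fragments=2000, capture_prob=0.7, seed=5)
            counts = count_terminals(sim(toy_genome, toy_truth, cfg), mode, toy_genome)
            for c in counts.contigs.values():
                assert (c.k_plus <= c.n_plus).all()
                assert (c.k_minus <= c.n_minus).all()

    def test_elevated_k_lands_exactly_on_truth(self, toy_genome, toy_truth):
        """With guaranteed capture the top-k positions are the truth sites."""
        cfg = SimConfig(n_fragments=3000, capture_prob=1.0, seed=1)
        frags = simulate_fragments_endo(toy_genome, toy_truth, cfg)
        counts = count_terminals(frags, "endo", toy_genome)
        c = counts.contigs["contig1"]
        m = len(toy_truth)
        ranked = []
        for strand, k in (("+", c.k_plus), ("-", c.k_minus)):
            for pos in np.argsort(k)[::-1][:m]:
                ranked.append((int(k[pos]), ("contig1", int(pos), strand)))
        top = {key for _, key in sorted(ranked, reverse=True)[:m]}
        assert top == toy_truth.positions()


class TestBackground:
    def test_exo_p0_close_to_inverse_fragment_length(self):
        from mmseq.simdata import simulate_genome, simulate_fragments_exo

        genome = simulate_genome(1, 100_000, 0.5, 2)
        cfg = SimConfig(n_fragments=25_000, seed=2)  # 50k alignments
        frags = simulate_fragments_exo(genome, MethylationTruth(), cfg)
        counts = count_terminals(frags, "exo", genome)
        p0 = estimate_background(counts).p0
        assert abs(p0 - 1 / 150) / (1 / 150) < 0.2

    def test_null_strata_exchangeable(self):
        """Without methylation the A and non-A strata see the same rate."""
        from mmseq.simdata import simulate_genome

        genome = simulate_genome(1, 100_000, 0.5, 4)
        frags = simulate_wga(genome, SimConfig(n_fragments=30_000, seed=4))
        counts = count_terminals(frags, "endo", genome)
        k_a = n_a = k_o = n_o = 0
        for c in counts.contigs.values():
            for k, n, mask in (
                (c.k_plus, c.n_plus, c.a_plus),
                (c.k_minus, c.n_minus, c.a_minus),
            ):
                k_a += k[mask].sum()
                n_a += n[mask].sum()
                k_o += k[~mask].sum()
                n_o += n[~mask].sum()
        ratio = (k_a / n_a) / (k_o / n_o)
        assert 0.8 < ratio < 1.25

    def test_zero_events_degenerate(self):
        genome = Genome({"c1": "ACGT" * 50})
        counts = count_terminals([], "exo", genome)
        with pytest.raises(ValueError):
            estimate_background(counts)
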