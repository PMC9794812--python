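"""Synthetic genomes, planted 6mA truth, and fragment simulators.

The simulators emulate the two enzymatic readouts of antibody-guided
nuclease mapping of N6-methyladenine:

* **endo** — a structure-selective endonuclease (T7E1/MBN-like) cleaves the
  antibody-stabilized duplex at the methylated adenine, so one random shear
  fragment becomes two abutting fragments whose facing termini flank the
  modified base.
* **exo** — a 5'->3' exonuclease (Lambda-like) digests each strand from its
  5' end and stalls at the first antibody-bound 6mA, so the methylated
  adenine becomes the residual strand's 5'-terminal base.

Whole-genome-amplified (WGA) material carries no modification and yields the
pure random-shear null used to check false-positive control.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import (
    Genome,
    IUPAC_SETS,
    MethylationTruth,
    MotifRule,
    ReadAlignment,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "simulate_genome",
    "find_motif_adenines",
    "plant_methylation",
    "simulate_fragments_endo",
    "simulate_fragments_exo",
    "simulate_wga",
    "mix_spikein",
]

MIN_FRAGMENT_LENGTH = 20

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one fragment-simulation run.

    capture_prob is the probability that a 6mA covered by a fragment's
    duplex actually produces a cleavage (endo) or digestion stop (exo); it
    folds antibody binding and enzyme efficiency into one number and is
    multiplied by the site's methyl fraction per fragment copy.

    Fragment lengths are truncated-normal (minimum 20 nt) around
    ``frag_len_mean``; the default of 150 +/- 30 nt emulates a sonicated
    short-insert sequencing library.
    """

    n_fragments: int
    capture_prob: float = 0.3
    frag_len_mean: int = 150
    frag_len_sd: int = 30
    endo_cut_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if not 0.0 <= self.capture_prob <= 1.0:
            raise ValueError("capture_prob must lie in [0, 1]")
        if self.frag_len_mean < MIN_FRAGMENT_LENGTH:
            raise ValueError(f"frag_len_mean must be >= {MIN_FRAGMENT_LENGTH}")
        if self.frag_len_sd < 0:
            raise ValueError("frag_len_sd must be non-negative")


def simulate_genome(n_contigs: int, length: int, gc: float, seed: int) -> Genome:
    """Random genome of ``n_contigs`` contigs with i.i.d. bases at GC fraction ``gc``."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    if length < 100:
        raise ValueError("contig length must be >= 100")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = {}
    for i in range(n_contigs):
        seq = rng.choice(_BASES, size=length, p=p)
        contigs[f"contig{i + 1}"] = "".join(seq)
    return Genome(contigs)


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(
        c if c in "ACGT" else "[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in pattern
    )
    return re.compile(f"(?=({body}))")


def find_motif_adenines(genome: Genome, rule: MotifRule) -> List[Tuple[str, int, str]]:
    """All methylatable adenines matching ``rule``, as (contig, position, strand).

    Positions are plus-strand coordinates; a minus-strand entry marks the
    adenine on the reverse strand (plus-strand base T). For a palindromic
    pattern with ``both_strands`` the two adenines of one duplex occurrence
    appear as consecutive plus/minus entries with the same pattern span.
    """
    fwd = _pattern_regex(rule.pattern)
    rev = _pattern_regex(reverse_complement(rule.pattern))
    out: List[Tuple[str, int, str]] = []
    for name in genome:
        seq = genome[name]
        for m in fwd.finditer(seq):
            out.append((name, m.start() + rule.methyl_offset, "+"))
        if rule.both_strands:
            off = len(rule.pattern) - 1 - rule.methyl_offset
            for m in rev.finditer(seq):
                out.append((name, m.start() + off, "-"))
    out.sort()
    return out


def duplex_occurrences(genome: Genome, rule: MotifRule) -> List[Tuple[str, int]]:
    """Plus-strand start coordinates of each duplex occurrence of a palindromic rule."""
    if not rule.is_palindromic():
        raise ValueError(f"pattern {rule.pattern!r} is not palindromic")
    fwd = _pattern_regex(rule.pattern)
    return [(name, m.start()) for name in genome for m in fwd.finditer(genome[name])]


def plant_methylation(
    genome: Genome,
    rule: MotifRule,
    fraction: float,
    seed: int,
    methyl_fraction: float = 1.0,
    joint_duplex: bool = True,
) -> MethylationTruth:
    """Mark motif adenines as methylated, each with probability ``fraction``.

    For a palindromic both-strand rule (e.g. GATC) and ``joint_duplex`` the
    two adenines of one duplex occurrence are included or excluded together,
    emulating fully methylated duplexes; otherwise every adenine is an
    independent Bernoulli draw. Included sites carry ``methyl_fraction`` as
    their per-copy methylation stoichiometry.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = MethylationTruth()
    if joint_duplex and rule.both_strands and rule.is_palindromic():
        plus_off = rule.methyl_offset
        minus_off = len(rule.pattern) - 1 - rule.methyl_offset
        for contig, start in duplex_occurrences(genome, rule):
            if fraction == 1.0 or rng.random() < fraction:
                truth.add(contig, start + plus_off, "+", methyl_fraction)
                truth.add(contig, start + minus_off, "-", methyl_fraction)
    else:
        for contig, pos, strand in find_motif_adenines(genome, rule):
            if fraction == 1.0 or rng.random() < fraction:
                truth.add(contig, pos, strand, methyl_fraction)
    truth.validate(genome)
    return truth


# ---------------------------------------------------------------------------
# fragment shearing
# ---------------------------------------------------------------------------


def _shear_spans(genome: Genome, cfg: SimConfig, rng: np.random.Generator):
    """Random fragment spans: per contig, arrays of (start, end).

    Fragments are allocated to contigs proportionally to length; lengths are
    truncated normal (min 20, max contig length); starts are uniform over the
    positions where the fragment fits.
    """
    names = list(genome)
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    counts = rng.multinomial(cfg.n_fragments, lengths / lengths.sum())
    spans: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for name, count in zip(names, counts):
        if count == 0:
            spans[name] = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
            continue
        clen = genome.length(name)
        raw = rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, size=count)
        frag_len = np.clip(np.rint(raw).astype(np.int64), MIN_FRAGMENT_LENGTH, clen)
        start = rng.integers(0, clen - frag_len + 1)
        spans[name] = (start, start + frag_len)
    return spans


def _truth_arrays(truth: MethylationTruth):
    """Per-contig sorted arrays of truth sites (position, strand flag, fraction)."""
    per: Dict[str, list] = {}
    for (contig, pos, strand), frac in truth.sites.items():
        per.setdefault(contig, []).append((pos, 1 if strand == "+" else -1, frac))
    out = {}
    for contig, rows in per.items():
        rows.sort()
        arr = np.array(rows, dtype=float)
        out[contig] = (
            arr[:, 0].astype(np.int64),
            arr[:, 1].astype(np.int64),
            arr[:, 2],
        )
    return out


def simulate_fragments_endo(
    genome: Genome, truth: MethylationTruth, cfg: SimConfig
) -> List[ReadAlignment]:
    """Random shear plus endonuclease cleavage at captured 6mA sites.

    Each 6mA whose duplex is covered by a fragment is captured independently
    with probability ``capture_prob * methyl_fraction``; a captured site cuts
    the fragment at the phosphodiester bond immediately 3' of the methylated
    adenine on its strand (shifted by ``endo_cut_offset``). Cut pieces carry
    the strand of the cut that created them so the downstream both-termini
    counter recovers the modified position exactly; uncut fragments are
    emitted as-is with a random strand.
    """
    truth.validate(genome)
    rng = np.random.default_rng(cfg.seed)
    spans = _shear_spans(genome, cfg, rng)
    sites = _truth_arrays(truth)
    out: List[ReadAlignment] = []
    for contig in genome:
        starts, ends = spans[contig]
        if contig not in sites or cfg.capture_prob == 0:
            # pure shear: no cut candidates anywhere on this contig
            shear_strand = rng.random(len(starts)) < 0.5
            out.extend(
                ReadAlignment(contig, int(s), int(e), "+" if w else "-", "shear")
                for s, e, w in zip(starts, ends, shear_strand)
            )
            continue
        pos, strand_flag, frac = sites[contig]
        # breakpoint of a cut at each site: 3' of the A on the methylated
        # strand, shifted by the configurable offset
        cut_b = np.where(
            strand_flag > 0, pos + 1 + cfg.endo_cut_offset, pos - cfg.endo_cut_offset
        )
        order = np.argsort(cut_b, kind="stable")
        cut_b = cut_b[order]
        cut_strand = strand_flag[order]
        cut_frac = frac[order]
        lo = np.searchsorted(cut_b, starts + 1, side="left")
        hi = np.searchsorted(cut_b, ends - 1, side="right")

        shear_strand = rng.random(len(starts)) < 0.5
        for i in range(len(starts)):
            s, e = int(starts[i]), int(ends[i])
            n_cand = hi[i] - lo[i]
            by_b: Dict[int, int] = {}
            if n_cand > 0:
                hit = rng.random(n_cand) < cfg.capture_prob * cut_frac[lo[i]: hi[i]]
                for j in np.nonzero(hit)[0]:
                    b = int(cut_b[lo[i] + j])
                    if s < b < e:
                        flag = int(cut_strand[lo[i] + j])
                        # a palindromic duplex cuts both strands at the same
                        # bond: record it as a double-strand break (flag 0)
                        by_b[b] = flag if by_b.get(b, flag) == flag else 0
            if not by_b:
                out.append(
                    ReadAlignment(contig, s, e, "+" if shear_strand[i] else "-", "shear")
                )
                continue
            chosen = sorted(by_b.items())
            bounds = [s] + [b for b, _ in chosen] + [e]
            # Piece strands decide which cut events the terminal counter
            # recovers: a single-strand cut is witnessed by both neighbours
            # on the cut strand (3' terminus upstream, 5'-mapped terminus
            # downstream), while a double-strand break needs its two
            # neighbours on OPPOSITE strands (one reports the plus-strand
            # adenine, the other the minus-strand adenine), so strands
            # alternate across double-cut boundaries.
            strands: List[str] = []
            first_flag = chosen[0][1]
            strands.append("+" if first_flag >= 0 else "-")
            for piece in range(1, len(bounds) - 1):
                flag = chosen[piece - 1][1]
                if flag == 0:
                    strands.append("-" if strands[-1] == "+" else "+")
                else:
                    strands.append("+" if flag > 0 else "-")
            for piece in range(len(bounds) - 1):
                ps, pe = bounds[piece], bounds[piece + 1]
                tag = "endo_up" if piece == 0 else "endo_down"
                out.append(ReadAlignment(contig, ps, pe, strands[piece], tag))
    return out


def simulate_fragments_exo(
    genome: Genome, truth: MethylationTruth, cfg: SimConfig
) -> List[ReadAlignment]:
    """Random shear plus 5'->3' exonuclease digestion stopping at captured 6mA.

    Each sheared duplex yields one alignment per strand. On each strand the
    exonuclease enters at the 5' end; every covered 6mA on that strand is
    captured independently with probability ``capture_prob * methyl_fraction``
    and the 5'-most captured site blocks digestion there, trimming the strand
    so the methylated adenine is its 5'-terminal base. With no captured site
    the strand's native (shear) 5' end is kept.
    """
    truth.validate(genome)
    rng = np.random.default_rng(cfg.seed)
    spans = _shear_spans(genome, cfg, rng)
    sites = _truth_arrays(truth)
    out: List[ReadAlignment] = []
    for contig in genome:
        starts, ends = spans[contig]
        if contig not in sites or cfg.capture_prob == 0:
            out.extend(
                aln
                for s, e in zip(starts, ends)
                for aln in (
                    ReadAlignment(contig, int(s), int(e), "+", "shear"),
                    ReadAlignment(contig, int(s), int(e), "-", "shear"),
                )
            )
            continue
        pos, strand_flag, frac = sites[contig]
        plus_pos, plus_frac = pos[strand_flag > 0], frac[strand_flag > 0]
        minus_pos, minus_frac = pos[strand_flag < 0], frac[strand_flag < 0]
        p_lo = np.searchsorted(plus_pos, starts, side="left")
        p_hi = np.searchsorted(plus_pos, ends, side="left")
        m_lo = np.searchsorted(minus_pos, starts, side="left")
        m_hi = np.searchsorted(minus_pos, ends, side="left")
        for i in range(len(starts)):
            s, e = int(starts[i]), int(ends[i])
            # plus strand: digestion runs left->right, stop at first capture
            stop_plus = -1
            for j in range(p_lo[i], p_hi[i]):
                if rng.random() < cfg.capture_prob * plus_frac[j]:
                    stop_plus = int(plus_pos[j])
                    break
            if stop_plus >= 0:
                out.append(ReadAlignment(contig, stop_plus, e, "+", "exo_stop"))
            else:
                out.append(ReadAlignment(contig, s, e, "+", "shear"))
            # minus strand: digestion runs right->left
            stop_minus = -1
            for j in range(m_hi[i] - 1, m_lo[i] - 1, -1):
                if rng.random() < cfg.capture_prob * minus_frac[j]:
                    stop_minus = int(minus_pos[j])
                    break
            if stop_minus >= 0:
                out.append(ReadAlignment(contig, s, stop_minus + 1, "-", "exo_stop"))
            else:
                out.append(ReadAlignment(contig, s, e, "-", "shear"))
    return out


def simulate_wga(genome: Genome, cfg: SimConfig, mode: str = "endo") -> List[ReadAlignment]:
    """Unmodified (whole-genome amplified) control: pure random shear.

    Identical to running the corresponding fragment simulator with an empty
    truth set; the negative control for familywise false-positive checks.
    """
    empty = MethylationTruth()
    if mode == "endo":
        frags = simulate_fragments_endo(genome, empty, cfg)
    elif mode == "exo":
        frags = simulate_fragments_exo(genome, empty, cfg)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [replace(f, source_tag="wga") for f in frags]


def mix_spikein(
    host: Sequence[ReadAlignment],
    spike: Sequence[ReadAlignment],
    host_prefix: str,
    spike_prefix: str,
) -> List[ReadAlignment]:
    """Pool spike-in control alignments with host alignments.

    Contig names gain their namespace prefix so the pooled set can later be
    partitioned exactly (the in-silico analogue of mapping pooled reads to
    the spike-in genome first and the host genome second).
    """
    if host_prefix == spike_prefix:
        raise ValueError("host and spike prefixes must differ")
    if host_prefix.startswith(spike_prefix) or spike_prefix.startswith(host_prefix):
        raise ValueError(
            f"ambiguous prefixes {host_prefix!r} / {spike_prefix!r}: one is a prefix of the other"
        )
    out = [replace(a, contig=host_prefix + a.contig) for a in host]
    out += [replace(a, contig=spike_prefix + a.contig) for a in spike]
    return out
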