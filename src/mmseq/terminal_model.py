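"""Per-position terminal-event counts and the random-shear background rate.

The statistical readout of nuclease-based 6mA mapping is, per genomic
position and strand, the pair (k, n):

* ``k`` — terminal events: in **exo** mode the strand-specific 5'-terminal
  positions of alignments; in **endo** mode both termini of every fragment,
  mapped back to the candidate modified base (see below).
* ``n`` — fragment coverage: alignments on the same strand whose span covers
  the position.

Endonuclease cleavage 3' of a methylated adenine at position p produces an
upstream fragment whose 3' terminus IS p and a downstream fragment whose 5'
terminus is p+1. Counting therefore maps a 3' terminus to itself and a 5'
terminus to the base immediately 5' of it on the alignment's strand — the
inverse of the cut rule — so both termini of one cut accumulate on the
modified base. Because the 5'-mapped candidate lies one base outside the
alignment span, endo-mode coverage extends one base past the 5' end, which
keeps k <= n pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .core import Genome, ReadAlignment

__all__ = [
    "TerminalCounts",
    "BackgroundModel",
    "dedup_alignments",
    "count_terminals",
    "estimate_background",
]

MODES = ("endo", "exo")


@dataclass
class ContigCounts:
    """Count arrays for one contig: k and n per strand, plus adenine masks."""

    k_plus: np.ndarray
    k_minus: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    a_plus: np.ndarray  # True where the plus-strand base is A
    a_minus: np.ndarray  # True where the minus-strand base is A (plus base T)


@dataclass
class TerminalCounts:
    mode: str
    contigs: Dict[str, ContigCounts] = field(default_factory=dict)

    def total_k(self) -> int:
        return int(
            sum(c.k_plus.sum() + c.k_minus.sum() for c in self.contigs.values())
        )

    def get(self, contig: str, position: int, strand: str) -> Tuple[int, int]:
        """(k, n) at one position/strand."""
        c = self.contigs[contig]
        if strand == "+":
            return int(c.k_plus[position]), int(c.n_plus[position])
        return int(c.k_minus[position]), int(c.n_minus[position])

    def to_rows(self) -> Iterable[Tuple[str, int, str, int, int]]:
        """Non-empty positions as (contig, position, strand, k, n) rows."""
        for name in sorted(self.contigs):
            c = self.contigs[name]
            for strand, k, n in (("+", c.k_plus, c.n_plus), ("-", c.k_minus, c.n_minus)):
                idx = np.nonzero((k > 0) | (n > 0))[0]
                for i in idx:
                    yield name, int(i), strand, int(k[i]), int(n[i])

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#mode={self.mode}\n")
            fh.write("contig\tposition\tstrand\tk\tn\n")
            for row in self.to_rows():
                fh.write("\t".join(map(str, row)) + "\n")


def read_counts_mode(path: str) -> str:
    """Mode recorded in the header of a serialized counts table."""
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#mode="):
        raise ValueError(f"{path}: missing #mode= header")
    return first.split("=", 1)[1]


def read_counts_tsv(path: str, genome: Genome) -> "TerminalCounts":
    """Load a serialized counts table back into per-contig arrays."""
    mode = read_counts_mode(path)
    counts = _empty_counts(mode, genome)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig\t"):
                continue
            contig, pos_s, strand, k_s, n_s = line.rstrip("\n").split("\t")
            if contig not in counts.contigs:
                raise ValueError(f"{path}: contig {contig!r} absent from genome")
            c = counts.contigs[contig]
            pos = int(pos_s)
            if strand == "+":
                c.k_plus[pos], c.n_plus[pos] = int(k_s), int(n_s)
            else:
                c.k_minus[pos], c.n_minus[pos] = int(k_s), int(n_s)
    return counts


def _empty_counts(mode: str, genome: Genome) -> "TerminalCounts":
    counts = TerminalCounts(mode=mode)
    for name in genome:
        L = genome.length(name)
        seq = np.frombuffer(genome[name].encode(), dtype="S1")
        counts.contigs[name] = ContigCounts(
            k_plus=np.zeros(L, dtype=np.int64),
            k_minus=np.zeros(L, dtype=np.int64),
            n_plus=np.zeros(L, dtype=np.int64),
            n_minus=np.zeros(L, dtype=np.int64),
            a_plus=(seq == b"A"),
            a_minus=(seq == b"T"),
        )
    return counts


@dataclass(frozen=True)
class BackgroundModel:
    """Probability p0 that a covering fragment contributes a terminal event
    at a given position under random shear alone."""

    p0: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie strictly between 0 and 1")


def dedup_alignments(alignments: Sequence[ReadAlignment]) -> List[ReadAlignment]:
    """Collapse exact (contig, start, end, strand) duplicates, keeping first.

    A simplified stand-in for upstream PCR-duplicate removal; order-stable
    and idempotent. Records differing only in strand are both kept.
    """
    seen = set()
    out: List[ReadAlignment] = []
    for a in alignments:
        key = (a.contig, a.start, a.end, a.strand)
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out


def _group_arrays(alignments: Sequence[ReadAlignment]):
    grouped: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for a in alignments:
        grouped.setdefault((a.contig, a.strand), []).append((a.start, a.end))
    return {
        key: (np.array([s for s, _ in spans]), np.array([e for _, e in spans]))
        for key, spans in grouped.items()
    }


def count_terminals(
    alignments: Sequence[ReadAlignment], mode: str, genome: Genome
) -> TerminalCounts:
    """Accumulate terminal events k and coverage n per (position, strand)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    counts = _empty_counts(mode, genome)
    grouped = _group_arrays(alignments)
    for (name, strand), (starts, ends) in grouped.items():
        if name not in counts.contigs:
            raise ValueError(f"alignment on contig {name!r} absent from genome")
        c = counts.contigs[name]
        L = len(c.k_plus)
        if ends.max() > L:
            raise ValueError(f"alignment end beyond contig {name!r} length {L}")
        k = c.k_plus if strand == "+" else c.k_minus
        n = c.n_plus if strand == "+" else c.n_minus
        diff = np.zeros(L + 1, dtype=np.int64)
        if mode == "exo":
            term = starts if strand == "+" else ends - 1
            np.add.at(k, term, 1)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        else:  # endo: both termini, 5' terminus mapped one base 5' of itself
            if strand == "+":
                np.add.at(k, ends - 1, 1)  # 3' termini
                cand5 = starts - 1
                np.add.at(k, cand5[cand5 >= 0], 1)
                np.add.at(diff, np.maximum(starts - 1, 0), 1)
                np.add.at(diff, ends, -1)
            else:
                np.add.at(k, starts, 1)  # 3' termini
                cand5 = ends  # one base 5' of the minus-strand 5' terminus
                np.add.at(k, cand5[cand5 < L], 1)
                np.add.at(diff, starts, 1)
                np.add.at(diff, np.minimum(ends + 1, L), -1)
        n += np.cumsum(diff[:-1])
    return counts


def estimate_background(counts: TerminalCounts) -> BackgroundModel:
    """Estimate the random-shear terminal rate p0 from the non-adenine stratum.

    True 6mA signal can only sit on adenines, so positions whose strand base
    is not A measure pure shear background regardless of how heavily the
    genome is methylated. Falls back to the global rate when the non-A
    stratum is empty.
    """
    k_non_a = n_non_a = k_all = n_all = 0
    for c in counts.contigs.values():
        for k, n, a_mask in (
            (c.k_plus, c.n_plus, c.a_plus),
            (c.k_minus, c.n_minus, c.a_minus),
        ):
            covered = n > 0
            k_all += int(k[covered].sum())
            n_all += int(n[covered].sum())
            stratum = covered & ~a_mask
            k_non_a += int(k[stratum].sum())
            n_non_a += int(n[stratum].sum())
    if n_all == 0:
        raise ValueError("cannot estimate background: zero coverage everywhere")
    if n_non_a > 0 and k_non_a > 0:
        return BackgroundModel(p0=k_non_a / n_non_a)
    if k_all == 0:
        raise ValueError("cannot estimate background: no terminal events observed")
    return BackgroundModel(p0=k_all / n_all)
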