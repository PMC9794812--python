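"""Shared domain types for the 6mA mapping toolkit.

Coordinate conventions used throughout the package:

* Every interval is 0-based, half-open ``[start, end)`` (the BED frame).
  GFF input is converted at the boundary.
* ``strand`` is ``"+"`` or ``"-"``; for an alignment it names the strand
  whose 5' end defines the fragment's 5'-terminal base.
* The 5' terminal of a plus-strand alignment is ``start``; the 5' terminal
  of a minus-strand alignment is ``end - 1`` (its rightmost base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

__all__ = [
    "Genome",
    "MotifRule",
    "MethylationTruth",
    "ReadAlignment",
    "Region",
    "TssRecord",
    "IUPAC_SETS",
    "complement",
    "reverse_complement",
    "iupac_match",
]

# Restricted IUPAC alphabet: the four bases plus the two degenerate codes
# needed for the 6mA consensus contexts (VATB, GATC) and N.
IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "V": frozenset("ACG"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTVBN", "TGCABVN")


def complement(seq: str) -> str:
    """Complement of a sequence over the restricted IUPAC alphabet."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` (ACGT) matches ``pattern`` position by position."""
    if len(pattern) != len(seq):
        return False
    return all(base in IUPAC_SETS[code] for code, base in zip(pattern, seq))


class Genome:
    """Ordered collection of named contigs over the ACGT alphabet.

    The genome defines the coordinate frame for every other object in the
    package. Contig names must be unique and non-empty; sequences are
    uppercase ACGT only.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        clean: Dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig names must be non-empty")
            if name in clean:
                raise ValueError(f"duplicate contig name: {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} has an empty sequence")
            if set(seq) - set("ACGT"):
                bad = sorted(set(seq) - set("ACGT"))
                raise ValueError(f"contig {name!r} contains non-ACGT characters: {bad}")
            clean[name] = seq
        self._contigs = clean

    @property
    def contigs(self) -> Dict[str, str]:
        return dict(self._contigs)

    def names(self) -> Tuple[str, ...]:
        return tuple(self._contigs)

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self._contigs.values())

    def base(self, contig: str, position: int, strand: str = "+") -> str:
        """Base at ``position`` on the requested strand."""
        b = self._contigs[contig][position]
        return b if strand == "+" else complement(b)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._contigs == other._contigs

    def __repr__(self) -> str:
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self._contigs.items())
        return f"Genome({parts})"


@dataclass(frozen=True)
class MotifRule:
    """Sequence context of a methylatable adenine.

    ``pattern`` is an IUPAC string restricted to {A,C,G,T,V,B,N} with a
    literal A at ``methyl_offset`` (the methylated position). With
    ``both_strands`` the rule is also applied to the reverse strand.
    """

    name: str
    pattern: str
    methyl_offset: int
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        unknown = set(self.pattern) - set(IUPAC_SETS)
        if unknown:
            raise ValueError(f"unsupported IUPAC codes in pattern: {sorted(unknown)}")
        if not 0 <= self.methyl_offset < len(self.pattern):
            raise ValueError("methyl_offset outside pattern")
        if self.pattern[self.methyl_offset] != "A":
            raise ValueError(
                f"pattern {self.pattern!r} must carry A at offset {self.methyl_offset}"
            )
        if self.pattern.count("A") != 1:
            raise ValueError("pattern must contain exactly one literal A")

    def is_palindromic(self) -> bool:
        """True when the pattern equals its own reverse complement (e.g. GATC)."""
        return self.pattern == reverse_complement(self.pattern)


# Common rules: Dam GATC (palindromic, bacterial methylome) and the green
# algal VATB consensus.
GATC_RULE = MotifRule("GATC", "GATC", 1, both_strands=True)
VATB_RULE = MotifRule("VATB", "VATB", 1, both_strands=True)


@dataclass
class MethylationTruth:
    """Planted 6mA ground truth: (contig, position, strand) -> methyl fraction.

    ``position`` is the 0-based plus-strand coordinate of the adenine; for a
    minus-strand site the plus-strand base at that coordinate is therefore T.
    """

    sites: Dict[Tuple[str, int, str], float] = field(default_factory=dict)

    def add(self, contig: str, position: int, strand: str, fraction: float = 1.0) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r}")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("methyl fraction must lie in [0, 1]")
        self.sites[(contig, position, strand)] = fraction

    def positions(self) -> set:
        return set(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: Tuple[str, int, str]) -> bool:
        return key in self.sites

    def validate(self, genome: Genome) -> None:
        """Check every site is an in-bounds adenine on its strand."""
        for (contig, pos, strand) in self.sites:
            if contig not in genome:
                raise ValueError(f"truth site on unknown contig {contig!r}")
            if not 0 <= pos < genome.length(contig):
                raise ValueError(f"truth site {contig}:{pos} out of bounds")
            if genome.base(contig, pos, strand) != "A":
                raise ValueError(
                    f"truth site {contig}:{pos}:{strand} is not an adenine on its strand"
                )


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned, deduplicated sequenced fragment (or single strand).

    ``source_tag`` is simulator-only provenance (shear, endo_up, endo_down,
    exo_stop, wga); the caller never depends on it.
    """

    contig: str
    start: int
    end: int
    strand: str
    source_tag: str = "shear"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Position of the strand-specific 5'-terminal base."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Region:
    """Generic half-open genomic interval (peak, blacklist, truth span)."""

    contig: str
    start: int
    end: int
    name: Optional[str] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass(frozen=True)
class TssRecord:
    """Transcription start site: 0-based position of the first transcribed base."""

    contig: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.position < 0:
            raise ValueError("TSS position must be non-negative")
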