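"""Downstream characterization of called 6mA sites.

Covers the standard post-calling questions: what sequence context do the
sites sit in (motif fractions, flanking base frequencies), are palindromic
motif occurrences methylated on both strands or one (full vs hemi), how do
sites distribute around transcription start sites (and with what spatial
period), how concordant are two site sets or a site set and peak regions,
and how do pooled spike-in alignments partition back into their genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Genome,
    MotifRule,
    ReadAlignment,
    Region,
    TssRecord,
    iupac_match,
    reverse_complement,
)
from .simdata import duplex_occurrences
from .site_caller import SiteCall, passed_site_keys

__all__ = [
    "MotifSummary",
    "SymmetryCall",
    "TssProfile",
    "OverlapSummary",
    "motif_summary",
    "classify_symmetry",
    "tss_profile",
    "overlap_sites",
    "sites_in_regions",
    "partition_by_namespace",
]

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass
class MotifSummary:
    total_sites: int
    excluded_edge: int
    fraction_matching: Dict[str, float]
    base_freq: np.ndarray  # 4 x (2*flank + 1); rows A,C,G,T, columns sum to 1
    flank: int
    base_order: str = _BASE_ORDER


@dataclass(frozen=True)
class SymmetryCall:
    contig: str
    start: int  # plus-strand start of the duplex motif occurrence
    status: str  # full | hemi_plus | hemi_minus | unmethylated


@dataclass
class TssProfile:
    distances: np.ndarray  # signed strand-oriented distance to nearest TSS
    histogram: np.ndarray  # counts over [-window, window], 1-bp bins
    window: int
    dominant_period: Optional[float]
    period_score: Optional[float]


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_intersection: int
    jaccard: float

    @property
    def fraction_a_in_b(self) -> float:
        return self.n_intersection / self.n_a if self.n_a else 0.0


def _passed(calls: Sequence[SiteCall], passed_only: bool) -> List[SiteCall]:
    return [c for c in calls if c.passed] if passed_only else list(calls)


def motif_summary(
    calls: Sequence[SiteCall],
    genome: Genome,
    rules: Sequence[MotifRule],
    flank: int = 5,
    passed_only: bool = True,
) -> MotifSummary:
    """Strand-oriented sequence context of called sites.

    For each site the +/- ``flank`` context is extracted 5'->3' on the
    called strand (minus-strand contexts reverse-complemented), so the
    center column is the methylated adenine itself. Sites too close to a
    contig edge for a full window are excluded and counted.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    used = _passed(calls, passed_only)
    width = 2 * flank + 1
    counts = np.zeros((4, width), dtype=np.int64)
    contexts: List[str] = []
    excluded = 0
    for c in used:
        seq = genome[c.contig]
        lo, hi = c.position - flank, c.position + flank + 1
        if lo < 0 or hi > len(seq):
            excluded += 1
            continue
        ctx = seq[lo:hi]
        if c.strand == "-":
            ctx = reverse_complement(ctx)
        contexts.append(ctx)
        for j, base in enumerate(ctx):
            counts[_BASE_INDEX[base], j] += 1
    total = len(contexts)
    freq = counts / total if total else np.zeros((4, width))
    fractions: Dict[str, float] = {}
    for rule in rules:
        if rule.methyl_offset > flank or len(rule.pattern) - rule.methyl_offset - 1 > flank:
            raise ValueError(f"flank {flank} too small for rule {rule.name}")
        lo = flank - rule.methyl_offset
        n_match = sum(
            iupac_match(rule.pattern, ctx[lo : lo + len(rule.pattern)]) for ctx in contexts
        )
        fractions[rule.name] = n_match / total if total else 0.0
    return MotifSummary(
        total_sites=total,
        excluded_edge=excluded,
        fraction_matching=fractions,
        base_freq=freq,
        flank=flank,
    )


def classify_symmetry(
    calls: Sequence[SiteCall], genome: Genome, rule: MotifRule
) -> List[SymmetryCall]:
    """Full vs hemi methylation status of each duplex occurrence of a
    palindromic motif (e.g. GATC): ``full`` when the adenines on both strands
    were called, ``hemi_plus``/``hemi_minus`` when only one was."""
    if not rule.is_palindromic():
        raise ValueError(f"rule {rule.name!r} is not palindromic")
    called = passed_site_keys(calls)
    plus_off = rule.methyl_offset
    minus_off = len(rule.pattern) - 1 - rule.methyl_offset
    out: List[SymmetryCall] = []
    for contig, start in duplex_occurrences(genome, rule):
        plus_hit = (contig, start + plus_off, "+") in called
        minus_hit = (contig, start + minus_off, "-") in called
        if plus_hit and minus_hit:
            status = "full"
        elif plus_hit:
            status = "hemi_plus"
        elif minus_hit:
            status = "hemi_minus"
        else:
            status = "unmethylated"
        out.append(SymmetryCall(contig, start, status))
    return out


def tss_profile(
    calls: Sequence[SiteCall],
    tss: Sequence[TssRecord],
    window: int = 2000,
    min_lag: int = 50,
    max_lag: int = 300,
    passed_only: bool = True,
) -> TssProfile:
    """Signed distance of each site to its nearest TSS, and the dominant
    spatial period of the distance histogram.

    Distances are oriented by the TSS strand (downstream of transcription is
    positive). The period is the lag of the autocorrelation peak of the
    mean-centered 1-bp histogram, searched over [min_lag, max_lag].
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    if not tss:
        raise ValueError("TSS list is empty")
    per_contig: Dict[str, List[TssRecord]] = {}
    for t in tss:
        per_contig.setdefault(t.contig, []).append(t)
    sorted_tss = {
        contig: sorted(records, key=lambda t: t.position)
        for contig, records in per_contig.items()
    }
    tss_pos = {c: np.array([t.position for t in recs]) for c, recs in sorted_tss.items()}

    distances: List[int] = []
    for call in _passed(calls, passed_only):
        if call.contig not in tss_pos:
            continue
        pos_arr = tss_pos[call.contig]
        i = int(np.searchsorted(pos_arr, call.position))
        # nearest of the flanking TSSs; tie broken toward the upstream one
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(pos_arr):
                d_abs = abs(call.position - int(pos_arr[j]))
                if best is None or d_abs < best[0]:
                    best = (d_abs, j)
        if best is None:
            continue
        t = sorted_tss[call.contig][best[1]]
        d = call.position - t.position
        if t.strand == "-":
            d = -d
        distances.append(d)

    dist_arr = np.array(distances, dtype=np.int64)
    hist = np.zeros(2 * window + 1, dtype=np.int64)
    in_win = dist_arr[np.abs(dist_arr) <= window]
    np.add.at(hist, in_win + window, 1)

    dominant_period = None
    score = None
    max_lag = min(max_lag, len(hist) - 1)
    if hist.sum() >= 2 and min_lag <= max_lag:
        h = hist.astype(float) - hist.mean()
        denom = float(np.dot(h, h))
        if denom > 0:
            lags = np.arange(min_lag, max_lag + 1)
            ac = np.array([np.dot(h[:-lag], h[lag:]) for lag in lags]) / denom
            best_i = int(np.argmax(ac))
            if ac[best_i] > 0:
                dominant_period = float(lags[best_i])
                score = float(ac[best_i])
    return TssProfile(
        distances=dist_arr,
        histogram=hist,
        window=window,
        dominant_period=dominant_period,
        period_score=score,
    )


def overlap_sites(a: Sequence[SiteCall], b: Sequence[SiteCall]) -> OverlapSummary:
    """Exact (contig, position, strand) overlap between two passed site sets."""
    set_a, set_b = passed_site_keys(a), passed_site_keys(b)
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        n_intersection=inter,
        jaccard=inter / union if union else 0.0,
    )


def sites_in_regions(
    calls: Sequence[SiteCall], regions: Sequence[Region], passed_only: bool = True
) -> OverlapSummary:
    """How many called sites fall inside at least one region (half-open)."""
    used = _passed(calls, passed_only)
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    for r in regions:
        per_contig.setdefault(r.contig, []).append((r.start, r.end))
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for contig, ivals in per_contig.items():
        ivals.sort()
        starts: List[int] = []
        ends: List[int] = []
        for s, e in ivals:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[contig] = (np.array(starts), np.array(ends))
    inside = 0
    for c in used:
        if c.contig not in merged:
            continue
        starts, ends = merged[c.contig]
        i = int(np.searchsorted(starts, c.position, side="right")) - 1
        if i >= 0 and c.position < ends[i]:
            inside += 1
    return OverlapSummary(
        n_a=len(used),
        n_b=len(regions),
        n_intersection=inside,
        jaccard=inside / len(used) if used else 0.0,
    )


def partition_by_namespace(
    alignments: Sequence[ReadAlignment],
    spike_prefix: str,
    host_prefix: Optional[str] = None,
    strip: bool = False,
) -> Tuple[List[ReadAlignment], List[ReadAlignment]]:
    """Split pooled alignments into (host, spike) by contig-name prefix.

    The in-silico analogue of mapping pooled spike-in libraries to the
    spike genome first and assigning the remainder to the host. When
    ``host_prefix`` is given, any record matching neither prefix is an
    error; with ``strip`` the prefixes are removed again (exact inverse of
    pooling).
    """
    from dataclasses import replace

    host: List[ReadAlignment] = []
    spike: List[ReadAlignment] = []
    offenders: List[str] = []
    for a in alignments:
        if spike_prefix and a.contig.startswith(spike_prefix):
            spike.append(
                replace(a, contig=a.contig[len(spike_prefix):]) if strip else a
            )
        elif host_prefix is None or a.contig.startswith(host_prefix):
            if strip and host_prefix:
                host.append(replace(a, contig=a.contig[len(host_prefix):]))
            else:
                host.append(a)
        else:
            offenders.append(a.contig)
    if offenders:
        uniq = sorted(set(offenders))
        raise ValueError(f"contigs without a namespace prefix: {uniq}")
    return host, spike
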