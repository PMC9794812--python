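"""Binomial calling of single-base 6mA sites from terminal-count excess.

Under random shear every covered position receives terminal events at the
background rate p0, so at a position with coverage n the event count k is
Binomial(n, p0). A genuine 6mA adds cleavage/stop events on top, inflating
k; the caller reports the one-sided upper-tail probability P(X >= k),
corrects it for the number of tested positions, and applies the coverage
gate and base filter.

Defaults follow the published analysis settings: coverage cutoff 5,
Bonferroni correction, adjusted p <= 0.01. Benjamini-Hochberg is available
as the less conservative alternative reading of "FDR <= 0.01".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Genome, Region
from .terminal_model import BackgroundModel, TerminalCounts

__all__ = [
    "CallerConfig",
    "SiteCall",
    "binomial_pvalue",
    "adjust_pvalues",
    "call_sites",
    "filter_blacklist",
    "passed_site_keys",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_calls_bed",
]


@dataclass(frozen=True)
class CallerConfig:
    coverage_cutoff: int = 5
    alpha: float = 0.01
    correction: str = "bonferroni"
    require_A: bool = True

    def __post_init__(self) -> None:
        if self.coverage_cutoff < 1:
            raise ValueError("coverage_cutoff must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class SiteCall:
    """One tested position with its test statistics and pass flag."""

    contig: str
    position: int
    strand: str
    base: str
    k: int
    n: int
    p_raw: float
    p_adj: float
    passed: bool

    def key(self) -> Tuple[str, int, str]:
        return (self.contig, self.position, self.strand)


def binomial_pvalue(k: int, n: int, p0: float) -> float:
    """Exact one-sided upper-tail probability P(X >= k), X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    return float(stats.binom.sf(k - 1, n, p0))


def adjust_pvalues(
    p: Sequence[float], method: str = "bonferroni", m: int | None = None
) -> List[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m * p) with m the number of tested hypotheses
    (defaults to len(p)). ``bh``: Benjamini-Hochberg step-up.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m = len(arr) if m is None else m
        return list(np.minimum(1.0, m * arr))
    if method == "bh":
        _, adj, _, _ = multipletests(arr, method="fdr_bh")
        return list(adj)
    raise ValueError(f"unknown correction {method!r}")


def call_sites(
    counts: TerminalCounts,
    bg: BackgroundModel,
    genome: Genome,
    cfg: CallerConfig = CallerConfig(),
) -> List[SiteCall]:
    """Test every position with coverage >= cutoff (and adenine base when
    ``require_A``); the correction denominator is the number of tested
    positions. Returns all tested positions sorted by (contig, position,
    strand), passed or not.
    """
    if bg is None:
        raise ValueError("background model required")
    per_contig: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name in counts.contigs:
        if name not in genome:
            raise ValueError(f"counts contig {name!r} absent from genome")
        c = counts.contigs[name]
        for strand, k, n, a_mask in (
            ("+", c.k_plus, c.n_plus, c.a_plus),
            ("-", c.k_minus, c.n_minus, c.a_minus),
        ):
            tested = n >= cfg.coverage_cutoff
            if cfg.require_A:
                tested &= a_mask
            idx = np.nonzero(tested)[0]
            per_contig[(name, strand)] = (idx, k[idx], n[idx])

    all_p: List[np.ndarray] = []
    order: List[Tuple[str, str]] = []
    for key, (idx, k, n) in per_contig.items():
        p = stats.binom.sf(k - 1, n, bg.p0) if idx.size else np.empty(0)
        all_p.append(np.asarray(p, dtype=float))
        order.append(key)
    flat = np.concatenate(all_p) if all_p else np.empty(0)
    adj = np.array(adjust_pvalues(flat, method=cfg.correction)) if flat.size else flat

    calls: List[SiteCall] = []
    offset = 0
    for key, p_chunk in zip(order, all_p):
        name, strand = key
        idx, k, n = per_contig[key]
        a_chunk = adj[offset : offset + len(p_chunk)]
        offset += len(p_chunk)
        for i in range(len(idx)):
            pos = int(idx[i])
            base = genome.base(name, pos, strand)
            p_adj = float(a_chunk[i])
            passed = p_adj <= cfg.alpha and (base == "A" or not cfg.require_A)
            calls.append(
                SiteCall(
                    contig=name,
                    position=pos,
                    strand=strand,
                    base=base,
                    k=int(k[i]),
                    n=int(n[i]),
                    p_raw=float(p_chunk[i]),
                    p_adj=p_adj,
                    passed=bool(passed),
                )
            )
    calls.sort(key=lambda s: (s.contig, s.position, s.strand))
    return calls


def filter_blacklist(calls: Sequence[SiteCall], blacklist: Sequence[Region]) -> List[SiteCall]:
    """Drop calls whose position falls inside any blacklist region (strand
    ignored; intervals half-open)."""
    if not blacklist:
        return list(calls)
    per_contig: Dict[str, List[Tuple[int, int]]] = {}
    for r in blacklist:
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
    out: List[SiteCall] = []
    for call in calls:
        if call.contig in merged:
            starts, ends = merged[call.contig]
            i = int(np.searchsorted(starts, call.position, side="right")) - 1
            if i >= 0 and call.position < ends[i]:
                continue
        out.append(call)
    return out


def passed_site_keys(calls: Sequence[SiteCall]) -> set:
    """Set of (contig, position, strand) for calls that passed all filters."""
    return {c.key() for c in calls if c.passed}


def write_calls_tsv(calls: Sequence[SiteCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tstrand\tbase\tk\tn\tp_raw\tp_adj\tpassed\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.position}\t{c.strand}\t{c.base}\t{c.k}\t{c.n}\t"
                f"{c.p_raw:.6e}\t{c.p_adj:.6e}\t{int(c.passed)}\n"
            )


def read_calls_tsv(path: str) -> List[SiteCall]:
    calls: List[SiteCall] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"{path}: missing calls header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                SiteCall(
                    contig=f[0],
                    position=int(f[1]),
                    strand=f[2],
                    base=f[3],
                    k=int(f[4]),
                    n=int(f[5]),
                    p_raw=float(f[6]),
                    p_adj=float(f[7]),
                    passed=bool(int(f[8])),
                )
            )
    return calls


def write_calls_bed(calls: Sequence[SiteCall], path: str, passed_only: bool = True) -> None:
    """BED6 of calls; score = min(1000, round(-10 log10 p_adj))."""
    with open(path, "w") as fh:
        for c in calls:
            if passed_only and not c.passed:
                continue
            if c.p_adj <= 0:
                score = 1000
            else:
                score = min(1000, int(round(-10.0 * np.log10(c.p_adj))))
            fh.write(
                f"{c.contig}\t{c.position}\t{c.position + 1}\t{c.base}\t{max(score, 0)}\t{c.strand}\n"
            )
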