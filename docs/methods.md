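# Methods

## Background and model

`mmseq` implements single-base calling of N6-methyladenine (6mA) from the
terminal positions of sequenced DNA fragments, as produced by
antibody-guided nuclease digestion. Two enzymatic readouts are supported:

* **Endonuclease mode (endo).** A structure-selective endonuclease
  (T7E1/MBN-like) cleaves the duplex where an antibody has stabilized the
  flipped-out methyladenine. A cleaved fragment becomes two abutting
  fragments; the cut is modeled at the phosphodiester bond immediately 3' of
  the methylated adenine on its strand, so the upstream fragment's 3'
  terminus is the adenine itself and the downstream fragment's 5' terminus
  is the next base. Both termini of every fragment are counted; a 3'
  terminus nominates its own position as the candidate site, a 5' terminus
  nominates the base immediately 5' of it on the same strand (the exact
  inverse of the cut rule). On the synthetic 59-nt duplex with its single
  6mA at the 25th base this geometry yields the expected 25-nt upstream
  cleavage product.
* **Exonuclease mode (exo).** A 5'->3' exonuclease (Lambda-like) digests
  each strand from its 5' end and stalls at the first antibody-bound 6mA,
  leaving the methylated adenine as the residual strand's 5'-terminal base.
  Only 5' termini are counted, and each nominates its own position.

### The test statistic

For every genomic position and strand we accumulate

* `k` — terminal events nominated at that position, and
* `n` — coverage: same-strand alignments whose span covers the position
  (endo-mode coverage extends one base past an alignment's 5' end, because
  the bond-mapped candidate of its own 5' terminus lies just outside the
  span; this keeps `k <= n` pointwise).

Under random shearing alone, `k ~ Binomial(n, p0)` where `p0` is the
per-covered-position terminal rate (approximately `1/L` in exo mode and
`2/(L+1)` in endo mode for mean fragment length `L`). A 6mA adds
cleavage/stop events on top of shear, inflating `k`. The caller reports the
exact one-sided upper tail `P(X >= k)`, adjusts it across all tested
positions (Bonferroni by default; Benjamini-Hochberg step-up as the
alternative), and flags positions with adjusted `p <= alpha`.

### Background estimation

`p0` is estimated from the **non-adenine stratum**: positions whose
strand-specific base is not A cannot carry 6mA, so their pooled `sum(k) /
sum(n)` measures pure shear background even in genomes that are methylated
at essentially every motif occurrence (e.g. Dam-saturated GATC). If the
stratum is empty or eventless the estimator falls back to the global rate,
and errors out when there are no terminal events at all.

### Testing and correction policy

* Only positions with `n >=` the coverage cutoff (default 5) are tested, and
  only adenines on the tested strand unless `require_A` is disabled (the
  damage-detection mode: terminal excess at non-A bases).
* The correction denominator `m` is the number of tested positions
  genome-wide, not the genome length: untested positions carry no
  hypothesis.
* Defaults are coverage cutoff 5 and Bonferroni-adjusted `p <= 0.01`, the
  settings the method's published analysis chained together; a boundary
  value exactly equal to alpha passes.

## The simulator

The `simdata` module emulates the wet readout so sensitivity and
false-positive control are measurable without real data:

1. i.i.d. random genomes at a requested GC content;
2. motif-based truth planting (IUPAC patterns restricted to
   {A,C,G,T,V,B,N}); for a palindromic both-strand rule such as GATC the
   two adenines of one duplex occurrence are planted jointly (fully
   methylated duplexes) unless independent planting is requested;
3. fragment shearing: fragments allocated to contigs by length, lengths
   truncated-normal with minimum 20 nt, uniform placement;
4. enzyme action as described above, gated per fragment copy by
   `capture_prob * methyl_fraction` (antibody binding, enzyme efficiency and
   per-site stoichiometry folded into one Bernoulli probability);
5. WGA (whole-genome amplified) null libraries: the same shearing with no
   cleavage/stop events, byte-identical to running either simulator with an
   empty truth set;
6. spike-in pooling/partitioning by contig-name namespace prefixes,
   mirroring the map-to-spike-genome-first analysis of pooled libraries.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `frag_len_mean` / `frag_len_sd` | 150 / 30 nt | typical sonicated short-insert library; minimum 20 nt |
| `capture_prob` | 0.3 | moderate antibody+enzyme efficiency; per-copy Bernoulli |
| `endo_cut_offset` | 0 | cut at the bond immediately 3' of the adenine (reproduces the 25-nt product on the 59-nt duplex); configurable for sensitivity analysis since the published data also show adenine enrichment at endonuclease 5' termini, which a single-bond model cannot produce |
| coverage cutoff / alpha / correction | 5 / 0.01 / bonferroni | published analysis settings |

### Numerical and convention choices

* **Strand of a piece after cutting.** Counting recovers a cut only through
  the strand attribute of the sequenced piece. A single-strand cut labels
  both pieces with the cut strand. A palindromic duplex (GATC) that is
  captured on both strands in the same fragment cuts both strands at the
  same bond — a double-strand break; its two events (plus-strand adenine,
  minus-strand adenine) are recovered by giving the two flanking pieces
  opposite strands, alternating across consecutive double-cut boundaries.
  Chains mixing single and double cuts can rarely leave one terminus
  attributed to the wrong strand; this is unbiased noise at realistic
  capture probabilities.
* **One stop per strand per fragment (exo).** The exonuclease cannot pass
  its first block, so the 5'-most captured site on a strand wins; sites
  shadowed by an upstream stop lose that fragment's event but keep its
  coverage, mildly reducing exo-mode power relative to endo mode at equal
  depth.
* **Minus-strand 5' terminal** is the alignment's rightmost base
  (`end - 1`); stated once, used everywhere.
* **Coordinates** are 0-based half-open throughout; GFF input is converted
  at the boundary (minus-strand TSS = feature end).
* **Nearest-TSS assignment** for the distance profile (ties broken toward
  the upstream TSS); the period of the distance histogram is the lag of the
  autocorrelation peak of the mean-centered 1-bp histogram over lags
  50-300 bp — more robust than a spectral fit at the site counts desk-scale
  simulations produce.
* **Tie at alpha**: adjusted p exactly equal to alpha passes.
* **Degenerate inputs**: empty truth sets are valid (pure shear); zero
  coverage or zero terminal events make background estimation error out
  rather than guess.

## What the tests show (and what they do not)

The validation suite runs the full chain on simulated readouts at desk
scale: familywise false-positive control on 20 unmodified (WGA) null
libraries (100-kb genome, 50,000 fragments each), methylome recovery on a
200-kb genome with every GATC duplex methylated (30x fragment coverage,
capture 0.3: recall >= 0.95 at precision >= 0.99, >= 99% of calls in the
planted motif), endo/exo concordance on one truth at equal depth (Jaccard
>= 0.90 at 60x, where both routes are well powered — the exonuclease route
yields one informative terminus per event versus two for the endonuclease,
so it needs roughly twice the depth for equal power), duplex-symmetry
classification (>= 95% full on fully methylated simulations, >= 95%
hemi-plus on plus-strand-only simulations), recovery of a planted 130-bp
TSS-distance period, and the 5'-terminal adenine bias of exo libraries
against matched WGA nulls.

The simulator omits several features of real libraries: sequencing errors
and base qualities, PCR amplification bias and duplicates, mappability and
alignment artifacts, antibody enrichment of methylated fragments (capture
is modeled per covered site, not as library-level IP enrichment),
nucleotide-composition-dependent shear bias, and chromatin context. Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model, not performance on
any particular real dataset.

## Known limitations

* The background model is global; locally elevated shear (e.g. fragile
  sites, repeats) is handled by blacklist filtering, not by a windowed null.
* Endo-mode counting assumes the cut bond used by the counter matches the
  simulator/enzyme offset; a mismatch shifts candidates off the adenine and
  is caught by the `require_A` filter rather than silently absorbed.
* Stoichiometry is reported only as `k/n`; no explicit methylation-fraction
  estimator is provided.
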