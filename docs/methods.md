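# Methods

## The two-allele re-association model

A cell heterozygous for a TR template variant contains two telomerase
pools writing different hexamers (TTAGGG from the wild-type template,
TTAGGT from the variant). The model tracks, repeat by repeat, which pool
wrote each unit:

* after depositing a repeat, the enzyme continues processively with
  probability `p_x` (per allele: `p_x_wt`, `p_x_var`);
* otherwise it dissociates, and the next repeat is written by whichever
  enzyme re-associates — the variant-template enzyme with probability
  `rho` (default 0.5, equal expression of both alleles), wild-type with
  `1 − rho`.

Processive continuation and same-allele re-association are mutually
exclusive routes to a same-class repeat, so the continuation probability
of a run is `P(Add) = p_x + (1 − p_x)·rho` (with `rho` replaced by
`1 − rho` for wild-type runs). Maximal same-class runs are geometric in
length: `S(x) = P(Add)^(x−1)`, linear in `log2` with slope
`log2 P(Add)`. The estimator fits that line and inverts
`p_x = (2^slope − rho)/(1 − rho)`.

Assumptions: the model is first-order (no memory beyond the current
allele), stationary along the telomere, and symmetric in mechanism
between alleles — only `p_x` differs. It does not model pause sites,
template-boundary effects, shelterin stimulation, or selection on
telomere length.

## Estimator choices

* **Run-survival definition.** S(x) is the fraction of *runs* with length
  ≥ x. This is the definition under which log2 S is exactly linear for a
  geometric process (slope log2 P(Add)) and reproduces the non-processive
  sequence 0.5, 0.25, … A repeats-weighted variant (each repeat weighted
  by the run it sits in) is available via `weighting="repeats"` for
  sensitivity analysis; it is not log-linear and is never used for the
  reported estimates.
* **Fit range.** Points x = 1 … the largest x whose cumulative run count
  is ≥ `min_runs` (default 5). This keeps log2 of noisy tail proportions
  out of the unweighted OLS. S(1) = 1 is included by default
  (`include_s1`); both choices are configurable and exact for noiseless
  geometric curves.
* **OLS** is unweighted (`scipy.stats.linregress`); no error model on the
  points is assumed.
* **Clamping.** A fitted slope steeper than the pure re-association limit
  implies `p_x < 0`, which the model cannot represent; `p_x` is clamped
  into [0, 1] and flagged. `p_add = 2^slope` and the inversion identity
  hold for the raw (pre-clamp) values.
* **Degenerate inputs.** A class with no runs raises a "no runs"
  estimation error (the other class is still estimated); a curve with
  fewer than two usable points raises "insufficient run-length range";
  constant survival (the fully processive limit) yields slope exactly 0,
  `p_x = 1`, with undefined r².

## Read-level processing

Detection, trimming, and orientation follow fixed rules: a read is
telomeric if a single greedy left-to-right scan finds ≥ 13 non-overlapping
occurrences of TTAGGG/TTAGGT/CCCTAA/ACCTAA anywhere in the untrimmed
read; telomeric reads are then cut to their first 60 bases (positional,
not quality-adaptive, for reproducibility) and reverse-complemented when
C-strand motifs strictly outnumber G-strand motifs (ties keep the read as
given). Composition counts bases covered by TTAGGG/TTAGGT placements from
the same greedy scan, TTAGGG tried first at equal positions; everything
else in the trimmed read is "other". Greedy placement is optimal for
in-frame tandem hexamer text and is property-tested against a brute-force
placement oracle.

**Censoring.** Runs are confined to single trimmed reads (no assembly),
so a 60 bp read caps observable runs at 10 units and boundary-truncated
runs are counted at their observed length. This is a real and deliberate
bias: windowing shortens the observed run distribution and pulls
read-level `p_x` estimates down substantially once mean run length is no
longer small against the window (e.g. a generating `p_x` of 0.4 yields
read-level estimates near 0.22; at `p_x` near 0.9, mean run length
exceeds the window entirely). Unit-level estimation
(`RunLengthTable.from_unit_classes` on array ground truth, or longer
windows) is unbiased, and the test suite checks the read pipeline against
a windowed unit-level oracle rather than against the generating value.
Parameter-recovery results quoted for this package are unit-level.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not a sequencing instrument:

* **Telomere arrays** follow the re-association model exactly, then an
  i.i.d. per-unit "degeneracy" overwrite (default 0.15) replaces a
  deposited hexamer with a uniformly random non-canonical hexamer —
  a minimal stand-in for telomere degeneracy, sub-telomeric and
  interstitial telomere-like sequence, and base-calling noise, which in
  real data are neither i.i.d. nor uniform (they cluster
  sub-telomerically). The generating allele label is recorded per unit
  regardless of overwrites. One linear array stands in for all
  chromosome ends; composition and run statistics are
  position-independent, so diploidy and per-end variation are not
  modeled.
* **WGS-like reads** (default 150 bp) are drawn from either strand with
  substitution errors at 0.001 per base before position 60 and 0.02
  after, matching the observed quality cliff in telomeric reads; quality
  strings encode the Phred score of the generating rate. By default read
  starts are aligned to hexamer boundaries so base-fraction composition
  recovers the array composition exactly; with `frame_aligned=False`
  starts are base-uniform, as in real libraries, and the partial hexamers
  at read edges add ~6 unclassifiable bases to most trimmed reads
  (≈ 8% of trimmed length), inflating `frac_other` by about that much —
  a frame-truncation artifact to keep in mind when comparing absolute
  "other" fractions to real data.
* **Terminal reads** have the structure
  `[non-G adapter-like prefix][G-run = drawn C-tail length][reverse
  complement of the terminus in a drawn register]`. Because the
  telomeric alphabet on the G strand is {T, A, G}, its read-strand
  complement contains no G, so the tail G-run never absorbs telomeric
  sequence (property-tested over all 12 registers). Junk reads violate
  exactly one of the three quality filters each. Default register
  weights are illustrative (wild-type-dominated, −GGTTAG and −GGTTTA
  favored); tail lengths are uniform on 7–15.

Passing tests on this generator demonstrates correct and internally
consistent analysis of data that obey the model; it does not demonstrate
robustness to real-data features the generator omits (adapter
contamination, indels, PCR duplicates, clustered degeneracy, variable
read lengths).

## Terminal-permutation stage

The three filters (≥ 5 combined non-overlapping CTAACC/CTAAAC, a G-run of
≥ 6, and 12 defined bases after the first such run) are themselves the
quality control; no additional trimming is applied. "≥ 5 repeats" is read
as a combined count over both motifs. Classification uses only the
terminal hexamer of the reverse-complemented 12-mer, matched exactly
against the 12 rotations (checked pairwise-distinct at import);
non-matching termini are counted as "other" rather than dropped. Reads
are counted per read, not deduplicated — without UMIs, PCR duplication
bias cannot be corrected and is a known limitation.

## Problem sizes and reproducibility

Stochastic checks use 10⁵-unit arrays (20 seeds per operating point for
parameter recovery) and 10⁴-read composition samples — sizes at which
binomial/fit noise is comfortably inside the tested tolerances. Every
stochastic routine takes an explicit integer seed (numpy `default_rng`);
a pipeline run derives all stage seeds from the single configured seed,
and identical config + seed reproduces byte-identical FASTQ and reports.
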