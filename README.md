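# telovar

Analysis of **variant telomere repeats** in short-read sequencing data.

Human telomeres are tandem arrays of the hexamer TTAGGG written by
telomerase from the template of its RNA component (TR/TERC). A template
point variant (TERC r.50C>A) makes telomerase write **TTAGGT** instead, so
a heterozygous carrier's telomeres become a mosaic of wild-type and
variant repeats. `telovar` implements the three computations needed to
characterize such a mosaic from raw FASTQ reads, plus a ground-truthed
simulator, since patient WGS data of this kind is typically access
protected:

1. **Repeat composition** — detect telomeric reads (≥ 13 non-overlapping
   occurrences of TTAGGG / TTAGGT / CCCTAA / ACCTAA anywhere in the read),
   trim to the high-quality first 60 bp, orient to the G strand, and
   quantify the base fractions of wild-type, variant, and other sequence.
2. **In-vivo repeat-addition processivity (RAP)** — estimate each
   allele's processivity from how long consecutive same-repeat runs are.
3. **3′ terminal permutations** — from C-tailed terminal sequencing
   reads, classify which rotation of the repeat (e.g. −GGTTAG vs −GGTTTA)
   sits at the chromosome's 3′ end.

## The model

After adding a repeat, telomerase either continues processively with
probability *P(x)*, or dissociates; a re-associating enzyme carries the
variant template with probability ρ (0.5 when both TR alleles are equally
expressed). The probability that the next repeat matches the current
allele is therefore

    P(Add) = P(x) + (1 − P(x)) · ρ

Maximal runs of same-class repeats are then geometric: the fraction of
runs reaching length ≥ x is S(x) = P(Add)^(x−1), so log₂ S(x) is linear
in x with slope log₂ P(Add). `telovar` tabulates runs, fits that line by
ordinary least squares, and inverts

    P(x) = (2^slope − ρ) / (1 − ρ)

For a fully non-processive enzyme P(Add) = 0.5 (S(2) = 0.5, S(3) = 0.25);
for P(x) = 0.9, P(Add) = 0.95.

## Worked example

`examples/processivity_estimation.py` simulates a 100,000-repeat telomere
with a highly processive wild-type enzyme and a poorly processive variant
enzyme, then estimates both from the run-length survival fit:

```
wt: slope=-0.0681  P(Add)=2^slope=0.9539  P(x)=0.9077  (generating 0.91)  r^2=0.9991  points=137
var: slope=-0.5209  P(Add)=2^slope=0.6969  P(x)=0.3938  (generating 0.39)  r^2=0.9962  points=20
```

The fitted slopes of log₂ S(x) give P(Add) per allele, and inverting the
re-association model recovers the generating processivities (0.91 and
0.39) to within sampling error. Similarly,
`examples/composition_from_simulated_wgs.py` recovers the simulated
variant load and the 15% "other" (degenerate) sequence fraction from
reads alone, and `examples/terminal_permutation_spectrum.py` prints which
terminal registers dominate wild-type and variant chromosome ends:

```
terminal class fractions: wt=0.799, var=0.180, other=0.020
most frequent wt register: -GGTTAG (0.620 of wt ends)
most frequent var register: -GGTTTA (0.551 of var ends)
```

## Library and command line

Everything is importable (`telovar.compose`, `telovar.estimate_from_reads`,
`telovar.spectrum`, `telovar.simulate_telomere_array`, ...). A thin CLI
wraps the same functions for shell pipelines:

```bash
telovar simulate-wgs      --seed 1 --out sim/
telovar composition       --fastq sim/wgs_reads.fastq --min-repeats 13 --trim 60 --out reports/
telovar processivity      --fastq sim/wgs_reads.fastq --rho 0.5 --min-runs 5 --out reports/
telovar simulate-terminal --seed 1 --out sim/
telovar terminal          --fastq sim/terminal_reads.fastq --out reports/
```

Reports are TSV with JSON mirrors, plus a provenance block (config hash,
seed, version); identical config + seed reproduces byte-identical output.

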