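# Methods

## Abundance units and summaries

All screens run on TPM (transcripts per kilobase of exon model per million
mapped reads). From counts, `TPM_g = 1e6 · (c_g/ℓ_g) / Σ_h (c_h/ℓ_h)` with
`ℓ` the effective gene length in kb; every column sums to 1e6 by
construction, and this invariant is validated strictly on matrices built in
memory and as a warning on file load (files may carry rounded values).

Expressed genes (EGs) are genes with TPM strictly above 1.00, tiered
half-open: LEG (1, 10), MEG [10, 30), HEG [30, 300), VHEG [300, ∞). Boundary
values therefore belong to the upper tier (10 → MEG, 30 → HEG, 300 → VHEG).
Top-N transcriptome shares rank EGs by TPM descending with lexicographic
gene-id tie-break, so summaries are deterministic and invariant to row order;
samples with fewer than N EGs use all of them and set a shortfall flag.

Sample–sample Pearson correlation is computed on raw TPM by default; a
log2(TPM+1) option exists but is off because the atlas-relatedness heat maps
this mirrors are conventionally drawn on raw abundances. Constant columns
yield NaN entries with a warning — never a silent 0.

## Specificity screens

A gene is specific to the target when (1) its target abundance is ≥ 1 TPM
(the screen threshold is inclusive, "at least 1"; note EG classification is
strict > 1 — the two conventions differ only on the measure-zero boundary)
and (2) target / max(reference maximum, floor) ≥ 100, inclusive. The
reference maximum is the per-gene max over the 8 reference tissues; samples
can be excluded per screen (anthers from the pollen screen, pollen from the
anther screen) because late anthers already contain mature pollen and would
otherwise absorb genuinely pollen-specific genes into the denominator.

The zero-denominator rule floors the reference maximum at
`eg_cutoff / fold_threshold = 0.01` TPM: a gene silent in every reference is
the strongest specificity evidence and must pass, not crash. The anther
screen aggregates by unweighted mean over the 13 anther libraries; stage
screens (tetrad 6–7 mm, tapetal-degradation 11–12 mm, anther-dehiscence
19–24 mm bud) use the single stated library. All thresholds live in one
`ScreenConfig`.

Overlap percentages are reported at one decimal with half-up rounding
(`Decimal`, not banker's rounding) so printed tables are reproducible
exactly; the pipeline stores every percentage next to its integer numerator
and denominator and re-audits the arithmetic before returning a report.

## Exact test at fixed dispersion

With one library per condition the dispersion cannot be estimated, so it is
fixed through the biological coefficient of variation: `φ = BCV² = 0.09`
(BCV 0.3). Counts are NB with variance `μ + φμ²`.

Normalisation is TMM (trimmed mean of M-values): gene-wise log2 ratios
against a reference sample, genes zero in either library removed, double
trimming (30% each tail on M, 5% on A), weights equal to the inverse
asymptotic variance of M, and factors rescaled to geometric mean 1. A pure
depth difference gives factors of exactly 1. TMM is the default with an off
switch; whether the original unreplicated analyses used TMM or library-size
normalisation is generally unstated, and the default follows the edgeR
convention this test re-implements.

Both counts are rescaled to the common effective library size
`L = √(f_A N_A · f_B N_B)` (expectation-preserving). For integer rescaled
counts the two-sided p-value is conditional: given total `n = a + b`, the
null distribution of `a` is beta-binomial `(n, r, r)` with `r = 1/φ` (the
exact conditional law of one NB count given the sum of two iid NB counts),
and `p = Σ pmf(k)` over all `k` with `pmf(k) ≤ pmf(a)` (the
"sum of probabilities ≤ observed" two-sided rule; doubling one tail was
rejected because it does not match full-support enumeration). The pmf is
computed from `Γ(k+r)/Γ(r) = Π_{j<k}(r+j)` as a cumulative sum of logs,
which is exact and stable for arbitrarily large `r` — the φ → 0 limit
reproduces the binomial test to full precision. Non-integer rescaled counts
are resolved by bilinear interpolation of p over the four neighbouring
integer pairs (deterministic; rescaled values within 1e-9 of an integer are
snapped so equal libraries reduce to the pure integer test).

The conditional support is enumerated exactly; the cap defaults to 100,000
outcomes. Pipeline runs on the synthetic atlas raise the cap (10⁷) because
the top-heavy pollen profile legitimately yields per-gene totals above 1e5
at the emulated depth; the enumeration is O(n) per gene so this stays cheap.

DEGs are called at raw p < 0.05, following the unreplicated convention the
test targets; BH-adjusted p is emitted as an extra column but plays no role
in calling. The count filter (≥1 in at least one library) runs before
testing. log2 fold changes are display values computed on normalised counts
with pseudo-count 0.5 per cell; the pseudo-count never enters the test.
Under a simulated null (equal NB means, φ = 0.09) the observed rejection
rate at nominal 0.05 is ≈ 0.046 — the exact test is mildly conservative, and
the test suite asserts the rate stays ≤ 0.07.

## Enrichment

Standard over-representation: `p = P(X ≥ k)`, X hypergeometric(N, K, n),
exact tail summation. The universe defaults to all annotated genes present
in the expression matrix (configurable — real studies rarely state theirs).
BH is applied within the tested term list; q-values fix π₀ = 1, so q
coincides with BH-adjusted p — deterministic and conservative by choice
(reproducibility over power). Terms with fewer than 3 universe genes are
skipped by default as noise control. Set genes absent from the universe are
dropped and logged before testing. No term-graph propagation is performed;
annotations are taken as given.

## Promoters and motif scanning

Promoters are the `length` (default 2000) bases immediately upstream of the
annotated CDS start codon — "upstream of the ATG", not of the transcription
start site: + strand windows end just before the first CDS base, − strand
windows start just after the last CDS base and are reverse-complemented.
Contig-edge windows are clipped and flagged truncated; genes without a CDS
are skipped with a warning. Coordinates are 0-based half-open internally and
1-based inclusive in files.

Motifs are IUPAC patterns expanded to regular expressions with a lookahead
so overlapping occurrences all count. Both strands are scanned; a
palindromic pattern matching both strands at one offset counts twice, by
default and documented (a collapse flag exists) — scanning databases differ
on this convention and double-counting is the simpler, stated choice.
Per-class frequency is total sites / number of promoters, zero-hit promoters
included in the denominator. The shipped catalogue is a representative
fixture of ~24 literature-standard consensus elements across the 11
functional classes; full inventories are supplied as a user YAML dictionary.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a 22-tissue atlas: 1 pollen +
13 anther + 8 reference libraries plus an HT pollen library, 5000 genes,
NB counts at BCV 0.3, library size 2×10⁶ ± 10% (a consistent scale-down of
~30 M reads over ~70 k genes to ~400 reads per gene). Background baselines
are lognormal (median 30 TPM, σ = 1) with per-tissue lognormal effects
(σ = 0.4); 15% of genes are rare (median 0.3 TPM), populating the notEG
tier. The pollen column expresses 20% of background genes, drawn from the
upper half of the baseline distribution with fold effects up to 20× — this
keeps the pollen profile sparse and top-heavy (EG count far below the
references, top-300 share far above) while keeping background specificity
ratios in the tens, well clear of the 100-fold line, and keeps reference
expression far from the zero-floor regime.

Planted specific genes (50 pollen, 50 anther, 50 per stage) are silent in
the reference panel, the way real tissue-specific genes are undetected
outside their tissue; their ratio therefore exceeds any finite threshold
(the config accepts a finite planted fold ≥ 200 instead, which divides the
target level into the references). Stage-planted genes necessarily also
satisfy the anther-mean criterion (one expressed anther library, silent
references), so the ground-truth anther-specific set includes them — truth
is defined by the criterion, not the planting label. Planted DEGs (40 up at
4×, 160 down at 0.25×) are restricted to genes with expected pollen counts
≥ 50, where a 4× effect at φ = 0.09 is reliably detectable; 10 of them are
planted inside the pollen-specific set, mirroring a small
development-and-stress overlap. Promoter planting inserts Poisson(λ = 3)
non-overlapping copies per planted motif (two concrete 8–10 bp elements with
negligible background match rates) at recorded positions and strands;
annotation planting over-samples planted-set genes into two terms.

Not emulated: isoform structure, GC/length biases, correlated gene modules,
batch effects, mapping ambiguity, and realistic genome content. Passing the
recovery suites therefore demonstrates that the screening logic, the exact
test and the scanners do what they claim under the stated noise model — not
that any particular biological dataset would yield particular set sizes.
Absolute published set sizes from real atlases require the original raw
data and genome and are out of scope; they are covered by the planted-truth
and property suites at the reduced scale instead.

## Problem sizes and numerical choices

The default test suite runs a 600-gene atlas for generic checks and ten
5000-gene atlases for the recovery suite (~35 s total); the acceptance
script runs five 5000-gene atlases plus a 2000-gene null calibration
(~15 s). Exact-test equivalence against brute-force enumeration is verified
for every count pair with total ≤ 40 and spot-checked to total ≤ 50.
Floating-point ties in the two-sided outcome selection are tolerated at
1e-8 on the log scale; p-values within 1e-9 of 1 are snapped to 1. Gene
identifiers are opaque strings; all TSV dialects are UTF-8 with '.'
decimals.

## Known limitations

* The exact test's bilinear interpolation at non-integer rescaled counts is
  a documented convention, not the only defensible one (edgeR splits counts
  differently); differences are confined to sub-count resolution.
* q-values with π₀ = 1 are conservative; a spline π₀ estimator was
  deliberately not implemented.
* The motif catalogue is a fixture, not a replica of any curated database;
  frequencies on real promoters depend entirely on the supplied dictionary.
* With one library per condition, the fixed-BCV test quantifies sampling
  noise under an assumed dispersion — it cannot discover the true
  biological variance, and calls should be treated as screening hypotheses.
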