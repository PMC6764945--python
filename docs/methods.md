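# Methods

This note documents the models implemented in `mirarmkit`, the defaults
chosen where the underlying experimental conventions leave room, and
what the synthetic-data generators do and do not emulate.

## Relative and absolute quantification (`arm_stats`)

Relative expression uses the comparative-Ct convention: replicate wells
are summarized by the **median** (robust to outlier wells) before
differencing; ΔCT = Ct(target) − Ct(reference) per condition, ΔΔCT =
ΔCT(case) − ΔCT(calibrator), ratio = 2^−ΔΔCT. A ratio below 1.0 is
called *low* in the case sample; everything else — including exactly
1.0 — is *high*. The boundary is configurable (`low_threshold`) but the
high-by-default convention at 1.0 is deliberate and matches the
ratio-threshold rule the call is built on. Amplification efficiency
(10^(−1/slope) − 1) is reported from standard curves but **not** used to
correct ΔΔCT; the plain 2^−ΔΔCT form is what the downstream risk calls
assume.

Absolute quantification fits Ct against log₁₀(copies) by ordinary least
squares over a dilution series (≥ 3 distinct points spanning ≥ 2
decades) and inverts the line. Copy numbers from mass use

    copies = 6.02×10²³ · amount(g) / (length · 308.95 g mol⁻¹ · 2)

with the factor 2 dropped for single-stranded templates. The grouping
of the denominator (length × mean residue mass × strands) is the only
dimensionally consistent reading of the formula and is asserted against
an independent arithmetic oracle in the tests.

### Risk factors, risk score, survival

A patient contributes one risk factor for 5p upregulation (ratio > 1,
strict) and one for 3p downregulation (ratio < 1, strict); a ratio of
exactly 1.0 contributes neither, so rf_count ∈ {0, 1, 2}. The risk
score is a linear combination of the two arms. Because no coefficients
or standardization are canonical, the default is unit weights on
cohort-standardized log₂ ratios:

    score = w₅ · z(log₂ ratio_5p) − w₃ · z(log₂ ratio_3p),  w₅ = w₃ = 1,

which is strictly increasing in 5p and decreasing in 3p expression.
When survival data are available, `cox_risk_weights` estimates (w₅, w₃)
from a proportional-hazards fit instead. Survival stratification uses
the product-limit estimator and the (multivariate) log-rank test from
`lifelines`.

### Arm-pair trend classification

Per-arm direction over a paired cohort combines two gates: a paired
Wilcoxon signed-rank test on log ratios at α (default 0.05) **and** a
minimum median fold change (default 2). The fold-change gate is
standard differential-expression practice and is what keeps the
family-wise false-call rate of a *pair* (two tests) below α; with the
rank test alone, two independent α-level gates would mislabel ≈ 1 −
(1−α)² of null pairs. Trends follow from the two directions: both
moved, same sign → `same`; both moved, opposite signs → `opposite`;
one moved → `single`; neither → `none`. The classes are mutually
exclusive and exhaustive.

## Pull-down enrichment (`pulldown`)

The enrichment ratio per gene is

    ER = ((bait_pd + ε)/(ctrl_pd + ε)) / ((bait_input + ε)/(ctrl_input + ε))

with pseudocount ε = 0.01 FPKM by default to guard against zero
denominators (ε = 0 is allowed when denominators are positive; the
choice only matters near the detection limit). The expression filter
(abundance > 0.1 in at least one library, strict) is applied **before**
ER computation by default; both the order and the boundary are
configurable. Candidates are genes with ER strictly above 1.2.
Potential targets are candidates whose overexpression log2FC (computed
with pseudo-count 1) is negative; a stricter mode additionally requires
a negative-signed DE flag (|log2FC| > 1, strict, and FDR < 0.001). FDR
values are accepted as an input column; when absent, a per-gene
two-sided binomial count test with Benjamini–Hochberg adjustment serves
as a simple stand-in and is not claimed to reproduce any particular
read-level DE tool. CDF shifts between target sets and background use
the two-sample Kolmogorov–Smirnov test, two-sided by default. Gene
identity is exact string match; no symbol aliasing.

## Duplex architecture (`duplex`)

Pairing is score-based complementarity, not thermodynamic folding:
Watson–Crick +2, G:U wobble +1, mismatch 0, bulge open −2 and extend
−1, computed by a three-state (Gotoh) affine DP restricted to a
diagonal band of half-width 4 (widened by the length difference). The
miRNA is aligned end to end; target overhangs beyond the miRNA are
free, the natural convention for a site embedded in a longer
transcript. Ties resolve deterministically (match state preferred,
leftmost end), which in practice means leftmost-in-miRNA optima with
the fewest bulges. The tests hold this aligner to score equality with
an independent Waterman–Smith–Beyer-style search that maximizes over
explicit gap-run lengths.

Classification uses, in order:

* **extensive** — ≥ 90 % of miRNA positions paired (WC or wobble) and
  no central loop;
* **tdmd_competent** — all six seed positions (2–7) Watson–Crick
  paired (wobbles do not count in the seed, matching the strict-WC
  convention of seed-based target prediction; they do count toward 3′
  coverage), a central loop or target bulge opposite positions 9–12,
  ≥ 7 paired positions in the 3′-adjacent window 13..L−3, and at most
  2 unpaired nucleotides at the miRNA 3′ extremity — the terminal
  mismatch tolerance reflects the observation that sites mismatched at
  the very 3′ end but complementary to the adjacent region still
  trigger decay;
* **seed_only** — full seed with 3′-adjacent pairing below the
  threshold;
* **none** otherwise.

Transcript scanning anchors on perfect matches to the reverse
complement of the seed (positions 2–7 by default, 2–8 available),
expands each anchor to a window of at most L+8 nt, aligns and
classifies. Coordinates are 0-based half-open on the supplied strand;
only that strand is scanned. Windows truncated below L−4 at transcript
edges are skipped.

Sponge design concatenates n (default 6) copies of the reverse
complement carrying a 4-nt insertion between the partners of miRNA
positions 10 and 11 (configurable within the 9–12 window; positions
touching the seed are rejected), joined by 4-nt spacers. The inserted
bases copy a central miRNA base so they cannot pair. Rescanning a
designed construct yields exactly n TDMD-competent sites for
non-repetitive miRNAs; low-complexity miRNAs (e.g. UG-repeat arms) can
produce additional overlapping seed anchors that also classify as
TDMD-competent — these are genuine overlapping registers of the same
repeat, not artifacts, but they mean "exactly n sites" is only
guaranteed for sequences without internal seed repeats.

## isomiR profiling (`isomir`)

Reads shorter than 14 nt or with overlapping-dinucleotide Shannon
entropy below 0.5 bits are removed. The entropy cutoff was chosen so
that libraries of genuine miRNA-derived reads lose well under 1 % while
homopolymers and two-letter repeats (entropy ≤ 1 bit) are caught; it is
configurable.

Assignment is an exact anchored matcher, not a genome aligner: each
read is compared ungapped against each mature sequence in its precursor
context at 5′ offsets of up to ±3 nt, with mismatches counted on the
mature-overlapping portion only and capped at 2; reads with more than
100 acceptable placements are discarded. Multi-assigned reads keep the
fewest-mismatch placements with equal fractional weights (weights of a
read sum to 1, so total weight equals assigned reads). The
genome-mismatch filter of an alignment pipeline is replaced by its
precursor-scale analogue: a read is discarded if any precursor region
*outside* the mature windows matches it with fewer mismatches. These
are behavioral, not bit-exact, reimplementations of an aligner-based
workflow.

Isoform classes: canonical (exact mature), trimmed (3′ shortened),
tailed (3′ extended), trimmed_tailed, and five_prime_variant (5′ offset
≠ 0, which overrides and is excluded from the trimming/tailing
proportions by default, since 3′ remodeling is the TDMD signature of
interest). A tail is *templated* if it equals the precursor bases
immediately downstream of the read's 3′ end, *non-templated* if no
tail base matches, *mixed* otherwise; both accounting modes (templated
tails as tailing or as extended matches) can be derived from the
reported fields. Normalization divides per-miRNA counts by the library
total, multiplies by the mean library total and applies log2(x+1);
proportions are unaffected by library scaling.

## Synthetic data (`synthetic`)

One integer seed drives a single `numpy` generator passed through all
sub-generators; identical configurations reproduce identical outputs.
Expression noise is lognormal (multiplicative), the natural model for
fold-change data. Two dispersions are distinguished:

* `lognormal_sd` (default 0.3) — biological patient-to-patient
  dispersion in the paired cohort, a moderate spread typical of tissue
  qPCR/small-RNA panels;
* `tech_sd` (default 0.03) — technical library-to-library noise of
  abundance estimates in the pull-down/overexpression tables, matching
  the few-percent CVs of deeply sequenced, well-expressed genes when
  one lysate is split across libraries. Conflating the two would make
  either the cohort unrealistically clean or the pull-down
  unrealistically noisy.

Cohort defaults plant trend classes at fractions emulating a large
tumor/normal arm-pair survey (≈ 35.9 % same-trend, ≈ 9.1 %
opposite-trend, the remainder single-arm or null) with a 4-fold effect
on dysregulated arms. The pull-down generator spikes `n_enriched`
genes with a true ER of 3 and a −1 log2FC depletion in the
overexpression library. Reference generation plants one site of each
class per transcript, with backgrounds rejection-sampled to contain no
seed complement, so "none" transcripts are guaranteed clean; planted
TDMD sites keep full terminal pairing so their coordinates are
alignment-unambiguous. Read generation draws the
canonical/trimmed/tailed_nt/tailed_t mixture (default 0.70/0.20/
0.05/0.05); non-templated tail bases are drawn from the three bases
differing from the corresponding downstream precursor base, making the
templated/non-templated truth unambiguous. Survival times are
exponential with hazard h₀·exp(β·score) (h₀ = ln 2/1000 days, i.e. a
~3-year baseline median); censoring is independent with probability
`censor_rate`, uniform over the subject's event time.

The generators do **not** emulate: realistic sequencing error profiles
or adapter contamination, expression-dependent (heteroskedastic)
measurement variance, correlated genes, 5′ isomiRs, secondary
structure, or informative censoring. Recovery tests on these data
therefore demonstrate correctness of the statistics and bookkeeping
under the stated models — not robustness to every pathology of real
libraries.

## Problem sizes

The validation suite and `scripts/acceptance.py` use the generators'
study conditions directly: 800 arm pairs × 50 paired samples for trend
recovery, 5 000 genes with 200 spikes (and 100 null cohorts) for the
pull-down, 10 000 reads for isomiR mixtures, 200 random miRNA/site
pairs plus 50 sponges for the alignment oracle, and 100 cohorts of 200
patients for log-rank power and size. These sizes put Monte-Carlo error
well below the decision thresholds while keeping a full run in the
tens of seconds.
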