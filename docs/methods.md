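# Methods

This note documents the models, parameter choices and limitations behind
`esocnv`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and synthetic cohorts

A cohort is described by a `CohortConfig`: group sizes, background CNV rates,
length distributions, planted loci, noise levels and a seed. The generator is
fully deterministic given the seed; per-sample noise streams are derived from
`(seed, crc32(sample_id))` so that batch and single-sample simulation agree
bit-for-bit.

**LRR.** The diploid baseline is 0 with Gaussian noise whose standard
deviation is the sample's own LRR_SD metric (drawn around 0.16, the typical
value for Illumina-style arrays). A copy-state segment shifts the mean by
−3.5 (CN0), −0.55 (CN1), +0.35 (CN3) or +0.65 (CN4). These shifts are not a
published constant of any specific caller; they are chosen to match standard
array behaviour, and truth recovery — not the shift values — is what the
tests check. A GC-correlated waviness term `WF × standardized(GC)` emulates
the genomic-wave artifact; the toy GC track is sinusoidal in position, so the
wave is sinusoidal too.

**BAF.** Drawn from state-specific cluster mixtures: diploid near
{0, ½, 1} (heterozygote fraction 0.34), CN1 without a heterozygote band,
CN3 near {0, ⅓, ⅔, 1}, CN4 near {0, ¼, ½, ¾, 1}, CN0 uniform noise. Cluster
noise is N(0, 0.03), clipped to [0, 1]; the BAF_DRIFT metric adds a small
extra jitter.

**Background CNVs** are Poisson per sample (0.8 deletions, 1.1 duplications
per person) with log-normal lengths (σ_log = 0.6) whose means are set from
the group mean *total* lengths divided by the rate — 220.7/0.8 kb per
deletion in cases versus 177.8/0.8 kb in controls, and 419.6/1.1 versus
258/1.1 kb for duplications. Lengths are truncated below at 12 markers so
that background events survive the ≥ 10-marker filter and contribute to
burden; cohort-level burden means are calibration inputs, not reproduction
targets.

**Risk loci** are planted as independent Bernoulli carrier draws per sample
at group-specific frequencies, with ±0–2 markers of breakpoint jitter per
carrier so that the segmental test sees distinct breakpoints. A locus may
carry a *nested* sub-locus: samples that do not carry the full span may carry
the shorter shared segment at its own frequencies, reproducing the
full/partial carrier structure of recurrent duplications. A configurable
fraction of cases (default 0.145 in the study configuration) are relatives
who copy their proband's risk-locus status and share a family id.

**Scaling and placement.** The bundled study configuration uses 1614 cases /
3922 controls on a toy genome of 4 chromosomes × 1000 markers at 5 kb
spacing (4000 markers). This problem size keeps a 20-seed full-pipeline
battery tractable on a single CPU while preserving the quantities that drive
the statistics: cohort sizes, carrier frequencies and permutation counts.
Two consequences of compressing a 3 Gb genome ~750-fold are handled
explicitly:

- Background events are placed **outside** the configured risk loci, with a
  100-marker exclusion margin (`risk_zone_margin_markers`). On the real
  genome the chance that a random background CNV overlaps — or lands within
  ~0.5 Mb of — a specific locus is ~10⁻⁴ per sample and negligible next to
  carrier frequencies of 0.1–0.5 %; under uniform placement on the toy
  genome both would be routine. Without the margin, a carrier's locus call
  can merge with the same sample's adjacent background event and the
  extended call then chains (by 50 % reciprocal overlap) into recurrent
  background clusters, which the control-frequency filter would delete
  wholesale. The margin makes near-locus background as improbable as it is
  in reality.
- Background events unavoidably recur at overlapping positions across
  samples, so the > 1 %-of-controls frequency filter removes most of them in
  the full pipeline (as it would remove genuinely recurrent polymorphisms).
  The planted risk duplications survive because their control carrier
  frequencies are below 1 %. Burden properties of the generator itself are
  therefore tested on truth-derived calls, while the pipeline battery tests
  the case–control duplication-length difference on whatever survives
  curation — both show the configured case excess.

What passing tests on this synthetic data do **not** show: robustness to real
array artifacts beyond the modelled ones (no probe-level call-rate structure,
no mosaicism, no X/Y dosage, no batch effects), or the behaviour of the real
PennCNV/QuantiSNP numerics.

## The HMM caller

Five states (copy numbers 0–4, diploid = 2), joint emissions = Gaussian LRR
density × BAF cluster-mixture density, and distance-independent transitions:
probability `p_enter` of jumping from diploid into one specific CNV state per
marker step and `p_return` of returning (cross-CNV transitions at 10⁻⁶).
Distance-dependent transitions of the real callers are deliberately out of
scope: downstream stages consume only the interface (calls + confidence).

The caller's BAF model gives the homozygous clusters at {0, 1} identical
weight (0.33) in every state, so runs of homozygosity are copy-neutral by
construction, and mixes in a 1 % uniform floor for outlier robustness. The
emission means are shared with the simulator's signal model — the caller is
calibrated to its platform — while the two bundled profiles differ where real
callers differ, in their noise prior and transition penalties:

| profile | lrr_sd | p_enter | p_return |
|---------|--------|---------|----------|
| callerA | 0.13   | 1e-3    | 0.04     |
| callerB | 0.14   | 2.5e-3  | 0.05     |

These values satisfy a design constraint verified by test: on noise-free
signal, the weakest detectable event (a 3-marker CN3 segment made entirely of
homozygous markers, worth 3 × 0.35²/(2 σ²) log-likelihood units of LRR
evidence and nothing from BAF) still outweighs each profile's
transition penalty, so noise-free truth of ≥ 3 markers is recovered exactly.
At default noise the profiles' differing penalties produce overlapping but
non-identical call sets — the precondition for the consensus intersection to
be meaningful.

**GC-wave adjustment** regresses LRR on GC per chromosome and keeps the
residuals. The fit is two-pass: markers whose first-pass residual exceeds 0.5
in absolute value (real CNV segments, spikes) are masked and the line refit.
Without the second pass, a single large deletion shifts the chromosome's
baseline upward and manufactures shared false duplications elsewhere — the
failure mode that motivated the design.

**Confidence** is the summed per-marker log-likelihood ratio of the called
state against diploid. The filter defaults (deletions < 25, duplications
< 10 removed) are expressed on this scale and are configuration parameters,
not universal constants: the empirical cutoffs of the emulated study live on
a different caller's score scale, so threshold *behaviour* (deletions held to
a stricter standard than duplications) is what carries over.

**Viterbi decoding** accumulates in float64 inside a numba kernel (ties break
toward the lower copy state); a pure-python oracle in the test suite checks
path equality on random emissions.

## Curation semantics

- *Merging*: same sample, caller and copy state; merge when intervening
  markers < 20 % of the two segments' combined marker count. The denominator
  excludes the gap, following the literal reading of the rule; the
  alternative (gap included) is available via
  `include_gap_in_denominator=True`. Iterated to a fixpoint; merged
  confidence is the sum.
- *Intersection*: "same copy number" is interpreted as same class (DEL/DUP),
  since two callers may disagree on CN0 vs CN1 at a shared deletion and the
  downstream analysis distinguishes classes only; `strict_state=True`
  restores integer-CN matching. Disagreement within a class resolves to the
  state closer to diploid. Consensus confidence is the min of the pair.
- *Filter order* is fixed and logged: size → markers → artifact → common →
  confidence → control frequency. A call is charged to the first rule it
  fails; order affects per-rule counts but not the final set when rules are
  independent.
- *"Present in" controls* (the > 1 % filter) uses single-linkage clustering
  at ≥ 50 % reciprocal overlap — the standard criterion for treating two
  calls as the same event — and counts distinct control carriers per
  cluster. Exceeding clusters are removed entirely, case members included.
- Catalog entries without a frequency are treated as common (frequency 1).

## Burden and association

Burden comparisons use a two-sided label-permutation test of the group mean
difference — the study framing is permutation-based throughout, and the test
is assumption-free. Samples for which a metric is undefined (mean length with
zero calls) are excluded from that metric's test. Size-bin odds ratios take
"exposed = burden in bin" versus all other samples (so every row's table sums
to the cohort size); the zero-burden-reference alternative would change the
estimand, and the exposed-vs-rest reading is the one used.

The per-locus statistic is the Pearson chi-square of the carrier 2×2. The
emulated study's association tool does not print its statistic; chi-square
makes max(T) comparable across loci with different carrier counts, and a
one-sided case-enrichment variant is available via `alternative=
"case-enriched"` (whether the original test was one- or two-sided is
unstated; two-sided is the conservative default). Carrier status at a locus
requires ≥ 1 bp overlap (configurable); empirical p-values use the
(r+1)/(n+1) convention, so no reported p can undercut 1/(n_perm+1).

Woolf confidence intervals do not reproduce the printed intervals of the
emulated study exactly (e.g. 4.9–41.0 here versus a printed 5.4–38.1 at the
same table), which is expected — the original interval method is unstated,
possibly exact/conditional — so CI bounds are checked only for internal
consistency; odds-ratio point estimates are checked exactly.

The subtype chi-square implements the procedure (Pearson statistic,
df = (rows−1)(columns−1)) and validates margins; the study's full
subtype-by-locus table is not printed, so only the procedure and its degrees
of freedom are testable, not the published statistic.

Relatedness: `keep_one_per_family` retains the sample with the lowest LRR_SD
per family; a property test checks that a family-consistent signal stays
significant after the subset, mirroring the unrelated-subset re-test.

## Numerical and degenerate-input choices

- Permutation comparisons use `T* ≥ T − 10⁻⁹` so exact ties count against the
  null (conservative).
- Chi-square is defined as 0 when a table margin is empty.
- Haldane–Anscombe 0.5 is applied only when a 2×2 cell is zero, and flagged.
- Empty exposed bins and genes without exon models are reported/skipped, not
  errors; zero chi-square margins and locus intervals containing no markers
  are errors.
- Problem sizes used by the test suite: the acceptance battery runs 20 full
  pipeline seeds at 1614/3922 samples × 4000 markers with 10⁴ permutations;
  the permutation-floor check runs 10⁶ permutations on a 600-sample cohort;
  exhaustive-enumeration oracles run at ≤ 12 samples.

## Power of full-recovery at the empirical floor

Because carriers are drawn per sample as independent Bernoulli events,
individual cohorts can draw substantially weaker carrier tables than the
configured expectation (e.g. 18 case vs 9 control carriers where 23 vs 4 is
expected). Such a cohort's chi-square can fall to ~20, at which point a few
of the 10⁴ permutation maxima exceed it and the locus — though still
genome-wide significant — no longer sits exactly at the minimum attainable
corrected p. For the two weaker planted loci this happens in roughly 3 % of
cohorts each under pure binomial draws, and 6–7 % each when the relative
fraction is included (relatives clone carrier status, inflating draw
variance). Recovery of *all three* loci at the floor is therefore the
typical but not guaranteed outcome of a simulated cohort; the null-locus
and burden clauses are stable across seeds.

## Known limitations

- The toy genome's density makes cross-sample background overlap far more
  common than on a real genome (see Scaling above); per-rule removal counts
  in full pipeline runs are therefore dominated by the control-frequency
  rule in a way real data would not be.
- The HMM has no distance-dependent transitions, no trio mode, and no
  allele-specific copy numbers beyond the five states.
- The simulator does not model genotype call rate at the probe level,
  X/Y intensity dosage, or mosaicism.
- The generator's relatives share only risk-locus carrier status, not
  background CNVs; this is sufficient to exercise the unrelated-subset
  logic but understates true sibling sharing.
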