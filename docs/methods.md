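# Methods

## Assay model

The pipeline analyses a sort-seq multiplexed assay of variant effect.
Each cell expresses one integrated BRCA1 cDNA variant identified by a
short DNA barcode. Under three siRNA conditions the probability that a
cell converts GFP-positive (i.e. repairs an induced double-strand break
by homology-directed repair) is:

| condition      | P(GFP+) per cell                     | interpretation |
|----------------|--------------------------------------|----------------|
| `control`      | p_max                                | endogenous BRCA1 repairs regardless of the variant |
| `siBRCA1_3UTR` | p_bg + (p_max − p_bg) · r_v          | only the integrated variant (rescue fraction r_v) can repair |
| `siBRCA1_CDS`  | p_bg                                 | both copies silenced; assay noise floor |

r_v ∈ [0, 1] is the variant's HDR activity as a fraction of wild type.
The GFP-negative bin is carried through all tables but takes no part in
scoring; only input and GFP-positive frequencies enter the score.

## Scoring

Replicate score: log₂ of the pseudocounted GFP-positive/input frequency
ratio, centred by the median of the same quantity over the synonymous
cohort. Choices:

* **Pseudocount 0.5** added to every count before frequency computation
  (the Enrich2 convention; configurable). Consequence: scores are
  invariant under uniform depth rescaling of a bin only up to a residual
  of order pseudocount/count — negligible (<0.01 log₂ units) at the
  hundreds-of-reads-per-variant depths the pipeline targets, but not an
  exact identity.
* **Synonymous median, not mean**, for centring: robust to the occasional
  outlier synonymous variant. By construction the synonymous cohort's
  median score is exactly 0 in every replicate/condition.
* **Replicates combined by arithmetic mean**; the unbiased sample
  variance feeds the variance filter. Variants with fewer than two
  replicate scores are emitted as unscored, not dropped silently. No
  standard-error weighting or random-effects model is attempted.

## Filtering and cutoffs

* Variance filter: replicate variance strictly greater than 1 removes a
  variant (a variance of exactly 1 is retained). Read filter: minimum
  input-bin count across replicates below the configured threshold
  (default 10; tunable against singleton discordance, see below).
  Filtering is idempotent and every removal carries its reasons.
* Normal/intermediate cutoff: Gaussian fit (sample mean, unbiased sd) to
  the missense scores from the control condition, evaluated at the 1st
  percentile. The fit uses the missense variants that survive the
  filters; the cutoff's provenance block records n, μ, σ and the
  percentile so the choice is auditable.
* LOF/intermediate cutoff: smallest multiple of 0.01 strictly greater
  than the highest-scoring nonsense variant under knockdown. Strictness
  means a maximum landing exactly on a hundredth moves the cutoff one
  hundredth up, preserving the nonsense-always-LOF guarantee. The
  hundredths ceiling is computed after rounding the score×100 to six
  decimals to dodge binary-float artefacts.
* Tie policy: a score equal to a cutoff takes the more-functional class
  (cutoffs are open lower bounds of the class above them).
* Cutoffs are derived once on the pooled dataset, not per sublibrary.

## Singleton calibration and read-threshold tuning

The singleton assay reports rescue fractions on a linear scale; cutoffs
0.4 (log₂ −1.32) and 0.7 (log₂ −0.51) give
nonfunctional/intermediate/normal calls. Hard discordance (LOF on one
platform, normal on the other) drives `tune_read_threshold`: candidate
thresholds are the observed minimum-input-count values, and the smallest
candidate eliminating the requested number of discordant variants wins.
If the most-covered variant is itself discordant no candidate can remove
it; the error reports the maximum achievable elimination rather than
silently extending the candidate set.

## Clinical concordance and OddsPath

Sensitivity = pathogenic/likely-pathogenic controls called LOF over
pathogenic controls scored; specificity = benign/likely-benign controls
called normal over benign controls scored. Intermediate calls count as
failures for both metrics; unscored variants leave the denominators; an
empty control set makes a metric undefined (None), never 0. Joins use
amino-acid-level labels, deliberately ignoring nucleotide-level
differences between assay constructs and database entries.

OddsPath: with prior P1 = pathogenic/(pathogenic+benign) over controls
and P2 the pathogenic proportion among controls with a given readout,
OddsPath = P2(1−P1) / ((1−P2)P1). "Abnormal readout" means LOF only;
intermediate controls are excluded. When concordance is perfect the
relevant confusion cell is empty and the odds would be unbounded, so one
hypothetical discordant control is added to that readout set (a benign
control to the abnormal set for PS3; a pathogenic control to the normal
set for BS3). An 11-pathogenic/5-benign perfectly concordant panel then
gives PS3 odds 5.0 and BS3 odds 1/11 ≈ 0.091 — both moderate under the
default strength bands (PS3 supporting/moderate/strong/very-strong at
2.1/4.3/18.7/350; BS3 at 0.48/0.23/0.053), which are configurable since
they come from the ACMG calibration framework, not from any one assay.

## Synthetic data generator

The generator emulates the experiment's structure at its reported scale:
a 297-codon region (residues 1280–1576, sublibraries CC1/CC2/CC3), one
missense variant per codon plus 40 nonsense and 30 synonymous variants
(~367 variants, matching the few-hundred-variant scale of the assay),
barcodes per variant ~ 1 + Poisson(mean − 1) with mean 3, an integration
bottleneck drawn as a single multinomial of 4×10⁵ cells over barcodes
(sorted-cohort cell counts were a few ×10⁵), per-replicate cell
allocation, per-cell Bernoulli GFP conversion, and multinomial read
sampling at 10⁶ reads per bin. One global seed drives everything through
two seed-sequence children (library vs assay), with draw order fixed and
documented in the code.

True-class mixture among missense variants: 12% LOF, 8% intermediate
(the assay found ~9% of missense variants LOF and ~9% of the final set
intermediate). Rescue fractions: functional ~ N(1.0, 0.05) truncated to
[0,1]; intermediate ~ U(0.3, 0.6); LOF ~ N(0.02, 0.02) truncated;
synonymous exactly 1. Nonsense variants are always LOF.

p_max = 0.05 reflects a typical HDR reporter conversion rate. The noise
floor p_bg = 0.02 = 0.4·p_max mirrors the singleton assay's own
convention that activity below 0.4 of wild type is nonfunctional — the
assay cannot distinguish function below that floor. This floor also
keeps LOF variants at GFP-positive cell counts (tens per variant) where
the variance filter measures real replicate scatter rather than Poisson
zeros; at a substantially lower floor the filter starts discarding LOF
variants wholesale, which is a property of sparse real data the default
conditions deliberately avoid.

What the generator does **not** model: PacBio read errors or consensus
building, cell-cycle/transfection-efficiency variation, barcode
sequencing errors (counting is exact-match by design), abundance skew
beyond the multinomial bottleneck, and splicing effects (the assay uses
cDNA). Passing recovery tests on synthetic data therefore demonstrates
the correctness of the analysis chain under the stated noise model, not
the assay's real-world error rates. The wild-type amino-acid sequence is
a seeded random synthetic sequence; annotation functions accept any
user-supplied sequence.

## Numerical and degenerate-input choices

* Zero-count bins are handled by the pseudocount; empty synonymous
  cohorts, empty nonsense sets, zero-variance cutoff fits and inverted
  cutoffs raise typed errors rather than producing NaNs.
* The GFP pre-sort QC gate aborts a run when the knockdown GFP-positive
  fraction is not below the control fraction (a library with LOF variants
  must convert fewer cells under knockdown).
* All writers emit deterministic provenance-headed TSV/JSON (version,
  seed, input hashes; no timestamps), so identical config + seed gives
  byte-identical artifacts, and each stage reproduces its outputs from
  its written inputs.

## Problem sizes

Default end-to-end runs use ~367 variants × ~1100 barcodes × 3
replicates × 3 conditions at 10⁶ reads per bin (<1 s per run); recovery
statistics average 10 seeded runs; property tests use 15–50-codon
libraries. These sizes were chosen so the full suite and the
reproduction script each complete in seconds while keeping per-variant
read depth in the regime the scoring model targets.

## Known limitations

* The scoring is a two-bin ratio method; time-series/regression scoring
  (multi-timepoint designs) is out of scope.
* Exact-match barcode counting only; reads one substitution away from a
  known barcode are tallied as unmatched, never corrected or imputed.
* No splicing-based interpretation: the assay reads out cDNA function,
  and variants whose clinical effect is splice-mediated will look normal.
* The read-count filter threshold is a required analysis parameter; the
  package provides the singleton-discordance tuning procedure rather
  than a universal default.
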