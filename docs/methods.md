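# Methods

## Statistical model

The proteomic unit of analysis is one protein's vector of label-free
quantification (LFQ) intensities across 2k samples (k per group, k = 5
by default). Intensities are modelled as log2-normal within protein and
group: log2 x<sub>gij</sub> = b<sub>g</sub> + δ<sub>g</sub>·1[j ∈ MCT] +
ε<sub>gij</sub>, ε ~ N(0, σ²<sub>g</sub>). Non-detection is encoded as a
literal zero in the matrix.

Inference on δ<sub>g</sub> uses the empirical-Bayes moderated t. The
pooled residual variance s²<sub>g</sub> has d<sub>g</sub> = 2k − 2
degrees of freedom; an inverse-χ² prior with hyperparameters (d₀, s₀²)
is fitted by the method of moments on log s²<sub>g</sub>: with
e<sub>g</sub> = log s²<sub>g</sub> − ψ(d<sub>g</sub>/2) + log(d<sub>g</sub>/2),
the mean of e identifies s₀² and the excess of var(e) over
ψ′(d<sub>g</sub>/2) identifies ψ′(d₀/2), inverted by Newton iteration
on the trigamma function. When the observed variances are no more
dispersed than sampling explains, d₀ = ∞ and every posterior variance
collapses to s₀² (the t reference becomes normal). The posterior
variance is the df-weighted blend s̃²<sub>g</sub> =
(d₀s₀² + d<sub>g</sub>s²<sub>g</sub>)/(d₀ + d<sub>g</sub>) and the
statistic is referred to t with d₀ + d<sub>g</sub> df. An ordinary
pooled-t mode (the d₀ → 0 limit) is available for comparison. The test
suite verifies the whole chain against Bioconductor limma at 1e-8
tolerance (observed agreement ~1e-14).

The z-score classification standardizes log2 ratios across proteins
with the sample SD (n−1): it asks which proteins sit in the tails of
the study's own effect distribution, and ±1.96 marks the two-sided 5%
tails under a normal reading. The cut is applied inclusively (a protein
printed exactly at the threshold is retained); the q < 0.05 cut is
strict.

Multiple testing uses the Benjamini–Hochberg step-up exactly:
q<sub>(i)</sub> = min<sub>j≥i</sub> p<sub>(j)</sub>·m/j capped at 1,
with a stable sort so ties resolve deterministically.

## Preprocessing order

Zeros are replaced by the per-sample 1st percentile (quantile 0.01,
sort-and-interpolate) of that sample's nonzero intensities, computed on
the **full** matrix; the presence filter (≥ 3 originally-positive
values in **each** group) is decided on the pre-imputation zero
pattern. Imputing on the full matrix and then subsetting is not the
same as imputing the filtered matrix — the per-sample quantile depends
on the row set — so the order is fixed as stated and the tests pin the
well-defined invariants: the filter decision never depends on
imputation, observed values are never altered, and the imputed matrix
is strictly positive. An all-zero sample column is a hard error (its
floor is undefined). The "1st percentile of nonzero values, per sample"
reading was chosen over a global or 0.0001-quantile reading because a
per-sample low-abundance floor is the standard LFQ practice; the
quantile and the per-group minimum count are both exposed as
parameters.

No sample-level normalization is applied by default (the preprocessing
recipe names none); a median-centering flag (`median_normalize`)
exists for matrices that need it.

## Integration and prioritization

Identifier resolution is file-based: a (uniprot, ensembl, symbol)
table, with a curation-override table that wins over it; unmapped
accessions are carried through and reported, multi-mapping proteins are
expanded with a flag and later deduplicated by smallest q (stable
tiebreak on accession). The omics join key is the gene symbol — the key
displayed by the published target tables — with Ensembl id retained for
disambiguation.

Concordance is a function of the sign pair only; a zero effect on
either side is unclassifiable and excluded with a warning. The
dual-stringency filter retains pairs with protein q < 0.05 and |z| ≥
1.96 and transcript FDR < 0.05 and |linear fold| > 1.5 (|log2 FC| >
log2 1.5 ≈ 0.585).

External studies report folds in three conventions — linear ratio
(0.37 = down), signed fold (−1.66 = down), log2 — all normalized onto
log2 before comparison; signed folds strictly inside (−1, 1) violate
their convention and are rejected rather than guessed at. A target
counts as commonly regulated in an external study only if the study
reports a value for its symbol (dash dialects "—", "-", "", "NA" are
absences, not zeros) and the normalized sign matches. Overlap
percentages state their denominator explicitly because |A∩B|/|A| and
|A∩B|/|B| differ.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) for k selected genes among K term genes in an N-gene
universe with n selected. The universe is the set of genes that
entered the differential analysis — not the genome — since detection
itself is biased. BH is applied within each GO domain separately, as
results are reported per domain. Annotations are used as given (no
ancestor propagation), keeping the module database-free. The
enrichment-map network connects enriched terms with Jaccard ≥ 0.25 of
their selected-gene sets, the conventional enrichment-map default.
Exactness of the p-value is tested against full enumeration of all
C(N, n) draws for N ≤ 12.

## Physiology

Derived indices follow the standard estimators: mPAP = 0.6·RVSP + 2,
PVR = (mPAP − LVEDP)/CO (mmHg/ml/min), free-wall thickening
(sys − dia)/dia, RV–PA coupling TAPSE/RVSP, Fulton index
RV/(LV+septum). The index chain is per animal; means of per-animal
ratios are not ratios of means, so no group-level recombination is
done. Two-group tests can be run from published summaries (mean, SEM,
n): t = Δmean/√(SEM₁²+SEM₂²) with pooled df (exact for equal n) or
Welch–Satterthwaite df. qPCR folds use 2^−ΔΔCt against a reference
probe and a control group; the control group's geometric mean fold is 1
by construction.

## Synthetic data generator

The generator emulates the study conditions end to end: 3,100 proteins
× (5+5) samples; per-protein baselines N(23, 2²) on log2 (MaxQuant-like
LFQ magnitudes); within-group noise σ = 0.5; 10% of proteins carry a
planted effect of exactly 2 log2 units (mean |log2 FC| = 2 by
construction), direction 50/50; transcripts of differential proteins
are concordant with probability 0.9, with magnitudes jittered around
the protein effect and an extra 30% transcript-only genes making the
merge a proper partial join; the mapping covers 90% of accessions; the
annotation plants one BP term enriched among differential genes.
Dropout is missing-not-at-random: a cell is zeroed with probability
expit(8 − 0.5·log2 intensity), so low-abundance cells vanish more
often (≈6% of cells overall at the default baseline). All draws come
from per-operation child streams of a single seed, in documented order,
so planted counts (e.g. contra pairs) can be replayed exactly.

What the generator does **not** emulate: peptide-level structure and
rollup, correlated proteins (co-regulation, complexes), batch or run
order effects, heavy-tailed or heteroscedastic noise, realistic
annotation topology. Passing tests therefore demonstrate correctness
and calibration of the machinery under the stated generative model,
not performance guarantees on any particular real data set.

## Numerical and calibration notes

* Trigamma inversion: Newton iteration with asymptotic start, relative
  tolerance 1e-10; closed-form branches for extreme arguments.
* With the degenerate dropout configuration (intercept −∞, a supported
  boundary case) the null pipeline is calibrated: p-values pass a KS
  uniformity check at α = 0.01 across seeds. With dropout on, floor
  imputation deflates some within-group variances' effective tails and
  the null p distribution becomes mildly **conservative** (fewer than
  5% of null p below 0.05); BH false-discovery control is preserved
  (the measured null false-positive proportion is ~0). This is a known
  property of constant-floor imputation, not of the test statistic,
  which is limma-exact.
* The same mechanism bounds sensitivity: proteins whose dropouts are
  floor-imputed carry inflated variances, and ~2% of planted-DE
  proteins are removed by the presence filter outright. At the default
  configuration the stringent set recovers ≈80% of planted effects
  (30-seed ensemble in the test suite; the acceptance script recomputes
  it for any seed).
* Determinism: identical configurations give byte-identical outputs;
  the pipeline manifest stores sha256 digests of every file, and ties
  everywhere (BH ranks, merge collisions, network edges) resolve by
  stable sorts on named keys.

## Problem sizes

Test-suite simulations use 250–3,100 proteins and 20–30-seed ensembles;
the acceptance script uses the default 3,100-protein configuration with
a 20-seed ensemble. These sizes give seed-ensemble standard errors of
~0.6 percentage points on the recovery estimate.
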