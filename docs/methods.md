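# Methods

This note documents the models, numerical choices, and limitations behind
each pipeline stage, and what the synthetic-data generators do and do not
emulate.

## Fingerprint alignment and similarity

Peaks from all batches are pooled, sorted by retention time, and clustered
by greedy single linkage: a new consensus column starts whenever the gap to
the previous peak exceeds the window (default 0.1 min, the convention of
fingerprint similarity evaluation software). The consensus RT is the median
of member RTs, which guarantees consecutive consensus RTs are separated by
more than the window, so re-aligning an aligned matrix is a no-op
(idempotence). A sample absent from a column gets area 0; if one sample
contributes two peaks to a column (possible under heavy jitter) their areas
are summed. Common peaks are columns with nonzero area in every batch.

The reference fingerprint *R* is the column-wise median — robust to a
single aberrant batch, unlike the mean. Similarity is the congruence
(cosine) coefficient, which is scale-invariant: two batches with the same
relative composition but different total load score 1. The software
convention behind published similarity ranges is not public, so a
mean-centered correlation variant is exposed via `method="correlation"`;
results for well-behaved positive profiles are close. Published intragroup
similarity ranges cannot be recomputed without the raw chromatograms, so
tests assert the metric's mathematical properties, not those ranges.

## PCA comprehensive scores and HCA

PCA is performed on the correlation matrix of the common-peak areas
(autoscaled columns, sample sd with n−1). The retention rule "eigenvalue
> 0.99" only makes sense on a correlation matrix, where the average
eigenvalue is 1; that motivated the matrix choice. Loading vectors are
oriented so the largest-magnitude element is positive — scores are then
reproducible across LAPACK implementations. The comprehensive score is the
weighted sum of retained PC scores with weights proportional to the
variance contributions, renormalized over the retained set (the exact
weighting behind published score tables is unstated; raw-contribution
weights are exposed as an option and differ only by a positive scale factor,
so the ranking is identical). Ties in ranking are broken by sample id.
Published per-batch score tables are not reproducible because the underlying
peak-area matrices are unpublished; the tests instead verify trace
conservation, score orthogonality, an independent weighted-sum oracle, and
origin recovery on synthetic data.

HCA defaults to Ward linkage on Euclidean distances of the autoscaled
matrix — the standard choice for compositional quality data when the
original software settings are unreported. Dendrograms export as Newick
with merge heights as branch lengths.

If every batch is identical (zero-noise limit) the correlation matrix is
undefined; the pipeline then reports the trivial ranking (all scores 0,
deterministic order) rather than failing.

## Box–Behnken design and desirability optimization

The 3-factor BBD has 12 edge midpoints (all (±1, ±1) pairs with the third
factor at 0) plus n_center ≥ 1 center replicates (default 5, i.e. 17 runs).
Factors carry a center/step coding, here (8 mL/g, 1), (45 min, 15),
(30 min, 10).

Desirability is the linear larger-is-better rescale dᵢ = (Yᵢ − Ymin)/(Ymax −
Ymin). Bounds default to the observed per-response min/max over the design,
with a supplied-bounds override (then clipped to [0,1]). Overall
desirability is the geometric mean, so any zero component zeroes the run.
Note the packaged design table's printed OD column is **not** reproducible
from its response columns under observed bounds (run 3 prints 0.988 where
recomputation gives ≈0.933 — the bounds or weights actually used upstream
are unstated), so the printed OD column is treated as the given regression
input; recomputing OD from the responses remains available via
`response_columns`.

The full quadratic (10 coefficients) is fitted by OLS in coded units —
coded-unit magnitudes are directly comparable across factors. With 17 runs
the residual has 7 df. ANOVA reports the model F, per-term F from squared
coefficient t statistics (equivalent to type III; the linear and interaction
columns of a BBD are orthogonal), and lack-of-fit vs the pure error of the
center replicates (3 and 4 df here). On noiseless synthetic data the
denominators vanish; F is capped at 1e12 and flagged with p = 0 rather than
returning inf.

Optimization is exact: a quadratic restricted to any face of the cube
[−1,1]³ is a quadratic, so the global maximum is a stationary point of one
of the 27 patterns (each coordinate free or fixed at ±1). All feasible
pattern solutions are enumerated and the best taken; tests verify the result
dominates a 101³ dense grid. On the packaged design this gives the optimum
at coded (0.081, 1, 1) → (8.081 mL/g, 60 min, 40 min), predicted OD 1.061.

## Mass arithmetic and annotation

Atomic masses (C 12 exactly, H 1.00782503, N 14.00307401, O 15.99491462,
S 31.97207117, Cl 34.96885268) are frozen in the package so outputs cannot
drift with mass-table library versions; a test cross-checks them against an
independent mass calculator. All ionic arithmetic is electron-corrected:
[M±H]∓ uses the proton mass 1.0072765 Da, the formate adduct is
+HCOOH −H⁺, and [M+Cl]⁻ adds a Cl atom plus one electron (0.0005486 Da) —
required to reproduce printed chloride-adduct values to 0.0005 Da. ppm error
is (measured − calculated)/calculated × 10⁶.

Annotation enumerates parent × modification-multiset (size ≤ max_depth,
default 3 — published metabolite tables include triple stacks) × adduct
candidates, drops chemically impossible ones (negative element counts),
keeps candidates within tol_ppm (default 10; printed errors are all below
5 ppm), and ranks by |ppm|, then fewer modifications, then parent name — a
deterministic, parsimony-biased order. A test asserts the search returns
exactly the brute-force enumeration.

Fragment ladders subtract an ordered list of neutral losses (built-in
library: glucose 162.0528, xylose 132.0423, deoxyhexose 146.0579, CH₃, CO,
CH₃OH) from the precursor ion; MS² matching is greedy nearest-ppm with each
observed peak and ladder step used once.

Known data errata in the packaged tables (documented in the tests): one
compound row's printed calculated mass is inconsistent with its printed
formula by ~5.8 mDa, and one row's printed ppm cannot be recovered from its
printed mass columns; one plasma prototype row's adduct label contradicted
its (positive-mode) mass values and was transcribed with the consistent
adduct.

## Synthetic data: what it emulates and what it does not

The fingerprint generator draws, per origin, an archetype area vector
(lognormal around 10³ area units, σ = 0.6, on an 11-peak grid spaced 2 min);
batches multiply the archetype by lognormal noise at the configured CV
(default 5%, a typical chromatographic area CV), jitter RTs by N(0,
0.01 min), and drop peaks with the configured probability. Defaults mirror
the study scale: 15 batches (3 origins × 5), 11 shared peaks. Areas stay
positive by construction (multiplicative noise), and dropout is applied
before alignment so common-peak detection is exercised. It does **not**
simulate raw chromatogram traces, co-eluting peaks, baseline drift, or
origin-correlated RT shifts — passing tests demonstrate the pipeline's
statistical behaviour on well-formed peak tables, not robustness to peak
picking errors.

The response generator evaluates a known quadratic surface (default: the
fitted extraction model, noise sd 0.02 — the scale of the center-replicate
scatter) at the design points plus Gaussian noise. The feature generator
emits ions of uniformly drawn parent × modification-stack × adduct
combinations with Gaussian ppm noise (default 2 ppm, Q-TOF-like). Its
default parents (stachydrine, apigenin, chlorogenic acid, akebia saponin B)
and rules (glucuronidation, sulfation, hydroxylation; depth ≤ 2) were chosen
once so every candidate ion is separated from its neighbours by far more
than the annotation tolerance (a test asserts > 50 ppm): recovery then
measures the annotator, not label ambiguity. Demethylation is excluded from
the generator default because −CH₂ +O maps some flavonoid parents onto each
other exactly, making the "true" label genuinely undecidable. All generators
derive their randomness from one seed and are byte-reproducible.

## Problem sizes

Tests and the acceptance script run the 17-run design fit (closed-form OLS),
mass arithmetic over the 80 packaged ion rows, a 1000-feature annotation
recovery experiment, 15-batch fingerprint sets, and a 200-replicate
Monte-Carlo check of coefficient unbiasedness — sizes matching the study's
own scale, so everything completes in seconds.

## Limitations

- Desirability supports only linear larger-is-better transforms (the study's
  form); no two-sided or target-is-best shapes, no response weighting.
- Only the four adducts observed in the tables are implemented.
- No isotope-pattern scoring, RT prediction, or spectral-library search; an
  annotation is a mass hypothesis, not an identification.
- PCA assumes more samples than effective rank of interest; with 15 samples
  and 11 peaks the correlation matrix is estimable but eigenvalues beyond
  the first few are noisy.
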