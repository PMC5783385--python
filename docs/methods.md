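# Methods

`pacavoc` reimplements, as a tested pipeline, a comparative bioacoustic
analysis of the spotted paca (*Cuniculus paca*) and its caviomorph
relatives: measuring vocal elements, validating the call-type repertoire
statistically, quantifying roar–groan call combinations, testing whether
roar frequency bands behave like vocal-tract formants, and regressing
group size on repertoire size across species with phylogenetically
independent contrasts. This note records the models, the conventions and
tunable parameters, what the synthetic data do and do not emulate, and the
design choices made where the original workflow left the procedure open.

## Acoustic measurement (`pacavoc.acoustics`)

Spectrograms are Hann-windowed short-time power spectra with the reference
settings: window 1460 samples, 90% overlap, 4096-point FFT at 48 kHz.
Conventions are fixed for testability: frame hop = floor(window·(1 −
overlap)) (with an epsilon so 1460·0.1 floors to 146, not the float
artifact 145), frequency bin centers at k·rate/fft_size, time coordinates
at frame centers.

Five parameters are measured per element (a continuous sound without
interruption) inside a time–frequency selection box: duration, dominant
frequency (bin of maximum power), minimum and maximum frequency, and the
number of harmonics under 1 kHz. In the original workflow the min/max
bounds were drawn by hand in a sound-analysis GUI; here they are the
outermost bins whose in-selection power exceeds −20 dB relative to the
selection peak. The threshold is a parameter (`floor_db`); −20 dB is a
conventional spectral-floor choice, and measurements are invariant to
uniform amplitude scaling by construction. The fundamental for harmonic
counting is the lowest spectral peak above the floor; the count includes
integer multiples below 1 kHz that exceed the floor. Emission rates are
counts divided by observation hours (note: they are *hourly* rates; some
published summaries label the same numbers "calls/s").

## Repertoire validation (`pacavoc.repertoire`)

Features are the four varying parameters (duration, dominant, minimum and
maximum frequency); the harmonic count shows no within-type variation and
is excluded (attempting to standardize it raises `ConstantFeatureError`
deliberately). Z-scores use the sample (n − 1) SD convention
(`ddof` switchable).

The discriminant model solves the generalized eigenproblem S_b v = λ S_w v
on standardized features; axes are scaled to unit pooled within-class
variance and sign-fixed so each axis' largest-magnitude coefficient is
positive. Explained variance per axis is the eigenvalue fraction; loadings
are feature–score correlations. The MANOVA reports Wilks' Λ =
det(W)/det(T) with Rao's F approximation (cross-checked against
statsmodels in the tests; the LDA eigenstructure is cross-checked against
scikit-learn).

Classification is nearest class centroid in discriminant space with equal
priors — the design is balanced (50 per type) and the reference analysis
reports centroids — with distance ties broken by class label order.
Leave-one-out cross-validation refits *both* the standardization and the
discriminant functions on each fold, honoring "all cases other than the
one being classified" strictly; the tests pin this to a literal refit
oracle bit-for-bit. Accuracy is tested against the 1/8 chance level with
a one-sided (upper-tail) exact binomial test, one-sided because the
hypothesis is directional.

The age × call-type model is a two-way fixed-effects OLS on per-individual
mean parameters with effect (sum-to-zero) coding and partial type-III-style
sums of squares, the defensible choice for the unbalanced per-individual
design (`ss_type` switchable). Terms inestimable through empty cells are
reported by name rather than silently dropped. Inter-observer agreement
uses Kendall's W from rank sums with tie correction; under independent
raters E[W] = 1/m, which the tests respect.

## Call combinations (`pacavoc.combinations`)

Each combination pattern over roar (A) and groan (B) is summarized by mean
duration, element count and rhythm (elements/s). Clustering is Ward's
criterion on Euclidean distances, implemented with the Lance–Williams
update on squared distances; merge heights are reported as the increase in
total within-cluster variance (scipy's `linkage` reports √(2·height), and
the tests check that correspondence as well as an exhaustive per-step
minimizer). Variables enter unscaled by default (standardization is a
flag). Ties are broken by lexicographically smallest member pair, making
the dendrogram invariant to input order.

The original workflow cut the dendrogram with a proprietary spreadsheet
"automatic truncation (entropy and tries)" whose formula is unpublished.
The surrogate implemented here cuts at the largest relative jump between
successive merge heights; an alternative that weights each candidate gap
by the normalized Shannon entropy of the resulting cluster sizes sits
behind `method="entropy"`. Both recover the published three-group
structure ({ABA, ABAB, ABABA} together; BA and ABABAB apart) on fixtures
with that geometry.

## Formants and the uniform tube (`pacavoc.formants`)

Formant tracking follows the standard speech pipeline: pre-emphasis above
50 Hz, resampling so Nyquist equals the maximum formant frequency
(defaults mirror the reference settings: time step 0.01 s, window 0.01 s,
6 formants, 11 kHz ceiling), then per-frame Burg autoregressive fits of
order 2 × max_formants (via `statsmodels.regression.linear_model.burg`).
Positive-frequency poles below the ceiling give candidate formants; poles
with bandwidth above 600 Hz are discarded (they model spectral tilt or
noise, not resonances; threshold configurable), and the lowest five
survivors are kept — six are estimated but five analyzed, so the highest
pole can absorb tilt.

Measured dispersion Df is the per-frame mean adjacent-formant interval,
averaged over frames; the interval SD (pooled over frames) relative to Df
quantifies the uniform-tube approximation. Frames must carry the full
five-formant complement: a frame missing one formant would contribute a
double-width interval artifact. Aggregation is per-frame intervals →
per-call mean → per-animal mean. The uniform-tube prediction is
c/(2·VTL) with c = 350 m/s; measured and predicted dispersions are
compared by a two-sided paired t-test.

End-to-end on synthetic tube signals the tracker recovers Df within ~3% of
c/(2·VTL), with a small systematic negative bias (pre-emphasis and LPC
pole interaction). Because the synthetic fixture has near-zero
between-animal variance, the paired t-test *detects* that bias —
unlike noisy field measurements, where the same test is dominated by
sampling variance. The per-animal anatomical data behind the published
t statistic are not distributed, so that exact value is validated by a
direct-formula oracle instead.

## Synthetic data (`pacavoc.synth`)

The generators emulate exactly the statistical structure the pipeline
assumes, and no more:

- **Element tables** draw each parameter from a zero-truncated Gaussian
  with the published per-type means/SDs (Table constants in
  `TABLE_SPECS`), resampling rows violating min ≤ max. Truncation at zero
  is forced by physics but shifts the mean upward when the coefficient of
  variation is large (e.g. groan maximum frequency); tests therefore
  compare sample means against the truncated-normal mean, not the raw
  spec mean. Real calls have correlated parameters and per-individual
  structure that the generator does not model beyond round-robin
  individual assignment; repertoire-level statistics on these tables
  exercise the code path, not the species.
- **Formant waveforms** are impulse trains filtered by cascaded two-pole
  resonators plus a trace of seeded noise for AR conditioning — the
  source–filter structure the formant stage assumes, with no attempt at
  perceptual realism.
- **Brownian traits** accumulate Gaussian increments with variance
  σ²·branch length along root-to-tip paths (tip covariance = σ² × shared
  path, verified empirically), with a second trait coupled linearly plus
  independent tip noise — the generative model under which independent
  contrasts are iid.
- **Combination sequences** use per-pattern mean durations
  (`FIG2_COMBINATION_DURATIONS`, a synthetic stand-in: the underlying
  recordings are not distributed). With fixed per-symbol element
  durations the three alternating patterns could never cluster apart from
  BA and ABABAB — element count grows linearly along the pattern — so the
  fixture fixes per-pattern durations chosen to reproduce the published
  dendrogram geometry: slow sparse BA (8 s), fast alternating runs
  (3–4 s), long ABABAB trains (12 s).

A single integer seed drives every generator (numpy `default_rng`);
identical seeds give bit-identical outputs.

## Comparative engine (`pacavoc.phylo`)

Branch lengths follow the Nee transformation: every node sits at height
log10(number of descendant tips) above the tips, the standard fallback
when true branch lengths are unknown; it is idempotent, total depth is
log10(n), and all edges are positive on a binary tree (non-binary trees
are rejected rather than silently resolved). Contrasts are Felsenstein's:
raw contrast x₁ − x₂, standardized by √(b₁+b₂) on adjusted branches,
nodal value the precision-weighted mean, parent branch extended by
b₁b₂/(b₁+b₂). The recursion is pinned, on 10³ random trees of up to 8
tips, to an independent GLS oracle that estimates each child subtree's
ancestral state by explicit matrix algebra.

The regression of group-size contrasts on repertoire contrasts is OLS
with intercept. Contrast signs are arbitrary (child order), and with an
intercept the fit is not sign-invariant, so the sign convention matters:
the default positivizes each predictor contrast and flips the paired
response contrast accordingly (the standard comparative-methods
convention); raw child-order signs are available by flag. Traits are
log10(mid-range group size) and log10(adult repertoire size), repertoire
counts excluding mechanical signals and juvenile-only calls.

The focal species' group size is predicted by inversion: its standardized
repertoire contrast x against its sister lineage (nodal value and
adjusted branch length from the usual recursion over the sister subtree)
feeds the regression; the predicted response contrast is un-standardized
at the same node (ŷ·√(b₁+b₂) added to the sister's nodal group-size
value) to give log10 group size, then exponentiated. The 95% interval is
a *prediction* interval (a single new species' value is predicted; the
mean-response interval is available by flag) propagated through the same
affine inversion. The focal attachment point (sister to *Dasyprocta*, the
default and the usual Cuniculidae–Dasyproctidae resolution; sister to the
cavioid clade; or at the root) and the sign convention form the
documented configuration space, and `scan_configurations` fits all of
them and ranks them against reference values if given.

### Reproducibility of the published comparative statistics

The published regression (slope 1.59, intercept 0.27, R² 0.72, F(1,4)
10.41) is **not recoverable** from the published species data on any
configuration of this engine. The implementation agrees exactly with
R's `ape::pic` on the encoded topology, yet yields slope 2.17 / R² 0.575
(positivized) or slope 1.11 / R² 0.34 (raw signs). An exhaustive scan over
all 10,395 labeled 7-tip topologies, all per-node contrast sign
assignments, and eight algorithm variants (log10/natural-log Nee depths,
Grafen and unit branch lengths, with and without Felsenstein branch
adjustment, weighted vs naive nodal means, standardized vs raw contrasts)
reproduces the published R² only on topologies incompatible with
caviomorph systematics — the expected false-positive rate of a scan that
size. The published prediction chain is also internally inconsistent: the
reported focal contrast (0.17) implies a standardization denominator of
≈0.73, while the reported inversion (0.55 → 0.94 in log10 units) implies
≈1.16. The denominator at the *Dasyprocta* cherry under log10-Nee lengths
is 0.776, giving a focal contrast of 0.161 — within rounding of 0.17 —
which suggests the published intermediate values came from a spreadsheet
computation that cannot be reconstructed from the described method. The
package therefore reports what the stated method actually yields under
the pinned default configuration, and `analysis/05_group_size_contrasts.py`
prints the full configuration table so the discrepancy is visible rather
than smoothed over.

## Problem sizes

Defaults throughout are the study's own scales: 8 call types × 50
elements, 5 combination patterns, 4 animals × 10 calls for the formant
comparison, 7 species + 1 focal tip for the comparative analysis.
Simulation-based checks use 100 replicates for slope recovery (5%
tolerance on the mean), 500 replicates for type-I error calibration
(±2 percentage points around 5%), 10³ random trees for the contrasts
oracle, and 10³ replicates for the Brownian covariance check.

## Known limitations

- Element segmentation is out of scope: selections are inputs.
- The synthetic element tables carry no cross-parameter correlation, so
  discrimination accuracies on them characterize the pipeline, not the
  species (they nonetheless land near the published overall accuracy).
- The truncation criterion for dendrograms is a reconstruction, not the
  original proprietary algorithm.
- The comparative results are faithful to the stated method but cannot
  match the published coefficients (see above); the configuration scan is
  the honest boundary of what the described procedure pins down.
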