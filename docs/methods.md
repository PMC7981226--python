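# Methods

This note documents the models, conventions, and design choices behind the
package, in the order the pipeline runs.

## Acoustic measurements

Spectrograms are magnitude-squared short-time Fourier transforms (Hann
window, FFT length 1024, 50% overlap by default — the window and FFT size
follow the standard desk workflow for this song type; the overlap is our
choice since hop size barely affects energy quantiles). Frame times refer to
frame centres, bin frequencies to bin centres, and selection boxes are closed
intervals on both axes. Power is kept linear (not dB) because the robust
box measurements are energy quantiles:

* **Δt₉₀ / Δf₉₀** — the span between the 5% and 95% cumulative-energy
  quantiles of the time/frequency marginal within the box, linearly
  interpolated between frame/bin centres. Interpolation halves the
  discretisation bias of a step-function quantile; both spans are bounded by
  the box extents by construction.
* **Peak frequency** — frequency of the global power maximum in the box.
* **Centre frequency** — the 50% energy quantile over frequency.
* **Peak-frequency contour** — per-frame argmax frequency. Frames whose
  in-box power falls below 10⁻⁶ × the maximum frame power are excluded so
  numerically silent frames cannot supply contour endpoints. First/last
  frequency are the contour endpoints; element slope is last − first,
  exactly.

All measurements are invariant to uniform gain. Exact spectral scaling
inside commercial tools is not published, so cumulative linear-energy
quantiles are the documented convention here; the measurement-oracle tests
(pure tones, constant envelopes, linear chirps) pin the implementation to
closed-form DFT expectations within one bin/hop.

## Component labelling

The song is partitioned deterministically (the field workflow classifies by
inspection, which a pipeline cannot): elements before the first
inter-element gap exceeding 0.6 s — searched only among the first three
gaps — are introductory (0.6 s is the lower end of the observed intro–body
pause of 1.28 ± 0.85 s); the last element is the final element, labelled
`buzz_final` when its Δf₉₀ exceeds 1.5 kHz with |slope| < 200 Hz (broadband
and flat — thresholds calibrated on synthetic buzzes); everything else is
body. A last element that is neither ascending nor a buzz leaves the song
flagged `final_absent`, and such songs are excluded from final-element
analyses only. On default synthetic corpora the labeller agrees with ground
truth on ≥95% of elements; the residual disagreement is almost entirely
intro–body pauses drawn below the 0.6 s threshold, which is exactly the
ambiguity a human annotator would face.

## Feature tables, transforms, exclusions

Song-level variables follow the standard seven-summary scheme (duration
including inter-element intervals; 90% song bandwidth = 95% frequency of the
highest-peaked element minus the 5% frequency of the lowest-peaked element;
highest/lowest peak; CVs of peak frequency and element duration; slope of
centre frequency against element midpoint time — midpoints because only
"against time" is conventionally specified). Intro durations are log₁₀
transformed; final-element last frequencies are reflected and compressed as
log₁₀(4000 − f), with rows at or above 4 kHz excluded and logged (the
transform's domain ends there). Log base is irrelevant after z-scaling.
Variables are z-scaled per analysis; constant columns are a hard error.
Correlated variables are pruned greedily (drop the variable with the largest
mean absolute correlation until all pairwise |r| < 0.7; ties break by name so
runs are reproducible). Multivariate outliers are flagged where the squared
Mahalanobis distance of a row's PCA scores from the centroid exceeds the
χ² quantile at 1 − α (α = 0.001), separately per analysis scope; flagged
rows are removed and the scope re-scaled and re-decomposed.

## pDFA

Songs are nested in individuals, and individuals are the exchangeable unit.
The observed statistic averages balanced train/held-out splits: per
individual, k songs train a linear discriminant classifier and the
individual's remaining songs are cross-classified. k is the corpus-wide
minimum per-individual count; when the corpus is perfectly balanced (every
individual at the minimum) k drops to ⌊min/2⌋ so a held-out set exists —
otherwise no song would ever be out of sample. The null distribution
reapplies the *identical* procedure (same number of selections) to datasets
in which whole individuals are reassigned to populations with group sizes
preserved; p = (#{null ≥ observed} + 1)/(B + 1). Using more selections for
the observed statistic than for each null value would shrink the observed
value's variance relative to the null's and break exchangeability; the
shared-selection design keeps the type-I error at its nominal level (the
calibration suite verifies the p<0.05 rate over 200 null datasets against
the exact binomial band). Resubstitution accuracy is reported alongside the
cross-classified value since either convention appears in the literature.
Permuted assignments are stored on the result for audit.

## Acoustic distances, Mantel tests, dendrograms

PCA is the eigendecomposition of the correlation matrix of the z-scaled
variables (signs fixed so each component's largest-magnitude loading is
positive). Retention is two-stage: components under 10% variance are
dropped; the smallest remaining prefix reaching 75% (song-level scopes) or
80% (element-level scopes) cumulative variance is kept. Population distances
are squared Mahalanobis distances D² between centroids under the pooled
within-population covariance (n − G degrees of freedom). D² rather than D is
reported; both are monotone transforms of each other, so permutation-based
Mantel conclusions and UPGMA topologies are unaffected.

Mantel tests correlate lower-triangle entries, permute row/column labels of
one matrix jointly, and are one-sided (greater) — the isolation-by-distance
hypothesis is directional. r is the test statistic; r² is reported alongside
because effect sizes are conventionally printed that way. With six
populations there are only 720 distinct relabellings, so p-values below
~1/720 are unattainable regardless of permutation count; Monte-Carlo draws
may also repeat the identity permutation, which is why the attainable
minimum is 1/(B+1) only for label sets large enough that repeats are
negligible. Dendrograms are average-linkage (UPGMA) trees on the D² matrix,
exported as Newick with branch lengths that reproduce the merge heights
(leaf depth = height/2).

## Geographic separation

Population centroids are arithmetic means of member coordinates.
Straight-line distances are great-circle (haversine, R = 6 371 000 m) —
geodesic needs no projection choice and differs from planar by <0.5% at the
~100 km study scale. Habitat suitability rasters (ESRI ASCII grid, values in
[0, 1]) are inverted to resistance = 1 − suitability. Least-cost paths run
on the 8-connected cell graph with edge cost = mean of the two cell
resistances × centre-to-centre distance; for geographic-CRS rasters east–west
cell sizes are corrected by cos(latitude) per row. Endpoints snap to the
nearest valid cell within 3 cells; failure is an error, never silent, as is
an unreachable pair. Under this edge-cost convention the accumulated
Dijkstra cost equals path length × mean per-cell resistance, so the two
readings of "length times resistance" coincide; both numbers are emitted.
The Dijkstra optimum is pinned to an independent branch-and-bound exhaustive
path enumeration on small random grids, and cost is verified monotone under
single-cell resistance increases.

## Synthetic corpus generator

The generator emulates the study design: six populations (default
coordinates spread over ~100 km of subtropical montane terrain), five males
each, up to 30 songs per male; three-part songs with 1–3 broadband intro
elements near 2.8 kHz (~0.1 s), an intro–body pause of 1.28 ± 0.85 s
(truncated to [0.3, 3] s so it remains a recognisable pause), 5–25 body
elements (typically ~16, keeping songs near 5 s), and one ascending final
element near 2.3 kHz, replaced by a broadband buzz with probability 0.237 in
one designated population (matching the one field population that buzzes).

**Dialect model.** A population's dialect is a vector of offsets in four
acoustic *roles* — uniform frequency shift, frequency tilt across the body,
duration scaling, and sweep-width scaling. These four were chosen because
the song-level summaries measure them as signed, approximately linear
quantities; a fifth role (alternating-element frequency spread) exists but
is excluded from the default because max/min/CV summaries fold away its
sign, which corrupts any distance metric built on the measured variables.
Body and final offsets are distance-coupled: E‖μ_i − μ_j‖² = rate² · d_ij
(rate in Hz per √km, distance in km). The coupling is realised as a
deterministic isometric embedding of the √distance metric (the scaled
eigenvectors of the Brownian-motion covariance over the distance matrix,
i.e. the expectation part of Brownian cultural drift) plus a random Brownian
residual; a `drift_stochasticity` fraction (default 0.1) sets how much of
the divergence variance is idiosyncratic. A pure random-drift model was
examined first: its chi-squared realisation scatter across only a handful of
acoustic dimensions caps the achievable distance–divergence correlation near
r ≈ 0.5–0.75 regardless of rate, which is weaker coupling than the cline-like
pattern the pipeline is designed to detect; the deterministic-plus-residual
model keeps the same expectation law while representing a smooth dialect
cline along the habitat. Intro offsets are i.i.d. across populations —
distance-independent by construction, emulating introductory elements that
imitate different model species in different populations.

**Variance components.** Within-population (between-male) offsets are drawn
per role (sd 40 Hz), body variants are discrete per-population mean offsets
shared by all males (2 variants, sd 60 Hz), and element-level jitter is
30 Hz. None of these is reported for the real system; the defaults were
calibrated once so that the synthetic corpus reproduces the field study's
*observed* effect sizes — correct classification near 78% for the body and
~85% for the full song, body Mantel r² ≈ 0.4–0.7, final-element divergence
detectable but weak, intro divergence large but geographically unstructured
— and are documented here as the package's definition of a realistic corpus.
Divergence rates are 80 Hz/√km (body), 20 Hz/√km (final), 300 Hz i.i.d.
(intro).

**What the generator does not emulate:** natural lyrebird timbre, mimicry
of model species, amplitude structure, recording-channel artefacts, or
individuals changing dialect over time. Passing the end-to-end tests
therefore demonstrates that the *statistical machinery* recovers dialect
structure of the assumed form from measured features, not that it would
segment or measure raw field recordings of arbitrary quality.

**Waveforms.** Elements render as Hann-enveloped linear chirps (broadband
elements add a detuned chirp pair), with optional pink noise at a stated SNR
measured over the song's active region. The default sample rate is 32 kHz —
all song energy sits below 4 kHz, so desk-scale rates are ample even though
field recordings are made at much higher rates. The statistical pipeline can
also run directly on ground-truth element measures (the noise-free
measurements implied by each element's parameters), which is how the
replicated end-to-end tests stay fast.

**Landscape.** Synthetic resistance rasters have a noisy high-resistance
background and low-resistance corridors (1 cell wide, resistance 0.05)
along a minimum-spanning-tree of the population layout, so least-cost routes
detour through intermediate habitat the way ridgelines do, and at least one
population pair shows an LCP much longer than its straight line.

## Problem sizes and numerical conventions

The replicated tests use the sizes that make their statistics meaningful at
desk scale: pDFA calibration uses 200 null datasets of 6 × 5 × 10 songs at
99 permutations; Mantel calibration 500 pairs at 99 permutations; the
end-to-end contrast 50 default corpora at 199 permutations; the acceptance
script one default corpus with 200 pDFA permutations and 999 Mantel
replicates. Eigenvalues below 10⁻¹⁰ of the largest are treated as rank
deficiency (warned, dropped). The Brownian covariance is clipped to its
positive eigenspace (haversine distances are not exactly of negative type).
A pooled covariance with condition number above 10¹² is reported as
singular, naming collinearity as the likely cause. All randomness flows
through seeded `numpy` generators; identical configurations reproduce
byte-identical output files, and every pipeline run writes a manifest with
its seed, per-scope exclusion counts, and a content hash.

## Known limitations

* No automatic element detection: selections come from files or ground
  truth, as in the manual-annotation workflow the pipeline mirrors.
* The pDFA supports only the nested design (individuals within populations),
  not crossed factors.
* With six populations, Mantel p-values are coarse (720 distinct
  relabellings) and single-study power is inherently limited; the replicated
  tests quantify this rather than hide it.
* Least-cost distances inherit raster resolution: endpoint snapping can
  shift short pairs by up to half a cell, and 8-connected routing overshoots
  true geodesics by up to ~8%.
* GeoTIFF rasters are not read; use single-band ESRI ASCII grids.
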