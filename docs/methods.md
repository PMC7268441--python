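# Methods

This note records the models, estimators and numerical choices behind
each pipeline stage, what the synthetic data do and do not emulate, and
the known limitations.

## Segmentation

**Maxima finding.** Nuclear markers produce compact, peaked signal, so
detection is by topographic prominence: a local maximum is reported iff
it cannot be reached from a higher maximum without descending more than
`noise_tolerance` below its own peak. The implementation floods the
image in descending intensity order with a union-find; when two
catchment components meet at saddle level *v*, the lower-peaked one is
either reported (prominence `peak − v` > tolerance) or silently merged.
The final surviving component is reported iff `peak − min(image)`
exceeds the tolerance, so a constant image yields nothing. Plateau
maxima report the centroid of the plateau pixels; ties between
equal-height maxima connected above the tolerance level keep exactly
one representative. This is checked in the tests against a brute-force
flood-fill oracle.

`noise_tolerance` is in raw intensity counts and must be set relative
to the image's amplitude scale: the historical default of 100 suits the
acquisition scale it came from, while the rendered phantoms (amplitude
10 000, noise SD 500) need a tolerance comfortably above the noise
prominence scale — the tests use 500. The CLI exposes
`--noise-tolerance`.

**Otsu threshold.** Computed on the native 16-bit histogram (65 536
bins), not a rebinned 8-bit version, so faint signal is not quantised
away; the mask is `pixels > threshold`. Constant images raise a
degenerate-histogram error.

**Objects.** Maxima inside the mask seed a watershed of the inverted
intensity restricted to the mask; regions below `min_area` (default
3 px, configurable — meant only to suppress single-pixel noise) are
dropped. Centroids are intensity-weighted for sub-pixel stability.
Ellipse axes come from the second central moments of the binary region
(4√eigenvalue, the moment-equivalent ellipse); a degenerate (e.g.
single-row) region gets its minor axis floored at 1 px and a warning
flag rather than an infinite roundness.

## Stack alignment

Sections are registered sequentially (k to k−1), matching how serial
sections are aligned in practice; drift can accumulate on long stacks
and is accepted. The rigid model is rotation about the image centre
plus translation. Rotation is found by a bounded search (±10°, 1°
coarse grid refined to 0.1° then 0.02° around the best candidate —
mounting jitter is small, and an unbounded search is unidentifiable on
near-isotropic tissue), scoring each candidate by the sub-pixel phase-
correlation residual; translation comes from the correlation peak at
the best rotation (upsampling factor 20, i.e. 0.05 px resolution). On
phantoms at SNR 20 with |shift| ≤ 10 px and |θ| ≤ 5°, recovery is
within 0.5 px / 0.2° (typically ~0.05 px / 0.1°).

Cell clouds assemble with z = section index × spacing (default 100 µm,
the slide-series spacing); the density projection bins (x, y) positions
and convolves with an isotropic Gaussian (default bandwidth 50 µm,
grid 10 µm). The grid extends three bandwidths past the data so the
map's integral equals the cell count to well under 1%.

## Spatial statistics

**Zone counting.** Best-of-`n_init` K-means (squared-Euclidean,
scikit-learn's k-means++ seeding) for each candidate K; the dispersion
curve is the mean distance of points to their centroid. The elbow is
the K maximising the second difference of the **log** dispersion curve.
The logarithm makes the criterion scale-free: with raw dispersions, a
configuration of four zones arranged as two distant pairs puts the
largest curvature at K = 2 even though four zones are cleanly
separable. With fewer than three candidate K values no curvature
exists and the smallest-dispersion K is returned.

**Distance CDFs.** The empty-space function F̂(r) is the fraction of
regularly gridded reference locations (default ~1000) whose nearest
pattern point lies within r; Ĝ(r) is the CDF of nearest-neighbour
distances. Both use the reduced-sample border correction (locations
closer than r to the boundary are excluded at that r). Two numerical
conventions: beyond the window inradius, where no location is eligible,
the uncorrected estimate is used so the curve stays defined; and the
curve is returned as its running maximum, since the raw reduced-sample
estimator can dip slightly as the eligible set shrinks while a CDF
must be nondecreasing.

**Envelope test.** The null is CSR conditioned on the observed count in
the same window. Five realizations (configurable) average into the
null-mean curve; an independent set of 39 forms the pointwise min/max
envelope (≈95% pointwise for 39), or the α/2 quantile curves for larger
sets. Because the two sets are independent, the averaged curve could in
principle poke outside the raw envelope; the envelope is widened to
contain it so `lower ≤ null_mean ≤ upper` holds by construction.
A pattern is called non-random only when the empirical curve stays
outside the envelope for ≥ 3 consecutive grid distances (single-bin
excursions are noise), and the direction is read per statistic:
clustering shifts G up but *depresses* F (clustered points leave more
empty space), so "above the upper envelope" means attraction for G and
repulsion for F. When runs occur on both sides — typical for hard-core
patterns, whose G is zero below the inhibition radius and then
overshoots — the earlier excursion in r decides, since it reflects the
short-range structure the test targets. The default r grid (26 points
out to the 99% quantile of the null nearest-distance CDF) keeps the
run rule meaningful; much finer grids inflate false calls under CSR.
With these defaults, CSR is called random in ≈94% of runs and the
Thomas-cluster / hard-core generators are classified correctly in
≈100%.

## Group statistics

Standardized proliferation is PH3⁺/DAPI⁺ × 100 (a mitotic index in
percent, robust to embryo-size differences). Stage dynamics are
percent change between consecutive stages ((next − prev)/prev × 100,
so "ninefold" is +800%).

The one-way ANOVA reports the classical F; comparisons against a named
reference (outgroup) species use Dunnett's many-to-one procedure by
default (`tukey` and `holm` are config switches — the choice matters
because many-to-one and all-pairs adjustments give slightly different
adjusted p-values for the same contrasts). Zero within-group variance
reports an infinite F with a warning instead of raising, so toy
pipelines proceed. Tukey's HSD uses the studentized-range distribution
with pooled within-group variance; rows are labelled "B−A" for sorted
labels, so the difference column is exactly the difference of group
means and is reproducible from published means alone — the CI bounds
and adjusted p-values additionally depend on replicate-level spread.
Wilcoxon rank-sum tests enumerate the exact null when both n ≤ 10
without ties and otherwise use the normal approximation with
continuity and tie correction; the default multiplicity adjustment is
Holm. Shapiro–Wilk (3 ≤ n ≤ 5000) uses the standard Royston
approximation.

## Ancestral state reconstruction

Under Brownian motion with rate σ², the trait covariance of two tips is
σ² × shared root-to-tip path length. The ML estimate of an internal
node's state is the BM-weighted tip average obtained by re-rooting the
tree at that node and running Felsenstein pruning: a tip contributes
(x, branch variance), and a node combines children as
x̂ = Σ(xᵢ/vᵢ)/Σ(1/vᵢ) with effective variance 1/Σ(1/vᵢ). Node
variance is σ² × the effective pruning variance at the node. σ² is
estimated by REML (the contrasts estimator, computed as a GLS residual
quadratic form divided by n−1; ML divides by n, selectable). With very
few tips the rate estimate is poor — on a 4-taxon tree a z-interval
built from σ̂² covers ~85%, not 95%, purely from rate-estimation error
— so `asr_ml_bm` accepts a known σ², and the calibration tests supply
the simulation truth to validate the variance structure itself.

Squared-change parsimony minimises Σ(Δ on branch)²·w over internal
states, w = 1 (unweighted) or 1/branch length (weighted); the normal
equations form a small sparse linear system solved exactly. The
weighted variant is algebraically identical to the ML states, which
the tests verify to 1e-8 on random trees against a dense GLS oracle —
two independent code paths (re-rooted pruning vs. linear system) that
must agree.

The four-taxon study topology (MN,(GS,(CP,AJ))) ships with placeholder
all-equal branch lengths because the molecular lengths behind the
published comparative analysis are not printed anywhere recoverable;
node values computed on the placeholder tree are illustrative, not
comparable to the published node estimates, and any real analysis
should supply its own Newick.

## Synthetic data: what it emulates, what it does not

The generators reproduce the acquisition geometry (10 µm sections every
100 µm, 16-bit two-channel images, default 0.65 µm/px — a typical 20×
slide-scanner value, configurable, since no acquisition pixel size is
recoverable), Gaussian-blob nuclei of scale 2.5 µm (≈ a 7 µm nucleus),
additive Gaussian noise, per-section rigid mounting jitter, sparse
mitotic subsets of dense nuclear point sets, multi-zone clustered
layouts, and BM trait evolution. Depth assignment is slab membership
only — no partial-volume rendering, justified because the 10 µm slab
exceeds the nucleus diameter. Not emulated: uneven illumination,
staining artifacts, tissue deformation (nonrigid), anisotropic PSFs,
autofluorescence, or cell-shape variation beyond isotropic blobs.
Passing tests therefore demonstrate correctness of the algorithms
under the stated image-formation model, not robustness to every
artifact of real histology.

The alignment fixtures use a *columnar* phantom (the same planar
nucleus layout repeated in every slab) so consecutive sections share
structure to register on, standing in for the anatomical continuity of
real tissue; truly independent sparse sections would be unregistrable
under any method.

## Problem sizes

Default test and acceptance runs use: 50-nucleus sections at SNR 20
(390² px at 1.3 µm/px), 4-section alignment stacks, 800–1200-point
zone phantoms over 50 seeds, 100-seed CSR calibrations, 50-seed
envelope classification per regime, 100 random trees (≤ 12 tips), 500
BM replicates, and 5000-replicate null calibrations for ANOVA and
Shapiro–Wilk. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances.

## Known limitations

- Sequential pairwise alignment accumulates drift on long stacks.
- The reduced-sample border correction discards information near the
  boundary; no Kaplan–Meier or translation correction is provided.
- The envelope test is pointwise, not a global rank envelope; its
  family-wise behaviour is controlled only through the run rule.
- Tukey CI bounds and adjusted p-values require replicate-level data;
  from published group means only the difference column is exact.
- No Ripley's K/L or pair-correlation function; no inhomogeneous
  intensity models; no OU/early-burst model comparison in the
  phylogenetic stage.
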