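# Methods

## The measurement problem

Drosophila larvae pupate on transparency film lining the vial wall. The
film, photographed over bottom illumination, shows pupae as dark capsule
silhouettes on a bright background, together with a 16.25 mm coin used as
a scale reference. The pipeline's job is to return one length per pupa in
millimetres, a confidence class per object, and a per-vial density proxy,
with no per-image human input.

## Imaging chain

**Detection.** The image is lightly denoised (Gaussian, σ = 1 px,
configurable), thresholded (Otsu on the raw intensities by default; a
fixed threshold can be supplied), and dark connected components are
labelled with 8-connectivity. No size filtering happens here: debris and
the coin are labelled alongside pupae and sorted out later.

**Calibration.** Among the detected objects, the coin is the unique large
(diameter ≥ 100 px), highly circular object. Circularity is 4πA/P² with
the Crofton perimeter estimator, which is unbiased for rasterized discs
(the chain-code perimeter overestimates by enough to sink a genuine disc
below the 0.9 cut). Candidate masks are closed and hole-filled before
judging roundness so pixel noise cannot disqualify the coin.
mm-per-px = 16.25 / measured equivalent diameter; it can also be given
explicitly.

**Untangling.** Larvae often pupate touching one another, so neighbouring
silhouettes fuse into one component. Components between ~1.6× and ~12× a
single expected capsule area are candidate clusters (anything larger is
the coin or debris, never a 2–3 pupa cluster). The splitter exploits a
physical fact about back-lit contact: two rigid bodies touch along a
line, leaving a *brighter seam* in the image even when the thresholded
mask is solid. Markers are the connected "dark cores" below a strict
threshold (midway between the object's median interior intensity and the
detection threshold); a watershed on the intensity landscape then cuts
along the seam. When no intensity image is supplied, or the cores do not
separate, the fallback is the classical distance-transform watershed
seeded at ridge maxima spaced at least 0.8 expected widths apart.
Fragments smaller than a quarter of a capsule veto the split; blobs that
cannot be split pass through and are routed to low confidence by the
shape filters. This is a deliberate functional replacement for published
worm-untangling shape-model algorithms: for capsule-shaped pupae it does
the same job with far less machinery, and heavily *overlapping* (not just
touching) silhouettes are accepted as losses, as they are in practice.

**Boundary refinement.** Each mask is eroded by a 3 px disc and regrown
by a watershed on the Sobel gradient magnitude, with the far outside
(beyond a 3 px dilation) as the competing marker — i.e. the boundary
settles on the strongest local intensity gradient. A seed that erodes
away entirely, a featureless neighbourhood, or a regrown mask drifting
outside 0.5–2× the original area falls back to the original mask.

**Length.** The length of a (possibly curved) pupa is measured along the
body: the mask is skeletonized, the longest geodesic path through the
skeleton graph is extracted (two Dijkstra sweeps), the pixel path is
smoothed (Gaussian along the path, σ = 3 samples) to remove staircase
zigzag, and its polyline arc length is extended at both ends to the mask
boundary along the terminal directions. The extension locates the 0.5
crossing of the bilinearly interpolated mask, giving a sub-pixel edge.
On noise-free rendered capsules this measures 100 px capsules with mean
error −0.1 px and SD 0.34 px across orientations. Width is twice the
mean distance-transform value along the skeleton; masks too thin to
skeletonize (max EDT < 1.5 px) fall back to the ellipse major axis and
are flagged. The ellipse axis is always recorded as a secondary column.

**Confidence classes.** *Low*: fails the size filters (defaults: length
1.5–5.0 mm, length/width 2.0–5.0, area bounds derived from these; the
originals' exact filter set is not public, so these are documented
stand-ins). Otherwise *high* if no other object lies within 20 px,
*medium* if one does. The neighbour distance is the minimum
boundary-to-boundary gap: for side-by-side pupae a centroid-based rule
would call a 10 px gap "high" purely because bodies are wide, which
contradicts the intent of the 20 px rule; the metric is configurable.

## Vial statistics

A vial summary averages high- and medium-confidence, non-excluded pupae;
the count of those pupae is the density proxy D. Vials with fewer than
15 measured pupae fail QC — the subsampling analysis below is the
justification. Manual curation is emulated by seeded Bernoulli exclusion
at 0.02 (high) and 0.10 (medium); excluded rows are flagged, never
deleted. Precision is assessed exactly as one would with physical films:
re-measure after rotating 180°, map pass-2 centroids through
(H−1−r, W−1−c), match isolated pupae (gap > 15 px) to the nearest
candidate within 10 px (ambiguous matches dropped and counted), and
report mean |Δ|, its SD, and the pass-2-on-pass-1 slope and R².

## Density covariate

Crowded vials produce shorter pupae. Per stock, mean vial length is
regressed on D (OLS); across stocks the slopes concentrate near
−0.002 mm/pupa, and the mode is extracted from a fixed-width histogram
(0.0005 bins, ties broken toward the median). The correction
`corrected = (D − M)·S + Q` moves a measurement to the experiment-wide
mean density M (default 65). Two deliberate conventions: (1) corrected
values are written to a separate column — the reference analyses never
applied the correction to their results, and neither do we by default;
(2) the formula is kept exactly as printed even though, evaluated with
the quoted negative S, it amplifies rather than removes a fitted negative
trend — the S that cancels a fitted slope s is −s, and the trend-removal
property is stated and tested that way.

## Heritability

**Narrow sense.** h² is the OLS slope of offspring value on the
midparent (parental average). The offspring of a cross can enter as
their vial mean (one point per cross) or individually (midparent
repeated); under additivity both estimate the same slope, and the
package verifies they agree on simulated cohorts. Regressions on a
single parent estimate h²/2; mother–father asymmetry flags parental
effects. Because parents are measured with error, the slope converges to
σ²_A / (σ²_A + σ²_E + σ²_m), not σ²_A / (σ²_A + σ²_E): with σ_m =
0.038 mm against a phenotypic SD of 0.21 mm the attenuation is ≈ 3%
(0.44 → 0.426). Recovery tests target the attenuated value, which is
what the estimator is actually consistent for.

**Broad sense.** H² comes from the one-way random-effects model
y_ij = μ + α_j + e_ij on replicate vial means of (effectively homozygous)
inbred lines, estimated by the ANOVA method of moments for unbalanced
data: n₀ = (N − Σn_i²/N)/(k−1), σ²_between = max(0, (MS_b − MS_w)/n₀),
H² = σ²_between/(σ²_between + σ²_within), F = MS_b/MS_w with its F-test
p-value. Lines need ≥ 3 replicates. A negative moment estimate is
truncated at zero and flagged. MINQUE was not implemented: for these
designs the two estimators agree to two decimals, and the ANOVA estimator
is transparent and testable by hand (the unit tests freeze a hand-worked
3×4 table).

**Additive link.** For inbred parents mated at random, a purely additive
trait implies H² = 2h²/(1+h²); observed H² close to that expectation
bounds the role of dominance and epistasis. The function is exact and
rounding is left to presentation.

## Subsampling variance

Both design questions — pupae per vial, vials per RIL — use the same
machinery: draw subsamples *without replacement* (so the deviation at
full size is exactly zero by construction), 100 draws per size, deviation
= subsample mean − full mean, pooled across (unit, draw) pairs, with the
2.5/97.5 percentiles (linear interpolation) as the band. Deviations are
unbiased and their SD follows the finite-population law
σ·√(1/n_s − 1/N), which the tests check to 10%. At within-vial SD
0.13 mm and vials of 55, size-15 subsamples keep 95% of deviations within
±0.07 mm — the basis of the ≥15 QC rule; six replicate vials keep 95% of
RIL-mean estimates within ±0.1 mm at a between-vial SD of 0.07 mm.

## Genome scan

RIL mean phenotypes (unweighted means of replicate vial means) are
regressed position-by-position on founder-indicator dummies (k−1 columns
for the k founders present). For a categorical design RSS_full is the
pooled within-founder sum of squares, so the scan reduces to group-sum
arithmetic — and the permutation null (shuffle phenotypes, take the
genome-wide max LOD, threshold at the 1−α quantile) vectorizes into
matrix products over permutation batches. LOD = (n/2)·log₁₀(RSS₀/RSS₁),
floored at RSS₁ ≥ 10⁻¹²·RSS₀ with capped positions flagged; positions
with a single founder get LOD 0 and a flag; a constant phenotype yields a
degenerate (flagged) threshold of 0. Founder genotypes are taken as
known — the RIL resources this emulates ship precomputed genotypes, and
probabilistic founder inference is out of scope. The implementation is
checked against an explicit least-squares oracle on a toy panel, and for
affine invariance of the phenotype.

## The synthetic generators, and what passing tests do not show

**Cohorts.** The default architecture is 100 biallelic loci of equal
|effect| at frequency 0.5, rescaled so Σ2p(1−p)a² equals σ²_A exactly
(n_loci = 0 selects the Gaussian infinitesimal model). Defaults: mean
length 3.4 mm, individual phenotypic SD 0.21 mm, within-vial SD 0.14 mm,
measurement σ_m = 0.038 mm (back-computed from a mean absolute duplicate
difference of 0.043 mm via E|N(0, 2σ²_m)| = (2/√π)σ_m), densities
Poisson with mean ~60, density slope 0 unless set. Trio offspring inherit
one gamete per parent, so Mendelian sampling variance σ²_A/2 arises
mechanically. RIL panels use Markov-switching founder blocks
(switch probability 0.02 per 10 kb bin by default) and line values built
from founder effects; realized components are standardized so planted
causal fractions and σ²_G are exact, and the default σ²_G = 0.0135,
σ²_vial = 0.009 give a true vial-mean H² of 0.6. One caveat discovered
and documented here: with long founder blocks a *polygenic* trait is
genuinely mappable (each position's founder partition captures its whole
block's variance share), so "polygenic ⇒ flat scan" only holds when
blocks are short relative to the genome — the null-scan checks therefore
use genotype-independent phenotypes.

**Films.** Pupae are anti-aliased capsules (length ~N(3.4, 0.21) mm,
width/length 0.29) at 0.035 mm/px on a 1400×1800 canvas with one coin
disc, Gaussian PSF (σ = 1 px, with ±0.35 px per-exposure focus jitter)
and additive pixel noise (SD 15 on the 0–255 scale). Touching clusters
of 2–3 lie near-parallel with a 1.2–2.8 px gap: the PSF fuses them into
one thresholded component while the gray seam line survives for the
untangler. Perfectly tangent parallel capsules would leave a sub-pixel
seam invisible at raster scale — that regime is exactly what shape-model
untangling exists for and is accepted as loss here. The noise default was
set by a pilot run against the measurement pipeline as the highest level
at which detection stays robust; notably, end-to-end duplicate precision
on these films plateaus near 0.015–0.02 mm regardless of pixel noise,
because smooth ideal capsules re-measure more repeatably than real pupae
with textured, irregular outlines. Passing the ≤0.05 mm precision bound
on synthetic films therefore bounds, and does not certify, precision on
real films; the same holds for capture rate, since the renderer's
clusters are cleaner than real pupation tangles.

## Problem sizes and numerical choices

Monte-Carlo recovery checks use 200 cohorts at the study scales (363 and
67 crosses; 81 RILs × 5 replicates); imaging checks use 20 films of 60
pupae plus 8 films spanning densities 15–120; null-scan calibration uses
195 RILs × 500 positions with 100 permutations per seed across 20 seeds
(1000 permutations in the analysis scripts). Coordinates are 0-based
(row, col); lengths are reported in mm (3 decimals at presentation);
percentiles use linear interpolation; all simulators take explicit seeds
and every derived generator is seeded deterministically from them.

## Known limitations

- Heavily overlapping pupae are not recovered (routed to low confidence);
  the capture-rate figures bound, not match, real-film performance.
- The size filters are stand-ins for the original (unpublished) filter
  set; they are configurable.
- The scan fits founder indicators, not founder probabilities; with known
  homozygous genotypes the two coincide, but the implementation is an
  approximation to probabilistic-genotype scans.
- Sexual dimorphism (~8% size difference) is not modelled or corrected;
  heritability estimates are for unsexed pupae.
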