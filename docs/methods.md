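# Methods

`rodentfc` implements the computational chain of a longitudinal two-strain
rodent imaging study — an epileptic strain versus its non-epileptic control,
imaged monthly from 3 to 8 months — covering resting-state functional
connectivity, graph-theoretic network analysis, permutation-based network
inference, voxelwise manganese-enhanced MRI (MEMRI) statistics, and
atlas-based volumetry.  Because no public scans accompany the design, the
package ships a synthetic cohort generator with planted ground truth; every
claim the test suite makes is a recovery or calibration statement about that
ground truth.

## Preprocessing

Motion traces (three translations in mm, three rotations in degrees, one row
per volume) drive epoch selection: the earliest continuous window (default
900 volumes = 15 min at TR 1 s) whose per-axis range stays below 0.2 mm and
0.3°.  Thresholds are applied per axis; a combined-displacement criterion
would be an alternative reading, but per-axis is the simplest reproducible
rule and is what we document.  When no window qualifies the first window is
used with a logged warning.

Spatial smoothing is strictly in-plane: a truncated 3×3-pixel Gaussian with
FWHM 0.6 mm (σ = FWHM/(2√(2 ln 2)) converted to pixels), unit-sum
normalised.  Outside the image the kernel is renormalised over its in-image
support (normalised convolution), so constant images are exact fixed points
including at borders.  Temporal filtering is a brick-wall Fourier low-pass
at 0.1 Hz: per-voxel FFT, coefficients strictly above the cutoff zeroed, DC
preserved; the operation is idempotent by construction.  Global-signal
regression fits each voxel on [intercept, in-mask mean time course] by OLS
and keeps the residuals; when the global regressor is numerically degenerate
(e.g. the data were already regressed) the fit falls back to intercept-only,
which keeps the operation idempotent instead of amplifying rounding noise.

Temporal SNR (mean/SD per voxel, n−1 denominator, averaged over an ROI) is
computed on the raw epoch before filtering — a low-passed series would
report inflated tSNR and defeat the QC purpose.

## Connectivity: the multi-seed-region approach

Each atlas region contributes a seed: the centre-of-mass voxel plus its
in-label 6-neighbours (for concave regions the centroid snaps to the nearest
in-label voxel, ties broken by lowest linear index).  A single voxel would
be noise-dominated and the whole region would blur the seed; a 7-voxel patch
is the smallest stable compromise.  The seed-patch mean course is Pearson-
correlated with every in-brain voxel; p-values come from
t = r√((n−2)/(1−r²)).  Each seed map is thresholded with the
Benjamini–Yekutieli step-up at q = 0.05 — BY rather than BH because voxel
maps are strongly dependent and BY is valid under arbitrary dependence.  The
matrix entry (i, j) is the mean r over region-j voxels surviving seed i's
mask (0 if none survive — keeping entries total-ordered for density
thresholding), giving an asymmetric n×n matrix per scan.  Entries are Fisher
z-transformed with negatives zeroed (|r| = 1 clips at atanh(0.999999) with a
warning); z-matrices are averaged per subject across sessions 3–5
(juvenile) and 6–8 (adult) — transform first, then average, since all group
statistics operate on z values.

## Graph metrics

Matrices are symmetrised by the element-wise mean of (i, j) and (j, i)
(preserves total weight) and thresholded to density k: the m = round(nk/2)
largest-weight edges, ties broken by (weight desc, row, col) so edge sets
are deterministic and nested across k.  k = 6 is the working density (240
edges on 80 nodes ≈ 8% of 3160 pairs; 342 on 114 nodes).

Global metrics use the binarised graph: average local clustering C and
characteristic path length L (mean shortest-path length over connected node
pairs only; the component count is reported separately).  Both are
normalised by their means over uniform G(n, m) random graphs with identical
node and edge counts — γ = C/⟨C_rand⟩, λ = L/⟨L_rand⟩, σ = γ/λ.  Degree-
preserving rewiring would be an alternative null; the equal-nodes-equal-
edges ensemble is the documented choice.  The ensemble size defaults to
1,000; tests and the acceptance script use 100 per graph, which bounds the
ensemble-mean error well below the ±0.1 tolerance they assert.

Local metrics: degree, strength (sum of retained z-weights — the only
weighted metric, mirroring the degree/strength split), per-node clustering,
per-node mean shortest-path distance (missing for isolates), and normalised
betweenness.  The hub score is a composite we define explicitly, since
"hub" criteria vary: the mean of the node's percentile ranks for degree,
betweenness and inverse path length, with nodes above the 90th percentile
flagged.  The laterality index for a bilateral metric pair is
LI = (L−R)/(L+R) (0 when both are 0), |LI| > 0.3 flagged as lateralised.

## Community detection and the network-based statistic

Communities come from Louvain modularity optimisation (networkx
implementation) on the retained z-weights with a seeded node order.

NBS tests epileptic vs control on subject-level z-matrices.  The edge
universe is the union of the two group-mean graphs thresholded at k; per
edge a homoscedastic two-sample t is computed; edges with two-sided
p < α_primary (default 0.05 — the key sensitivity knob, always logged) are
split by sign, and connected components are formed per sign, so "stronger"
and "weaker" subnetworks are reported separately.  FWE-corrected component
p-values come from full subject-label permutations with the +1 correction:
p = (1 + #{perm max ≥ observed})/(n_perm + 1).

Two design points matter for validity:

1. **The edge universe is re-selected inside every permutation.**  Selecting
   the top-density edges from the observed group means and freezing that
   universe across permutations looks innocuous but is badly anticonservative
   — the selection itself is label-dependent (we measured null FWE near 50%
   on 80-node networks with a frozen universe).  Re-running the selection
   under each relabeling restores exchangeability.
2. **The component statistic is edge count with a continuous tie-break.**
   Supra-threshold components in sparse graphs have sizes 1–5, so a pure
   integer statistic produces heavily tied permutation nulls and a
   conservative test (measured level ≈ 0.03 at nominal 0.05).  We add a
   bounded increment m/(1+m) of the component's summed |t| mass m: edge
   count remains the primary ordering, ties break continuously, and the
   measured level is 0.043 over 300 independent null cohorts.

## MEMRI voxel statistics

Registered T1w volumes are median-smoothed (7×7×7, edge-replicated), then a
pooled-variance two-sample t-map is computed (df = n_a + n_b − 2; zero-
variance voxels get t = 0).  Threshold-free cluster enhancement integrates
cluster extent and height: TFCE(v) = Σ_h e(h,v)^E · h^H · dh over thresholds
h = dh, 2dh, … max, with the standard E = 0.5, H = 2, dh = max|t|/100 and
26-connectivity (all configurable); negative values are enhanced on the
negated map and returned negative.  On a uniform cuboid of c voxels at
height h₀ this converges to c^0.5·h₀³/3, which the tests check to 2%.

Multiple-comparison correction permutes group labels (default 100 distinct
relabelings, observed labeling excluded), recomputes the full pipeline per
permutation, pools all in-mask permutation values, and thresholds the
observed map at the pooled 99.9th percentile.  Whether the percentile is
taken on the enhanced map or on raw t values is genuinely ambiguous in this
family of protocols; both run behind the `pipeline` flag ("tfce" default,
"t" reproduces a percentile-on-t reading).  Significant-voxel masks are
cluster-filtered (components larger than 500 voxels by default).

Region-wise intensity tests are unpaired homoscedastic t-tests on per-
subject region means, FDR-corrected across regions with BH (BY is reserved
for voxel maps, where dependence is the concern).

## Volumetry

Region volumes are voxel counts × voxel volume from integer label images;
tissue-class totals sum member regions.  Group comparisons are per-region
unpaired (or paired, for pre/post designs) t-tests, plus a whole-label
total.  Nonlinear registration is out of scope: the generator produces
per-subject label images directly.

## The synthetic cohort

The generator's defaults mirror the study design: 12 subjects per strain,
sessions at months 3–8, an 80-region mirror-symmetric bilateral atlas of
cuboid parcels (≥ 27 voxels each; a 114-region variant serves the MEMRI
analyses), TR 1 s, 900-volume series.

Region signals are band-limited Gaussian noise (0.01–0.08 Hz, inside the
0.1 Hz resting-state band) mixed by the Cholesky factor of a target
correlation matrix, giving exact control of region-level covariance.  The
target encodes three planted communities (within-block r = 0.6, between
0.1), homotopic left-right coupling (r = 0.5), and — epileptic group only —
an additive increment on a focal cortical edge block.  Slightly indefinite
user specs are projected to the nearest PSD correlation matrix with a
warning.  Voxels add independent Gaussian noise and a 100-unit baseline (so
tSNR is realistic, ~70 at unit noise).  Motion traces are Gaussian jitter
(0.01 mm / 0.01°) with optional step jumps; MEMRI volumes are base + region
offset + noise; subject label volumes dilate selected parcels by one voxel
layer in the epileptic group and toggle a binomial number of boundary
voxels per region so volumes vary across subjects (without that jitter
within-group variance is zero and group t-tests are undefined).

One consequence of band-limiting worth knowing: a 900-volume series carries
only ~2·BW·T ≈ 126 effective samples, so empirical null correlations have a
noise floor near |r| ≈ 0.07, not the 1/√900 ≈ 0.03 an iid calculation
suggests.  Test tolerances are set from Monte-Carlo measurements of this
floor.

What the generator does **not** emulate: hemodynamic response shapes,
spike-wave discharge waveforms, scanner drift/physiological noise
structure, registration error, and partial-volume effects.  Passing tests
therefore demonstrate the correctness and calibration of the analysis chain
on data with known covariance structure — not robustness to every artifact
of real scans.

A matrix-level generator (`simulate_subject_matrices`) draws subject
z-matrices directly around a group ground truth (between-subject SD 0.15,
the order of session-averaged Fisher-z sampling noise plus biological
variability).  NBS calibration and power studies use it so that hundreds of
cohorts are simulated in seconds; the full-volume path is exercised by the
pipeline tests at reduced grid sizes (20–30 regions, 150–600 volumes), a
scaling chosen to keep the suite fast while leaving every code path
identical to full scale.

## Known limitations

- The FDR annotation "n = 6 time points" sometimes attached to q = 0.05 in
  this protocol family is treated as session-count metadata, not an FDR
  parameter.
- Hub score and NBS primary threshold are documented interpretations, not
  recoveries of any proprietary implementation; both are configurable.
- Path length on disconnected graphs averages over connected pairs, which
  flatters fragmented networks; read it together with the component count.
- The BY step-up divides by c(m) ≈ ln m + γ, so even q → 1 does not reject
  everything; monotonicity in q is the invariant that holds unconditionally.
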