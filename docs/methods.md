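# Methods

This note documents the models, numerical choices and limitations of
the pipeline, stage by stage.

## Tensor phantoms

White-matter voxels carry an axially symmetric tensor with eigenvalues
(λ1, λ2, λ2), principal axis along the local geometry tangent. λ2 is
solved in closed form from the requested fractional anisotropy: for an
axially symmetric tensor FA = (λ1−λ2)/sqrt(λ1²+2λ2²), which yields the
quadratic (1−2FA²)λ2² − 2λ1λ2 + (1−FA²)λ1² = 0 whose root in (0, λ1]
is taken (the FA = 1/√2 case degenerates to a linear equation and is
handled separately). The phantom FA is therefore exact to machine
precision, and the tractography oracle — the bundle geometry — is
analytic. Three geometries are provided: a straight slab (length
fidelity, retention window), a quarter arc of radius R (curved-length
fidelity vs πR/2), and an orthogonal crossing interface (the angular
stop). Grey-matter caps sit at the bundle endpoints; background
voxels are isotropic. Construction uses no randomness.

The phantoms stand in for acquired diffusion MRI: no diffusion-weighted
signal, gradient scheme or noise model is simulated — the tensor field
itself is the input, as the tracking stage consumes tensors only.

## Tractography

FACT-style deterministic propagation: nearest-neighbour orientation
lookup in the voxel grid, fixed step of half the smallest voxel
dimension (so the angular check is evaluated at sub-voxel resolution),
eigenvector sign chosen for continuity with the previous direction
(the first step grows in both signs — bidirectional growth). A voxel
whose two largest eigenvalues differ by < 1e-9, or whose tensor is
zero, has no defined orientation and terminates propagation. Seeds:
4 per white voxel at fixed sub-voxel offsets (±¼, ±¼, 0), which makes
whole-volume tractography reproducible without an RNG. Retention
requires both ends in grey matter and arc length in [3, 1000] mm;
these bounds and the 60° maximum bend are the tracking defaults.

On the straight slab, retained length deviates from the slab thickness
by at most two steps (the two terminal steps into grey); on the
40³-voxel quarter arc (R = 20 mm, 3 mm tube) the mean tracked length
is within 2% of the analytic πR/2 — the residual is the outward bias
of tube seeds away from the central arc line plus the terminal steps.

The original pipeline's step size, interpolation and sub-voxel seed
placement are not published; the choices above are this package's own
and are validated against the analytic phantoms, not claimed to match
any particular implementation.

## Parcellation

70 nodes: 33 gyral cortical regions per hemisphere (the standard
surface-atlas gyri minus the insula) plus hippocampus and amygdala
bilaterally. Node order groups regions by hemisphere and lobe, so
near-diagonal matrix cells correspond to anatomically adjacent regions
and hence short fibers. The limbic unit comprises the four cingulate
parts, entorhinal, parahippocampal, hippocampus and amygdala. The
frontal pole, temporal pole and banks of the superior temporal sulcus
are flagged `excluded`: they remain matrix nodes (so totals and lobar
sums are unchanged) but are dropped from the regional post-hoc tests,
where their unreliable delineation would matter.

## Connection matrices

Endpoint assignment is the label of the voxel containing the terminal
point — no dilation, since retention already guarantees grey-matter
termination. Fibers with background or out-of-volume endpoints are
excluded from all matrices and counted (`n_unassigned`); assigned +
unassigned always equals retained (asserted every build). Count,
density Σ1/l(f) and bundle-mean FA are accumulated together. The
statistics below run on the count matrix ("number of fibers"); the
density matrix is always produced and exported as the connectome
deliverable. Self-connections live on the diagonal, count toward
subject totals, and are never tested regionally.

Per-fiber mean FA averages the FA of the distinct voxels the polyline
visits (each voxel once); with a step of half a voxel no traversed
voxel is skipped.

## Edge filter

Three steps on control subjects only: (1) normalize each subject's
mean-FA matrix by its own maximum edge (values in (0,1]; division by
the subject mean is available as a config alternative); (2) average
normalized matrices per edge over the subjects in which the edge is
present (zero-filling absences is a config flag; skipping them is the
default); (3) walk the percentiles q = 1, 2, 3, … of the present-edge
distribution, inspecting edges in ascending order, and stop at the
first inspected edge farther than `diagonal_band` (default 1) from the
matrix diagonal — i.e. the first value that is not a short-fiber cell.
All edges strictly below the stopping edge's value are excluded.

"Stepping by integer percentiles" and "scanning edges one by one" can
disagree when several edges fall between consecutive percentile
values; the implementation inspects, at step q, every not-yet-seen
edge with value ≤ the q-th percentile value, which makes the two
formulations exactly equivalent — this equivalence against an
independent sorted-scan oracle is tested on random bimodal instances.
The recorded `stop_quantile` is the stopping edge's
interpolation-consistent percentile rank, so
`np.percentile(values, stop_quantile) == threshold` exactly. With
fewer than 100 present edges the percentile values come from order
statistics with linear interpolation, so small matrices exercise the
identical procedure. The numeric threshold is a property of the cohort
at hand — on the simulated cohort the scan stops around the 5–6th
percentile at a normalized FA near the gap between the two FA modes —
and no attempt is made to reproduce any particular published value.

Excluded cells become missing for the per-connection statistics;
subject totals for the global comparison stay unmasked.

## Simulated cohorts

The generator produces what the imaging stages would deliver: one
symmetric 70×70 count/density/FA matrix per subject plus a subject
table. Conditions are fixed at the study scale: n = 30 per group,
ages ~7–25 (mean ≈ 14.8, sd ≈ 3.9), ~45% female, control total fiber
count calibrated to mean ≈ 47 400, and a patient/control global ratio
of 0.90.

Per-edge counts: baseline rates λ_e are lognormal (σ = 1) scaled to
the control total; each subject draws a unit-mean lognormal scale
(sd 0.115, reproducing the ≈12% between-subject spread of totals,
i.e. sd ≈ 5 000–5 700 at the study scale) and unit-mean lognormal
per-edge noise (sd 0.25); counts are negative binomial (θ = 50)
around the resulting means — Poisson is available but understates the
observed spread. No published description of the per-edge count
distribution exists; this family is the package's own choice.
Patients' rates are multiplied by the global ratio and by any
configured lobe-pair effects. The demo configuration plants the nine
reported lobar effects (each reported absolute percentage divided by
the 90% global), and by default rescales non-planted edges so the
expected total ratio stays exactly 0.90 — in real data the global
ratio already contains the lobar deviations, so they must net out.

Per-edge FA is bimodal: near-diagonal edges (|i−j| ≤ 1, the
short-fiber band) draw from a low mode (0.22 ± 0.05), all others from
a high mode (0.60 ± 0.10), giving the edge filter the distribution
shape it was designed for. Age and sex are drawn independently of
group; white-matter volume and mean FA carry mild positive age trends
(population correlations ≈ 0.42 and ≈ 0.32/0.22 for controls/patients)
while fiber totals are age-independent, exercising the age-regression
analysis with the qualitative pattern the covariate adjustment is
meant to handle.

What the generator does **not** emulate: spatial structure within
parcels, distance-dependent edge probability, FA–count correlation,
scanner or motion artefacts, and any direct coupling between the FA
matrices and the count matrices. Passing statistics tests therefore
demonstrates calibration and recovery properties of the *analysis*,
not robustness to real-data artefacts.

## Statistics

Design matrices code group 0 (control) / 1 (patient) and sex 0/1;
with a single 0/1 group term the type-III F equals the partial
(extra-sum-of-squares) F, which is how it is computed. A degenerate
guard returns F = 0 when the group term's extra sum of squares is
numerically zero relative to the null model (zero-noise responses make
the ratio 0/0 otherwise). ANCOVA fits use ordinary least squares
(statsmodels); the Wilks MANCOVA is implemented directly:
Λ = det(E)/det(H+E) with H the SSCP reduction when the group column
enters, p-value via Rao's F approximation (exact for a 1-df
hypothesis). Both are cross-checked in the test suite against an
independent normal-equations/projection oracle (1e-8) and against
statsmodels' MANOVA.

The three lobar families are tested jointly (15, 15 and 25 responses;
the inter-hemispheric family is defined as all 5×5 L-lobe × R-lobe
combinations — only its significant members would ever be reported in
a study table, so the family definition is a package choice). With
n = 60 and 5 design columns the 25-response family leaves 30 error
degrees of freedom; the implementation refuses configurations where
the error SSCP would be singular. Multiple-testing flags
(Benjamini–Hochberg FDR and Bonferroni, α = 0.05) are computed within
each family, and across all parcels in the regional post-hoc.

Difference percentages use least-squares means at the covariate grand
means, adjusted for age and sex only: additionally conditioning on
total fibers would re-centre every ratio near 100% and erase the
global reduction that the relative percentage is defined against
(raw means are available via config). The identity
relative = absolute − global holds exactly by construction and is
validated against all 22 reported connection rows.

Age regressions report two-sided Pearson p-values by default; a
one-sided flag exists because published one-tailed conventions vary.

## Problem sizes and calibration checks

The suite calibrates the covaried ANCOVA's type-I error over 2000 null
cohorts (exchangeable groups) and requires the rejection rate at
α = 0.05 to lie in [0.03, 0.07]; null cohorts for this sweep use a
10-region matrix, since the calibration of the F test on subject
totals does not depend on matrix size. Recovery of the planted 0.90
global ratio is averaged over 200 cohorts of n = 30/30 and required
within ±0.02. The MANCOVA's null p-values are checked uniform by a
Kolmogorov–Smirnov test over 2000 replicates at 3 responses.

## Determinism

Phantoms and tracking use no randomness; cohort simulation is fully
determined by the config seed. Two pipeline runs with the same seed
produce byte-identical numeric artefacts; wall-clock stage timings go
to a separate `pipeline.log`, which is the only file excluded from
that contract. Every artefact embeds the seed and a hash of the
scientific configuration (output paths excluded from the hash).

## Known limitations

- Nearest-neighbour orientation with half-voxel steps quantizes
  curvature; tracked lengths on curved bundles carry a small positive
  bias (≈2% on the quarter arc).
- The generator's independence assumptions (FA ⟂ counts, edges
  independent given the subject scale) make the MANCOVA's planted
  effects easier to detect than in real data; reported F statistics on
  planted cohorts are correspondingly large.
- Endpoint assignment is voxel-based; surface/mesh-based assignment is
  out of scope.
- Graph-theoretic network measures, IQ/symptom covariates and
  longitudinal modelling are out of scope.
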