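# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish. Units are a consistent mm–N–MPa
system throughout.

## Synthetic mandible generator

Real comparative studies start from segmented µCT scans; this package's
testable stand-in is a parametric generator that reproduces the features
that matter mechanically downstream: a hollow cuticle shell of
controllable thickness, a curved tapering blade, a masticatory margin with
optional teeth and an apical tooth, two articulation patches at the base,
and an apodeme-insertion patch.

The outer shape is an approximate signed-distance function: an elliptical
cross-section swept along a quadratically curving centerline, with width
and height tapering toward the tip and tooth bumps unioned along the inner
margin. Four morphotype presets span the disparity seen across ant
workers — shovel (the common Bauplan: narrow base, triangular blade),
falcate (sickle-like, strongly curved), trap-jaw (elongate and straight;
blade length at least 4× blade width is enforced), and robust major
(short, broad, thick-walled). Preset dimensions are at realistic ant-worker
scale (blades 0.9–1.6 mm, cuticle 45–100 µm).

The shell is the set of points within the cuticle thickness of the outer
surface; at thin teeth and tips the local thickness is clamped to half the
local cross-section so those stay solid. The shell is voxelized and each
cube is split into six tetrahedra (Kuhn subdivision), which makes the mesh
conforming, positively oriented and watertight *by construction* — voxel
shells may contain pinched (non-manifold but closed) edges, and the
watertightness check accepts those. Stray voxels disconnected from the
main shell are dropped. Everything downstream of the seed is vectorized
and deterministic, so identical parameters give bit-identical meshes.

Anatomical node sets are tagged geometrically from the parametric frame:
the margin is the outer surface strip on the inner (concave) side of the
distal two-thirds of the blade, the apical tooth is the distal margin
segment (anchored at the actual distal end of the voxelized surface, since
strong taper can truncate the shell slightly short of the nominal length),
and articulations and apodeme insertion are small surface patches near the
base (patch radius is a free parameter; nothing downstream is sensitive to
it beyond needing enough nodes to suppress rigid-body modes, and at least
six nodes are always taken). Articulation tags take precedence where
patches would overlap the margin or apodeme sets, keeping fixed and loaded
sets disjoint.

Default voxel size targets a few thousand tetrahedra per mandible (the
packaged study stays under ~5k per specimen). That is deliberately desk
scale — two orders of magnitude below segmented-scan meshes — chosen so the
whole study and its double-run determinism check complete in minutes; the
volume-fraction statistics the Intervals Method consumes are insensitive
to this because they are ratios over the same mesh.

What the generator does **not** emulate: real cuticle-thickness gradients,
surface sculpturing and hairs, genuine tooth shapes, the condyle geometry
of the articulations, and smooth surfaces (the shell is blocky at the
voxel scale, so absolute stress values carry discretization roughness).
Passing tests on these models therefore validate the *pipeline* —
solver correctness, conservation and invariance properties, determinism,
and directional contrasts between load cases — not species-level
geometric conclusions, which require the real scan-derived meshes.

## Finite element solver

Static small-strain linear elasticity with homogeneous isotropic material
(defaults E = 2750 MPa, ν = 0.3, published values for ant mandible
cuticle) on 4-node constant-strain tetrahedra. The global system is
assembled sparse and solved by direct LU factorization (SuperLU); a
relative residual above 1e-6 on the free equations is treated as a
constraint error (near-singular system). Loads on a region are distributed
over its nodes in proportion to tributary areas (one third of each
boundary triangle fully contained in the region) — the consistent load
vector for a uniform traction — with an equal split as fallback for sets
spanning no complete triangle. Reactions are reported at constrained nodes
so global equilibrium is checkable; solves in the packaged study balance
to ~1e-12 relative.

Element choice and solver settings of external FE packages are not
replicated; the solver is validated against closed forms instead: exact
uniform stress on a roller-constrained uniaxial patch, interior stress
within 1% of F/A under full end fixation, tip deflection within 10% of
Euler–Bernoulli theory for a slender cantilever at 8 elements through the
depth (constant-strain tets converge to bending from the stiff side, so
this is the dominant discretization error, not a material issue), exact
linearity in load, frame invariance of von Mises stress under rigid
rotation, and entry-wise agreement of the assembly with a naive dense
per-element oracle.

Mesh-convergence checking mirrors field practice: von Mises stress is
probed as the mean of up to six elements nearest the centroid of 3–6
anatomical regions over a coarse-to-fine ladder, and the coarsest density
whose probe values change by less than 5% (default) relative to the next
finer level is accepted. Probes inside fully fixed regions are identically
zero at every density and count as converged rather than 0/0. On blocky
voxel shells at desk-scale densities the probes genuinely fluctuate more
than 5% between adjacent coarse levels; the check reports that honestly
(non-convergence with a per-probe trace) rather than hiding it.

## Scenarios and normalization

Strike scenarios load the bite contact and fix only the articulations;
pressure scenarios load the apodeme insertion along the closer muscle's
line of action and additionally fix the bite contact. The strike load
direction is not uniquely defined by anatomy alone; the default is the
mesh's global bite-closure direction (perpendicular to the articulation
axis, stored by the generator), with the mean inward surface normal of
the contact patch available as a config option.

Load normalization is exact ratio arithmetic (SA_i / SA_max, reference
1 N); printed-style rounding (half-up, 4 decimals) is applied only at
reporting time. Color-map comparability across specimens uses a reference
model: fields are divided by a scale statistic of the reference field.
The default scale is the volume-weighted 98th percentile — robust against
exactly the artifact peaks the Intervals Method trims — with `"max"`
available when a self-normalized peak of exactly 1 is wanted. The
reference defaults to the largest (1 N) specimen.

## Intervals Method

Choices where the original description leaves room, all configurable:

* **Trim count** is ⌈p·n⌉ with ties broken by removing higher element ids
  first, making trimming fully deterministic.
* **Zero-stress elements** (possible next to constraints) are floored to
  the smallest positive stress before the log, with a logged count.
* **The scenario threshold** is a volume-weighted inverted-CDF quantile of
  the *pooled* distribution of all specimens in a scenario (one threshold
  per scenario); volume weighting matches the method's volume-centric
  logic.
* **The interval lower bound** is the pooled minimum log-stress: after the
  log transform the original method's implicit zero lower bound is
  invalid, since log-stresses are routinely negative.
* **The top interval** is open-ended above the threshold, so profiles
  always conserve total volume (they sum to 1 to ~1e-14 in practice).
* **PCA** standardizes interval variables to unit variance
  (correlation-matrix PCA, the common default of multivariate
  morphometric software); zero-variance intervals are dropped with a
  warning; component signs are fixed by orienting the largest loading
  positive.
* **Interval-count convergence**: R² between PC1 score vectors of
  consecutive candidate counts; the chosen count is the first after which
  the R² gain saturates (increase ≤ ε, default 0.01). Identical scores
  throughout select the first candidate; a monotonically increasing R²
  ladder returns the largest candidate flagged non-converged. PC2 R² is
  reported alongside but does not drive the choice.

A useful consequence of data-driven bounds: multiplying every specimen's
applied load by a common factor shifts all log-stresses, the pooled
quantiles, and the lower bound by the same constant, so interval profiles
are exactly invariant — the method measures distribution *shape*, not
scale.

## The packaged study and what it shows

The packaged configuration solves six specimens (shovel, robust-major and
trap-jaw morphotypes at two sizes each, seed 1) under all four scenarios;
trap-jaw specimens are excluded from apical scenarios, giving 20
(specimen, scenario) rows. On these models, pressure biting consistently
places a larger volume fraction in the upper third of the stress intervals
than strike biting for the shovel and robust morphotypes (crushing loads
entering at the small apodeme patch spread high relative stress through
the basal half, while strike loads spread over the long margin concentrate
stress near the articulations), whereas the elongate trap-jaw blade shows
the opposite contrast — a reminder that such directional statements are
morphology-dependent. The study is deterministic: rerunning with the same
seed reproduces the intervals tables byte for byte.

## Known limitations

Homogeneous material only (no cuticle property gradients or heavy-metal
enrichment of the margin), small strains, no contact or dynamics; voxel
shells approximate smooth cuticle only to first order; the interval-count
convergence rule involves a tolerance the original description leaves
unspecified; and PCA variance percentages computed on few specimens (as in
the packaged six-specimen study) are upward-biased relative to a
25-specimen study and are not comparable to published values from real
datasets.
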