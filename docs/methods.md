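# Methods

This note documents the models and numerical choices behind `atriamesh`: how
a closed left-atrial endocardial surface is reconstructed from sparse 2D MRI
contours, how a second reconstruction is fitted to an intra-chamber
ultrasound (ICUS)-style point cloud, how the two are rigidly co-registered
and compared, and how per-vertex conduction fields are analysed against
adjacent thoracic structures.

## Contour stacks

The MRI input is a stack of closed planar contours, each with a slice pose
(origin plus two orthonormal in-plane axes, all in mm in one right-handed
patient frame).  Typical acquisition geometry is strongly anisotropic —
about 2.8 mm in-plane resolution against 8 mm slice spacing — so the stack
is a sparse sampling of the chamber along its axis.  Two lid points beyond
the extreme slices allow a closed surface; when absent they default to the
extreme-contour centroids offset outward along the stack axis by half the
median slice spacing.

A single transverse (y-normal) contour can correct slice-to-slice
misalignment: the transverse polyline crosses each axial plane at (usually
two) points, and each axial contour receives the in-plane translation that
brings its boundary closest to those crossing points.  Only translation is
adjusted — slice orientation is trusted — and a tiny ridge penalty
(1e-4 per mm^2) selects the smallest correction when the two crossing points
leave a flat direction in the objective.  Rotation correction was
deliberately left out: with two crossing points it is poorly identified.

Resampling to K equally spaced vertices operates in arc length along the
closed polyline, starts at the original first vertex, and normalises winding
to counter-clockwise about the slice normal.

## Contour-path surface reconstruction

1. **Initial ruled surface.**  Every contour is resampled to K vertices
   (default 64); each ring's index origin is rotated to minimise the summed
   rung length to its predecessor, which removes twist; consecutive rings
   are joined by triangle strips and the extreme rings are closed by fans to
   the lid points.  The result is closed, consistently oriented, genus 0.
2. **Attractors.**  A fixed set of A attractor points (default 400) is
   selected from densely resampled contour vertices by greedy farthest-point
   sampling (deterministic; ties break to the lowest candidate index), so
   the data term covers all contours roughly uniformly.
3. **Bounded attraction.**  For each attractor Q_i, P_i is the closest point
   on the current surface (any point of any triangle, found by exact
   point-to-triangle queries).  The target is
   Q_i' = P_i + beta (Q_i - P_i)/|Q_i - P_i| with step length beta
   (default 1 mm); an attractor closer than beta captures P_i entirely,
   which also avoids the vanishing-norm direction.
4. **Thin-plate-spline fit.**  The deformation minimises
   lambda * sum_i |F(P_i) - Q_i'|^2 + J(F), where J is the second-order
   bending energy in three dimensions, whose kernel is phi(r) = r.  The
   regularized square system carries 1/lambda on the kernel diagonal
   (default lambda = 1e3); affine maps are reproduced exactly, lambda -> inf
   approaches interpolation and lambda -> 0 the affine least-squares fit.
5. **Guarded application.**  Vertices move through F; any step that would
   flip a face orientation is halved (up to 6 times) and, failing that,
   rejected — a practical surrogate for applying the field
   diffeomorphically.
6. **Smoothing.**  Uniform-umbrella Laplacian smoothing
   p_i <- p_i + w (mean of neighbours - p_i), simultaneous updates, default
   w = 0.3 for 2 sweeps per outer iteration.
7. **Refinement schedule.**  On a fixed schedule (every 3rd outer iteration
   until the face budget is reached) the mesh is refined by
   **modified-butterfly (interpolating) subdivision** and brought back to
   the budget (default 6000 faces, matching final meshes of roughly 3000
   vertices) by quadric-error edge collapse with optimal vertex placement
   and link-condition/normal-flip guards.  The interpolating scheme is a
   deliberate choice over midpoint subdivision: with 8 mm slice spacing the
   ruled mesh is a stack of cone frusta whose enclosed volume is biased low
   by 5-6% on a 30 mm sphere, and an interpolating smooth limit surface
   regains the convex bulge between slices from smoothness alone — no
   template shape is ever introduced.  Approximating schemes (e.g. Loop)
   were rejected because they shrink, compounding the bias the step is
   meant to remove.
8. **Acceptance and convergence.**  After each outer iteration the mean
   contour-to-mesh distance (contours densely resampled to at least 100
   points each) is measured; steps that worsen it are rejected and beta is
   halved, so the fidelity metric is non-increasing over accepted
   iterations.  The loop stops when the improvement falls below 0.01 mm
   (after all scheduled refinements) or after 50 outer iterations, returning
   the best mesh with a warning if the tolerance was not met.

None of beta, lambda, the smoothing weight, or the schedule counts are
prescribed by the clinical acquisition; they are exposed in
`ReconstructionConfig` with the defaults above.  On the noise-free sphere
phantom (r = 30 mm, 8 mm slices) the pipeline reaches ~0.02 mm mean contour
distance and ~2.5% volume error; the remaining volume deficit is the polar
caps, which no contour constrains.

## Point-cloud path (ICUS emulation)

The ultrasound route fits a surface to an unorganised point cloud by a grid
Poisson indicator fit: normals estimated from 16-point neighbourhood PCA and
oriented outward from the centroid are splatted onto a regular grid
(trilinear weights, Gaussian smoothing of 1.2 voxels), the Poisson equation
for the smoothed indicator is solved spectrally (discrete sine transform,
zero Dirichlet boundary) on a 64^3 grid padded 18% beyond the cloud, and the
iso-surface at the mean indicator value over the samples is extracted by
marching cubes.  No smoothing is applied to the resulting mesh.  Stray
points are removed beforehand by the 3-sigma centroid-radius rule,
emulating manual cleanup of far reflections.  On a 4000-point noise-free
sphere cloud the volume error is below 0.5%.

A known behaviour of this route, reproduced synthetically: when the cloud
mixes endocardial and epicardial reflections (half the points displaced
outward by 1.9 mm), the fitted surface lands between the layers and the
enclosed volume is strictly larger than from the endocardial layer alone.
Dividing the volume excess of an outer over an inner reconstruction by the
inner surface area gives the *equivalent wall thickness*; on the synthetic
endo/epi pair this returns ~2.0 mm for a 1.9 mm offset (the small excess is
the curvature term t/r of a spherical shell).

## Rigid co-registration

Generalized ICP between the vertex sets: each point carries a locally planar
covariance (two unit tangential eigenvalues, epsilon = 1e-3 along the local
normal, from 20-neighbour PCA), correspondences are nearest neighbours
within 20 mm, and the rigid update is a Gauss-Newton step on the summed
Mahalanobis cost with step halving, so the freshly evaluated cost never
increases.  Initialisation is centroid alignment plus principal axes; the
sign ambiguity of the axes is resolved by refining from all four proper
sign combinations and keeping the basin with the lowest final cost —
near-symmetric chambers otherwise lock into a flipped local minimum.  The
MRI-derived mesh is the moving source, the ICUS-derived mesh the fixed
target (the mapping system's frame); the inverse transform is available for
reporting in either direction.

## Comparison metrics

Editing before registration removes faces touching labelled spheres (mitral
valve, pulmonary veins, appendage proxies); capping closes each boundary
loop with a centroid fan.  Capping must be requested explicitly when a
volume is needed, so editing errors cannot be hidden by silent hole
filling.  Surface distance is vertex-to-triangle (not vertex-to-vertex);
the symmetric report averages the two directed means and pools the
per-point lists.  Enclosed volume uses the divergence formula on the closed
oriented mesh and is reported in ml; areas in mm^2.

## Field analysis

Per-vertex fields are conduction velocity (m/s, three rhythm protocols) or
pathological-conduction-pattern (PCP) event frequencies (1/s; focal firing
FF, localized rotational activation LRA, localized irregular activity LIA),
with NaN as the missing-value marker and pairwise deletion in statistics.
Transfer between co-registered meshes is nearest-neighbour by vertex.
Area-weighted histograms give each vertex one third of its incident face
area; CV histograms exclude values above 1.5 m/s (a physiological
plausibility bound) rather than capping them, and the bookkeeping is exact:
bin areas plus excluded area equal the total surface area.

Proximity analysis measures each atrial vertex's Euclidean distance to the
nearest surface point of an adjacent structure (the same rigid transform
applied to the atrium is applied to structures segmented in the MRI frame).
A vertex within 3 mm (inclusive) of any structure is "in contact" — the
union rule over structures.  Contact and non-contact groups are compared by
the Mann-Whitney U test: pooled n <= 20 uses the exact permutation
distribution by full enumeration (correct under ties, two-sided p as twice
the smaller tail, capped at 1), larger samples the tie-corrected normal
approximation with continuity correction — exact enumeration at ~3000
vertices per mesh is not feasible and the approximation error there is
negligible.  Pearson correlations carry Fisher-z 95% intervals; Spearman is
computed as mid-rank transform followed by the Pearson machinery.  Volumes
between paired reconstructions are compared with the paired Student's t.

## Synthetic phantoms

The phantom module generates the full study's inputs with known ground
truth; all outputs are deterministic under a fixed seed.

* **Shapes:** sphere (r = 30 mm), ellipsoid (30x25x20 mm semi-axes), and a
  "blended atrium" — an ellipsoid body with four tapered tube stubs
  (pulmonary-vein proxies, deliberately unequal radii so the shape has no
  near-symmetry to trap the registration) and one lateral pouch (appendage
  proxy), blended with a smooth-minimum field and extracted by marching
  cubes.
* **Contour slicing:** plane sections at the 8 mm default spacing, largest
  loop kept, resampled to 80 vertices; in-plane Gaussian jitter (default
  sd 0.5 mm, roughly a fifth of the in-plane voxel) applied *radially*
  about the loop centroid — the distance to the true boundary is N(0, sd)
  to first order either way, but radial perturbation cannot self-intersect
  a star-shaped loop.  A mid-height transverse contour is attached for the
  alignment step.
* **Point clouds:** area-weighted surface sampling, optional epicardial
  layer displaced 1.9 mm outward (the dual-reflection hypothesis), Gaussian
  noise along the normal, and a configurable fraction of far outliers.
* **Fields:** CV as smooth low-order angular patterns clipped to
  [0.2, 1.5] m/s; PCP frequencies as Poisson counts over a 60 s recording
  window at base rates FF 0.05, LRA 0.2, LIA 0.65 per second (LIA dominant,
  matching its reported clinical prevalence), multiplied by a contact
  effect (default 3) within 3 mm of the adjacent structure.

What the phantoms do not emulate: real segmentation error structure
(correlated, not iid), anisotropic ICUS noise and shadowing, true atrial
anatomy (the blended shape has the right scale and topology only), and any
actual electrophysiology — PCP fields are independent Poisson draws, with
no spatial correlation beyond the contact effect.  Passing phantom tests
therefore validates the geometry/statistics machinery, not clinical
accuracy on patient data.

## Power and calibration conditions

With the 3x contact effect and 60 s windows on the sphere-with-cylinder
configuration (45 contact vertices of 2562), the contact comparison detects
the effect (p < 0.01) in 100% of 100 seeded replicates; under the null
(effect 1) the rejection rate at alpha = 0.05 over 200 seeds falls in a
three-sigma binomial band [0.01, 0.10] around the nominal level.

## Problem sizes and determinism

Default problem sizes throughout (chosen as the package's standard
conditions): 2562-vertex icospheres, ~1024-face initial tubular meshes
refined to a 6000-face budget, 4000-point clouds on a 64^3 Poisson grid,
400 attractors, 100/200-replicate power studies.  All randomness flows
through explicit `numpy` generators seeded per operation; there is no
global random state.

## Known limitations

* The polar caps of a sliced shape are unconstrained by data; their
  geometry is whatever the interpolating subdivision and lid rule imply.
  This is the dominant term in the residual volume error.
* The diffeomorphism of the TPS step is enforced only via the
  orientation-flip guard, not by velocity-field integration.
* Exclusion regions are spheres; clinical editing draws free-form regions.
* The Mann-Whitney exact branch enumerates up to pooled n = 20 only.
* Registration is rigid by design; no scaling or non-rigid refinement.
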