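# Methods

## The measurement problem

Body height (BH), body straight length (BL), body slant length, and the
abdominal/chest circumferences (AC/CC) of cattle walking through a
measurement channel are derived from three RGB-D views — one camera above
the channel, one on each side beyond the fence. The channel environment is
hostile to 3D sensing: railing bars occlude vertical stripes of the side
views, outdoor lighting punches holes and outlier clumps into the depth
data, the ventral surface is invisible to every camera, and the animal
stands in an arbitrary posture. The pipeline is built so that each of
these degradations is absorbed by a dedicated mechanism rather than
propagated into the measurements.

## Pipeline

### Reference frame and units

All geometry is metric (metres internally; reports print centimetres to
one decimal). The reference frame is the top camera's: x along the animal
toward the hip, y toward the left-view camera, z pointing at the ground.
The ground plane coordinate H0 (2.48 m for the standard rig) therefore
*exceeds* the z of the animal's back, and all heights are computed as
|z − H0| so either sign convention of input data yields the same numbers.

### Per-view cleanup

1. **Pass-through crop** — an axis-aligned box around the channel,
   configured per view; it removes gross background.
2. **DBSCAN cluster filtering** — density clustering with radius r and
   core threshold N, then selection of the single cluster whose
   bounding-box extent best matches a cattle body (smallest summed
   |log(extent/expected)|, ties to the larger cluster;
   expected extent defaults to 2.0 × 0.8 × 1.5 m). Ground plane, railing
   fragments and outlier clumps all fail the extent test.
   The radius default (r = 0.08 m) is deliberately larger than a railing
   bar (0.05 m): bars cut a side view into stripes, and any r below the
   void width disconnects the stripes so single-cluster selection would
   silently keep one stripe and discard the rest of the view.
   N = 12 tolerates the several-fold sparser sampling of surface seen at
   grazing angles (the lower flank in a side view). Border points join
   the first core cluster that reaches them in scan order, which makes
   labels deterministic for a fixed point order.
3. **Statistical outlier removal** — per-point mean distance μᵢ to its
   k = 20 nearest neighbours; points with μᵢ > mean(μ) + α·std(μ)
   (α = 3.0) are deleted. This global form expresses the stated intent —
   points close to the average spacing of their surroundings are kept —
   whereas the literal per-point rule (flag pᵢ when any neighbour
   distance exceeds its own μᵢ + α·σᵢ) fires on nearly every point of any
   cloud with local spread; that variant remains available behind
   `literal=True` for comparison experiments.

### Registration

The top view defines the reference frame (it is unoccluded and evenly
lit); the side views are first coarse-aligned with their mounted-camera
extrinsics and then fine-aligned to the top cloud by point-to-plane ICP.
Because adjacent views share only a narrow flank strip, correspondences
are restricted to the **overlap-possible region**: each coarse-aligned
side point's nearest distance to the top cloud is computed through a
KD-tree, and the fraction fp = 0.25 with the smallest distances (selected
by a bounded max-heap of negated distances, ties to the lower index) is
retained as the ICP source. The fine transform is estimated on that
region but applied to the whole view, so the merged model is complete.

ICP details: target normals from the best-fit plane of k = 20 neighbours,
oriented toward the acquiring camera; per-iteration small-angle
linearization of Σ[(R·s + t − q)·n]² solved in closed form;
correspondences beyond 5× the median pair distance rejected each
iteration; convergence when the Frobenius norm of the 4×4 update falls
below 1e−6 or after 50 iterations. If an update fails to reduce the RMS
the step is reverted and iteration stops, which makes the recorded RMS
series non-increasing by construction. A half-cylinder-like target with
no end geometry leaves translation along its axis unobservable to the
point-to-plane objective — physical bodies (and the test fixtures) have
ends, which close that null space.

### Landmarks

Detection is upstream; the package ingests named pixel+depth landmarks
per view (CSV or JSON; depth optionally sampled from a depth map with a
5×5 median to resist speckle) and back-projects them through the pinhole
model, ((x−cx)·z/fx, (y−cy)·z/fy, z), into the reference frame using the
ICP-corrected view transform. A landmark whose pixel falls on a railing
bar back-projects onto the bar, not the body; measurements that can
tolerate this (height, girth planes) use such landmarks anyway, and those
that cannot fall back as described below.

### Linear measures

* BL: polyline length over the five ordered top-view landmarks
  (neck → back → abdomen → aid → buttocks).
* BH: mean of |z − H0| over available views' back landmarks. Only z is
  used, so a railing-projected back landmark is harmless as long as the
  ray to the back is near-horizontal — true when the side cameras stand
  at about back height. H0 comes from the rig configuration, or failing
  that from the modal z of the lowest 2-cm slab of the merged cloud.
* Slant length: per-side foreleg–buttocks distance, averaged. When a
  side's pair is flagged occluded, the x–z plane distance is used
  instead, because the railing projection corrupts mainly the lateral
  (y) coordinate. This fallback is approximate by nature: railing
  projection also scales the axial coordinate toward the camera by the
  fence/flank distance ratio, and in degraded synthetic runs the slant
  error from this fallback reaches a few percent — the price of
  measuring through a fence.
* Missing views degrade to means over what is available, flagged in the
  report.

### Girths

The central design idea is **posture normalization**: the section plane's
normal is the animal's own spine direction, the vector from the aid
landmark to the abdomen landmark in the top view, so a yawed or oblique
stance cuts the same transverse section as a square one. The plane passes
through the side-view abdomen (AC) or chest (CC) landmark; a
railing-projected reference landmark shifts the plane slightly along the
spine (bounded by the fence/flank geometry) but never tilts it.

1. Points within ±τ of the plane (τ = 4 cm; the slab must exceed a
   railing bar's 5 cm so a bar crossing the station cannot blank a whole
   view's contribution) are orthogonally projected into plane coordinates
   u (lateral, toward +y) and v (up), with a detached band at the bottom
   of the chart dropped as ground return (band within 5 cm of the lowest
   v, dropped only when separated from the body by more than 10 cm).
2. Polar transform about an interior origin: θ = deg(atan2(Δv, Δu) + π)
   mod 360 (the +u direction maps to 180°), ρ the radial distance. The
   origin is the robust mid-range of each chart axis (0.5 % quantiles),
   not the centroid: density differences between view overlaps and the
   ventral gap pull the centroid off the bilateral symmetry axis, and the
   later mirror-fusion reflects about the vertical through this origin,
   so the origin must sit on that axis. If the mid-range point is not
   interior the Chebyshev centre of the hull is used.
3. **SVR profile repair**: ε-SVR with RBF kernel regresses ρ on θ, after
   augmenting the data with ±60° wrap-around copies for continuity across
   the 0/360 seam. Hyperparameters come from randomized search
   (40 draws, 5-fold CV, MSE objective) over C ∈ log-U[0.1, 1000],
   γ ∈ log-U[10⁻³, 10], ε ∈ log-U[10⁻⁴, 10⁻²] m, all seeded. The
   regression feature is θ in *radians*: on that ~unit scale the γ
   decades map to RBF kernel widths between ~13° and beyond a full
   turn, so no draw can oscillate below the angular sampling scale —
   which matters on near-circular sections, where every candidate
   scores within noise of every other and an oscillatory winner would
   explode the later polyline length. The search
   runs on a seeded subsample of ≤250 points and the final fit on ≤800
   (SVR cost grows superlinearly in n; profile accuracy on the analytic
   ellipse oracle is unchanged by these caps), with the SMO iteration
   count bounded so pathological hyperparameter draws cannot dominate
   wall time — an under-converged draw simply loses the CV selection.
   The fit is evaluated on a 1° grid restricted to arcs with data
   support; gaps wider than 15° are left to the bridge.
4. **Bilateral fusion**: the fitted curve is split at its dorsal apex
   (topmost Cartesian point) into the left-view branch — the shaded,
   more distorted side — and the right-view branch; the right branch is
   mirrored about the vertical axis through the origin (θ → 540° − θ,
   exact on the integer grid), resampled onto the left branch's grid and
   averaged with it. Bilateral body symmetry makes the mirrored branch an
   independent estimate of the same half, so one-sided distortion is
   halved.
5. **Bézier bridge**: the unobserved ventral arc is closed by one cubic
   segment between the two branch ends, control points a third of the
   chord along each end tangent (Pc1 = P0 + (d/3)·t̂0,
   Pc2 = P1 − (d/3)·t̂1) — the Hermite-equivalent placement, giving
   tangent continuity at both joins. Against analytic elliptical arcs
   this bridge is accurate to 0.1 % of the perimeter for 60° gaps and
   under 1 % even at 120°.
6. The girth is the polyline length of fused branch + kept branch +
   bridge (plus the infinitesimal apex junction).

Reported per girth: R² and MAEP of the SVR fit against the observed polar
data, roughness (mean |first difference|) of the repaired branch before
and after fusion, and the SVR hyperparameters chosen.

### Quality metrics

R² = 1 − SSE/SST (the printed explained-variance numerator variant is
available behind a flag; it coincides with the standard form only under
OLS orthogonality and the standard form matches the "closer to 1 is
better" usage). MAEP = mean |y−ŷ|/y × 100. Smoothness = mean absolute
first difference (0 for a constant series, |d| for an arithmetic one).
MAE/MRE compare measured against reference values pairwise; MRE and MAEP
are the same formula kept as separate entry points mirroring their
separate uses (fit quality vs measurement accuracy).

## Synthetic study conditions

The generator sweeps elliptic cross-sections along a straight spine:
half-axes a(s), b(s) taper elliptically along the body (peak lateral
half-axis 0.35 m at mid-body, peak vertical half-axis 0.30 m at the back
station), spine axis 0.85 m above ground, length 2.0 m; a constant-
section variant provides the exact-cylinder oracle. Everything a test
asserts is therefore closed-form: girths via Ramanujan's perimeter
π[3(a+b) − √((3a+b)(a+3b))] at the landmark stations, lengths from the
analytic landmark positions, height from the dorsal profile. Poses
(yaw/pitch about the body centre) change none of these truths.

The virtual rig matches the physical layout: top camera 2.48 m above
ground at the frame origin, fence 0.45 m from the channel centre, side
cameras 1.15 m beyond the fence at 1.15 m height (near-horizontal rays to
the back, which is what makes railing-projected back landmarks
height-safe), 2208×1242 pinhole sensors. Captures apply z-buffer
visibility on a binned pixel grid, then the degradations: vertical
railing stripes (5 cm bars every 25 cm, bar phase drawn per scene) in the
side views, a 60° unobserved ventral arc, Gaussian noise (σ = 5 mm along
view rays), clustered outlier blobs, illumination holes, a ground plane,
and 3°/5 cm miscalibration of the side extrinsics for the ICP to correct.
Landmarks are exact projections of the analytic anatomical points, with
railing-occluded side landmarks given the depth of the fence intersection
and flagged.

What the generator does not emulate — legs, head/neck geometry, fur and
specular artifacts, non-rigid motion between views, detector error in
landmark placement — bounds what passing tests show: they validate the
geometry processing and repair chain, not landmark detection robustness
or soft-tissue effects on real animals.

Default problem sizes keep a full scene (capture → report) at well under
a minute: 40 000 surface samples for single scenes, 25 000 for the
multi-scene studies (posture sweep, 10-body herd), SVR search/fit caps as
above. Girth accuracy is insensitive to these sizes; they are chosen so
the whole verification suite runs comfortably on one CPU.

## Numerical choices and degenerate inputs

* Rigid transforms re-orthonormalize rotations built from axis-angle via
  SVD; zero-angle/zero-axis updates return the identity (the ICP
  fixed-point case).
* Overlap selection ties break to the lower query index; DBSCAN border
  ties to scan order; target-cluster ties to the larger cluster —
  everything that could depend on order is pinned.
* A constant polar profile (perfect circle) skips the hyperparameter
  search (any parameters reproduce a constant).
* Degenerate spine landmarks (< 1 mm apart), empty slabs, sections with
  fewer than 50 points, one-sided profiles and zero-length bridge chords
  all raise named errors that the pipeline wraps with the failing stage.
* Duplicate-point clouds (zero distance variance) pass statistical
  filtering untouched; the point with the globally smallest mean k-NN
  distance is never removed.

## Known limitations

* The slant-length occlusion fallback inherits railing-projection error
  in the axial coordinate; expect a few percent under heavy occlusion.
* A railing-projected girth reference landmark shifts the section plane
  along the spine by up to a few centimetres; at strongly tapered
  stations (chest) this biases the girth by ~1 %.
* The ventral arc is never observed; its contribution rests entirely on
  the bilateral-symmetry assumption and the bridge. Bodies with
  asymmetric or pendulous underlines will be measured as their
  symmetrized selves.
* Single-animal scenes only; multi-animal disambiguation is out of scope.
* PCD input is ASCII v0.7 read-only; PLY is the canonical format.
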