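# Methods

`zernpatch` quantifies the geometric fit of the two molecular surfaces at a
protein–protein interface. The result of a run is a single number, the
Zernike distance D_z between the two binding patches, together with a null
distribution of the same number computed against random surface patches.
Low distance relative to the null means the two surfaces are shaped like
mold and cast — the lock-and-key signature of a well-packed interface.

## Pipeline

1. **Structure input.** PDB/CIF/mmCIF files are read with gemmi. Only
   protein heavy atoms of the first model are used; waters, hydrogens and
   (by default) heteroatom groups are discarded, and alternate locations
   collapse to the highest-occupancy conformer. The user names two disjoint
   chain groups, the *template* and the *target*.

2. **Surface.** Each partner's solvent-accessible surface is sampled as an
   oriented point cloud: every atom contributes a deterministic Fibonacci
   lattice (default 256 points) on its solvent-inflated sphere
   (van der Waals radius + 1.4 Å probe; Bondi radii, fallback 1.80 Å), and
   points strictly inside any other inflated sphere are removed. Normals
   are the radial directions from the generating atoms. The lattice is
   generated once in a fixed orientation and translated to each atom, so
   the cloud is exactly translation-equivariant and rotation-equivariant up
   to the lattice resolution. A Connolly-type solvent-excluded surface
   could be substituted behind the same point-cloud contract.

3. **Interface and patches.** A surface point belongs to the binding
   region when its nearest point on the other partner's surface is closer
   than 3 Å (exact k-d-tree search; residues enter the interface if they
   own at least one such point). On each side, one circular patch (default
   radius 8 Å, Euclidean ball, minimum 16 points) is cut around the surface
   point nearest that side's interface centroid — a deterministic centre
   that is guaranteed to lie on the surface.

4. **Orientation.** Each patch is translated so its centre is the origin
   and rotated by the minimal rotation taking its mean normal to +z
   (template) or −z (target); the antiparallel case falls back to a 180°
   rotation about x. Because the outward normals of the two partners point
   toward each other across the interface, this places both patches in a
   common frame approximating the complex geometry: the template surface
   seen from inside the template, the target surface lying just above it.

5. **Cone projection.** A cone with its vertex on the z-axis *below* the
   patch and half-angle 45° is fitted by bisection so that it exactly
   contains the patch (max point angle = 45° within 1e-6°). Points map to
   the unit disk by their (x, y) scaled by the patch's maximal in-plane
   radius, and each pixel of a 64×64 grid over [−1, 1]² stores the mean
   Euclidean distance from its points to the vertex. The vertex sits on
   the −z side for *both* patches: complementary surfaces, which nearly
   coincide in the common frame (the target is the template's parallel
   offset at the contact gap), are then viewed from the same side and
   produce nearly identical depth maps. (Placing each vertex opposite the
   patch's own normal instead would undo the ±z convention and make
   complementary maps anti-correlated — the convention is what converts
   complementarity into image similarity.) Pixel values compare *shape*,
   not absolute size, because of the per-patch radial normalization.

6. **Zernike descriptors.** The depth map is expanded in the 2D Zernike
   basis Z_nm(r, θ) = R_nm(r) e^{imθ} up to order 20 (121 coefficients;
   m ≥ 0 only since the image is real). Radial polynomials are evaluated
   via the Jacobi identity R_nm = (−1)^((n−m)/2) r^m P^{(m,0)}_{(n−m)/2}(1−2r²),
   stable beyond order 40. Coefficients are estimated by least squares on
   the masked pixels — equivalently, the textbook projection
   c_nm = (n+1)/π ∫ f Z̄_nm dA premultiplied by the inverse discrete Gram
   matrix. On a full fine grid this reduces to the plain projection; on a
   64×64 grid it removes the pixelization cross-talk between basis
   functions (which otherwise reaches 3–8% per unit coefficient and breaks
   rotation invariance of the moduli), and it treats unhit pixels as
   missing data rather than zeros. A relative SVD cutoff of 3e-2
   (inactive on full-disk designs, whose singular-value ratio is ≈0.17)
   damps the near-degenerate directions of sparse patch masks that would
   otherwise amplify pixel-level noise.

7. **Distance and null.** The rotation-invariant descriptor is the vector
   of moduli |c_nm| (rotation shifts only phases). The complementarity
   score is D_z = sqrt(Σ (|c_nm| − |c′_nm|)²) — a true Euclidean metric;
   an alternative mode differences squared moduli instead. The null is
   built from (default) 100 decoy patches centred at surface points drawn
   uniformly at random from the target cloud, each pushed through the
   identical patch→descriptor pipeline; the run reports the percentile of
   the real distance in the decoy distribution and its z-score. Decoy
   centres may optionally exclude the interface region; decoys can also be
   sampled on the template surface instead. ROC AUC (midrank Mann–Whitney,
   "interface lower than decoy" positive) summarizes discrimination over
   sets of complexes or synthetic pairs.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| probe radius | 1.4 Å | water probe for the accessible surface |
| lattice points/atom | 256 | surface sampling density (~2 points/Å²) |
| interface cutoff | 3.0 Å | surface-to-surface contact distance |
| patch radius | 8.0 Å | size of the compared surface piece |
| cone half-angle | 45° | depth-map contrast of the projection |
| grid size | 64 | disk image resolution |
| expansion order | 20 | descriptor detail (121 invariants) |
| n decoys | 100 | null-distribution size |

Radius 8 Å and orders in the 10–20 range are the regime where interface
vs. random discrimination is strongest; pushing the order beyond 20 adds
no discrimination but more noise-sensitive coefficients.

## Synthetic data

The generators provide ground-truth inputs at three levels:

* **Bump/mold patch pairs** (`make_bump_pair`): a Gaussian bump
  (amplitude 1.5 Å, width 2.5 Å) sampled at 400 points over the patch
  disk, and the same surface with inverted normals as the pre-oriented
  counter-patch, each with independent 0.1 Å positional noise. These emulate
  an ideally complementary contact at realistic surface-sampling density.
  `make_random_patch` (five random Gaussians, roughness 1.5 Å) is the
  uncorrelated negative control.
* **Toy complex** (`make_toy_complex`): two mirror-image strands of
  pseudo-residues at a controlled surface gap — touching at gap < 3 Å,
  separated at large gaps. Used for parsing, interface and determinism
  tests. A mirror image is *not* a complementary mold (a reflected bump
  faces a bump), so this fixture makes no complementarity claim.
* **Mold complex** (`make_mold_complex`): a bulky jittered block (chain A)
  plus a chain B whose atoms are laid out at a constant offset along A's
  surface normals, so B's accessible surface tracks the parallel offset of
  A's — a constructed lock-and-key complex. Both solids are thick enough
  (~13 Å) that the 8 Å patch ball stays on one side of each, as it would
  on a globular protein.

What the fixtures do **not** emulate: real side-chain chemistry and packing
statistics, large or curved interfaces that would need multiple patches,
and the conformational noise of crystal structures. Passing the synthetic
benchmark shows the geometry engine converts constructed complementarity
into low descriptor distances; it does not certify the discrimination
accuracy reported on real complex collections.

## Numerical choices and degenerate inputs

* Occlusion uses a strict-interior test with 1e-9 slack, so coincident
  atoms deterministically keep their shared surface.
* The interface test is a strict `< cutoff` on exact distances; an empty
  interface aborts the pipeline with a named stage error.
* Patch-centre ties break to the lowest point index; patches with fewer
  than 16 points, patches with vanishing mean normal, and axis-only
  geometries that admit no containing cone each raise a specific error.
  Decoys hitting such degeneracies are skipped and counted; a run aborts
  if more than half fail.
* Disk binning uses half-open pixels (lower edge inclusive); the boundary
  point at u = 1 is clipped into the last pixel so every patch point lands
  in exactly one pixel.
* All randomness (jitter, noise, decoy centres) flows from explicit seeds;
  a run with the same configuration and seed reproduces every output file
  byte for byte.

## Known limitations

* One patch per side: large interfaces are summarized by their central
  patch only.
* The descriptor distance is mildly asymmetric under template/target
  relabelling (each patch is normalized by its own in-plane radius);
  on symmetric fixtures the effect is below 10%.
* The accessible-surface point cloud is a sampled, not analytic, surface;
  mold fidelity at the default density is ~0.3 Å, which sets the floor of
  the real-interface distance on constructed complexes.
* Coefficients above order ~20 at grid 64 sit close to the pixelization
  noise floor; comparisons should use matched order and grid on both sides
  (enforced by the distance function).
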