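# Methods

## Measurement model

The package grades the bone bridge that secondary alveolar bone grafting
(SABG) leaves in a unilateral alveolar cleft, using the contralateral
(non-cleft) side of the same patient as control.  All measurements live in
a frame standardized to the assessed side's **central incisor long axis**:
the volume is resampled (nearest-neighbor, rotation about the volume
center) so the axis is the third index array axis, and depths are measured
along it from the **cementoenamel junction (CEJ)** — operationally, the
most apical enamel voxel on the incisor's midsagittal plane, with ties
broken by distance to the root centroid and then by smallest index.

At each assessment depth *d* ∈ {3, 5, 7, 9} mm below the CEJ a
cross-section perpendicular to the axis is extracted.  The **bridge
width** at a level is the minimum, over mesiodistal stations strictly
between the incisor and canine root regions, of the labiolingual thickness
of contiguous spanning bone at that station; it is 0 if any station
carries no bone.  Only bone whose in-plane 8-connected component is
adjacent to both root regions counts, so two overlapping but disconnected
bone flaps cannot masquerade as a bridge.  The **root width** is the
maximal labiolingual extent of the incisor root label in the same section.
Widths are reported as voxel count × spacing with no sub-voxel
interpolation: at the 0.2 mm default spacing this matches the ~0.4 mm
effective spatial resolution of small-field CBCT, and all validation
geometry keeps configured widths more than two voxels away from any score
boundary.

**Bridge presence** is a 3D property: a single 26-connected bone component
must touch both the incisor-side and canine-side segments.  The reported
bridge depth is the depth of the component's widest inter-root
cross-section; when several slices tie, the midpoint of the tied run is
used.

## Scoring

Each level receives score 0–3 from the ratio ρ = bridge width / incisor
root width: 0 iff ρ = 0, then 1, 2, 3 on [0, ½), [½, 1), [1, ∞).  The top
anchor (bridge at least as thick as the root) is fixed by the scale's
definition; the ½ cut between scores 1 and 2 is the package's convention —
a symmetric midpoint consistent with that anchor — exposed as the
configurable `boundaries` argument and recorded in the output provenance.
A ratio exactly at a cut takes the higher score, consistent with the
"at least" phrasing of the top anchor.

The four scores sum to a 0–12 total: failure (0), poor (1–4), moderate
(5–8), good (9–12).  A total of 0 is reserved for sides without any
bridge, which forces two modification rules:

* **Between-level bridge.**  If a 3D bridge exists but every level scored
  0, the bridge is measured at its own (widest) depth and that score is
  assigned to the nearest level, ties going to the more coronal level (the
  clinically conservative choice).  The rule is applied strictly under the
  all-levels-zero precondition.  In the degenerate case of a spanning
  component with no measurable single-slice width (a voxel zigzag), the
  nearest level receives the minimal nonzero score 1 — a bridge is present
  but below level resolution.
* **Severe root resorption.**  If the incisor root no longer reaches the
  9 mm plane, the 9 mm denominator becomes the root diameter 0.5 mm
  beneath the apex.  The trigger is operationalized exactly as "root label
  absent in the 9 mm section", since that is when the normal comparison
  becomes impossible.

## Phantom generator

Phantoms rasterize an analytic scene: two tapered elliptical-cone roots
(central incisor, canine) with enamel caps above their CEJs, and a bone
slab of configurable labiolingual width profile spanning the inter-tooth
gap.  Defaults emulate the imaging conditions of small field-of-view CBCT
— 0.2 mm isotropic voxels, 5 cm × 5 cm field of view (250³ voxels) — with
anatomy-typical defaults: incisor root 13 mm long tapering 6.3 → 2.5 mm
labiolingually, canine 17 mm and 7.0 → 3.0 mm, mesiodistal widths 0.8× the
labiolingual ones, an 8 mm inter-tooth gap, and a default bridge profile
representing a typical post-graft cleft side (total 3, poor).  Tests and
the acceptance script use smaller explicit grids (e.g. 60×110×120, i.e.
12×22×24 mm) that still contain the full dentition — the package's own
problem-size choice; the geometry is identical at any grid that passes the
sizing checks.

Ground truth is analytic: level scores follow directly from the configured
profiles through the same scoring rules, so pipeline validation is exact
score recovery, not approximate agreement.  Optional boundary noise flips
a seeded fraction of surface voxels to a random 6-neighbor label,
emulating partial-volume ambiguity.  Noise is deliberately excluded from
the strict-recovery library: at the bone–root interface every bone voxel
in a station column is a surface voxel, so even 2% flips can fragment the
narrowest station and legitimately change a min-width score.  Noise
robustness is therefore validated separately with the weaker claims that
hold (3D bridge continuity preserved, totals never inflated).

What phantoms do **not** model: beam hardening, scatter, metal artifacts,
grayscale segmentation, real root-surface irregularity, or a lateral
incisor in the segment.  Passing the recovery suite shows the geometry and
scoring machinery is correct on clean labels; it does not certify
performance on real, noisy, rater-segmented scans.

## Statistics

* **Wilcoxon signed-rank** (cleft vs non-cleft, paired): zero differences
  are discarded by default (Pratt ranking available), ties get midranks,
  and the two-sided p is exact — the sign-flip distribution over all 2^m
  assignments, computed by polynomial convolution (doubled midranks make
  the statistic integral).  For m > 25 a tie- and continuity-corrected
  normal approximation is used; it tracks the exact p within 10% outside
  the extreme tail (exact p ≥ 0.05), which is the only regime where a
  Gaussian tail can hold a *relative* error bound against a discrete
  distribution.
* **Cohen's kappa** is the unweighted closed form over categories
  {0,1,2,3}; degenerate full agreement on a single category returns 1.
* **Bootstrap power** implements the stated hypotheses literally: H0
  resamples both sides from the control empirical distribution, H1 draws
  the cleft side from the cleft empirical distribution.  Because published
  marginals carry no patient-level pairing, replicates pair independently
  resampled sides; this is recorded in the result's `method_detail`.  The
  critical p-value is calibrated on the H0 replicates (the
  ⌊α·n_reps⌋-th smallest p), an order-statistic choice whose achieved
  level is ≈ α, and power is the H1 rejection fraction.  The default
  10,000 replicates put the Monte-Carlo standard error of a power near
  0.05 at ~0.002.

The study's patient-level p-values and kappa ranges cannot be recomputed
from published marginals (the pairings and individual rating series are
not public); the statistical machinery is instead validated against
enumeration oracles, closed forms and calibration properties.

## Numerical conventions and edge cases

* Nearest-neighbor everywhere labels are resampled; sampling coordinates
  round as ⌊x + ½⌋, making axis-aligned paths exact.
* Connectivity: 26 in 3D, 8 in 2D — permissive, to avoid false bridge
  breaks from voxelization.
* All randomness flows through per-call seeded `numpy` generators; the
  seed is recorded in outputs.  Identical (config, seed) phantoms are
  bit-identical; pipeline reruns produce bit-identical CSVs.
* Percentages for table comparison are rounded half-up to two decimals;
  medians use the midpoint convention for even n.
* Degenerate inputs fail loudly with typed errors (sizing errors name the
  violated axis; a missing enamel label requests external landmarks; a
  bridge present with total 0 is an internal contract violation rather
  than silent output).

## Known limitations

* The 1-vs-2 score cut is a convention, not a published threshold; results
  at that boundary depend on it (it is configurable and logged).
* The station sweep spans the incisor-to-canine gap regardless of an
  intervening lateral incisor; segments with one are not modeled.
* Min-width measurement is sensitive to label noise at tooth–bone
  interfaces (see the phantom section); real-scan use would warrant a
  segmentation-quality check upstream.
* The power analysis inherits the independent-pairing assumption; with
  positive within-patient correlation the paired test's true power is
  higher, so the estimate is conservative.
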