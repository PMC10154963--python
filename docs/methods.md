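# Methods

## HU calibration and binning

Voxel values are assumed to be calibrated Hounsfield units from a
two-point air/water calibration: air = −1000 HU, water/soft tissue =
0 HU. The air fraction of a voxel is the affine interpolation between
those anchors (−500 HU ⇒ 50 % air); values outside the anchors are
clamped before mapping. No beam-hardening or other nonlinear correction
is modeled.

Bin schemes partition the HU axis into contiguous intervals. The
`default` scheme (`[-1000,-600,-500,-400,-300,-200,0]`, six bins) spans
aerated parenchyma up to connective tissue; `mod` splits the most
aerated range at −700 and −600 HU for extra specificity where
ground-glass change first appears; `range` builds uniform user-defined
bins, truncating the last bin when the width does not divide the span.
Printed bin lists share boundary values, so an ownership convention is
required: bins are half-open `[lo, hi)` with the final bin closed at
its top edge. This makes every scheme a true partition — each voxel
receives exactly one bin index or the explicit `OUT_OF_RANGE` sentinel,
which is reported as its own table row rather than dropped, so the
conservation check (bin counts + out-of-range = mask count, fractions
sum to 1) always holds.

## Segmentation pipeline

`segment_lung` composes five deterministic stages.

* **Threshold** `[-32768, -200]` HU, closed on both ends. The low bound
  is the int16 minimum: padding/sentinel values are treated as deep
  air, not missing data, so they cannot split the air component.
* **Connected components.** 3D labeling with face (6-) connectivity by
  default; 26-connectivity is available by flag but permits diagonal
  leakage between the lung and bowel gas, which is why it is not the
  default. Components are relabeled largest-first with ties broken by
  the lexicographically smallest first voxel, so labels are
  reproducible across runs and platforms.
* **Selection.** Seed and explicit-label modes reproduce the
  interactive "verify the label" step non-interactively. The automatic
  mode picks the largest component touching fewer than 4 of the 6
  volume faces: the exterior-air component wraps the animal and touches
  most faces, while the lung is interior. If no interior component
  exists (e.g. an all-air volume) selection fails with a message
  advising seed mode.
* **Refinement order** is erode → slice-wise 2D hole fill → dilate.
  Erosion first severs thin bridges (trachea/esophagus) before filling
  can cement them; dilation last re-includes the pleural rim. Hole
  filling is 2D per slice rather than 3D because a 3D fill cannot close
  cavities open at the stack ends, and per-slice filling matches how a
  reader validates slices.
* **Refinement radii.** Defaults are erosion 2, dilation 1 (iterations
  of the 6-neighborhood structuring element). These were chosen on the
  phantom: Gaussian partial-volume blur pulls the −200 HU isosurface
  *outward* into adjacent soft tissue, so the raw selected component is
  already ~5 % larger than the true lung and a net-dilating setting
  overshoots. A net one-voxel erosion brings volume recovery to ~2 %
  with Dice ≈ 0.98 while still covering ≥ 95 % of true lung voxels.
  On data with different edge characteristics the radii should be
  revisited; both are exposed as parameters.
* **Base crop.** The z index increases base → apex; all slices below
  the chosen base slice are zeroed. `to_apex` and `full_stack` keep the
  same voxels and differ only in the reported apex extent.

## Quantification

Volumetric measurement counts masked voxels per bin and multiplies by
the voxel volume (spacing product, mm³); per-slice ROI measurement uses
the in-plane pixel area (mm²). Both report voxel counts alongside the
physical measure so either convention of "area" is available, and both
emit `OUT_OF_RANGE` and `TOTAL` rows (`TOTAL` = in-range bins only,
i.e. the total lung tissue volume). Summing per-slice areas times slice
spacing reproduces the volumetric table exactly.

The semi-manual workflow's interpolation step re-anchors a manual 2D
ROI on offset slices. The default offsets are `[-5, +5]` — two
additional measured slices per manual slice; the source material also
describes a denser reading (every slice within ±5), so the offsets are
fully configurable. Offsets falling outside the stack are dropped with
a warning.

## Agreement statistics

Differences are `b − a`. Bland-Altman limits are the standard 95 %
limits of agreement, bias ± 1.96 × sample SD (ddof = 1); the dashed
"confidence interval" lines of the plot are these limits. Regression
agreement is ordinary least squares of b on a with Pearson r on the
same pairs; a constant predictor is rejected rather than silently
returning NaNs. Analyst deviance summarizes per-slice differences from
a reference series — the across-analyst mean by default, or a
designated expert — as median/quartiles/range, dropping slices not
shared by all analysts.

## Synthetic phantom

The phantom emulates a whole-body mouse micro-CT: a body ellipsoid with
a chest-wall shell (+300 ± 150 HU) around soft tissue (−100 ± 60 HU),
containing a two-lobed ellipsoidal lung of parenchyma (−650 ± 120 HU,
clipped to [−1000, −300]) with an embedded cylindrical airway lumen
(−950 ± 20 HU) and a spherical cardiac notch, surrounded by exterior
air (−1000 ± 10 HU). A gas pocket (−800 ± 30 HU) below the diaphragm is
placed deliberately: it passes the rough threshold, so only the base
crop (or component selection) removes it. Default grid 128×128×192 at
0.107 mm isotropic — a 1/4 linear-scale analog of a 512×512×768
scanner reconstruction, chosen so the full pipeline runs in seconds on
a desktop; dimensions, spacing and seed are parameters.

Noise is independent Gaussian per voxel (class-specific SD, scalable by
`noise_scale`), followed by a Gaussian blur of σ = 0.6 voxels for
partial-volume averaging — the simplest model that spreads lung voxels
across neighboring HU bins the way real parenchyma does. The ground
truth is the exact pre-blur parenchyma + intra-lung-airway voxel set.
The `fibrotic` preset shifts the parenchyma mean to −450 HU and shrinks
the lung axes by 15 %, reproducing the qualitative injury signature
(smaller aerated volume, right-shifted histogram); it makes no claim to
the magnitude of any real treatment effect.

What the phantom does *not* emulate: airway trees, lobar fissures,
cardiac/respiratory motion, beam hardening, reconstruction artifacts,
or anatomically realistic tissue texture. Passing the phantom tests
therefore demonstrates the correctness of the algorithmic chain (and
its determinism), not reader-level performance on real scans.

Simulated "manual" ROIs perturb a true lung slice by a random
morphological jitter (erosion/dilation up to ±1 voxel by default),
emulating boundary disagreement between readers; at default noise six
readers' areas vary with CV < 15 %.

## Numerical and degenerate-input choices

* HU are held as float32 in memory regardless of on-disk type; int16
  and float inputs are accepted, DICOM rescale slope/intercept applied.
* The DICOM writer stores rounded int16 values; integral volumes
  round-trip exactly. DICOM slice spacing must be uniform within 1 %.
* CSV floats are written with 9 significant digits so tables re-parse
  to within 1e−9.
* Empty masks: labeling an empty mask yields zero components;
  refinement raises naming the stage that emptied the mask; measurement
  of an empty selection reports zero counts and zero fractions (no 0/0).
* Test problem sizes: the default phantom (128×128×192) for recovery
  and agreement checks, 48×48×72 for I/O and CLI round trips, and 50
  random 8×8×8 grids against the brute-force flood-fill oracle.
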