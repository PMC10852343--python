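# Methods

This note documents the measurement model the package implements, the
conventions chosen where the procedure it reimplements left details open,
what the synthetic scenes do and do not emulate, and the problem sizes
used by the shipped tests and the acceptance script.

## The measurement pipeline

All measurements operate on raw stored intensities (arbitrary fluorescent
units, AFU); nothing is normalised, so every threshold is on the
instrument scale. Coordinates are row-major, 0-based, origin top-left.
No operation mutates its inputs; every derived mask is a new object.

Per section, in order:

1. **Tissue mask.** The pan-neuronal marker channel (PGP9.5) is
   Gaussian-smoothed (σ = 3 px), thresholded and hole-filled. The mask
   depends only on that channel; its pixel area is the denominator of the
   T-cell density.
2. **Neuron instances.** 8-connected components of supra-threshold
   neuron-marker signal, gated by equivalent-diameter (default 8–60 μm)
   and mean intensity. Nerve fibres — long thin ribbons of marker
   signal — are rejected by shape: eccentricity > 0.97, or skeleton
   length exceeding 5× the component's mean width (area / skeleton
   length). No watershed splitting of touching somata is attempted; the
   synthetic scenes guarantee separation, and real-image instance
   splitting is out of scope.
3. **Shrink (4 px).** Each instance is eroded independently by a
   Euclidean disc of radius 4, so the border offset is isotropic. This
   keeps perisomatic (satellite glial) signal out of the somatic MPI.
   Erosion is computed as `EDT(mask) > k` with out-of-frame pixels
   treated as background; instances eroded to extinction are dropped with
   a log entry. The exhaustive distance-definition oracle in the test
   suite checks this operator bitwise.
4. **Non-neuronal MHCII mask + Grow (7 px).** Components with MHCII
   ≥ 25,000 AFU and immune-cell size (default 5–15 μm equivalent
   diameter) are dilated by a disc of radius 7 to capture their
   low-intensity fringe. Where grown instances would overlap, pixels go
   to the nearest seed; exact distance ties go to the smaller label, a
   fixed rule that makes the output reproducible bitwise.
5. **Logical exclusion.** Grown non-neuronal pixels are subtracted from
   the shrunk neurons. The surviving pixels are the neuron's *measurable*
   set; a fully covered neuron is flagged unmeasurable and drops out of
   both numerator and denominator of every positive fraction (it carries
   no intensity evidence either way).
6. **MPI and classification.** MPI is the arithmetic mean of a channel
   over the measurable pixels. MHCII positivity uses a threshold computed
   from isotype-control sections: the 99th percentile — linear
   interpolation between order statistics, position `1 + 0.99·(n−1)` —
   of the per-neuron MPI distribution pooled across the isotype
   sections. All positivity comparisons are strict `>`, matching the one
   printed comparator in the source workflow (the RFX1 rule); an MPI
   exactly at the threshold is negative. By construction, applying the
   threshold back to its own reference population flags ≈1% positive.
7. **Puncta.** Per neuron, local background is the *median* MHCII over
   the measurable pixels — robust to the puncta themselves (a cell 90%
   at 1000 AFU with 10% puncta at 2500 has median 1000 where the mean
   would be 1150). Puncta pixels satisfy
   `intensity ≥ background + 800 AFU` per pixel; 8-connected components
   with area ≥ ⌈1.5⌉ = 2 px count. The `≥1.5 px` rule is stated over
   integer component areas, so 2 is the smallest admissible size. Percent
   puncta area divides the summed puncta area by the neuron's *total*
   (pre-shrink) area. The offset is read as a per-pixel criterion, not a
   component-mean one; an annulus background estimator (median over a
   5-px outside ring) is provided as a sensitivity switch.
8. **Polarization (cultured cells).** Polarized pixels carry
   ≥1.7-fold the local background, in components of ≥2 px; the score is
   100 × polarized area / cell area. A zero background with nonzero
   signal leaves the fold undefined; it is scored against a 1 AFU floor
   with a warning.
9. **T cells.** CD3 and CD4 components are detected independently (size
   and intensity gates); a CD3 component is a CD4⁺ T cell when ≥50% of
   its pixels lie in CD4 components (robust to small channel
   registration error) and its centroid falls inside the tissue mask.
   Density pools counts over pooled tissue area across a mouse's
   sections — the ratio of sums, not the mean of per-section ratios —
   which is unbiased when sections differ in area.
10. **RFX1.** DAPI components are size/intensity-gated; a nucleus is
    neuronal iff its centroid lies inside a neuron instance. Each neuron
    with a neuronal nucleus gets a nuclear RFX1 MPI; positivity is strict
    `>` against a fixed cutoff (config default 37.19 AFU). Only neurons
    with a visible nucleus enter the RFX1 fraction.
11. **Morphometry.** Diameter = 2·√(area·k/π) with k the pixel-area
    conversion (default 6.718 μm²/px). Small ≤25 μm, large >30 μm; the
    25–30 μm band is reported as "intermediate" rather than forced into
    either class, because the two printed cutoffs do not meet. The
    diameter fit is a single-Gaussian ML fit (sample mean, sd with
    ddof = 0) intended for one size population at a time; the overall
    bimodality is handled by the size classes, not by mixture modelling.
12. **Summaries.** The mouse is the analysis unit: neurons pool within
    mouse, mice average within group (mean ± SEM; SEM blank for one
    mouse). Positive fractions are pooled counts over pooled neurons.
    Inferential statistics are out of scope; the emitted long-format
    tables are designed to feed standard routines.

Thermal place preference scoring is independent of imaging: percent =
100 × seconds on the test plate / trial length (default 180 s); a mouse
below 30 s on the test plate at habituation (strict `<`) is excluded and
its test trials are dropped.

## The synthetic scenes

Scenes exist so that each stage can be verified against known truth.
A section scene renders, on a 768×768 frame at 0.42 μm²/px:

* an elliptical tissue patch (50% of the frame) at 1,500 AFU in the
  neuron-marker channel;
* 35 small + 15 large somata as ellipses (axis ratio 0.8–1.0) with
  truncated-normal diameters — small N(18, 3²) on (8, 25] μm, large
  N(38, 4²) on (30, 60] μm — at 10,000 AFU marker intensity. Fifty
  somata per scene makes a 20-scene study pool 1,000 neurons;
* a Bernoulli fraction of MHCII⁺ somata (default 0.30; the two-condition
  study plants 0.25 and 0.55) carrying 4,000 AFU MHCII plus 4–12 puncta
  of 2–6 px at +1,200 AFU, placed ≥6 px inside the border and ≥2 px
  apart so a 4-px shrink cannot clip them and components never merge;
* 8 immune cells (10 μm discs) at 28,000 AFU MHCII — seven-fold the
  neuronal level, above the 25,000 AFU gate;
* 4 CD3⁺CD4⁺ T cells and 3 CD3-only cells (8 μm discs, 12,000 AFU).
  Four cells over ≈0.124 mm² of tissue plants a density ≈32/mm², the
  order reported for infiltrated DRG;
* one DAPI nucleus per soma (0.45× soma diameter, clamped to 4.5–13 μm)
  plus 15 free non-neuronal nuclei; nuclear RFX1 at 600 AFU for a 0.40
  Bernoulli fraction of somata, 0 otherwise;
* additive Gaussian noise (sd 100 AFU — one eighth of the 800 AFU
  puncta offset, the study's default signal-to-noise condition), clipped
  to the 16-bit container and rounded.

Isotype scenes share their seed's exact geometry but render only noise in
the MHCII channel. Culture scenes render 12 isolated somata with uniform
surface signal (2,000 AFU); half of them concentrate a polar cap — the
12% of the cell's pixels furthest along a random direction — at 2.0-fold
base, comfortably above the 1.7-fold gate. The truth table records each
cell's realised cap fraction.

Placement is uniform rejection sampling with a 2-px minimum gap
(objects never touch). One integer seed drives the whole scene;
identical seeds give bitwise-identical images.

**Resolution choice.** The scenes are rendered at 0.42 μm²/px
(≈0.65 μm/px) rather than at the 6.718 μm²/px morphometry conversion
scale. At 2.6 μm/px a 4-px border erosion spans 10.4 μm and would consume
every small (≤25 μm) soma, and sub-cellular puncta could not occupy two
pixels — no self-consistent scene exists at that sampling. The coarse
constant is retained as the default *conversion* in `MorphometryParams`,
where it only scales areas to physical units; each synthetic scene uses
its own pixel size consistently end to end.

**What the scenes do not emulate** — and therefore what passing tests do
not demonstrate about real images: optics (no PSF, uniform focus),
touching or overlapping somata, satellite-glial rings around neurons,
immune cells directly abutting somata (they are kept ≥12 px away so the
grown exclusion mask cannot clip planted puncta; the exclusion logic
itself is tested on constructed geometry), intensity gradients,
autofluorescence structure, and 3D effects. Real-image use requires
calibrating the per-channel thresholds (the symbolic ones default to
Otsu, all overridable with absolute AFU values in the config) and
accepting that touching-cell separation is out of scope.

**Intensity scales** are chosen for signal-to-noise realism, not to match
any instrument's absolute AFU values: all recovery tests compare against
planted truth, never against absolute published intensities. For the
same reason the synthetic RFX1 scale (600 vs 0 AFU, scene threshold 300)
departs from the fixed 37.19 AFU config default, whose provenance on the
original instrument scale is unknown.

## Numerical conventions

* Percentile: linear interpolation between order statistics ("type 7"),
  the common default, fixed for reproducibility.
* Connectivity: 8-connected components everywhere, fixed.
* Shrink/Grow structuring element: the Euclidean disc
  {offsets with ‖·‖ ≤ k}; grow ties resolve to the smaller label at
  exactly equal distance.
* Degenerate inputs: constant channels resolve Otsu to an empty mask;
  neurons under 25 measurable pixels are flagged and not puncta-scored;
  diameter fits reject n < 10 and sd = 0 samples; densities require
  positive tissue area.
* Puncta *count* is not monotone in the intensity offset (lowering the
  offset can merge two spots into one component); the total puncta
  pixel area is, and the tests assert exactly that.

## Problem sizes

The default test suite and `scripts/acceptance.py` use 768² scenes with
50 neurons each: 20 stained scenes (10 per planted condition), 10
isotype sections (500 reference neurons), and 6 culture fields (72
cells); oracle equivalence runs on 200 random masks ≤40×40 px
(morphology, bitwise) and 100 random neurons ≤50×50 px (puncta,
identical pixel sets). The noiseless-recovery check verifies neuron
count, per-neuron area, puncta counts and percent areas, T-cell count
and RFX1 calls *exactly* against the truth table on a full default
scene.

## Known limitations

* No instance splitting of touching somata and no machine-learned
  segmentation; crowded real sections will undercount.
* The fibre filter is a shape heuristic; fibres thicker than ~1/5 of
  their length, or genuinely elongated somata, can be misrouted.
* Per-neuron MPI ignores within-cell spatial structure beyond the
  puncta/polarization metrics.
* `grow_mask` computes one distance transform per instance; it is meant
  for the handful of immune-cell instances per section, not for
  thousand-instance masks.
* Behavioral scoring consumes timed plate-occupancy logs; it does not
  track video.
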