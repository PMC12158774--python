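# Methods

This note documents the models and procedures implemented in `synaptomap`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Detection chain

A molecular channel (immunolabelling or deep-learning prediction map) is
converted to point annotations in six steps.

1. **Contrast rescale.** Intensities are mapped linearly from
   [lo, P(hi)] to [0, 1] and clipped. `lo` defaults to 101 counts, the
   camera offset of the sCMOS detector (the background sits "around 100"
   counts; 101 is the operating value of the detection chain). The upper
   percentile is marker- and z-step-specific (see the preset table below).
   Percentiles use linear interpolation over all voxels. A degenerate range
   (everything at or below `lo`) yields an all-zero volume with a warning
   rather than an error: an empty channel is valid input.
2. **Difference-of-Gaussians background subtraction.**
   G(σ_signal) − G(σ_background), negatives clipped to zero. Sigmas are
   isotropic in *voxel* units (the operating parameters are stated in
   voxels), with reflective boundaries. The relatively large σ_signal
   deliberately merges the lattice of presynaptic puncta into one blob per
   synapse, avoiding oversegmentation of a single active zone.
3. **Otsu binarization** over a 256-bin histogram spanning the data range.
   The threshold returned is the *upper edge* of the optimal split bin, so
   `value > threshold` reproduces the bin partition exactly. This matters
   when Otsu runs on a short list (the structural gate below): with the
   usual bin-centre convention, a cluster of values sharing one bin can be
   cut in half. Degenerate input (a single distinct value) produces an
   empty foreground for volume thresholding, but "keep everything" for the
   gate — silently discarding all detections would be the worse failure,
   and the condition is logged.
4. **26-connected component labelling** (full 3D connectivity).
5. **Structural gate.** For every region the maximum of the underlying
   structural (pan-protein) channel is recorded; immunolabelling background
   over dim structural regions separates from synaptic signal over bright
   features as a bimodal distribution, split again by Otsu. Regions below
   the split are flagged `unspecific` and retained (never deleted) so
   downstream validation can inspect them. The gate runs *before* the size
   filters, matching the narrated operator order.
6. **Size / z-extent filter and centroids.** Regions under 60 voxels or
   spanning fewer than the preset number of z planes are flagged with their
   failure cause. Surviving specific regions become points at their
   structural-intensity-weighted centroids (unweighted fallback when all
   weights are zero). z-extent is the bounding-box span in planes, which
   for a 26-connected region equals the number of distinct planes touched.

Parameter presets, keyed by (marker, imaging z-step):

| marker  | z step | upper pct | σ_signal/σ_bg | min z planes |
|---------|--------|-----------|---------------|--------------|
| bassoon | 300 nm | P99.5     | 5 / 11        | 13           |
| SHANK2  | 300 nm | P99       | 4 / 11        | 13           |
| bassoon | 200 nm | P99.95    | 6 / 10        | 14           |
| SHANK2  | 200 nm | P99       | 6 / 12        | 12           |
| SHANK2  | 400 nm | P99       | 6 / 12        | 12           |
| bassoon | 400 nm | P99.95    | 6 / 10        | 12           |

`min_voxels = 60` everywhere. The bassoon/400-nm row is not covered by a
stated preset; it reuses the 200-nm contrast and DoG settings with the
shared 400-nm plane minimum, and remains configurable. Note the upper
percentiles presuppose a roughly physiological synapse density (~1 µm⁻³):
in a volume with much sparser signal, P99.5 of a bassoon channel falls into
the background and the rescale degenerates. Synthetic test scenes therefore
hold density near 1 µm⁻³.

Two variants share the primitives: `detect_simple` (gephyrin-style
channels) replaces the structural gate with a binary opening (ball radius
2) and uses self-weighted centroids — whether the original workflow
weighted gephyrin centroids by the structural channel is not stated, and
self-weighting is the conservative reading; `predmap_to_points` (prediction
maps) rescales to [P1, P99.95], blurs with σ = 5, and filters at
60 voxels / 13 planes without a gate (prediction maps carry no non-specific
immunolabelling). `make_training_target` produces the soft target maps for
training such predictors: the gated binary mask of specific regions blurred
with σ = 1 voxel, plus a min-max-normalized 8-bit structural companion.

## Synapse assembly

Point distances are Euclidean in voxel-index space — the cutoffs
(*d*_matching, *r*_matching, both 30 voxels) are defined in voxels — and nm
distances are reported alongside for interpretation. Pairing is two passes
of a nearest-first rule over the cost matrix S_ij: (1) every post point
takes its nearest pre if S < d_matching (each post ≤ 1 edge; a pre may
collect several, the 1:2 motif); (2) every pre still floating takes its
nearest post under the same cutoff, even if that post is already paired
(the 2:1 motif). Nothing else is connected, which is what distinguishes
this from "connect everything within d_matching". Ties break to the lowest
point index; the cutoff is strict (`<`). A pass-2 pre may attach to a post
that already holds another pass-2 edge; the rule does not forbid it.

**Rescue.** Unpaired rows/columns of M_ij trigger a local search in the
structural channel: a 100³-voxel box (truncated at volume edges) is cropped
around the seed, rescaled to [P1, P99.95], DoG-filtered (σ = 2/10), and
thresholded at thr = p95 + c·(p100 − p95) with c = 0.4 (a 0.5 variant is a
config value; both coefficients appear in practice and the structure of the
data does not determine which dataset used which). The percentiles are
taken over the background-subtracted crop — thresholding follows background
removal in the processing narrative — with a `raw` switch provided. Voxels
already claimed by existing detection label volumes are zeroed (the literal
"inverted segmentation" reading, no dilation), the mask is opened with a
ball of radius 2, components under 20 voxels dropped, and a
structural-weighted centroid is accepted as a new *opposite-kind* point iff
it lies within 30 voxels of the seed. Existing detections are never
removed; pairing is re-run on the augmented lists.

## Validation

Point-level scoring builds the cost matrix C_ij of Euclidean distances,
replaces entries above *r*_matching with a 10⁶ sentinel, and solves the
linear assignment problem; any realized pair above the cutoff is dissolved
into FP + FN (the sentinel guard). A full-synapse edge is TP iff both
endpoints are point-level TPs *and* their assigned ground-truth points are
connected; otherwise the edge is one FP (an edge failing several rules is
not double-counted). Ground-truth edges without a TP counterpart are FNs.
Border revision promotes an FN to TP iff it is matched against the
unfiltered detection list, unmatched against the filtered one, and its
ground-truth z lies in the first or last 10 planes — recovering synapses
whose regions were cut by the z-extent filter at volume borders.
Precision/recall/F1 use the 0-on-empty-denominator convention. Reported
percentages round half-up at the printed precision (`round_half_up`), so
worked-example arithmetic is exact.

## Segment mapping

A point is assigned to the non-zero segment at its rounded coordinate, or
else to the nearest non-zero voxel *in its own z plane* within a 20×20
neighbourhood, accepted when the in-plane squared distance is below
30 voxel² (the literal printed constant, ≈ 5.48-voxel radius) and, when
class checking is on, the segment class matches the synaptic side
(pre→axon, post→dendrite). Ties break to the lowest segment id.
Per-segment synapse tables dilate the segment mask with a ball of radius 6
(5 accepted) and select detections inside. Assignment is purely local, so
patch-wise processing is exactly equivalent to whole-volume processing.

## Distortion statistics

The expansion factor is the scale of the closed-form least-squares
similarity fit (Umeyama) between pre- and post-expansion landmarks;
rotation is constrained to det +1, and degenerate (collinear or duplicated)
configurations raise. The affine fit is ordinary least squares. The elastic
registration that produces dense displacement fields is out of scope here:
fields are inputs, from file or from the phantom generator. The
measurement-error curve samples both endpoints of each pair independently
and uniformly over the mask (2×10⁵ pairs by default), computes
|Δu| = |u(p₂) − u(p₁)| per pair, and bins by pre-vector length in 1-px bins
(bin width configurable; the original binning is unstated). RMS is taken
over per-bin means. The σ = 1/6/16 image smoothings applied before
registration are preprocessing of the registrar's inputs and are
documented, not implemented, here.

## Synthetic scenes

`synthgen.generate_scene` renders three channels at a default effective
voxel size of 9.7 × 9.7 × 19.4 nm³ (axis order z, y, x):

- per synapse, a presynaptic cluster of 2–5 Gaussian puncta on a hexagonal
  lattice in the active-zone plane, spacing ~N(97, 28) nm truncated at
  50 nm (dense projections are ~80-nm bodies and cannot interpenetrate);
  punctum σ = (45, 35, 35) nm, i.e. the nanocluster size convolved with the
  ~20/50-nm lateral/axial effective PSF;
- a PSD disc (radius 150 nm, Gaussian thickness σ = 60 nm, soft 30-nm edge)
  offset ~N(154, 19) nm along the synapse axis, rendered into the
  postsynaptic marker channel and (with the presynaptic features) into the
  structural channel over a smoothed-noise background;
- non-specific molecular blobs (antibody aggregates, 1.2–2.2× punctum
  size) placed only where the structural channel carries essentially no
  feature light, so the structural gate receives a cleanly bimodal input —
  they are the designed foil for the gate;
- camera offset 100 counts and optional noise: Poisson shot noise on the
  signal plus Gaussian read noise (σ = 3), or Gaussian only.

Synapse centres are dart-thrown with a 600-nm minimum separation, and the
synapse axis is resampled until each PSD centre clears neighbouring PSDs by
450 nm — PSDs of distinct synapses do not abut, and without this constraint
two discs occasionally merge into one detected region (undersegmentation,
a known failure mode of the real pipeline rather than a property worth
planting in every scene). Requested motif fractions (1:1, 1:2, 2:1) are
honoured exactly via largest-remainder allocation. One RNG stream drives
placement and separate streams drive noise and non-specific placement, so
toggling noise does not reshuffle geometry; scenes are bit-reproducible
from the seed. Distribution shapes are a choice: means and s.d.s are
measured quantities, and zero-truncated normals are assumed.

What the generator does *not* emulate: neurite morphology (the structural
background is smoothed noise, not membranes), marker copy-number variation
and epitope loss (except via the explicit `drop_post_marker` list), depth-
dependent aberrations, stitching seams, and segmentation errors. Passing
end-to-end tests therefore demonstrates correctness of the operator chain
under the stated geometry and noise, not real-data accuracy — the real-data
F1 benchmarks (0.90–0.95) live on teravoxel volumes that are not packaged.

The end-to-end checks run on a 3.7-µm cube with 50 synapses
(≈ 1.0 µm⁻³, the physiological density the detection presets assume) with
noise off and with Poisson–Gaussian noise; the rescue check uses a 2.5-µm
cube with 15 synapses, one of which lacks its postsynaptic marker. These
problem sizes keep the whole suite within a few minutes on one CPU while
exercising every stage at full parameter fidelity.

## Known limitations

- The structural gate assumes a bimodal distribution of per-region
  structural maxima; volumes with no non-specific background (e.g. clean
  prediction maps) should use the ungated variants, as a forced Otsu split
  on unimodal input will discard valid detections.
- Otsu on short lists is sensitive to far outliers; with only a handful of
  regions a single extreme maximum can dominate the split.
- Rescue candidate acceptance uses only distance-to-seed; in extremely
  dense neuropil, a bright feature of an unrelated synapse inside the
  accept radius would be adopted.
- `measurement_error_curve` looks displacement vectors up at integer pixel
  positions (no interpolation), adequate for smooth fields at the sampled
  scales.
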