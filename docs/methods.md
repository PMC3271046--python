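# Methods

## Non-informative frame detection

The detector exploits a compression argument: an image with few edges is
easy for DCT-based codecs to compress because its spectrum is narrow, with
energy condensed in the low-order harmonics. Motion blur, defocus and lens
contamination all remove edges, so spectral sparsity is a proxy for
diagnostic uselessness without needing to localize any edge.

Pipeline per frame:

1. colour frames are reduced to luminance (ITU-R BT.601 luma,
   `0.299 R + 0.587 G + 0.114 B`). The broadcast luma was chosen over HSV
   value; since the decision threshold is trained downstream, the choice of
   greyscale convention is recoverable and only needs to be frozen.
2. the luminance is resized bilinearly to `working_size x working_size`
   (default 256). A raw non-zero count depends on resolution; fixing the
   size and reporting a *fraction* makes both the magnitude cutoff and the
   trained threshold portable across cameras.
3. the single full-image orthonormal 2-D DCT-II is taken (`scipy.fft.dctn`,
   `norm="ortho"`), not 8x8 JPEG blocks. Orthonormal scaling must be stated
   because the magnitude cutoff is only meaningful under a fixed
   normalization.
4. coefficients with magnitude below `magnitude_threshold` (default 20) are
   zeroed and the surviving fraction is the frame's score.

Classification is `informative iff fraction >= decision_threshold`; the
boundary case counts as informative. The threshold is fitted by sweeping
candidates (0, 1, and midpoints between consecutive distinct training
fractions) and maximizing F-measure with non-informative as the positive
class; ties go to the larger threshold, i.e. the more blur-sensitive model.
When `train_decision_threshold` is given a `split_seed`, the data are first
split evenly at random and the fit uses the training half only, with
held-out metrics reported alongside; without a seed the provided examples
are the training set.

The magnitude cutoff of 20 is exposed in config: it was tuned on clinical
material of unknown resolution and DCT normalization, so absolute
comparability is not guaranteed and re-tuning (or just re-training the
decision threshold, which compensates in practice) is expected on new
sources.

## Bifurcation detection

Down the bronchoscope axis the airway lumen is a large non-illuminated
region; a branching view shows two or more. Steps, on the luminance:

- binary mask = complement of luminance thresholded at
  `255 - dark_threshold` (equivalently luminance <= `dark_threshold`,
  default 40 — lumen interiors are near-black);
- morphological opening (dilation of the erosion) removes speckle, then
  closing (erosion of the dilation) fills pinholes; both use a disk of
  radius `se_radius` (default 5 px). Opening-before-closing is a frozen
  ordering choice: speckle first, holes second;
- 8-connected labelling (fixed for reproducibility), then regions with area
  >= `min_area_fraction` (default 1%) of the frame are kept, sorted by area
  descending. Area, not diameter, operationalizes "large": it needs no
  second parameter;
- `is_branching` = at least two surviving regions.

Non-informative frames are never passed to this detector: blur destroys the
dark-region geometry, and the pipeline orders classification first.

## Summary assembly

Inclusion criteria: physician annotations, treatment markers, lesion tags
(consumed as input annotations; lesion *detection* is out of scope),
detected branching views, and representative samples of the informative
material in between. Exclusion criterion: non-informative frames.

Budget: `round(max(frame_count / ratio, min(min_summary_seconds * fps,
frame_count)))` with `ratio = 12` (one minute of source per five seconds of
summary) and `min_summary_seconds = 30`. The floor is capped at the source
length, so a 10-second video yields at most a 10-second summary; a 60-second
source is lifted to the 30-second floor; a 600-second source gets the pure
twelve-fold reduction (50 s).

Shot building: for each tag class, maximal tagged runs among informative
frames are padded by `pad_frames` (default 12, about half a second at
25 fps) on each side — padding extends only through informative frames,
never resurrecting excluded ones — and runs separated by an informative gap
shorter than `merge_gap_frames` (default 12) merge. Merging across a gap
containing non-informative frames is refused for the same reason. Every
frame then takes its single highest-priority class, in the order
`annotation > marker > lesion > branching`: explicit physician input
outranks automatic detections, and the weights are configurable in spirit
by reordering. Untagged informative stretches become `representative`
segments.

Selection: priority classes are admitted in order, shots within a class
temporally; a shot that would overflow the budget is truncated symmetrically
about its centre and admission stops. When the priority material alone
exceeds the budget, lesion shots longer than `lesion_core_seconds`
(default 2 s) are first thinned to their central core — the intermediate
frames of a lesion shot are its most representative. Leftover budget is
spread over representative segments by *deterministic centred subsampling*:
each segment contributes a centred sub-shot proportional to its length, with
a one-frame minimum per segment while budget allows, topped up in temporal
order until the budget is exactly met. Determinism was chosen over random
sampling so identical inputs always produce identical summaries.

Consequences provable from the construction and asserted by tests: EDL shots
are sorted and disjoint; total length never exceeds the budget and equals it
(within one frame) whenever enough material exists; no non-informative frame
appears unless the `--keep-noninformative` override is set; and reducing the
budget never drops an annotation shot while lower-priority material remains.

## Synthetic data

The generator emulates exactly the image features the two detectors key on,
not bronchial anatomy:

- **wall texture**: seeded band-pass filtered Gaussian noise (difference of
  Gaussians, sigmas 0.6 and 4.0 px), scaled to std 28 around a mean of 175,
  under a mild radial vignette (factor 1 down to ~0.78 at the corners). The
  band-pass guarantees rich mid/high-frequency DCT content, standing in for
  mucosal texture;
- **lumina**: 1-3 non-overlapping disks of radius 0.10-0.14 x size with
  interior luminance <= 15, pairwise separated (edge to edge) by at least
  the larger radius, placed by rejection sampling — a placement failure
  raises rather than degrading the margin;
- **non-informative counterparts**: Gaussian blur with reflected boundaries,
  sigma in [6, 12] for fixtures — gross blur well beyond focus jitter, while
  still leaving the task non-trivial at sigma 6;
- **scripted videos**: segment kinds `sharp_single_lumen`,
  `sharp_bifurcation`, `blurred`, `lesion_tagged`; frames are rendered
  lazily and deterministically (per-frame seeds derived from the script
  seed), the ground-truth track marks blurred segments non-informative and
  bifurcation segments branching, and each lesion segment carries one lesion
  annotation at its central frame.

Under the default parameters the sharp and blurred score distributions are
disjoint by a wide margin (fractions around 0.3 versus below 0.01), which is
asserted as a property. This is deliberate: it licenses reading the
benchmark metrics as *lower bounds* the implementation must meet, but it
also means a perfect benchmark score says nothing about clinical frames,
where the two classes genuinely overlap (partial blur, secretions,
specularities). The generator also omits specular highlights, bleeding and
secretions entirely, so false dark regions and texture-free bright patches —
both real failure modes — are not represented.

One measured caveat: very strong blur does not empty the thresholded
spectrum as fast as a texture-only argument suggests. The lumen/vignette
macrostructure (about 100 grey levels of swing) keeps roughly a dozen
low-order coefficients above magnitude 20 at sigma = size/4; the spectrum is
down to <= 3 surviving coefficients only around sigma = 0.75 x size.

## Evaluation protocol

`run_benchmark(n_per_class, seed)` generates `n_per_class` sharp frames and
as many blurred counterparts (sigma uniform in [6, 12], lumen counts cycling
1-3), pools them, splits evenly at random (extra item to the training half
when odd), trains the decision threshold on the training half and reports
both halves. Reported metrics, with non-informative positive:

- sensitivity tp/(tp+fn);
- `precision_as_paper_specificity` tp/(tp+fp) — precision, reported under
  this explicit name because published tables for this task have printed
  this formula under the heading "Specificity";
- `specificity_standard` tn/(tn+fp);
- accuracy (tp+tn)/n;
- F-measure 2PR/(P+R), the standard F1 (with P = R = 0.93 this reproduces a
  printed 0.92, which a harmonic mean lacking the factor 2 cannot).

Zero-denominator metrics are reported as undefined (`None`) with a warning,
never coerced to 0, so degenerate classifiers cannot pass silently.

Default problem sizes — 200 frames per class for the benchmark, 256-px
frames, 50 scripted tracks for the summarizer property suite — keep the
whole test suite under a minute on one core while leaving every split and
sweep statistically non-degenerate.

## Known limitations

- The DCT detector is a global blur score: a frame sharply focused on one
  half and smeared on the other scores mid-range, and localized
  uselessness (a secretion blob over the lesion) is invisible to it.
- The branch detector counts dark blobs; mucus pools, deep shadows or a
  partially occluded lumen can mimic or hide openings. No attempt is made
  to estimate bronchial-generation depth or match branch points to the
  anatomic tree.
- Frame rate metadata for image-sequence sources defaults to 25 fps
  (PAL-region clinical equipment) and must be overridden when wrong, since
  the budget floor is specified in seconds.
- Container-file decoding requires an imageio backend for the format;
  PNG/JPEG image sequences are the always-available path.
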