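# Methods

This note documents the models, conventions and numerical choices behind
`hydroseg`, the assumptions they rest on, and what the phantom-based tests
do and do not establish about real data.

## Coordinate and intensity conventions

Arrays are indexed `(slice, row, col)`, 0-based, origin at the top-left of
each slice. Frames default to 324 rows × 384 columns. Intensities live on
a 0–1000 scale so that the standard 400/1000 display window (level/width)
used when annotating hydrops MRI maps meaningfully onto them.

The per-side crop windows are 100×100 pixels anchored at reference points
`[215, 238]` (left ear) and `[204, 92]` (right ear). Whether such
reference pairs read (row, col) or (x, y), and whether they name the
window's corner or its center, is not a universal convention, so both are
configuration options on `CropSpec`. The default is **(row, col), top-left
corner**: it is the only reading under which both default windows lie
fully inside a 324×384 frame with the 8-pixel slack that shift
augmentation requires, and it places the two windows on opposite lateral
halves of the frame, as paired inner ears demand. (Under a (col, row)
reading the left window would extend to row 338 of a 324-row frame.)

## Derived images and the EH ratio

`HYDROPS = PPI − PEI` and `HYDROPS-Mi2 = HYDROPS × MRC` are computed in a
signed wide representation (int64 for integer inputs, float64 otherwise)
and never clipped: the negative values *are* the signal, and they must
survive to the ratio stage. The EH ratio of a segmented region is the
count of strictly negative HYDROPS-Mi2 pixels over the region size.
"Negative" is read strictly (< 0): zero-valued pixels count as
non-endolymph. An empty segmentation makes the ratio undefined and raises
an error rather than returning 0; predicted masks that contain no pixels
of an organ are reported as missing, not as ratio 0. The ratio depends
only on signs, so it is invariant to any strictly positive rescaling of
the image — a property the test suite asserts.

## Phantoms

The phantom generator emulates the statistical structure the pipeline
relies on, not inner-ear anatomy:

* Each organ is a parametric shape inside its crop window — the cochlea a
  set of nested annular arcs (a topological proxy for the basal, middle
  and apical turns), the vestibule an ellipse — with jittered centers and
  a through-plane size profile that peaks at the central slice. Shapes
  keep a margin larger than jitter + shift range, so masks are never
  truncated by augmentation recropping; violations raise a sizing error.
* The endolymph subregion is carved out of each organ by ranking a
  smoothed Gaussian random field inside the organ and taking the lowest
  `round(f·area)` voxels, where `f` is the requested fraction. The
  subregion's shape therefore varies between subjects while its area is
  exact to one pixel — the source of the "within 1/area" recovery
  guarantee.
* Intensities: background 100, perilymph 800 on PPI, endolymph 800 on
  PEI, fluid 900 on MRC, additive Gaussian noise (default SD 20) clipped
  to [0, 1000]. Real acquisitions publish no intensity statistics for
  these sequences, so these are package choices, fixed once; only the
  *sign structure* (PPI − PEI < 0 exactly on endolymph before noise) is
  load-bearing.
* Cohorts sample per-organ fractions uniformly (default 0.1–0.6), choose
  one organ of interest per side, flag the other organ visible with
  probability 0.7, and assign each (subject, side) to the fully-annotated
  pool with probability 0.3 — matching the roughly 30/70 split of fully
  vs selectively annotated patches in clinical practice for this
  protocol.

What phantoms do **not** emulate: MR physics, bias fields, partial-volume
effects, anatomical shape variation, or inter-sequence misregistration.
Passing phantom tests shows the *pipeline* is correct (arithmetic, label
bookkeeping, training loop, statistics), not that the segmentation
network reaches clinical accuracy on real MRI.

## Augmentation

Three scales with exact multiplicities per original patch: low 144
(geometric only), moderate 1,584 (× 11 brightness offsets, −50…50 step
10), high 14,544 (× 101 offsets, step 1). The geometric count decomposes
as 2 flip states × 9 directional shift states (center + 8 compass
directions) × 8 sampled offsets per state, with shift magnitudes bounded
by 8 pixels in the Chebyshev norm. This decomposition is the only one
consistent with the printed counts and the nine directional states, but
the per-direction sampling detail is inferred, so it remains
configurable. Shifts are drawn once from a seeded generator at
dataset-build time and frozen — epochs see a fixed augmented set.
Geometric transforms apply identically to image and mask; a horizontal
flip swaps left/right class labels (the anatomy is mirror-symmetric);
brightness shifts apply to the image only, on raw intensities before any
normalization, clipped to [0, 1000]. Because network inputs are
per-patch min-max normalized, an unclipped brightness shift is absorbed
by normalization; its effect enters only through clipping. The augmented
set is a lazy sequence (geometric variants stored once, brightness applied
on access), so building it at any scale is cheap while indexing remains
exact.

## Segmentation network

The encoder is the convolutional front of VGG-19 — 3×3 convolutions with
channel plan 64-64 / 128-128 / 256×4 / 512×4 / 512×4 and 2× max-pools at
the block boundaries — truncated at `encoder_depth` convolutions
(default 15, i.e. through the third convolution of the fifth block),
followed by three added 3×3 convolutions with dropout. The decoder is
three transposed convolutions restoring the input size exactly (explicit
output sizes handle odd dimensions from pooling), with two skip
connections: the decoder's two intermediate stages concatenate the
encoder features whose spatial sizes match — by default the pre-pool
features of the two deepest pooling stages. Which encoder layers the two
skips tap is configurable (`skip_taps`) because the choice is not forced
by the architecture's description; the default is the geometry-matching
one.

* **3into3**: three parallel encoder streams, one per slice of a
  three-slice triplet centred on the slice of interest (boundary slices
  replicate the main slice). Each stream runs its own encoder and added
  convolutions; the resulting feature maps are summed before the decoder.
  Streams have independent weights by default; `share_streams=True` ties
  them (with tied weights and identical inputs the fused feature is
  exactly 3× one stream's, which the tests use as an oracle).
  Skip connections come from the main (centre) stream.
* **concat3into1**: one encoder over the 3-channel stacked triplet.

Other choices the architecture description leaves open, fixed here: loss
is per-pixel softmax cross-entropy over the five classes (the standard
choice for semantic segmentation); one softmax covers
{background, LC, LV, RC, RV} with argmax ties broken toward background;
inputs are per-patch min-max normalized to [0, 1]; weights are seeded
He-normal initializations — pretrained encoder weights are not bundled,
keeping runs download-free and bit-reproducible. `channel_scale`
multiplies every layer width (e.g. 0.125 for CPU-scale experiments);
1.0 reproduces the full-width network.

The engine underneath (`hydroseg.nn`) is a small numpy implementation —
im2col convolutions, zero-interleaving transposed convolutions, 2× max
pooling, inverted dropout, Adam — with hand-written backward passes
verified against finite differences in the test suite. It is exact, fully
deterministic given its seeds, and adequate for desk-scale networks; it
makes no claim to GPU-scale performance.

## Training, cross-validation, curriculum

Annotation modes: SA keeps only the side's organ-of-interest label;
FA keeps all visible organs; FA′ restricts the FA patches to the organ of
interest; FASA and FA′SA are unions of pools. Validation IoU is always
scored on the organ of interest of each patch, and the per-class IoU
averages exclude background and classes absent from the ground truth
(the stricter reading); classes predicted but absent from the truth are
skipped with a log entry.

5-fold cross-validation partitions *original* patch ids (sizes differing
by at most one; 372 ids split 75/75/74/74/74); augmented variants follow
their original so no augmented copy of a validation patch leaks into
training. Each fold trains on the other four and reports its best-epoch
validation IoU; the aggregate is mean ± SD over folds. Best-epoch
selection by validation IoU; early stopping is off by default. The
curriculum schedule trains from scratch on the simple pool, then resumes
the *final* (not best-epoch) weights and fine-tunes on the harder pool,
validating on the same held-out samples throughout; zero fine-tune epochs
return the stage-1 model unchanged.

Defaults mirror the clinical-scale recipe (Adam, learning rate 1e-6,
dropout 0.6, batch size 4). The package's own desk-scale reference
regime — frozen in `hydroseg.experiments` — is deliberately different,
because a randomly initialized reduced network trained from scratch for
tens of epochs needs a workable step size: 8 subjects at 0.24 geometry
scale (24-pixel windows), MRC noise SD 60, encoder depth 8, channel scale
0.125, learning rate 3e-3, dropout 0.1, 20 epochs (10+10 for the
curriculum arms). In this regime a from-scratch run reaches mid-range IoU
in ~10 s on one CPU, leaving headroom for the two architectures and the
two schedules to separate. The comparisons assert *orderings only*
(multi-stream ≥ channel-stacked; curriculum ≥ scratch at matched budget
and seeds); absolute phantom IoU values do not transfer to clinical data
and are not claimed.

## Agreement statistics

ICC is the single-score two-way model, computed via pingouin's ANOVA
decomposition and checked in the tests against a from-scratch mean-squares
oracle. The description "single-score, two-way" leaves the
absolute-agreement vs consistency distinction open; the default is
two-way random-effects, absolute agreement, single measurement
(ICC(2,1)), with the consistency variant available as an option. Fewer
than 3 pairs, non-finite values, or zero total variance raise errors
rather than returning numbers. Bland–Altman limits are mean difference
± 1.96 × SD (ddof 1) of the paired differences. The cohort report emits
three blocks — overall, cochlea-only, vestibule-only — flagging any block
with fewer than 3 pairs as insufficient.

## Pipeline and determinism

The CLI pipeline (phantom → derive → train → predict → quantify) caches
each stage under a hash of the configuration slice it depends on; a stage
re-runs when its stamp is stale, its outputs are missing, or an upstream
stage re-ran. Seeds are mandatory configuration. Two runs with identical
configuration produce byte-identical EH-ratio reports; the acceptance
script verifies this at run time. Stacks are written as 16-bit PNG per
slice or NIfTI; signed derived images as NIfTI (PNG cannot hold
negatives); masks as 8-bit indexed PNG; reports as CSV and JSON.

## Known limitations

* Phantom realism is intentionally minimal (see above); clinical
  performance claims require clinical data.
* The numpy engine is single-threaded-CPU oriented; full-width (channel
  scale 1.0) training is possible but slow, and no pretrained encoder is
  shipped.
* DICOM support covers reading series directories (sorted by filename or
  InstanceNumber); writing DICOM is out of scope, as is PACS
  connectivity and any inter-sequence registration — inputs are assumed
  co-registered.
* The EH ratio is reported as a measurement; clinical grading of hydrops
  severity and diagnosis are out of scope.
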