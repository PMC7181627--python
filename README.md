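# hydroseg

Quantification of endolymphatic hydrops (EH) from inner-ear MRI: image
derivation, CNN-based segmentation of cochlea and vestibule, EH-ratio
measurement, and rater-vs-model agreement statistics — with a synthetic
phantom generator so the full pipeline is testable without clinical data.

## The problem

Ménière's disease is marked histologically by endolymphatic hydrops, a
distension of the endolymph-filled spaces of the inner ear. With delayed
intravenous-gadolinium MRI, hydrops can be quantified in vivo: three
co-registered sequences — MR cisternography (**MRC**, total inner-ear
fluid), a positive perilymph image (**PPI**) and a positive endolymph image
(**PEI**) — are combined into derived images

```
HYDROPS     = PPI − PEI          (negative exactly where endolymph dominates)
HYDROPS-Mi2 = HYDROPS × MRC      (same sign pattern, higher contrast-to-noise)
```

and, inside a segmented organ region *S*, the **EH ratio** is

```
EH ratio = #{ pixels in S with HYDROPS-Mi2 < 0 } / #{ pixels in S }
```

Doing this by hand — windowing images at level/width 400/1000, outlining
each cochlea and vestibule, counting negative pixels — takes an expert
15–20 minutes per scan. `hydroseg` automates the measurement: a
convolutional encoder–decoder segments the four organ classes
(left/right cochlea, left/right vestibule) on 100×100-pixel patches
cropped around fixed per-side reference points of the 384×324 frame, the
EH ratio is counted inside the predicted masks, and agreement with
reference measurements is summarized by the single-score two-way
intraclass correlation coefficient (ICC), Pearson's r, and Bland–Altman
limits of agreement.

Two architectures are provided: **3into3** feeds three consecutive MRC
slices into three parallel VGG-19-style encoder streams and sums their
features before a three-stage deconvolutional decoder with two skip
connections; **concat3into1** feeds the channel-stacked triplet to a
single encoder. Training supports the selective/full annotation pools
(SA / FA / FASA / FA′ / FA′SA), exact flip–shift–brightness augmentation
enumeration (144 / 1,584 / 14,544 variants per patch), 5-fold
cross-validation with per-epoch IoU tracking, and a two-stage curriculum
schedule (train on the simple pool, fine-tune on the harder one).

Clinical hydrops-protocol MRI is IRB-restricted, so the package ships a
phantom generator (`hydroseg.phantom`) producing MRC/PPI/PEI stacks with
organ-shaped structures, controllable true endolymph fractions, noise and
through-plane continuity — every stage is validated against this known
ground truth. The network engine is a small, fully tested numpy
implementation (convolution, transposed convolution, pooling, dropout,
Adam), deterministic given its seeds and sized for CPU-scale experiments.

## Worked example

```python
import hydroseg as hs

subjects, manifest = hs.generate_cohort(
    20, hs.PhantomSpec(noise_sd=0.0),
    hs.CohortRanges(endolymph_fraction=(0.1, 0.6), noise_sd=(0.0, 0.0)), seed=5)
report = hs.cohort_eh_report(subjects)
merged = report.merge(manifest[["subject_id", "label", "requested_fraction"]],
                      on=["subject_id", "label"])
blocks = hs.agreement_report(merged.gt_ratio, merged.requested_fraction,
                             merged.organ_type)
```

prints (see `examples/05_eh_ratio_agreement.py`):

```
80 organ measurements; max |error| = 0.50 pixels
  overall: n= 80  ICC=1.0000 CI=(1.0, 1.0)  r=1.0000  LoA=[-0.0007, +0.0007]
  cochlea: n= 40  ICC=1.0000 CI=(1.0, 1.0)  r=1.0000  LoA=[-0.0005, +0.0004]
vestibule: n= 40  ICC=1.0000 CI=(1.0, 1.0)  r=1.0000  LoA=[-0.0009, +0.0009]
```

On noiseless phantoms the ground-truth-mask EH ratio recovers the
specified endolymph fraction to within half a pixel of rasterization per
organ, and the measured-vs-true agreement is ICC ≈ 1 — the measurement
pipeline itself adds no error. `examples/` contains one short script per
capability (phantom generation, image derivation, augmentation
enumeration, training/prediction, agreement analysis, the cached
end-to-end pipeline); `hydroseg --help` exposes the same pipeline from the
shell.

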