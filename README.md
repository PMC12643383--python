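# octaskin

Preprocessing, en-face projection and vessel-segmentation evaluation for
dermatological OCT angiography (OCTA) volumes.

Skin OCTA images the dermal microvasculature in 3D without dye, but the
raw volumes carry a heavy artifact load: skin tilt, per-B-scan gain
fluctuations that appear as vertical stripes in en-face views, speckle,
depth attenuation, and projection tails — false flow signal replicated
below superficial vessels that masquerades as deep vasculature.  Anyone
developing or benchmarking vessel-segmentation methods on such data needs
(a) a reproducible enhancement pipeline, (b) band-resolved en-face
projections and reference masks, and (c) evaluation metrics that are
sensitive to vascular topology, not just voxel overlap.  `octaskin`
provides all three, plus a seeded synthetic phantom generator so the
whole chain can be exercised and tested without patient data.

## What it computes

**Pipeline** (each stage a pure volume→volume transform, runnable
individually or cumulatively): surface flattening → B-scan normalization
(unit mean per frame) → projection-artifact attenuation (step-down
exponential filter `out(z) = max(0, in(z) − w·C(z))` with
`C(z) = λ·C(z−1) + in(z−1)`) → 3D median + percentile contrast stretch →
multiscale Frangi vesselness (scales 4:2:8, α = 0.01, β = 1, explicit
suppression where λ₂ > 0 or λ₃ > 0).

**En face**: superficial/deep split at a configurable depth (default
400 µm), average-intensity projections clipped at the 99th percentile,
reference masks by global threshold + closing + removal of components
smaller than 100 voxels, Otsu-binarized 2D masks.

**Metrics** (2D and 3D): Dice, precision, recall, balanced accuracy;
vascular density VD = |S|/|Ω|, fragmentation VF = #components
(8-/26-connected), box-counting fractal dimension FD (20 scales, 5
offsets), each with the signed relative difference against the reference;
and the connectivity–area–length index

CAL = [1 − min(1, |#c(Sgt) − #c(S)|/|Sgt|)] ·
|(δ₂S ∩ Sgt) ∪ (S ∩ δ₂Sgt)|/|S ∪ Sgt| ·
|(φS ∩ δ₃Sgt) ∪ (δ₃S ∩ φSgt)|/|φS ∪ φSgt|

with δr dilation by a disc/ball of radius r and φ skeletonization —
1 for a perfect prediction, 0 for complete failure.

## Worked example

```
octaskin demo --seed 42 --out demo_out/
```

generates a 90×128×128 phantom (two vessel plexuses, speckle, gain
stripes, projection tails), runs the five stages, writes 15 en-face PNGs
(5 stages × 3 bands), segments every stage with the reference-mask
recipe, and evaluates each segmentation against the ground truth.  It
prints:

```
            stage dims     dice      cal
         original   3d 0.402759 0.143664
         original   2d 0.837771 0.755399
       normalized   3d 0.402964 0.137571
       normalized   2d 0.854875 0.732522
    pa_attenuated   3d 0.876434 0.977506
    pa_attenuated   2d 0.877309 0.805438
contrast_enhanced   3d 0.429641 0.214741
contrast_enhanced   2d 0.819580 0.694108
       vesselness   3d 0.458749 0.292713
       vesselness   2d 0.690915 0.625431
```

Reading the numbers: on the raw and merely normalized volumes, the 3D
Otsu segmentation swallows the projection tails (precision 0.26, Dice
0.40) — the tails are bright enough to cross the threshold throughout the
deep band.  After the step-down filter (`pa_attenuated`) 3D Dice jumps to
0.88 and CAL to 0.98: the false deep vessels are gone and the topology
matches.  The 2D rows are flatter because depth-collapsed projections
hide most of the tail artifact.  The full 17-column table (all eleven
metrics plus the VD/VF/FD relative differences per row) is written to
`demo_out/metrics.csv`; the run is byte-reproducible for a fixed seed.

The same pieces are available as subcommands (`octaskin phantom`,
`preprocess`, `project`, `refmask`, `evaluate`) and as plain functions:

```python
import octaskin as ok

vol = ok.read_volume("volume.tif")
stages = ok.run_pipeline(vol, "contrast_enhanced")
mask = ok.make_reference_mask(stages["pa_attenuated"])
report = ok.evaluate(mask, ok.read_mask("gt_mask.tif", role="gt"))
print(report.dice, report.cal, report.rpd_vd)
```

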