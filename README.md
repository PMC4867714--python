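# odseg — optic-disc localization and segmentation in retinal fundus images

The optic disc (OD) is the bright, roughly circular region where the optic
nerve and the retinal vessels enter the eye. Finding its center and tracing
its boundary is the first step of automated glaucoma screening (the cup-to-disc
ratio) and a common anchor for locating the fovea and measuring vascular
change. Both tasks are harder than they look: illumination varies wildly
between cameras and across a single photograph, vessels blur the disc rim, and
bright lesions (exudates) mimic the disc.

`odseg` implements a classical, fully deterministic pipeline for both tasks:

1. **Shade correction.** The green channel *I* (highest disc contrast) is
   opened with a small disc element, a background estimate
   *I*<sub>bg</sub> (89×89 arithmetic-mean filter) is subtracted,
   *I*<sub>norm</sub> = *I*<sub>open</sub> − *I*<sub>bg</sub>, and a global
   linear map pins the modal (background) intensity at 0.5:
   *I*<sub>SC</sub> = clip(*I*<sub>norm</sub> − mode(*I*<sub>norm</sub>) + 0.5, 0, 1).
2. **Detection.** A grayscale closing fills in the vasculature, the image is
   resized to a 565-px working width, and a circular Hough transform
   accumulates edge votes for circles (x−a)² + (y−b)² = r² over r ∈ [29, 50] px.
   A strict-to-permissive sensitivity ladder keeps the strongest circle of the
   first level that fires.
3. **Grow-cut segmentation.** Each pixel is an automaton cell (l, θ, C):
   label, strength, intensity. Foreground seeds (a small disk at the detected
   center) and background seeds (everything beyond 2.5 r) attack their
   8-neighbors with force λ = g·θ, g = 1 − |C<sub>p</sub> − C<sub>x</sub>|/C<sub>max</sub>;
   a cell is conquered when λ exceeds its own strength. Labels flood uniform
   regions and stall at the disc rim.
4. **Ellipse approximation.** The traced grow-cut boundary is fitted with a
   direct least-squares ellipse (optionally a circle), giving the reported
   smooth outline and bridging vessel notches.

Evaluation (`odseg.metrics`) provides confusion counts, SN/SP/Acc/PPV/FDR,
Dice, Jaccard overlap and a boundary Hausdorff distance; `odseg.phantom`
generates seeded synthetic fundus images — bright elliptical disc, converging
vessels, illumination gradient, exudates, Gaussian / salt-&-pepper / speckle
noise — with exact ground-truth masks.

## Worked example

```sh
python examples/03_segment_growcut.py
```

```
grow-cut iterations   : 148 (converged=True)
raw grow-cut mask     : Dice 0.9439, overlap 0.8938
ellipse approximation : Dice 0.9675, overlap 0.9371
fitted ellipse        : center (280.1, 190.0), axes 40.8 x 34.8 px
boundary error        : Hausdorff 2.8 px (0.037 of the disc diameter)
```

The phantom's true disc is a 40-px ellipse centered at (280, 190); the
automaton converges in 148 sweeps, and the ellipse fit recovers the center to
sub-pixel accuracy. The Dice score compares the predicted and true masks
(1 = identical); overlap is the Jaccard index, always ≤ Dice. The other
examples (`examples/01…04`) generate phantoms, run detection alone, and
evaluate a jittered batch.

The same pipeline is scriptable from a shell:

```sh
odseg synth --n 5 --out phantoms --seed 42        # images + truth masks
odseg detect phantoms/img_0000.png --out det.json
odseg run phantoms/img_0000.png --out results     # all artifacts
```

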