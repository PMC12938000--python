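# nir2a

Fluorescence angiography in the first near-infrared window (NIR-I,
700–1000 nm) is fast and clinically established but blurred by light
scattering, tissue autofluorescence and a dominant hepatic signal.
Imaging beyond 1300 nm (NIR-IIa) gives sharp, low-background vessels at
the cost of long exposures and special probes.  `nir2a` implements the
"probe-plus-AI" route between the two: it simulates co-registered
NIR-I/NIR-IIa image pairs, trains a convolutional-encoder /
Swin-Transformer / convolutional-decoder network to translate NIR-I
frames into NIR-IIa-like frames, and quantifies the result with the
field's standard statistics

* **SBR** — signal-to-background ratio, the mean of three vascular
  ROI intensities over the mean of three adjacent background ROIs,
* **FWHM** — the full width at half maximum of a cross-vessel intensity
  profile (for a Gaussian profile, 2√(2 ln 2)σ),

plus the small photophysics utilities used to characterise probes:
Stokes shift, photostability retention, hemolysis percentage, and a
mono-exponential circulation half-life fit.

The intended audience is imaging-methods researchers who want a fully
reproducible, CPU-only re-enactment of this workflow: every stage is
seeded, every reported number is recomputable from persisted artifacts,
and the network runs on a small numpy autodiff engine included in the
package (no GPU framework required).

## Worked example

```bash
python analysis/01_simulate_phantoms.py
python analysis/02_enhancement_experiment.py
python analysis/03_photophysics_circulation.py
python analysis/04_cross_condition_transfer.py
```

`02_enhancement_experiment.py` generates 80 co-registered phantom pairs
(120×120 px), trains the network on 64 of them and evaluates the 8
held-out test pairs.  A run of the packaged configuration printed:

```
test-split medians (seed 1, 80 pairs, 15 epochs):
  SBR input    1.45
  SBR enhanced 6.24  (4.31-fold)
  SBR target   2.62
  |FWHM err| input    0.613 mm
  |FWHM err| enhanced 0.082 mm
```

Read: raw NIR-I-like frames have vessel contrast barely above tissue
(SBR 1.45); after translation the frames are high-contrast (background
suppressed even below the raw NIR-IIa target, hence SBR above the
target's 2.62), and apparent vessel widths land within 0.1 mm of the
ground-truth channel instead of 0.6 mm too wide.
`03_photophysics_circulation.py` prints the probe-arithmetic checks —
Stokes shifts of 58 nm (ICG-like) and 350 nm (the NIR-II AIE probe), the
2.63-fold SBR ratio of the two windows, and 45 h half-life recovery in
≥ 90/100 noisy replicates.

The same pipeline is scriptable through one CLI:

```bash
nir2a generate --n-pairs 200 --seed 0 --out data/phantoms
nir2a train --manifest data/phantoms/manifest.json --out model/
nir2a enhance --weights model/checkpoint.npz --in frame.tif --out enhanced.tif
nir2a quantify --image enhanced.tif --metric fwhm --line 40 10 40 110 --pixel-size 0.1
nir2a run --config config.yaml --out results/run1
```

## Layout

```
src/nir2a/        library: phantom, network (+autodiff/nn), metrics,
                  pipeline_io, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property, acceptance)
scripts/          acceptance.py
docs/methods.md   model assumptions, defaults, limitations
```
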