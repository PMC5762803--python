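# abiret

Analyzer-based X-ray imaging: Monte Carlo simulation and parametric
retrieval of apparent absorption, refraction angle and ultra-small-angle
scattering width.

In analyzer-based imaging a perfect-crystal analyzer between sample and
detector acts as an angular band-pass filter whose transmission versus
angular offset (the *rocking curve*) is well approximated by a unit-peak
Gaussian of width `sigma`. A sample pixel modulates the local curve through
three parameters — transmission `I_R` (including extinction), mean beam
deviation `dtheta_r` (microradians) and Gaussian scattering width `sigma_s`
— and the convolution of the two Gaussians has a closed form. Measuring
intensities at three distinct analyzer offsets therefore allows an *exact
algebraic inversion* for all three parameters per pixel, valid far beyond
the linear-Taylor regime of classical diffraction-enhanced imaging.

The package provides:

- **`abiret.model`** — the Gaussian forward model, the three-image
  inversion, two-image reductions (scatter-free and refraction-free), and
  pixel-wise retrieval of parametric maps with degeneracy masking.
- **`abiret.rocking`** — Gaussian fitting of measured rocking-curve samples
  and working-point location (closed form or interpolated from samples).
- **`abiret.simulate`** — a Monte Carlo photon simulator for phantoms built
  from absorbing/refracting cylinders (two-interface Snell deflection) and
  Gaussian scatter foils, plus factories for a rod + 12-foil reference
  phantom and a layered "stairway" phantom.
- **`abiret.mir`** — multiple-image retrieval: a vectorized per-pixel
  Gaussian fit over many analyzer angles, the precision reference for the
  three-image method.
- **`abiret.imgio`** — TIFF I/O (16-bit counts, 32-bit float maps),
  offset/slope correction against the peak-position flat, ROI statistics
  and angle manifests.
- **`abiret.experiments`** — end-to-end validation experiments
  (inversion sweeps, foil recovery, triad robustness, stairway + MIR).

## Command line

```sh
# emit a built-in phantom description
abiret phantom rod-foils --out phantom.yaml

# simulate a three-image set at the two half slopes and the peak
abiret simulate --config phantom.yaml --sigma 8.6 \
    --angles -10.1257,0,10.1257 --photons 10000 --seed 1 --out-dir stack/

# retrieve the three parametric maps
abiret retrieve stack/ --sigma 8.6 --out-dir maps/

# two-image reductions, multi-angle retrieval, rocking-curve fitting
abiret retrieve2 pair/ --mode scatter --sigma 8.6 --out-dir maps2/
abiret mir stack30/ --sigma 8.6 --out-dir mirmaps/
abiret fit-rc rc_samples.txt
```

Image stacks are directories of TIFFs with a sidecar `angles.txt` manifest
(filename, analyzer offset in microradians) and a `normalization.txt`
carrying the per-pixel photon budget. All intensities follow one
normalization contract: an object-free pixel at offset `theta` reads the
analyzer transmission at `theta` (images are divided by the peak-position
flat, never by per-angle flats).

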