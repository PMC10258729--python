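# swirdos

Simulation and analysis toolkit for a wearable shortwave-infrared (SWIR)
diffuse optical probe that quantifies **water and lipid volume fractions**
in emulsion-like media from continuous-wave, multi-distance diffuse
reflectance.

## Who this is for

Biomedical-optics researchers who want to (a) forward-model spatially
resolved diffuse reflectance of water/lipid emulsions with a white Monte
Carlo look-up table, (b) train and evaluate a small neural-network inverse
model for chromophore recovery, and (c) process raw probe voltages
(gain correction, dark subtraction, phantom calibration, SNR/drift
characterization) into calibrated reflectance.

## The model

**Forward.** A sample is described by volume fractions of water, lipid and
optionally heavy water (D2O), plus a scattering power law

&nbsp;&nbsp;&nbsp;&nbsp;μs′(λ) = A · (λ / 980 nm)^(−b)

Absorption follows Beer's law over literature pure-chromophore spectra,

&nbsp;&nbsp;&nbsp;&nbsp;μa(λ) = f_w · ε_water(λ) + f_l · ε_lipid(λ) + f_d · ε_water(λ)/10,

with the D2O coefficient one tenth of water's in this band.  Spatially
resolved diffuse reflectance Rd(ρ) at source-detector separations
ρ ∈ {7, 10, 13, 16} mm is tabulated by a white Monte Carlo simulation of a
6 × 6 × 10 cm slab (g = 0.7, n = 1.435): photons random-walk at zero
absorption, and absorption over 0.001–0.2 mm⁻¹ is applied afterwards by
Beer–Lambert reweighting of recorded path lengths.

**Inverse.** A fully connected network (12 or 9 reflectance inputs → three
hidden layers of 20 ReLU units → linear water/lipid outputs) is trained
with Adam (lr 10⁻³, MSE loss) on log-normalized reflectance of randomized
synthetic samples (water ~ U(0,100) %, lipid the complement,
A ~ U(0.2, 10) mm⁻¹, b ~ N(1.29, 0.52), 5 % relative Gaussian channel
noise).

**Measurement pipeline.** Raw probe voltages are gain-corrected and
dark-subtracted; a calibration phantom of known optical properties maps a
per-channel voltage to the LUT's theoretical Rd, giving linear scale
factors that convert sample voltages to reflectance for the network.
SNR = 10·log₁₀(mean/SD) of the dark-subtracted series (dB) and drift is
the fitted slope normalized to the initial voltage (% V/h).

## Worked example

```python
from swirdos import (
    GeneratorConfig, InverseModel, build_lut, evaluate_recovery,
    make_dataset, swir_geometry, train,
)

lut = build_lut(n_photons=100_000, seed=0)        # ~10 min on one CPU
geom = swir_geometry()                            # 980/1200/1300 nm x 7-16 mm
gen = GeneratorConfig(noise_sigma=0.05)
train_set = make_dataset(20_000, gen, geom, lut, seed=1)
test_set = make_dataset(5_000, gen, geom, lut, seed=2)

model = InverseModel(12, geom.channel_labels(), seed=3)
train(model, train_set.rd, train_set.labels_pct, epochs=2000, seed=4,
      early_stopping=False)
print(evaluate_recovery(model, test_set.rd, test_set.labels_pct))
```

This prints (up to training stochasticity):

```
water error -0.15 +/- 1.39 %, lipid error +0.10 +/- 1.39 %
```

meaning the network recovers water content of unseen noisy samples with
essentially no bias and a ~1.4 % standard deviation — the headline
accuracy of the SWIR band.  Swapping in `nir_geometry()` (900/930/970 nm)
degrades the standard deviation to ~2.2 %, showing the SWIR advantage for
water/lipid work.

The same comparison is packaged as a driver:

```bash
swirdos compare-swir-nir --profile desk --seed 1
swirdos emulsion --profile ci --seed 1     # synthetic emulsion phantom series
swirdos d2o --profile ci --seed 1          # synthetic heavy-water dilution series
```

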