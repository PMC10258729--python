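# Methods

This note documents the models, parameter choices and numerical decisions
behind `swirdos`, and what its synthetic experiments do and do not show.

## Chromophore model

Absorption is Beer's law over pure-chromophore absorption coefficients
(mm⁻¹ at unit volume fraction) at the six probe wavelengths.  The shipped
table is assembled from standard literature compilations — Hale & Querry
(1973) and Kou et al. (1993) for water, van Veen et al. (2005) soybean-oil
measurements for lipid — rounded and tagged with their source per row.
Users can override it from a CSV with columns
`chromophore, wavelength_nm, mua_per_unit_fraction_mm-1, source`.

Two constraints shaped the table:

* ε_lipid(900 nm) is set to 0.0011 mm⁻¹ (literature spread ~0.0008–0.0012)
  so that a 100 %-lipid draw stays at or above the look-up table's
  absorption floor of 0.001 mm⁻¹; the generator and the LUT are only
  mutually consistent under this condition.
* The table reproduces the qualitative anchors of the band: water rising
  monotonically from 980 to 1300 nm, the lipid band peaking near 1200 nm,
  and 1 % Intralipid μa spanning ≈0.04–0.13 mm⁻¹ across the SWIR triplet.

Heavy water is not a separate table entry: its absorption is modelled as
spectrally collinear with H2O at exactly one tenth the magnitude, the
standard approximation for this band.  Volume fractions are carried in
percent (0–100) everywhere; conversion to [0, 1] happens only inside the
absorption computation.

## Photon transport

White Monte Carlo in a homogeneous 60 × 60 × 100 mm slab: pencil beam,
exponential steps at μs = μs′/(1−g) with g = 0.7, Henyey–Greenstein
scattering, Fresnel reflection at the top boundary for n = 1.435 against
air (specular reflection at launch removed from the photon weight), and
absorbing bottom/side boundaries (negligible for this slab, which
approximates a semi-infinite medium).  Absorption is applied after the
fact: each detected photon's contribution at absorption μa is
w·exp(−μa·L) with L its total path length.

Numerical choices:

* **Detection.** Annular rings of half-width 1.5 mm centred on each
  source–detector separation, exploiting radial symmetry; Rd is
  normalized per unit ring area (mm⁻²) so the ring width cancels to first
  order.  Any residual area-convention constant is absorbed by the
  phantom calibration in the measurement pipeline and is irrelevant to
  the inverse network, which trains on the same forward model.
* **Path cutoff.** Photons are terminated once their path exceeds 40 slab
  diagonals (≈5.2 m).  The cutoff was sized against the diffusion-theory
  check below: at the LUT's absorption floor (0.001 mm⁻¹) the truncated
  tail contributes under ~1 % to any ring, whereas a short cutoff (e.g.
  10 diagonals) biases Rd at high μs′ / low μa / 16 mm by tens of percent
  because typical detected path lengths there exceed it.
* **Weight ledger.** Specular + top-escape + boundary-absorbed + residual
  weight sums to the launched weight exactly; the residual (cutoff)
  fraction is the only tolerance term and stays below a few percent.
* **Grids.** 15 linear μs′ nodes over 0.2–10 mm⁻¹ and 20 log-spaced μa
  nodes over 0.001–0.2 mm⁻¹ by default (configurable); interpolation is
  bilinear in (μs′, ln μa), exact at nodes, and out-of-grid queries raise
  rather than extrapolate.  Interpolation error is far below the 5 %
  channel noise used downstream.
* **Statistics.** Each LUT cell carries a Monte Carlo standard error
  (per-photon contributions are i.i.d.).  Rd is strictly decreasing in μa
  by construction.  Monotonicity in separation is asserted statistically:
  strictly decreasing wherever the cell is resolved (SE < 10 % of the
  value) and no significant violation (3σ) anywhere.  At the extreme
  corner (μa = 0.2 mm⁻¹, μs′ ≈ 4–10, 13–16 mm) Rd is ~10⁻¹² mm⁻² and the
  effective sample size at desk-scale photon budgets is of order one;
  exact ordering there is a statement about statistics, not physics.

The transport is validated against the closed-form extrapolated-boundary
dipole solution for a semi-infinite medium: for μs′ ≥ 2 mm⁻¹,
μa ≤ 0.01 mm⁻¹ and separations ≥ 10 mm, white-MC Rd agrees within 15 %.

## Synthetic samples

The generator draws the study conditions: water ~ U(0, 100) % with lipid
the complement (sum-to-100 mode); scatter amplitude A ~ U(0.2, 10) mm⁻¹
referenced to 980 nm and slope b ~ N(1.29, 0.52), redrawn as a pair until
μs′ stays inside the LUT range at every probe wavelength (the redraw rate
is recorded on the dataset); and 5 % relative zero-mean Gaussian noise,
i.i.d. per channel, floored at a tiny positive value so log-normalization
stays defined.  Relative (multiplicative) noise is used because the
channels span orders of magnitude of Rd and detector shot/gain noise
scales with signal.

The dilution mode fixes scattering to 1 % Intralipid values
(0.78/0.58/0.49 mm⁻¹ at 980/1200/1300 nm, inside the 0.49–0.78 mm⁻¹ range
characteristic of such suspensions), draws lipid ~ U(0, 2) %, and assigns
the remaining volume to D2O; compositions do not sum water + lipid to 100.
The exact lipid bound for this mode is a package choice (the dilution
phantoms hold lipid near 1 %).

Channel ordering is wavelength-major, separation-minor everywhere, stored
with datasets and models; prediction refuses mismatched orderings.

## Inverse network

Architecture fixed at input → 20 → 20 → 20 → 2 with ReLU hidden units and
linear outputs; Adam with learning rate 10⁻³; MSE loss on labels scaled
from percent to fraction (so converged losses are in fraction² units);
inputs log-normalized with training-set statistics stored alongside the
weights.  Implementation is plain numpy (the network is tiny and fully
specified); a scikit-learn MLP with the same architecture serves as an
independent cross-check in the test suite.

Choices within the protocol's unstated freedom:

* **Batch size 128**, shuffled each epoch.  Loss-versus-epoch curves
  depend on this; converged behaviour does not, and 128 converged best
  among the sizes tried at desk scale.
* **Initialization** is uniform fan-in, tied to a recorded seed.
* **Early stopping** (optional) halts when the mean loss over the last
  200 epochs is no longer below the mean over the 200 before that.
* **Training noise.** The default trains on noise-added data (the same
  5 % as the test sets); noiseless training is a switch used for the
  training-loss diagnostics.

## Problem sizes

The study-scale protocol is 75 000 training / 25 000 test samples, 3 000
epochs, ~10⁶ photons per LUT node.  The package's desk-scale default —
used by `scripts/acceptance.py` and mirrored at reduced size in the test
suite — is 30 000/5 000 samples, 3 000 epochs, 10⁵ photons per node, which
reproduces the converged error statistics to within their seed-to-seed
spread (recovery-error SDs change by well under 0.2 percentage points
between 20 k and 30 k training samples at 2 000 epochs).

## The SWIR-vs-NIR comparison, and a caveat

Under identical protocols the SWIR triplet (980/1200/1300 nm) recovers
water and lipid with ≈1.4 % error SD and near-zero mean at 5 % channel
noise, and the NIR triplet (900/930/970 nm) is strictly worse at ≈2.2 %.
The direction of the effect — stronger, more distinctive water/lipid
absorption in the SWIR — is robust here.

The magnitude of the NIR penalty is smaller than reported for the probe
this package models (≈5.8 %).  With literature extinction spectra, an
idealized ring-binned forward model, and well-converged training, the NIR
inverse problem is simply not badly conditioned: its noiseless training
MSE converges near 10⁻⁵ (fraction²), on par with SWIR, rather than
plateauing at 10⁻⁴.  Reproducing the larger published gap would require
forward-model or optimization details (discrete-detector Monte Carlo
statistics, exact extinction compilations, specific training
configurations) that are not derivable from the published description.
The package reports what its own model yields and does not tune the NIR
band downward.

## Measurement pipeline

All stages before the network are linear in voltage: gain correction to a
1 MΩ reference, dark subtraction using a pre-acquisition dark frame,
calibration scale s = Rd_theory/V_cal per channel from a phantom of known
optical properties, then Rd = s·V.  Scaling all sample and calibration
voltages together leaves Rd unchanged, so slow gain drifts common to both
cancel.  Drift is normalized to the fitted intercept at t = 0 rather than
the first raw sample, for noise robustness.  Rows whose dark voltage
exceeds the sample voltage are flagged and excluded from calibration
rather than silently dropped.

Because the probe's raw phantom measurements are not public, the
emulsion (lipid 65–85 % in 5 % steps, 85 % calibrates, 9 channels) and
heavy-water dilution (H2O 99–9 % in 10 % steps, n = 1.33, 12 channels)
experiments run on fabricated voltage series: the forward model supplies
Rd, an arbitrary per-channel responsivity and dark offset produce
voltages, and the same 5 % relative noise model applies.  These stand-ins
validate the pipeline's algebra and the end-to-end consistency of
calibration + inversion — the calibration phantom is recovered
near-exactly and series errors match the network's own test-set error at
the same noise — but they cannot validate instrument physics such as LED
spectral width (~80 nm FWHM, not modelled; the forward model uses discrete
wavelengths), detector nonlinearity, or emulsion preparation variability.

## Known limitations

* Homogeneous slab only; no layered media, no time/frequency domain.
* Chromophore set is water/lipid/D2O; hemoglobin is out of scope, so the
  model applies to bloodless phantoms, not tissue.
* The absolute Rd scale depends on the detector convention; only
  calibrated or self-consistent uses are meaningful.
* Scattering of concentrated emulsions is approximated by a power law or
  fixed fixture values; dependent-scattering corrections are not modelled.
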