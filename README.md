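# brisma

Correlative **Br**illouin–Raman **s**pheroid **m**echano-chemical
**a**nalysis.

Brillouin microscopy reads out the GHz-frequency longitudinal viscoelastic
response of living tissue: light scattered by thermally excited acoustic
waves is shifted by the Brillouin frequency ω_B (a stiffness proxy) and
broadened by the linewidth Γ (acoustic attenuation). For a multicellular
tumor spheroid probed with a low-magnification objective, the scattering
volume averages over two compartments — cells and the hydrated
extracellular matrix (ECM) — whose peaks are far closer than their
linewidth, so the spectrum shows a single merged peak. `brisma` implements
the analysis chain that untangles mechanics from composition in that
setting, for anyone analyzing (or simulating) correlative Brillouin + Raman
acquisitions of 3D cell aggregates:

1. **DHO fitting** (`brisma.brillouin`) — the damped-harmonic-oscillator
   lineshape

   I(ν) = B + A·Γ·ω_B² / ((ν² − ω_B²)² + (Γν)²)

   fitted in two stages: Stokes and anti-Stokes peaks separately (symmetry
   check; the axis is rigidly shifted if the elastic line has drifted),
   then a single DHO over the whole spectrum.
2. **Raman CH/OH composition** (`brisma.raman`) — high-wavenumber
   processing: spline fluorescence baseline removal, subtraction of
   PDMS-chip and culture-medium reference spectra with factors calibrated
   against an off-chip spheroid reference, then the band-area ratio
   R = A_CH/A_OH (CH ≈ 2900 cm⁻¹ tracks dry mass, OH ≈ 3300 cm⁻¹ tracks
   water).
3. **Biphasic decomposition** (`brisma.biphasic`) — spheroids as cells
   (fixed ~70/30 water/dry-mass split) plus quasi-aqueous ECM with volume
   fractions Φ_cell + Φ_ECM = 1. The ratio inverts in closed form,

   R = κ·d_cell·Φ_cell / (w_cell·Φ_cell + w_ecm·Φ_ECM),

   with the scattering-efficiency constant κ calibrated on compressed
   spheroids (interstitial water expelled, Φ_ECM ≈ 0). The merged Brillouin
   peak obeys the linear mixing rule ω_B = ω_ECM·Φ_ECM + ω_cell·Φ_cell,
   applied forward and inverse (e.g. recovering ω_ECM ≈ 8 GHz for hydrated
   ECM from compressed/uncompressed pairs).
4. **Morphometry** (`brisma.morphometry`) — nuclear aspect ratios by
   center/periphery zone, marker-positive nuclear fractions under
   control-normalized thresholds, invasive/core area ratios, and
   background-subtracted region intensities, all on segmented label/mask
   images.
5. **Synthetic data** (`brisma.synthetic`) — a seeded generator emitting
   two-component Brillouin spectra, composition-encoding Raman spectra with
   realistic contamination, and morphometry images, each with full
   ground-truth sidecars; every analysis stage is validated by parameter
   recovery against it.

A batch pipeline (`brisma.pipeline`), a normality-gated group-comparison
layer (`brisma.stats`) and a `brisma` command-line interface tie the stages
together.

## Worked example

```python
from brisma.synthetic import PRESETS, make_brillouin, make_raman, make_reference_set
from brisma.brillouin import BrillouinDHOModel
from brisma.biphasic import CompositionModel
from brisma.composition import SpheroidCompositionModel, kappa_from_reference_samples

# --- Brillouin: fit a synthetic control spheroid spectrum -------------
spec, truth = make_brillouin(PRESETS["control"], seed=1)
print(BrillouinDHOModel(spec).fit().summary())

# --- Raman -> composition: calibrate kappa on compressed spheroids ----
cal_refs = make_reference_set(5, preset=PRESETS["compressed"])
cal = [make_raman(PRESETS["compressed"], 100 + i)[0] for i in range(10)]
kappa = kappa_from_reference_samples(cal, cal_refs, phi_ecm_ref=0.0)

refs = make_reference_set(0, preset=PRESETS["control"])
sample, _ = make_raman(PRESETS["control"], seed=2)
result = SpheroidCompositionModel(sample, refs,
                                  composition=CompositionModel(kappa=kappa)).fit()
print(result.summary())
```

prints

```
Brillouin DHO fit
=================
points fitted          1734
omega_B   [GHz]            8.1712  (se 0.0009)
Gamma     [GHz]            1.2138  (se 0.0028)
...
Raman CH/OH analysis
====================
A_CH                     176.7092
A_OH                     726.5429
R = A_CH/A_OH             0.24322
alpha_pdms                 0.1879
alpha_medium               0.4780
...
Biphasic composition
====================
kappa                      0.7056
w_cell / d_cell          0.70 / 0.30
Phi_ECM                    0.1455  (se 0.0000)
Phi_cell                   0.8545
```

The fitted composite shift 8.171 GHz sits on the mixture of the generator's
component shifts (0.15·8.0 + 0.85·8.2 = 8.17 GHz), and the recovered ECM
volume fraction 14.6% matches the generating 15% despite the chip and
medium contamination (whose subtraction factors, 0.19 and 0.48, recover the
injected 0.20 and 0.50 levels).

From the shell, the same stages are available as subcommands:

```sh
brisma simulate --conditions control,rock,compressed --n 10 --seed 42 --out data/
brisma run --manifest data/manifest.csv --out results/
brisma report --results results/results.csv --value phi_ecm
```

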