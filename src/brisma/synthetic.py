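"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator stands in for the instrument: it emits

* two-component Brillouin spectra (cell + ECM damped-harmonic-oscillator
  doublets obeying the linear mixing rule, an elastic-line tail, Poisson
  photon-counting noise),
* high-wavenumber Raman spectra whose CH and OH band areas encode the
  biphasic composition (CH total area proportional to kappa * d_cell *
  Phi_cell, OH area to w_cell * Phi_cell + w_ecm * Phi_ECM), with
  fluorescence baseline, PDMS-chip and culture-medium contamination and
  additive Gaussian (CCD) noise,
* morphometry images (non-overlapping elliptical nuclei inside a spheroid
  mask, invasion core/total masks, interstitial dextran intensity) with
  per-object ground truth.

Every output is deterministic given its seed, and every generative
parameter is recorded in a ground-truth sidecar so any recovery test can be
scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .biphasic import forward_omega
from .brillouin import dho_lineshape
from .exceptions import ConfigurationError, PackingError, BrismaError
from .io import Spectrum, SampleRecord, write_manifest, write_spectrum, write_image
from .raman import RamanReferences

__all__ = [
    "ConditionPreset",
    "PRESETS",
    "make_brillouin",
    "make_raman",
    "make_reference_set",
    "make_nuclei_image",
    "make_invasion_masks",
    "make_dextran_image",
    "make_dataset",
    "NucleiSample",
]

# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------


@dataclass
class ConditionPreset:
    """Ground-truth generative parameters for one experimental condition.

    The composition anchors are phi_ecm = 0.15 (control), 0.24 (ROCK
    inhibition), 0 (compressed: interstitial spaces squeezed out) and
    omega_ecm = 8.0 GHz for hydrated ECM, with cells at a fixed 70/30
    water/dry volume split.  Component shifts, linewidths, kappa and noise
    levels are plausible 532 nm backscattering values chosen to preserve the
    ordinal relationships between conditions; all are overridable and every
    generated sample records them in its ground truth.
    """

    name: str
    phi_ecm: float
    omega_cell: float  # GHz
    omega_ecm: float = 8.0  # GHz
    gamma: float = 1.2  # GHz full linewidth
    w_cell: float = 0.70
    w_ecm: float = 1.0
    kappa: float = 0.7
    noise_snr: float = 50.0  # peak signal-to-noise
    baseline_coeffs: tuple = (0.40, 0.50, -0.30)  # fluorescence polynomial, peak-relative
    pdms_level: float = 0.20
    medium_level: float = 0.50
    elastic_amplitude: float = 2.0  # elastic tail height relative to Brillouin peak

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_ecm <= 0.5:
            raise ConfigurationError("phi_ecm outside the physiological band [0, 0.5]")
        for omega in (self.omega_cell, self.omega_ecm):
            if not 6.0 <= omega <= 10.0:
                raise ConfigurationError("component shifts must lie in [6, 10] GHz")
        if not 0.3 <= self.gamma <= 3.0:
            raise ConfigurationError("gamma must lie in [0.3, 3] GHz")
        if self.noise_snr is not None and self.noise_snr <= 0:
            raise ConfigurationError("noise_snr must be positive (or None for noiseless)")

    def replace(self, **kwargs) -> "ConditionPreset":
        d = asdict(self)
        d.update(kwargs)
        return ConditionPreset(**d)


#: Default presets per condition. The compressed preset shares omega_cell
#: with control: compression expels interstitial ECM water (phi_ecm -> 0)
#: while single-cell volume, hence the cell component shift, is unchanged.
PRESETS: dict[str, ConditionPreset] = {
    "control": ConditionPreset("control", phi_ecm=0.15, omega_cell=8.20),
    "rock": ConditionPreset("rock", phi_ecm=0.24, omega_cell=8.10),
    "rhoa": ConditionPreset("rhoa", phi_ecm=0.15, omega_cell=8.28, gamma=1.5),
    "compressed": ConditionPreset("compressed", phi_ecm=0.0, omega_cell=8.20),
    "flow": ConditionPreset("flow", phi_ecm=0.15, omega_cell=8.22),
    "cycle1": ConditionPreset("cycle1", phi_ecm=0.15, omega_cell=8.25),
    "cycle4": ConditionPreset("cycle4", phi_ecm=0.15, omega_cell=8.30),
}


# ---------------------------------------------------------------------------
# Brillouin spectra
# ---------------------------------------------------------------------------

#: Elastic-line Lorentzian half-width (GHz).
ELASTIC_WIDTH = 0.3

#: Flat detector background relative to the Brillouin peak height.
BACKGROUND_LEVEL = 0.02

#: Arbitrary intensity scale for noiseless spectra.
NOISELESS_SCALE = 1000.0


def make_brillouin(
    preset: ConditionPreset,
    seed: int,
    n_points: int = 2000,
    span: tuple[float, float] = (-15.0, 15.0),
    axis_offset: float = 0.0,
    noise_snr: float | None = "preset",
) -> tuple[Spectrum, dict]:
    """Two-component DHO Brillouin spectrum with known mixture ground truth.

    The intensity is an elastic-line Lorentzian tail plus a Phi_cell-weighted
    DHO doublet at +/- omega_cell and a Phi_ECM-weighted doublet at
    +/- omega_ecm (comparable scattering efficiency), a flat background, and
    Poisson counting noise scaled so the Brillouin peak holds
    ``noise_snr**2`` counts.  ``axis_offset`` rigidly shifts the frequency
    axis to emulate spectrometer drift.  ``noise_snr=None`` gives a
    noiseless trace.
    """
    if noise_snr == "preset":
        noise_snr = preset.noise_snr
    omega_max = max(preset.omega_cell, preset.omega_ecm)
    if span[0] > -(omega_max + 3 * preset.gamma) or span[1] < omega_max + 3 * preset.gamma:
        raise ConfigurationError(
            f"span {span} too narrow: must cover +/-{omega_max + 3 * preset.gamma:.1f} GHz"
        )
    nu = np.linspace(span[0], span[1], n_points)
    phi_c = 1.0 - preset.phi_ecm
    brillouin = phi_c * dho_lineshape(nu, preset.omega_cell, preset.gamma, 1.0, 0.0)
    if preset.phi_ecm > 0:
        brillouin = brillouin + preset.phi_ecm * dho_lineshape(
            nu, preset.omega_ecm, preset.gamma, 1.0, 0.0
        )
    peak_height = float(
        max(
            dho_lineshape(preset.omega_cell, preset.omega_cell, preset.gamma, 1.0, 0.0),
            1e-12,
        )
    )
    elastic = preset.elastic_amplitude * peak_height * ELASTIC_WIDTH**2 / (nu**2 + ELASTIC_WIDTH**2)
    background = BACKGROUND_LEVEL * peak_height
    signal = brillouin + elastic + background
    if noise_snr is None or not np.isfinite(noise_snr):
        intensity = signal * NOISELESS_SCALE
    else:
        # scale counts so the Brillouin peak (above background+tail) carries
        # snr^2 photons -> Poisson SNR == noise_snr at the peak
        idx = int(np.argmin(np.abs(nu - preset.omega_cell)))
        scale = noise_snr**2 / max(signal[idx], 1e-12)
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(signal * scale).astype(float)
    truth = {
        "kind": "brillouin",
        "condition": preset.name,
        "phi_ecm": preset.phi_ecm,
        "omega_cell": preset.omega_cell,
        "omega_ecm": preset.omega_ecm,
        "omega_b_mix": forward_omega(preset.omega_cell, preset.omega_ecm, preset.phi_ecm),
        "gamma": preset.gamma,
        "axis_offset": axis_offset,
        "noise_snr": None if noise_snr is None else float(noise_snr),
        "elastic_amplitude": preset.elastic_amplitude,
        "seed": seed,
    }
    spec = Spectrum(
        kind="brillouin",
        axis=nu + axis_offset,
        intensity=intensity,
        meta={"condition": preset.name, "seed": str(seed)},
    )
    return spec, truth


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

#: (center cm^-1, sigma cm^-1, weight) Gaussian components; weights sum to 1
#: so each profile integrates to unit area.
CH_COMPONENTS = ((2850.0, 25.0, 0.35), (2885.0, 25.0, 0.25), (2935.0, 30.0, 0.40))
OH_COMPONENTS = ((3230.0, 85.0, 0.55), (3420.0, 95.0, 0.45))
PDMS_COMPONENTS = ((2905.0, 18.0, 0.45), (2965.0, 16.0, 0.55))
#: Culture medium is water-dominated; its OH profile is restructured
#: relative to spheroid water: dissolved salts and organics weaken the
#: tetrahedrally coordinated (~3230 cm^-1) sub-band in favour of the
#: ~3420 cm^-1 one, so the medium reference leans 3420-heavy while
#: intracellular/interstitial water leans 3230-heavy.
MEDIUM_COMPONENTS = ((3230.0, 85.0, 0.42), (3420.0, 95.0, 0.58))

#: Overall Raman area scale (area units per unit volume fraction term).
RAMAN_SCALE = 1000.0
#: Reference-spectrum total areas (area units).
PDMS_REF_AREA = 0.25 * RAMAN_SCALE
MEDIUM_REF_AREA = 0.70 * RAMAN_SCALE

RAMAN_AXIS = (2400.0, 4000.0)


def _profile(x: np.ndarray, components) -> np.ndarray:
    """Sum of Gaussians with unit total area."""
    out = np.zeros_like(x)
    for center, sigma, weight in components:
        out += weight / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return out


def raman_truth_areas(preset: ConditionPreset) -> dict:
    """Closed-form CH/OH areas implied by a preset's composition."""
    phi_c = 1.0 - preset.phi_ecm
    a_ch = RAMAN_SCALE * preset.kappa * (1.0 - preset.w_cell) * phi_c
    a_oh = RAMAN_SCALE * (preset.w_cell * phi_c + preset.w_ecm * preset.phi_ecm)
    return {"a_ch": a_ch, "a_oh": a_oh, "ratio": (a_ch / a_oh) if a_oh > 0 else np.inf}


def make_raman(
    preset: ConditionPreset,
    seed: int,
    with_pdms: bool = True,
    with_medium: bool = True,
    with_baseline: bool = True,
    n_points: int = 801,
    noise_snr: float | None = "preset",
) -> tuple[Spectrum, dict]:
    """High-wavenumber Raman spectrum with analytic band-area ground truth.

    CH band: three Gaussians (2850/2885/2935 cm^-1) with total area
    proportional to kappa * d_cell * Phi_cell.  OH band: two broad Gaussians
    (3230/3420 cm^-1) with total area proportional to
    w_cell * Phi_cell + w_ecm * Phi_ECM.  Optional polynomial fluorescence
    baseline, PDMS-chip doublet at ``pdms_level`` of the chip reference and
    culture-medium OH at ``medium_level`` of the medium reference, plus
    additive Gaussian noise (CCD-dominated regime).
    """
    if noise_snr == "preset":
        noise_snr = preset.noise_snr
    x = np.linspace(RAMAN_AXIS[0], RAMAN_AXIS[1], n_points)
    areas = raman_truth_areas(preset)
    signal = areas["a_ch"] * _profile(x, CH_COMPONENTS) + areas["a_oh"] * _profile(x, OH_COMPONENTS)
    pdms_level = preset.pdms_level if with_pdms else 0.0
    medium_level = preset.medium_level if with_medium else 0.0
    if pdms_level:
        signal = signal + pdms_level * PDMS_REF_AREA * _profile(x, PDMS_COMPONENTS)
    if medium_level:
        signal = signal + medium_level * MEDIUM_REF_AREA * _profile(x, MEDIUM_COMPONENTS)
    peak = float(signal.max()) or 1.0
    if with_baseline:
        u = (x - RAMAN_AXIS[0]) / (RAMAN_AXIS[1] - RAMAN_AXIS[0])
        baseline = peak * np.polyval(list(reversed(preset.baseline_coeffs)), u)
        signal = signal + baseline
    if noise_snr is not None and np.isfinite(noise_snr):
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, peak / noise_snr, size=x.size)
    truth = {
        "kind": "raman",
        "condition": preset.name,
        "phi_ecm": preset.phi_ecm,
        "w_cell": preset.w_cell,
        "w_ecm": preset.w_ecm,
        "kappa": preset.kappa,
        "a_ch": areas["a_ch"],
        "a_oh": areas["a_oh"],
        "ratio": areas["ratio"],
        "pdms_level": pdms_level,
        "medium_level": medium_level,
        "noise_snr": None if noise_snr is None else float(noise_snr),
        "seed": seed,
    }
    spec = Spectrum(
        kind="raman",
        axis=x,
        intensity=np.clip(signal, 0.0, None),
        meta={"condition": preset.name, "seed": str(seed)},
    )
    return spec, truth


def make_reference_set(
    seed: int,
    preset: ConditionPreset | None = None,
    noise_snr: float | None = 500.0,
    n_points: int = 801,
) -> RamanReferences:
    """Reference spectra for the subtraction chain.

    pdms: chip doublet only; medium: OH band only; offchip: a clean spheroid
    spectrum of the given condition preset (no chip or medium contamination,
    no fluorescence).  The off-chip spheroid defines the expected clean band
    areas, so it must match the condition of the samples being analysed
    (default: control).  References are acquired long and averaged, hence
    the high default SNR.
    """
    preset = preset or PRESETS["control"]
    x = np.linspace(RAMAN_AXIS[0], RAMAN_AXIS[1], n_points)

    def _noisy(y: np.ndarray, sub: int) -> np.ndarray:
        if noise_snr is None or not np.isfinite(noise_snr):
            return y
        peak = float(np.max(y)) or 1.0
        child = np.random.default_rng(np.random.SeedSequence([seed, sub]))
        return np.clip(y + child.normal(0.0, peak / noise_snr, size=y.size), 0.0, None)
    pdms = PDMS_REF_AREA * _profile(x, PDMS_COMPONENTS)
    medium = MEDIUM_REF_AREA * _profile(x, MEDIUM_COMPONENTS)
    offchip, _ = make_raman(
        preset, seed=seed, with_pdms=False, with_medium=False, with_baseline=False,
        n_points=n_points, noise_snr=noise_snr,
    )
    return RamanReferences(
        pdms=Spectrum("raman", x, _noisy(pdms, 1), meta={"role": "pdms"}),
        medium=Spectrum("raman", x, _noisy(medium, 2), meta={"role": "medium"}),
        offchip=offchip,
    )


# ---------------------------------------------------------------------------
# morphometry images
# ---------------------------------------------------------------------------


@dataclass
class NucleiSample:
    """Synthetic nuclei image bundle: labels, spheroid mask, optional
    intensity channel, and per-nucleus ground truth."""

    labels: np.ndarray
    mask: np.ndarray
    intensity: np.ndarray | None
    truth: dict


def _ellipse_mask(shape, rc, cc, a, b, theta, supersample: int = 1) -> np.ndarray:
    """Boolean raster of an ellipse (semi-axes a, b; a along theta)."""
    n = shape[0] * supersample
    m = shape[1] * supersample
    rows = (np.arange(n) + 0.5) / supersample - 0.5
    cols = (np.arange(m) + 0.5) / supersample - 0.5
    dy = rows[:, None] - rc
    dx = cols[None, :] - cc
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_nuclei_image(
    n: int = 200,
    ar_mean: float = 1.30,
    ar_sd: float = 0.15,
    zone_effect: float = 0.0,
    seed: int = 0,
    size: int = 512,
    band: float = 25.0,
    minor_mean: float = 7.0,
    minor_sd: float = 0.8,
    positive_fraction_true: float = 0.0,
    positive_shift_sd: float = 5.0,
    control_mean: float = 100.0,
    control_sd: float = 10.0,
    max_retries: int = 2000,
) -> NucleiSample:
    """Non-overlapping elliptical nuclei inside a circular spheroid mask.

    Aspect ratios are drawn per zone: nuclei whose centroid lies within
    ``band`` pixels of the mask boundary are peripheral and get mean
    ``ar_mean + zone_effect``.  When ``positive_fraction_true`` > 0 an
    intensity channel is emitted where that fraction of nuclei is brightened
    by ``positive_shift_sd`` control SDs above the control level.
    """
    rng = np.random.default_rng(seed)
    radius = 0.45 * size
    center = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2
    labels = np.zeros((size, size), dtype=np.int32)
    occupancy = np.zeros((size, size), dtype=bool)
    nuclei = []
    for i in range(1, n + 1):
        placed = False
        for _ in range(max_retries):
            minor = float(np.clip(rng.normal(minor_mean, minor_sd), 4.0, minor_mean + 3 * minor_sd))
            rho_max = radius - (ar_mean + zone_effect + 3 * ar_sd) * minor - 2.0
            rho = rho_max * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            rc = center + rho * np.sin(ang)
            cc = center + rho * np.cos(ang)
            dist_to_boundary = radius - rho
            zone = "periphery" if dist_to_boundary <= band else "center"
            mean_ar = ar_mean + (zone_effect if zone == "periphery" else 0.0)
            ar = float(max(1.02, rng.normal(mean_ar, ar_sd)))
            theta = rng.uniform(0, np.pi)
            major = ar * minor
            pix = _ellipse_mask((size, size), rc, cc, major, minor, theta)
            guard = _ellipse_mask((size, size), rc, cc, major + 1.5, minor + 1.5, theta)
            if not occupancy[guard].any():
                labels[pix] = i
                occupancy |= guard
                nuclei.append(
                    {
                        "label": i,
                        "centroid": (rc, cc),
                        "aspect_ratio": ar,
                        "major_axis": 2 * major,
                        "minor_axis": 2 * minor,
                        "orientation": theta,
                        "zone": zone,
                        "dist_to_boundary": dist_to_boundary,
                    }
                )
                placed = True
                break
        if not placed:
            raise PackingError(f"could not place nucleus {i} of {n} after {max_retries} retries")
    intensity = None
    if positive_fraction_true > 0:
        intensity = np.zeros((size, size), dtype=float)
        positives = rng.uniform(size=n) < positive_fraction_true
        for rec, pos in zip(nuclei, positives):
            level = rng.normal(control_mean, control_sd)
            if pos:
                level += positive_shift_sd * control_sd
            intensity[labels == rec["label"]] = level
            rec["is_positive"] = bool(pos)
            rec["intensity"] = float(level)
    truth = {
        "kind": "nuclei",
        "n": n,
        "ar_mean": ar_mean,
        "ar_sd": ar_sd,
        "zone_effect": zone_effect,
        "band": band,
        "radius": radius,
        "positive_fraction_true": positive_fraction_true,
        "control_mean": control_mean,
        "control_sd": control_sd,
        "nuclei": nuclei,
        "seed": seed,
    }
    return NucleiSample(labels=labels, mask=mask.astype(np.uint8), intensity=intensity, truth=truth)


def make_invasion_masks(
    core_radius: float = 60.0,
    spread: float = 40.0,
    n_protrusions: int = 8,
    seed: int = 0,
    size: int | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Core disk plus radial protrusions; truth areas by fine quadrature.

    The core is a disk; the total outline adds ``n_protrusions`` radially
    oriented elliptical protrusions centered on the core boundary.  Truth
    areas come from an 8x supersampled raster of the same continuous
    geometry (the ellipse-circle union has no convenient closed form).
    """
    rng = np.random.default_rng(seed)
    if size is None:
        size = int(2 * (core_radius + max(spread, 0)) + 21)
    center = size / 2.0
    ss = 8

    def _disk(supersample):
        m = _ellipse_mask((size, size), center, center, core_radius, core_radius, 0.0, supersample)
        return m

    core = _disk(1)
    core_fine = _disk(ss)
    total = core.copy()
    total_fine = core_fine.copy()
    protrusions = []
    if spread > 0 and n_protrusions > 0:
        spacing = 2 * np.pi / n_protrusions
        for k in range(n_protrusions):
            ang = k * spacing + rng.uniform(-0.2, 0.2) * spacing
            a = spread * rng.uniform(0.6, 1.0)  # radial semi-axis
            b = rng.uniform(8.0, 14.0)  # tangential half-width
            rc = center + core_radius * np.sin(ang)
            cc = center + core_radius * np.cos(ang)
            theta = np.arctan2(np.sin(ang), np.cos(ang))
            total |= _ellipse_mask((size, size), rc, cc, a, b, theta)
            total_fine |= _ellipse_mask((size, size), rc, cc, a, b, theta, ss)
            protrusions.append({"angle": ang, "a": a, "b": b})
    core_area = float(core_fine.sum()) / ss**2
    total_area = float(total_fine.sum()) / ss**2
    truth = {
        "kind": "invasion",
        "core_radius": core_radius,
        "spread": spread,
        "n_protrusions": n_protrusions,
        "core_area": core_area,
        "core_area_analytic": float(np.pi * core_radius**2),
        "total_area": total_area,
        "ratio": (total_area - core_area) / core_area,
        "protrusions": protrusions,
        "seed": seed,
    }
    return core.astype(np.uint8), total.astype(np.uint8), truth


def make_dextran_image(
    size: int = 256,
    radius: float = 100.0,
    interstitial_level: float = 50.0,
    background: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Interstitial dextran intensity image over a spheroid mask."""
    rng = np.random.default_rng(seed)
    center = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - center) ** 2 + (xx - center) ** 2 <= radius**2
    image = np.full((size, size), background, dtype=float)
    image[mask] += interstitial_level
    image += rng.normal(0.0, noise_sd, size=image.shape)
    truth = {
        "kind": "dextran",
        "interstitial_level": interstitial_level,
        "background": background,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return image, mask.astype(np.uint8), truth


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _child_seed(master: int, *idx: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([master, *idx]).generate_state(1)[0] % (2**31 - 1))


def make_dataset(
    conditions: list[str],
    n_per: int,
    seed: int,
    outdir: str | Path,
    overwrite: bool = False,
    n_calibration: int = 10,
    with_images: bool = True,
) -> Path:
    """Write a complete synthetic dataset tree with manifest and ground truth.

    Per condition: ``n_per`` samples (Brillouin + Raman spectra, nuclei
    label/mask images) with JSON ground-truth sidecars, plus a matching
    reference set under ``refs/<condition>/``.  A calibration set of
    compressed-preset Raman spectra (known Phi_ECM = 0) is always included
    under ``calibration/`` for kappa calibration.  Returns the manifest path.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise BrismaError(f"{outdir} exists and is not empty; pass overwrite=True")
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    records: list[SampleRecord] = []
    for ci, cond in enumerate(conditions):
        if cond not in PRESETS:
            raise ConfigurationError(f"no preset for condition {cond!r}")
        preset = PRESETS[cond]
        refdir = outdir / "refs" / cond
        refdir.mkdir(parents=True, exist_ok=True)
        refs = make_reference_set(_child_seed(seed, ci, 9000), preset=preset)
        write_spectrum(refs.pdms, refdir / "pdms.txt")
        write_spectrum(refs.medium, refdir / "medium.txt")
        write_spectrum(refs.offchip, refdir / "offchip.txt")
        for j in range(n_per):
            sid = f"{cond}_{j:03d}"
            sdir = outdir / "samples"
            bspec, btruth = make_brillouin(preset, _child_seed(seed, ci, j, 1))
            rspec, rtruth = make_raman(preset, _child_seed(seed, ci, j, 2))
            bpath = sdir / f"{sid}_brillouin.txt"
            rpath = sdir / f"{sid}_raman.txt"
            write_spectrum(bspec, bpath)
            write_spectrum(rspec, rpath)
            image_path = None
            itruth = {}
            if with_images:
                nuc = make_nuclei_image(n=60, size=256, band=20.0, seed=_child_seed(seed, ci, j, 3))
                image_path = sdir / f"{sid}_labels.tif"
                write_image(nuc.labels, image_path)
                write_image(nuc.mask, sdir / f"{sid}_mask.tif")
                itruth = nuc.truth
            truth = {"brillouin": btruth, "raman": rtruth, "image": itruth}
            (sdir / f"{sid}_truth.json").write_text(json.dumps(truth, sort_keys=True, default=str))
            # manifest paths are relative to the manifest so the tree is
            # relocatable and byte-identical across runs
            records.append(
                SampleRecord(
                    sample_id=sid,
                    condition=cond,
                    objective="20x",
                    time_bin_min="",
                    brillouin_path=str(bpath.relative_to(outdir)),
                    raman_path=str(rpath.relative_to(outdir)),
                    image_path=str(image_path.relative_to(outdir)) if image_path else None,
                )
            )
    caldir = outdir / "calibration"
    caldir.mkdir(parents=True, exist_ok=True)
    cal_preset = PRESETS["compressed"]
    cal_refs = make_reference_set(_child_seed(seed, 99, 9000), preset=cal_preset)
    write_spectrum(cal_refs.pdms, caldir / "pdms.txt")
    write_spectrum(cal_refs.medium, caldir / "medium.txt")
    write_spectrum(cal_refs.offchip, caldir / "offchip.txt")
    for j in range(n_calibration):
        cspec, ctruth = make_raman(cal_preset, _child_seed(seed, 99, j))
        write_spectrum(cspec, caldir / f"compressed_{j:03d}_raman.txt")
        (caldir / f"compressed_{j:03d}_truth.json").write_text(
            json.dumps(ctruth, sort_keys=True, default=str)
        )
    manifest = write_manifest(records, outdir / "manifest.csv")
    return manifest
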