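"""Brillouin spectrum analysis: DHO lineshape fitting.

The measured Brillouin doublet (Stokes at +omega_B, anti-Stokes at -omega_B,
symmetric about the elastic line in a calibrated spectrum) is modelled with a
damped harmonic oscillator (DHO) spectral function

    I(nu) = B + A * Gamma * omega_B**2 / ((nu**2 - omega_B**2)**2 + (Gamma*nu)**2)

with omega_B the Brillouin frequency shift (GHz), Gamma the full linewidth
(GHz, acoustic attenuation), A the amplitude (peak height ~ A/Gamma) and B a
flat background.  Evaluated at both signs of nu, one parameter set describes
both peaks.

The analysis protocol is two-stage:

1. fit the Stokes and anti-Stokes peaks separately and check their symmetry
   with respect to the elastic line; if asymmetric, rigidly shift the
   frequency axis until symmetric (drift recalibration);
2. fit a single DHO to the whole (recentered) spectrum, excluding a window
   around the elastic line, and use its parameters downstream.

:class:`BrillouinDHOModel` / :class:`DHOResults` wrap the protocol in a
model/results pair; :func:`locate_peaks`, :func:`recenter_axis` and
:func:`fit_dho` expose the individual stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model as _LmfitModel
from scipy.signal import find_peaks

from .exceptions import CalibrationError, FitError, PeakDetectionError
from .io import Spectrum

__all__ = [
    "DEFAULT_EXCLUSION_GHZ",
    "dho_lineshape",
    "PeakPair",
    "DHOFit",
    "locate_peaks",
    "recenter_axis",
    "fit_dho",
    "BrillouinDHOModel",
    "DHOResults",
    "normalize_to_controls",
]

#: Half-width (GHz) of the elastic-line exclusion window around nu = 0.
DEFAULT_EXCLUSION_GHZ = 2.0

#: Largest plausible drift of the elastic line; beyond this the instrument
#: is grossly miscalibrated rather than drifting.
DEFAULT_MAX_OFFSET_GHZ = 0.5

#: Symmetry tolerance (GHz) after recentering.
DEFAULT_SYMMETRY_TOL_GHZ = 0.01


def dho_lineshape(nu, omega_b, gamma, amplitude, background):
    """DHO spectral function, valid at both signs of ``nu``."""
    nu = np.asarray(nu, dtype=float)
    return background + amplitude * gamma * omega_b**2 / (
        (nu**2 - omega_b**2) ** 2 + (gamma * nu) ** 2
    )


@dataclass
class PeakPair:
    """Stokes / anti-Stokes peak positions from the symmetry-check stage."""

    nu_stokes: float  # GHz, > 0
    nu_antistokes: float  # GHz, < 0

    @property
    def asymmetry(self) -> float:
        """nu_stokes + nu_antistokes; 0 for a calibrated axis."""
        return self.nu_stokes + self.nu_antistokes


@dataclass
class DHOFit:
    """Parameters of a converged single-DHO fit."""

    omega_b: float  # GHz
    gamma: float  # GHz, full linewidth
    amplitude: float
    background: float
    recenter_offset: float  # GHz axis shift applied before the final fit
    rss: float
    se_omega: float
    se_gamma: float
    converged: bool = True
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.omega_b <= self.gamma / 4:
            warnings.warn(
                f"omega_b={self.omega_b:.3f} GHz <= gamma/4={self.gamma / 4:.3f} GHz: "
                "peak barely resolvable",
                RuntimeWarning,
                stacklevel=2,
            )


def _robust_noise(y: np.ndarray) -> float:
    """Noise scale from the median absolute successive difference."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def _side_fit(nu: np.ndarray, y: np.ndarray, nu0: float, width0: float):
    """Fit a single-sided DHO (in |nu|) around the detected grid peak.

    Returns the refined |peak position| on this half axis.
    """
    x = np.abs(nu)
    model = _LmfitModel(dho_lineshape)
    p = model.make_params(
        omega_b=dict(value=abs(nu0), min=x.min(), max=x.max()),
        gamma=dict(value=max(width0, 0.1), min=0.02, max=10.0),
        amplitude=dict(value=max((y.max() - y.min()) * max(width0, 0.1), 1e-12), min=0.0),
        background=dict(value=max(float(np.min(y)), 0.0), min=0.0),
    )
    try:
        res = model.fit(y, p, nu=x, method="least_squares", fit_kws={"xtol": 1e-13, "ftol": 1e-13})
    except Exception as exc:  # pragma: no cover - lmfit internal failure
        raise FitError(f"single-sided DHO fit failed: {exc}") from exc
    return float(res.params["omega_b"].value)


def locate_peaks(
    spectrum: Spectrum,
    exclusion: float = DEFAULT_EXCLUSION_GHZ,
    prominence_factor: float = 8.0,
    refine: bool = True,
) -> PeakPair:
    """Find the most prominent Brillouin peak on each side of the elastic line.

    Candidates are detected on the grid with a prominence threshold of
    ``prominence_factor`` times the robust noise level, outside the
    ``|nu| < exclusion`` window, then (optionally) refined by a single-sided
    DHO fit on each half axis, which is the Stokes/anti-Stokes stage of the
    fitting protocol.

    Raises
    ------
    PeakDetectionError
        If either side lacks a sufficiently prominent peak (empty or turbid
        acquisition).
    """
    if spectrum.kind != "brillouin":
        raise ValueError("locate_peaks expects a Brillouin spectrum")
    nu, y = spectrum.axis, spectrum.intensity
    if nu[0] >= -exclusion or nu[-1] <= exclusion:
        raise PeakDetectionError(
            "spectrum must cover both signs of frequency outside the elastic-line window"
        )
    noise = _robust_noise(y)
    positions: dict[str, float] = {}
    for side in ("antistokes", "stokes"):
        mask = nu <= -exclusion if side == "antistokes" else nu >= exclusion
        xs, ys = nu[mask], y[mask]
        floor = max(noise * prominence_factor, 1e-3 * (y.max() - y.min()), 1e-30)
        idx, props = find_peaks(ys, prominence=floor)
        # a real peak must also rise clearly above the side's typical level,
        # which rejects pure-noise excursions that pass the prominence floor
        height_floor = float(np.median(ys)) + prominence_factor * noise
        keep = ys[idx] >= height_floor
        idx, prominences = idx[keep], props["prominences"][keep]
        if idx.size == 0:
            raise PeakDetectionError(
                f"no {side} peak with prominence >= {floor:.3g} outside |nu| < {exclusion} GHz"
            )
        best = idx[np.argmax(prominences)]
        nu0 = xs[best]
        if refine:
            pos = _side_fit(xs, ys, nu0, 0.5)
        else:
            pos = abs(float(nu0))
        positions[side] = pos if side == "stokes" else -pos
    # account for an axis offset: the single-sided fits are in |nu|, so the
    # signed grid positions carry the offset while the fit refines magnitude
    return PeakPair(nu_stokes=positions["stokes"], nu_antistokes=positions["antistokes"])


def recenter_axis(
    spectrum: Spectrum,
    pair: PeakPair | None = None,
    tol: float = DEFAULT_SYMMETRY_TOL_GHZ,
    max_offset: float = DEFAULT_MAX_OFFSET_GHZ,
    exclusion: float = DEFAULT_EXCLUSION_GHZ,
    max_iter: int = 6,
) -> tuple[Spectrum, float]:
    """Shift the frequency axis so Stokes/anti-Stokes peaks are symmetric.

    The offset is ``asymmetry / 2`` from the single-sided peak fits, applied
    iteratively until ``|asymmetry|`` drops below ``min(tol, 2e-3)`` GHz (the
    iteration converges in one or two steps for drift-scale offsets).

    Raises
    ------
    CalibrationError
        If the cumulative offset exceeds ``max_offset`` (gross
        miscalibration rather than drift).
    """
    if pair is None:
        pair = locate_peaks(spectrum, exclusion=exclusion)
    inner_tol = min(tol, 2e-3)
    total = 0.0
    current = spectrum
    for _ in range(max_iter):
        offset = pair.asymmetry / 2.0
        if abs(total + offset) > max_offset:
            raise CalibrationError(
                f"axis offset {total + offset:+.3f} GHz exceeds max_offset={max_offset} GHz"
            )
        total += offset
        current = current.copy(axis=current.axis - offset)
        pair = locate_peaks(current, exclusion=exclusion)
        if abs(pair.asymmetry) < inner_tol:
            break
    if abs(pair.asymmetry) >= tol:
        raise CalibrationError(
            f"residual asymmetry {pair.asymmetry:+.4f} GHz after recentering (tol {tol} GHz)"
        )
    return current, total


def fit_dho(
    spectrum: Spectrum,
    init: DHOFit | None = None,
    exclusion: float = DEFAULT_EXCLUSION_GHZ,
    recenter_offset: float = 0.0,
    n_restarts: int = 3,
) -> DHOFit:
    """Fit a single DHO to the whole two-sided spectrum.

    The fit excludes ``|nu| < exclusion`` (the elastic line is never
    modelled).  Initialization comes from :func:`locate_peaks` positions and
    half-prominence widths unless an explicit seed is given.  On
    non-convergence, up to ``n_restarts`` seeded random restarts perturb the
    initial values.

    Standard errors are taken from the residual covariance (chi-square
    scaled); ``rss`` is the residual sum of squares over the fitted points.
    """
    nu, y = spectrum.axis, spectrum.intensity
    mask = np.abs(nu) >= exclusion
    xf, yf = nu[mask], y[mask]
    if xf.size < 8:
        raise FitError("too few points outside the elastic-line exclusion window")
    if np.ptp(yf) <= 0:
        raise FitError("constant spectrum: nothing to fit")

    if init is None:
        try:
            pair = locate_peaks(spectrum, exclusion=exclusion)
        except PeakDetectionError as exc:
            raise FitError(f"cannot initialize DHO fit: {exc}") from exc
        omega0 = (pair.nu_stokes - pair.nu_antistokes) / 2.0
        gamma0 = 1.0
        bg0 = max(float(np.percentile(yf, 5)), 0.0)
        amp0 = max((float(yf.max()) - bg0) * gamma0, 1e-12)
    else:
        omega0, gamma0, amp0, bg0 = init.omega_b, init.gamma, init.amplitude, init.background

    model = _LmfitModel(dho_lineshape)
    gamma_min = 0.02

    def _run(o0, g0, a0, b0):
        p = model.make_params(
            omega_b=dict(value=o0, min=exclusion, max=float(np.abs(xf).max())),
            gamma=dict(value=g0, min=gamma_min, max=10.0),
            amplitude=dict(value=a0, min=0.0),
            background=dict(value=b0, min=0.0),
        )
        return model.fit(
            yf, p, nu=xf, method="least_squares", fit_kws={"xtol": 1e-14, "ftol": 1e-14, "gtol": 1e-14}
        )

    result = _run(omega0, gamma0, amp0, bg0)
    rng = np.random.default_rng(0)
    tries = 0
    while not result.success and tries < n_restarts:
        jitter = rng.uniform(0.7, 1.3, size=3)
        result = _run(omega0 * jitter[0], gamma0 * jitter[1], amp0 * jitter[2], bg0)
        tries += 1
    if not result.success:
        raise FitError(f"DHO fit did not converge after {n_restarts} restarts: {result.message}")

    pv = result.params
    if pv["gamma"].value <= gamma_min * 1.01:
        warnings.warn("gamma collapsed to its lower bound: degenerate linewidth", RuntimeWarning)

    def _se(name: str) -> float:
        err = pv[name].stderr
        return float(err) if err is not None and np.isfinite(err) else float("nan")

    return DHOFit(
        omega_b=float(pv["omega_b"].value),
        gamma=float(pv["gamma"].value),
        amplitude=float(pv["amplitude"].value),
        background=float(pv["background"].value),
        recenter_offset=float(recenter_offset),
        rss=float(np.sum(result.residual**2)),
        se_omega=_se("omega_b"),
        se_gamma=_se("gamma"),
        converged=bool(result.success),
        n_points=int(xf.size),
    )


@dataclass
class DHOResults:
    """Results of :meth:`BrillouinDHOModel.fit`.

    Carries the fitted :class:`DHOFit` plus the symmetry-stage diagnostics,
    with a statsmodels-style :meth:`summary`.
    """

    fit: DHOFit
    pair: PeakPair | None
    model: "BrillouinDHOModel"

    @property
    def omega_b(self) -> float:
        return self.fit.omega_b

    @property
    def gamma(self) -> float:
        return self.fit.gamma

    def as_dict(self) -> dict:
        d = dict(self.fit.__dict__)
        if self.pair is not None:
            d["nu_stokes"] = self.pair.nu_stokes
            d["nu_antistokes"] = self.pair.nu_antistokes
            d["asymmetry"] = self.pair.asymmetry
        return d

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Brillouin DHO fit",
            "=================",
            f"points fitted          {f.n_points}",
            f"omega_B   [GHz]        {f.omega_b:10.4f}  (se {f.se_omega:.4f})",
            f"Gamma     [GHz]        {f.gamma:10.4f}  (se {f.se_gamma:.4f})",
            f"amplitude              {f.amplitude:10.4g}",
            f"background             {f.background:10.4g}",
            f"recenter offset [GHz]  {f.recenter_offset:+10.4f}",
            f"RSS                    {f.rss:10.4g}",
            f"converged              {f.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay the data and the fitted lineshape."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.spectrum_recentered or self.model.spectrum
        ax.plot(s.axis, s.intensity, ".", ms=3, label="data")
        xs = np.linspace(s.axis[0], s.axis[-1], 1000)
        f = self.fit
        ax.plot(xs, dho_lineshape(xs, f.omega_b, f.gamma, f.amplitude, f.background), "-", label="DHO fit")
        ax.set_xlabel("frequency shift (GHz)")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


class BrillouinDHOModel:
    """Two-stage DHO model for a Brillouin spectrum.

    Parameters
    ----------
    spectrum:
        A Brillouin :class:`~brisma.io.Spectrum` covering both signs of
        frequency.
    exclusion:
        Half-width of the elastic-line exclusion window (GHz).
    recenter:
        Run the Stokes/anti-Stokes symmetry check and axis recentering
        before the final single-DHO fit.
    """

    def __init__(
        self,
        spectrum: Spectrum,
        exclusion: float = DEFAULT_EXCLUSION_GHZ,
        recenter: bool = True,
        symmetry_tol: float = DEFAULT_SYMMETRY_TOL_GHZ,
        max_offset: float = DEFAULT_MAX_OFFSET_GHZ,
    ):
        self.spectrum = spectrum
        self.exclusion = exclusion
        self.recenter = recenter
        self.symmetry_tol = symmetry_tol
        self.max_offset = max_offset
        self.spectrum_recentered: Spectrum | None = None

    def fit(self, init: DHOFit | None = None) -> DHOResults:
        offset = 0.0
        working = self.spectrum
        pair = locate_peaks(working, exclusion=self.exclusion)
        if self.recenter:
            working, offset = recenter_axis(
                working,
                pair,
                tol=self.symmetry_tol,
                max_offset=self.max_offset,
                exclusion=self.exclusion,
            )
            pair = locate_peaks(working, exclusion=self.exclusion)
        self.spectrum_recentered = working
        fit = fit_dho(working, init=init, exclusion=self.exclusion, recenter_offset=offset)
        return DHOResults(fit=fit, pair=pair, model=self)


def normalize_to_controls(
    omega: np.ndarray,
    condition: np.ndarray,
    batch: np.ndarray | None = None,
    control_label: str = "control",
) -> np.ndarray:
    """Divide each fitted shift by the mean control shift of its batch.

    ``batch`` typically encodes the objective (20x vs 60x) or acquisition
    session, matching per-panel normalization of grouped measurements.
    """
    omega = np.asarray(omega, float)
    condition = np.asarray(condition)
    if batch is None:
        batch = np.zeros(omega.shape, dtype=int)
    batch = np.asarray(batch)
    out = np.full_like(omega, np.nan)
    for b in np.unique(batch):
        sel = batch == b
        ctrl = omega[sel & (condition == control_label)]
        if ctrl.size == 0:
            raise ValueError(f"batch {b!r} has no {control_label!r} samples to normalize against")
        out[sel] = omega[sel] / ctrl.mean()
    return out
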