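"""End-to-end synthetic validation studies.

These reproduce, at desk scale, the two quantitative readouts of the
analysis on generated data with known ground truth:

* :func:`composition_recovery_study` — the Raman -> biphasic-composition
  chain: generate contaminated on-chip spectra for one condition, calibrate
  kappa on a compressed-spheroid reference set (known Phi_ECM = 0), and
  estimate the ECM/cell volume fractions per sample.
* :func:`ecm_shift_inversion_study` — the Brillouin mixture inversion:
  fit matched compressed (pure-cell) and uncompressed spheroid spectra with
  the single-DHO protocol and invert the linear mixing rule for the ECM
  component shift.

Seeding is hierarchical: every random stream derives deterministically from
one master seed.
"""

from __future__ import annotations

import numpy as np

from .biphasic import CompositionModel, estimate_phi, invert_omega_ecm
from .brillouin import BrillouinDHOModel
from .composition import kappa_from_reference_samples
from .raman import ch_oh_ratio
from .synthetic import PRESETS, make_brillouin, make_raman, make_reference_set

__all__ = ["composition_recovery_study", "ecm_shift_inversion_study"]


def _child(master: int, *idx: int) -> int:
    return int(np.random.SeedSequence([master, *idx]).generate_state(1)[0] % (2**31 - 1))


def composition_recovery_study(
    condition: str = "control",
    n: int = 20,
    master_seed: int = 42,
    n_calibration: int = 10,
) -> dict:
    """Run the full Raman composition chain on one synthetic condition.

    Generates ``n`` on-chip spectra (with PDMS and medium contamination) and
    the matching reference set, calibrates kappa on ``n_calibration``
    compressed-preset spectra, and estimates Phi_ECM / Phi_cell per sample.

    Returns a dict with per-sample estimates and their means, plus the
    calibrated kappa and the generator truth.
    """
    preset = PRESETS[condition]
    cal_preset = PRESETS["compressed"]
    cal_refs = make_reference_set(_child(master_seed, 9, 0), preset=cal_preset)
    cal_samples = [
        make_raman(cal_preset, _child(master_seed, 9, 1 + i))[0] for i in range(n_calibration)
    ]
    model = CompositionModel(w_cell=preset.w_cell, w_ecm=preset.w_ecm)
    kappa = kappa_from_reference_samples(cal_samples, cal_refs, phi_ecm_ref=0.0, model=model)
    model = CompositionModel(w_cell=preset.w_cell, w_ecm=preset.w_ecm, kappa=kappa)

    refs = make_reference_set(_child(master_seed, 1, 0), preset=preset)
    phi_ecm, phi_cell, ratios = [], [], []
    for i in range(n):
        sample, _ = make_raman(preset, _child(master_seed, 2, i))
        result = ch_oh_ratio(sample, refs)
        est = estimate_phi(result.ratio, model)
        ratios.append(result.ratio)
        phi_ecm.append(est.phi_ecm)
        phi_cell.append(est.phi_cell)
    return {
        "condition": condition,
        "n": n,
        "kappa": kappa,
        "ratios": ratios,
        "phi_ecm": phi_ecm,
        "phi_cell": phi_cell,
        "mean_phi_ecm": float(np.mean(phi_ecm)),
        "mean_phi_cell": float(np.mean(phi_cell)),
        "truth_phi_ecm": preset.phi_ecm,
    }


def ecm_shift_inversion_study(
    phi_ecm: float,
    n_pairs: int = 10,
    master_seed: int = 7,
    uncompressed_condition: str = "control",
) -> dict:
    """Recover the ECM component shift from compressed/uncompressed pairs.

    For each pair, the compressed spheroid's single-DHO fit gives the cell
    component shift (its interstitial spaces are negligible) and the
    uncompressed fit gives the composite; the linear mixing rule is inverted
    at the externally supplied ``phi_ecm`` (normally the Raman-chain
    estimate for the uncompressed condition).
    """
    comp = PRESETS["compressed"]
    unc = PRESETS[uncompressed_condition]
    omega_ecm = []
    omega_cell_fits = []
    omega_b_fits = []
    for i in range(n_pairs):
        spec_c, _ = make_brillouin(comp, _child(master_seed, i, 0))
        spec_u, _ = make_brillouin(unc, _child(master_seed, i, 1))
        fit_c = BrillouinDHOModel(spec_c).fit()
        fit_u = BrillouinDHOModel(spec_u).fit()
        value, _ = invert_omega_ecm(fit_u.omega_b, fit_c.omega_b, phi_ecm)
        omega_cell_fits.append(fit_c.omega_b)
        omega_b_fits.append(fit_u.omega_b)
        omega_ecm.append(value)
    return {
        "n_pairs": n_pairs,
        "phi_ecm": phi_ecm,
        "omega_cell_fits": omega_cell_fits,
        "omega_b_fits": omega_b_fits,
        "omega_ecm": omega_ecm,
        "mean_omega_ecm": float(np.mean(omega_ecm)),
        "truth_omega_ecm": unc.omega_ecm,
    }
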