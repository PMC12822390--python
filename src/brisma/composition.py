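"""Model/results wrapper tying the Raman pipeline to the biphasic model.

:class:`SpheroidCompositionModel` takes a raw on-chip Raman spectrum plus
the reference set and, on :meth:`fit`, runs the full processing chain
(baseline, factor calibration, subtractions, band integration) and inverts
the biphasic water model for the cell/ECM volume fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biphasic import (
    CompositionEstimate,
    CompositionModel,
    calibrate_kappa,
    estimate_phi,
)
from .exceptions import CalibrationError
from .io import Spectrum
from .raman import BandWindows, RamanReferences, RamanResult, ch_oh_ratio

__all__ = ["SpheroidCompositionModel", "CompositionResults", "kappa_from_reference_samples"]


def kappa_from_reference_samples(
    samples: list[Spectrum],
    refs: RamanReferences,
    phi_ecm_ref: float,
    model: CompositionModel | None = None,
    windows: BandWindows | None = None,
) -> float:
    """Calibrate kappa from spectra of known composition.

    Typically the known-composition samples are compressed spheroids
    (interstitial water expelled, Phi_ECM ~ 0) processed with their own
    matching reference set; the mean measured CH/OH ratio anchors kappa.
    """
    if not samples:
        raise CalibrationError("need at least one reference sample for kappa calibration")
    model = model or CompositionModel()
    ratios = [ch_oh_ratio(s, refs, windows=windows).ratio for s in samples]
    r_ref = sum(ratios) / len(ratios)
    return calibrate_kappa(r_ref, phi_ecm_ref, model)


@dataclass
class CompositionResults:
    """Results of :meth:`SpheroidCompositionModel.fit`."""

    raman: RamanResult
    estimate: CompositionEstimate
    model: CompositionModel

    @property
    def phi_ecm(self) -> float:
        return self.estimate.phi_ecm

    @property
    def phi_cell(self) -> float:
        return self.estimate.phi_cell

    @property
    def ratio(self) -> float:
        return self.raman.ratio

    def summary(self) -> str:
        lines = [
            self.raman.summary(),
            "",
            "Biphasic composition",
            "====================",
            f"kappa                {self.model.kappa:12.4f}",
            f"w_cell / d_cell      {self.model.w_cell:8.2f} / {self.model.d_cell:.2f}",
            f"Phi_ECM              {self.estimate.phi_ecm:12.4f}  (se {self.estimate.se_phi:.4f})",
            f"Phi_cell             {self.estimate.phi_cell:12.4f}",
        ]
        if self.estimate.clamped:
            lines.append("note: phi clamped to the physical range (noise)")
        return "\n".join(lines)


class SpheroidCompositionModel:
    """Biphasic composition model for one on-chip Raman acquisition.

    Parameters
    ----------
    sample:
        Raw Raman spectrum acquired on a spheroid inside the chip.
    references:
        PDMS, medium and off-chip references (off-chip spheroid matched to
        the sample's condition).
    composition:
        Compartment parameters; ``composition.kappa`` must be calibrated
        (see :func:`kappa_from_reference_samples`) before :meth:`fit`.
    windows:
        CH/OH integration windows.
    """

    def __init__(
        self,
        sample: Spectrum,
        references: RamanReferences,
        composition: CompositionModel,
        windows: BandWindows | None = None,
    ):
        self.sample = sample
        self.references = references
        self.composition = composition
        self.windows = windows or BandWindows()

    def fit(self) -> CompositionResults:
        if self.composition.kappa is None:
            raise CalibrationError("composition.kappa must be calibrated before fitting")
        raman = ch_oh_ratio(self.sample, self.references, windows=self.windows)
        # ratio SE from the factor-matching residual is not separable here;
        # propagate only when the caller supplies replicate spread upstream
        estimate = estimate_phi(raman.ratio, self.composition)
        return CompositionResults(raman=raman, estimate=estimate, model=self.composition)
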