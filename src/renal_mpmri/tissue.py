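"""Tissue parameter sets for the renal-lesion phantom.

The ground-truth classes mirror the histological spectrum of TSC renal
cystadenomas — fluid-filled cysts, papillary projections and solid adenomas —
embedded in normal parenchyma, with a blood-vessel reference used for
T2-intensity normalization. Quantitative values are chosen to reproduce the
study's operating points at 14.1 T: lesion ADC spanning 0.0007–0.0033 mm²/s
around a 0.0019 mm²/s mean, lesion T1 near 3 s, normalized T2 intensity near
10, and K^trans contrasting poorly-perfused cysts (0.04 min⁻¹) with permeable
solid lesions (0.33 min⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["TissueParams", "TISSUE_CLASSES", "LESION_CLASSES"]


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue quantitative MR parameters.

    pd is an arbitrary-unit proton density into which sequence-constant
    weighting (coil gain, TE decay for sequences where it is fixed) may be
    folded. kep = ktrans/ve must be finite, so ve > 0 always.
    """

    pd: float
    t1_s: float
    t2_ms: float
    adc_mm2_s: float
    ktrans_per_min: float = 0.0
    ve: float = 0.3

    def __post_init__(self) -> None:
        if self.pd <= 0 or self.t1_s <= 0 or self.t2_ms <= 0:
            raise ValueError("pd, t1_s and t2_ms must be positive")
        if self.adc_mm2_s < 0:
            raise ValueError("adc_mm2_s must be non-negative")
        if self.ktrans_per_min < 0:
            raise ValueError("ktrans_per_min must be non-negative")
        if not 0.0 < self.ve <= 1.0:
            raise ValueError("ve must lie in (0, 1]")

    @property
    def kep_per_min(self) -> float:
        return self.ktrans_per_min / self.ve

    def with_(self, **kwargs) -> "TissueParams":
        return replace(self, **kwargs)


#: Default ground-truth parameters per tissue class.
TISSUE_CLASSES: dict[str, TissueParams] = {
    # background: essentially signal-free surround (air/fat-suppressed)
    "background": TissueParams(
        pd=0.05, t1_s=1.0, t2_ms=10.0, adc_mm2_s=0.001, ktrans_per_min=0.0, ve=0.1
    ),
    "parenchyma": TissueParams(
        pd=1.0, t1_s=1.8, t2_ms=18.0, adc_mm2_s=0.0015, ktrans_per_min=0.25, ve=0.4
    ),
    # blood reference for T2 normalization; blood T2 is very short at 14.1 T
    "vessel": TissueParams(
        pd=0.9, t1_s=2.2, t2_ms=5.0, adc_mm2_s=0.003, ktrans_per_min=0.0, ve=1.0
    ),
    # fluid-filled cyst: high ADC/T2/T1, poorly perfused
    "cystic": TissueParams(
        pd=1.3, t1_s=3.2, t2_ms=70.0, adc_mm2_s=0.0028, ktrans_per_min=0.04, ve=0.6
    ),
    # papillary projections: most cellular, lowest ADC
    "papillary": TissueParams(
        pd=1.1, t1_s=2.6, t2_ms=35.0, adc_mm2_s=0.0011, ktrans_per_min=0.20, ve=0.3
    ),
    # solid adenoma: cellular and well perfused
    "solid": TissueParams(
        pd=1.0, t1_s=2.8, t2_ms=25.0, adc_mm2_s=0.0016, ktrans_per_min=0.33, ve=0.3
    ),
}

#: Lesion classes in deterministic order (also the digitization priority order).
LESION_CLASSES: tuple[str, ...] = ("cystic", "papillary", "solid")
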