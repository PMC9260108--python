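"""Quantitative parameter-map container with fit diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry

__all__ = ["ParameterMap", "QUANTITIES"]

QUANTITIES = ("adc_mm2_s", "t1_s", "m0", "t2norm", "ktrans_per_min", "ve", "conc_mM")


@dataclass
class ParameterMap:
    """A 3D quantitative map with units fixed by ``quantity``.

    ``mask`` marks voxels where a fit was attempted and succeeded; voxels that
    failed (non-positive signals, slope out of range, out-of-range estimates)
    are False in ``mask`` and listed in the QC table built by
    :meth:`qc_table` — never silently zeroed.
    """

    quantity: str
    values: np.ndarray
    geometry: AcquisitionGeometry
    mask: np.ndarray
    r2: np.ndarray | None = None
    residual_norm: np.ndarray | None = None
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")

    @property
    def fitted_values(self) -> np.ndarray:
        return self.values[self.mask]

    def qc_table(self):
        """Per-flag voxel counts (import-light; returns a plain dict)."""
        out = {"fitted": int(self.mask.sum()), "unfitted": int((~self.mask).sum())}
        for name, flag in self.flags.items():
            out[name] = int(np.asarray(flag).sum())
        return out
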