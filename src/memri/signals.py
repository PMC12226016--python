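"""The SignalRecord container: a magnitude signal on a TE/TI grid.

This is the universal currency between the synthetic generator, the
fitting routines and the file I/O layer.  Times are stored in
milliseconds, matching the tabular interchange schema
(condition_label, batch_id, ti_ms, te_ms, magnitude, sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = ["SignalRecord"]


@dataclass
class SignalRecord:
    """One acquired (or synthesized) signal.

    For a single-echo T2 series ti_ms is None and te_ms runs over the
    echo times.  For an inversion-recovery multi-echo acquisition both
    ti_ms and te_ms are per-sample arrays of equal length (one row per
    echo), te_ms counted from the excitation that follows each inversion.
    """

    condition_label: str
    batch_id: str
    te_ms: np.ndarray
    magnitude: np.ndarray
    ti_ms: np.ndarray | None = None
    sigma: float = 0.0

    def __post_init__(self):
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.te_ms.shape != self.magnitude.shape:
            raise DomainError("te_ms and magnitude must have equal length")
        if self.ti_ms is not None:
            self.ti_ms = np.asarray(self.ti_ms, dtype=float)
            if self.ti_ms.shape != self.te_ms.shape:
                raise DomainError("ti_ms must align with te_ms")
        if self.sigma < 0:
            raise DomainError("sigma must be nonnegative")

    @property
    def is_inversion_recovery(self) -> bool:
        return self.ti_ms is not None

    def unique_tis(self) -> np.ndarray:
        if self.ti_ms is None:
            raise DomainError("record carries no inversion times")
        # preserve acquisition order
        _, idx = np.unique(self.ti_ms, return_index=True)
        return self.ti_ms[np.sort(idx)]
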