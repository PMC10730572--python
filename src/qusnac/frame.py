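"""The RF frame container shared by the simulator and the estimators."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import TransducerSpec

__all__ = ["RFFrame"]


@dataclass
class RFFrame:
    """Raw radiofrequency echo data with acquisition metadata.

    ``samples`` is (axial samples x lines); depth of sample ``i`` is
    ``depth_origin + (i + 0.5) * c / (2 * sampling_rate)``.
    """

    samples: np.ndarray
    sampling_rate: float
    line_spacing: float
    depth_origin: float
    transducer: TransducerSpec
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D (axial x lines) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_sample_spacing(self) -> float:
        return self.transducer.sound_speed / (2.0 * self.sampling_rate)

    def sample_depths(self) -> np.ndarray:
        """Depth (m) of each axial sample centre."""
        return self.depth_origin + (np.arange(self.n_samples) + 0.5) * self.axial_sample_spacing
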