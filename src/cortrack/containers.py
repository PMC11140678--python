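"""Shared in-memory containers for evoked responses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EvokedSet:
    """Per-participant evoked responses on a common time axis.

    ``data`` is (n_stimuli, n_sensors, n_times) at ``rate`` Hz; sample
    index ``onset`` is stimulus onset (t = 0), preceded by a baseline
    window.  Responses to shorter stimuli are zero-plus-noise padded to
    the common length.
    """

    data: np.ndarray
    rate: float
    onset: int
    stimulus_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_stimuli, n_sensors, n_times)")
        if not self.stimulus_ids:
            self.stimulus_ids = list(range(self.data.shape[0]))
        if len(self.stimulus_ids) != self.data.shape[0]:
            raise ValueError("stimulus_ids length does not match data")
        if not 0 <= self.onset < self.data.shape[2]:
            raise ValueError("onset index outside the time axis")

    @property
    def n_stimuli(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]
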