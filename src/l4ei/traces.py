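"""In-memory containers for voltage-clamp / current-clamp recordings.

All currents are in pA, times in ms, potentials in mV.  Sign convention:
traces store the raw clamp current, so EPSCs recorded at the inhibitory
reversal (-70 mV) are inward (negative) deflections and IPSCs recorded at
the excitatory reversal (0 mV) are outward (positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "SweepSet", "TrialSet", "FIRecording", "LTDExperiment"]


@dataclass
class Trace:
    """A sampled current time series with holding potential and markers."""

    samples: np.ndarray  # pA
    sample_interval: float  # ms
    holding_potential: float = -70.0  # mV
    stimulus_markers: list = field(default_factory=list)  # [(time_ms, label)]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_interval <= 0:
            raise ValueError("invalid spec: sample_interval must be positive")
        for t, _label in self.stimulus_markers:
            if not 0 <= t <= self.duration:
                raise ValueError(f"stimulus marker at {t} ms outside trace extent")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size * self.sample_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval

    @property
    def polarity(self) -> int:
        """Expected deflection sign of synaptic currents at this holding
        potential: outward (+1) near the excitatory reversal, inward (-1)
        near the inhibitory reversal."""
        return 1 if self.holding_potential >= -35.0 else -1


@dataclass
class SweepSet:
    """Paired EPSC/IPSC sweep families across stimulus intensities.

    Each element of ``pairs`` is (intensity, EPSC trace at -70 mV, IPSC
    trace at 0 mV).
    """

    pairs: list  # [(intensity, Trace, Trace)]

    def __post_init__(self) -> None:
        for level, epsc, ipsc in self.pairs:
            if abs(epsc.holding_potential - (-70.0)) > 5.0:
                raise ValueError(f"EPSC sweep at level {level} not held near -70 mV")
            if abs(ipsc.holding_potential) > 5.0:
                raise ValueError(f"IPSC sweep at level {level} not held near 0 mV")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TrialSet:
    """Minimal-stimulation trials: short sweeps sharing one stimulus time."""

    trials: list  # [Trace]
    stim_time: float  # ms, common to all trials

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class FIRecording:
    """Responses of one neuron to a family of square current steps."""

    currents: np.ndarray  # pA, one per step
    step_duration: float  # ms
    dt: float  # ms
    voltages: list  # [np.ndarray] voltage trace per step (incl. t=0)
    spike_times: list  # [np.ndarray] ms per step

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.voltages) != self.currents.size:
            raise ValueError("one voltage trace required per current step")


@dataclass
class LTDExperiment:
    """Once-per-minute evoked EPSC amplitudes around an LTD induction."""

    minutes: np.ndarray  # minute stamps, strictly increasing
    amplitudes: np.ndarray  # pA
    induction_end: int  # minute index at which induction finished

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.minutes.size != self.amplitudes.size:
            raise ValueError("minutes and amplitudes must align")
        if np.any(np.diff(self.minutes) <= 0):
            raise ValueError("minutes must be strictly increasing")
        if not self.minutes.min() <= self.induction_end <= self.minutes.max():
            raise ValueError("induction_end outside the recorded series")
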