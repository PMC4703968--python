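"""Digital twin of the electrolyte film's pulse response.

During each rectangular pulse the film passes a charging current that decays
from an onset peak toward a plateau; when the pulse ends, the polarization
layer drives a discharging current of opposite sign that relaxes back to
zero.  Both transients are well described by a plateau-plus-biexponential
(R//C-like) form.  Plasticity enters through the peak envelopes: the i-th
pulse's charging segment is scaled by the depression weight ``W_i(D)`` and
its discharging segment by the facilitation weight ``W_i(F)``.

At high stimulation frequency a discharge tail has not relaxed to zero when
the next pulse arrives; re-applying the external field terminates the
back-diffusion current, so each tail is truncated at the next pulse onset
rather than superposed under it.  This keeps onset/offset peak reads equal
to the weights times the first-pulse peaks, which is what peak extraction
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ExtractionError,
    NormalizationError,
    ProtocolError,
    ResolutionError,
)
from .model import (
    FULL_DECAY_MS,
    Branch,
    Provenance,
    PulseProtocol,
    WeightSequence,
)

#: Minimum samples that must span one pulse width.
MIN_SAMPLES_PER_WIDTH = 5


@dataclass(frozen=True)
class TraceModel:
    """Plateau-plus-biexponential pulse-response shape.

    The numeric defaults are synthetic fixtures chosen to honor the device's
    printed constraints — a fast sub-width and a slow super-width charging
    term, and a discharge that relaxes below 1% of its peak within the
    0.52 s full-decay period — not measured values.
    """

    plateau: float = 0.2
    charge_amps: tuple[float, float] = (0.6, 0.4)
    charge_taus: tuple[float, float] = (1.0, 20.0)     # ms
    discharge_amps: tuple[float, float] = (0.6, 0.4)
    discharge_taus: tuple[float, float] = (5.0, 100.0)  # ms
    full_decay_ms: float = FULL_DECAY_MS

    def __post_init__(self):
        for tau in (*self.charge_taus, *self.discharge_taus):
            if tau <= 0:
                raise ProtocolError(f"time constants must be > 0, got {tau}")
        peak = sum(self.discharge_amps)
        if peak > 0:
            t = self.full_decay_ms
            residual = sum(
                a * np.exp(-t / tau)
                for a, tau in zip(self.discharge_amps, self.discharge_taus)
            )
            if residual > 0.01 * peak:
                raise ProtocolError(
                    "discharge does not relax below 1% of its peak within "
                    f"the {t} ms full-decay period"
                )

    def charge_current(self, t_local: np.ndarray) -> np.ndarray:
        out = np.full_like(t_local, self.plateau, dtype=float)
        for a, tau in zip(self.charge_amps, self.charge_taus):
            out += a * np.exp(-t_local / tau)
        return out

    def discharge_current(self, t_local: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t_local, dtype=float)
        for a, tau in zip(self.discharge_amps, self.discharge_taus):
            out += a * np.exp(-t_local / tau)
        return -out

    @property
    def charge_peak(self) -> float:
        return self.plateau + sum(self.charge_amps)

    @property
    def discharge_peak(self) -> float:
        return sum(self.discharge_amps)


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled time/current record for one protocol.

    Positive currents are charging, negative discharging.  The trace spans
    the whole pulse train plus one full decay period after the last pulse.
    """

    sample_period: float  # ms
    currents: np.ndarray
    protocol: PulseProtocol

    def __post_init__(self):
        if self.sample_period <= 0:
            raise ResolutionError(f"sample period must be > 0, got {self.sample_period}")
        if self.protocol.width / self.sample_period < MIN_SAMPLES_PER_WIDTH:
            raise ResolutionError(
                f"need >= {MIN_SAMPLES_PER_WIDTH} samples per {self.protocol.width} ms "
                f"pulse width; period {self.sample_period} ms is too coarse"
            )
        cur = np.asarray(self.currents, dtype=float)
        cur.flags.writeable = False
        object.__setattr__(self, "currents", cur)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.currents.size) * self.sample_period

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "current": self.currents})

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)


def _segment_samples(protocol: PulseProtocol, sample_period: float,
                     full_decay_ms: float):
    """ON/OFF segment lengths in whole samples (boundaries snapped to grid).

    Returns (on_lengths, off_lengths) in samples; the last OFF segment is
    the full decay period.  Snapping keeps every pulse onset and end exactly
    on a sample so that peak reads are free of sub-sample phase error.
    """
    on = int(round(protocol.width / sample_period))
    if on < MIN_SAMPLES_PER_WIDTH:
        raise ResolutionError(
            f"{sample_period} ms sampling gives {on} samples per pulse width; "
            f"need >= {MIN_SAMPLES_PER_WIDTH}"
        )
    offs = [int(round(dt / sample_period)) for dt in protocol.intervals]
    offs.append(int(round(full_decay_ms / sample_period)))
    return [on] * protocol.n_pulses, offs


def synthesize_trace(
    model: TraceModel,
    protocol: PulseProtocol,
    d_weights: WeightSequence,
    f_weights: WeightSequence,
    sample_period: float = 0.5,
) -> CurrentTrace:
    """Render a current trace whose peak envelopes follow the two branches.

    Pulse *i*'s ON segment carries ``W_i(D) * (plateau + biexponential)``
    scaled by the protocol amplitude; its OFF segment carries the
    discharging biexponential scaled by ``-W_i(F)``, truncated at the next
    onset.  A zero-amplitude protocol yields the zero trace.
    """
    n = protocol.n_pulses
    if len(d_weights) != n or len(f_weights) != n:
        raise ProtocolError(
            f"weight sequences (lengths {len(d_weights)}, {len(f_weights)}) "
            f"must match the {n}-pulse protocol"
        )
    on_lens, off_lens = _segment_samples(protocol, sample_period, model.full_decay_ms)
    scale = protocol.amplitude
    chunks = []
    for i in range(n):
        t_on = np.arange(on_lens[i]) * sample_period
        chunks.append(scale * d_weights.weights[i] * model.charge_current(t_on))
        t_off = np.arange(off_lens[i]) * sample_period
        chunks.append(scale * f_weights.weights[i] * model.discharge_current(t_off))
    return CurrentTrace(sample_period, np.concatenate(chunks), protocol)


def extract_peaks(
    trace: CurrentTrace, full_decay_ms: float = FULL_DECAY_MS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse charging and discharging peak magnitudes.

    ``D_i`` is the maximum current in a one-width window opening at pulse
    *i*'s onset; ``F_i`` is the maximum discharge magnitude (most negative
    current) in a one-width window opening at the pulse end.  Pulses whose
    windows contain no current of the expected sign are reported together
    in an :class:`ExtractionError`.
    """
    protocol = trace.protocol
    on_lens, off_lens = _segment_samples(protocol, trace.sample_period, full_decay_ms)
    cur = trace.currents
    n = protocol.n_pulses
    d_peaks = np.empty(n)
    f_peaks = np.empty(n)
    bad: list[int] = []
    pos = 0
    for i in range(n):
        on_win = cur[pos: pos + on_lens[i]]
        pos += on_lens[i]
        # F window = one pulse width after the pulse end, possibly spilling
        # into the next ON segment at high frequency; only negative samples
        # are discharge current.
        f_win = cur[pos: pos + on_lens[i]]
        pos += off_lens[i]
        d = on_win.max(initial=-np.inf)
        f = -f_win.min(initial=np.inf)
        if not d > 0:
            bad.append(i + 1)
            continue
        if not f > 0:
            bad.append(i + 1)
            continue
        d_peaks[i] = d
        f_peaks[i] = f
    if bad:
        raise ExtractionError(
            f"no charging/discharging peak found for pulses {bad}", pulse_indices=bad
        )
    return d_peaks, f_peaks


def normalize_weights(
    peaks: np.ndarray,
    branch: Branch | str,
    protocol: PulseProtocol | None = None,
    provenance: Provenance = Provenance.MEASURED,
) -> WeightSequence:
    """Weight modification ``W_i = peak_i / peak_1`` (baseline-normalized)."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 1 or peaks[0] <= 0:
        raise NormalizationError(
            "first peak must be positive to serve as the baseline"
        )
    if protocol is None:
        protocol = PulseProtocol(intervals=(0.0,) * (peaks.size - 1))
    return WeightSequence(Branch(branch), peaks / peaks[0], protocol, provenance)
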