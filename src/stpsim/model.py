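"""Recursive weight model for short-term depression and facilitation.

A synapse driven by a rectangular pulse train responds with a per-pulse
weight sequence ``W_1..W_n`` (peak current of pulse *i* normalized by the
first-pulse peak).  Two branches are modelled:

* **depression** (STD): each pulse releases a fraction ``f`` of the current
  state; during the following interval the state recovers by a fraction
  ``k`` of the gap to the full state.  Weights start at 1 and relax
  monotonically toward a steady state below 1.
* **facilitation** (STF): the state decays by a fraction ``f`` during each
  interval and each pulse enhances it by a fraction ``k`` of the gap to a
  ceiling ``I > 1``.  Weights start at 1 and grow toward a steady state.

Both recursions contract with geometric ratio ``(1-f)(1-k)``, so the
closed-form fixed point is reached after a few tens of pulses at the
parameter values typical of the 1-142 Hz stimulation range.
"""

from __future__ import annotations

import enum
import io
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterDomainError, ProtocolError

logger = logging.getLogger("stpsim")

#: Relative step below which a weight sequence is reported as saturated.
SATURATION_RTOL = 1e-6

#: OFF interval (ms) beyond which the device state recovers fully; weights
#: of both branches stay within 1% of unity for longer intervals.
FULL_DECAY_MS = 520.0

#: Frequency band (Hz) over which the characteristic-parameter laws are
#: calibrated; evaluation outside it is extrapolation and is logged.
CALIBRATED_BAND_HZ = (1.0, 142.0)


class Branch(str, enum.Enum):
    """Which short-term plasticity branch a parameter set or sequence encodes."""

    DEPRESSION = "depression"
    FACILITATION = "facilitation"


class Provenance(str, enum.Enum):
    SIMULATED = "simulated"
    MEASURED = "measured"
    FITTED = "fitted"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class STPParams:
    """One branch's recursion parameters.

    Parameters
    ----------
    branch : Branch
        Depression or facilitation.
    f : float
        Per-pulse release (shrinking) fraction for depression, or
        per-interval decay (reduction) fraction for facilitation.
        Must lie in (0, 1]; a value of exactly 0 is accepted only for
        facilitation's degenerate no-decay limit.
    k : float
        Per-interval recovery fraction toward the full state (depression)
        or per-pulse enhancement fraction toward the ceiling (facilitation).
        Must lie in (0, 1].
    I : float
        Intensity scale: exactly 1 for depression (the baseline state),
        strictly greater than 1 for facilitation (the ceiling).
    """

    branch: Branch
    f: float
    k: float
    I: float = 1.0

    def __post_init__(self):
        branch = Branch(self.branch)
        object.__setattr__(self, "branch", branch)
        f_low = 0.0 if branch is Branch.FACILITATION else None
        if not (0.0 < self.f <= 1.0 or (f_low == 0.0 and self.f == 0.0)):
            raise ParameterDomainError(
                f"f={self.f} outside (0, 1] for branch {branch.value}"
            )
        if not 0.0 < self.k <= 1.0:
            raise ParameterDomainError(f"k={self.k} outside (0, 1]")
        if branch is Branch.DEPRESSION and self.I != 1.0:
            raise ParameterDomainError("depression requires I = 1 exactly")
        if branch is Branch.FACILITATION and self.I <= 1.0:
            raise ParameterDomainError(
                f"facilitation requires ceiling I > 1, got I={self.I}"
            )


@dataclass(frozen=True)
class PulseProtocol:
    """A rectangular pulse train.

    ``intervals`` holds the OFF time (ms) between consecutive pulses, so a
    train of *n* pulses carries *n - 1* intervals.  A uniform train at
    frequency ``nu`` with width ``w`` has interval ``1000/nu - w`` (a 1 Hz
    train of 5 ms pulses rests for 995 ms between pulses).
    """

    amplitude: float = 0.5
    width: float = 5.0
    intervals: tuple[float, ...] = ()

    def __post_init__(self):
        if self.width <= 0:
            raise ProtocolError(f"pulse width must be > 0, got {self.width}")
        ivals = tuple(float(x) for x in self.intervals)
        if any(x < 0 for x in ivals):
            raise ProtocolError("inter-pulse intervals must be >= 0")
        object.__setattr__(self, "intervals", ivals)

    @classmethod
    def uniform(
        cls,
        frequency_hz: float,
        n_pulses: int,
        amplitude: float = 0.5,
        width: float = 5.0,
    ) -> "PulseProtocol":
        """Uniform train at ``frequency_hz``; interval = 1000/nu - width."""
        if n_pulses < 1:
            raise ProtocolError(f"need at least one pulse, got {n_pulses}")
        if frequency_hz <= 0:
            raise ProtocolError(f"frequency must be > 0, got {frequency_hz}")
        interval = 1000.0 / frequency_hz - width
        if interval < 0:
            raise ProtocolError(
                f"{frequency_hz} Hz leaves no OFF time for width {width} ms"
            )
        return cls(amplitude, width, (interval,) * (n_pulses - 1))

    @property
    def n_pulses(self) -> int:
        return len(self.intervals) + 1

    @property
    def is_uniform(self) -> bool:
        return len(set(self.intervals)) <= 1

    @property
    def frequency_hz(self) -> float | None:
        """Pulse rate of a uniform train; None for mixed-interval trains."""
        if not self.intervals:
            return None
        if not self.is_uniform:
            return None
        return 1000.0 / (self.width + self.intervals[0])

    def instantaneous_frequencies(self) -> np.ndarray:
        """Per-interval pulse rate 1000/(width + interval), length n - 1."""
        return 1000.0 / (self.width + np.asarray(self.intervals, dtype=float))


@dataclass(frozen=True)
class WeightSequence:
    """Normalized per-pulse weights for one branch under one protocol."""

    branch: Branch
    weights: np.ndarray
    protocol: PulseProtocol
    provenance: Provenance = Provenance.SIMULATED

    def __post_init__(self):
        object.__setattr__(self, "branch", Branch(self.branch))
        object.__setattr__(self, "provenance", Provenance(self.provenance))
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ProtocolError("weights must be a non-empty 1-d sequence")
        if w.size != self.protocol.n_pulses:
            raise ProtocolError(
                f"{w.size} weights for a {self.protocol.n_pulses}-pulse protocol"
            )
        if not math.isclose(w[0], 1.0, rel_tol=0, abs_tol=1e-9):
            raise ProtocolError(f"W_1 must equal 1 (baseline), got {w[0]}")
        if np.any(w <= 0):
            raise ProtocolError("weights must be positive")
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        freq = self.protocol.frequency_hz
        return pd.DataFrame(
            {
                "pulse_index": np.arange(1, len(self) + 1),
                "weight": self.weights,
                "branch": self.branch.value,
                "frequency_hz": np.nan if freq is None else freq,
            }
        )

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)

    def to_dict(self) -> dict:
        return {
            "branch": self.branch.value,
            "provenance": self.provenance.value,
            "weights": self.weights.tolist(),
            "protocol": {
                "amplitude": self.protocol.amplitude,
                "width": self.protocol.width,
                "intervals": list(self.protocol.intervals),
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "WeightSequence":
        proto = PulseProtocol(
            amplitude=payload["protocol"]["amplitude"],
            width=payload["protocol"]["width"],
            intervals=tuple(payload["protocol"]["intervals"]),
        )
        return cls(
            branch=Branch(payload["branch"]),
            weights=np.asarray(payload["weights"], dtype=float),
            protocol=proto,
            provenance=Provenance(payload.get("provenance", "simulated")),
        )

    @classmethod
    def from_json(cls, text_or_path: str) -> "WeightSequence":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls.from_dict(payload)

    @classmethod
    def from_csv(cls, path_or_buf, protocol: PulseProtocol | None = None,
                 provenance: Provenance = Provenance.MEASURED) -> "WeightSequence":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        df = pd.read_csv(path_or_buf).sort_values("pulse_index")
        branch = Branch(df["branch"].iloc[0])
        if protocol is None:
            freq = df["frequency_hz"].iloc[0]
            if not np.isfinite(freq):
                raise ProtocolError(
                    "CSV lacks a uniform frequency; pass the protocol explicitly"
                )
            protocol = PulseProtocol.uniform(float(freq), len(df))
        return cls(branch, df["weight"].to_numpy(), protocol, provenance)


# ---------------------------------------------------------------------------
# recursion
# ---------------------------------------------------------------------------


def _check_pulses(n_pulses: int) -> None:
    if n_pulses < 1:
        raise ProtocolError(f"need at least one pulse, got {n_pulses}")


def depression_weights(
    params: STPParams, n_pulses: int, protocol: PulseProtocol | None = None
) -> WeightSequence:
    """Depressing weight sequence ``W_i = I * S_i``.

    ``S_1 = 1``; each pulse releases a fraction ``f`` of the state and the
    following interval recovers a fraction ``k`` of the gap to the full
    state:  ``S_{i+1} = S_i (1-f) + k (1 - S_i (1-f))``.
    """
    if Branch(params.branch) is not Branch.DEPRESSION:
        raise ParameterDomainError("depression_weights requires a depression branch")
    _check_pulses(n_pulses)
    f, k, intensity = params.f, params.k, params.I
    s = np.empty(n_pulses)
    s[0] = 1.0
    for i in range(1, n_pulses):
        released = s[i - 1] * (1.0 - f)
        s[i] = released + k * (1.0 - released)
    if protocol is None:
        protocol = PulseProtocol(intervals=(0.0,) * (n_pulses - 1))
    return WeightSequence(Branch.DEPRESSION, intensity * s, protocol)


def facilitation_weights(
    params: STPParams, n_pulses: int, protocol: PulseProtocol | None = None
) -> WeightSequence:
    """Facilitating weight sequence.

    ``W_1 = 1``; the state decays by a fraction ``f`` during each interval
    and the next pulse enhances it by a fraction ``k`` of the gap to the
    ceiling ``I``:  ``W_{i+1} = (1-f) W_i + k (I - (1-f) W_i)``.
    """
    if Branch(params.branch) is not Branch.FACILITATION:
        raise ParameterDomainError("facilitation_weights requires a facilitation branch")
    _check_pulses(n_pulses)
    f, k, ceiling = params.f, params.k, params.I
    w = np.empty(n_pulses)
    w[0] = 1.0
    for i in range(1, n_pulses):
        decayed = (1.0 - f) * w[i - 1]
        w[i] = decayed + k * (ceiling - decayed)
    if protocol is None:
        protocol = PulseProtocol(intervals=(0.0,) * (n_pulses - 1))
    return WeightSequence(Branch.FACILITATION, w, protocol)


def simulate_weights(
    params: STPParams, n_pulses: int, protocol: PulseProtocol | None = None
) -> WeightSequence:
    """Dispatch to the branch-appropriate recursion."""
    if Branch(params.branch) is Branch.DEPRESSION:
        return depression_weights(params, n_pulses, protocol)
    return facilitation_weights(params, n_pulses, protocol)


def steady_state(params: STPParams) -> float:
    """Fixed point of the recursion (the n -> infinity weight).

    Both branches contract toward ``I * k / (1 - (1-f)(1-k))``; the
    denominator ``f + k - f k`` is positive for all admissible fractions.
    """
    f, k = params.f, params.k
    return params.I * k / (1.0 - (1.0 - f) * (1.0 - k))


def saturation_index(weights: np.ndarray, rtol: float = SATURATION_RTOL) -> int | None:
    """1-based pulse index at which the relative step first drops below rtol."""
    w = np.asarray(weights, dtype=float)
    steps = np.abs(np.diff(w)) / np.abs(w[:-1])
    hits = np.nonzero(steps < rtol)[0]
    return None if hits.size == 0 else int(hits[0]) + 2


def weights_for_intervals(
    params: STPParams, protocol: PulseProtocol, law
) -> WeightSequence:
    """Evaluate the recursion under a (possibly mixed-interval) protocol.

    ``f`` and ``k`` are frequency functions, so each transition from pulse
    *i* to *i + 1* uses the parameters evaluated at that interval's
    instantaneous frequency ``nu_i = 1000 / (width + interval_i)``.  For a
    uniform train this reduces exactly to the constant-parameter recursion.
    Frequencies outside the calibrated 1-142 Hz band are extrapolated with
    a logged warning; fractions are clamped into (0, 1].
    """
    from .freq_laws import eval_params  # deferred: freq_laws imports our types

    branch = Branch(params.branch)
    n = protocol.n_pulses
    if n == 1:
        return WeightSequence(branch, np.ones(1), protocol, Provenance.SIMULATED)

    freqs = protocol.instantaneous_frequencies()
    lo, hi = CALIBRATED_BAND_HZ
    outside = (freqs < lo) | (freqs > hi)
    if np.any(outside):
        logger.warning(
            "extrapolating the frequency laws outside [%g, %g] Hz at %s Hz",
            lo, hi, np.unique(np.round(freqs[outside], 3)),
        )

    w = np.empty(n)
    w[0] = 1.0
    state = 1.0  # depression tracks the ENR state S_i; facilitation tracks W_i
    for i, nu in enumerate(freqs):
        p = eval_params(law, float(nu), branch, clamp=True)
        if branch is Branch.DEPRESSION:
            released = state * (1.0 - p.f)
            state = released + p.k * (1.0 - released)
            w[i + 1] = params.I * state
        else:
            decayed = (1.0 - p.f) * state
            state = decayed + p.k * (p.I - decayed)
            w[i + 1] = state
    return WeightSequence(branch, w, protocol, Provenance.SIMULATED)
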