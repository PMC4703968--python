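"""Seeded generators of synthetic pulse-response experiments.

Device recordings behind the published weight curves are not deposited, so
validation runs on synthetic data with the statistical structure the
analysis assumes: recursion-generated weight envelopes, multiplicative
Gaussian peak noise (peak ratios are the analysed quantity, so noise acts on
peaks rather than on trace samples), and optional additive trace noise.
Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device import CurrentTrace, TraceModel, synthesize_trace
from .exceptions import ProtocolError
from .freq_laws import FreqLawCoefficients, eval_params
from .model import (
    Branch,
    PulseProtocol,
    STPParams,
    WeightSequence,
    simulate_weights,
    weights_for_intervals,
)


@dataclass(frozen=True)
class NoiseModel:
    """Stationary measurement-noise description.

    ``multiplicative_sd`` perturbs each peak as ``peak * (1 + eps)`` with
    ``eps ~ N(0, sd^2)``; ``additive_sd`` (current units) adds white noise
    to trace samples.  The defaults mirror the few-percent run-to-run
    variability reported across devices.
    """

    multiplicative_sd: float = 0.02
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise ProtocolError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _perturb_weights(
    seq: WeightSequence, sd: float, rng: np.random.Generator
) -> WeightSequence:
    """Multiplicative noise on the underlying peaks, then re-normalization.

    Noise on the baseline peak propagates to every ratio as a shared scale,
    exactly as it would in measured ``peak_i / peak_1`` data, so the noisy
    sequence is renormalized to keep the ``W_1 = 1`` contract.
    """
    if sd == 0:
        return seq
    noisy = seq.weights * (1.0 + rng.normal(0.0, sd, size=len(seq)))
    noisy = np.abs(noisy)  # peaks are magnitudes; sd << 1 makes flips negligible
    return WeightSequence(seq.branch, noisy / noisy[0], seq.protocol, seq.provenance)


def generate_weight_dataset(
    law: FreqLawCoefficients,
    frequencies,
    n_pulses: int,
    noise: NoiseModel,
    replicates: int = 1,
    branches=(Branch.DEPRESSION, Branch.FACILITATION),
) -> dict[tuple[float, str], list[WeightSequence]]:
    """Noisy recursion weights for every frequency x branch x replicate.

    Returns a mapping ``(frequency_hz, branch) -> [WeightSequence, ...]``.
    With zero noise each replicate equals the exact recursion output.
    """
    if replicates < 1:
        raise ProtocolError(f"replicates must be >= 1, got {replicates}")
    rng = noise.rng()
    out: dict[tuple[float, str], list[WeightSequence]] = {}
    for nu in frequencies:
        protocol = PulseProtocol.uniform(nu, n_pulses)
        for branch in branches:
            branch = Branch(branch)
            params = eval_params(law, nu, branch)
            clean = simulate_weights(params, n_pulses, protocol)
            out[(float(nu), branch.value)] = [
                _perturb_weights(clean, noise.multiplicative_sd, rng)
                for _ in range(replicates)
            ]
    return out


def generate_pulse_package(
    law: FreqLawCoefficients,
    segment_frequencies,
    pulses_per_segment: int,
    noise: NoiseModel | None = None,
    amplitude: float = 0.5,
    width: float = 5.0,
) -> tuple[PulseProtocol, WeightSequence, WeightSequence]:
    """A mixed-frequency pulse package and its two weight envelopes.

    Each segment contributes ``pulses_per_segment`` pulses at its frequency;
    the interval between segments takes the incoming segment's value.  The
    weights are evaluated with per-interval law parameters, so a single
    segment reduces to the uniform-train recursion.
    """
    segs = list(segment_frequencies)
    if not segs:
        raise ProtocolError("segment frequency list must be non-empty")
    if pulses_per_segment < 1:
        raise ProtocolError(
            f"pulses per segment must be >= 1, got {pulses_per_segment}"
        )
    intervals: list[float] = []
    for si, nu in enumerate(segs):
        dt = 1000.0 / nu - width
        if dt < 0:
            raise ProtocolError(f"{nu} Hz leaves no OFF time for width {width} ms")
        count = pulses_per_segment if si > 0 else pulses_per_segment - 1
        intervals.extend([dt] * count)
    protocol = PulseProtocol(amplitude, width, tuple(intervals))
    d = weights_for_intervals(
        STPParams(Branch.DEPRESSION, f=0.5, k=0.5, I=1.0), protocol, law
    )
    f = weights_for_intervals(
        STPParams(Branch.FACILITATION, f=0.5, k=0.5, I=law.IF_value), protocol, law
    )
    if noise is not None and noise.multiplicative_sd > 0:
        rng = noise.rng()
        d = _perturb_weights(d, noise.multiplicative_sd, rng)
        f = _perturb_weights(f, noise.multiplicative_sd, rng)
    return protocol, d, f


def generate_trace_dataset(
    model: TraceModel,
    law: FreqLawCoefficients,
    frequencies,
    n_pulses: int,
    noise: NoiseModel,
    sample_period: float = 0.5,
) -> dict[float, CurrentTrace]:
    """Synthetic current traces, one per frequency.

    Peak-level multiplicative noise perturbs the weight envelopes before
    rendering; additive trace noise (if any) is applied to the samples.
    """
    rng = noise.rng()
    out: dict[float, CurrentTrace] = {}
    for nu in frequencies:
        protocol = PulseProtocol.uniform(nu, n_pulses)
        d = simulate_weights(eval_params(law, nu, Branch.DEPRESSION), n_pulses, protocol)
        f = simulate_weights(eval_params(law, nu, Branch.FACILITATION), n_pulses, protocol)
        d = _perturb_weights(d, noise.multiplicative_sd, rng)
        f = _perturb_weights(f, noise.multiplicative_sd, rng)
        trace = synthesize_trace(model, protocol, d, f, sample_period)
        if noise.additive_sd > 0:
            currents = trace.currents + rng.normal(0.0, noise.additive_sd,
                                                   size=trace.currents.size)
            trace = CurrentTrace(sample_period, currents, protocol)
        out[float(nu)] = trace
    return out
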