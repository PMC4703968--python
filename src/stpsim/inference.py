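"""Parameter estimation from weight sequences.

For constant per-step parameters both recursions share the geometric form

    W_i = W_inf + (1 - W_inf) * rho^(i-1),      rho = (1-f)(1-k),

with ``W_inf = I k / (1 - rho)``; fitting is bounded nonlinear least
squares on the weights.  Because near-constant sequences leave a flat
valley in (f, k) — and, for facilitation, a trade-off between the ceiling
``I`` and ``k`` — the optimizer is run from a small grid of starting
points and the Jacobian is inspected for rank deficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import InferenceError
from .freq_laws import CALIBRATED_CEILING, FreqLawCoefficients, fit_laws
from .model import Branch, STPParams, WeightSequence

_MIN_PULSES = 5
_MIN_PANEL_FREQS = 4
_EPS = 1e-12

#: (f, k) starting grid for the multi-start optimizer.
_STARTS = ((0.1, 0.5), (0.3, 0.3), (0.5, 0.6), (0.05, 0.2), (0.7, 0.4))


def _model_weights(n: int, f: float, k: float, intensity: float) -> np.ndarray:
    rho = (1.0 - f) * (1.0 - k)
    w_inf = intensity * k / (1.0 - rho)
    i = np.arange(n)
    return w_inf + (1.0 - w_inf) * rho**i


def _moment_start(y: np.ndarray, intensity: float) -> tuple[float, float] | None:
    """Method-of-moments (f, k) start for the geometric sequence.

    The tail level estimates the steady state and a lag-1 regression of the
    deviations estimates the contraction ratio rho; inverting
    ``W_inf = I k / (1 - rho)`` and ``rho = (1-f)(1-k)`` gives the start.
    Returns None when the sequence is too flat to localize a basin.
    """
    tail = float(np.median(y[-max(len(y) // 4, 2):]))
    dev = y - tail
    num = float(dev[1:-1] @ dev[2:])
    den = float(dev[1:-1] @ dev[1:-1])
    if den <= 0 or abs(1.0 - tail) < 1e-12:
        return None
    rho = float(np.clip(num / den, 0.01, 0.99))
    k = float(np.clip(tail * (1.0 - rho) / intensity, 0.01, 0.99))
    f = float(np.clip(1.0 - rho / (1.0 - k), 0.01, 0.99))
    return f, k


@dataclass
class FitDiagnostics:
    """Convergence and identifiability report for one fit."""

    rms: float
    converged: bool
    cost: float
    n_starts: int
    identifiable: bool
    message: str = ""
    stderr: dict = field(default_factory=dict)  # Jacobian-based, approximate

    def to_dict(self) -> dict:
        return {
            "rms": self.rms,
            "converged": self.converged,
            "cost": self.cost,
            "n_starts": self.n_starts,
            "identifiable": self.identifiable,
            "message": self.message,
            "stderr": self.stderr,
        }


def _identifiability(jac: np.ndarray) -> bool:
    sv = np.linalg.svd(jac, compute_uv=False)
    return bool(sv[-1] > 1e-8 * sv[0])


def _stderr(jac: np.ndarray, residuals: np.ndarray, names) -> dict:
    """Asymptotic standard errors from the Jacobian (not a paper quantity;
    provided as a convenience and labelled approximate)."""
    dof = max(residuals.size - jac.shape[1], 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        return {n: float(np.sqrt(max(v, 0.0))) for n, v in zip(names, np.diag(cov))}
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}


def fit_sequence(
    weights: WeightSequence | np.ndarray,
    branch: Branch | str | None = None,
    fix_I: float | None = None,
    robust: bool = False,
    fit_scale: bool = False,
) -> tuple[STPParams, FitDiagnostics]:
    """Estimate (f, k[, I]) from one weight sequence.

    Depression fixes ``I = 1``; facilitation frees the ceiling on (1, 10]
    unless ``fix_I`` pins it.  ``robust=True`` switches to a soft-L1 loss.
    ``fit_scale=True`` adds a free scale nuisance on pulses 2..n: measured
    weights are ratios to a noisy first peak, so baseline noise rescales
    the whole tail of the sequence; absorbing that scale stops it from
    masquerading as fast early decay.  On noiseless recursion-generated
    input the generating parameters are recovered to optimizer precision
    (well below 1e-6).
    """
    if isinstance(weights, WeightSequence):
        branch = weights.branch if branch is None else Branch(branch)
        y = weights.weights
    else:
        if branch is None:
            raise InferenceError("branch must be given for bare arrays")
        branch = Branch(branch)
        y = np.asarray(weights, dtype=float)
    if y.size < _MIN_PULSES:
        raise InferenceError(
            f"need >= {_MIN_PULSES} pulses to fit, got {y.size}"
        )
    n = y.size
    depression = branch is Branch.DEPRESSION
    free_I = (not depression) and fix_I is None
    if depression:
        intensity_fixed = 1.0
    elif fix_I is not None:
        if fix_I <= 1.0:
            raise InferenceError(f"facilitation ceiling must exceed 1, got {fix_I}")
        intensity_fixed = float(fix_I)

    near_constant = float(np.ptp(y)) < 1e-3
    if free_I:
        # the sequence is geometric with two observable quantities, so
        # (f, k, I) has a one-parameter equivalent family: any rescaling
        # I -> cI, k -> k/c (with f re-solved) fits identically
        warnings.warn(
            "facilitation ceiling I is not identifiable from a single weight "
            "sequence (I and k trade off exactly); pass fix_I to pin it",
            stacklevel=2,
        )

    def residual(theta):
        pos = 0
        if free_I:
            f, k, intensity = theta[0], theta[1], theta[2]
            pos = 3
        else:
            f, k, intensity = theta[0], theta[1], intensity_fixed
            pos = 2
        model = _model_weights(n, f, k, intensity)
        if fit_scale:
            model = model * theta[pos]
            model[0] = 1.0  # the baseline ratio W_1 = 1 is exact by construction
        return model - y

    lo_f = 0.0 if not depression else _EPS
    lo, hi = [lo_f, _EPS], [1.0, 1.0]
    if free_I:
        lo.append(1.0 + 1e-9)
        hi.append(10.0)
    if fit_scale:
        lo.append(0.9)
        hi.append(1.1)
    loss = "soft_l1" if robust else "linear"

    rng = np.random.default_rng(1234)  # start-jitter only; fits are deterministic
    i0 = intensity_fixed if not free_I else max(float(y.max()), 1.1)
    moment = _moment_start(y, i0)
    starts = _STARTS if moment is None else (moment, *_STARTS)
    best = None
    for f0, k0 in starts:
        jit = 1.0 + 0.05 * rng.standard_normal(2)
        x0 = [min(max(f0 * jit[0], 0.01), 0.99), min(max(k0 * jit[1], 0.01), 0.99)]
        if free_I:
            x0.append(max(float(y.max()), 1.1))
        if fit_scale:
            x0.append(1.0)
        sol = least_squares(
            residual, x0, bounds=(lo, hi), loss=loss,
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise InferenceError(
            f"fit did not converge: {'' if best is None else best.message}"
        )

    if free_I:
        f_hat, k_hat, I_hat = best.x[0], best.x[1], best.x[2]
        names = ("f", "k", "I", "scale") if fit_scale else ("f", "k", "I")
    else:
        f_hat, k_hat, I_hat = best.x[0], best.x[1], intensity_fixed
        names = ("f", "k", "scale") if fit_scale else ("f", "k")
    res = residual(best.x)
    diags = FitDiagnostics(
        rms=float(np.sqrt(np.mean(res**2))),
        converged=bool(best.success),
        cost=float(best.cost),
        n_starts=len(starts),
        identifiable=_identifiability(best.jac) and not near_constant and not free_I,
        message=str(best.message),
        stderr=_stderr(best.jac, res, names),
    )
    params = STPParams(
        branch=branch,
        f=float(np.clip(f_hat, _EPS if depression else 0.0, 1.0)),
        k=float(np.clip(k_hat, _EPS, 1.0)),
        I=1.0 if depression else float(max(I_hat, 1.0 + 1e-9)),
    )
    return params, diags


@dataclass
class PanelFit:
    """Per-frequency parameter fits plus the recovered frequency laws."""

    params_by_freq: dict  # {frequency_hz: {"depression": STPParams, ...}}
    law: FreqLawCoefficients
    diagnostics: dict

    def to_table(self) -> pd.DataFrame:
        rows = []
        for nu in sorted(self.params_by_freq):
            d = self.params_by_freq[nu].get(Branch.DEPRESSION.value)
            f = self.params_by_freq[nu].get(Branch.FACILITATION.value)
            rows.append(
                {
                    "frequency_hz": nu,
                    "I_D": None if d is None else d.I,
                    "f_D": None if d is None else d.f,
                    "k_D": None if d is None else d.k,
                    "I_F": None if f is None else f.I,
                    "f_F": None if f is None else f.f,
                    "k_F": None if f is None else f.k,
                }
            )
        return pd.DataFrame(rows).set_index("frequency_hz")


def _stack(group: list[WeightSequence]) -> np.ndarray:
    lens = {len(s) for s in group}
    if len(lens) != 1:
        raise InferenceError("replicates at one frequency must share pulse count")
    return np.stack([s.weights for s in group])


def fit_frequency_panel(
    dataset: dict[tuple[float, str], list[WeightSequence]],
    shared_IF: bool = True,
    ceiling: float | None = None,
) -> PanelFit:
    """Fit every frequency's parameters, then the frequency laws.

    ``dataset`` maps ``(frequency_hz, branch)`` to replicate sequences, as
    produced by :func:`stpsim.synthetic.generate_weight_dataset`.  With
    ``shared_IF`` every facilitation fit shares one ceiling — ``ceiling`` if
    given, else the calibrated convention of 1.582.  The ceiling must be
    fixed rather than estimated: each constant-frequency sequence pins only
    its steady state and contraction ratio, so the likelihood is exactly
    flat along the ``I``/``k`` trade-off even jointly across frequencies.
    With ``shared_IF=False`` the ceiling is freed per frequency and the fits
    are flagged non-identifiable.  Needs at least four distinct frequencies
    per branch so the exponential laws are determined.
    """
    freqs_dep = sorted({nu for (nu, b) in dataset if b == Branch.DEPRESSION.value})
    freqs_fac = sorted({nu for (nu, b) in dataset if b == Branch.FACILITATION.value})
    if len(freqs_dep) < _MIN_PANEL_FREQS or len(freqs_fac) < _MIN_PANEL_FREQS:
        raise InferenceError(
            f"need >= {_MIN_PANEL_FREQS} distinct frequencies per branch "
            f"(got {len(freqs_dep)} depression, {len(freqs_fac)} facilitation)"
        )

    params_by_freq: dict[float, dict[str, STPParams]] = {}
    diagnostics: dict = {"per_fit": {}}

    # depression: independent per-frequency fits on the replicate mean
    for nu in freqs_dep:
        group = _stack(dataset[(nu, Branch.DEPRESSION.value)])
        mean_seq = group.mean(axis=0)
        mean_seq = mean_seq / mean_seq[0]
        p, d = fit_sequence(mean_seq, Branch.DEPRESSION, fit_scale=True)
        params_by_freq.setdefault(nu, {})[Branch.DEPRESSION.value] = p
        diagnostics["per_fit"][(nu, "depression")] = d

    if shared_IF:
        I_shared = CALIBRATED_CEILING if ceiling is None else float(ceiling)
        if I_shared <= 1.0:
            raise InferenceError(f"shared ceiling must exceed 1, got {I_shared}")
        diagnostics["shared_IF"] = I_shared

    for nu in freqs_fac:
        group = _stack(dataset[(nu, Branch.FACILITATION.value)])
        m = group.mean(axis=0)
        m = m / m[0]
        if shared_IF:
            p, d = fit_sequence(m, Branch.FACILITATION, fix_I=I_shared,
                                fit_scale=True)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, d = fit_sequence(m, Branch.FACILITATION, fit_scale=True)
        params_by_freq.setdefault(nu, {})[Branch.FACILITATION.value] = p
        diagnostics["per_fit"][(nu, "facilitation")] = d

    pairs = []
    sigmas = {}
    for nu, branches in params_by_freq.items():
        for br, p in branches.items():
            pairs.append((nu, p))
            d = diagnostics["per_fit"].get((nu, br))
            if d is not None:
                sigmas[(float(nu), br)] = (
                    d.stderr.get("f", np.nan), d.stderr.get("k", np.nan)
                )
    law = fit_laws(pairs, sigmas=sigmas)
    return PanelFit(params_by_freq=params_by_freq, law=law, diagnostics=diagnostics)
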