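"""Flash-step damping model and its inversion to donor equilibrium constants.

A train of saturating flashes oxidizes one donor cytochrome per open RC per
flash.  The observed oxidation steps Δ1 ≥ Δ2 ≥ Δ3 shrink ("damping") because
the availability of reduced cytochrome to P+ drops with every turnover.  In
terms of generalized donor-side equilibrium constants K_Di (one per flash)
and acceptor-side constants K_Ai (interquinone electron equilibria):

    Δ1 = K_D1/(1+K_D1)
    Δ2 = [K_A1/(1+K_A1)] · Δ1 · K_D2/(1+K_D2)
    Δ3 = [K_A1/(1+K_A1)][K_A2/(1+K_A2)] · Δ1 · [K_D2/(1+K_D2)][K_D3/(1+K_D3)]

Because the acceptor-side constants are much larger than 1 in vivo, the
inversion neglects them by default (they can be supplied for an exact
finite-K_A inversion):

    K_D1 = Δ1/(1−Δ1),   K_D2 = r2/(1−r2),   K_D3 = r3/(1−r3)

with r2 = Δ2/Δ1 and r3 = Δ3/Δ2.

When the flash spacing T is varied, the step ratio follows the RC re-opening
law with an asymptotic damping level R_inf:

    ratio(T) = R_inf · (1 − e^{−k_A T})(1 − e^{−k_D T})

whose fit separates the donor and acceptor relaxation rates.  The law is
symmetric in the two rates, so the fit reports them as {slow, fast}; the
slow one is the rate-limiting step (its assignment to the acceptor side is a
biological interpretation, not a mathematical one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import lmfit

from .errors import DampingError, FitError, IdentifiabilityError

__all__ = [
    "StepHeights",
    "EquilibriumConstants",
    "DampingCurve",
    "DampingFit",
    "forward_steps",
    "invert_steps",
    "damping_ratio",
    "damping_vs_delay",
    "fit_damping_curve",
    "titration_to_kd",
]


def _frac(K: float) -> float:
    """K/(1+K) with K = inf mapped to 1 and K = 0 to 0."""
    if K is None or math.isinf(K):
        return 1.0
    return K / (1.0 + K)


@dataclass(frozen=True)
class StepHeights:
    """Cytochrome-oxidation increments per flash, in cyt3+/RC."""

    delta1: float
    delta2: float
    delta3: float

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.delta1, self.delta2, self.delta3)

    def to_dict(self) -> dict:
        return {"delta1": self.delta1, "delta2": self.delta2, "delta3": self.delta3}

    @classmethod
    def from_dict(cls, d: dict) -> "StepHeights":
        return cls(d["delta1"], d["delta2"], d["delta3"])


@dataclass(frozen=True)
class EquilibriumConstants:
    """Donor (K_D1..3) and acceptor (K_A1..2) generalized equilibrium constants.

    All dimensionless and >= 0; acceptor constants may be infinite (the
    in-vivo limit in which the inversion formulas are exact).
    """

    kd1: float
    kd2: float
    kd3: float
    ka1: float = math.inf
    ka2: float = math.inf

    def __post_init__(self):
        for name in ("kd1", "kd2", "kd3", "ka1", "ka2"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    def donor(self) -> Tuple[float, float, float]:
        return (self.kd1, self.kd2, self.kd3)

    def to_dict(self) -> dict:
        def enc(v):
            return "inf" if math.isinf(v) else v
        return {"kd1": self.kd1, "kd2": self.kd2, "kd3": self.kd3,
                "ka1": enc(self.ka1), "ka2": enc(self.ka2)}

    @classmethod
    def from_dict(cls, d: dict) -> "EquilibriumConstants":
        def dec(v):
            return math.inf if v in ("inf", None) else float(v)
        return cls(float(d["kd1"]), float(d["kd2"]), float(d["kd3"]),
                   dec(d.get("ka1", "inf")), dec(d.get("ka2", "inf")))


def forward_steps(K: EquilibriumConstants) -> StepHeights:
    """Predicted flash steps Δ1, Δ2, Δ3 from the equilibrium constants.

    For any non-negative constants the output satisfies
    0 <= Δ3 <= Δ2 <= Δ1 <= 1.
    """
    d1 = _frac(K.kd1)
    d2 = _frac(K.ka1) * d1 * _frac(K.kd2)
    d3 = _frac(K.ka1) * _frac(K.ka2) * d1 * _frac(K.kd2) * _frac(K.kd3)
    return StepHeights(d1, d2, d3)


def _odds(r: float, what: str, clip_tol: Optional[float]) -> float:
    """r/(1-r) with the no-damping guard; optional clipping of r >= 1."""
    if r >= 1.0:
        if clip_tol is not None and r <= 1.0 + clip_tol:
            r = 1.0 - 1e-9
        else:
            raise DampingError(
                f"{what} = {r:.6g} >= 1: no damping, equilibrium constant "
                "unidentifiable")
    if r <= 0.0:
        raise DampingError(f"{what} = {r:.6g} <= 0: equilibrium constant undefined")
    return r / (1.0 - r)


def invert_steps(steps: StepHeights,
                 acceptor: Optional[Tuple[float, float]] = None,
                 clip_tol: Optional[float] = None) -> EquilibriumConstants:
    """Recover donor equilibrium constants from measured step heights.

    By default the acceptor-side terms are taken as 1 (K_A >> 1).  Passing
    ``acceptor=(ka1, ka2)`` divides the step ratios by K_Ai/(1+K_Ai) first,
    making the inversion exact for finite acceptor constants.

    ``clip_tol``: if set, ratios in (1, 1+clip_tol] (noise overshoot) are
    clipped to just below 1 instead of raising; the default is to raise,
    since a ratio >= 1 means the constant is unidentifiable.
    """
    d1, d2, d3 = steps.as_tuple()
    if d1 <= 0.0:
        raise DampingError("delta1 <= 0: K_D1 undefined")
    ka1, ka2 = (math.inf, math.inf) if acceptor is None else acceptor
    kd1 = _odds(d1, "delta1", clip_tol)
    r2 = (d2 / d1) / _frac(ka1)
    kd2 = _odds(r2, "delta2/delta1 (acceptor-corrected)" if acceptor else "delta2/delta1",
                clip_tol)
    if d2 <= 0.0:
        raise DampingError("delta2 <= 0: K_D3 undefined")
    r3 = (d3 / d2) / _frac(ka2)
    kd3 = _odds(r3, "delta3/delta2 (acceptor-corrected)" if acceptor else "delta3/delta2",
                clip_tol)
    return EquilibriumConstants(kd1, kd2, kd3, ka1, ka2)


@dataclass
class DampingCurve:
    """Step ratio (Δ2/Δ1 or Δ3/Δ2) as a function of interflash delay."""

    delays: np.ndarray       # s, strictly increasing, > 0
    ratios: np.ndarray       # dimensionless, in [0, 1.05]
    flash_pair: str = "2/1"  # "2/1" or "3/2"

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.delays.shape != self.ratios.shape or self.delays.ndim != 1:
            raise ValueError("delays and ratios must be matching 1-D arrays")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.delays <= 0):
            raise ValueError("delays must be positive")
        if self.flash_pair not in ("2/1", "3/2"):
            raise ValueError("flash_pair must be '2/1' or '3/2'")
        if np.any(self.ratios < 0) or np.any(self.ratios > 1.05):
            raise ValueError("ratios must lie in [0, 1.05]")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# flash_pair: {self.flash_pair}\n")
            fh.write("delay_s,ratio\n")
            for t, r in zip(self.delays, self.ratios):
                fh.write(f"{float(t)!r},{float(r)!r}\n")

    @classmethod
    def from_csv(cls, path) -> "DampingCurve":
        pair = "2/1"
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    if "flash_pair" in line:
                        pair = line.split(":", 1)[1].strip()
                    continue
                if not line or line.startswith("delay_s"):
                    continue
                t, r = line.split(",")
                rows.append((float(t), float(r)))
        arr = np.array(rows)
        return cls(delays=arr[:, 0], ratios=arr[:, 1], flash_pair=pair)


def damping_ratio(delay, k_A: float, k_D: float, r_inf: float = 1.0):
    """Model step ratio at interflash delay T (vectorized; T = 0 gives 0)."""
    delay = np.asarray(delay, dtype=float)
    if np.any(delay < 0):
        raise ValueError("delay must be >= 0")
    if not (k_A > 0 and k_D > 0):
        raise ValueError("rate constants must be positive")
    if not 0 < r_inf <= 1.05:
        raise ValueError("r_inf must be in (0, 1.05]")
    out = r_inf * -np.expm1(-k_A * delay) * -np.expm1(-k_D * delay)
    return float(out) if out.ndim == 0 else out


def damping_vs_delay(k_A: float, k_D: float, r_inf: float,
                     delays: Sequence[float], flash_pair: str = "2/1") -> DampingCurve:
    """Evaluate the damping model on a delay grid and package it as a curve."""
    delays = np.asarray(delays, dtype=float)
    ratios = damping_ratio(delays, k_A, k_D, r_inf)
    return DampingCurve(delays=delays, ratios=np.asarray(ratios), flash_pair=flash_pair)


@dataclass
class DampingFit:
    """Result of fitting the damping-vs-delay model."""

    k_slow: float            # rate-limiting relaxation rate, s^-1
    k_fast: float
    r_inf: float
    result: "lmfit.minimizer.MinimizerResult" = field(repr=False)

    @property
    def k_slow_reciprocal_time(self) -> float:
        """1/k of the slow rate (the paper-style 'half time' convention)."""
        return 1.0 / self.k_slow

    @property
    def k_slow_halftime_ln2(self) -> float:
        """ln(2)/k of the slow rate (the strict exponential half-time)."""
        return math.log(2.0) / self.k_slow

    def summary(self) -> dict:
        return {
            "k_slow_per_s": self.k_slow,
            "k_fast_per_s": self.k_fast,
            "r_inf": self.r_inf,
            "k_slow_time_1_over_k_s": self.k_slow_reciprocal_time,
            "k_slow_halftime_ln2_over_k_s": self.k_slow_halftime_ln2,
            "redchi": float(self.result.redchi) if self.result.redchi is not None else None,
            "success": bool(self.result.success),
        }


def fit_damping_curve(curve: DampingCurve,
                      init: Optional[Tuple[float, float]] = None,
                      sigma: Optional[np.ndarray] = None) -> DampingFit:
    """Least-squares fit of ``R_inf (1-e^{-k1 T})(1-e^{-k2 T})`` to a curve.

    Because the model is symmetric in the two rates they are returned sorted
    as (slow, fast); the slow one is rate-limiting.  ``init`` optionally
    provides starting rates; ``sigma`` optional per-point standard deviations
    (unweighted by default — no instrument error model is assumed).

    Raises :class:`IdentifiabilityError` when the ratios are flat (all
    delays past the relaxation: no kinetic information).
    """
    T = curve.delays
    y = curve.ratios
    if T.size < 4:
        raise IdentifiabilityError("need at least 4 delay points to fit two rates")
    if np.ptp(y) < 0.05 * max(np.max(np.abs(y)), 1e-12):
        raise IdentifiabilityError(
            "ratios are flat over the delay range: relaxation rates "
            "unidentifiable (delays too long?)")

    r0 = float(np.clip(np.max(y), 1e-3, 1.05))
    if init is None:
        # half-rise heuristic for the slow rate; fast rate started above it
        half = 0.5 * r0
        idx = int(np.searchsorted(y, half)) if np.all(np.diff(y) >= 0) else int(np.argmin(np.abs(y - half)))
        t_half = T[min(max(idx, 0), T.size - 1)]
        k1 = 1.6 / max(t_half, T[0])
        k2 = 10.0 / T[0]
    else:
        k1, k2 = init

    params = lmfit.Parameters()
    params.add("k_a", value=float(k1), min=1e-2, max=1e9)
    params.add("k_d", value=float(k2), min=1e-2, max=1e9)
    params.add("r_inf", value=r0, min=1e-6, max=1.05)

    def resid(p):
        m = damping_ratio(T, p["k_a"].value, p["k_d"].value, p["r_inf"].value)
        r = m - y
        return r / sigma if sigma is not None else r

    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise FitError(f"damping-curve fit failed: {out.message}")
    ka, kd = out.params["k_a"].value, out.params["k_d"].value
    return DampingFit(k_slow=min(ka, kd), k_fast=max(ka, kd),
                      r_inf=out.params["r_inf"].value, result=out)


def titration_to_kd(step_series: Iterable[Tuple[float, StepHeights]],
                    acceptor: Optional[Tuple[float, float]] = None,
                    clip_tol: Optional[float] = None,
                    ) -> list[Tuple[float, EquilibriumConstants]]:
    """Apply :func:`invert_steps` along an incubation-time series.

    Ordering is preserved; an inversion failure is re-raised with the
    incubation time of the offending element in the message.
    """
    out: list[Tuple[float, EquilibriumConstants]] = []
    for t_inc, steps in step_series:
        try:
            out.append((t_inc, invert_steps(steps, acceptor=acceptor, clip_tol=clip_tol)))
        except DampingError as exc:
            raise DampingError(f"incubation time {t_inc:g} s: {exc}") from exc
    return out
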