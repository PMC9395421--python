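"""Mechanistic chain-of-links model of reaction-center (RC) turnover.

The photosynthetic RC is modelled as a cross product of four discrete
coordinates:

* special pair redox state  ``P`` / ``P+``,
* primary quinone electrons on Q_A  (0 or 1),
* secondary quinone site  ``QB`` / ``QB-`` / ``QBH2`` / ``empty``,
* cytochrome docking site  ``vacant`` / ``cyt2+`` / ``cyt3+``.

That is 2 x 2 x 4 x 3 = 48 states; no combination is physically excluded,
so all 48 are retained.  Mean-field occupancies evolve under linear rate
equations plus two nonlinear couplings: docking-site binding draws from a
finite periplasmic cytochrome pool, and re-reduction of the pool by the
cytochrome bc1 complex consumes exported quinol electrons.

Light enters either as a continuous excitation rate ``k_L`` (photochemistry
``P,Q_A -> P+,Q_A-``) or as instantaneous saturating flashes that project all
open RCs (P reduced and Q_A oxidized) into the charge-separated state.

The donor side supports a *generalized* equilibrium: the bound-cytochrome
electron transfer ``P+ + cyt2+ <-> P + cyt3+`` may be reversible, with a
per-link equilibrium constant indexed by the number of electrons held on the
acceptor side (1, 2 or 3 — one constant per flash in a three-flash train).
Combined with fast exchange against a pool of reduced fraction ``r`` this
yields an effective donor availability ``K_D = K_e(link) * r / (1 - r)``,
i.e. a stable post-flash plateau of oxidized cytochrome.  With the default
``donor_link_K = (None, None, None)`` the transfer is irreversible and the
classical saturation limits hold exactly (1 cyt3+/RC under an interquinone
block; 3 cyt3+/RC for a three-flash train without quinol exchange).

``reopening_fraction`` is the closed-form re-opening law for a single closed
RC relaxing through one donor and one acceptor branch:
``(1 - exp(-k_A t)) * (1 - exp(-k_D t))``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ProtocolError

__all__ = [
    "RCState",
    "RCStateVector",
    "RateSet",
    "IlluminationProtocol",
    "SimulationResult",
    "enumerate_states",
    "apply_flash",
    "simulate_continuous",
    "simulate_flash_train",
    "reopening_fraction",
    "electron_balance_residual",
    "N_STATES",
]

P_STATES = ("P", "P+")
QA_STATES = (0, 1)
QB_STATES = ("QB", "QB-", "QBH2", "empty")
DONOR_STATES = ("vacant", "cyt2+", "cyt3+")

#: electrons carried by each Q_B-site species
QB_ELECTRONS = {"QB": 0, "QB-": 1, "QBH2": 2, "empty": 0}

#: half-saturation of bc1 resupply in exported electrons per RC.  The bc1
#: complex re-reduces the cytochrome pool from quinol; without exported
#: quinol there is no substrate and the pool is not resupplied.  Exported
#: quinol dilutes into the membrane quinone pool (tens of quinones per RC),
#: so bc1 reaches its full ~(10 ms)^-1 pace only after many turnovers —
#: during a 1 ms flash train its contribution is marginal, matching the
#: observed ~10 ms re-reduction of the oxidized cytochromes.
BC1_QUINOL_HALF = 10.0


class RCState(NamedTuple):
    """One discrete RC state (special pair, Q_A, Q_B site, donor site)."""

    p: str
    qa: int
    qb: str
    donor: str

    @property
    def acceptor_electrons(self) -> int:
        return self.qa + QB_ELECTRONS[self.qb]


def enumerate_states() -> list[RCState]:
    """Deterministic ordered list of all 48 discrete RC states.

    Order: special pair (P, P+) slowest, then Q_A (0, 1), then Q_B site
    (QB, QB-, QBH2, empty), then donor site (vacant, cyt2+, cyt3+) fastest.
    No combination is physically excluded.
    """
    return [
        RCState(p, qa, qb, d)
        for p, qa, qb, d in itertools.product(P_STATES, QA_STATES, QB_STATES, DONOR_STATES)
    ]


STATES: tuple[RCState, ...] = tuple(enumerate_states())
N_STATES: int = len(STATES)  # 48
_INDEX = {s: i for i, s in enumerate(STATES)}

# index groups used throughout
_OPEN = np.array([i for i, s in enumerate(STATES) if s.p == "P" and s.qa == 0])
_OPEN_TARGET = np.array([_INDEX[RCState("P+", 1, s.qb, s.donor)] for s in (STATES[i] for i in _OPEN)])
_PPLUS = np.array([i for i, s in enumerate(STATES) if s.p == "P+"])
_BOUND = np.array([i for i, s in enumerate(STATES) if s.donor != "vacant"])
_BOUND_OX = np.array([i for i, s in enumerate(STATES) if s.donor == "cyt3+"])
_VACANT = np.array([i for i, s in enumerate(STATES) if s.donor == "vacant"])
_VACANT_TO_RED = np.array([_INDEX[RCState(s.p, s.qa, s.qb, "cyt2+")] for s in (STATES[i] for i in _VACANT)])
_VACANT_TO_OX = np.array([_INDEX[RCState(s.p, s.qa, s.qb, "cyt3+")] for s in (STATES[i] for i in _VACANT)])

_QA_E = np.array([s.qa for s in STATES], dtype=float)
_QB_E = np.array([QB_ELECTRONS[s.qb] for s in STATES], dtype=float)


@dataclass(frozen=True)
class RateSet:
    """Microscopic rate constants, pool sizes and inhibitor flags.

    Rates are first-order (s^-1).  ``N_pool`` is the number of periplasmic
    cytochromes per RC available to the docking site.  ``donor_link_K`` holds
    the per-link equilibrium constants of the bound-cytochrome electron
    transfer for acceptor electron counts 1, 2, 3; ``None`` means
    irreversible transfer (equilibrium constant infinity).
    """

    k_L: float = 0.0            # photon absorption / excitation rate
    k_AB1: float = 1.0e4        # first interquinone transfer  Q_A- Q_B  -> Q_A Q_B-
    k_AB2: float = 6.0e3        # second interquinone transfer Q_A- Q_B- -> Q_A Q_BH2
    k_Qex: float = 1.0e3        # quinol release and quinone rebinding (each step)
    k_bind: float = 1.0e6       # cytochrome binding to the docking site
    k_unbind: float = 1.0e5     # cytochrome unbinding (either redox form)
    k_ET: float = 1.0e6         # P+ <- bound cyt2+ electron transfer (forward)
    N_pool: float = 10.0        # reduced cytochromes per RC (dark-adapted)
    k_bc1: float = 100.0        # pool re-reduction by the bc1 complex, (10 ms)^-1
    k_ext: float = 0.0          # pseudo-first-order external donor (ferrocene)
    donor_link_K: Tuple[Optional[float], Optional[float], Optional[float]] = (None, None, None)
    pool_reduced_fraction_0: float = 1.0  # dark-adapted reduced fraction of the pool
    terbutryne: bool = False    # blocks both interquinone transfers
    myxothiazol: bool = False   # inhibits bc1 (k_bc1 -> k_bc1 / 10)
    dithionite: bool = False    # acceptor side pre-reduced; photochemistry disabled

    def __post_init__(self):
        for name in ("k_L", "k_AB1", "k_AB2", "k_Qex", "k_bind", "k_unbind",
                     "k_ET", "N_pool", "k_bc1", "k_ext"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.pool_reduced_fraction_0 <= 1.0:
            raise ValueError("pool_reduced_fraction_0 must be in [0, 1]")
        if len(self.donor_link_K) != 3:
            raise ValueError("donor_link_K must have three entries (links 1..3)")
        for K in self.donor_link_K:
            if K is not None and (not np.isfinite(K) or K <= 0):
                raise ValueError(f"donor link equilibrium constants must be positive, got {K!r}")

    # effective rates after inhibitor flags
    @property
    def k_AB1_eff(self) -> float:
        return 0.0 if self.terbutryne else self.k_AB1

    @property
    def k_AB2_eff(self) -> float:
        return 0.0 if self.terbutryne else self.k_AB2

    @property
    def k_bc1_eff(self) -> float:
        return self.k_bc1 * 0.1 if self.myxothiazol else self.k_bc1

    @property
    def k_L_eff(self) -> float:
        return 0.0 if self.dithionite else self.k_L

    @property
    def photochemistry_enabled(self) -> bool:
        return not self.dithionite

    def with_(self, **kwargs) -> "RateSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "k_L": self.k_L, "k_AB1": self.k_AB1, "k_AB2": self.k_AB2,
            "k_Qex": self.k_Qex, "k_bind": self.k_bind, "k_unbind": self.k_unbind,
            "k_ET": self.k_ET, "N_pool": self.N_pool, "k_bc1": self.k_bc1,
            "k_ext": self.k_ext,
            "donor_link_K": list(self.donor_link_K),
            "pool_reduced_fraction_0": self.pool_reduced_fraction_0,
            "terbutryne": self.terbutryne, "myxothiazol": self.myxothiazol,
            "dithionite": self.dithionite,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        d = dict(d)
        if "donor_link_K" in d:
            d["donor_link_K"] = tuple(d["donor_link_K"])
        return cls(**d)


@dataclass(frozen=True)
class IlluminationProtocol:
    """Excitation protocol: continuous light or a train of saturating flashes."""

    mode: str                       # "continuous" | "flash_train"
    duration: float                 # s
    flash_times: Tuple[float, ...] = ()
    saturating: bool = True
    sampling_dt: float = 50e-6      # instrument time resolution

    def __post_init__(self):
        if self.mode not in ("continuous", "flash_train"):
            raise ProtocolError(f"unknown mode {self.mode!r}")
        if self.duration <= 0:
            raise ProtocolError("duration must be positive")
        if self.sampling_dt <= 0:
            raise ProtocolError("sampling interval must be positive")
        ft = self.flash_times
        if self.mode == "continuous" and ft:
            raise ProtocolError("continuous protocol takes no flash times")
        if any(t < 0 or t > self.duration for t in ft):
            raise ProtocolError("flash times must lie within [0, duration]")
        if any(b <= a for a, b in zip(ft, ft[1:])):
            raise ProtocolError("flash times must be strictly increasing")
        if any(b - a < self.sampling_dt for a, b in zip(ft, ft[1:])):
            raise ProtocolError(
                "flash spacing below the sampling interval cannot be resolved")
        if self.mode == "flash_train" and not self.saturating:
            raise ProtocolError("only saturating flashes are modelled")

    @classmethod
    def continuous(cls, duration: float, sampling_dt: float = 50e-6) -> "IlluminationProtocol":
        return cls(mode="continuous", duration=duration, sampling_dt=sampling_dt)

    @classmethod
    def flash_train(cls, n_flashes: int = 3, spacing: float = 400e-6,
                    first_flash: float = 400e-6, tail: float = 500e-6,
                    sampling_dt: float = 50e-6) -> "IlluminationProtocol":
        """Standard train: three saturating flashes 400 us apart."""
        times = tuple(first_flash + i * spacing for i in range(n_flashes))
        duration = (times[-1] if times else first_flash) + tail
        return cls(mode="flash_train", duration=duration,
                   flash_times=times, sampling_dt=sampling_dt)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "duration": self.duration,
                "flash_times": list(self.flash_times),
                "saturating": self.saturating, "sampling_dt": self.sampling_dt}

    @classmethod
    def from_dict(cls, d: dict) -> "IlluminationProtocol":
        d = dict(d)
        d["flash_times"] = tuple(d.get("flash_times", ()))
        return cls(**d)


@dataclass
class RCStateVector:
    """Occupancies over the 48 discrete states plus bookkeeping scalars."""

    occupancies: np.ndarray                 # shape (48,), sums to 1
    cyt3_per_rc: float = 0.0                # light-induced oxidized cytochrome per RC
    reduced_pool_fraction: float = 1.0
    exported_electrons: float = 0.0         # electrons that left as quinol
    external_donated: float = 0.0           # electrons delivered by an external donor

    def __post_init__(self):
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if self.occupancies.shape != (N_STATES,):
            raise ValueError(f"occupancies must have shape ({N_STATES},)")

    @classmethod
    def dark_adapted(cls, rates: RateSet) -> "RCStateVector":
        """Dark-adapted start: P reduced, quinones oxidized, donor docked.

        With dithionite the primary quinone starts reduced (acceptor side
        chemically reduced), which keeps the RC closed to photochemistry.
        If there are no periplasmic cytochromes (``N_pool == 0``) the docking
        site is vacant.
        """
        occ = np.zeros(N_STATES)
        qa0 = 1 if rates.dithionite else 0
        r0 = rates.pool_reduced_fraction_0
        if rates.N_pool > 0:
            occ[_INDEX[RCState("P", qa0, "QB", "cyt2+")]] = r0
            occ[_INDEX[RCState("P", qa0, "QB", "cyt3+")]] = 1.0 - r0
        else:
            occ[_INDEX[RCState("P", qa0, "QB", "vacant")]] = 1.0
        return cls(occupancies=occ, cyt3_per_rc=0.0, reduced_pool_fraction=r0)

    @property
    def pplus_per_rc(self) -> float:
        return float(self.occupancies[_PPLUS].sum())

    @property
    def open_fraction(self) -> float:
        return float(self.occupancies[_OPEN].sum())


def apply_flash(state: RCStateVector) -> RCStateVector:
    """Instantaneous saturating flash operator.

    All occupancy in open states (P reduced and Q_A oxidized) is projected
    into the corresponding charge-separated state ``P+, Q_A-``; closed states
    are untouched.  The operator is linear and idempotent and conserves total
    occupancy.
    """
    occ = state.occupancies.copy()
    moved = occ[_OPEN].copy()
    occ[_OPEN] = 0.0
    np.add.at(occ, _OPEN_TARGET, moved)
    return RCStateVector(occupancies=occ,
                         cyt3_per_rc=state.cyt3_per_rc,
                         reduced_pool_fraction=state.reduced_pool_fraction,
                         exported_electrons=state.exported_electrons,
                         external_donated=state.external_donated)


def reopening_fraction(t, k_A: float, k_D: float):
    """Closed-form fraction of re-opened RCs after a saturating flash.

    ``(1 - exp(-k_A t)) * (1 - exp(-k_D t))`` — both the acceptor branch
    (interquinone transfer, rate ``k_A``) and the donor branch (P+
    re-reduction, rate ``k_D``) must have relaxed for the RC to be open.
    Symmetric in the two rates; tends to 1 as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if not (k_A > 0 and k_D > 0):
        raise ValueError("rate constants must be positive")
    out = -np.expm1(-k_A * t) * -np.expm1(-k_D * t)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# ODE machinery


# donor ET back-reaction wiring: (P, cyt3+) -> (P+, cyt2+)
_BACK_SRC = np.array([i for i, s in enumerate(STATES)
                      if s.p == "P" and s.donor == "cyt3+"])
_BACK_DST = np.array([_INDEX[RCState("P+", s.qa, s.qb, "cyt2+")]
                      for s in (STATES[i] for i in _BACK_SRC)])

#: cumulative-turnover anchors at which the per-link donor equilibrium
#: constants apply under continuous light (mid-link positions)
_LINK_ANCHORS = np.array([0.5, 1.5, 2.5])


class _Machinery:
    """Precomputed transition structure for one RateSet.

    The donor ET back-reaction rate is segment- or state-history dependent:
    ``back_K`` fixes the active link equilibrium constant (None =
    irreversible), while ``interp_links`` (continuous light) log-interpolates
    the link constants against the cumulative light-induced turnover
    ``H - h0``, realizing the per-flash constants of the chain scheme.
    """

    def __init__(self, rates: RateSet, back_K: Optional[float] = None,
                 interp_links: Optional[Sequence[float]] = None,
                 h0: float = 0.0):
        self.rates = rates
        self.back_K = back_K
        self.h0 = h0
        if interp_links is not None:
            self.log_links = np.log(np.asarray(interp_links, dtype=float))
        else:
            self.log_links = None
        M = np.zeros((N_STATES, N_STATES))

        def add(i: int, j: int, k: float) -> None:
            if k > 0:
                M[i, i] -= k
                M[j, i] += k

        kL = rates.k_L_eff
        for i, s in enumerate(STATES):
            if s.p == "P" and s.qa == 0 and kL > 0:
                add(i, _INDEX[RCState("P+", 1, s.qb, s.donor)], kL)
            if s.qa == 1 and s.qb == "QB":
                add(i, _INDEX[RCState(s.p, 0, "QB-", s.donor)], rates.k_AB1_eff)
            if s.qa == 1 and s.qb == "QB-":
                add(i, _INDEX[RCState(s.p, 0, "QBH2", s.donor)], rates.k_AB2_eff)
            if s.qb == "QBH2":
                add(i, _INDEX[RCState(s.p, s.qa, "empty", s.donor)], rates.k_Qex)
            if s.qb == "empty":
                add(i, _INDEX[RCState(s.p, s.qa, "QB", s.donor)], rates.k_Qex)
            if s.p == "P+" and s.donor == "cyt2+":
                add(i, _INDEX[RCState("P", s.qa, s.qb, "cyt3+")], rates.k_ET)
            if s.donor != "vacant":
                add(i, _INDEX[RCState(s.p, s.qa, s.qb, "vacant")], rates.k_unbind)
            if s.p == "P+" and rates.k_ext > 0:
                add(i, _INDEX[RCState("P", s.qa, s.qb, s.donor)], rates.k_ext)
        self.M = M

        # bookkeeping flux coefficient vectors over occupancies
        et_fwd = np.zeros(N_STATES)
        for i, s in enumerate(STATES):
            if s.p == "P+" and s.donor == "cyt2+":
                et_fwd[i] = rates.k_ET
        self.et_fwd = et_fwd
        self.qexp = np.where(np.array([s.qb == "QBH2" for s in STATES]), 2.0 * rates.k_Qex, 0.0)
        self.extv = np.where(np.array([s.p == "P+" for s in STATES]),
                             rates.k_ext, 0.0)
        self.ox_ind = np.zeros(N_STATES)
        self.ox_ind[_BOUND_OX] = 1.0
        self.bound_ind = np.zeros(N_STATES)
        self.bound_ind[_BOUND] = 1.0

    # state vector layout: y = [occ(48), cyt3_total, exported, ext_donated]
    def _pool(self, occ: np.ndarray, H: float) -> tuple[float, float, float, float]:
        N = self.rates.N_pool
        occ_ox = float(self.ox_ind @ occ)
        occ_b = float(self.bound_ind @ occ)
        holes = max(H - occ_ox, 0.0)
        pool_red = max(N - occ_b - holes, 0.0)
        if N > 0:
            br = self.rates.k_bind * pool_red / N
            bo = self.rates.k_bind * holes / N
        else:
            br = bo = 0.0
        return holes, pool_red, br, bo

    def _back_rate(self, H: float) -> float:
        """Active donor back-reaction rate k_ET / K at cumulative turnover H."""
        if self.log_links is not None:
            h_light = H - self.h0
            if h_light <= 1e-9:
                return 0.0
            logK = float(np.interp(h_light, _LINK_ANCHORS, self.log_links))
            return self.rates.k_ET / math.exp(logK)
        if self.back_K is None:
            return 0.0
        return self.rates.k_ET / self.back_K

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        occ = y[:N_STATES]
        H, E = y[N_STATES], y[N_STATES + 1]
        docc = self.M @ occ
        holes, _pool_red, br, bo = self._pool(occ, H)
        if br > 0 or bo > 0:
            ov = occ[_VACANT]
            dv = np.zeros(N_STATES)
            np.add.at(dv, _VACANT, -(br + bo) * ov)
            np.add.at(dv, _VACANT_TO_RED, br * ov)
            np.add.at(dv, _VACANT_TO_OX, bo * ov)
            docc = docc + dv
        dH = float(self.et_fwd @ occ)
        kb = self._back_rate(H)
        if kb > 0:
            src = occ[_BACK_SRC]
            np.add.at(docc, _BACK_SRC, -kb * src)
            np.add.at(docc, _BACK_DST, kb * src)
            dH -= kb * float(src.sum())
        dE = float(self.qexp @ occ)
        dX = float(self.extv @ occ)
        if self.rates.k_bc1_eff > 0 and holes > 0 and E > 0:
            ret = self.rates.k_bc1_eff * holes * E / (E + BC1_QUINOL_HALF)
            dH -= ret
            dE -= ret
        out = np.empty_like(y)
        out[:N_STATES] = docc
        out[N_STATES] = dH
        out[N_STATES + 1] = dE
        out[N_STATES + 2] = dX
        return out

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        n = N_STATES
        J = np.zeros((n + 3, n + 3))
        J[:n, :n] = self.M
        occ = y[:n]
        H, E = y[n], y[n + 1]
        holes, _pr, br, bo = self._pool(occ, H)
        for v, tr, to in zip(_VACANT, _VACANT_TO_RED, _VACANT_TO_OX):
            J[v, v] -= br + bo
            J[tr, v] += br
            J[to, v] += bo
        # pool-composition coupling of the binding rates (br, bo depend on
        # occupancies and on total oxidized cytochrome H)
        N = self.rates.N_pool
        if N > 0 and self.rates.k_bind > 0:
            kN = self.rates.k_bind / N
            h_pos = 1.0 if (H - float(self.ox_ind @ occ)) > 0 else 0.0
            d_sum = np.zeros(n + 3)      # d(br+bo)/dy
            d_br = np.zeros(n + 3)
            d_bo = np.zeros(n + 3)
            d_sum[:n] = -kN * self.bound_ind
            d_br[:n] = kN * (h_pos * self.ox_ind - self.bound_ind)
            d_br[n] = -kN * h_pos
            d_bo[:n] = -kN * h_pos * self.ox_ind
            d_bo[n] = kN * h_pos
            for v, tr, to in zip(_VACANT, _VACANT_TO_RED, _VACANT_TO_OX):
                ov = occ[v]
                if ov != 0.0:
                    J[v, :] -= ov * d_sum
                    J[tr, :] += ov * d_br
                    J[to, :] += ov * d_bo
        J[n, :n] = self.et_fwd
        kb = self._back_rate(H)
        if kb > 0:
            for src, dst in zip(_BACK_SRC, _BACK_DST):
                J[src, src] -= kb
                J[dst, src] += kb
                J[n, src] -= kb
        J[n + 1, :n] = self.qexp
        J[n + 2, :n] = self.extv
        kb = self.rates.k_bc1_eff
        if kb > 0 and holes > 0 and E > 0:
            sat = E / (E + BC1_QUINOL_HALF)
            dsat = BC1_QUINOL_HALF / (E + BC1_QUINOL_HALF) ** 2
            J[n, n] -= kb * sat
            J[n, n + 1] -= kb * holes * dsat
            J[n, :n] += kb * sat * self.ox_ind
            J[n + 1, n] -= kb * sat
            J[n + 1, n + 1] -= kb * holes * dsat
            J[n + 1, :n] += kb * sat * self.ox_ind
        return J


def _initial_y(rates: RateSet, state: Optional[RCStateVector] = None) -> np.ndarray:
    if state is None:
        state = RCStateVector.dark_adapted(rates)
    y = np.zeros(N_STATES + 3)
    y[:N_STATES] = state.occupancies
    # total oxidized cytochrome includes any chemically pre-oxidized pool
    occ_ox = float(state.occupancies[_BOUND_OX].sum())
    pre_ox = max(rates.N_pool - 0.0, 0.0) * (1.0 - rates.pool_reduced_fraction_0)
    y[N_STATES] = max(pre_ox, occ_ox)
    y[N_STATES + 1] = state.exported_electrons
    y[N_STATES + 2] = state.external_donated
    return y


def _integrate(mach: _Machinery, y0: np.ndarray, t0: float, t1: float,
               t_eval: np.ndarray, rtol: float, atol: float) -> np.ndarray:
    """Integrate one dark/light segment; returns solution at t_eval columns."""
    if t1 <= t0:
        raise ValueError("segment must have positive length")
    sol = solve_ivp(mach.rhs, (t0, t1), y0, method="LSODA", jac=mach.jac,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        r = mach.rates
        raise IntegrationError(
            "ODE integration failed (status %r) in regime k_L=%.3g, k_AB1=%.3g, "
            "k_AB2=%.3g, k_Qex=%.3g, k_ET=%.3g, k_bind=%.3g, k_unbind=%.3g"
            % (sol.status, r.k_L, r.k_AB1, r.k_AB2, r.k_Qex, r.k_ET,
               r.k_bind, r.k_unbind))
    return sol.y


@dataclass
class SimulationResult:
    """Sampled trajectory of the chain model.

    ``cyt3_per_rc`` is the light-induced oxidized cytochrome per RC (total
    oxidized minus the pre-illumination amount), matching what a difference
    absorbance measurement reports.
    """

    time: np.ndarray
    occupancies: np.ndarray          # (n_times, 48)
    cyt3_per_rc: np.ndarray
    pplus_per_rc: np.ndarray
    exported_electrons: np.ndarray
    external_donated: np.ndarray
    reduced_pool_fraction: np.ndarray
    rates: RateSet
    protocol: IlluminationProtocol
    flash_increments: Tuple[float, ...] = ()
    step_heights: Optional["StepHeights"] = None  # set for 3-flash trains

    def state_at(self, i: int) -> RCStateVector:
        return RCStateVector(
            occupancies=self.occupancies[i].copy(),
            cyt3_per_rc=float(self.cyt3_per_rc[i]),
            reduced_pool_fraction=float(self.reduced_pool_fraction[i]),
            exported_electrons=float(self.exported_electrons[i]),
            external_donated=float(self.external_donated[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_s": self.time,
                "cyt3plus_per_rc": self.cyt3_per_rc,
                "pplus_per_rc": self.pplus_per_rc}
        for j, s in enumerate(STATES):
            cols[f"occ[{s.p}|QA{s.qa}|{s.qb}|{s.donor}]"] = self.occupancies[:, j]
        return pd.DataFrame(cols)

    def sidecar(self) -> dict:
        return {"rates": self.rates.to_dict(), "protocol": self.protocol.to_dict()}


def _collect(times: np.ndarray, ys: np.ndarray, rates: RateSet,
             protocol: IlluminationProtocol, h0: float) -> SimulationResult:
    occ = ys[:N_STATES].T
    H = ys[N_STATES]
    E = ys[N_STATES + 1]
    X = ys[N_STATES + 2]
    pplus = occ[:, _PPLUS].sum(axis=1)
    occ_ox = occ[:, _BOUND_OX].sum(axis=1)
    occ_b = occ[:, _BOUND].sum(axis=1)
    holes = np.clip(H - occ_ox, 0.0, None)
    denom = rates.N_pool - occ_b
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, 1.0 - np.minimum(holes / np.maximum(denom, 1e-12), 1.0), 0.0)
    return SimulationResult(
        time=times, occupancies=occ,
        cyt3_per_rc=H - h0, pplus_per_rc=pplus,
        exported_electrons=E, external_donated=X,
        reduced_pool_fraction=np.clip(r, 0.0, 1.0),
        rates=rates, protocol=protocol)


def _sample_grid(protocol: IlluminationProtocol) -> np.ndarray:
    n = int(round(protocol.duration / protocol.sampling_dt))
    grid = np.arange(n + 1) * protocol.sampling_dt
    return grid[grid <= protocol.duration + 1e-12 * protocol.sampling_dt]


def simulate_continuous(rates: RateSet, protocol: IlluminationProtocol,
                        rtol: float = 1e-10, atol: float = 1e-13) -> SimulationResult:
    """Integrate the chain model under continuous excitation ``k_L``."""
    if protocol.mode != "continuous":
        raise ProtocolError("simulate_continuous requires a continuous protocol")
    y0 = _initial_y(rates)
    links = rates.donor_link_K
    if any(K is not None for K in links):
        if any(K is None for K in links):
            raise ValueError(
                "continuous illumination requires donor links that are all "
                "finite or all irreversible")
        mach = _Machinery(rates, interp_links=links, h0=float(y0[N_STATES]))
    else:
        mach = _Machinery(rates)
    grid = _sample_grid(protocol)
    t_eval = grid if grid[-1] == protocol.duration else np.append(grid, protocol.duration)
    ys = _integrate(mach, y0, 0.0, protocol.duration, t_eval, rtol, atol)
    ys = ys[:, : len(grid)]
    return _collect(grid, ys, rates, protocol, h0=y0[N_STATES])


def simulate_flash_train(rates: RateSet, protocol: IlluminationProtocol,
                         rtol: float = 1e-10, atol: float = 1e-13) -> SimulationResult:
    """Alternate instantaneous saturating flashes with dark relaxation.

    Samples at flash times carry the pre-flash (left-limit) value, matching
    an instrument whose conversion happens just before the flash artifact.
    Per-flash increments are the oxidized-cytochrome plateau just before the
    next flash (or the end of the trace) minus the plateau just before the
    flash; for a three-flash train they are also returned as
    :class:`~photocyt.damping.StepHeights`.
    """
    from .damping import StepHeights  # local import to avoid cycle at import time

    if protocol.mode != "flash_train":
        raise ProtocolError("simulate_flash_train requires a flash_train protocol")
    links = rates.donor_link_K
    grid = _sample_grid(protocol)
    tol = protocol.sampling_dt * 1e-9
    y = _initial_y(rates)
    h0 = y[N_STATES]
    ys = np.empty((N_STATES + 3, len(grid)))
    ys[:, 0] = y
    boundaries = [0.0, *protocol.flash_times, protocol.duration]
    # drop a zero-length leading segment when the first flash is at t=0
    pre_flash_H: list[float] = []
    t_prev = 0.0
    fire = rates.photochemistry_enabled and protocol.saturating
    machinery_cache: dict[Optional[float], _Machinery] = {}

    def mach_for(n_fired: int) -> _Machinery:
        # the active donor-link constant follows the number of productive
        # flashes: the period after the i-th charge separation is governed by
        # K_e(i); before the first flash the dark-adapted state is taken as
        # equilibrated (no back-reaction)
        back_K = None if n_fired == 0 else links[min(n_fired, 3) - 1]
        if back_K not in machinery_cache:
            machinery_cache[back_K] = _Machinery(rates, back_K=back_K)
        return machinery_cache[back_K]

    n_productive = 0
    for seg_i, t_next in enumerate(boundaries[1:]):
        is_flash = seg_i < len(protocol.flash_times)
        mach = mach_for(n_productive)
        if t_next > t_prev + tol:
            mask = (grid > t_prev + tol) & (grid <= t_next + tol)
            pts = np.minimum(grid[mask], t_next)  # guard 1-ulp overshoot
            if pts.size and abs(pts[-1] - t_next) <= tol:
                t_eval = pts
            else:
                t_eval = np.append(pts, t_next)
            sol = _integrate(mach, y, t_prev, t_next, t_eval, rtol, atol)
            if pts.size:
                ys[:, np.flatnonzero(mask)] = sol[:, : pts.size]
            y = sol[:, -1]
        if is_flash:
            pre_flash_H.append(float(y[N_STATES]))
            if fire:
                occ = y[:N_STATES].copy()
                moved = occ[_OPEN].copy()
                occ[_OPEN] = 0.0
                np.add.at(occ, _OPEN_TARGET, moved)
                y[:N_STATES] = occ
                # a flash that excites essentially no RC (e.g. all closed by
                # an interquinone block) does not advance the chain link
                if float(moved.sum()) > 0.05:
                    n_productive += 1
        t_prev = t_next
    final_H = float(y[N_STATES])
    increments = tuple(
        (pre_flash_H[i + 1] if i + 1 < len(pre_flash_H) else final_H) - pre_flash_H[i]
        for i in range(len(pre_flash_H)))
    result = _collect(grid, ys, rates, protocol, h0=h0)
    result.flash_increments = increments
    if len(increments) == 3:
        result.step_heights = StepHeights(*increments)
    return result


def electron_balance_residual(result: SimulationResult) -> np.ndarray:
    """Electron bookkeeping residual at every output sample.

    Every photochemical turnover puts one electron on the acceptor side and
    one hole on P; holes are filled by cytochromes (counted in
    ``cyt3_per_rc``) or an external donor.  Therefore

        cyt3 + external_donated + P+ - (Q_A e- + Q_B e- + exported) = const

    (the constant is the initial acceptor-side electron count).  The residual
    returned here is that expression minus its value at t = 0; it should be
    zero to integrator precision whenever bc1 resupply is inactive.
    """
    acceptor = result.occupancies @ (_QA_E + _QB_E) + result.exported_electrons
    expr = (result.cyt3_per_rc + result.external_donated
            + result.pplus_per_rc - acceptor)
    return expr - expr[0]
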