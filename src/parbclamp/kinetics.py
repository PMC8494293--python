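"""Analytic steady state of the coarse clamp cycle and ultra-affinity quantities.

The coarse network has four protein species — open/closed conformation, free or
DNA-bound — plus free DNA.  Only the open conformation exchanges with DNA (the
closed clamp can neither bind nor release substrate); closure runs at ``k_oc``
off DNA and ``k_oc_dna`` on DNA, spontaneous opening at ``k_co`` / ``k_co_dna``,
and CTP hydrolysis returns closed clamps to the open pool at ``k_h`` on and off
DNA alike.  Because hydrolysis consumes nucleotide, the stationary state is a
nonequilibrium one: when the DNA substrate catalyzes closure
(``k_oc_dna > k_oc``) the apparent dissociation constant of the total protein
pool drops below the open-form equilibrium constant ``kd_open``.

Canonical units are s^-1 for rates and uM for concentrations; converters for
min^-1 inputs live in :mod:`parbclamp.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp


class DegenerateParameterizationError(ValueError):
    """Raised when a rate combination makes a steady-state ratio undefined."""


@dataclass(frozen=True)
class RateSet:
    """Kinetic constants of the clamp cycle.

    Parameters
    ----------
    k_oc, k_co:
        Closure and opening rates of free protein (s^-1).
    k_oc_dna, k_co_dna:
        Closure and opening rates of the DNA-bound protein (s^-1).  For a parS
        substrate ``k_oc_dna`` is the catalyzed closure rate; for nonspecific
        DNA it equals ``k_oc``.
    k_h:
        CTP hydrolysis rate (s^-1), assumed identical on and off DNA.
    kd_open:
        Equilibrium dissociation constant of the open form for the DNA
        substrate (uM).
    k_on:
        Association rate of the open form (uM^-1 s^-1).  Only dynamic solvers
        (ODE, stochastic) need it; the analytic theory depends on ``kd_open``
        alone.  When ``None``, solvers pick a default fast enough that binding
        equilibrates well before the slowest conformational transition.
    """

    k_oc: float
    k_co: float
    k_oc_dna: float
    k_co_dna: float
    k_h: float
    kd_open: float
    k_on: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("k_oc", "k_co", "k_oc_dna", "k_co_dna", "k_h", "kd_open"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.k_on is not None and not (math.isfinite(self.k_on) and self.k_on > 0):
            raise ValueError(f"k_on must be finite and > 0, got {self.k_on!r}")

    def resolved_k_on(self) -> float:
        """k_on to use in dynamic solvers, defaulting to a fast-binding value.

        The default sets the open-form off-rate ``k_on * kd_open`` to 100x the
        fastest conformational rate, so DNA binding is always pre-equilibrated
        relative to the conformational cycle. Overridable by supplying k_on.
        """
        if self.k_on is not None:
            return self.k_on
        fastest = max(self.k_oc, self.k_co, self.k_oc_dna, self.k_co_dna, self.k_h, 1e-3)
        kd = self.kd_open if self.kd_open > 0 else 1.0
        return 100.0 * fastest / kd

    @property
    def k_off_open(self) -> float:
        """Dissociation rate of the open bound form (s^-1)."""
        return self.resolved_k_on() * self.kd_open

    def with_(self, **kwargs) -> "RateSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (uM) of the four protein species plus free DNA."""

    parb_open_free: float
    parb_closed_free: float
    parb_open_bound: float
    parb_closed_bound: float
    dna_free: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < -1e-12:
                raise ValueError(f"{name} must be >= 0, got {v!r}")

    def as_dict(self) -> dict:
        return {
            "parb_open_free": self.parb_open_free,
            "parb_closed_free": self.parb_closed_free,
            "parb_open_bound": self.parb_open_bound,
            "parb_closed_bound": self.parb_closed_bound,
            "dna_free": self.dna_free,
        }

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.parb_open_free,
                self.parb_closed_free,
                self.parb_open_bound,
                self.parb_closed_bound,
                self.dna_free,
            ]
        )

    @property
    def parb_total(self) -> float:
        return (
            self.parb_open_free
            + self.parb_closed_free
            + self.parb_open_bound
            + self.parb_closed_bound
        )

    @property
    def parb_free(self) -> float:
        return self.parb_open_free + self.parb_closed_free

    @property
    def parb_bound(self) -> float:
        return self.parb_open_bound + self.parb_closed_bound

    @property
    def bound_fraction(self) -> float:
        return self.parb_bound / self.parb_total


SPECIES_ORDER = (
    "parb_open_free",
    "parb_closed_free",
    "parb_open_bound",
    "parb_closed_bound",
    "dna_free",
)


def open_closed_partition(rates: RateSet, on_dna: bool = False) -> tuple[float, float]:
    """Steady-state (open, closed) fractions of a conformational pair.

    At stationarity the one-way hydrolysis flux adds to spontaneous opening, so
    the open fraction is ``(k_co* + k_h) / (k_oc* + k_co* + k_h)`` where ``*``
    selects the on- or off-DNA rates.  With ``k_h = 0`` this reduces to the
    detailed-balance ratio ``k_oc*/k_co*``.
    """
    k_oc = rates.k_oc_dna if on_dna else rates.k_oc
    k_co = rates.k_co_dna if on_dna else rates.k_co
    denom = k_oc + k_co + rates.k_h
    if denom == 0:
        raise DegenerateParameterizationError(
            "k_oc + k_co + k_h is zero: the open/closed partition is undefined"
        )
    open_frac = (k_co + rates.k_h) / denom
    return open_frac, 1.0 - open_frac


def kd_observed(rates: RateSet) -> float:
    """Apparent dissociation constant of the total protein pool at steady state.

    ``Kd_obs = kd_open * (k_co_dna + k_h)/(k_co + k_h)
                       * (k_oc + k_co + k_h)/(k_oc_dna + k_co_dna + k_h)``

    equal to ``[ParB][DNA]/[ParB.DNA]`` with total (open + closed) pools.  Three
    limiting cases: a hydrolysis-dead mutant (``k_h = 0`` with unchanged
    conformational equilibrium on DNA) and nonspecific DNA (on-DNA rates equal
    to off-DNA rates) both give ``kd_open``; a closure-catalyzing site with
    ``k_oc_dna >> k_co_dna, k_h`` gives the ultra-affinity reduction
    ``~ kd_open * k_h / (k_oc_dna + k_h)``.
    """
    if rates.kd_open <= 0:
        raise DegenerateParameterizationError("kd_open must be > 0")
    d1 = rates.k_co + rates.k_h
    d2 = rates.k_oc_dna + rates.k_co_dna + rates.k_h
    if d1 == 0:
        raise DegenerateParameterizationError(
            "k_co + k_h is zero: the free closed pool never reopens"
        )
    if d2 == 0:
        raise DegenerateParameterizationError(
            "k_oc_dna + k_co_dna + k_h is zero: on-DNA partition undefined"
        )
    return (
        rates.kd_open
        * (rates.k_co_dna + rates.k_h)
        / d1
        * (rates.k_oc + rates.k_co + rates.k_h)
        / d2
    )


def kd_observed_approx(rates: RateSet) -> float:
    """Ultra-affinity approximation ``kd_open * k_h / (k_oc_dna + k_h)``.

    Valid when hydrolysis dominates the free-protein conformational rates
    (``k_h >> k_co, k_oc``, ensuring closed clamps recycle rather than
    accumulate) and on-DNA closure dominates on-DNA opening
    (``k_oc_dna >> k_co_dna``).
    """
    denom = rates.k_oc_dna + rates.k_h
    if denom <= 0:
        raise DegenerateParameterizationError("k_oc_dna + k_h must be > 0")
    return rates.kd_open * rates.k_h / denom


def fold_reduction(k_h: float, k_oc_parS: float, on_zero: str = "inf") -> float:
    """Fold by which catalyzed closure + hydrolysis lowers the apparent Kd.

    Equals ``(k_oc_parS + k_h) / k_h = kd_open / kd_observed_approx``.  With no
    catalysis (``k_oc_parS = 0``) there is no ultra-affinity and the fold is 1.
    """
    if k_h < 0 or k_oc_parS < 0:
        raise ValueError("rates must be >= 0")
    if k_h == 0:
        if on_zero == "inf":
            return math.inf
        raise DegenerateParameterizationError("k_h is zero: fold reduction diverges")
    return (k_oc_parS + k_h) / k_h


def catalytic_capacity(k_oc_parS: float, k_h: float, on_zero: str = "inf") -> float:
    """Closure events one parS site can catalyze per hydrolysis turnover time.

    ``k_oc_parS / k_h``; a large value means closure is fast relative to the
    rate-limiting hydrolysis step, so substoichiometric parS suffices to keep
    the whole protein pool cycling.
    """
    if k_h < 0 or k_oc_parS < 0:
        raise ValueError("rates must be >= 0")
    if k_h == 0:
        if on_zero == "inf":
            return math.inf
        raise DegenerateParameterizationError("k_h is zero: capacity diverges")
    return k_oc_parS / k_h


def steady_state(
    rates: RateSet,
    parb_total: float,
    dna_total: float,
    dna_clamped: bool = False,
) -> SpeciesState:
    """Unique nonnegative steady state of the coarse network.

    Flux balance fixes the open fractions of the free and bound pools
    independently; the binding edge then enforces
    ``[open free] * [DNA free] = kd_open * [open bound]``, which in terms of
    total pools reads ``[free] * [DNA] = Kd_obs * [bound]``.  Combined with
    conservation of protein (and of DNA unless ``dna_clamped`` holds free DNA
    at ``dna_total``, the excess-substrate approximation) this yields a single
    quadratic for the bound pool.
    """
    if parb_total <= 0:
        raise ValueError("parb_total must be > 0")
    if dna_total < 0:
        raise ValueError("dna_total must be >= 0")

    open_free, _ = open_closed_partition(rates, on_dna=False)
    open_bound, _ = open_closed_partition(rates, on_dna=True)

    if dna_total == 0:
        return SpeciesState(
            parb_open_free=open_free * parb_total,
            parb_closed_free=(1 - open_free) * parb_total,
            parb_open_bound=0.0,
            parb_closed_bound=0.0,
            dna_free=0.0,
        )

    kd = kd_observed(rates)
    if dna_clamped:
        dna_free = dna_total
        bound = parb_total * dna_free / (kd + dna_free)
    else:
        # bound^2 - (P + D + Kd) bound + P D = 0; smaller root in the
        # cancellation-free (citardauq) form since Kd may dwarf the totals
        s = parb_total + dna_total + kd
        disc = s * s - 4.0 * parb_total * dna_total
        bound = 2.0 * parb_total * dna_total / (s + math.sqrt(max(disc, 0.0)))
        bound = min(bound, parb_total, dna_total)
        dna_free = dna_total - bound
    free = parb_total - bound
    return SpeciesState(
        parb_open_free=open_free * free,
        parb_closed_free=(1 - open_free) * free,
        parb_open_bound=open_bound * bound,
        parb_closed_bound=(1 - open_bound) * bound,
        dna_free=dna_free,
    )


@dataclass(frozen=True)
class Relaxation:
    """Mass-action trajectory of the coarse network."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 5), columns SPECIES_ORDER
    dna_clamped: bool

    @property
    def final(self) -> SpeciesState:
        return self.state_at(-1)

    def state_at(self, i: int) -> SpeciesState:
        row = self.states[i]
        return SpeciesState(*row)

    def parb_totals(self) -> np.ndarray:
        return self.states[:, :4].sum(axis=1)


def _mass_action_rhs(rates: RateSet, dna_clamped: bool, dna_total: float):
    k_on = rates.resolved_k_on()
    k_off = k_on * rates.kd_open

    def rhs(_t, y):
        po, pc, bo, bc, d = y
        if dna_clamped:
            d = dna_total
        bind = k_on * po * d
        unbind = k_off * bo
        dpo = -rates.k_oc * po + (rates.k_co + rates.k_h) * pc - bind + unbind
        dpc = rates.k_oc * po - (rates.k_co + rates.k_h) * pc
        dbo = -rates.k_oc_dna * bo + (rates.k_co_dna + rates.k_h) * bc + bind - unbind
        dbc = rates.k_oc_dna * bo - (rates.k_co_dna + rates.k_h) * bc
        dd = 0.0 if dna_clamped else (unbind - bind)
        return [dpo, dpc, dbo, dbc, dd]

    return rhs


def relax_ode(
    rates: RateSet,
    initial: SpeciesState,
    t_end: float,
    n_points: int = 200,
    dna_clamped: bool = False,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Relaxation:
    """Integrate the mass-action ODEs of the coarse network to ``t_end``.

    Serves as a numerical oracle for :func:`steady_state`: for ``t_end`` much
    longer than the slowest network timescale the terminal state converges to
    the analytic fixed point.  Uses an implicit stiff solver since binding is
    deliberately fast relative to the conformational cycle.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    y0 = initial.as_array()
    rhs = _mass_action_rhs(rates, dna_clamped, initial.dna_free)
    times = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, t_eval=times, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed ({sol.message}); try a smaller t_end "
            "or looser tolerances"
        )
    states = np.clip(sol.y.T, 0.0, None)
    if dna_clamped:
        states[:, 4] = initial.dna_free
    return Relaxation(times=sol.t, states=states, dna_clamped=dna_clamped)
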