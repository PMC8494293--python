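"""Exact stochastic simulation of the clamp-cycle reaction schemes.

Two networks are provided: the coarse scheme (four protein species, open or
closed conformation crossed with free or DNA-bound, plus free DNA) whose
stationary law the analytic theory in :mod:`parbclamp.kinetics` solves, and a
detailed scheme resolving nucleotide occupancy (apo / CTP) and the tethered,
untethered and gate-closed conformations, with clamp loading at parS and the
post-hydrolysis competition between nucleotide exchange (clamp stays on DNA)
and unloading.

Sampling uses the direct method: exponential waiting times from the total
propensity, reaction choice proportional to individual propensities.  The
networks are small, so exact sampling is cheap and there is no need for
approximate leaping.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from parbclamp.kinetics import RateSet


@dataclass(frozen=True)
class Reaction:
    """Elementary reaction: stoichiometries map species name -> count."""

    reactants: dict
    products: dict
    rate: float  # stochastic rate constant (propensity units)
    name: str = ""
    is_hydrolysis: bool = False

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be >= 0 in reaction {self.name!r}")
        for stoich in (self.reactants, self.products):
            for sp, n in stoich.items():
                if not (isinstance(n, (int, np.integer)) and n >= 0):
                    raise ValueError(f"stoichiometry of {sp!r} must be a nonnegative integer")


@dataclass
class ReactionNetwork:
    """A mass-action jump process over integer copy numbers.

    ``volume`` converts concentrations to copy numbers (copies per uM);
    bimolecular stochastic rate constants must already be divided by it.
    ``moieties`` names conserved groups of species (e.g. all protein states)
    for conservation reporting.
    """

    species: tuple
    initial: np.ndarray
    reactions: list
    volume: float = 1.0
    moieties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.initial = np.asarray(self.initial, dtype=np.int64)
        if len(self.initial) != len(self.species):
            raise ValueError("initial counts and species lists differ in length")
        if (self.initial < 0).any():
            raise ValueError("copy numbers must be >= 0")
        self._index = {s: i for i, s in enumerate(self.species)}
        n_sp, n_rx = len(self.species), len(self.reactions)
        self._react = np.zeros((n_rx, n_sp), dtype=np.int64)
        self._delta = np.zeros((n_rx, n_sp), dtype=np.int64)
        for j, rx in enumerate(self.reactions):
            for sp, n in rx.reactants.items():
                self._react[j, self._index[sp]] += n
                self._delta[j, self._index[sp]] -= n
            for sp, n in rx.products.items():
                self._delta[j, self._index[sp]] += n

    def index(self, species: str) -> int:
        return self._index[species]

    @property
    def delta(self) -> np.ndarray:
        """State-change matrix, one row per reaction."""
        return self._delta

    def conserved_totals(self, counts: Optional[np.ndarray] = None) -> dict:
        """Totals of the declared conserved moieties at the given state."""
        c = self.initial if counts is None else np.asarray(counts)
        return {
            name: int(sum(c[self._index[s]] for s in members))
            for name, members in self.moieties.items()
        }

    def verify_moieties(self) -> None:
        """Check declared moieties are truly conserved by every reaction."""
        for name, members in self.moieties.items():
            idx = [self._index[s] for s in members]
            net = self._delta[:, idx].sum(axis=1)
            if (net != 0).any():
                bad = [self.reactions[j].name for j in np.nonzero(net)[0]]
                raise ValueError(f"moiety {name!r} not conserved by reactions {bad}")

    def network_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.species).encode())
        h.update(self.initial.tobytes())
        for rx in self.reactions:
            h.update(
                repr((sorted(rx.reactants.items()), sorted(rx.products.items()), rx.rate)).encode()
            )
        return h.hexdigest()[:16]

    def describe(self) -> str:
        """Human-readable reaction list."""
        lines = [f"# species: {', '.join(self.species)}", f"# volume: {self.volume} copies/uM"]
        for rx in self.reactions:
            lhs = " + ".join(f"{n} {s}" if n > 1 else s for s, n in sorted(rx.reactants.items())) or "0"
            rhs = " + ".join(f"{n} {s}" if n > 1 else s for s, n in sorted(rx.products.items())) or "0"
            tag = "  [hydrolysis]" if rx.is_hydrolysis else ""
            lines.append(f"{rx.name or '?'}: {lhs} -> {rhs}  rate={rx.rate:g}{tag}")
        return "\n".join(lines)


@dataclass
class Trajectory:
    """One exact sample path: event times, reaction indices, and metadata.

    Species counts are reconstructed on demand from the initial state and the
    per-event state changes, keeping storage linear in the number of events.
    """

    network: ReactionNetwork
    times: np.ndarray  # event times, strictly increasing
    reaction_index: np.ndarray
    t_end: float
    seed: int

    @property
    def metadata(self) -> dict:
        return {"seed": self.seed, "network_hash": self.network.network_hash(), "t_end": self.t_end}

    @property
    def n_events(self) -> int:
        return len(self.times)

    def species_counts(self) -> np.ndarray:
        """Counts after each event; row 0 is the initial state."""
        if self.n_events == 0:
            return self.network.initial[None, :].copy()
        steps = self.network.delta[self.reaction_index]
        counts = np.empty((self.n_events + 1, len(self.network.species)), dtype=np.int64)
        counts[0] = self.network.initial
        np.cumsum(steps, axis=0, out=counts[1:])
        counts[1:] += self.network.initial
        return counts

    def hydrolysis_events(self) -> np.ndarray:
        """Times of hydrolysis-tagged events."""
        hyd = np.array([rx.is_hydrolysis for rx in self.network.reactions])
        return self.times[hyd[self.reaction_index]]

    def time_average(self, burn_in: float = 0.0) -> np.ndarray:
        """Time-weighted mean copy number of each species over [burn_in, t_end]."""
        if burn_in >= self.t_end:
            raise ValueError("burn_in must be < t_end")
        counts = self.species_counts()
        edges = np.concatenate([[0.0], self.times, [self.t_end]])
        lo = np.clip(edges[:-1], burn_in, self.t_end)
        hi = np.clip(edges[1:], burn_in, self.t_end)
        w = hi - lo
        return (counts * w[:, None]).sum(axis=0) / (self.t_end - burn_in)

    def counts_at(self, t: float) -> np.ndarray:
        """State occupied at time t."""
        i = int(np.searchsorted(self.times, t, side="right"))
        counts = self.network.initial.copy()
        if i > 0:
            counts += self.network.delta[self.reaction_index[:i]].sum(axis=0)
        return counts


def simulate(
    network: ReactionNetwork,
    t_end: float,
    seed: int,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Direct-method exact simulation of the network up to ``t_end``.

    Reproducible: (seed, network) fully determines the trajectory.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = np.random.default_rng(seed)

    n_rx = len(network.reactions)
    counts = network.initial.astype(np.int64).copy()
    # flat per-reaction views for the inner loop
    react_rows = [np.nonzero(network._react[j])[0] for j in range(n_rx)]
    react_stoich = [network._react[j][rows] for j, rows in enumerate(react_rows)]
    delta_rows = [np.nonzero(network.delta[j])[0] for j in range(n_rx)]
    delta_vals = [network.delta[j][rows] for j, rows in enumerate(delta_rows)]
    rates = np.array([rx.rate for rx in network.reactions], dtype=float)

    react_rows_l = [list(map(int, r)) for r in react_rows]
    react_stoich_l = [list(map(int, s)) for s in react_stoich]
    delta_rows_l = [list(map(int, r)) for r in delta_rows]
    delta_vals_l = [list(map(int, v)) for v in delta_vals]
    counts_l = [int(c) for c in counts]
    rates_l = list(rates)

    def propensity(j: int) -> float:
        a = rates_l[j]
        for i, s in zip(react_rows_l[j], react_stoich_l[j]):
            c = counts_l[i]
            if s == 1:
                a *= c
            elif s == 2:
                a *= c * (c - 1) / 2.0
            else:
                for k in range(s):
                    a *= (c - k) / (k + 1)
        return a

    props = [propensity(j) for j in range(n_rx)]
    total = sum(props)

    times: list = []
    rxn_idx: list = []
    t = 0.0
    block = rng.random(2 * 65536)
    bi = 0
    while True:
        if total <= 0.0:
            break  # absorbing state: no reaction can fire
        if bi + 2 > len(block):
            block = rng.random(2 * 65536)
            bi = 0
        u1, u2 = block[bi], block[bi + 1]
        bi += 2
        t += -np.log1p(-u1) / total
        if t > t_end:
            break
        if len(times) >= max_events:
            raise RuntimeError(f"event budget {max_events} exhausted at t={t:.3g}")
        # pick reaction
        target = u2 * total
        acc = 0.0
        j = n_rx - 1
        for jj in range(n_rx):
            acc += props[jj]
            if target < acc:
                j = jj
                break
        for i, v in zip(delta_rows_l[j], delta_vals_l[j]):
            counts_l[i] += v
        times.append(t)
        rxn_idx.append(j)
        # refresh propensities of reactions touching changed species
        props = [propensity(jj) for jj in range(n_rx)]
        total = sum(props)
        if total > 1e300:
            raise OverflowError("total propensity overflow")

    return Trajectory(
        network=network,
        times=np.asarray(times, dtype=float),
        reaction_index=np.asarray(rxn_idx, dtype=np.int32),
        t_end=t_end,
        seed=seed,
    )


COARSE_SPECIES = ("parb_open_free", "parb_closed_free", "parb_open_bound", "parb_closed_bound", "dna_free")


def build_coarse_network(
    rates: RateSet,
    parb_copies: int,
    dna_copies: int,
    volume: float = 500.0,
) -> ReactionNetwork:
    """Coarse clamp-cycle network with integer copy numbers.

    ``volume`` is in copies per uM; the open-form association rate constant
    (uM^-1 s^-1) is divided by it to give the stochastic bimolecular constant.
    The closed form binds and releases nothing.
    """
    if parb_copies < 0 or dna_copies < 0:
        raise ValueError("copy numbers must be >= 0")
    k_on = rates.resolved_k_on()
    rxns = [
        Reaction({"parb_open_free": 1}, {"parb_closed_free": 1}, rates.k_oc, "close_free"),
        Reaction({"parb_closed_free": 1}, {"parb_open_free": 1}, rates.k_co, "open_free"),
        Reaction(
            {"parb_closed_free": 1}, {"parb_open_free": 1}, rates.k_h, "hydrolyze_free",
            is_hydrolysis=True,
        ),
        Reaction({"parb_open_bound": 1}, {"parb_closed_bound": 1}, rates.k_oc_dna, "close_bound"),
        Reaction({"parb_closed_bound": 1}, {"parb_open_bound": 1}, rates.k_co_dna, "open_bound"),
        Reaction(
            {"parb_closed_bound": 1}, {"parb_open_bound": 1}, rates.k_h, "hydrolyze_bound",
            is_hydrolysis=True,
        ),
        Reaction(
            {"parb_open_free": 1, "dna_free": 1}, {"parb_open_bound": 1},
            k_on / volume, "bind",
        ),
        Reaction(
            {"parb_open_bound": 1}, {"parb_open_free": 1, "dna_free": 1},
            k_on * rates.kd_open, "unbind",
        ),
    ]
    initial = np.zeros(5, dtype=np.int64)
    initial[0] = parb_copies
    initial[4] = dna_copies
    net = ReactionNetwork(
        species=COARSE_SPECIES,
        initial=initial,
        reactions=rxns,
        volume=volume,
        moieties={
            "ParB": ["parb_open_free", "parb_closed_free", "parb_open_bound", "parb_closed_bound"],
            "DNA": ["dna_free", "parb_open_bound", "parb_closed_bound"],
        },
    )
    net.verify_moieties()
    return net


DETAILED_SPECIES = (
    "parb_apo",          # autoinhibited, no nucleotide
    "parb_ctp_intra",    # CTP bound, N-M tethered (autoinhibited)
    "parb_ctp_open",     # untethered, binding-competent
    "parb_closed_free",  # gate closed off DNA
    "parb_open_parS",    # untethered, parS-engaged
    "parb_clamp_dna",    # closed clamp entrapping DNA
    "parS_free",
)

_DETAILED_STEPS = {
    "ctp_on": "step 1 (CTP binding)",
    "ctp_off": "step 1 (CTP release)",
    "ctp_conc": "step 1 (CTP concentration)",
    "k_untether": "step 2/3 (N-M untethering)",
    "k_retether": "step 2/3 (N-M retethering)",
    "k_close_free": "step 4 (closure off DNA)",
    "k_on_parS": "step 4' (parS engagement)",
    "k_off_parS": "step 4' (parS release)",
    "k_close_parS": "step 4' (closure on parS)",
    "k_h": "step 5/5' (CTP hydrolysis)",
    "kd_ctp": "step 5' (CTP re-capture affinity)",
}


def build_detailed_network(
    params: dict,
    parb_copies: int = 500,
    parS_copies: int = 10,
    volume: float = 500.0,
) -> ReactionNetwork:
    """Detailed scheme with nucleotide state and the exchange/unload split.

    ``params`` must supply every key in ``ctp_on, ctp_off, ctp_conc,
    k_untether, k_retether, k_close_free, k_on_parS, k_off_parS, k_close_parS,
    k_h, kd_ctp`` (uM, s^-1, uM^-1 s^-1 as appropriate).  After hydrolysis on
    DNA, the clamp either exchanges CDP for CTP in place (probability
    ``p_retain = [CTP]/([CTP] + kd_ctp)``) or unloads and reverts to the apo
    autoinhibited dimer.  The untether/retether rates are free parameters:
    no measured values constrain them.
    """
    missing = [k for k in _DETAILED_STEPS if k not in params]
    if missing:
        detail = "; ".join(f"{k} ({_DETAILED_STEPS[k]})" for k in missing)
        raise ValueError(f"missing detailed-network rates: {detail}")
    p = {k: float(params[k]) for k in _DETAILED_STEPS}
    if p["kd_ctp"] < 0 or p["ctp_conc"] < 0:
        raise ValueError("ctp_conc and kd_ctp must be >= 0")
    denom = p["ctp_conc"] + p["kd_ctp"]
    p_retain = p["ctp_conc"] / denom if denom > 0 else 0.0

    rxns = [
        Reaction({"parb_apo": 1}, {"parb_ctp_intra": 1}, p["ctp_on"] * p["ctp_conc"], "1_ctp_bind"),
        Reaction({"parb_ctp_intra": 1}, {"parb_apo": 1}, p["ctp_off"], "1_ctp_release"),
        Reaction({"parb_ctp_intra": 1}, {"parb_ctp_open": 1}, p["k_untether"], "2_untether"),
        Reaction({"parb_ctp_open": 1}, {"parb_ctp_intra": 1}, p["k_retether"], "3_retether"),
        Reaction({"parb_ctp_open": 1}, {"parb_closed_free": 1}, p["k_close_free"], "4_close_free"),
        Reaction(
            {"parb_ctp_open": 1, "parS_free": 1}, {"parb_open_parS": 1},
            p["k_on_parS"] / volume, "4p_parS_engage",
        ),
        Reaction(
            {"parb_open_parS": 1}, {"parb_ctp_open": 1, "parS_free": 1},
            p["k_off_parS"], "4p_parS_release",
        ),
        Reaction({"parb_open_parS": 1}, {"parb_clamp_dna": 1}, p["k_close_parS"], "4p_close_parS"),
        Reaction(
            {"parb_closed_free": 1}, {"parb_apo": 1}, p["k_h"], "5_hydrolyze_free",
            is_hydrolysis=True,
        ),
        Reaction(
            {"parb_clamp_dna": 1}, {"parb_clamp_dna": 1}, p["k_h"] * p_retain,
            "5p_hydrolyze_exchange", is_hydrolysis=True,
        ),
        Reaction(
            {"parb_clamp_dna": 1}, {"parb_apo": 1, "parS_free": 1},
            p["k_h"] * (1.0 - p_retain), "5p_hydrolyze_unload", is_hydrolysis=True,
        ),
    ]
    initial = np.zeros(len(DETAILED_SPECIES), dtype=np.int64)
    initial[0] = parb_copies
    initial[DETAILED_SPECIES.index("parS_free")] = parS_copies
    net = ReactionNetwork(
        species=DETAILED_SPECIES,
        initial=initial,
        reactions=rxns,
        volume=volume,
        moieties={
            "ParB": [s for s in DETAILED_SPECIES if s.startswith("parb")],
            "parS": ["parS_free", "parb_open_parS", "parb_clamp_dna"],
        },
    )
    net.verify_moieties()
    return net


def slowest_timescale(network: ReactionNetwork) -> float:
    """1 / (smallest positive effective rate): a burn-in yardstick.

    For bimolecular reactions the stochastic constant is scaled up by the
    conserved-moiety capacity of the partner species, giving a pseudo-first-
    order rate per molecule rather than the raw per-pair constant.
    """
    capacity = {}
    for i, sp in enumerate(network.species):
        cap = int(network.initial[i])
        for members in network.moieties.values():
            if sp in members:
                cap = max(cap, network.conserved_totals()[_moiety_name(network, sp)])
        capacity[sp] = max(cap, 1)
    effective = []
    for rx in network.reactions:
        if rx.rate <= 0:
            continue
        slots = []
        for sp, n in rx.reactants.items():
            slots.extend([sp] * n)
        eff = rx.rate
        for sp in slots[1:]:
            eff *= capacity[sp]
        effective.append(eff)
    if not effective:
        raise ValueError("network has no active reactions")
    return 1.0 / min(effective)


def _moiety_name(network: ReactionNetwork, species: str) -> str:
    for name, members in network.moieties.items():
        if species in members:
            return name
    raise KeyError(species)


def hydrolysis_flux(trajectory: Trajectory, burn_in: Optional[float] = None) -> float:
    """Hydrolysis events per protein copy per unit time, after burn-in.

    Default burn-in is 10x the slowest network timescale (capped at half the
    trajectory).  Mirrors the solution CTPase-rate measurement, whose typical
    readout is ~0.15/min basal rising to ~1/min with parS stimulation.
    """
    if burn_in is None:
        burn_in = min(10.0 * slowest_timescale(trajectory.network), 0.5 * trajectory.t_end)
    duration = trajectory.t_end - burn_in
    if duration <= 0:
        raise ValueError("trajectory duration must exceed burn_in")
    totals = trajectory.network.conserved_totals()
    n_parb = totals.get("ParB")
    if not n_parb:
        raise ValueError("network declares no ParB moiety to normalize by")
    events = trajectory.hydrolysis_events()
    n = int((events > burn_in).sum())
    return n / n_parb / duration
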