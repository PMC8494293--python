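"""Exact stochastic simulation: waiting times, stationary laws, model reduction."""

import numpy as np
import pytest
from scipy import stats

from parbclamp import RateSet
from parbclamp.kinetics import open_closed_partition, steady_state
from parbclamp.ssa import (
    Reaction,
    ReactionNetwork,
    build_coarse_network,
    build_detailed_network,
    hydrolysis_flux,
    simulate,
    slowest_timescale,
)

MIN_PER_S = 1.0 / 60.0


def _single_reaction_network(n_a: int, k: float) -> ReactionNetwork:
    return ReactionNetwork(
        species=("A", "B"),
        initial=np.array([n_a, 0]),
        reactions=[Reaction({"A": 1}, {"B": 1}, k, "convert")],
        moieties={"total": ["A", "B"]},
    )


class TestSimulate:
    def test_first_event_time_is_exponential(self):
        # A -> B at rate k with n_A copies: first waiting time ~ Exp(k * n_A)
        n_a, k, reps = 5, 0.4, 10_000
        net = _single_reaction_network(n_a, k)
        first = np.array([simulate(net, t_end=1e6, seed=s).times[0] for s in range(reps)])
        expected = 1.0 / (k * n_a)
        se = expected / np.sqrt(reps)
        assert abs(first.mean() - expected) < 3 * se

    def test_absorbing_state_terminates(self):
        net = _single_reaction_network(3, 1.0)
        traj = simulate(net, t_end=1e9, seed=0)
        assert traj.n_events == 3
        assert (traj.species_counts()[-1] == [0, 3]).all()

    def test_two_state_occupancy_is_binomial(self):
        # independent open<->closed molecules: stationary open count ~ Binomial
        rates = RateSet(k_oc=1.0, k_co=0.4, k_oc_dna=1.0, k_co_dna=1.0, k_h=0.6, kd_open=1.0)
        n = 40
        net = build_coarse_network(rates, parb_copies=n, dna_copies=0, volume=n)
        p_open, _ = open_closed_partition(rates, on_dna=False)
        traj = simulate(net, t_end=4000.0, seed=21)
        # sample at spacings >> relaxation time 1/(k_oc+k_co+k_h) = 0.5 s
        sample_times = np.arange(100.0, 4000.0, 10.0)
        counts = traj.species_counts()[:, net.index("parb_open_free")]
        idx = np.searchsorted(traj.times, sample_times, side="right")
        opens = counts[idx]
        support = np.arange(n + 1)
        pmf = stats.binom.pmf(support, n, p_open)
        # pool low-probability tails so expected counts stay >= 5
        expected = pmf * len(opens)
        keep = expected >= 5
        obs = np.array([(opens == i).sum() for i in support], dtype=float)
        obs_pooled = np.concatenate([[obs[~keep].sum()], obs[keep]])
        exp_pooled = np.concatenate([[expected[~keep].sum()], expected[keep]])
        chi2, p = stats.chisquare(obs_pooled, exp_pooled * obs_pooled.sum() / exp_pooled.sum())
        assert p > 0.01

    def test_same_seed_identical_trajectory(self, generic_rates):
        net = build_coarse_network(generic_rates, 50, 10, volume=50.0)
        t1 = simulate(net, t_end=20.0, seed=99)
        t2 = simulate(net, t_end=20.0, seed=99)
        assert t1.metadata == t2.metadata
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.reaction_index, t2.reaction_index)

    def test_invalid_horizon(self, generic_rates):
        net = build_coarse_network(generic_rates, 10, 5)
        with pytest.raises(ValueError):
            simulate(net, t_end=0.0, seed=1)


class TestCoarseNetwork:
    def test_structure_and_conservation(self, generic_rates):
        net = build_coarse_network(generic_rates, 500, 100, volume=500.0)
        assert len(net.species) == 5
        # no closed-form binding/unbinding reactions
        for rx in net.reactions:
            touching_closed = "parb_closed_free" in rx.reactants or "parb_closed_bound" in rx.reactants
            if touching_closed:
                assert "dna_free" not in rx.reactants and "dna_free" not in rx.products
        net.verify_moieties()
        assert net.conserved_totals() == {"ParB": 500, "DNA": 100}

    def test_counts_conserved_at_every_event(self, generic_rates):
        net = build_coarse_network(generic_rates, 200, 40, volume=200.0)
        traj = simulate(net, t_end=50.0, seed=3)
        counts = traj.species_counts()
        assert (counts[:, :4].sum(axis=1) == 200).all()
        assert (counts >= 0).all()
        assert (np.diff(traj.times) > 0).all()

    def test_detailed_balance_without_hydrolysis(self):
        rates = RateSet(k_oc=0.8, k_co=0.4, k_oc_dna=1.0, k_co_dna=1.0, k_h=0.0, kd_open=1.0)
        net = build_coarse_network(rates, parb_copies=300, dna_copies=0, volume=300.0)
        traj = simulate(net, t_end=600.0, seed=17)
        avg = traj.time_average(burn_in=60.0)
        closed_over_open = avg[net.index("parb_closed_free")] / avg[net.index("parb_open_free")]
        assert closed_over_open == pytest.approx(rates.k_oc / rates.k_co, rel=0.06)

    def test_time_averaged_bound_fraction_matches_analytic(self):
        rates = RateSet(
            k_oc=0.4, k_co=0.2, k_oc_dna=2.0, k_co_dna=0.2, k_h=0.5, kd_open=1.0, k_on=2.0
        )
        volume = 500.0
        net = build_coarse_network(rates, parb_copies=500, dna_copies=100, volume=volume)
        t_end = 110.0 * slowest_timescale(net)  # >= 100x slowest timescale
        seeds = [101, 102, 103]
        fracs = []
        for s in seeds:
            traj = simulate(net, t_end=t_end, seed=s)
            avg = traj.time_average(burn_in=0.15 * t_end)
            bound = avg[net.index("parb_open_bound")] + avg[net.index("parb_closed_bound")]
            fracs.append(bound / 500.0)
        ss = steady_state(rates, parb_total=500 / volume, dna_total=100 / volume)
        mean, se = np.mean(fracs), np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - ss.bound_fraction) < 3 * se + 1e-3


DETAILED_PARAMS = dict(
    ctp_on=10.0, ctp_off=0.1, ctp_conc=1000.0,
    k_untether=2.0, k_retether=0.5,
    k_close_free=0.01, k_on_parS=5.0, k_off_parS=1.0, k_close_parS=1.0,
    k_h=MIN_PER_S, kd_ctp=8.0,
)


class TestDetailedNetwork:
    def test_missing_rate_error_names_the_step(self):
        params = dict(DETAILED_PARAMS)
        del params["k_untether"]
        with pytest.raises(ValueError, match="step 2/3"):
            build_detailed_network(params)

    def test_moieties_conserved(self):
        net = build_detailed_network(DETAILED_PARAMS, parb_copies=100, parS_copies=5)
        net.verify_moieties()
        traj = simulate(net, t_end=100.0, seed=5)
        counts = traj.species_counts()
        parb_idx = [net.index(s) for s in net.species if s.startswith("parb")]
        assert (counts[:, parb_idx].sum(axis=1) == 100).all()

    def test_zero_hydrolysis_accumulates_closed_states(self):
        params = dict(DETAILED_PARAMS, k_h=0.0)
        net = build_detailed_network(params, parb_copies=300, parS_copies=10, volume=300.0)
        traj = simulate(net, t_end=2000.0, seed=8)
        assert hydrolysis_flux(traj, burn_in=10.0) == 0.0
        counts = traj.species_counts()
        closed = (
            counts[:, net.index("parb_closed_free")] + counts[:, net.index("parb_clamp_dna")]
        )
        # no recycling path: the closed pool only grows, up to (nearly) everything
        assert (np.diff(closed) >= 0).all()
        assert closed[-1] > 0.95 * 300

    def test_retention_probability_equals_ctp_competition(self):
        # fraction of on-DNA hydrolysis events that keep the clamp loaded
        params = dict(DETAILED_PARAMS, ctp_conc=8.0, kd_ctp=8.0, k_h=0.5)
        net = build_detailed_network(params, parb_copies=300, parS_copies=100, volume=300.0)
        traj = simulate(net, t_end=400.0, seed=12)
        names = np.array([rx.name for rx in net.reactions])
        fired = names[traj.reaction_index]
        n_keep = (fired == "5p_hydrolyze_exchange").sum()
        n_unload = (fired == "5p_hydrolyze_unload").sum()
        n = n_keep + n_unload
        assert n > 200
        p = 8.0 / (8.0 + 8.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(n_keep / n - p) < 3 * se

    def test_fast_exchange_limit_reduces_to_coarse_scheme(self):
        # apo and tethered states made transient; no retether; negligible
        # CTP re-capture: the scheme collapses onto the coarse cycle with
        # k_oc = closure off DNA, k_co = 0, catalyzed closure on parS, and a
        # weakly bound open state that releases much faster than it recloses
        k_h, k_close_free, k_close_parS = 0.3, 0.05, 0.4
        kd_open, k_on = 4.0, 10.0
        params = dict(
            ctp_on=1000.0, ctp_off=0.0, ctp_conc=1.0,
            k_untether=1000.0, k_retether=0.0,
            k_close_free=k_close_free,
            k_on_parS=k_on, k_off_parS=k_on * kd_open, k_close_parS=k_close_parS,
            k_h=k_h, kd_ctp=1e9,
        )
        volume, n_parb, n_parS = 100.0, 400, 200
        coarse = RateSet(
            k_oc=k_close_free, k_co=0.0, k_oc_dna=k_close_parS, k_co_dna=0.0,
            k_h=k_h, kd_open=kd_open, k_on=k_on,
        )
        ss = steady_state(coarse, parb_total=n_parb / volume, dna_total=n_parS / volume)
        net = build_detailed_network(params, parb_copies=n_parb, parS_copies=n_parS, volume=volume)
        fracs = []
        for s in (31, 32, 33, 34, 35):
            traj = simulate(net, t_end=150.0, seed=s)
            avg = traj.time_average(burn_in=30.0)
            clamped = avg[net.index("parb_clamp_dna")] + avg[net.index("parb_open_parS")]
            fracs.append(clamped / n_parb)
        mean, se = np.mean(fracs), np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(mean - ss.bound_fraction) < 3 * se + 5e-3


class TestHydrolysisFlux:
    def test_parS_stimulation_of_flux(self):
        # closure rate-limiting without parS, hydrolysis rate-limiting with
        # parS: the per-protein hydrolysis flux rises well above basal
        base = dict(DETAILED_PARAMS, k_close_free=0.002, k_h=1.0)
        with_parS = build_detailed_network(base, parb_copies=300, parS_copies=300, volume=300.0)
        without = build_detailed_network(base, parb_copies=300, parS_copies=0, volume=300.0)
        f_with = hydrolysis_flux(simulate(with_parS, t_end=300.0, seed=41), burn_in=30.0)
        f_without = hydrolysis_flux(simulate(without, t_end=300.0, seed=41), burn_in=30.0)
        assert f_with > 3 * f_without

    def test_flux_invariant_to_volume_at_fixed_concentrations(self, generic_rates):
        fluxes = {}
        for volume in (150.0, 450.0):
            fs = []
            for s in (61, 62, 63):
                net = build_coarse_network(
                    generic_rates,
                    parb_copies=int(volume),  # 1 uM ParB at every volume
                    dna_copies=int(0.2 * volume),
                    volume=volume,
                )
                fs.append(hydrolysis_flux(simulate(net, t_end=150.0, seed=s), burn_in=20.0))
            fluxes[volume] = (np.mean(fs), np.std(fs, ddof=1) / np.sqrt(len(fs)))
        (m1, se1), (m2, se2) = fluxes.values()
        assert abs(m1 - m2) < 3 * np.hypot(se1, se2) + 1e-3

    def test_zero_duration_rejected(self, generic_rates):
        net = build_coarse_network(generic_rates, 20, 5)
        traj = simulate(net, t_end=5.0, seed=2)
        with pytest.raises(ValueError):
            hydrolysis_flux(traj, burn_in=5.0)
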