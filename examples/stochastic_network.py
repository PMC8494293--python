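"""Exact stochastic simulation of the clamp cycle vs the analytic steady state.

Builds the coarse reaction network at 500 protein copies, samples one exact
trajectory, and compares the time-averaged bound fraction and the per-protein
hydrolysis flux with the analytic predictions.
"""

from parbclamp import RateSet, build_coarse_network, hydrolysis_flux, simulate, steady_state

rates = RateSet(k_oc=0.4, k_co=0.2, k_oc_dna=2.0, k_co_dna=0.2, k_h=0.5, kd_open=1.0, k_on=2.0)
volume = 500.0  # copies per uM
net = build_coarse_network(rates, parb_copies=500, dna_copies=100, volume=volume)

traj = simulate(net, t_end=600.0, seed=42)
avg = traj.time_average(burn_in=60.0)
bound = avg[net.index("parb_open_bound")] + avg[net.index("parb_closed_bound")]

ss = steady_state(rates, parb_total=500 / volume, dna_total=100 / volume)
closed_frac = (ss.parb_closed_free + ss.parb_closed_bound) / ss.parb_total

print(f"events sampled            : {traj.n_events}")
print(f"bound fraction (simulated): {bound / 500:.4f}")
print(f"bound fraction (analytic) : {ss.bound_fraction:.4f}")
flux = hydrolysis_flux(traj)
print(f"hydrolysis flux (simulated): {flux * 60:.3f} per protein per min")
print(f"hydrolysis flux (analytic) : {rates.k_h * closed_frac * 60:.3f} per protein per min")
print()
print("The exact sampler reproduces the nonequilibrium stationary state of the")
print("cycle; the flux is the CTPase rate a phosphate-release assay would see.")
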