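"""Ultra-affinity at parS: how hydrolysis-driven recycling lowers the apparent Kd.

Evaluates the steady-state theory of the coarse clamp cycle at the headline
rates (CTP hydrolysis ~1/min, parS-catalyzed closure ~1/s) and prints the
observed dissociation constant, its closed-form approximation, and the fold
reduction relative to the open-form equilibrium constant.
"""

from parbclamp import (
    RateSet,
    catalytic_capacity,
    fold_reduction,
    kd_observed,
    kd_observed_approx,
    steady_state,
)

MIN_PER_S = 1.0 / 60.0

# slow spontaneous transitions off DNA, catalyzed closure on parS
rates = RateSet(k_oc=0.001, k_co=0.001, k_oc_dna=1.0, k_co_dna=0.0, k_h=MIN_PER_S, kd_open=1.0)

print(f"kd_open              = {rates.kd_open:.4g} uM  (equilibrium, open form)")
print(f"kd_observed          = {kd_observed(rates):.4g} uM  (full steady-state expression)")
print(f"kd_observed_approx   = {kd_observed_approx(rates):.4g} uM  (recycling-regime approximation)")
print(f"fold_reduction       = {fold_reduction(rates.k_h, rates.k_oc_dna):.4g}")
print(f"catalytic_capacity   = {catalytic_capacity(rates.k_oc_dna, rates.k_h):.4g} closures per turnover")

# bound fraction with free parS held at kd_open: near-saturation despite an
# open-form affinity of only 50%
ss = steady_state(rates, parb_total=1.0, dna_total=rates.kd_open, dna_clamped=True)
print(f"bound fraction at [parS] = kd_open: {ss.bound_fraction:.4f} (vs 0.5 at equilibrium)")
print()
print("A fold reduction of ~61 means the protein pool binds parS ~61x more")
print("tightly than any equilibrium (hydrolysis-dead) version of the same cycle.")
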