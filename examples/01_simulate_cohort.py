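"""Simulate a two-genotype pharmacological fMRI cohort with ground truth.

Builds the default study design — 80-min runs at TR = 1 s, vehicle
injection at minute 20, drug injection at minute 50, 7 wild-type (WT)
and 7 receptor-knockout (KO) animals, 30 ROIs — and prints what was
injected: which edges the drug transiently modulates (WT only), which
edges both injections perturb (the artifacts), and the slow-5 power
gain carried by the oscillator network.
"""

import pharmfc as pf

config = pf.SimulationConfig(seed=1)
cohort, truth = pf.simulate_cohort(config)

print(f"cohort: {cohort.n_animals} animals x {cohort.n_roi} ROIs x "
      f"{cohort.n_t} samples (TR = {cohort.tr_s} s)")
print(f"injections at {cohort.vehicle_onset_s:.0f} s (vehicle) and "
      f"{cohort.drug_onset_s:.0f} s (drug)")

print("\ndrug-modulated edges (WT only; delta in correlation units,")
print("rising over ~6 min, then halving every 13 min):")
for (a, b), delta, onset, halflife in truth.modulated_edges:
    print(f"  {a:>4s} - {b:<4s}  delta = {delta:+.2f}")

print("\ninjection-common artifact edges (both genotypes, one 10-min")
print("interval after EACH injection — the exclusion rule's targets):")
for a, b, delta in truth.artifact_edges:
    print(f"  {a:>4s} - {b:<4s}  delta = {delta:+.2f}")

print("\nband power gains (genotype, condition, band) -> factor:")
for key, gain in truth.band_gain_table.items():
    print(f"  {key} -> x{gain}")
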