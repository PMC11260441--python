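"""Classical quantitative-genetics statistics on simulated data.

Mid-parent regression (slope estimates narrow-sense heritability under
additive inheritance), the dam + sire mixed model, and repeatability of
repeated measurements.
"""

import pandas as pd

from pedvar import (DesignConfig, VarianceComponents, generate_pedigree,
                    lmm_random_intercept, midparent_regression,
                    repeatability, simulate_phenotypes,
                    simulate_repeated_measurements)

ped, asg = generate_pedigree(DesignConfig(seed=1))
vc = VarianceComponents()  # h2 = 0.5
table = simulate_phenotypes(ped, asg, vc, seed=2)
value_of = table.set_index("id")["rbw"]
off = table[table["dam"] != ""]

# brood-mean offspring RBW on mid-parent RBW
brood = off.groupby("brood").agg(y=("rbw", "mean"), dam=("dam", "first"),
                                 sire=("sire", "first"))
mp = 0.5 * (value_of[brood["dam"]].to_numpy()
            + value_of[brood["sire"]].to_numpy())
reg = midparent_regression(brood["y"], mp)
print(f"mid-parent regression: slope = {reg.slope:.2f} "
      f"(t = {reg.tvalues['midparent']:.2f}, "
      f"p = {reg.pvalues['midparent']:.2g}, R2 = {reg.r_squared:.2f}, "
      f"n = {reg.n} broods)")
print(f"  -> the slope estimates h2 (truth {vc.h2:.2f}), but with only 20 "
      "broods its standard error")
print(f"     is large ({reg.se['midparent']:.2f}); single draws scatter "
      "widely around the truth.")

# the same regression on a 400-brood design shows the expectation
big = DesignConfig(n_dams=400, n_sires=400, n_broods=400,
                   brood_size_range=(4, 4), n_offspring=1600,
                   frac_paternal_halfsib=0.0, frac_maternal_halfsib=0.0,
                   frac_unconnected=1.0, frac_split_broods=0.0, seed=9)
bped, basg = generate_pedigree(big)
btable = simulate_phenotypes(bped, basg, vc, seed=10)
bvalue = btable.set_index("id")["rbw"]
boff = btable[btable["dam"] != ""]
bbrood = boff.groupby("brood").agg(y=("rbw", "mean"), dam=("dam", "first"),
                                   sire=("sire", "first"))
bmp = 0.5 * (bvalue[bbrood["dam"]].to_numpy()
             + bvalue[bbrood["sire"]].to_numpy())
breg = midparent_regression(bbrood["y"], bmp)
print(f"same regression, 400 broods: slope = {breg.slope:.2f} "
      f"(SE {breg.se['midparent']:.2f}) -> converges on h2 = {vc.h2:.2f}")

# dam and sire trait values as separate predictors, brood as random intercept
fixed = pd.DataFrame({"dam_rbw": value_of[off["dam"]].to_numpy(),
                      "sire_rbw": value_of[off["sire"]].to_numpy()})
lmm = lmm_random_intercept(off["rbw"].to_numpy(), fixed, off["brood"])
print(f"dam/sire LMM: est_dam = {lmm.params['dam_rbw']:.2f}, "
      f"est_sire = {lmm.params['sire_rbw']:.2f} "
      f"(each parent transmits half its breeding value: expectation h2/2)")

# repeatability of 4 noisy measurements per fish
reps = simulate_repeated_measurements(off, n_replicates=4,
                                      measurement_sd=0.012, seed=3)
R = repeatability(reps["value"], reps["id"], n_boot=200, seed=4)
print(f"repeatability: R = {R.R:.2f} "
      f"[{R.ci_low:.2f}, {R.ci_high:.2f}], p = {R.p:.2g} "
      f"({R.n_measurements} measurements of {R.n_individuals} fish)")
print("  -> R upper-bounds heritability: trait variance that is not even "
      "repeatable within an individual cannot be heritable")
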