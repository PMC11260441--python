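"""Fit Bayesian animal models with alternative random-effect structures.

The animal model places a pedigree-structured random effect on every
individual (covariance proportional to the additive relationship matrix
A) and partitions trait variance into additive genetic, maternal (dam),
brood, and residual components.  Comparing DIC across random-effect
structures asks which sources of resemblance the data support.
"""

from pedvar import (ChainSettings, DesignConfig, ModelSpec,
                    VarianceComponents, fit_animal_model, generate_pedigree,
                    simulate_phenotypes)

ped, asg = generate_pedigree(DesignConfig(seed=1))
vc = VarianceComponents()  # truth: h2=0.5, dam=0.1, brood=0.1
table = simulate_phenotypes(ped, asg, vc, seed=2)
off = table[table["dam"] != ""].reset_index(drop=True)

chain = ChainSettings(n_iterations=60_000, burn_in=5_000, thin=25, seed=3)
print(f"{'random terms':<20} {'DIC':>9} {'h2 mode (95% HPD)':>22} "
      f"{'explained':>10}")
for terms in [("animal",), ("animal", "dam"), ("animal", "dam", "brood")]:
    fit = fit_animal_model(off, ped, ModelSpec(random=terms), chain)
    lo, hi = fit.hpd["animal"]
    print(f"{'+'.join(terms):<20} {fit.dic:>9.2f} "
          f"{fit.modes['animal']:>8.2f} ({lo:.2f}-{hi:.2f}) "
          f"{fit.total_variance_explained:>10.2f}")
print()
print("Lower DIC = better support.  With only ~113 offspring in 20 broods,")
print("dam and brood terms are confounded with the pedigree: when included")
print("they absorb variance that the animal-only model calls additive, so")
print("the h2 estimate depends strongly on the chosen random structure.")
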