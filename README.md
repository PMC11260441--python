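# pedvar

Pedigree-based variance-component analysis of quantitative traits:
Bayesian animal models fitted by Gibbs sampling, DIC model comparison,
classical parent–offspring statistics, and a breeding-design simulator —
built for small laboratory pedigrees where genetic and environmental
sources of family resemblance are confounded and the analysis must say so.

The motivating problem comes from behavioral ecology: the width of a
carotenoid-based color bar in a mouthbrooding cichlid, measured as a
proportion of body length (relative bar width, RBW), runs in families.  Is
that additive genetics, maternal effects, or the shared environment of a
brood?  With ~113 offspring from 20 broods (13 dams, 12 sires, partial
half-sib connectivity) the three are only partly separable, and the answer
depends on the random-effect structure of the model.  `pedvar` implements
the full analysis: fit the alternatives, compare them by DIC, and run a
pedigree-conditioned simulation to measure what the design can and cannot
identify.

## The model

The animal model is a Gaussian mixed model in which every individual
carries an additive-genetic random effect with covariance structured by
the pedigree:

    y = Xβ + Z_a u_a + Z_d u_d + Z_b u_b + e
    u_a ~ N(0, A σ²_a)    u_d ~ N(0, I σ²_dam)
    u_b ~ N(0, I σ²_brood)    e ~ N(0, I σ²_e)

where `A` is the additive relationship matrix (2 × kinship; diagonal
1 + F), built by the tabular method.  Narrow-sense heritability is
h² = σ²_a / (σ²_a + σ²_dam + σ²_brood + σ²_e).  Variances carry
scaled-inverse-chi-square (V, ν) priors; a Gibbs sampler draws all
location effects jointly from the mixed-model equations and each variance
from its conjugate full conditional.  Results are reported as posterior
modes and 95% HPD intervals of the per-draw variance ratios, with DIC for
model comparison.  See `docs/methods.md` for the full account, including a
prior-scale effect worth knowing about before trusting any boundary
estimate.

## A worked example

```python
from pedvar import (DesignConfig, VarianceComponents, ChainSettings,
                    ModelSpec, generate_pedigree, simulate_phenotypes,
                    fit_animal_model)

ped, asg = generate_pedigree(DesignConfig(seed=1))   # 20 broods, 113 offspring
vc = VarianceComponents()                            # truth: h2=0.5, dam/brood 0.1
table = simulate_phenotypes(ped, asg, vc, seed=2)
off = table[table["dam"] != ""].reset_index(drop=True)

chain = ChainSettings(n_iterations=60_000, burn_in=5_000, thin=25, seed=3)
for terms in [("animal",), ("animal", "dam"), ("animal", "dam", "brood")]:
    fit = fit_animal_model(off, ped, ModelSpec(random=terms), chain)
    print(terms, round(fit.dic, 2), round(fit.modes["animal"], 2))
```

Running this (it is `examples/04_animal_model.py`) prints:

```
random terms               DIC      h2 mode (95% HPD)  explained
animal                 -526.93     0.64 (0.40-0.83)       0.64
animal+dam             -522.79     0.32 (0.16-0.59)       0.75
animal+dam+brood       -519.70     0.22 (0.08-0.43)       0.80
```

Read it like this: DIC (lower = better) prefers the simplest structure,
but the heritability estimate swings from 0.64 to 0.22 depending on
whether dam and brood intercepts are allowed to absorb family resemblance
— at this design size the components are genuinely confounded, which is
precisely the caution the identifiability simulation
(`examples/05_identifiability_simulation.py`) quantifies: on data
simulated with *only* additive signal, the full model still attributes
~40% of the variance to dam and brood terms, while DIC picks the correct
animal-only structure in most replicates.

The other examples cover pedigree algebra (`01`), the design simulator
(`02`), and mid-parent regression, the dam/sire mixed model and
repeatability (`03`).  Each runs in seconds to a couple of minutes and
prints what the numbers mean.

## Command line

A thin CLI wraps the library for pipeline use:

```sh
pedvar simulate-pedigree --seed 1 --pedigree-out ped.csv --assignments-out asg.csv
pedvar simulate-phenotypes --pedigree ped.csv --assignments asg.csv --seed 2 --out pheno.csv
pedvar fit-animal-model --pedigree ped.csv --phenotypes pheno.csv \
    --random animal,dam,brood --iters 500000 --burn-in 10000 --thin 50 --seed 3
pedvar midparent-sim --pedigree ped.csv --phenotypes pheno.csv --sd 0.03 --n 100 --seed 4
pedvar classic-stats midparent --phenotypes pheno.csv
pedvar report --config run.yaml          # the whole pipeline from one file
```

File formats are plain CSV (`id,sire,dam` pedigrees with empty/`NA` for
unknown parents; `id,rbw,sex,brood,dam,sire,condition` phenotypes, RBW as
a proportion in (0, 1) — percentage-scale values are rejected loudly).

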