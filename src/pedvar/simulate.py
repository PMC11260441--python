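"""Synthetic breeding-design and phenotype simulation.

Emulates a two-generation laboratory breeding study on a mouthbrooding
cichlid in which the measured trait is relative bar width (RBW): the width
of a yellow flank bar divided by standard body length, a proportion.  Wild
caught founders (assumed unrelated) are mated into full-sib broods such
that a target fraction of broods share a sire (paternal half-sibs), a
target fraction share a dam (maternal half-sibs), and the rest are
unconnected; no dam-sire pair mates twice.  The default design mirrors the
study this package reanalyses: 13 dams and 12 sires producing 20 broods of
4-15 offspring, of which 13 broods are paternally and 10 maternally
half-sib connected and 3 are unconnected, with offspring split among three
rearing conditions (intermittent feeding "IF" vs "control" within split
broods, whole broods under "standard").

Phenotypes are gene-dropped down the pedigree under an additive +
maternal + brood + residual variance-component model:

    founder breeding value   a ~ N(0, V_a)
    offspring breeding value a = (a_sire + a_dam) / 2 + m,  m ~ N(0, V_a/2)
    phenotype                y = mu + a + dam_effect + brood_effect + e

Founders receive ``y = mu + a + e*`` where e* has variance
V_e + V_dam + V_brood: wild-caught parents experienced maternal and brood
environments of their own, unobservable but real, so holding the
*phenotypic* variance constant across generations is the faithful choice —
it also makes the offspring-on-mid-parent regression slope exactly h2 in
expectation.  Parental phenotypes therefore exist for mid-parent
regressions.  The
Mendelian-sampling variance is V_a/2 because no inbreeding can arise in a
two-generation design with unrelated founders; with one unknown parent the
unknown side contributes an independent founder draw, raising the sampling
variance to 3/4 V_a (and V_a for both unknown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, validate_pedigree

__all__ = [
    "DesignConfig",
    "VarianceComponents",
    "DesignError",
    "generate_pedigree",
    "simulate_phenotypes",
    "simulate_repeated_measurements",
]


class DesignError(ValueError):
    """Raised when a breeding design is internally infeasible."""


@dataclass(frozen=True)
class DesignConfig:
    """Breeding-design parameters; defaults reproduce the study design."""

    n_dams: int = 13
    n_sires: int = 12
    n_broods: int = 20
    brood_size_range: tuple = (4, 15)
    #: total offspring target; brood sizes are drawn within the range to sum
    #: to this (None = uniform sizes in the range).  The default matches the
    #: emulated study: 113 progeny in 20 broods.
    n_offspring: int | None = 113
    frac_paternal_halfsib: float = 13 / 20
    frac_maternal_halfsib: float = 10 / 20
    frac_unconnected: float = 3 / 20
    #: fraction of broods raised under the split IF/control regime; the
    #: remainder are whole-brood "standard"
    frac_split_broods: float = 12 / 20
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.brood_size_range
        if self.n_broods < 1:
            raise DesignError("n_broods must be >= 1")
        if not (1 <= lo <= hi):
            raise DesignError(f"invalid brood_size_range {self.brood_size_range}")
        for name in ("frac_paternal_halfsib", "frac_maternal_halfsib",
                     "frac_unconnected", "frac_split_broods"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DesignError(f"{name} must be in [0, 1], got {v}")
        if self.n_offspring is not None and not (
                self.n_broods * lo <= self.n_offspring <= self.n_broods * hi):
            raise DesignError(
                f"n_offspring={self.n_offspring} unreachable with "
                f"{self.n_broods} broods of {lo}-{hi}")


@dataclass(frozen=True)
class VarianceComponents:
    """Trait mean and variance components, in RBW-proportion units.

    Defaults put the phenotypic variance at V_p = 0.0009 (sd 0.03) around a
    mean of 0.33, spanning roughly the range seen in wild fish (bar widths
    of about 27-40% of standard length), with half the variance additive
    genetic and the rest split among dam, brood and residual sources.
    """

    mu: float = 0.33
    V_a: float = 0.00045
    V_dam: float = 0.00009
    V_brood: float = 0.00009
    V_e: float = 0.00027

    def __post_init__(self):
        for name in ("V_a", "V_dam", "V_brood", "V_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative variance component {name}")

    @property
    def V_p(self) -> float:
        return self.V_a + self.V_dam + self.V_brood + self.V_e

    @property
    def h2(self) -> float:
        return self.V_a / self.V_p if self.V_p > 0 else float("nan")

    def replace(self, **kw) -> "VarianceComponents":
        return replace(self, **kw)


def _partition(total: int, n_parts: int, min_size: int, rng) -> list:
    """Random composition of ``total`` into ``n_parts`` parts each >= min_size."""
    if n_parts == 0:
        if total:
            raise DesignError("cannot partition a nonzero total into 0 parts")
        return []
    extra = total - n_parts * min_size
    if extra < 0:
        raise DesignError(f"cannot split {total} broods into {n_parts} "
                          f"shared-parent groups of at least {min_size}")
    sizes = np.full(n_parts, min_size, dtype=int)
    for slot in rng.integers(0, n_parts, size=extra):
        sizes[slot] += 1
    return sizes.tolist()


def generate_pedigree(design: DesignConfig):
    """Generate a two-generation pedigree matching the design.

    Returns
    -------
    pedigree : Pedigree
        Founders (dams ``D..``, sires ``S..``) plus offspring ``O..``.
    assignments : pandas.DataFrame
        One row per offspring: ``id, brood, dam, sire, sex, condition``.
        Conditions are "IF"/"control" (half of each split brood) or
        "standard" (whole brood).

    Raises
    ------
    DesignError
        If the requested connectivity is arithmetically infeasible for the
        given numbers of dams, sires and broods.
    """
    rng = np.random.default_rng(design.seed)
    B = design.n_broods
    P = round(design.frac_paternal_halfsib * B)
    M = round(design.frac_maternal_halfsib * B)
    U = round(design.frac_unconnected * B)
    if P + M + U < B:
        raise DesignError(
            f"connectivity targets leave {B - P - M - U} broods unclassified: "
            "paternal + maternal + unconnected fractions must cover all broods")
    O = P + M + U - B  # broods that are both paternally and maternally connected
    if O > min(P, M):
        raise DesignError("overlap between paternal and maternal half-sib sets "
                          "exceeds one of the sets; lower frac_unconnected")
    pat_only, mat_only = P - O, M - O

    # each brood needing a unique dam consumes one dam; shared dams cover the
    # M maternally connected broods in groups of >= 2
    d_shared = design.n_dams - U - pat_only
    s_shared = design.n_sires - U - mat_only
    if M == 0 and d_shared != 0:
        raise DesignError(f"design needs exactly {U + pat_only} dams when no "
                          f"maternal half-sibs are requested, got {design.n_dams}")
    if M > 0 and not (1 <= d_shared <= M // 2):
        raise DesignError(
            f"{design.n_dams} dams cannot realize {M} maternally connected "
            f"broods plus {U + pat_only} unique-dam broods "
            f"(need between {U + pat_only + 1} and {U + pat_only + M // 2} dams)")
    if P == 0 and s_shared != 0:
        raise DesignError(f"design needs exactly {U + mat_only} sires when no "
                          f"paternal half-sibs are requested, got {design.n_sires}")
    if P > 0 and not (1 <= s_shared <= P // 2):
        raise DesignError(
            f"{design.n_sires} sires cannot realize {P} paternally connected "
            f"broods plus {U + mat_only} unique-sire broods")

    dams = [f"D{k + 1:02d}" for k in range(design.n_dams)]
    sires = [f"S{k + 1:02d}" for k in range(design.n_sires)]

    for _attempt in range(200):
        # brood slots: 0..U-1 unconnected, then pat-only, then both, then mat-only
        kinds = (["unconnected"] * U + ["pat"] * pat_only
                 + ["both"] * O + ["mat"] * mat_only)
        brood_dam = [None] * B
        brood_sire = [None] * B

        unique_dam_iter = iter(rng.permutation(design.n_dams - d_shared))
        shared_dam_pool = list(range(design.n_dams - d_shared, design.n_dams))
        unique_sire_iter = iter(rng.permutation(design.n_sires - s_shared))
        shared_sire_pool = list(range(design.n_sires - s_shared, design.n_sires))

        mat_slots = [b for b in range(B) if kinds[b] in ("both", "mat")]
        pat_slots = [b for b in range(B) if kinds[b] in ("pat", "both")]
        rng.shuffle(mat_slots)
        rng.shuffle(pat_slots)
        dam_groups = _partition(M, d_shared, 2, rng)
        sire_groups = _partition(P, s_shared, 2, rng)

        pos = 0
        for dk, g in zip(shared_dam_pool, dam_groups):
            for b in mat_slots[pos:pos + g]:
                brood_dam[b] = dams[dk]
            pos += g
        pos = 0
        for sk, g in zip(shared_sire_pool, sire_groups):
            for b in pat_slots[pos:pos + g]:
                brood_sire[b] = sires[sk]
            pos += g
        for b in range(B):
            if brood_dam[b] is None:
                brood_dam[b] = dams[next(unique_dam_iter)]
            if brood_sire[b] is None:
                brood_sire[b] = sires[next(unique_sire_iter)]
        pairs = list(zip(brood_dam, brood_sire))
        if len(set(pairs)) == B:  # no dam-sire pair repeated
            break
    else:
        raise DesignError("could not realize the design without repeating a "
                          "dam-sire pair; relax the connectivity targets")

    shuffle = rng.permutation(B)
    brood_dam = [brood_dam[b] for b in shuffle]
    brood_sire = [brood_sire[b] for b in shuffle]
    brood_ids = [f"B{k + 1:02d}" for k in range(B)]

    lo, hi = design.brood_size_range
    if design.n_offspring is None:
        sizes = rng.integers(lo, hi + 1, size=B)
    else:
        sizes = np.full(B, lo)
        for _ in range(design.n_offspring - B * lo):
            open_slots = np.flatnonzero(sizes < hi)
            sizes[open_slots[rng.integers(open_slots.size)]] += 1
    n_split = round(design.frac_split_broods * B)
    split = np.zeros(B, dtype=bool)
    split[rng.permutation(B)[:n_split]] = True

    rows = []
    counter = 1
    for b in range(B):
        size = int(sizes[b])
        if split[b]:
            n_if = size // 2 + (rng.random() < 0.5 if size % 2 else 0)
            conds = ["IF"] * int(n_if) + ["control"] * (size - int(n_if))
            conds = list(rng.permutation(conds))
        else:
            conds = ["standard"] * size
        for k in range(size):
            rows.append({
                "id": f"O{counter:03d}",
                "brood": brood_ids[b],
                "dam": brood_dam[b],
                "sire": brood_sire[b],
                "sex": "F" if rng.random() < 0.5 else "M",
                "condition": conds[k],
            })
            counter += 1
    assignments = pd.DataFrame(rows)

    records = [(d, UNKNOWN, UNKNOWN) for d in dams]
    records += [(s, UNKNOWN, UNKNOWN) for s in sires]
    records += [(r["id"], r["sire"], r["dam"]) for r in rows]
    return validate_pedigree(records), assignments


def simulate_phenotypes(
    pedigree: Pedigree,
    assignments: pd.DataFrame,
    vc: VarianceComponents,
    seed: int,
    return_effects: bool = False,
):
    """Gene-drop breeding values and assemble phenotypes for all individuals.

    Returns a phenotype table with columns ``id, rbw, sex, brood, dam,
    sire, condition`` covering founders (brood/dam/sire empty, condition
    ``"wild"``) and offspring.  Deterministic under ``seed``.  With
    ``return_effects`` also returns a dict of the latent draws (breeding
    values aligned with ``pedigree.ids``, dam and brood effect maps).
    """
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    idx = {ind: k for k, ind in enumerate(pedigree.ids)}

    a = np.zeros(n)
    for k, ind in enumerate(pedigree.ids):
        s, d = pedigree.sire[k], pedigree.dam[k]
        known = [p for p in (s, d) if p != UNKNOWN]
        mean = 0.5 * sum(a[idx[p]] for p in known)
        mendelian = vc.V_a * (1.0 - 0.25 * len(known))
        a[k] = mean + rng.normal(0.0, math.sqrt(mendelian)) if mendelian > 0 else mean

    info = assignments.set_index("id") if len(assignments) else pd.DataFrame()
    dam_levels = sorted(info["dam"].unique()) if len(info) else []
    brood_levels = sorted(info["brood"].unique()) if len(info) else []
    dam_eff = dict(zip(dam_levels,
                       rng.normal(0.0, math.sqrt(vc.V_dam), len(dam_levels))))
    brood_eff = dict(zip(brood_levels,
                         rng.normal(0.0, math.sqrt(vc.V_brood), len(brood_levels))))
    e = rng.normal(0.0, math.sqrt(vc.V_e), n)
    # founders carry their own (unobserved) maternal/brood environments, so
    # their phenotypic variance matches the offspring generation
    e_founder = rng.normal(0.0, math.sqrt(vc.V_dam + vc.V_brood), n)

    rows = []
    for k, ind in enumerate(pedigree.ids):
        if ind in info.index:
            r = info.loc[ind]
            y = vc.mu + a[k] + dam_eff[r["dam"]] + brood_eff[r["brood"]] + e[k]
            rows.append({"id": ind, "rbw": y, "sex": r["sex"], "brood": r["brood"],
                         "dam": r["dam"], "sire": r["sire"],
                         "condition": r["condition"]})
        else:
            y = vc.mu + a[k] + e[k] + e_founder[k]
            sex = "F" if ind.startswith("D") else ("M" if ind.startswith("S") else "U")
            rows.append({"id": ind, "rbw": y, "sex": sex, "brood": "",
                         "dam": "", "sire": "", "condition": "wild"})
    table = pd.DataFrame(rows)
    if return_effects:
        return table, {"breeding_values": a, "dam_effects": dam_eff,
                       "brood_effects": brood_eff}
    return table


def simulate_repeated_measurements(
    phenotypes: pd.DataFrame,
    n_replicates: int,
    measurement_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Repeated trait measurements: true value plus iid measurement error.

    Returns a long table ``id, replicate, value``; the expected
    repeatability is V_p / (V_p + measurement_sd**2) by construction.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    ids = np.repeat(phenotypes["id"].to_numpy(), n_replicates)
    truth = np.repeat(phenotypes["rbw"].to_numpy(), n_replicates)
    noise = rng.normal(0.0, measurement_sd, truth.size)
    rep = np.tile(np.arange(1, n_replicates + 1), len(phenotypes))
    return pd.DataFrame({"id": ids, "replicate": rep, "value": truth + noise})
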