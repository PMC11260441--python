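"""Pedigree-conditioned identifiability simulation.

Can a dataset of this size and pedigree shape tell additive genetic
variance apart from maternal and brood effects?  The check: hold the
pedigree and the parental phenotypes fixed, simulate each offspring's
trait as its mid-parent value plus Gaussian noise (so additive
inheritance is the *only* structured source of variance), then fit the
competing random-effect structures to every simulated dataset and compare
DIC and the variance partitions.  If models containing dam and brood
terms still soak up variance, those components are not identifiable from
data of this shape — a caution for interpreting the empirical fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import ChainSettings, ModelSpec, PosteriorSummary, fit_animal_model
from .pedigree import Pedigree

__all__ = [
    "IdentifiabilityConfig",
    "ComparisonTable",
    "simulate_midparent_noise",
    "midparent_variance_explained",
    "run_model_comparison",
    "exclude_unconnected_broods",
    "find_unconnected_broods",
    "DEFAULT_SPECS",
]

#: the three random-effect structures compared throughout
DEFAULT_SPECS = (
    ModelSpec(random=("animal",)),
    ModelSpec(random=("animal", "dam")),
    ModelSpec(random=("animal", "dam", "brood")),
)


@dataclass(frozen=True)
class IdentifiabilityConfig:
    n_datasets: int = 100
    noise_sd: float = 0.03
    specs: tuple = DEFAULT_SPECS
    chain: ChainSettings = field(default_factory=ChainSettings)
    seed: int = 0
    exclude_broods: tuple = ()

    def __post_init__(self):
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ComparisonTable:
    """Median outcomes per model spec over the simulated datasets."""

    table: pd.DataFrame          # index: spec label
    per_fit: pd.DataFrame        # one row per (dataset, spec) fit
    n_datasets: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_datasets": self.n_datasets,
            "seed": self.seed,
            "specs": {
                label: {k: (None if pd.isna(v) else float(v))
                        for k, v in row.items()}
                for label, row in self.table.iterrows()
            },
        }


def _offspring_mask(phenotypes: pd.DataFrame) -> pd.Series:
    dam = phenotypes.get("dam", pd.Series("", index=phenotypes.index))
    sire = phenotypes.get("sire", pd.Series("", index=phenotypes.index))
    return (dam.fillna("").astype(str).str.len() > 0) & \
        (sire.fillna("").astype(str).str.len() > 0)


def _midparent_values(phenotypes: pd.DataFrame) -> pd.Series:
    """Mid-parent trait value for each offspring row; parents are looked up
    among the table's own rows."""
    value_of = phenotypes.set_index("id")["rbw"]
    off = phenotypes[_offspring_mask(phenotypes)]
    mp = []
    for _, row in off.iterrows():
        missing = [p for p in (row["dam"], row["sire"]) if p not in value_of.index
                   or pd.isna(value_of[p])]
        if missing:
            raise ValueError(
                f"offspring {row['id']!r} lacks a phenotype for parent(s) "
                f"{missing}")
        mp.append(0.5 * (value_of[row["dam"]] + value_of[row["sire"]]))
    return pd.Series(mp, index=off.index)


def simulate_midparent_noise(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    n_datasets: int,
    noise_sd: float,
    seed: int,
) -> list:
    """Simulate offspring trait values as mid-parent value + N(0, sd^2).

    Parental phenotype rows are held fixed (they anchor the simulation to
    the observed parental trait distribution); only offspring values are
    redrawn, with an independent derived seed per dataset.  Returns one
    phenotype table per dataset with identical ids/broods/parents.
    """
    for ind in phenotypes["id"]:
        if ind not in pedigree:
            raise ValueError(f"phenotyped individual {ind!r} not in pedigree")
    mp = _midparent_values(phenotypes)
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        tbl = phenotypes.copy()
        tbl.loc[mp.index, "rbw"] = mp.to_numpy() + rng.normal(0.0, noise_sd,
                                                              mp.size)
        out.append(tbl)
    return out


def midparent_variance_explained(phenotypes: pd.DataFrame) -> float:
    """R^2 of the individual-level OLS of offspring trait on mid-parent value
    (uncorrected for non-independence among sibs)."""
    mp = _midparent_values(phenotypes)
    y = phenotypes.loc[mp.index, "rbw"].to_numpy(dtype=float)
    x = mp.to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("mid-parent values are constant; R^2 undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.rsquared)


def run_model_comparison(
    datasets: Sequence,
    pedigree: Pedigree,
    specs: Sequence = DEFAULT_SPECS,
    chain: ChainSettings = ChainSettings(),
    seed: int = 0,
) -> ComparisonTable:
    """Fit every spec to every dataset; summarize medians and DIC wins.

    Offspring rows (both parents known) are the model response, matching
    the empirical analysis where only lab-bred progeny enter the model.
    Each (dataset, spec) fit gets an independent seed derived from
    ``seed``.  Fit failures are recorded (``ok = False``) and medians are
    taken over successes; a spec whose fits all fail raises.
    """
    datasets = list(datasets)
    specs = list(specs)
    if not datasets:
        raise ValueError("need at least one dataset")
    labels = [s.label for s in specs]
    streams = np.random.SeedSequence(seed).spawn(len(datasets) * len(specs))
    rows = []
    summaries: dict = {lab: [] for lab in labels}
    for i, data in enumerate(datasets):
        off = data[_offspring_mask(data)].reset_index(drop=True)
        for j, spec in enumerate(specs):
            fit_seed = int(streams[i * len(specs) + j].generate_state(1)[0]
                           % (2**31 - 1))
            cs = ChainSettings(n_iterations=chain.n_iterations,
                               burn_in=chain.burn_in, thin=chain.thin,
                               seed=fit_seed)
            row = {"dataset": i, "spec": spec.label, "seed": fit_seed}
            try:
                s = fit_animal_model(off, pedigree, spec, cs)
            except Exception as exc:  # recorded, medians over successes
                row.update(ok=False, error=str(exc))
                rows.append(row)
                continue
            summaries[spec.label].append((i, s))
            row.update(
                ok=True, dic=s.dic,
                total_variance_explained=s.total_variance_explained,
                **{f"ratio_mode_{k}": v for k, v in s.modes.items()},
            )
            rows.append(row)
    per_fit = pd.DataFrame(rows)
    for lab in labels:
        if not summaries[lab]:
            raise RuntimeError(f"all fits failed for spec {lab!r}")

    ok = per_fit[per_fit["ok"]]
    # DIC selection frequency over datasets where every spec succeeded
    wins = {lab: 0 for lab in labels}
    complete = 0
    for i in range(len(datasets)):
        sub = ok[ok["dataset"] == i]
        if len(sub) == len(specs):
            complete += 1
            wins[sub.loc[sub["dic"].idxmin(), "spec"]] += 1

    records = []
    for lab in labels:
        sub = ok[ok["spec"] == lab]
        rec = {
            "median_dic": sub["dic"].median(),
            "median_total_variance_explained":
                sub["total_variance_explained"].median(),
            "dic_win_fraction": wins[lab] / complete if complete else np.nan,
            "n_fits": len(sub),
        }
        for col in sub.columns:
            if col.startswith("ratio_mode_"):
                vals = sub[col].dropna()
                rec[f"median_{col}"] = vals.median() if len(vals) else np.nan
        records.append(rec)
    table = pd.DataFrame(records, index=pd.Index(labels, name="spec"))
    return ComparisonTable(table=table, per_fit=per_fit,
                           n_datasets=len(datasets), seed=seed)


def find_unconnected_broods(phenotypes: pd.DataFrame) -> list:
    """Broods sharing neither dam nor sire with any other brood."""
    off = phenotypes[_offspring_mask(phenotypes)]
    broods = off.groupby("brood").agg(dam=("dam", "first"),
                                      sire=("sire", "first"))
    dam_counts = broods["dam"].value_counts()
    sire_counts = broods["sire"].value_counts()
    return [
        b for b, row in broods.iterrows()
        if dam_counts[row["dam"]] == 1 and sire_counts[row["sire"]] == 1
    ]


def exclude_unconnected_broods(
    phenotypes: pd.DataFrame,
    brood_ids: Sequence,
    pedigree: Pedigree | None = None,
):
    """Drop all phenotype rows belonging to the listed broods.

    If a pedigree is supplied, it is pruned to the remaining phenotyped
    individuals and their ancestors (founders referenced only by excluded
    broods disappear), and ``(table, pruned_pedigree)`` is returned.
    """
    brood_ids = list(brood_ids)
    present = set(phenotypes.get("brood", pd.Series(dtype=str)).astype(str))
    unknown = [b for b in brood_ids if str(b) not in present]
    if unknown:
        raise ValueError(f"unknown brood id(s): {unknown}")
    if not brood_ids:
        return (phenotypes, pedigree) if pedigree is not None else phenotypes
    keep = phenotypes[~phenotypes["brood"].astype(str).isin(
        [str(b) for b in brood_ids])].reset_index(drop=True)
    if not len(keep) or not _offspring_mask(keep).any():
        raise ValueError("no phenotyped offspring remain after exclusion")
    if pedigree is not None:
        offspring = keep[_offspring_mask(keep)]["id"]
        pruned = pedigree.subset(list(offspring))
        keep = keep[keep["id"].isin(set(pruned.ids))].reset_index(drop=True)
        return keep, pruned
    return keep
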