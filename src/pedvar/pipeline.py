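"""Pipeline orchestration: one config, one seed, one results directory.

Stages mirror the analysis order of a heritability study on a laboratory
pedigree: classical statistics (mid-parent regression, dam/sire mixed
model), animal-model fits under the alternative random-effect structures
on the full and the connectivity-reduced dataset, optional prior
sensitivity scan, and the identifiability simulation.  Every artifact
embeds the master seed and a hash of the configuration so a rerun with
the same config file is reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classic, identifiability as ident, io as pio
from .model import ChainSettings, ModelSpec, fit_animal_model, \
    prior_sensitivity_scan
from .pedigree import Pedigree
from .simulate import DesignConfig, VarianceComponents, generate_pedigree, \
    simulate_phenotypes

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("pedvar")


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    out_dir: str = "pedvar_results"
    seed: int = 1
    # either read files...
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    # ...or simulate the study design
    simulate: bool = True
    design: dict = field(default_factory=dict)
    variance_components: dict = field(default_factory=dict)
    # model settings
    random_structures: tuple = (("animal",), ("animal", "dam"),
                                ("animal", "dam", "brood"))
    prior_V: float = 1.0
    prior_nu: float = 0.002
    chain: dict = field(default_factory=dict)
    reduced_dataset: bool = True
    # optional stages
    prior_sensitivity_nu: tuple = ()
    identifiability: dict = field(default_factory=dict)  # {} disables

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land never changes them
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def chain_settings(self, seed: int) -> ChainSettings:
        kw = dict(self.chain)
        kw["seed"] = seed
        return ChainSettings(**kw)

    def model_specs(self):
        priors = {"residual": (self.prior_V, self.prior_nu)}
        return [
            ModelSpec(random=tuple(r), priors=priors,
                      default_prior=(self.prior_V, self.prior_nu))
            for r in self.random_structures
        ]


def _derived_seed(master: int, *key) -> int:
    # stable across processes (never Python's randomized hash())
    digest = hashlib.sha256("/".join(map(str, key)).encode()).digest()
    ss = np.random.SeedSequence([master, int.from_bytes(digest[:4], "little")])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"seed": config.seed, "config_hash": config.config_hash(),
               **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=float) + "\n")


@_stage("data")
def _load_data(config: RunConfig):
    if config.simulate:
        design = DesignConfig(**{**config.design,
                                 "seed": _derived_seed(config.seed, "design")})
        vc = VarianceComponents(**config.variance_components)
        pedigree, assignments = generate_pedigree(design)
        phenotypes = simulate_phenotypes(pedigree, assignments, vc,
                                         _derived_seed(config.seed, "pheno"))
        return pedigree, phenotypes
    if not config.pedigree_path or not config.phenotype_path:
        raise PipelineError("[data] need pedigree_path and phenotype_path "
                            "when simulate is false")
    return (pio.read_pedigree(config.pedigree_path),
            pio.read_phenotypes(config.phenotype_path))


@_stage("classic_stats")
def _classic_stage(phenotypes: pd.DataFrame) -> dict:
    off = phenotypes[ident._offspring_mask(phenotypes)]
    value_of = phenotypes.set_index("id")["rbw"]
    brood = off.groupby("brood").agg(mean_rbw=("rbw", "mean"),
                                     dam=("dam", "first"),
                                     sire=("sire", "first"))
    midparent = 0.5 * (value_of[brood["dam"]].to_numpy()
                       + value_of[brood["sire"]].to_numpy())
    reg = classic.midparent_regression(brood["mean_rbw"], midparent)
    fixed = pd.DataFrame({
        "dam_rbw": value_of[off["dam"]].to_numpy(),
        "sire_rbw": value_of[off["sire"]].to_numpy(),
    })
    lmm = classic.lmm_random_intercept(off["rbw"], fixed, off["brood"])
    r2 = ident.midparent_variance_explained(phenotypes)
    return {
        "midparent_regression": {
            "slope": reg.params["midparent"], "intercept": reg.params["intercept"],
            "t": reg.tvalues["midparent"], "p": reg.pvalues["midparent"],
            "r_squared": reg.r_squared, "n_broods": reg.n,
        },
        "individual_midparent_r2": r2,
        "dam_sire_lmm": {
            "dam": lmm.params["dam_rbw"], "sire": lmm.params["sire_rbw"],
            "var_brood": lmm.var_group, "var_resid": lmm.var_resid,
            "n": lmm.n,
        },
    }


@_stage("animal_models")
def _animal_stage(config, phenotypes, pedigree, out: Path) -> dict:
    specs = config.model_specs()
    off = phenotypes[ident._offspring_mask(phenotypes)].reset_index(drop=True)
    datasets = {"full": (off, pedigree)}
    if config.reduced_dataset:
        drop = ident.find_unconnected_broods(phenotypes)
        if drop:
            tbl, ped = ident.exclude_unconnected_broods(phenotypes, drop,
                                                        pedigree)
            red = tbl[ident._offspring_mask(tbl)].reset_index(drop=True)
            datasets["reduced"] = (red, ped)
    results: dict = {}
    for dname, (tbl, ped) in datasets.items():
        results[dname] = {}
        for spec in specs:
            cs = config.chain_settings(
                _derived_seed(config.seed, "animal", dname, spec.label))
            summary = fit_animal_model(tbl, ped, spec, cs)
            results[dname][spec.label] = summary.to_dict()
            summary.chains_frame().to_csv(
                out / f"chain_{dname}_{spec.label.replace('+', '_')}.csv",
                index=False)
            logger.info("animal model [%s/%s]: DIC=%.3f min ESS=%.0f",
                        dname, spec.label, summary.dic,
                        min(summary.ess.values()))
    return results


@_stage("prior_sensitivity")
def _sensitivity_stage(config, phenotypes, pedigree) -> dict:
    off = phenotypes[ident._offspring_mask(phenotypes)].reset_index(drop=True)
    full = config.model_specs()[-1]
    cs = config.chain_settings(_derived_seed(config.seed, "sensitivity"))
    scans = prior_sensitivity_scan(off, pedigree, full,
                                   sorted(config.prior_sensitivity_nu), cs)
    return {str(nu): s.to_dict() for nu, s in scans.items()}


@_stage("identifiability")
def _identifiability_stage(config, phenotypes, pedigree, out: Path) -> dict:
    kw = dict(config.identifiability)
    n_datasets = int(kw.pop("n_datasets", 20))
    noise_sd = float(kw.pop("noise_sd", 0.03))
    chain_kw = kw.pop("chain", None)
    chain = (ChainSettings(**{**chain_kw, "seed": 0}) if chain_kw
             else config.chain_settings(0))
    datasets = ident.simulate_midparent_noise(
        pedigree, phenotypes, n_datasets, noise_sd,
        _derived_seed(config.seed, "ident-data"))
    r2s = [ident.midparent_variance_explained(d) for d in datasets]
    comparison = ident.run_model_comparison(
        datasets, pedigree, config.model_specs(), chain,
        seed=_derived_seed(config.seed, "ident-fits"))
    comparison.table.to_csv(out / "identifiability_medians.csv")
    comparison.per_fit.to_csv(out / "identifiability_fits.csv", index=False)
    return {"median_midparent_r2": float(np.median(r2s)),
            "noise_sd": noise_sd, **comparison.to_dict()}


def _summary_table(animal_results: dict) -> str:
    lines = ["Variance-ratio posterior modes (95% HPD) per random-effect "
             "structure", ""]
    for dname, per_spec in animal_results.items():
        lines.append(f"== {dname} dataset ==")
        header = f"{'':24s}" + "".join(f"{lab:>22s}" for lab in per_spec)
        lines.append(header)
        rows = ["DIC", "Total variance explained", "animal", "dam", "brood"]
        for row in rows:
            cells = []
            for lab, res in per_spec.items():
                if row == "DIC":
                    cells.append(f"{res['dic']:>22.2f}")
                elif row == "Total variance explained":
                    cells.append(f"{res['total_variance_explained']:>22.3f}")
                else:
                    comp = res["components"].get(row)
                    if comp is None:
                        cells.append(f"{'-':>22s}")
                    else:
                        lo, hi = comp["ratio_hpd95"]
                        cells.append(
                            f"{comp['ratio_mode']:.3f} ({lo:.2f}-{hi:.2f})"
                            .rjust(22))
            lines.append(f"{row:24s}" + "".join(cells))
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run all configured stages; returns the report bundle as a dict and
    writes JSON/CSV artifacts plus a human-readable summary to
    ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d config=%s", config.seed,
                config.config_hash())

    pedigree, phenotypes = _load_data(config)
    pio.write_pedigree(pedigree, out / "pedigree.csv")
    pio.write_phenotypes(phenotypes, out / "phenotypes.csv")

    bundle: dict = {"n_individuals": len(pedigree),
                    "n_phenotyped": int(len(phenotypes))}
    bundle["classic_stats"] = _classic_stage(phenotypes)
    _write_json(out / "classic_stats.json", bundle["classic_stats"], config)

    bundle["animal_models"] = _animal_stage(config, phenotypes, pedigree, out)
    _write_json(out / "animal_models.json", bundle["animal_models"], config)

    if config.prior_sensitivity_nu:
        bundle["prior_sensitivity"] = _sensitivity_stage(config, phenotypes,
                                                         pedigree)
        _write_json(out / "prior_sensitivity.json",
                    bundle["prior_sensitivity"], config)

    if config.identifiability:
        bundle["identifiability"] = _identifiability_stage(
            config, phenotypes, pedigree, out)
        _write_json(out / "identifiability.json", bundle["identifiability"],
                    config)

    (out / "summary.txt").write_text(_summary_table(bundle["animal_models"]))
    _write_json(out / "report.json", bundle, config)
    logger.info("pipeline done: %s", out)
    return bundle
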