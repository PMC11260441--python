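"""Breeding-design generator and gene-dropping phenotype simulation."""

import numpy as np
import pandas as pd
import pytest

from pedvar.pedigree import additive_relationship
from pedvar.simulate import (DesignConfig, DesignError, VarianceComponents,
                             generate_pedigree, simulate_phenotypes,
                             simulate_repeated_measurements)

from conftest import offspring_rows


def connectivity(assignments: pd.DataFrame):
    broods = assignments.groupby("brood").agg(dam=("dam", "first"),
                                              sire=("sire", "first"))
    dc = broods["dam"].value_counts()
    sc = broods["sire"].value_counts()
    pat = int(sum(sc[r.sire] > 1 for r in broods.itertuples()))
    mat = int(sum(dc[r.dam] > 1 for r in broods.itertuples()))
    unc = int(sum((sc[r.sire] == 1) and (dc[r.dam] == 1)
                  for r in broods.itertuples()))
    return pat, mat, unc, broods


class TestDesignGeneration:
    def test_study_design_structure(self, study):
        ped, asg, _, _ = study
        assert len(ped.founders) == 13 + 12
        assert len(asg) == 113
        pat, mat, unc, broods = connectivity(asg)
        assert len(broods) == 20
        assert (pat, mat, unc) == (13, 10, 3)
        assert broods["dam"].nunique() == 13
        assert broods["sire"].nunique() == 12
        # no dam-sire pair mates twice
        assert len(broods) == len(set(zip(broods["dam"], broods["sire"])))
        sizes = asg.groupby("brood").size()
        assert sizes.between(4, 15).all()
        # split broods have both IF and control; others are standard
        for _, grp in asg.groupby("brood"):
            conds = set(grp["condition"])
            assert conds == {"standard"} or conds == {"IF", "control"}

    def test_same_seed_same_design(self):
        p1, a1 = generate_pedigree(DesignConfig(seed=9))
        p2, a2 = generate_pedigree(DesignConfig(seed=9))
        assert p1.ids == p2.ids
        pd.testing.assert_frame_equal(a1, a2)

    def test_single_brood_full_sibs(self):
        design = DesignConfig(n_dams=1, n_sires=1, n_broods=1,
                              brood_size_range=(4, 4), n_offspring=4,
                              frac_paternal_halfsib=0.0,
                              frac_maternal_halfsib=0.0,
                              frac_unconnected=1.0, seed=5)
        ped, asg = generate_pedigree(design)
        assert len(asg) == 4
        A = additive_relationship(ped)
        kids = list(asg["id"])
        off = [A.loc(a, b) for i, a in enumerate(kids) for b in kids[i + 1:]]
        assert off == pytest.approx([0.5] * 6)

    @pytest.mark.parametrize("kw", [
        # too few dams for the requested maternal connectivity
        dict(n_dams=10, n_sires=12),
        # fractions leave broods unclassified
        dict(frac_paternal_halfsib=0.1, frac_maternal_halfsib=0.1,
             frac_unconnected=0.1),
        # offspring target unreachable
        dict(n_offspring=50),
    ])
    def test_infeasible_designs_raise(self, kw):
        with pytest.raises(DesignError):
            generate_pedigree(DesignConfig(**kw))


class TestPhenotypeSimulation:
    def test_all_variances_zero_gives_constant_trait(self, study):
        ped, asg, _, _ = study
        vc = VarianceComponents(V_a=0, V_dam=0, V_brood=0, V_e=0)
        tbl = simulate_phenotypes(ped, asg, vc, seed=1)
        assert (tbl["rbw"] == vc.mu).all()

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            VarianceComponents(V_a=-0.1)

    def test_deterministic_under_seed(self, study):
        ped, asg, _, vc = study
        t1 = simulate_phenotypes(ped, asg, vc, seed=77)
        t2 = simulate_phenotypes(ped, asg, vc, seed=77)
        pd.testing.assert_frame_equal(t1, t2)

    def test_founder_breeding_value_variance(self):
        """Founder breeding values are iid N(0, V_a): their empirical
        variance falls inside two-sided 99% chi-square bounds."""
        ped, asg = generate_pedigree(DesignConfig(seed=21))
        vc = VarianceComponents()
        _, eff = simulate_phenotypes(ped, asg, vc, seed=8, return_effects=True)
        founder_idx = [ped.index(f) for f in ped.founders]
        bv = eff["breeding_values"][founder_idx]
        n = len(bv)
        from scipy.stats import chi2
        s2 = bv.var(ddof=0) * n
        assert chi2.ppf(0.005, n) * vc.V_a <= s2 <= chi2.ppf(0.995, n) * vc.V_a

    def test_sib_covariances(self):
        """cov(full sibs) -> V_a/2 + V_dam + V_brood and cov(paternal half
        sibs) -> V_a/4, estimated over many simulated pairs."""
        vc = VarianceComponents(V_a=0.0004, V_dam=0.0002, V_brood=0.0001,
                                V_e=0.0002)
        # full sibs: many independent 2-offspring broods
        design = DesignConfig(n_dams=4000, n_sires=4000, n_broods=4000,
                              brood_size_range=(2, 2), n_offspring=8000,
                              frac_paternal_halfsib=0.0,
                              frac_maternal_halfsib=0.0, frac_unconnected=1.0,
                              frac_split_broods=0.0, seed=31)
        ped, asg = generate_pedigree(design)
        tbl = simulate_phenotypes(ped, asg, vc, seed=32)
        off = offspring_rows(tbl)
        wide = off.pivot_table(index="brood", values="rbw", aggfunc=list)
        pairs = np.array([v for v in wide["rbw"]])
        cov_fs = np.cov(pairs[:, 0], pairs[:, 1])[0, 1]
        expect_fs = 0.5 * vc.V_a + vc.V_dam + vc.V_brood
        assert cov_fs == pytest.approx(expect_fs, abs=3e-5)

        # paternal half sibs: sires shared by exactly two broods
        design = DesignConfig(n_dams=8000, n_sires=4000, n_broods=8000,
                              brood_size_range=(1, 1), n_offspring=8000,
                              frac_paternal_halfsib=1.0,
                              frac_maternal_halfsib=0.0, frac_unconnected=0.0,
                              frac_split_broods=0.0, seed=33)
        ped, asg = generate_pedigree(design)
        tbl = simulate_phenotypes(ped, asg, vc, seed=34)
        off = offspring_rows(tbl)
        by_sire = off.groupby("sire")["rbw"].apply(list)
        pairs = np.array([v[:2] for v in by_sire if len(v) >= 2])
        cov_hs = np.cov(pairs[:, 0], pairs[:, 1])[0, 1]
        assert cov_hs == pytest.approx(0.25 * vc.V_a, abs=3e-5)

    def test_midparent_regression_slope_estimates_h2(self):
        """Additive-only inheritance: brood-mean offspring trait on
        mid-parent value has expected slope h2 (checked at 0.2 and 0.8)."""
        from pedvar.classic import midparent_regression
        for h2, seed in [(0.2, 51), (0.8, 52)]:
            Vp = 0.0009
            vc = VarianceComponents(V_a=h2 * Vp, V_dam=0.0, V_brood=0.0,
                                    V_e=(1 - h2) * Vp)
            design = DesignConfig(n_dams=500, n_sires=500, n_broods=500,
                                  brood_size_range=(4, 4), n_offspring=2000,
                                  frac_paternal_halfsib=0.0,
                                  frac_maternal_halfsib=0.0,
                                  frac_unconnected=1.0,
                                  frac_split_broods=0.0, seed=seed)
            ped, asg = generate_pedigree(design)
            tbl = simulate_phenotypes(ped, asg, vc, seed=seed + 1)
            value_of = tbl.set_index("id")["rbw"]
            off = offspring_rows(tbl)
            brood = off.groupby("brood").agg(y=("rbw", "mean"),
                                             dam=("dam", "first"),
                                             sire=("sire", "first"))
            mp = 0.5 * (value_of[brood["dam"]].to_numpy()
                        + value_of[brood["sire"]].to_numpy())
            res = midparent_regression(brood["y"], mp)
            assert res.slope == pytest.approx(h2, abs=0.1)

    def test_brood_only_variance_recognized(self):
        """With V_a = 0 and a large brood effect, full sibs correlate at
        V_brood/V_p, and the full animal+dam+brood model assigns the
        resemblance to brood, keeping the additive ratio low.  (An
        animal-only model would instead absorb it into the additive term —
        the confounding the full model exists to guard against.)"""
        from pedvar.model import ChainSettings, ModelSpec, fit_animal_model
        vc = VarianceComponents(V_a=0.0, V_dam=0.0, V_brood=0.00045,
                                V_e=0.00045)
        design = DesignConfig(n_dams=50, n_sires=50, n_broods=50,
                              brood_size_range=(8, 8), n_offspring=400,
                              frac_paternal_halfsib=0.0,
                              frac_maternal_halfsib=0.0, frac_unconnected=1.0,
                              frac_split_broods=0.0, seed=9)
        ped, asg = generate_pedigree(design)
        iccs = []
        for seed in (10, 11, 12):
            t = simulate_phenotypes(ped, asg, vc, seed=seed)
            o = offspring_rows(t)
            g = o.groupby("brood")["rbw"]
            msb = 8 * ((g.mean() - o["rbw"].mean()) ** 2).sum() / 49
            msw = g.var(ddof=1).mean()
            sb = (msb - msw) / 8
            iccs.append(sb / (sb + msw))
        assert np.mean(iccs) == pytest.approx(vc.V_brood / vc.V_p, abs=0.1)
        tbl = simulate_phenotypes(ped, asg, vc, seed=10)
        off = offspring_rows(tbl)
        fit = fit_animal_model(
            off, ped, ModelSpec(random=("animal", "dam", "brood")),
            ChainSettings(n_iterations=8_000, burn_in=1_500, thin=6, seed=4))
        assert fit.modes["animal"] < 0.3
        assert fit.modes["brood"] + fit.modes["dam"] > fit.modes["animal"]

    def test_roundtrip_through_csv(self, study, tmp_path):
        from pedvar.io import (read_pedigree, read_phenotypes, write_pedigree,
                               write_phenotypes)
        ped, _, tbl, _ = study
        write_pedigree(ped, tmp_path / "ped.csv")
        write_phenotypes(tbl, tmp_path / "pheno.csv")
        ped2 = read_pedigree(tmp_path / "ped.csv")
        tbl2 = read_phenotypes(tmp_path / "pheno.csv")
        assert ped2.ids == ped.ids and ped2.sire == ped.sire
        np.testing.assert_allclose(tbl2["rbw"], tbl["rbw"])
        assert (tbl2["brood"] == tbl["brood"]).all()

    def test_repeated_measurements_shape(self, study):
        _, _, tbl, _ = study
        long = simulate_repeated_measurements(tbl, n_replicates=4,
                                              measurement_sd=0.005, seed=3)
        assert len(long) == 4 * len(tbl)
        assert set(long["replicate"]) == {1, 2, 3, 4}
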