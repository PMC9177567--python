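import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from svpangut import assoc, synthio
from svpangut.synthio import CohortBundle


def toy_bundle():
    """Hand-built cohort straddling every filter threshold (n=100).

    species occurrence: sp_keep 100%, sp_edge exactly 50%, sp_drop 49%.
    SV groups within sp_keep's present-samples: 50/50 keeper, 19% minority
    (drop), 21% minority (keep), exactly 20% (keep, per the 'below 20%'
    rule).  Metabolites: complete (keep), 92% present (keep), exactly 90%
    (drop, strict >), 80% (drop).
    """
    n = 100
    idx = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")
    rng = np.random.default_rng(0)

    abundance = pd.DataFrame(
        {
            "sp_keep": rng.lognormal(size=n),
            "sp_edge": np.where(np.arange(n) < 50, rng.lognormal(size=n), 0.0),
            "sp_drop": np.where(np.arange(n) < 49, rng.lognormal(size=n), 0.0),
        },
        index=idx,
    )

    def geno(present_mask, ones):
        g = np.full(n, np.nan)
        present_idx = np.flatnonzero(present_mask)
        g[present_idx] = 0.0
        g[present_idx[:ones]] = 1.0
        return g

    all_present = np.ones(n, dtype=bool)
    sv_genotype = pd.DataFrame(
        {
            "sp_keep:K1": geno(all_present, 50),
            "sp_keep:K2": geno(all_present, 19),
            "sp_keep:K3": geno(all_present, 21),
            "sp_keep:K4": geno(all_present, 20),
            "sp_edge:K5": geno(abundance["sp_edge"] > 0, 25),
            "sp_drop:K6": geno(abundance["sp_drop"] > 0, 24),
        },
        index=idx,
    )

    def met(missing):
        v = rng.lognormal(size=n)
        out = v.copy()
        if missing:
            out[:missing] = np.nan
        return out

    metabolites = pd.DataFrame(
        {"m_full": met(0), "m_92": met(8), "m_90": met(10), "m_80": met(20)},
        index=idx,
    )
    phenotype = pd.Series(rng.normal(size=n), index=idx, name="phenotype")
    covariates = pd.DataFrame(
        {"age": rng.integers(20, 70, n).astype(float),
         "sex": (rng.random(n) < 0.5).astype(float),
         "bmi": rng.normal(23, 3, n)},
        index=idx,
    )
    return CohortBundle(abundance, sv_genotype, metabolites, phenotype, covariates)


class TestFilterCohort:
    def test_threshold_enumeration(self):
        fc = assoc.filter_cohort(toy_bundle())
        assert set(fc.abundance.columns) == {"sp_keep", "sp_edge"}
        assert set(fc.sv_genotype.columns) == {"sp_keep:K1", "sp_keep:K3",
                                               "sp_keep:K4", "sp_edge:K5"}
        assert set(fc.metabolites.columns) == {"m_full", "m_92"}

    def test_filter_log_names_every_feature(self):
        fc = assoc.filter_cohort(toy_bundle())
        log = fc.filter_log
        assert set(log.loc[~log["kept"], "feature"]) >= {"sp_drop", "sp_keep:K2", "m_90", "m_80"}
        assert (log[log["feature"] == "sp_drop"]["rule"] == "species_min_occ").all()

    def test_empty_cohort_error(self):
        b = toy_bundle()
        sparse = b.abundance.copy()
        sparse.iloc[30:] = 0.0
        b2 = CohortBundle(sparse, b.sv_genotype, b.metabolites, b.phenotype, b.covariates)
        with pytest.raises(assoc.EmptyCohortError):
            assoc.filter_cohort(b2)


class TestSpearman:
    def test_monotone_extremes(self):
        assert assoc.spearman([1, 2, 3], [10, 20, 30])[0] == pytest.approx(1.0)
        assert assoc.spearman([1, 2, 3], [30, 20, 10])[0] == pytest.approx(-1.0)

    def test_midrank_hand_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        rho, _ = assoc.spearman(x, y)
        rx, ry = rankdata(x), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_small_n_p_matches_enumeration(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = assoc.spearman(x, y)
        # tie-free oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) over all y-orders
        rx = rankdata(x)
        n = 6
        obs = 1 - 6 * ((rx - rankdata(y)) ** 2).sum() / (n * (n**2 - 1))
        count = 0
        total = 0
        for perm in itertools.permutations(rankdata(y)):
            r = 1 - 6 * ((rx - np.array(perm)) ** 2).sum() / (n * (n**2 - 1))
            count += abs(r) >= abs(obs) - 1e-12
            total += 1
        assert rho == pytest.approx(obs, abs=1e-12)
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_pairwise_complete_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        rho, _ = assoc.spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning):
            rho, p = assoc.spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            assoc.spearman([1.0, 2.0], [3.0, 4.0])


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.04], [0.04]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.001, 0.9], [0.002, 0.9]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert assoc.bh_adjust(p) == pytest.approx(expected)

    def test_never_decreases_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = assoc.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_propagates_outside_family(self):
        q = assoc.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assoc.bh_adjust([0.5, 1.5])


class TestPartialSpearman:
    def test_constant_covariate_equals_plain_spearman(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho_plain, _ = assoc.spearman(x, y)
        with pytest.warns(UserWarning):  # constant column is collinear with intercept
            rho_part, _ = assoc.partial_spearman(x, y, np.ones((40, 1)))
        assert rho_part == pytest.approx(rho_plain, abs=1e-12)

    def test_controlling_for_self_kills_correlation(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(size=200)
        x = 0.7 * y + 0.3 * rng.uniform(size=200)
        rho_part, _ = assoc.partial_spearman(x, y, y[:, None])
        # ranks are not exactly linear in y, so a small remainder survives
        assert abs(rho_part) < 0.15

    def test_common_cause_removed(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=200)
        x = z + rng.normal(size=200)
        y = z + rng.normal(size=200)
        rho_marg, _ = assoc.spearman(x, y)
        rho_part, _ = assoc.partial_spearman(x, y, z[:, None])
        assert rho_marg > 0.3
        assert abs(rho_part) < 0.12


class TestCascade:
    def test_planted_triples_recovered(self):
        bundle = synthio.simulate_cohort(seed=5)
        screen, dissection, _ = assoc.run_cascade(bundle)
        confounded = dissection[dissection["verdict"] == "confounded"]
        found = {(r.species, r.ko, r.target) for r in confounded.itertuples()}
        want = {(t.species, t.ko, t.metabolite) for t in bundle.truth}
        assert len(want & found) >= 2

    def test_phenotype_screen_recovers_planted_species(self):
        bundle = synthio.simulate_cohort(seed=9, phenotype_noise=0.5)
        screen, _, _ = assoc.run_cascade(bundle, target_block="phenotype")
        sig_species = set(screen.loc[screen["significant"], "species"])
        planted = {t.species for t in bundle.truth}
        assert sig_species & planted

    def test_pipeline_deterministic(self):
        bundle = synthio.simulate_cohort(seed=6)
        s1, d1, l1 = assoc.run_cascade(bundle)
        s2, d2, l2 = assoc.run_cascade(bundle)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(l1, l2)

    def test_small_subgroup_gives_na_not_confounded(self):
        bundle = synthio.simulate_cohort(seed=7)
        fc = assoc.filter_cohort(bundle)
        screen = assoc.screen_pairs(fc)
        screen = screen.copy()
        # force a significant row, then starve one genotype group
        if not screen["significant"].any():
            screen.loc[screen.index[0], "q_all"] = 0.01
        row = screen[screen["q_all"] < 0.1].iloc[0]
        col = fc.sv_columns_for(row["species"])[0]
        g = fc.sv_genotype[col].copy()
        g[g == 1.0] = 0.0
        g.iloc[np.flatnonzero(g.notna())[:2]] = 1.0  # only 2 SV1 samples
        fc.sv_genotype = fc.sv_genotype.copy()
        fc.sv_genotype[col] = g
        dis = assoc.dissect_by_sv(fc, screen)
        rec = dis[(dis["species"] == row["species"]) & (dis["ko"] == col.split(":")[1])
                  & (dis["target"] == row["target"])].iloc[0]
        assert rec["n_sv1"] <= 2
        assert np.isnan(rec["p_sv1"])
        assert rec["verdict"] == "not_confounded"
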