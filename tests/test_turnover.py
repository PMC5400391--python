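import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy.special import gammaln

from famturn import (
    ModelSpec,
    SimulationConfig,
    enrichment_fisher,
    filter_families,
    fit_poisson,
    fit_poisson_mixed,
    linear_contrast,
    per_family_rates,
    reconcile_families,
    simulate_batch,
)
from famturn.turnover import FitError, build_design


def _toy_two_family():
    return pd.DataFrame({
        "family": ["f1"] * 3 + ["f2"] * 3,
        "branch": ["b1", "b2", "b3"] * 2,
        "dup": [2, 0, 1, 5, 3, 4],
        "loss": [0, 1, 0, 2, 1, 3],
        "length": [10.0, 20.0, 15.0] * 2,
    })


class TestNaivePoisson:
    def test_intercept_only_closed_form(self):
        # counts (2, 4) on lengths (10, 20): MLE rate = 6/30
        df = pd.DataFrame({"family": ["f", "f"], "branch": ["a", "b"],
                           "dup": [2, 4], "loss": [0, 0],
                           "length": [10.0, 20.0]})
        fit = fit_poisson(df, ModelSpec(response="duplication"))
        assert fit.params["const"] == pytest.approx(math.log(0.2), abs=1e-9)

    def test_all_zero_response_raises(self):
        df = pd.DataFrame({"family": ["f"], "branch": ["a"], "dup": [0],
                           "loss": [0], "length": [10.0]})
        with pytest.raises(FitError, match="all-zero"):
            fit_poisson(df, ModelSpec())

    def test_two_group_rate_ratio_recovery(self, rng):
        # branches in the "fast" set evolve at twice the base rate
        rows = []
        for f in range(500):
            for b, t, rate in [("slow", 40.0, 0.02), ("fast", 40.0, 0.04)]:
                rows.append({"family": f"f{f}", "branch": b,
                             "dup": rng.poisson(rate * t), "loss": 0,
                             "length": t})
        spec = ModelSpec(response="duplication",
                         branch_terms=(("fast", frozenset({"fast"})),))
        fit = fit_poisson(pd.DataFrame(rows), spec)
        est = math.exp(fit.params["fast"])
        se_ratio = fit.bse["fast"]
        assert abs(math.log(est) - math.log(2.0)) < 3 * se_ratio

    def test_aggregation_invariance(self):
        """Poisson additivity: per-branch rows and family-collapsed rows give
        the same intercept fit."""
        df = _toy_two_family()
        collapsed = df.groupby("family", as_index=False).agg(
            dup=("dup", "sum"), loss=("loss", "sum"), length=("length", "sum"))
        collapsed["branch"] = "TREE"
        f1 = fit_poisson(df, ModelSpec())
        f2 = fit_poisson(collapsed, ModelSpec())
        assert f1.params["const"] == pytest.approx(f2.params["const"], abs=1e-8)

    def test_rank_deficient_design_rejected(self):
        df = _toy_two_family()
        spec = ModelSpec(branch_terms=(
            ("all1", frozenset({"b1", "b2", "b3"})),))  # collinear with const
        with pytest.raises(ValueError, match="rank"):
            fit_poisson(df, spec)


class TestMixedPoisson:
    def test_matches_brute_force_integration(self):
        """Marginal log-likelihood vs direct numerical integration of the
        per-family integrals, at 15 quadrature nodes."""
        df = _toy_two_family()
        spec = ModelSpec(random_intercept=True, aghq_nodes=15)
        y, X, off, fam, ids = build_design(df, spec)
        from famturn.turnover import _marginal_loglik
        from numpy.polynomial.hermite import hermgauss

        lg = float(gammaln(y + 1).sum())
        z, w = hermgauss(15)
        for beta0, sig in [(-2.0, 0.5), (-1.5, 1.0), (-3.0, 0.2)]:
            got = _marginal_loglik(np.array([beta0, math.log(sig)]),
                                   y, X.to_numpy(), off, fam, 2, z, w, lg)
            want = 0.0
            eta0 = X.to_numpy() @ np.array([beta0]) + off
            u = np.linspace(-40.0, 40.0, 400_001)
            for f in range(2):
                m = fam == f
                eta = eta0[m][:, None] + sig * u[None, :]
                li = (y[m][:, None] * eta - np.exp(eta)).sum(axis=0) \
                    - float(gammaln(y[m] + 1).sum()) \
                    - 0.5 * u * u - 0.5 * math.log(2 * math.pi)
                lmax = li.max()  # shift before exponentiating: the raw
                # integrand can be ~1e-11, far below quad's default epsabs
                want += lmax + math.log(np.trapezoid(np.exp(li - lmax), u))
            assert got == pytest.approx(want, abs=1e-6)

    def test_quadrature_stabilizes_with_nodes(self):
        """At a fixed parameter point the quadrature error vanishes as nodes
        are added: the 15-node value is already converged to ~1e-6."""
        df = _toy_two_family()
        spec = ModelSpec(random_intercept=True)
        y, X, off, fam, ids = build_design(df, spec)
        from famturn.turnover import _marginal_loglik
        from numpy.polynomial.hermite import hermgauss

        lg = float(gammaln(y + 1).sum())
        theta = np.array([-1.6, math.log(0.66)])  # near the fitted optimum
        vals = {}
        for k in (7, 15, 25, 51):
            z, w = hermgauss(k)
            vals[k] = _marginal_loglik(theta, y, X.to_numpy(), off, fam, 2,
                                       z, w, lg)
        assert abs(vals[7] - vals[51]) < 1e-3
        assert abs(vals[15] - vals[51]) < 1e-6
        assert abs(vals[25] - vals[51]) < 1e-8

    def test_sigma_zero_limit_matches_naive(self, rng):
        rows = []
        for f in range(60):
            for b, t in [("b1", 10.0), ("b2", 20.0)]:
                rows.append({"family": f"f{f}", "branch": b,
                             "dup": rng.poisson(0.05 * t), "loss": 0,
                             "length": t})
        df = pd.DataFrame(rows)
        fn = fit_poisson(df, ModelSpec())
        fm = fit_poisson_mixed(df, ModelSpec(random_intercept=True))
        assert fm.boundary
        assert fm.sigma2 < 1e-4
        assert fm.params["const"] == pytest.approx(fn.params["const"], abs=1e-4)
        assert fm.llf >= fn.llf - 1e-8

    def test_sigma_recovery(self, rng):
        T = 500.0
        u = rng.normal(0.0, 1.0, 400)
        y = rng.poisson(np.exp(-4.0 + u) * T)
        df = pd.DataFrame({"family": [f"f{i}" for i in range(400)],
                           "branch": "TREE", "dup": y, "loss": 0,
                           "length": T})
        fm = fit_poisson_mixed(df, ModelSpec(random_intercept=True))
        assert math.sqrt(fm.sigma2) == pytest.approx(1.0, abs=0.15)

    def test_needs_two_families(self):
        df = _toy_two_family().query("family == 'f1'")
        with pytest.raises(FitError, match="2 families"):
            fit_poisson_mixed(df, ModelSpec(random_intercept=True))

    def test_matches_lme4_glmer(self, rng, tmp_path):
        """Independent oracle: lme4::glmer with the same nAGQ on identical
        data agrees on coefficients, sigma, and Wald SEs."""
        assert shutil.which("Rscript"), "Rscript is required for this oracle"
        F = 120
        u = rng.normal(0, 0.8, F)
        imm = (np.arange(F) < 30).astype(float)
        rows = []
        for f in range(F):
            for b, t in [("b1", 50.0), ("b2", 120.0), ("b3", 200.0)]:
                mu = np.exp(-4.5 + 0.4 * imm[f] + u[f]) * t
                rows.append({"family": f"f{f}", "branch": b,
                             "dup": rng.poisson(mu), "loss": 0, "length": t,
                             "immune": imm[f]})
        df = pd.DataFrame(rows)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer((dup+loss) ~ immune + (1|family), offset=log(d$length),"
            " family=poisson, data=d, nAGQ=7)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))[1]),"
            " sqrt(diag(as.matrix(vcov(m)))), sep='\\n')\n")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True)
        b0, b1, sig, se0, se1 = map(float, out.stdout.strip().split("\n"))
        ann = df[["family", "immune"]].drop_duplicates()
        fit = fit_poisson_mixed(df, ModelSpec(family_terms=("immune",),
                                              random_intercept=True), ann)
        assert fit.params["const"] == pytest.approx(b0, abs=1e-3)
        assert fit.params["immune"] == pytest.approx(b1, abs=1e-3)
        assert math.sqrt(fit.sigma2) == pytest.approx(sig, abs=1e-3)
        # the point estimates agree tightly; Wald SEs come from numerically
        # differentiated Hessians in both implementations and can differ by
        # tens of percent on a given dataset (both are calibrated on average)
        assert fit.bse["const"] == pytest.approx(se0, rel=0.25)
        assert fit.bse["immune"] == pytest.approx(se1, rel=0.25)


class TestContrasts:
    @pytest.fixture(scope="class")
    def fit(self):
        df = _toy_two_family()
        return fit_poisson(df, ModelSpec(
            branch_terms=(("b1", frozenset({"b1"})),)))

    def test_zero_contrast(self, fit):
        (res,) = linear_contrast(fit, [[0.0, 0.0]], adjust="none")
        assert res.estimate == 0.0 and res.p == 1.0

    def test_single_coefficient_matches_wald(self, fit):
        (res,) = linear_contrast(fit, [[0.0, 1.0]], adjust="none")
        assert res.p == pytest.approx(float(fit.pvalues["b1"]), abs=1e-12)
        assert res.se == pytest.approx(float(fit.bse["b1"]), abs=1e-12)

    def test_adjusted_p_not_below_raw(self, fit):
        for adjust in ("holm", "bonferroni"):
            results = linear_contrast(fit, [[0, 1], [1, 0], [1, 1]],
                                      adjust=adjust)
            for r in results:
                assert r.p_adj >= r.p - 1e-15

    def test_wrong_length_rejected(self, fit):
        with pytest.raises(ValueError, match="length"):
            linear_contrast(fit, [[1.0, 0.0, 0.0]])


class TestPerFamily:
    def _table(self, rng, n_fam=40, musca_mult=1.0, base=0.05):
        rows = []
        for f in range(n_fam):
            mult = musca_mult if f == 0 else 1.0
            for b, t in [("Mdom", 70.0), ("other", 500.0)]:
                rate = base * (mult if b == "Mdom" else 1.0)
                rows.append({"family": f"f{f}", "branch": b,
                             "dup": rng.poisson(rate * t),
                             "loss": rng.poisson(rate * t), "length": t})
        return pd.DataFrame(rows)

    def test_equal_rates_estimate_near_zero(self, rng):
        df = self._table(rng)
        res, skipped = per_family_rates(df, None, "Mdom")
        ok = res[~res["boundary"]]
        assert len(ok) >= 35
        assert abs(ok["estimate"].mean()) < 0.2

    def test_planted_acceleration_detected(self, rng):
        df = self._table(rng, musca_mult=30.0)
        res, _ = per_family_rates(df, None, "Mdom")
        row = res.set_index("family").loc["f0"]
        assert row["estimate"] > 1.0
        assert row["q"] < 0.05

    def test_bh_identity_on_emitted_pvalues(self, rng):
        res, _ = per_family_rates(self._table(rng), None, "Mdom")
        res = res.sort_values("p").reset_index(drop=True)
        m = len(res)
        # q_i = min_{j >= i} p_j * m / (j+1), capped at 1
        expect = np.minimum.accumulate(
            (res["p"].to_numpy() * m / np.arange(1, m + 1))[::-1])[::-1]
        np.testing.assert_allclose(res["q"].to_numpy(),
                                   np.minimum(expect, 1.0), atol=1e-12)

    def test_musca_only_events_flagged_boundary(self):
        df = pd.DataFrame({
            "family": ["f0"] * 2 + ["f1"] * 2,
            "branch": ["Mdom", "other"] * 2,
            "dup": [4, 0, 1, 2], "loss": [1, 0, 0, 1],
            "length": [70.0, 500.0] * 2,
        })
        res, _ = per_family_rates(df, None, "Mdom")
        assert bool(res.set_index("family").loc["f0", "boundary"])
        assert not bool(res.set_index("family").loc["f1", "boundary"])

    def test_zero_event_families_skipped(self):
        df = pd.DataFrame({
            "family": ["f0"] * 2 + ["f1"] * 2,
            "branch": ["Mdom", "other"] * 2,
            "dup": [0, 0, 1, 2], "loss": [0, 0, 0, 1],
            "length": [70.0, 500.0] * 2,
        })
        res, skipped = per_family_rates(df, None, "Mdom")
        assert skipped == ["f0"]


class TestFisher:
    def test_worked_example_counts(self):
        orat, p = enrichment_fisher(6, 148, 53, 4512)
        assert float(f"{p:.2g}") == 0.012
        assert orat == pytest.approx((6 * 4512) / (148 * 53), rel=1e-12)

    def test_symmetric_table(self):
        orat, p = enrichment_fisher(5, 5, 5, 5)
        assert orat == 1.0 and p == 1.0

    def test_matches_enumeration(self):
        """Two-sided p equals direct enumeration over all tables with the
        observed margins (sum of hypergeometric probabilities <= observed)."""
        from scipy.stats import hypergeom

        for (a, b, c, d) in [(3, 1, 1, 3), (6, 148, 53, 4512), (2, 7, 8, 2)]:
            n1, n2, m1 = a + b, c + d, a + c
            rv = hypergeom(n1 + n2, n1, m1)
            p_obs = rv.pmf(a)
            enum = sum(rv.pmf(x) for x in range(max(0, m1 - n2), min(m1, n1) + 1)
                       if rv.pmf(x) <= p_obs * (1 + 1e-9))
            _, p = enrichment_fisher(a, b, c, d)
            assert p == pytest.approx(enum, rel=1e-8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st_.tuples(*[st_.integers(1, 30)] * 4))
    def test_p_in_unit_interval(self, cells):
        _, p = enrichment_fisher(*cells)
        assert 0.0 <= p <= 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            enrichment_fisher(0, 0, 5, 5)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            enrichment_fisher(1.5, 2, 3, 4)


class TestFilterFamilies:
    def test_drops_non_basal_and_zero_event(self, abc_tree):
        from famturn import gene_tree_from_newick, build_event_table

        gts = {
            "basal_with_events": "((A_a1,A_a2),(B_b,C_c));",
            "drosophilid_only": "(A_a1,B_b1);",      # maps below the root
            "basal_no_events": "((A_a,B_b),C_c);",
        }
        table = build_event_table(
            [(k, gene_tree_from_newick(v, species_tree=abc_tree))
             for k, v in gts.items()], abc_tree)
        kept, report = filter_families(table, abc_tree)
        assert list(kept.families.index) == ["basal_with_events"]
        assert report["dropped_not_basal"] == 1
        assert report["dropped_no_events"] == 1

    def test_empty_result_errors(self, abc_tree):
        from famturn import gene_tree_from_newick, build_event_table

        table = build_event_table(
            [("f", gene_tree_from_newick("(A_a1,B_b1);", species_tree=abc_tree))],
            abc_tree)
        with pytest.raises(FitError, match="no families"):
            filter_families(table, abc_tree)

    def test_root_filtered_simulations_are_basal(self, dipteran_tree):
        """The simulator's root-survival filter and the basal-presence filter
        agree: no root survivor is dropped for non-basal presence."""
        cfg = SimulationConfig(duplication_rate=0.002, loss_rate=0.002,
                               n_families=200, rng_seed=1)
        fams, _ = simulate_batch(dipteran_tree, cfg)
        table = reconcile_families([f.gene_tree for f in fams], dipteran_tree,
                                   names=[f"f{i}" for i in range(len(fams))])
        kept, report = filter_families(table, dipteran_tree)
        assert report["dropped_not_basal"] == 0
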