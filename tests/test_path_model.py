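"""Recursive path analysis: specification, ML fit, effects, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from grazemulti.path_model import (PathModelSpec, SpecificationError,
                                   chi2_tail_probability, default_model,
                                   dummy_code, fit_path_model,
                                   residualize_by_block, total_effects_table)
from grazemulti.tables_io import DesignTable


def _chain_data(rng, n, a=0.6, b=0.5, c=0.0):
    x = rng.standard_normal(n)
    M = a * x + np.sqrt(1 - a * a) * rng.standard_normal(n)
    resid = np.sqrt(1 - b * b - c * c - 2 * a * b * c)
    Y = b * M + c * x + resid * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "M": M, "Y": Y})


CHAIN = PathModelSpec(["x", "M", "Y"], [("x", "M"), ("M", "Y")])
CHAIN_DIRECT = PathModelSpec(["x", "M", "Y"],
                             [("x", "M"), ("M", "Y"), ("x", "Y")])


class TestSpecification:
    def test_cycle_rejected(self):
        with pytest.raises(SpecificationError, match="cycle"):
            PathModelSpec(["a", "b"], [("a", "b"), ("b", "a")])

    def test_unknown_variable_rejected(self):
        with pytest.raises(SpecificationError, match="unknown"):
            PathModelSpec(["a"], [("a", "z")])

    def test_exogenous_endogenous_split(self):
        assert CHAIN.exogenous == ["x"]
        assert CHAIN.endogenous == ["M", "Y"]

    def test_from_dict_arrow_syntax(self):
        spec = PathModelSpec.from_dict(
            {"variables": ["a", "b", "c"], "edges": ["a -> b", "b -> c"]})
        assert spec.edges == [("a", "b"), ("b", "c")]

    def test_default_model_has_one_df(self, rng):
        model = default_model()
        assert len(model.variables) == 4
        # 10 moments - (5 edges + 3 disturbances + 1 exogenous variance)
        assert 10 - model.n_free_parameters() == 1


class TestDummyCodeAndResidualize:
    @pytest.fixture()
    def design(self):
        rows = [{"plot_id": f"{b}{t}", "block": b, "treatment": t}
                for b in ["b1", "b2"] for t in ["NG", "SG", "CG", "MG"]]
        return DesignTable(pd.DataFrame(rows))

    def test_dummy_marks_only_target_level(self, design):
        coded = dummy_code(design, "MG")
        assert coded.sum() == 2
        assert set(coded[coded == 1].index) == {"b1MG", "b2MG"}
        ng = dummy_code(design, "NG")  # indicator of ungrazed controls
        assert ng.sum() == 2

    def test_unknown_level_rejected(self, design):
        with pytest.raises(ValueError, match="unknown treatment"):
            dummy_code(design, "XX")

    def test_block_constant_response_residualizes_to_zero(self, design):
        y = pd.Series({p: 1.0 if p.startswith("b1") else 3.0
                       for p in design.plot_ids})
        res = residualize_by_block(y, design)
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_matches_explicit_block_mean_subtraction(self, design, rng):
        y = pd.Series(rng.normal(size=8), index=design.plot_ids)
        res = residualize_by_block(y, design)
        for b in ["b1", "b2"]:
            plots = [p for p in design.plot_ids if p.startswith(b)]
            expected = y[plots] - y[plots].mean()
            np.testing.assert_allclose(res[plots], expected, atol=1e-12)
            assert res[plots].sum() == pytest.approx(0.0, abs=1e-12)


class TestFit:
    def test_saturated_model_has_zero_chi2_zero_df(self, rng):
        data = _chain_data(rng, 100)
        fit = fit_path_model(data, CHAIN_DIRECT)
        assert fit.df == 0
        assert fit.chi2 == 0.0
        assert fit.p_chi2 == 1.0
        assert fit.rmsea == 0.0

    def test_pure_chain_parameter_recovery_large_n(self, rng):
        data = _chain_data(rng, 10_000, a=0.6, b=0.5)
        fit = fit_path_model(data, CHAIN)
        assert fit.direct.loc["M", "x"] == pytest.approx(0.6, abs=0.02)
        assert fit.direct.loc["Y", "M"] == pytest.approx(0.5, abs=0.02)
        assert fit.total.loc["Y", "x"] == pytest.approx(0.30, abs=0.02)
        assert fit.indirect.loc["Y", "x"] == pytest.approx(0.30, abs=0.02)
        fit_d = fit_path_model(data, CHAIN_DIRECT)
        assert fit_d.direct.loc["Y", "x"] == pytest.approx(0.0, abs=0.03)

    def test_total_equals_direct_plus_indirect(self, rng):
        data = _chain_data(rng, 200, c=0.2)
        fit = fit_path_model(data, CHAIN_DIRECT)
        np.testing.assert_allclose(fit.total.to_numpy(),
                                   (fit.direct + fit.indirect).to_numpy(),
                                   atol=1e-9)

    def test_total_effects_match_path_enumeration(self, rng):
        """(I - B)^-1 - I equals the brute-force sum over directed paths of
        coefficient products, on random recursive DAGs of up to 5 variables."""
        for rep in range(20):
            local = np.random.default_rng(rep)
            p = int(local.integers(3, 6))
            names = [f"v{i}" for i in range(p)]
            edges = [(names[i], names[j]) for i in range(p)
                     for j in range(i + 1, p) if local.random() < 0.6]
            if not edges:
                continue
            spec = PathModelSpec(names, edges)
            data = pd.DataFrame(local.standard_normal((50, p)), columns=names)
            fit = fit_path_model(data, spec)

            B = fit.direct
            def paths_total(src, dst):
                total = 0.0
                stack = [(src, 1.0)]
                while stack:
                    node, prod = stack.pop()
                    for s, t in edges:
                        if s == node:
                            contrib = prod * B.loc[t, s]
                            if t == dst:
                                total += contrib
                            else:
                                stack.append((t, contrib))
                return total

            for src in names:
                for dst in names:
                    if src != dst:
                        assert fit.total.loc[dst, src] == pytest.approx(
                            paths_total(src, dst), abs=1e-10)

    def test_ste_table_direct_plus_mediated(self, rng):
        data = _chain_data(rng, 5000, a=0.6, b=0.5, c=0.2)
        fit = fit_path_model(data, CHAIN_DIRECT)
        ste = total_effects_table(fit, "Y")
        a = fit.direct.loc["M", "x"]
        b = fit.direct.loc["Y", "M"]
        c = fit.direct.loc["Y", "x"]
        assert ste["x"] == pytest.approx(c + a * b, abs=1e-12)
        assert ste["M"] == pytest.approx(b, abs=1e-12)
        with pytest.raises(ValueError, match="exogenous"):
            total_effects_table(fit, "x")

    def test_r2_matches_regression_r2(self, rng):
        data = _chain_data(rng, 500)
        fit = fit_path_model(data, CHAIN)
        z = (data - data.mean()) / data.std(ddof=1)
        resid = z["Y"] - np.polyval(np.polyfit(z["M"], z["Y"], 1), z["M"])
        r2 = 1 - (resid ** 2).sum() / ((z["Y"] - z["Y"].mean()) ** 2).sum()
        assert fit.R2["Y"] == pytest.approx(r2, abs=1e-9)

    def test_constant_column_rejected(self, rng):
        data = _chain_data(rng, 50)
        data["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_path_model(data, CHAIN)

    def test_duplicate_edge_rejected(self):
        with pytest.raises(SpecificationError, match="duplicate"):
            PathModelSpec(["x", "Y"], [("x", "Y"), ("x", "Y")])


class TestFitStatistics:
    def test_reported_chi2_tail(self):
        """chi2 = 2.71 on 1 df lies just inside the 10% tail."""
        assert round(chi2_tail_probability(2.71, 1), 2) == 0.10

    def test_chi2_null_calibration(self):
        """Fitting the true chain model to its own data, chi2 ~ chi2(1)."""
        from scipy import stats

        rng = np.random.default_rng(2024)
        chis = [fit_path_model(_chain_data(rng, 200), CHAIN).chi2
                for _ in range(300)]
        ks = stats.kstest(chis, "chi2", args=(1,))
        assert ks.pvalue > 0.01

    def test_rmsea_zero_for_good_fit_positive_for_misfit(self, rng):
        good = fit_path_model(_chain_data(rng, 500), CHAIN)
        assert good.rmsea < 0.1
        # strong direct path omitted from the model: clear misfit
        data = _chain_data(rng, 500, a=0.5, b=0.3, c=0.5)
        bad = fit_path_model(data, CHAIN)
        assert bad.rmsea > 0.15
        assert bad.p_close < 0.05 < good.p_close


class TestBollenStine:
    def test_p_in_open_unit_interval_and_seeded(self, rng):
        data = _chain_data(rng, 120)
        f1 = fit_path_model(data, CHAIN, bootstrap=200, seed=9)
        f2 = fit_path_model(data, CHAIN, bootstrap=200, seed=9)
        assert f1.p_bollen_stine == f2.p_bollen_stine
        assert 0 < f1.p_bollen_stine <= 1

    def test_rank_agreement_with_chi2_p(self):
        """Across increasing misspecification, the bootstrap p falls with
        the analytic chi2 p."""
        rng = np.random.default_rng(5)
        ps, bs = [], []
        for c in (0.0, 0.25, 0.5):
            data = _chain_data(rng, 200, a=0.5, b=0.3, c=c)
            fit = fit_path_model(data, CHAIN, bootstrap=300, seed=1)
            ps.append(fit.p_chi2)
            bs.append(fit.p_bollen_stine)
        assert ps == sorted(ps, reverse=True)
        assert bs == sorted(bs, reverse=True)
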