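"""Blocked two-way ANOVA and Tukey post hoc letter display."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grazemulti.group_comparison import (UnbalancedDesignError, block_anova,
                                         compact_letter_display, tukey_hsd)
from grazemulti.tables_io import DesignTable


def _design(blocks, treatments):
    rows = [{"plot_id": f"{b}_{t}", "block": b, "treatment": t}
            for b in blocks for t in treatments]
    return DesignTable(pd.DataFrame(rows))


def _y(design, fn):
    vals = {r.plot_id: fn(r.block, r.treatment)
            for r in design.data.itertuples()}
    return pd.Series(vals)


@pytest.fixture()
def rcbd():
    return _design([f"b{i}" for i in range(1, 7)], ["NG", "SG", "CG", "MG"])


def test_block_only_variation_gives_zero_treatment_F(rcbd):
    y = _y(rcbd, lambda b, t: float(b[1]))
    res = block_anova(y, rcbd)
    assert res.F_treatment == pytest.approx(0.0, abs=1e-20)
    assert res.treatment_SS == pytest.approx(0.0, abs=1e-12)


def test_two_by_two_perfect_separation():
    design = _design(["b1", "b2"], ["t1", "t2"])
    y = _y(design, lambda b, t: 1.0 if t == "t2" else 0.0)
    res = block_anova(y, design)
    assert res.treatment_SS == pytest.approx(1.0)
    assert res.residual_SS == pytest.approx(0.0, abs=1e-12)
    assert res.perfect_separation
    assert np.isinf(res.F_treatment)


def test_matches_bruteforce_sums_of_squares(rcbd, rng):
    """Explicit group-mean arithmetic reproduces F to 1e-10."""
    y = pd.Series(rng.normal(size=24), index=rcbd.plot_ids)
    res = block_anova(y, rcbd)

    df = rcbd.data.assign(y=y.reindex(rcbd.data["plot_id"]).to_numpy())
    grand = df["y"].mean()
    ss_t = sum(6 * (df[df.treatment == t]["y"].mean() - grand) ** 2
               for t in rcbd.treatments)
    ss_b = sum(4 * (df[df.block == b]["y"].mean() - grand) ** 2
               for b in rcbd.blocks)
    ss_res = 0.0
    for r in df.itertuples():
        fitted = (grand + (df[df.block == r.block]["y"].mean() - grand)
                  + (df[df.treatment == r.treatment]["y"].mean() - grand))
        ss_res += (r.y - fitted) ** 2
    F = (ss_t / 3) / (ss_res / 15)
    assert res.F_treatment == pytest.approx(F, abs=1e-10)
    assert res.treatment_SS == pytest.approx(ss_t, abs=1e-10)
    assert res.block_SS == pytest.approx(ss_b, abs=1e-10)
    # additive decomposition of the total
    total = ((df["y"] - grand) ** 2).sum()
    assert res.block_SS + res.treatment_SS + res.residual_SS == pytest.approx(
        total, rel=1e-8)


def test_matches_statsmodels_ols_anova(rcbd, rng):
    """Independent fixed-effects route (statsmodels) gives the same F and p."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = pd.Series(rng.normal(size=24), index=rcbd.plot_ids)
    res = block_anova(y, rcbd)
    df = rcbd.data.assign(y=y.reindex(rcbd.data["plot_id"]).to_numpy())
    lm = smf.ols("y ~ C(block) + C(treatment)", data=df).fit()
    table = sm.stats.anova_lm(lm, typ=2)
    assert res.F_treatment == pytest.approx(table.loc["C(treatment)", "F"],
                                            rel=1e-9)
    assert res.p_treatment == pytest.approx(
        table.loc["C(treatment)", "PR(>F)"], rel=1e-9)


def test_plot_label_permutation_invariance(rcbd, rng):
    y = pd.Series(rng.normal(size=24), index=rcbd.plot_ids)
    res1 = block_anova(y, rcbd)
    perm = rng.permutation(len(rcbd.data))
    shuffled = DesignTable(rcbd.data.iloc[perm].reset_index(drop=True))
    res2 = block_anova(y, shuffled)
    assert res1.F_treatment == pytest.approx(res2.F_treatment, abs=1e-12)


def test_unbalanced_design_rejected(rcbd):
    df = rcbd.data.iloc[:-1].reset_index(drop=True)
    design = DesignTable(df)
    y = pd.Series(np.arange(23.0), index=df["plot_id"])
    with pytest.raises(UnbalancedDesignError):
        block_anova(y, design)


class TestTukey:
    def test_two_treatments_reduce_to_t_test(self, rng):
        design = _design([f"b{i}" for i in range(1, 7)], ["A", "B"])
        y = pd.Series(rng.normal(size=12), index=design.plot_ids)
        pairs, _ = tukey_hsd(y, design)
        res = block_anova(y, design)
        diff = (res.treatment_means["A"] - res.treatment_means["B"])
        tstat = abs(diff) / np.sqrt(res.ms_residual * 2 / 6)
        # q = t * sqrt(2); paired-comparison p identical to the F/t test
        assert pairs["q"].iloc[0] == pytest.approx(tstat * np.sqrt(2))
        p_t = 2 * stats.t.sf(tstat, res.df_residual)
        assert pairs["p_adj"].iloc[0] == pytest.approx(p_t, rel=1e-6)

    def test_identical_means_share_one_letter(self, rcbd, rng):
        # noise centered within each treatment: treatment means exactly equal
        noise = rng.normal(size=(6, 4))
        noise -= noise.mean(axis=0)
        cols = {t: j for j, t in enumerate(["NG", "SG", "CG", "MG"])}
        y = _y(rcbd, lambda b, t: float(b[1]) + noise[int(b[1]) - 1, cols[t]])
        pairs, letters = tukey_hsd(y, rcbd)
        np.testing.assert_allclose(pairs["p_adj"], 1.0, atol=1e-9)
        assert set(letters.values()) == {"a"}

    def test_known_means_against_q_table(self):
        """Hand-built case checked against the published studentized-range
        quantile q(0.10; 4, 15) = 3.14: pairs beyond q*se differ."""
        design = _design([f"b{i}" for i in range(1, 7)], ["NG", "SG", "CG", "MG"])
        means = {"NG": 0.0, "SG": 0.0, "CG": 1.0, "MG": 1.0}
        offsets = {f"b{i}": d for i, d in zip(range(1, 7),
                                              [-0.25, -0.15, -0.05, 0.05, 0.15, 0.25])}
        noise = np.random.default_rng(7).normal(0, 0.1, size=(6, 4))
        cols = {t: j for j, t in enumerate(["NG", "SG", "CG", "MG"])}
        y = _y(design, lambda b, t: means[t] + offsets[b]
               + noise[int(b[1]) - 1, cols[t]])
        pairs, letters = tukey_hsd(y, design, alpha=0.1)
        q_crit = 3.14  # q(0.10; 4, 15)
        for row in pairs.itertuples():
            assert (row.p_adj < 0.1) == (row.q > q_crit), row
        # the two low and the two high treatments form two letter groups
        assert letters["NG"] == letters["SG"]
        assert letters["CG"] == letters["MG"]
        assert letters["NG"] != letters["CG"]

    def test_degenerate_zero_residual_rejected(self):
        design = _design(["b1", "b2"], ["t1", "t2"])
        y = _y(design, lambda b, t: 1.0 if t == "t2" else 0.0)
        with pytest.raises(ValueError, match="zero"):
            tukey_hsd(y, design)


def test_compact_letter_display_insert_absorb():
    means = {"A": 3.0, "B": 2.0, "C": 1.0}
    # A differs from C only: expect overlapping letter groups ab / b? no:
    letters = compact_letter_display(means, {frozenset(("A", "C"))})
    assert letters["A"] != letters["C"]
    assert set(letters["B"]) & set(letters["A"])
    assert set(letters["B"]) & set(letters["C"])
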