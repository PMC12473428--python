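import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from seedpheno.anova import (
    AnovaRow,
    anova_table,
    estimate_genetic_parameters,
    fit_rcbd_anova,
    genetic_parameters_table,
)
from seedpheno.io import PhenotypeTable
from tests.conftest import random_rcbd


def brute_force_ss(y: np.ndarray) -> dict:
    """Textbook mean-deviation sums of squares, computed cell by cell."""
    g, r = y.shape
    grand = y.mean()
    ss_g = sum(r * (y[i].mean() - grand) ** 2 for i in range(g))
    ss_b = sum(g * (y[:, j].mean() - grand) ** 2 for j in range(r))
    ss_t = sum((y[i, j] - grand) ** 2 for i in range(g) for j in range(r))
    return {"ss_g": ss_g, "ss_b": ss_b, "ss_e": ss_t - ss_g - ss_b}


def test_hand_dataset_mean_squares(hand_rcbd):
    """3x2 hand case: SS_G = 13, SS_B = 1/6, SS_E = 13/3 by enumeration."""
    row = fit_rcbd_anova(hand_rcbd, "y")
    assert row.ms_genotypes == pytest.approx(13.0 / 2)
    assert row.ms_blocks == pytest.approx((1.0 / 6) / 1)
    assert row.ms_residual == pytest.approx((13.0 / 3) / 2)
    assert row.df_total == 5
    assert row.grand_mean == pytest.approx(3.5)


@pytest.mark.parametrize("seed", range(6))
def test_anova_matches_brute_force_oracle(seed):
    table = random_rcbd(4, 3, seed)
    row = fit_rcbd_anova(table, "y")
    y = table.plot_matrix("y").to_numpy()
    ss = brute_force_ss(y)
    assert row.ms_genotypes == pytest.approx(ss["ss_g"] / 3, abs=1e-10)
    assert row.ms_blocks == pytest.approx(ss["ss_b"] / 2, abs=1e-10)
    assert row.ms_residual == pytest.approx(ss["ss_e"] / 6, abs=1e-10)


def test_anova_matches_statsmodels(hand_rcbd):
    """Independent route: OLS with genotype + block factors."""
    fit = ols("value ~ C(genotype) + C(block)", data=hand_rcbd.data).fit()
    tbl = sm.stats.anova_lm(fit, typ=2)
    row = fit_rcbd_anova(hand_rcbd, "y")
    assert row.ms_genotypes == pytest.approx(
        tbl.loc["C(genotype)", "sum_sq"] / tbl.loc["C(genotype)", "df"]
    )
    assert row.ms_residual == pytest.approx(
        tbl.loc["Residual", "sum_sq"] / tbl.loc["Residual", "df"]
    )
    assert row.f_genotypes == pytest.approx(tbl.loc["C(genotype)", "F"])
    assert row.p_genotypes == pytest.approx(tbl.loc["C(genotype)", "PR(>F)"])


def test_degrees_of_freedom_identity():
    table = random_rcbd(43, 4, seed=0)
    row = fit_rcbd_anova(table, "y")
    assert (row.df_blocks, row.df_genotypes, row.df_residual, row.df_total) == (3, 42, 126, 171)
    assert row.df_total == row.df_blocks + row.df_genotypes + row.df_residual


def test_purely_additive_data_has_zero_residual():
    rows = []
    for i, gi in enumerate([0.0, 1.0, 2.0]):
        for j, bj in enumerate([0.0, 0.5]):
            rows.append(
                {"genotype": f"G{i}", "block": f"B{j}", "trait": "y", "value": 5 + gi + bj}
            )
    table = PhenotypeTable(pd.DataFrame(rows))
    with pytest.warns(UserWarning, match="zero residual"):
        row = fit_rcbd_anova(table, "y")
    assert row.ms_residual == pytest.approx(0.0, abs=1e-20)
    assert math.isinf(row.f_genotypes)
    params = estimate_genetic_parameters(row)
    assert params.h2 == pytest.approx(1.0)


def test_unbalanced_layout_rejected():
    df = random_rcbd(3, 2, seed=1).data.iloc[:-1]
    table = PhenotypeTable(df)
    with pytest.raises(ValueError, match="missing cells"):
        fit_rcbd_anova(table, "y")
    with pytest.warns(UserWarning, match="unbalanced"):
        out = anova_table(table)
    assert out.empty


def _row(msg, mse, mean=10.0, g=43, r=4):
    return AnovaRow(
        trait_id="x", g=g, r=r, df_blocks=r - 1, df_genotypes=g - 1,
        df_residual=(g - 1) * (r - 1), df_total=g * r - 1,
        ms_blocks=0.0, ms_genotypes=msg, ms_residual=mse,
        f_genotypes=msg / mse if mse else math.inf, p_genotypes=0.0,
        cv_pct=100 * math.sqrt(mse) / mean if mean else math.nan, grand_mean=mean,
    )


class TestGeneticParameters:
    def test_variance_identity_exact(self):
        gp = estimate_genetic_parameters(_row(5.0, 2.0))
        assert gp.sigma2_p == gp.sigma2_g + gp.sigma2_e_mean

    def test_vi_conventions(self):
        """Plot-level CVe gives VI = sqrt((MSG-MSE)/r)/sqrt(MSE)."""
        gp_plot = estimate_genetic_parameters(_row(4691.685, 1357.386, mean=51.6))
        assert gp_plot.vi == pytest.approx(
            math.sqrt((4691.685 - 1357.386) / 4) / math.sqrt(1357.386)
        )
        gp_mean = estimate_genetic_parameters(_row(4691.685, 1357.386, mean=51.6), cve_level="mean")
        assert gp_mean.vi == pytest.approx(gp_plot.vi * 2.0)

    def test_no_signal_when_msg_equals_mse(self):
        gp = estimate_genetic_parameters(_row(2.0, 2.0))
        assert gp.sigma2_g == 0.0 and gp.h2 == 0.0 and gp.vi == 0.0

    def test_negative_sigma2g_flagged_not_truncated(self):
        gp = estimate_genetic_parameters(_row(1.0, 2.0))
        assert gp.negative_sigma2g
        assert gp.sigma2_g == pytest.approx(-0.25)
        assert gp.h2 == 0.0 and gp.cv_g == 0.0

    def test_h2_monotone_in_msg(self):
        h2s = [estimate_genetic_parameters(_row(m, 2.0)).h2 for m in (2.5, 4.0, 8.0, 50.0)]
        assert h2s == sorted(h2s)
        assert all(0.0 <= h <= 1.0 for h in h2s)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="grand mean"):
            estimate_genetic_parameters(_row(5.0, 2.0, mean=0.0))


def test_tables_pipeline_and_bonferroni(hand_rcbd):
    anova = anova_table(hand_rcbd)
    assert list(anova["trait_id"]) == ["y"]
    assert (anova["p_bonferroni"] >= anova["p_genotypes"]).all()
    params = genetic_parameters_table(anova)
    assert params.loc[0, "h2_pct"] == pytest.approx(100 * params.loc[0, "h2"])
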