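import warnings

import numpy as np
import pandas as pd
import pytest

from seedpheno.anova import anova_table, fit_rcbd_anova, estimate_genetic_parameters
from seedpheno.divergence import cluster_criteria, gower_matrix, select_group_count, ward_linkage
from seedpheno.simulate import (
    SeedLotModel,
    SimulationConfig,
    TraitSim,
    default_config,
    measure_seed_lots,
    simulate_phenotypes,
    simulate_seed_lots,
)


def one_trait(sigma2_g=1.0, sigma2_b=0.1, sigma2_e=1.0, mean=10.0):
    return [TraitSim("y", mean, sigma2_g, sigma2_b, sigma2_e)]


def test_deterministic_given_seed():
    cfg = default_config(g=10, r=3, n_groups=2, delta=4.0, seed=7)
    t1, truth1 = simulate_phenotypes(cfg)
    t2, truth2 = simulate_phenotypes(default_config(g=10, r=3, n_groups=2, delta=4.0, seed=7))
    pd.testing.assert_frame_equal(t1.data, t2.data)
    pd.testing.assert_series_equal(truth1.group_labels, truth2.group_labels)
    t3, _ = simulate_phenotypes(default_config(g=10, r=3, n_groups=2, delta=4.0, seed=8))
    assert not t1.data["value"].equals(t3.data["value"])


def test_balanced_by_construction():
    table, _ = simulate_phenotypes(default_config(g=7, r=3, seed=1))
    assert table.balanced
    assert len(table) == 7 * 3 * 17


def test_no_noise_means_identical_replicates_and_h2_one():
    cfg = SimulationConfig(traits=one_trait(sigma2_b=0.0, sigma2_e=0.0), g=5, r=3, seed=2)
    table, truth = simulate_phenotypes(cfg)
    spread = table.data.groupby("genotype")["value"].agg(lambda s: s.max() - s.min())
    assert (spread == 0).all()
    assert truth.h2_true["y"] == 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # residual MS may be exactly zero
        row = fit_rcbd_anova(table, "y")
    assert estimate_genetic_parameters(row).h2 == pytest.approx(1.0)


def test_null_model_f_near_one_on_average():
    """sigma2_g = 0: E[F] = df_e / (df_e - 2) ~ 1."""
    fs = []
    for seed in range(60):
        cfg = SimulationConfig(traits=one_trait(sigma2_g=0.0), g=15, r=4, seed=seed)
        table, _ = simulate_phenotypes(cfg)
        fs.append(fit_rcbd_anova(table, "y").f_genotypes)
    assert np.mean(fs) == pytest.approx(1.05, abs=0.15)


def test_variance_components_recovered_at_large_g():
    cfg = SimulationConfig(
        traits=[TraitSim("y", 10.0, 2.0, 0.1, 1.5)], g=1000, r=4, seed=5
    )
    table, _ = simulate_phenotypes(cfg)
    row = fit_rcbd_anova(table, "y")
    gp = estimate_genetic_parameters(row)
    assert gp.sigma2_g == pytest.approx(2.0, rel=0.05)
    assert gp.sigma2_e_plot == pytest.approx(1.5, rel=0.05)


def test_genetic_correlation_realized():
    rg = np.array([[1.0, 0.8], [0.8, 1.0]])
    cfg = SimulationConfig(
        traits=[TraitSim("a", 0.0, 1.0, 0.0, 0.01), TraitSim("b", 0.0, 1.0, 0.0, 0.01)],
        g=800, r=2, rg=rg, seed=3,
    )
    _, truth = simulate_phenotypes(cfg)
    got = np.corrcoef(truth.genotype_effects["a"], truth.genotype_effects["b"])[0, 1]
    assert got == pytest.approx(0.8, abs=0.05)


def test_invalid_correlation_matrix_named_in_error():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PSD
    with pytest.raises(ValueError, match="rg"):
        SimulationConfig(
            traits=[TraitSim("a", 0, 1, 0, 1), TraitSim("b", 0, 1, 0, 1)],
            g=4, r=2, rg=bad,
        )


def test_group_structure_separates_centers():
    cfg = default_config(g=40, r=4, n_groups=4, delta=4.0, seed=9)
    _, truth = simulate_phenotypes(cfg)
    labels = truth.group_labels
    assert set(labels.unique()) == {1, 2, 3, 4}
    sizes = labels.value_counts()
    assert sizes.min() >= 1 and sizes.sum() == 40
    assert truth.group_centers.shape == (4, 17)


class TestSeedLots:
    def test_zero_wobble_gives_identical_replicates(self):
        cfg = default_config(g=3, r=3, seed=4)
        lots = simulate_seed_lots(cfg, SeedLotModel(wobble=0.0))
        table = measure_seed_lots(lots)
        spread = table.data.groupby(["genotype", "trait"])["value"].agg(
            lambda s: s.max() - s.min()
        )
        assert spread.max() == pytest.approx(0.0, abs=1e-12)

    def test_circular_genotype_measures_circular(self):
        cfg = default_config(g=2, r=2, seed=4)
        lots = simulate_seed_lots(
            cfg, SeedLotModel(elongation_range=(1.0, 1.0), exponent_range=(2.0, 2.0), wobble=0.0)
        )
        table = measure_seed_lots(lots)
        circ = table.data[table.data["trait"] == "b_circularity"]["value"]
        assert circ.min() > 0.99

    def test_two_shape_families_separate_into_two_groups(self):
        """End-to-end: distinct elongations -> Gower + Ward recovers the split."""
        round_cfg = default_config(g=4, r=3, seed=11)
        slim_cfg = default_config(g=4, r=3, seed=12)
        round_lots = simulate_seed_lots(
            round_cfg, SeedLotModel(elongation_range=(1.0, 1.05), wobble=0.01)
        )
        slim_lots = simulate_seed_lots(
            slim_cfg, SeedLotModel(elongation_range=(2.4, 2.5), wobble=0.01)
        )
        slim_lots["genotype"] = slim_lots["genotype"].str.replace("G", "S")
        lots = pd.concat([round_lots, slim_lots], ignore_index=True)
        profiles = measure_seed_lots(lots).genotype_means()
        tree = ward_linkage(gower_matrix(profiles))
        cut = tree.cut(2)
        families = cut.index.str[0]
        # the 2-cut must align perfectly with the two shape families
        assert cut.groupby(families).nunique().max() == 1
        assert cut.nunique() == 2

    def test_degenerate_axes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SeedLotModel(a_range=(0.0, 0.1))
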