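import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from diallelkit import (
    ConfigError,
    DesignError,
    DiallelDesign,
    GeneratorConfig,
    GriffingMethod2,
    TraitMeanTable,
    TraitSettings,
    classify_combiners,
    decompose_means,
    griffing_method2,
    simulate_trial,
)
from diallelkit.datamodel import HIGHER, LOWER

from conftest import random_mean_table


def constrained_ols_oracle(x: np.ndarray):
    """Least-squares fit of x_ij = mu + g_i + g_j + s_ij with the method-2
    constraints (sum g = 0; per array sum_j s_ij + s_ii = 0), solved via a
    stacked linear system — independent of the closed forms."""
    p = x.shape[0]
    pairs = [(i, j) for i in range(p) for j in range(i, p)]
    spos = {pr: k for k, pr in enumerate(pairs)}
    n_par = 1 + p + len(pairs)
    rows, rhs = [], []
    for (i, j) in pairs:
        a = np.zeros(n_par)
        a[0] = 1.0
        a[1 + i] += 1.0
        a[1 + j] += 1.0
        a[1 + p + spos[(i, j)]] = 1.0
        rows.append(a)
        rhs.append(x[i, j])
    c = np.zeros(n_par)
    c[1 : 1 + p] = 1.0  # sum g = 0
    rows.append(c)
    rhs.append(0.0)
    for i in range(p):  # sum_j s_ij + s_ii = 0
        a = np.zeros(n_par)
        for j in range(p):
            a[1 + p + spos[(min(i, j), max(i, j))]] += 1.0
        a[1 + p + spos[(i, i)]] += 1.0
        rows.append(a)
        rhs.append(0.0)
    theta, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    mu = theta[0]
    g = theta[1 : 1 + p]
    s = np.zeros((p, p))
    for (i, j), k in spos.items():
        s[i, j] = s[j, i] = theta[1 + p + k]
    return mu, g, s


@pytest.mark.parametrize("rep", range(20))
def test_closed_form_matches_constrained_ols(design8, rep):
    rng = np.random.default_rng(100 + rep)
    tm = random_mean_table(design8, rng)
    x = tm.matrix()
    mu, g, s, _, _ = decompose_means(x)
    mu_o, g_o, s_o = constrained_ols_oracle(x)
    assert mu == pytest.approx(mu_o, abs=1e-8)
    np.testing.assert_allclose(g, g_o, atol=1e-8)
    np.testing.assert_allclose(s, s_o, atol=1e-8)


@pytest.mark.parametrize("p", [3, 4, 6, 8, 10])
def test_identities_hold_for_any_size(p):
    rng = np.random.default_rng(p)
    x = rng.normal(50, 10, (p, p))
    x = (x + x.T) / 2
    mu, g, s, ss_gca, ss_sca = decompose_means(x)
    scale = np.abs(g).max() + 1e-12
    assert abs(g.sum()) < 1e-9 * max(1.0, scale)
    # saturation: x_ij = mu + g_i + g_j + s_ij, x_ii = mu + 2 g_i + s_ii
    recon = mu + g[:, None] + g[None, :] + s
    np.testing.assert_allclose(recon, x, atol=1e-9 * max(1.0, np.abs(x).max()))
    # per-array SCA constraint
    np.testing.assert_allclose(s.sum(axis=1) + np.diag(s), 0.0, atol=1e-8)
    # SS decomposition of total entry-mean SS
    iu = np.triu_indices(p)
    total = (x[iu] ** 2).sum() - x[iu].sum() ** 2 * 2 / (p * (p + 1))
    assert ss_gca + ss_sca == pytest.approx(total, rel=1e-9)
    assert ss_gca >= 0 and ss_sca >= -1e-9


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    vals=hnp.arrays(
        dtype=np.float64,
        shape=36,
        elements=st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
    )
)
def test_decomposition_identities_property(vals):
    """For any entry-mean table: sum g = 0, saturation holds, and the
    GCA/SCA sums of squares tile the total entry-mean SS."""
    p = 8
    x = np.zeros((p, p))
    x[np.triu_indices(p)] = vals
    x = x + np.triu(x, 1).T
    mu, g, s, ss_gca, ss_sca = decompose_means(x)
    scale = max(1.0, float(np.abs(x).max()))
    assert abs(g.sum()) < 1e-8 * scale
    recon = mu + g[:, None] + g[None, :] + s
    np.fill_diagonal(recon, mu + 2 * g + np.diag(s))
    assert np.abs(recon - x).max() < 1e-8 * scale
    iu = np.triu_indices(p)
    total = (x[iu] ** 2).sum() - x[iu].sum() ** 2 / 36.0
    assert abs(ss_gca + ss_sca - total) < 1e-7 * max(1.0, abs(total))


def test_df_and_study_layout(small_panel):
    from diallelkit import rcbd_anova

    table = rcbd_anova(small_panel, "grain_yield", "well_watered")
    ca = griffing_method2(
        small_panel.entry_means("grain_yield", "well_watered"),
        plot_error_ms=table.error_ms, error_df=table.error_df, r=3,
    )
    assert ca.df_gca == 7
    assert ca.df_sca == 28
    assert ca.df_error == 70
    assert ca.ms_error_term == pytest.approx(table.error_ms / 3)
    assert ca.gca_sca_ratio == pytest.approx(ca.ms_gca / ca.ms_sca)
    # Baker's predictability ratio lies in (0, 1] and is not the default ratio
    assert 0 < ca.baker_ratio <= 1


def test_constant_means_give_null_effects(design8):
    entries = design8.entries()
    means = pd.Series(
        7.5, index=pd.MultiIndex.from_tuples(entries, names=["parent_a", "parent_b"])
    )
    tm = TraitMeanTable(trait="t", regime="r", means=means, design=design8)
    ca = griffing_method2(tm, plot_error_ms=1.0, error_df=70, r=3)
    assert ca.mu_hat == pytest.approx(7.5)
    assert np.abs(ca.gca.to_numpy()).max() < 1e-12
    assert np.abs(ca.sca.to_numpy()).max() < 1e-12
    assert ca.ss_gca == pytest.approx(0, abs=1e-9)
    assert ca.ss_sca == pytest.approx(0, abs=1e-9)


def test_effects_equivariance_under_affine_maps(design8):
    rng = np.random.default_rng(5)
    tm = random_mean_table(design8, rng)
    ca = griffing_method2(tm, plot_error_ms=2.0, error_df=70, r=3)
    shifted = TraitMeanTable("t", "r", tm.means + 10.0, design8)
    ca_shift = griffing_method2(shifted, plot_error_ms=2.0, error_df=70, r=3)
    assert ca_shift.mu_hat == pytest.approx(ca.mu_hat + 10.0)
    np.testing.assert_allclose(ca_shift.gca, ca.gca, atol=1e-9)
    np.testing.assert_allclose(ca_shift.sca, ca.sca, atol=1e-9)
    scaled = TraitMeanTable("t", "r", tm.means * 3.0, design8)
    ca_scale = griffing_method2(scaled, plot_error_ms=2.0 * 9, error_df=70, r=3)
    assert ca_scale.mu_hat == pytest.approx(3 * ca.mu_hat)
    np.testing.assert_allclose(ca_scale.gca, 3 * ca.gca, rtol=1e-9)
    assert ca_scale.ss_gca == pytest.approx(9 * ca.ss_gca, rel=1e-9)
    assert ca_scale.f_gca == pytest.approx(ca.f_gca, rel=1e-9)


def test_standard_errors_and_lsd_reproduce_printed_values(design8):
    """With error term 1.38 on df 70 and r=3, the per-effect LSDs match the
    published grain-yield values (0.69 for g_i, 2.12 for s_ij at alpha 0.05)."""
    rng = np.random.default_rng(0)
    tm = random_mean_table(design8, rng)
    # plot-error MS whose mean-scale error term is 1.38
    ca = griffing_method2(tm, plot_error_ms=1.38 * 3, error_df=70, r=3)
    assert ca.ms_error_term == pytest.approx(1.38)
    assert ca.se_gi == pytest.approx(np.sqrt(1.38 * 7 / (8 * 10)), rel=1e-12)
    assert round(ca.lsd_gi_05, 2) == 0.69
    assert round(ca.lsd_gi_01, 2) == 0.92
    assert round(ca.lsd_sij_05, 2) == 2.12
    assert ca.se_sii == pytest.approx(np.sqrt(1.38 * 8 * 7 / (9 * 10)), rel=1e-12)
    assert ca.se_gi_diff == pytest.approx(np.sqrt(2 * 1.38 / 10), rel=1e-12)


def test_classify_combiners_rules(design8):
    rng = np.random.default_rng(1)
    tm = random_mean_table(design8, rng)
    ca = griffing_method2(tm, plot_error_ms=1.38 * 3, error_df=70, r=3)
    # overwrite effects to probe the labelling rules directly
    ca.gca[:] = 0.0
    ca.gca["P8"] = 2.28       # above LSD 0.69 -> favorable for higher-is-better
    ca.gca["P2"] = -4.85      # favorable only when lower is better
    ca.gca["P1"] = ca.lsd_gi_05  # exactly at the LSD -> not significant
    labels, _ = classify_combiners(ca, alpha=0.05, direction=HIGHER)
    assert labels["P8"] == "favorable-significant"
    assert labels["P2"] == "unfavorable-significant"
    assert labels["P1"] == "non-significant"
    labels_low, _ = classify_combiners(ca, alpha=0.05, direction=LOWER)
    assert labels_low["P2"] == "favorable-significant"
    assert labels_low["P8"] == "unfavorable-significant"
    with pytest.raises(ConfigError):
        classify_combiners(ca, alpha=0.10)


def test_noiseless_simulation_recovers_truth(noiseless_config):
    from diallelkit import rcbd_anova

    panel, truth = simulate_trial(noiseless_config)
    for regime in panel.design.regimes:
        table = rcbd_anova(panel, "grain_yield", regime)
        ca = griffing_method2(
            panel.entry_means("grain_yield", regime),
            plot_error_ms=table.error_ms, error_df=table.error_df, r=3,
        )
        t = truth.truth("grain_yield", regime)
        assert np.abs(ca.gca.to_numpy() - t.gca).max() < 1e-9
        assert np.abs(ca.sca.to_numpy() - t.sca).max() < 1e-9
        assert abs(ca.mu_hat - t.mu) < 1e-9


def test_gca_rmse_shrinks_with_replication(design8):
    """RMSE(g) should scale like 1/sqrt(r) at fixed plot-error variance."""
    from diallelkit import rcbd_anova

    rs = [2, 3, 5, 10]
    rmse = {}
    n_rep = 40
    for r in rs:
        design = DiallelDesign(design8.parent_ids, n_blocks=r, regimes=("ww",))
        errs = []
        for rep in range(n_rep):
            cfg = GeneratorConfig(
                design=design,
                traits={"y": TraitSettings(mu=30, sigma_gca=1.0, sigma_sca=0.8,
                                           sigma_error=2.0)},
                seed=10_000 + rep,
            )
            panel, truth = simulate_trial(cfg)
            table = rcbd_anova(panel, "y", "ww")
            ca = griffing_method2(
                panel.entry_means("y", "ww"),
                plot_error_ms=table.error_ms, error_df=table.error_df, r=r,
            )
            errs.append(np.mean((ca.gca.to_numpy() - truth.truth("y", "ww").gca) ** 2))
        rmse[r] = np.sqrt(np.mean(errs))
    # monotone decrease, and the r=2 -> r=10 drop tracks sqrt(5) within 25%
    assert rmse[2] > rmse[3] > rmse[5] > rmse[10]
    assert rmse[2] / rmse[10] == pytest.approx(np.sqrt(5), rel=0.25)


def test_too_few_parents_and_bad_error_rejected():
    d = DiallelDesign(parent_ids=("A", "B"), n_blocks=3, regimes=("r",))
    entries = d.entries()
    means = pd.Series(
        [1.0, 2.0, 3.0],
        index=pd.MultiIndex.from_tuples(entries, names=["parent_a", "parent_b"]),
    )
    tm = TraitMeanTable("t", "r", means, d)
    with pytest.raises(DesignError):
        griffing_method2(tm, plot_error_ms=1.0, error_df=4, r=3)


def test_negative_error_ms_rejected(design8):
    tm = random_mean_table(design8, np.random.default_rng(0))
    with pytest.raises(ConfigError):
        griffing_method2(tm, plot_error_ms=-1.0, error_df=70, r=3)


def test_estimator_api(design8):
    tm = random_mean_table(design8, np.random.default_rng(2))
    est = GriffingMethod2(n_blocks=3)
    assert est.get_params() == {"n_blocks": 3}
    est.fit(tm, plot_error_ms=2.0, error_df=70)
    assert est.gca_.shape == (8,)
    assert est.sca_.shape == (8, 8)
    assert est.result_.trait == "t"
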