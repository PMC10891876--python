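"""PCA, Kruskal-Wallis/BH, volcano contrasts, label selection and biomass
normalisation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cyanopept.deconvolution import impute_zeros, transform_scale
from cyanopept.model import Feature, FeatureTable, SampleMeta
from cyanopept.stats import (
    StatsConfig,
    kw_bh,
    normalize_biomass,
    run_pca,
    select_loading_labels,
    volcano,
)


def table_from_matrix(values, strains, biomass=None, prefix="f"):
    """values: features x samples array; strains: per-sample labels."""
    values = np.asarray(values, dtype=float)
    samples = []
    counts = {}
    for k, strain in enumerate(strains):
        counts[strain] = counts.get(strain, 0) + 1
        samples.append(
            SampleMeta(
                f"{strain}_r{counts[strain]}", strain, counts[strain],
                dry_biomass_mg=None if biomass is None else biomass[k],
            )
        )
    features = [
        Feature(f"{prefix}{i}", 600.0 + i, 3.0,
                {s.sample_id: float(values[i, k]) for k, s in enumerate(samples)})
        for i in range(values.shape[0])
    ]
    return FeatureTable.from_records(features, samples)


# -- PCA --------------------------------------------------------------------


def test_collinear_samples_put_all_variance_on_pc1():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    values = np.vstack([2 * t, -1 * t, 0.5 * t])
    values = values - values.mean(axis=1, keepdims=True)
    scaled = pd.DataFrame(values, index=["f0", "f1", "f2"],
                          columns=["s1", "s2", "s3", "s4"])
    pca = run_pca(scaled)
    assert pca.variance_pct[0] == pytest.approx(100.0)


def test_full_decomposition_reconstructs_the_centred_matrix():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(8, 6))
    values -= values.mean(axis=1, keepdims=True)
    scaled = pd.DataFrame(values, index=[f"f{i}" for i in range(8)],
                          columns=[f"s{j}" for j in range(6)])
    pca = run_pca(scaled)
    recon = pca.scores.to_numpy() @ pca.loadings.to_numpy().T
    np.testing.assert_allclose(recon, values.T, atol=1e-8)
    # variance fractions are non-increasing
    assert all(np.diff(pca.variance_pct) <= 1e-9)
    # sign convention: largest-magnitude loading of each PC is positive
    for col in pca.loadings.columns:
        v = pca.loadings[col].to_numpy()
        assert v[np.argmax(np.abs(v))] >= 0


def test_variance_fractions_invariant_under_sample_reordering():
    rng = np.random.default_rng(4)
    values = rng.normal(size=(6, 8))
    values -= values.mean(axis=1, keepdims=True)
    cols = [f"s{j}" for j in range(8)]
    scaled = pd.DataFrame(values, index=[f"f{i}" for i in range(6)], columns=cols)
    shuffled = scaled[cols[::-1]]
    shuffled = shuffled - shuffled.to_numpy().mean(axis=1, keepdims=True)
    np.testing.assert_allclose(
        run_pca(scaled).variance_pct, run_pca(shuffled).variance_pct, atol=1e-9
    )


def test_strains_separate_in_pc_space_on_strain_specific_profiles():
    from sklearn.metrics import silhouette_score

    rng = np.random.default_rng(5)
    n_strains, reps, per_strain = 6, 4, 5
    strains = [f"g{k}" for k in range(n_strains) for _ in range(reps)]
    values = np.full((n_strains * per_strain, n_strains * reps), 1e4)
    for k in range(n_strains):
        rows = slice(k * per_strain, (k + 1) * per_strain)
        cols = slice(k * reps, (k + 1) * reps)
        values[rows, cols] = 1e7
    values = values * rng.lognormal(0, 0.2, values.shape)
    table = table_from_matrix(values, strains)
    pca = run_pca(transform_scale(table))
    coords = pca.scores[["PC1", "PC2"]].to_numpy()
    assert silhouette_score(coords, strains) > 0


def test_pca_input_validation():
    scaled = pd.DataFrame([[0.0], [0.0]], index=["f0", "f1"], columns=["s1"])
    with pytest.raises(ValueError):
        run_pca(scaled)


# -- Kruskal-Wallis / BH ----------------------------------------------------


def test_constant_feature_has_zero_statistic_and_p_one():
    values = np.vstack([np.ones(8) * 5.0, np.r_[np.ones(4), 2 * np.ones(4)] * 1e6])
    table = table_from_matrix(values, ["a"] * 4 + ["b"] * 4)
    out = kw_bh(table)
    assert out.loc["f0", "statistic"] == 0.0
    assert out.loc["f0", "pvalue"] == 1.0
    assert not out.loc["f0", "significant"]
    assert out.loc["f1", "significant"] or out.loc["f1", "p_adj"] >= 0.01


def test_kw_requires_replicated_strains():
    values = np.ones((2, 3))
    table = table_from_matrix(values, ["a", "a", "b"])
    with pytest.raises(ValueError, match="fewer than two replicates"):
        kw_bh(table)


def test_bh_adjustment_matches_hand_stepup_on_six_pvalues():
    # statsmodels fdr_bh against the textbook step-up computed by hand:
    # raw     [.001, .002, .01, .02, .5, .9]
    # adjusted [.006, .006, .02, .03, .6, .9]
    from statsmodels.stats.multitest import multipletests

    raw = np.array([0.001, 0.002, 0.01, 0.02, 0.5, 0.9])
    _, adj, _, _ = multipletests(raw, method="fdr_bh")
    np.testing.assert_allclose(adj, [0.006, 0.006, 0.02, 0.03, 0.6, 0.9])


def test_adjusted_p_never_below_raw_and_flags_permutation_invariant():
    rng = np.random.default_rng(2)
    values = rng.lognormal(10, 1, size=(40, 12))
    table = table_from_matrix(values, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    out = kw_bh(table)
    assert (out["p_adj"] >= out["pvalue"] - 1e-12).all()
    perm = rng.permutation(40)
    shuffled = table.subset_features([f"f{i}" for i in perm])
    out2 = kw_bh(shuffled)
    assert (
        out.loc[out2.index, "significant"] == out2["significant"]
    ).all()


def test_null_simulation_never_over_rejects_at_study_scale():
    """At the quadruplicate design the chi-square Kruskal-Wallis level is
    conservative; the raw rejection rate on null data must stay at or
    below the binomial band around alpha (calibration at larger replicate
    counts is checked in the acceptance suite)."""
    rng = np.random.default_rng(77)
    values = rng.lognormal(10, 1, size=(500, 24))
    table = table_from_matrix(values, [f"g{k}" for k in range(6) for _ in range(4)])
    out = kw_bh(table)
    n_reject = int((out["pvalue"] < 0.01).sum())
    assert n_reject <= 11
    # and BH on a global null flags (essentially) nothing
    assert int(out["significant"].sum()) <= 1


# -- volcano ----------------------------------------------------------------


def test_equal_means_give_zero_log2_fold_change():
    values = np.vstack([np.r_[np.ones(4), np.ones(8)] * 100.0])
    table = table_from_matrix(values, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    out = volcano(table)
    assert out["log2_fc"].abs().max() == pytest.approx(0.0)
    assert (out["pvalue"] == 1.0).all()  # zero variance everywhere


def test_tenfold_mean_gives_log2_of_ten():
    rng = np.random.default_rng(1)
    a = 1000.0 * (1 + 0.01 * rng.normal(size=4))
    b = 100.0 * (1 + 0.01 * rng.normal(size=8))
    values = np.r_[a, b][None, :]
    # force exact 10x means
    values[0, :4] *= 1000.0 / values[0, :4].mean()
    values[0, 4:] *= 100.0 / values[0, 4:].mean()
    table = table_from_matrix(values, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    out = volcano(table)
    fc = out.set_index("strain").loc["a", "log2_fc"]
    assert fc == pytest.approx(math.log2(10.0), abs=1e-9)


def test_welch_pvalues_match_textbook_formula_on_a_4v20_toy():
    rng = np.random.default_rng(3)
    a = rng.lognormal(10, 0.3, 4)
    b = rng.lognormal(9.5, 0.4, 20)
    values = np.r_[a, b][None, :]
    table = table_from_matrix(values, ["a"] * 4 + ["b"] * 10 + ["c"] * 10)
    out = volcano(table).set_index("strain")
    # textbook Welch: t = (xa - xb)/sqrt(sa^2/na + sb^2/nb), Satterthwaite df
    va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 20
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 19)
    p = 2 * sps.t.sf(abs(t), df)
    assert out.loc["a", "pvalue"] == pytest.approx(p, rel=1e-9)


# -- label selection --------------------------------------------------------


def _pca_stub(loadings):
    from cyanopept.stats import PcaResult

    load = pd.DataFrame(loadings, columns=["PC1", "PC2"])
    load.index = [f"f{i}" for i in range(len(load))]
    return PcaResult(
        scores=pd.DataFrame(np.zeros((2, 2)), columns=["PC1", "PC2"]),
        loadings=load,
        variance_pct=np.array([60.0, 40.0]),
    )


def test_fully_disjoint_selections_give_strains_times_three_plus_quadrants():
    # 6 strains x 3 + 4 quadrants x 3 = 30 labels when selections are disjoint
    rng = np.random.default_rng(0)
    n = 60
    volcano_rows = []
    for s in range(6):
        for i in range(n):
            volcano_rows.append(
                {"feature_id": f"f{i}", "strain": f"g{s}",
                 # strain s "owns" features 10s..10s+2 with tiny p
                 "pvalue": 1e-6 if 10 * s <= i < 10 * s + 3 else 0.5,
                 "log2_fc": 1.0}
            )
    loadings = np.zeros((n, 2))
    signs = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    # quadrant q "owns" features 3+10q..5+10q with huge arrows, disjoint from
    # every strain pick (10s..10s+2); the rest get small mixed-sign arrows
    for i in range(n):
        sx, sy = signs[i % 4]
        loadings[i] = (0.01 * sx, 0.01 * sy)
    for q in range(4):
        for j in range(3):
            i = 3 + 10 * q + j
            loadings[i] = (signs[q][0] * (5 + j), signs[q][1] * (5 + j))
    labels = select_loading_labels(_pca_stub(loadings), pd.DataFrame(volcano_rows))
    assert len(labels) == 30


def test_duplicate_selections_count_once_and_match_brute_force():
    volcano_rows = [
        {"feature_id": f"f{i}", "strain": s, "pvalue": p, "log2_fc": fc}
        for s, picks in {
            "a": [(0, 1e-9, 2.0), (1, 1e-8, 1.0), (2, 1e-7, 1.0), (3, 0.9, 0.1)],
            "b": [(0, 1e-9, 2.0), (1, 0.5, 1.0), (2, 1e-6, 1.0), (3, 1e-5, 0.1)],
        }.items()
        for i, p, fc in picks
    ]
    loadings = np.array([[3.0, 3.0], [-2.0, 2.0], [-1.0, -1.0], [0.5, -0.5]])
    labels = select_loading_labels(
        _pca_stub(loadings), pd.DataFrame(volcano_rows), StatsConfig(label_top_t=2,
                                                                     label_top_arrows=1)
    )
    # brute force: strain a -> f0, f1; strain b -> f0, f2; quadrants -> all 4
    assert labels == ["f0", "f1", "f2", "f3"]


# -- biomass normalisation --------------------------------------------------


def test_biomass_normalisation_hand_values_and_monotonicity():
    values = np.array([[1000.0, 1000.0, 1000.0, 1000.0]])
    table = table_from_matrix(values, ["a", "a", "b", "b"],
                              biomass=[2.0, 4.0, 8.0, 10.0])
    normalized, summary = normalize_biomass(table)
    assert normalized.areas.iloc[0, 0] == 500.0
    # equal areas, different biomass: normalized ordered inversely to biomass
    assert list(normalized.areas.iloc[0]) == sorted(
        normalized.areas.iloc[0], reverse=True
    )
    row = summary.set_index(["strain", "feature_id"]).loc[("a", "f0")]
    assert row["mean_area_per_mg"] == pytest.approx((500.0 + 250.0) / 2)
    assert row["sd_area_per_mg"] == pytest.approx(np.std([500.0, 250.0], ddof=1))


def test_biomass_normalisation_requires_biomass_everywhere():
    values = np.ones((1, 4))
    table = table_from_matrix(values, ["a", "a", "b", "b"])
    with pytest.raises(ValueError, match="biomass"):
        normalize_biomass(table)
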