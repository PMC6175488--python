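import numpy as np
import pandas as pd
import pytest

from beakrates import simulate
from beakrates.correlates import (
    SPECIES_PREDICTORS,
    build_clade_table,
    build_species_table,
    clade_distinctiveness,
    clade_tree,
    competition_index,
    pgls,
    range_summaries,
    species_ages,
    vif,
)
from beakrates.rates import CladeRateFit
from beakrates.simulate import GridRangeMap
from beakrates.tree import PhyloTree


# ------------------------------------------------------------------ ages
def test_species_age_is_terminal_branch_length():
    tree = PhyloTree.from_newick("((A:1.0,B:1.0):0.5,(C:0.7,(D:0.3,E:0.3):0.4):0.8);")
    ages = species_ages(tree)
    assert ages == {"A": 1.0, "B": 1.0, "C": 0.7, "D": 0.3, "E": 0.3}


def test_species_ages_invariant_to_label_permutation():
    a = PhyloTree.from_newick("((A:1,B:2):1,(C:3,D:4):1);")
    b = PhyloTree.from_newick("((D:4,C:3):1,(B:2,A:1):1);")
    assert species_ages(a) == species_ages(b)


# ------------------------------------------------------------------ grid toys
def toy_grid(ranges, attrs=None, n_cells=6, island=(), temp=20.0):
    cells = pd.DataFrame(
        {
            "cell_id": range(n_cells),
            "x": range(n_cells),
            "y": [0] * n_cells,
            "area_km2": 1.0,
            "is_island": [c in island for c in range(n_cells)],
            "temperature": temp,
            "uvb": 100.0,
        }
    )
    species = list(ranges)
    if attrs is None:
        attrs = pd.DataFrame(
            {"family": "fam1", "diet": "diet1", "foraging": "forage1",
             "migratory": "resident"},
            index=species,
        )
    return GridRangeMap(cells=cells, ranges=ranges, species_attrs=attrs)


def test_competition_zero_when_alone():
    grid = toy_grid({"A": {0, 1}})
    assert competition_index(grid, "A") == 0.0


def test_competition_half_when_one_rival_in_one_of_two_cells():
    grid = toy_grid({"A": {0, 1}, "B": {0}})
    assert competition_index(grid, "A") == pytest.approx(0.5)  # mean of (1, 0)


def test_competition_requires_matching_guild_and_family():
    attrs = pd.DataFrame(
        {
            "family": ["fam1", "fam2", "fam1", "fam1"],
            "diet": ["diet1", "diet1", "diet2", "diet1"],
            "foraging": ["forage1", "forage1", "forage1", "forage2"],
            "migratory": "resident",
        },
        index=["A", "B", "C", "D"],
    )
    grid = toy_grid({"A": {0}, "B": {0}, "C": {0}, "D": {0}}, attrs)
    assert competition_index(grid, "A") == 0.0


def test_competition_identical_ranges_same_guild():
    grid = toy_grid({"A": {0, 1, 2, 3}, "B": {0, 1, 2, 3}})
    assert competition_index(grid, "A") == pytest.approx(1.0)
    assert competition_index(grid, "B") == pytest.approx(1.0)


def test_competition_bounded_by_species_count():
    grid = toy_grid({s: {0, 1} for s in "ABCDE"})
    for s in "ABCDE":
        assert competition_index(grid, s) <= 4


def test_range_summaries_island_share_and_means():
    grid = toy_grid({"A": {0, 1, 2, 3}}, island=(2,))
    out = range_summaries(grid, "A")
    assert out["range_size"] == pytest.approx(4.0)
    assert out["island_proportion"] == pytest.approx(0.25)
    assert out["mean_temperature"] == pytest.approx(20.0)
    with pytest.raises(KeyError):
        range_summaries(grid, "nope")


# -------------------------------------------------------------- distinctiveness
def test_distinctiveness_zero_for_whole_morphospace():
    traits = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 3)),
                          index=[f"s{i}" for i in range(10)])
    assert clade_distinctiveness(traits, list(traits.index)) == pytest.approx(0.0)


def test_distinctiveness_is_three_four_five():
    traits = pd.DataFrame(
        {"PC1": [3.0, 3.0, -3.0, -3.0], "PC2": [4.0, 4.0, -4.0, -4.0]},
        index=list("abcd"),
    )  # global centroid at the origin, clade centroid at (3, 4)
    assert clade_distinctiveness(traits, ["a", "b"]) == pytest.approx(5.0)


def test_distinctiveness_translation_invariant():
    rng = np.random.default_rng(1)
    traits = pd.DataFrame(rng.standard_normal((8, 2)), index=[f"s{i}" for i in range(8)])
    d1 = clade_distinctiveness(traits, ["s0", "s1", "s2"])
    d2 = clade_distinctiveness(traits + 17.5, ["s0", "s1", "s2"])
    assert d1 == pytest.approx(d2, abs=1e-9)


# ------------------------------------------------------------------- tables
@pytest.fixture(scope="module")
def small_world():
    tree = simulate.simulate_tree(24, 1.0, seed=5)
    species = tree.tip_labels()
    grid = simulate.simulate_range_grid(
        24, (8, 8), occupancy=0.2, seed=6, species=species
    )
    rng = np.random.default_rng(7)
    extra = pd.DataFrame(
        {
            "body_mass": rng.lognormal(4, 1, 24),
            "generation_length": rng.lognormal(1, 0.3, 24),
            "measurement_error": rng.uniform(0.01, 0.05, 24),
            "clade": [simulate.assign_clades(tree, 3)[s] for s in species],
            "migratory": "resident",
        },
        index=species,
    )
    tip_rates = {s: float(r) for s, r in zip(species, rng.lognormal(0, 0.5, 24))}
    return tree, grid, extra, tip_rates


def test_species_table_columns_and_log_transforms(small_world):
    tree, grid, extra, tip_rates = small_world
    table, response = build_species_table(tree, tip_rates, grid, extra)
    assert list(table.columns) == SPECIES_PREDICTORS + ["clade", "migratory"]
    assert len(table) == 24
    s = table.index[0]
    assert table.loc[s, "log_body_mass"] == pytest.approx(np.log(extra.loc[s, "body_mass"]))
    assert table.loc[s, "log_n_competitors"] == pytest.approx(
        np.log1p(competition_index(grid, s))
    )
    assert response[s] == pytest.approx(np.log(tip_rates[s]))


def test_species_table_drops_species_missing_from_grid(small_world):
    tree, grid, extra, tip_rates = small_world
    partial = GridRangeMap(
        cells=grid.cells,
        ranges={s: c for s, c in grid.ranges.items() if s != tree.tip_labels()[0]},
        species_attrs=grid.species_attrs,
    )
    table, _ = build_species_table(tree, tip_rates, partial, extra)
    assert len(table) == 23
    assert tree.tip_labels()[0] not in table.index


def test_clade_table_respects_min_size_and_reads_ages(small_world):
    tree, grid, extra, tip_rates = small_world
    clades = simulate.assign_clades(tree, 3)
    sizes = pd.Series(clades).value_counts()
    traits = pd.DataFrame(
        np.random.default_rng(8).standard_normal((24, 2)),
        index=tree.tip_labels(), columns=["PC1", "PC2"],
    )
    fit = CladeRateFit(
        rates={lab: 1.0 for lab in sizes.index}, loglik=0.0,
        loglik_single_rate=0.0, sigma=np.eye(2), alpha=np.zeros(2), dropped=[],
    )
    min_size = int(sizes.iloc[0])  # keep only the largest clade
    table = build_clade_table(tree, fit, traits, grid, clades, min_size=min_size)
    assert len(table) == (sizes >= min_size).sum()
    lab = table.index[0]
    members = [s for s, l in clades.items() if l == lab]
    mrca = tree.mrca(members)
    expect_age = tree.depth() - tree.node_depths()[mrca]
    assert table.loc[lab, "age"] == pytest.approx(expect_age)
    assert table.loc[lab, "richness"] == len(members)
    comps = [competition_index(grid, s) for s in members]
    assert table.loc[lab, "mean_competition"] == pytest.approx(np.mean(comps))


def test_clade_tree_preserves_between_clade_divergences():
    tree = PhyloTree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:2,F:2):1);")
    clades = {"A": "x", "B": "x", "C": "y", "D": "y", "E": "z", "F": "z"}
    ct = clade_tree(tree, clades)
    assert sorted(ct.tip_labels()) == ["x", "y", "z"]
    assert ct.mrca(["x", "y"]) != ct.mrca(["x", "z"])


# --------------------------------------------------------------------- PGLS
def test_pgls_lambda_zero_equals_ols():
    statsmodels = pytest.importorskip("statsmodels.api")
    tree = simulate.simulate_tree(40, 1.0, seed=9)
    table, resp, _ = simulate.simulate_predictors(tree, {"log_age": -0.5}, seed=1)
    fit = pgls(resp, table, tree, SPECIES_PREDICTORS, lam=0.0)
    X = statsmodels.add_constant(table[SPECIES_PREDICTORS].to_numpy(float))
    ols = statsmodels.OLS(resp.to_numpy(), X).fit()
    np.testing.assert_allclose(fit.params["slope"].to_numpy(), ols.params, atol=1e-8)
    np.testing.assert_allclose(fit.params["se"].to_numpy(), ols.bse, atol=1e-8)
    np.testing.assert_allclose(fit.params["p"].to_numpy(), ols.pvalues, atol=1e-8)


def test_pgls_worked_example_matches_dense_gls_oracle(balanced4):
    # printed tree ((A:1,B:1):1,(C:1,D:1):1), response (1,2,4,5),
    # predictor (0,1,2,3), lambda = 1: dense-oracle slope 9/7
    resp = pd.Series([1.0, 2.0, 4.0, 5.0], index=["A", "B", "C", "D"])
    design = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}, index=["A", "B", "C", "D"])
    fit = pgls(resp, design, balanced4, ["x"], lam=1.0)
    assert fit.coef("x") == pytest.approx(9 / 7, abs=1e-10)
    assert fit.coef("(Intercept)") == pytest.approx(15 / 14, abs=1e-10)


def test_pgls_ml_lambda_attains_profile_optimum():
    tree = simulate.simulate_tree(60, 1.0, seed=10)
    for rep in range(5):
        table, resp, _ = simulate.simulate_predictors(
            tree, {"log_age": -0.4}, lam=0.5, noise_sd=0.6, seed=20 + rep
        )
        fit = pgls(resp, table, tree, ["log_age", "log_body_mass"])
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            fixed = pgls(resp, table, tree, ["log_age", "log_body_mass"], lam=lam)
            assert fit.loglik >= fixed.loglik - 1e-6


def test_pgls_interactions_expand_to_product_terms():
    tree = simulate.simulate_tree(40, 1.0, seed=11)
    table, resp, _ = simulate.simulate_predictors(tree, {"log_age": -0.5}, seed=2)
    fit = pgls(
        resp, table, tree, ["log_age", "migratory"],
        interactions=[("log_age", "migratory")], lam=0.0,
    )
    assert any(":" in t for t in fit.terms)
    assert fit.df_resid == fit.n - len(fit.terms)


def test_pgls_reports_rank_deficiency():
    tree = simulate.simulate_tree(20, 1.0, seed=12)
    table, resp, _ = simulate.simulate_predictors(tree, {}, seed=3)
    table = table.copy()
    table["dup"] = table["log_age"]
    with pytest.raises(ValueError, match="aliased"):
        pgls(resp, table, tree, ["log_age", "dup"], lam=0.0)


# ---------------------------------------------------------------------- VIF
def test_vif_orthogonal_predictors_are_one():
    raw = np.random.default_rng(0).standard_normal((30, 3))
    raw -= raw.mean(axis=0)  # centered, so orthogonality survives the intercept
    X = pd.DataFrame(np.linalg.qr(raw)[0], columns=list("abc"))
    assert np.allclose(vif(X), 1.0, atol=1e-9)


def test_vif_correlated_pair_matches_closed_form():
    rng = np.random.default_rng(1)
    n = 100_000
    z = rng.standard_normal(n)
    x1 = z
    x2 = 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(n)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    out = vif(X)
    r2 = np.corrcoef(x1, x2)[0, 1] ** 2
    np.testing.assert_allclose(out, 1 / (1 - r2), rtol=1e-9)
    assert out["x1"] == pytest.approx(1 / (1 - 0.81), rel=0.02)


def test_vif_duplicate_column_is_infinite():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(50)
    out = vif(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(50)}))
    assert np.isinf(out["a"]) and np.isinf(out["b"])
    assert np.isfinite(out["c"])


def test_vif_agrees_with_statsmodels():
    smo = pytest.importorskip("statsmodels.stats.outliers_influence")
    rng = np.random.default_rng(3)
    X = rng.standard_normal((200, 4))
    X[:, 1] += 0.7 * X[:, 0]
    df = pd.DataFrame(X, columns=list("abcd"))
    mine = vif(df)
    import statsmodels.api as sm
    Xc = sm.add_constant(X)
    theirs = [
        smo.variance_inflation_factor(Xc, i + 1) for i in range(4)
    ]
    np.testing.assert_allclose(mine.to_numpy(), theirs, rtol=1e-8)
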