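"""Species- and clade-level correlates of evolutionary rates.

Builds the predictor tables (species age, competition index, range
summaries, morphospace distinctiveness) and fits phylogenetic generalized
least squares with Pagel's lambda, including categorical interactions and
variance inflation factors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .simulate import GridRangeMap
from .rates import CladeRateFit
from .tree import PhyloTree

__all__ = [
    "PGLSFit",
    "species_ages",
    "competition_index",
    "range_summaries",
    "clade_distinctiveness",
    "build_species_table",
    "build_clade_table",
    "clade_tree",
    "pgls",
    "vif",
]

log = logging.getLogger(__name__)

SPECIES_PREDICTORS = [
    "log_age",
    "log_body_mass",
    "log_generation_length",
    "mean_temperature",
    "mean_uvb",
    "log_range_size",
    "island_proportion",
    "log_n_competitors",
    "measurement_error",
]

CLADE_PREDICTORS = [
    "log_clade_age",
    "log_distinctiveness",
    "log_richness",
    "log_mean_range_size",
    "island_species_proportion",
    "log_mean_competition",
]


# =====================================================================
# Species-level predictors
# =====================================================================
def species_ages(tree: PhyloTree) -> dict:
    """Species age = length of the terminal branch leading to each tip."""
    ages = tree.terminal_branch_lengths()
    zero = [s for s, a in ages.items() if a <= 0]
    if zero:
        log.warning("zero-length terminal branches (log transform will fail): %s", zero[:5])
    return ages


def competition_index(grid: GridRangeMap, focal: str) -> float:
    """Mean per-cell count of confamilial same-diet same-foraging co-occupants.

    For each grid cell the focal species occupies, count the other species
    present that share its family, diet class, and foraging class; return the
    mean over the focal's occupied cells.
    """
    if focal not in grid.ranges or not grid.ranges[focal]:
        raise KeyError(f"{focal!r} occupies no grid cells")
    attrs = grid.species_attrs
    fa, di, fo = attrs.loc[focal, ["family", "diet", "foraging"]]
    rivals = [
        sp
        for sp in grid.ranges
        if sp != focal
        and attrs.loc[sp, "family"] == fa
        and attrs.loc[sp, "diet"] == di
        and attrs.loc[sp, "foraging"] == fo
    ]
    cells = grid.ranges[focal]
    counts = [sum(1 for sp in rivals if c in grid.ranges[sp]) for c in cells]
    return float(np.mean(counts))


def range_summaries(grid: GridRangeMap, focal: str) -> dict:
    """Range size (summed cell area), island area share, mean climate."""
    if focal not in grid.ranges or not grid.ranges[focal]:
        raise KeyError(f"{focal!r} occupies no grid cells")
    sub = grid.cells.set_index("cell_id").loc[sorted(grid.ranges[focal])]
    area = sub["area_km2"].sum()
    return {
        "range_size": float(area),
        "island_proportion": float(sub.loc[sub["is_island"], "area_km2"].sum() / area),
        "mean_temperature": float(sub["temperature"].mean()),
        "mean_uvb": float(sub["uvb"].mean()),
    }


def clade_distinctiveness(traits: pd.DataFrame, members) -> float:
    """Euclidean distance of the clade centroid to the overall morphospace centre."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    missing = set(members) - set(traits.index)
    if missing:
        raise KeyError(f"members not in trait table: {sorted(missing)[:5]}")
    centre = traits.to_numpy(dtype=float).mean(axis=0)
    clade = traits.loc[members].to_numpy(dtype=float).mean(axis=0)
    return float(np.linalg.norm(clade - centre))


# =====================================================================
# Tables
# =====================================================================
def build_species_table(
    tree: PhyloTree,
    tip_rates: dict,
    grid: GridRangeMap,
    extra: pd.DataFrame,
    log_response: bool = True,
) -> tuple:
    """Assemble the species-level design and its response.

    ``extra`` must supply body_mass, generation_length, measurement_error,
    clade, and migratory per species.  Body mass, generation length, range
    size, species age, and (as log1p, to stay defined at zero) competitor
    counts are log-transformed.  Species missing from any source are dropped
    with a logged count.  Returns ``(table, response)`` with the response the
    (log) tip rate.
    """
    ages = species_ages(tree)
    sources = set(ages) & set(tip_rates) & set(grid.ranges) & set(extra.index)
    species = [s for s in tree.tip_labels() if s in sources]
    dropped = len(set(tree.tip_labels()) - sources)
    if dropped:
        log.info("dropping %d species missing from some source", dropped)
    if not species:
        raise ValueError("no species present in every source")
    rows = []
    for s in species:
        rs = range_summaries(grid, s)
        rows.append(
            {
                "species": s,
                "log_age": math.log(ages[s]),
                "log_body_mass": math.log(extra.loc[s, "body_mass"]),
                "log_generation_length": math.log(extra.loc[s, "generation_length"]),
                "mean_temperature": rs["mean_temperature"],
                "mean_uvb": rs["mean_uvb"],
                "log_range_size": math.log(rs["range_size"]),
                "island_proportion": rs["island_proportion"],
                "log_n_competitors": math.log1p(competition_index(grid, s)),
                "measurement_error": extra.loc[s, "measurement_error"],
                "clade": extra.loc[s, "clade"],
                "migratory": extra.loc[s, "migratory"],
            }
        )
    table = pd.DataFrame(rows).set_index("species")
    resp = np.array([tip_rates[s] for s in species], dtype=float)
    response = pd.Series(np.log(resp) if log_response else resp,
                         index=species, name="rate")
    return table, response


def clade_tree(tree: PhyloTree, clades: dict) -> PhyloTree:
    """Clade-level tree: one representative tip per clade, relabeled.

    The species tree is pruned to the first member of each clade (in tip
    order) and tips take the clade labels, preserving the between-clade
    topology and divergence times for clade-level PGLS.
    """
    rep = {}
    for sp in tree.tip_labels():
        lab = clades.get(sp)
        if lab is not None and lab not in rep:
            rep[lab] = sp
    pruned = tree.retain_tips(rep.values())
    back = {sp: lab for lab, sp in rep.items()}
    pruned.labels = [back.get(l, l) for l in pruned.labels]
    return pruned


def build_clade_table(
    tree: PhyloTree,
    clade_rates: CladeRateFit,
    traits: pd.DataFrame,
    grid: GridRangeMap,
    clades: dict,
    min_size: int = 5,
) -> pd.DataFrame:
    """One row per retained clade with rate, distinctiveness, and predictors.

    Clades below ``min_size`` are dropped.  Age is the height of the clade's
    most recent common ancestor; competition and range size are averaged over
    member species; the island column is the proportion of members whose
    range is mostly (> 0.5) insular.
    """
    groups: dict = {}
    for sp, lab in clades.items():
        groups.setdefault(lab, []).append(sp)
    depths = tree.node_depths()
    depth = tree.depth()
    rows = []
    for lab in sorted(groups):
        members = groups[lab]
        if len(members) < min_size:
            log.info("clade %r dropped: %d < %d members", lab, len(members), min_size)
            continue
        if lab not in clade_rates.rates:
            log.info("clade %r has no fitted rate; skipped", lab)
            continue
        mrca = tree.mrca(members)
        comp = [competition_index(grid, s) for s in members if s in grid.ranges]
        rng_sum = [range_summaries(grid, s) for s in members if s in grid.ranges]
        rows.append(
            {
                "clade": lab,
                "rate": clade_rates.rates[lab],
                "distinctiveness": clade_distinctiveness(traits, members),
                "richness": len(members),
                "age": depth - float(depths[mrca]),
                "mean_range_size": float(np.mean([r["range_size"] for r in rng_sum])),
                "island_species_proportion": float(
                    np.mean([r["island_proportion"] > 0.5 for r in rng_sum])
                ),
                "mean_competition": float(np.mean(comp)),
            }
        )
    return pd.DataFrame(rows).set_index("clade")


# =====================================================================
# PGLS
# =====================================================================
@dataclass
class PGLSFit:
    """GLS fit under Pagel's lambda phylogenetic covariance."""

    params: pd.DataFrame        # term, slope, se, t, p
    lam: float
    loglik: float
    df_resid: int
    adj_r2: float
    n: int
    terms: list

    def coef(self, term: str) -> float:
        return float(self.params.loc[term, "slope"])

    def se(self, term: str) -> float:
        return float(self.params.loc[term, "se"])


def _design_matrix(design: pd.DataFrame, predictors, interactions) -> pd.DataFrame:
    """Expand a term spec to a numeric design with treatment contrasts."""
    cols = {}
    for name in predictors:
        col = design[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:  # treatment contrasts, first level is baseline
                cols[f"{name}[{lev}]"] = (col == lev).astype(float)
        else:
            cols[name] = col.astype(float)
    X = pd.DataFrame(cols, index=design.index)
    for a, b in interactions or []:
        for ca in [c for c in X.columns if c == a or c.startswith(f"{a}[")]:
            for cb in [c for c in X.columns if c == b or c.startswith(f"{b}[")]:
                X[f"{ca}:{cb}"] = X[ca] * X[cb]
    X.insert(0, "(Intercept)", 1.0)
    return X


def _gls_fit(y, X, C, lam):
    n, k = X.shape
    V = lam * C + (1 - lam) * np.diag(np.diag(C))
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdet_v = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2_ml) + logdet_v + n)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    return beta, rss, ll, XtX_inv, Xw, yw


def pgls(
    response: pd.Series,
    design: pd.DataFrame,
    tree: PhyloTree,
    predictors: list | None = None,
    interactions: list | None = None,
    lam: float | str = "ML",
) -> PGLSFit:
    """Phylogenetic GLS with Pagel's lambda residual covariance.

    The residual covariance is ``lam * C_offdiag + diag(C)`` with ``C`` the
    Brownian covariance of the tree.  With ``lam="ML"`` the profile
    likelihood is maximized by a 0..1 grid (step 0.01) plus bounded polish;
    ``lam=0`` reduces exactly to OLS.  Categorical predictors expand to
    treatment contrasts; ``interactions`` is a list of (name, name) pairs
    expanded to product terms.  Coefficient tests are two-sided t-tests with
    ``n - k`` degrees of freedom.
    """
    common = [s for s in response.index if s in design.index]
    if set(common) - set(tree.tip_labels()):
        raise ValueError("data contain species absent from the tree")
    sub = design.loc[common]
    mask = sub.notna().all(axis=1) & response.loc[common].notna()
    species = [s for s in common if mask[s]]
    if len(species) < len(common):
        log.info("dropping %d incomplete cases", len(common) - len(species))
    if predictors is None:
        predictors = list(design.columns)
    X = _design_matrix(design.loc[species], predictors, interactions)
    # detect aliased terms before fitting
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        aliased = []
        seen = []
        for j, c in enumerate(X.columns):
            trial = Xv[:, [*seen, j]]
            if np.linalg.matrix_rank(trial) < len(seen) + 1:
                aliased.append(c)
            else:
                seen.append(j)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    y = response.loc[species].to_numpy(dtype=float)
    C = tree.vcv(order=species)

    if lam == "ML":
        grid = np.linspace(0.0, 1.0, 101)
        lls = [
            _gls_fit(y, Xv, C, g)[2] for g in grid
        ]
        best = int(np.argmax(lls))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda g: -_gls_fit(y, Xv, C, g)[2],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-5},
            )
            lam_hat = float(res.x) if -res.fun >= lls[best] else float(grid[best])
        else:
            lam_hat = float(grid[best])
    else:
        lam_hat = float(lam)
        if not 0 <= lam_hat <= 1:
            raise ValueError("lambda must be in [0, 1]")

    beta, rss, ll, XtX_inv, Xw, yw = _gls_fit(y, Xv, C, lam_hat)
    n, k = Xv.shape
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    # GLS R^2 against the intercept-only model at the same lambda
    b0, rss0, *_ = _gls_fit(y, np.ones((n, 1)), C, lam_hat)
    r2 = 1.0 - rss / rss0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df
    params = pd.DataFrame(
        {"slope": beta, "se": se, "t": tvals, "p": pvals}, index=list(X.columns)
    )
    return PGLSFit(
        params=params,
        lam=lam_hat,
        loglik=float(ll),
        df_resid=df,
        adj_r2=float(adj_r2),
        n=n,
        terms=list(X.columns),
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: ``1 / (1 - R2_j)`` per predictor.

    Each predictor is regressed (with intercept) on the others; perfect
    collinearity yields ``inf`` rather than an exception.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 predictors")
    if np.any(X.var(axis=0) <= 0):
        raise ValueError("every predictor needs positive variance")
    out = {}
    for j, name in enumerate(design.columns):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        tss = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
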