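"""Synthetic data generation with known ground truth.

Every input the pipeline consumes can be generated here: ultrametric
birth-death trees, multivariate Brownian traits with planted branch/clade
rate shifts, multi-user landmark markups of a template beak (with the
corruption modes the QC stage must catch), species predictor tables with a
known regression structure under a Pagel-lambda error model, and gridded
occupancy maps with family/diet/foraging labels for the competition index.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .morpho import LandmarkConfiguration, MarkupSet, procrustes_distance
from .rates import BRANCH, CLADE, RateScalarConfiguration
from .tree import PhyloTree

__all__ = [
    "MVBMParams",
    "GridRangeMap",
    "simulate_tree",
    "plant_rate_shifts",
    "simulate_traits",
    "beak_template",
    "simulate_markups",
    "simulate_species_shapes",
    "simulate_predictors",
    "simulate_range_grid",
    "assign_clades",
    "select_clades",
]


# =====================================================================
# Trees
# =====================================================================
def simulate_tree(n_tips: int, birth: float, death: float = 0.0, seed: int = 0) -> PhyloTree:
    """Ultrametric constant-rate birth-death tree with exactly ``n_tips`` tips.

    Uses forward simulation conditioned on the extant tip count (general
    sampling approach, so terminal branches are strictly positive).  Tips are
    relabeled ``t1..tn`` deterministically; the same seed reproduces the same
    Newick string byte for byte.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth <= 0 or death < 0 or death >= birth:
        raise ValueError("need birth > death >= 0")
    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        gsa_ntax=max(2 * n_tips, n_tips + 2),
        rng=rng,
        repeat_until_success=True,
    )
    # deterministic relabeling in leaf-iteration order
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i}"
    dtree.seed_node.edge.length = None
    tree = PhyloTree.from_dendropy(dtree)
    tree.lengths[tree.root] = 0.0
    return tree


def plant_rate_shifts(
    tree: PhyloTree,
    n_branch: int,
    n_clade: int,
    scalar_range: tuple = (2.0, 50.0),
    seed: int = 0,
) -> RateScalarConfiguration:
    """Plant random rate shifts with log-uniform scalars on distinct edges.

    Clade shifts go on internal edges (stem-inclusive scope); branch shifts
    on any edge not already carrying one.  The returned configuration is the
    ground truth for recovery tests.
    """
    lo, hi = scalar_range
    if lo <= 0 or hi < lo:
        raise ValueError("scalar_range must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    edges = [i for i in range(tree.n_nodes) if i != tree.root]
    internal = [e for e in edges if tree.children[e]]
    if n_branch > len(edges) or n_clade > len(internal):
        raise ValueError("more shifts than available edges")
    entries = []
    clade_edges = rng.choice(internal, size=n_clade, replace=False) if n_clade else []
    used = set(int(e) for e in clade_edges)
    for e in clade_edges:
        r = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        entries.append((int(e), CLADE, r))
    free = [e for e in edges if e not in used]
    if n_branch > len(free):
        raise ValueError("more shifts than available edges")
    branch_edges = rng.choice(free, size=n_branch, replace=False) if n_branch else []
    for e in branch_edges:
        r = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        entries.append((int(e), BRANCH, r))
    return RateScalarConfiguration(entries)


# =====================================================================
# Traits
# =====================================================================
@dataclass
class MVBMParams:
    """Multivariate Brownian parameters: root state and per-time covariance."""

    alpha: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        p = self.alpha.size
        if self.sigma.shape != (p, p):
            raise ValueError("sigma must be p x p")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("sigma must be positive-definite")


def simulate_traits(
    tree: PhyloTree,
    scalars: RateScalarConfiguration | None,
    params: MVBMParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate correlated Brownian tip traits along the tree.

    Each edge contributes a ``MVN(0, rate * length * Sigma)`` increment; the
    root sits at ``alpha``.  Returns a species x trait DataFrame in the
    tree's tip order with columns ``PC1..PCp``.
    """
    rng = np.random.default_rng(seed)
    rates = (scalars or RateScalarConfiguration([])).effective_rates(tree)
    p = params.alpha.size
    L = np.linalg.cholesky(params.sigma)
    values = np.zeros((tree.n_nodes, p))
    values[tree.root] = params.alpha
    for node in tree.preorder():
        if node == tree.root:
            continue
        v = rates[node] * tree.lengths[node]
        step = L @ rng.standard_normal(p) * math.sqrt(v)
        values[node] = values[tree.parent[node]] + step
    tips = tree.tip_indices()
    return pd.DataFrame(
        values[tips],
        index=[tree.labels[i] for i in tips],
        columns=[f"PC{j + 1}" for j in range(p)],
    )


# =====================================================================
# Landmark markups
# =====================================================================
def beak_template(n_semi_per_curve: int = 25) -> LandmarkConfiguration:
    """Idealized beak landmark template.

    Four fixed landmarks — beak tip (0), posterior dorsal midline (1), and
    posterior left (2) / right (3) tomial edges — plus three semi-landmark
    curves: the dorsal profile (curve 0, tip to dorsal posterior) and the
    left (curve 1) and right (curve 2) tomial edges, each with
    ``n_semi_per_curve`` points (75 total at the default).
    """
    tip = np.array([1.0, 0.0, 0.0])
    dorsal_post = np.array([0.0, 0.0, 0.35])
    left_post = np.array([0.0, 0.30, 0.0])
    right_post = np.array([0.0, -0.30, 0.0])
    fixed = np.stack([tip, dorsal_post, left_post, right_post])

    s = np.linspace(0, 1, n_semi_per_curve + 2)[1:-1]  # interior points only

    def dorsal(t):
        return np.stack([1 - t, np.zeros_like(t), 0.35 * t**0.8], axis=1)

    def tomial(t, side):
        return np.stack([1 - t, side * 0.30 * t**0.9, -0.02 * np.sin(np.pi * t)], axis=1)

    coords = np.vstack([fixed, dorsal(s), tomial(s, +1), tomial(s, -1)])
    curve_id = np.concatenate(
        [np.full(4, -1), np.full(n_semi_per_curve, 0),
         np.full(n_semi_per_curve, 1), np.full(n_semi_per_curve, 2)]
    )
    return LandmarkConfiguration(
        coords=coords,
        curve_id=curve_id,
        curve_endpoints={0: (0, 1), 1: (0, 2), 2: (0, 3)},
    )


SWAP_TOMIAL_EDGES = "swap_tomial_edges"
SHUFFLE_CURVE_ORDER = "shuffle_curve_order"
OUTLIER_USER = "outlier_user"


def simulate_markups(
    template: LandmarkConfiguration,
    n_users: int,
    noise_sd: float,
    corruptions: list | None = None,
    seed: int = 0,
    specimen_id: str = "specimen",
    outlier_distance: float = 0.35,
) -> tuple:
    """Simulate multi-user markups of a template shape.

    Each user is the template plus iid Gaussian displacement of every
    landmark (sd ``noise_sd``, in template length units).  ``corruptions`` is
    a list of ``{"mode": <mode>, "user": <index>}`` with modes

    * ``swap_tomial_edges`` — exchange the left/right curve blocks (and the
      left/right posterior fixed landmarks);
    * ``shuffle_curve_order`` — permute the semi-landmarks within one curve;
    * ``outlier_user`` — smoothly deform the user's configuration until its
      Procrustes distance to the template reaches ``outlier_distance``.

    Returns ``(MarkupSet, ledger)``; the ledger maps user id to the list of
    applied corruption modes (QC ground truth).
    """
    if n_users < 1:
        raise ValueError("need at least one user")
    corruptions = corruptions or []
    for c in corruptions:
        if not 0 <= c["user"] < n_users:
            raise KeyError(f"corruption references missing user {c['user']}")
    rng = np.random.default_rng(seed)
    users = {}
    ledger = {f"user{u}": [] for u in range(n_users)}
    by_user = {}
    for c in corruptions:
        by_user.setdefault(c["user"], []).append(c["mode"])

    left = template.curve_indices(1)
    right = template.curve_indices(2)
    for u in range(n_users):
        coords = template.coords + noise_sd * rng.standard_normal(template.coords.shape)
        for mode in by_user.get(u, []):
            if mode == SWAP_TOMIAL_EDGES:
                coords[np.concatenate([left, [2]])], coords[np.concatenate([right, [3]])] = (
                    coords[np.concatenate([right, [3]])].copy(),
                    coords[np.concatenate([left, [2]])].copy(),
                )
            elif mode == SHUFFLE_CURVE_ORDER:
                curve = int(rng.integers(len(template.curves())))
                idx = template.curve_indices(template.curves()[curve])
                perm = rng.permutation(idx.size)
                while np.all(perm == np.arange(idx.size)):  # force a real shuffle
                    perm = rng.permutation(idx.size)
                coords[idx] = coords[idx[perm]]
            elif mode == OUTLIER_USER:
                # smooth low-frequency deformation, scaled to the target distance
                t = np.linspace(0, 2 * np.pi, coords.shape[0])
                direction = np.stack(
                    [np.sin(t + rng.uniform(0, 2 * np.pi)) for _ in range(3)], axis=1
                )
                scale = 0.05
                cand = coords + scale * direction
                for _ in range(60):
                    d = procrustes_distance(template.coords, cand)
                    if d >= outlier_distance:
                        break
                    scale *= 1.3
                    cand = coords + scale * direction
                coords = cand
            else:
                raise ValueError(f"unknown corruption mode {mode!r}")
            ledger[f"user{u}"].append(mode)
        users[f"user{u}"] = template.with_coords(coords)
    return MarkupSet(specimen_id=specimen_id, users=users), ledger


def simulate_species_shapes(
    tree: PhyloTree,
    template: LandmarkConfiguration,
    scalars: RateScalarConfiguration | None = None,
    n_modes: int = 8,
    mode_scales: np.ndarray | None = None,
    seed: int = 0,
) -> tuple:
    """Per-species shapes: the template deformed along smooth Brownian modes.

    Latent traits evolve by (variable-rates) Brownian motion on the tree;
    each trait displaces the template along a fixed smooth orthonormal
    deformation mode, with amplitudes ``mode_scales`` (default geometric
    decay ``0.08 * 0.7**j``).  Returns ``(shapes, latent)`` — a species ->
    LandmarkConfiguration dict plus the latent trait DataFrame.
    """
    rng = np.random.default_rng(seed)
    k = template.k
    if mode_scales is None:
        mode_scales = 0.08 * 0.7 ** np.arange(n_modes)
    mode_scales = np.asarray(mode_scales, dtype=float)
    # smooth random modes: low-frequency sinusoids of the point index
    t = np.linspace(0, 1, k)
    basis = []
    for j in range(n_modes):
        freq = 1 + j // 2
        phase = rng.uniform(0, 2 * np.pi, 3)
        m = np.stack([np.sin(2 * np.pi * freq * t + phase[d]) for d in range(3)], axis=1)
        basis.append(m.ravel())
    Q, _ = np.linalg.qr(np.stack(basis, axis=1))
    modes = Q.T.reshape(n_modes, k, 3)

    params = MVBMParams(alpha=np.zeros(n_modes), sigma=np.eye(n_modes))
    latent = simulate_traits(tree, scalars, params, seed=seed + 1)
    shapes = {}
    for sp, row in latent.iterrows():
        disp = np.tensordot(row.to_numpy() * mode_scales, modes, axes=1)
        shapes[sp] = template.with_coords(template.coords + disp)
    return shapes, latent


# =====================================================================
# Predictors
# =====================================================================
def assign_clades(tree: PhyloTree, n_clades: int) -> dict:
    """Split tips into ~``n_clades`` monophyletic groups.

    Repeatedly splits the largest remaining clade at its root until the
    target count is reached.  Returns species -> clade label.
    """
    groups = [tree.root]
    while len(groups) < n_clades:
        sizes = [len(tree.clade_tips(g)) for g in groups]
        i = int(np.argmax(sizes))
        node = groups[i]
        if not tree.children[node]:
            break
        groups = groups[:i] + list(tree.children[node]) + groups[i + 1:]
    out = {}
    for j, g in enumerate(groups):
        for sp in tree.clade_tips(g):
            out[sp] = f"clade{j + 1}"
    return out


def select_clades(tree: PhyloTree, n_clades: int, min_tips: int = 10,
                  max_tips: int = 30) -> dict:
    """Disjoint monophyletic clades of bounded size, leaving a background.

    Walks the tree in preorder and greedily keeps the first ``n_clades``
    disjoint clades whose tip counts fall in ``[min_tips, max_tips]``;
    species outside every chosen clade stay unlabeled (background).  A
    substantive background anchors the global rate scale in relative-rate
    fitting, which is only weakly identified when clades cover nearly every
    edge.  Returns species -> clade label for clade members only.
    """
    chosen, taken = [], set()
    for node in tree.preorder():
        if node == tree.root or not tree.children[node] or node in taken:
            continue
        tips = tree.clade_tips(node)
        if min_tips <= len(tips) <= max_tips:
            sub = set(tree.subtree_nodes(node).tolist())
            if sub & taken:
                continue
            chosen.append(node)
            taken |= sub
            if len(chosen) == n_clades:
                break
    return {
        sp: f"clade{j + 1}"
        for j, node in enumerate(chosen)
        for sp in tree.clade_tips(node)
    }


def simulate_predictors(
    tree: PhyloTree,
    betas: dict,
    lam: float = 0.6,
    noise_sd: float = 0.5,
    seed: int = 0,
    tip_rates: dict | None = None,
    n_clades: int = 4,
) -> tuple:
    """Predictor table with a known PGLS regression structure.

    Numeric predictors (``log_age`` from terminal branch lengths; log body
    mass, log generation length, log range size, island proportion, mean
    temperature, mean UVB, log(1+competitors), measurement error) are drawn
    with realistic positivity.  The response is
    ``design @ betas + eps`` with ``eps ~ MVN(0, noise_sd^2 * V(lambda))``
    where ``V`` is the Pagel-lambda transform of the tree covariance scaled
    to unit diagonal.  Returns ``(table, response, truth)``.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    species = tree.tip_labels()
    n = len(species)
    ages = tree.terminal_branch_lengths()
    table = pd.DataFrame(index=species)
    table["log_age"] = np.log([ages[s] for s in species])
    table["log_body_mass"] = np.log(rng.lognormal(math.log(50.0), 1.2, n))
    table["log_generation_length"] = np.log(rng.lognormal(math.log(3.0), 0.4, n))
    table["log_range_size"] = np.log(rng.lognormal(math.log(2.0e5), 1.5, n))
    table["island_proportion"] = rng.beta(0.3, 2.0, n)
    table["mean_temperature"] = rng.normal(15.0, 8.0, n)
    table["mean_uvb"] = rng.normal(250.0, 60.0, n)
    table["log_n_competitors"] = np.log1p(rng.poisson(1.5, n))
    table["measurement_error"] = np.abs(rng.normal(0.03, 0.01, n))
    clades = assign_clades(tree, n_clades)
    table["clade"] = [clades[s] for s in species]
    table["migratory"] = rng.choice(["resident", "migrant"], size=n, p=[0.75, 0.25])
    if tip_rates is not None:
        table["tip_rate"] = [tip_rates[s] for s in species]

    unknown = set(betas) - set(table.columns)
    if unknown:
        raise ValueError(f"betas refer to unknown predictors: {sorted(unknown)}")
    mu = np.zeros(n)
    for name, b in betas.items():
        mu += b * table[name].to_numpy(dtype=float)
    C = tree.vcv(order=species)
    C = C / np.mean(np.diag(C))
    V = lam * C + (1 - lam) * np.diag(np.diag(C))
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    eps = noise_sd * (L @ rng.standard_normal(n))
    response = pd.Series(mu + eps, index=species, name="response")
    truth = {"betas": dict(betas), "lambda": lam, "noise_sd": noise_sd}
    return table, response, truth


# =====================================================================
# Range grids
# =====================================================================
@dataclass
class GridRangeMap:
    """Equal-area occupancy grid with per-cell environment and guild labels.

    ``cells`` has columns cell_id, x, y, area_km2, is_island, temperature,
    uvb; ``ranges`` maps species to occupied cell-id sets;
    ``species_attrs`` has columns family, diet, foraging, migratory.
    """

    cells: pd.DataFrame
    ranges: dict
    species_attrs: pd.DataFrame

    def __post_init__(self):
        valid = set(self.cells["cell_id"])
        for sp, occ in self.ranges.items():
            bad = set(occ) - valid
            if bad:
                raise ValueError(f"species {sp} occupies unknown cells {sorted(bad)[:5]}")
        if (self.cells["area_km2"] <= 0).any():
            raise ValueError("cell areas must be positive")


def simulate_range_grid(
    n_species: int,
    grid_dims: tuple = (20, 20),
    cell_km: float = 110.0,
    occupancy: float = 0.1,
    n_families: int = 4,
    n_guilds: int = 3,
    island_fraction: float = 0.15,
    seed: int = 0,
    species: list | None = None,
) -> GridRangeMap:
    """Random contiguous species ranges on an abstract equal-area grid.

    Ranges grow by seeded flood-fill from a random cell to a target size
    drawn around ``occupancy`` x grid size (log-normal spread), giving
    realistic spatial autocorrelation for the competition index.  Cells carry
    island flags (Bernoulli ``island_fraction``) and smooth synthetic
    temperature/UVB fields; species carry family, diet, and foraging labels.
    """
    nx, ny = grid_dims
    if nx < 1 or ny < 1:
        raise ValueError("grid dims must be >= 1")
    if not 0 < occupancy <= 1:
        raise ValueError("occupancy must be in (0, 1]")
    if not 0 <= island_fraction <= 1:
        raise ValueError("island_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    total = nx * ny
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xs, ys = xs.ravel(), ys.ravel()
    lat = ys / max(ny - 1, 1)
    temperature = 27.0 - 22.0 * lat + 1.5 * np.sin(2 * np.pi * xs / max(nx, 1)) \
        + rng.normal(0, 0.5, total)
    uvb = 320.0 - 180.0 * lat + 10.0 * np.cos(2 * np.pi * xs / max(nx, 1)) \
        + rng.normal(0, 5.0, total)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(total),
            "x": xs,
            "y": ys,
            "area_km2": cell_km**2,
            "is_island": rng.random(total) < island_fraction,
            "temperature": temperature,
            "uvb": uvb,
        }
    )
    if species is None:
        species = [f"t{i + 1}" for i in range(n_species)]
    if len(species) != n_species:
        raise ValueError("species list length mismatch")

    def flood_fill(target_size: int) -> set:
        start = int(rng.integers(total))
        occ = {start}
        frontier = deque([start])
        while len(occ) < target_size and frontier:
            cur = frontier[int(rng.integers(len(frontier)))]
            cx, cy = divmod(cur, ny)
            nbrs = []
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                px, py = cx + dx, cy + dy
                if 0 <= px < nx and 0 <= py < ny:
                    cand = px * ny + py
                    if cand not in occ:
                        nbrs.append(cand)
            if nbrs:
                new = nbrs[int(rng.integers(len(nbrs)))]
                occ.add(new)
                frontier.append(new)
            else:
                frontier.remove(cur)
        return occ

    ranges = {}
    for sp in species:
        if occupancy >= 1.0:
            size = total
        else:  # lognormal spread around the target fraction
            size = int(np.clip(round(occupancy * total * rng.lognormal(0, 0.6)), 1, total))
        ranges[sp] = flood_fill(size)
    attrs = pd.DataFrame(
        {
            "family": rng.integers(1, n_families + 1, n_species),
            "diet": rng.integers(1, n_guilds + 1, n_species),
            "foraging": rng.integers(1, n_guilds + 1, n_species),
            "migratory": rng.choice(["resident", "migrant"], size=n_species, p=[0.75, 0.25]),
        },
        index=species,
    )
    attrs["family"] = "fam" + attrs["family"].astype(str)
    attrs["diet"] = "diet" + attrs["diet"].astype(str)
    attrs["foraging"] = "forage" + attrs["foraging"].astype(str)
    attrs.index.name = "species"
    return GridRangeMap(cells=cells, ranges=ranges, species_attrs=attrs)
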