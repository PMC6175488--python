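"""File formats and run configuration.

Formats are deliberately plain text: Newick trees, a landmark CSV dialect
(columns ``specimen_id, user_id, lm_index, x, y, z, lm_type, curve_id``),
CSV tables for scores/rates/predictors/grids, JSON-lines posteriors, and a
YAML run configuration.  Every reader validates headers and every
writer/reader pair round-trips.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .morpho import LandmarkConfiguration, MarkupSet, QCReport, ShapeSpace
from .rates import McmcSettings, RatePosterior
from .simulate import GridRangeMap
from .tree import PhyloTree

__all__ = [
    "read_newick",
    "write_newick",
    "write_markups",
    "read_markups",
    "write_qc_report",
    "write_shape_space",
    "write_posterior",
    "write_grid",
    "read_grid",
    "RunConfig",
    "load_config",
    "stage_seed",
]

MARKUP_COLUMNS = ["specimen_id", "user_id", "lm_index", "x", "y", "z", "lm_type", "curve_id"]


# =====================================================================
# Trees
# =====================================================================
def read_newick(path) -> PhyloTree:
    """Parse a Newick tree with branch lengths from ``path``.

    Malformed input raises with dendropy's position-reporting message;
    missing branch lengths raise an explicit error.
    """
    text = Path(path).read_text()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports row/column in its message
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    missing = [
        (nd.taxon.label if nd.taxon else "<internal>")
        for nd in dtree.preorder_node_iter()
        if nd.parent_node is not None and nd.edge.length is None
    ]
    if missing:
        raise ValueError(f"{path}: edges without branch lengths (e.g. above {missing[:3]})")
    return PhyloTree.from_dendropy(dtree)


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# =====================================================================
# Landmarks
# =====================================================================
def write_markups(markups, path) -> None:
    """Write one or more MarkupSets in the landmark CSV dialect."""
    if isinstance(markups, MarkupSet):
        markups = [markups]
    rows = []
    for m in markups:
        for user, cfg in m.users.items():
            for i in range(cfg.k):
                rows.append(
                    {
                        "specimen_id": m.specimen_id,
                        "user_id": user,
                        "lm_index": i,
                        "x": cfg.coords[i, 0],
                        "y": cfg.coords[i, 1],
                        "z": cfg.coords[i, 2],
                        "lm_type": "fixed" if cfg.curve_id[i] < 0 else "semi",
                        "curve_id": int(cfg.curve_id[i]),
                    }
                )
    pd.DataFrame(rows, columns=MARKUP_COLUMNS).to_csv(path, index=False)


def read_markups(path, curve_endpoints: dict | None = None) -> dict:
    """Read the landmark CSV dialect into specimen_id -> MarkupSet.

    ``curve_endpoints`` (curve -> (start_fixed, end_fixed)) can be supplied
    when the layout's bounding fixed landmarks are known; the dialect itself
    does not carry them.
    """
    df = pd.read_csv(path)
    if list(df.columns) != MARKUP_COLUMNS:
        raise ValueError(f"{path}: expected columns {MARKUP_COLUMNS}, got {list(df.columns)}")
    out = {}
    for spec, sdf in df.groupby("specimen_id", sort=False):
        users = {}
        for user, udf in sdf.groupby("user_id", sort=False):
            udf = udf.sort_values("lm_index")
            expect = (udf["lm_type"] == "fixed") == (udf["curve_id"] < 0)
            if not expect.all():
                raise ValueError(f"{path}: lm_type/curve_id inconsistent for {spec}/{user}")
            users[user] = LandmarkConfiguration(
                coords=udf[["x", "y", "z"]].to_numpy(float),
                curve_id=udf["curve_id"].to_numpy(int),
                curve_endpoints=curve_endpoints or {},
            )
        out[spec] = MarkupSet(specimen_id=str(spec), users=users)
    return out


def write_qc_report(reports, path) -> None:
    """QC verdicts as CSV with a reason-code column."""
    if isinstance(reports, QCReport):
        reports = [reports]
    rows = [
        {
            "specimen_id": r.specimen_id,
            "user_id": u,
            "verdict": r.verdicts[u],
            "reasons": ";".join(r.reasons[u]),
            "measurement_error": r.measurement_error,
        }
        for r in reports
        for u in r.verdicts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_shape_space(space: ShapeSpace, outdir) -> None:
    """ShapeSpace as consensus/eigenvalue/score CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(space.consensus, columns=["x", "y", "z"]).to_csv(
        outdir / "consensus.csv", index_label="lm_index"
    )
    pd.DataFrame(
        {
            "eigenvalue": space.eigenvalues,
            "variance_fraction": space.variance_fraction,
        },
        index=[f"PC{i + 1}" for i in range(len(space.eigenvalues))],
    ).to_csv(outdir / "eigenvalues.csv", index_label="axis")
    space.scores_frame().to_csv(outdir / "scores.csv", index_label="species")


# =====================================================================
# Posteriors
# =====================================================================
def write_posterior(post: RatePosterior, path) -> None:
    """Posterior as JSON-lines: one sample per line."""
    with open(path, "w") as fh:
        for i in range(post.n_samples):
            cfg = post.configurations[i]
            fh.write(
                json.dumps(
                    {
                        "iteration": int(post.iterations[i]),
                        "loglik": float(post.loglik[i]),
                        "logprior": float(post.logprior[i]),
                        "entries": [[int(e), s, float(r)] for e, s, r in cfg.entries],
                    }
                )
                + "\n"
            )


# =====================================================================
# Grids
# =====================================================================
def write_grid(grid: GridRangeMap, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid.cells.to_csv(outdir / "cells.csv", index=False)
    pd.DataFrame(
        [(sp, c) for sp, occ in grid.ranges.items() for c in sorted(occ)],
        columns=["species", "cell_id"],
    ).to_csv(outdir / "ranges.csv", index=False)
    grid.species_attrs.to_csv(outdir / "species.csv", index_label="species")


def read_grid(outdir) -> GridRangeMap:
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "cells.csv")
    ranges_df = pd.read_csv(outdir / "ranges.csv")
    attrs = pd.read_csv(outdir / "species.csv", index_col="species")
    need = {"cell_id", "x", "y", "area_km2", "is_island", "temperature", "uvb"}
    if not need <= set(cells.columns):
        raise ValueError(f"cells.csv missing columns {sorted(need - set(cells.columns))}")
    ranges = {
        sp: set(sdf["cell_id"].tolist()) for sp, sdf in ranges_df.groupby("species")
    }
    return GridRangeMap(cells=cells, ranges=ranges, species_attrs=attrs)


# =====================================================================
# Run configuration
# =====================================================================
@dataclass
class RunConfig:
    """Whole-pipeline configuration with the study's printed defaults.

    QC distance threshold 0.2, 99% cumulative variance for axis selection,
    PSRF gate 1.1, ESS gate 200, minimum clade size 5, 50% burn-in.  Stage
    seeds derive deterministically from ``seed`` so one number reproduces a
    run.
    """

    seed: int = 1
    outdir: str = "pipeline_out"
    # synthetic inputs
    n_species: int = 32
    birth: float = 1.0
    death: float = 0.0
    n_branch_shifts: int = 0
    n_clade_shifts: int = 1
    scalar_lo: float = 4.0
    scalar_hi: float = 32.0
    n_modes: int = 8
    n_users: int = 3
    noise_sd: float = 0.005
    corrupt_fraction: float = 0.0
    # grid
    grid_nx: int = 16
    grid_ny: int = 16
    cell_km: float = 110.0
    occupancy: float = 0.1
    n_families: int = 4
    n_guilds: int = 3
    island_fraction: float = 0.15
    # morphometrics
    qc_d_max: float = 0.2
    gpa_tol: float = 1e-8
    slide_iterations: int = 3
    cum_var: float = 0.99
    axes: str = "pca"              # "pca" | "ppca"
    # rates
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    n_chains: int = 2
    psrf_threshold: float = 1.1
    ess_threshold: float = 200.0
    min_clade_size: int = 5
    n_clades: int = 4
    # correlates
    pgls_lambda: str = "ML"
    log_tip_rates: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        mc = d.pop("mcmc", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if mc:
            cfg.mcmc = McmcSettings(**mc)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML RunConfig; ``overrides`` maps (dotted) keys to values."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        parts = key.split(".")
        target = raw
        for p in parts[:-1]:
            target = target.setdefault(p, {})
        target[parts[-1]] = value
    return RunConfig.from_dict(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the global seed."""
    h = np.uint64(global_seed)
    for ch in stage:
        h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**63))
    return int(h % np.uint64(2**31 - 1))
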