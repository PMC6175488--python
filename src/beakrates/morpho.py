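"""Geometric morphometrics: landmark QC, Procrustes alignment, shape axes.

Pipeline: multi-user 3D landmark sets per specimen are quality-controlled
(edge inversion, curve disorder, between-user discrepancy), averaged, aligned
by Generalized Procrustes Analysis, semi-landmarks are slid along curve
tangents to reduce thin-plate-spline bending energy against the consensus,
and PC / phylogenetic-PC trait axes are extracted from the aligned
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "LandmarkConfiguration",
    "MarkupSet",
    "QCReport",
    "ShapeSpace",
    "procrustes_distance",
    "qc_markups",
    "average_markups",
    "gpa",
    "slide_semilandmarks",
    "pca",
    "ppca",
    "select_axes",
]

log = logging.getLogger(__name__)

EDGE_INVERSION = "EDGE_INVERSION"
CURVE_DISORDER = "CURVE_DISORDER"
USER_DISCREPANCY = "USER_DISCREPANCY"


# =====================================================================
# Types
# =====================================================================
@dataclass
class LandmarkConfiguration:
    """One user's landmark set: k points in 3D with roles and curve ids.

    ``curve_id[i] == -1`` marks a fixed landmark; semi-landmarks share the id
    of their curve and are ordered along it by index.  Optionally each curve
    records the fixed landmarks bounding it (``curve_endpoints``), used for
    tangent estimation during sliding.
    """

    coords: np.ndarray                      # (k, 3)
    curve_id: np.ndarray                    # (k,) int, -1 = fixed
    curve_endpoints: dict = field(default_factory=dict)  # curve -> (start_fixed, end_fixed)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.curve_id = np.asarray(self.curve_id, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (k, 3)")
        if self.curve_id.shape != (self.coords.shape[0],):
            raise ValueError("curve_id length mismatch")
        if self.coords.shape[0] < 3:
            raise ValueError("need at least 3 landmarks")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def is_fixed(self) -> np.ndarray:
        return self.curve_id < 0

    def curves(self) -> list:
        return sorted(set(self.curve_id[self.curve_id >= 0]))

    def curve_indices(self, curve: int) -> np.ndarray:
        return np.flatnonzero(self.curve_id == curve)

    def same_layout(self, other: "LandmarkConfiguration") -> bool:
        return self.k == other.k and np.array_equal(self.curve_id, other.curve_id)

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class MarkupSet:
    """All users' markups of one specimen (identical layouts)."""

    specimen_id: str
    users: dict                             # user id -> LandmarkConfiguration

    def __post_init__(self):
        configs = list(self.users.values())
        if not configs:
            raise ValueError("markup set needs at least one user")
        ref = configs[0]
        if any(not ref.same_layout(c) for c in configs[1:]):
            raise ValueError("all users must share one landmark layout")


@dataclass
class QCReport:
    """Per-user verdicts plus the specimen's measurement error.

    ``measurement_error`` is the mean between-user Procrustes distance,
    computed over accepted users when at least two remain, otherwise over all
    users.
    """

    specimen_id: str
    verdicts: dict                          # user -> "accept" | "reject"
    reasons: dict                           # user -> list of reason codes
    pairwise_distances: pd.DataFrame
    measurement_error: float
    notes: list = field(default_factory=list)

    def accepted_users(self) -> list:
        return [u for u, v in self.verdicts.items() if v == "accept"]


@dataclass
class ShapeSpace:
    """Procrustes-aligned shapes with their principal axes.

    ``aligned`` is (m, k, 3) at unit centroid size and centered; scores are
    rows of centered vectorized shapes projected on ``eigenvectors`` columns.
    """

    labels: list
    aligned: np.ndarray
    consensus: np.ndarray
    layout: LandmarkConfiguration | None = None
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    variance_fraction: np.ndarray | None = None
    scores: np.ndarray | None = None
    kind: str = "pca"

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


# =====================================================================
# Superimposition primitives
# =====================================================================
def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def centroid_size(x: np.ndarray) -> float:
    c = _center(x)
    return float(np.sqrt((c**2).sum()))


def _unit(x: np.ndarray) -> np.ndarray:
    c = _center(x)
    s = np.sqrt((c**2).sum())
    if s == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return c / s


def optimal_rotation(b: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections disallowed) minimizing ||a - b R||."""
    H = b.T @ a
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d][: H.shape[0]])
    return U @ D @ Vt


def procrustes_distance(a: LandmarkConfiguration | np.ndarray,
                        b: LandmarkConfiguration | np.ndarray) -> float:
    """Full Procrustes distance between two same-layout configurations.

    Both shapes are centered and scaled to unit centroid size; ``b`` is then
    rotated (no reflection) and rescaled optimally onto ``a``.  Returns the
    root summed squared deviation; zero iff the shapes are
    similarity-equivalent.
    """
    if isinstance(a, LandmarkConfiguration) and isinstance(b, LandmarkConfiguration):
        if not a.same_layout(b):
            raise ValueError("layout mismatch")
        a, b = a.coords, b.coords
    A, B = _unit(np.asarray(a, float)), _unit(np.asarray(b, float))
    if A.shape != B.shape:
        raise ValueError("layout mismatch")
    R = optimal_rotation(B, A)
    # optimal scale for unit-size shapes is cos(rho) = trace of rotated xcov
    c = float(np.trace(B.T @ A @ R.T))
    return float(np.sqrt(max(0.0, 1.0 - c * c)))


def gpa(configs, tol: float = 1e-8, max_iter: int = 200):
    """Generalized Procrustes Analysis.

    Iteratively centers, scales to unit centroid size, and rotates every
    configuration onto the running consensus until the consensus stabilizes.
    Returns ``(aligned (m,k,3), consensus (k,3), residual_ss)``; the
    Procrustes sum of squares is non-increasing across iterations.
    """
    arrs = [c.coords if isinstance(c, LandmarkConfiguration) else np.asarray(c, float)
            for c in configs]
    if len(arrs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if isinstance(configs[0], LandmarkConfiguration):
        ref = configs[0]
        for c in configs[1:]:
            if isinstance(c, LandmarkConfiguration) and not ref.same_layout(c):
                raise ValueError("layout mismatch")
    X = np.stack([_unit(a) for a in arrs])
    consensus = _unit(X.mean(axis=0))
    for _ in range(max_iter):
        for i in range(X.shape[0]):
            X[i] = X[i] @ optimal_rotation(X[i], consensus)
        new_consensus = _unit(X.mean(axis=0))
        delta = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if delta < tol:
            break
    resid = float(((X - consensus) ** 2).sum())
    return X, consensus, resid


def average_markups(accepted) -> LandmarkConfiguration:
    """Pointwise mean of accepted users after alignment to their consensus."""
    accepted = list(accepted)
    if not accepted:
        raise ValueError("no accepted users to average")
    layout = accepted[0]
    if len(accepted) == 1:
        return layout
    if any(not layout.same_layout(c) for c in accepted[1:]):
        raise ValueError("layout mismatch")
    aligned, _, _ = gpa(accepted)
    return layout.with_coords(aligned.mean(axis=0))


# =====================================================================
# Quality control
# =====================================================================
def _curve_polyline(config_coords, layout: LandmarkConfiguration, curve: int) -> np.ndarray:
    idx = layout.curve_indices(curve)
    pts = config_coords[idx]
    ends = layout.curve_endpoints.get(curve)
    if ends is not None:
        start, end = ends
        pts = np.vstack([config_coords[start], pts, config_coords[end]])
    return pts


def _arc_positions(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Arc-length parameter of each point's projection onto a polyline."""
    seg_start = polyline[:-1]
    seg_vec = polyline[1:] - seg_start
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    params = np.zeros(points.shape[0])
    for i, pt in enumerate(points):
        rel = pt - seg_start
        denom = (seg_vec**2).sum(axis=1)
        t = np.clip(np.einsum("ij,ij->i", rel, seg_vec) / np.where(denom > 0, denom, 1.0), 0, 1)
        proj = seg_start + t[:, None] * seg_vec
        d2 = ((pt - proj) ** 2).sum(axis=1)
        j = int(np.argmin(d2))
        params[i] = cum[j] + t[j] * seg_len[j]
    return params


def _lr_orientation(coords: np.ndarray, layout: LandmarkConfiguration,
                    left_curve: int, right_curve: int) -> float:
    """Chirality of the left/right curve pair: a signed triple product.

    An axis is drawn between the two most-separated landmarks outside the
    left/right curves; the determinant of (axis, left centroid, right
    centroid) relative to the axis base measures handedness.  Swapping the
    left and right blocks flips the sign; rotation, translation, and
    positive scaling do not.
    """
    li = layout.curve_indices(left_curve)
    ri = layout.curve_indices(right_curve)
    other = np.setdiff1d(np.arange(layout.k), np.concatenate([li, ri]))
    if other.size < 2:
        return 0.0
    pts = coords[other]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    q0, q1 = pts[min(i, j)], pts[max(i, j)]
    vL = coords[li].mean(axis=0) - q0
    vR = coords[ri].mean(axis=0) - q0
    return float(np.linalg.det(np.stack([q1 - q0, vL, vR])))


def qc_markups(m: MarkupSet, d_max: float = 0.2,
               asym_ratio: float = 0.5, asym_floor: float = 0.05,
               left_curve: int = 1, right_curve: int = 2) -> QCReport:
    """Quality-control a specimen's multi-user markups.

    A user is rejected when (1) the left and right tomial-edge blocks are
    inverted (chirality opposite to the user majority) or strongly
    asymmetric against the clean-core consensus (``EDGE_INVERSION``),
    (2) semi-landmark arc positions along any curve are non-monotone
    (``CURVE_DISORDER``), or (3) the user's mean Procrustes distance to the
    other remaining users is at least ``d_max`` (``USER_DISCREPANCY``,
    applied by iteratively peeling the single worst user so one outlier
    cannot drag agreeing users over the threshold).  Reference shapes for
    rules (1)-(2) come from the consensus of users not already flagged, so a
    corrupted markup does not contaminate its own test.  The asymmetry flag
    fires when left/right mean deviations differ by more than ``asym_ratio``
    of the larger, above an absolute floor of ``asym_floor`` (pure noise is
    never flagged).
    """
    users = list(m.users)
    layout = m.users[users[0]]
    notes = []
    reasons = {u: [] for u in users}

    has_lr = left_curve in layout.curves() and right_curve in layout.curves()

    # (1a) edge inversion: chirality against the user majority
    if has_lr and len(users) >= 2:
        signs = {
            u: np.sign(_lr_orientation(m.users[u].coords, layout, left_curve, right_curve))
            for u in users
        }
        majority = np.sign(sum(signs.values()))
        if majority != 0:
            for u in users:
                if signs[u] == -majority:
                    reasons[u].append(EDGE_INVERSION)

    # (3) between-user discrepancy by iterative peeling
    dist = pd.DataFrame(0.0, index=users, columns=users)
    if len(users) >= 2:
        for i, ua in enumerate(users):
            for j, ub in enumerate(users):
                if j <= i:
                    continue
                d = procrustes_distance(m.users[ua], m.users[ub])
                dist.iloc[i, j] = dist.iloc[j, i] = d
        active = list(users)
        while len(active) >= 2:
            means = {u: dist.loc[u, [v for v in active if v != u]].mean() for u in active}
            worst = max(means, key=means.get)
            if means[worst] < d_max:
                break
            reasons[worst].append(USER_DISCREPANCY)
            active.remove(worst)
    else:
        notes.append("single user: between-user discrepancy test skipped")

    # reference consensus from users with no flags so far
    core = [u for u in users if not reasons[u]] or users
    if len(core) >= 2:
        core_aligned, consensus, _ = gpa([m.users[u] for u in core])
    else:
        consensus = _unit(m.users[core[0]].coords)
    li = layout.curve_indices(left_curve) if has_lr else None
    ri = layout.curve_indices(right_curve) if has_lr else None

    for u in users:
        x = _unit(m.users[u].coords)
        x = x @ optimal_rotation(x, consensus)
        # (1b) asymmetric left/right placement
        if has_lr and len(users) >= 2 and EDGE_INVERSION not in reasons[u]:
            dL = float(np.linalg.norm(x[li] - consensus[li], axis=1).mean())
            dR = float(np.linalg.norm(x[ri] - consensus[ri], axis=1).mean())
            big = max(dL, dR)
            if big >= asym_floor and abs(dL - dR) > asym_ratio * big:
                reasons[u].append(EDGE_INVERSION)
        # (2) curve order along the consensus polyline
        for curve in layout.curves():
            idx = layout.curve_indices(curve)
            if idx.size < 3:
                notes.append(f"user {u}: curve {curve} has < 3 points, order test skipped")
                continue
            poly = _curve_polyline(consensus, layout, curve)
            pos = _arc_positions(x[idx], poly)
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            spacing = float(seg.mean())
            if np.any(np.diff(pos) < -0.5 * spacing):
                reasons[u].append(CURVE_DISORDER)
                break

    verdicts = {u: ("reject" if reasons[u] else "accept") for u in users}
    accepted = [u for u in users if verdicts[u] == "accept"]
    pool = accepted if len(accepted) >= 2 else users
    if len(pool) >= 2:
        vals = [dist.loc[a, b] for i, a in enumerate(pool) for b in pool[i + 1:]]
        err = float(np.mean(vals))
    else:
        err = 0.0
        notes.append("fewer than 2 users available: measurement error set to 0")
    for u in users:
        if reasons[u]:
            log.info("specimen %s: user %s rejected (%s)", m.specimen_id, u,
                     ",".join(reasons[u]))
    return QCReport(
        specimen_id=m.specimen_id,
        verdicts=verdicts,
        reasons=reasons,
        pairwise_distances=dist,
        measurement_error=err,
        notes=notes,
    )


# =====================================================================
# Semi-landmark sliding
# =====================================================================
def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix for 3D reference landmarks.

    Uses the 3D polyharmonic kernel U(r) = -r (the sign that makes the
    kernel conditionally positive definite, hence the energy form PSD).
    Returns the k x k upper-left block of the inverse of [[K, Q], [Q', 0]];
    it annihilates affine deformations.
    """
    k = reference.shape[0]
    d = np.linalg.norm(reference[:, None, :] - reference[None, :, :], axis=2)
    K = -d  # U(r) = -r in 3D
    Q = np.hstack([np.ones((k, 1)), reference])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.pinv(L)
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)


def bending_energy(config: np.ndarray, B: np.ndarray) -> float:
    return float(sum(config[:, d] @ B @ config[:, d] for d in range(config.shape[1])))


def _tangents(coords: np.ndarray, layout: LandmarkConfiguration) -> tuple:
    """Unit tangents at each semi-landmark from its curve neighbours.

    Returns (semi indices, tangents (m,3), caps (m,)) where the cap is half
    the local inter-point spacing, used to bound sliding displacements so
    curve order is preserved.
    """
    semis, tangents, caps = [], [], []
    for curve in layout.curves():
        idx = layout.curve_indices(curve)
        if idx.size < 3 and layout.curve_endpoints.get(curve) is None:
            log.warning("curve %s has < 3 points and no endpoints; skipped in sliding", curve)
            continue
        ends = layout.curve_endpoints.get(curve)
        seq = list(idx)
        if ends is not None:
            seq = [ends[0]] + seq + [ends[1]]
        pts = coords[seq]
        for j, lm in enumerate(seq):
            if layout.curve_id[lm] != curve:
                continue  # bounding fixed landmark
            prev_pt = pts[j - 1] if j > 0 else pts[j]
            next_pt = pts[j + 1] if j < len(seq) - 1 else pts[j]
            t = next_pt - prev_pt
            norm = np.linalg.norm(t)
            if norm == 0:
                continue
            semis.append(lm)
            tangents.append(t / norm)
            d_prev = np.linalg.norm(pts[j] - prev_pt) if j > 0 else np.inf
            d_next = np.linalg.norm(next_pt - pts[j]) if j < len(seq) - 1 else np.inf
            caps.append(0.5 * min(d_prev, d_next))
    return np.array(semis, dtype=int), np.array(tangents), np.array(caps)


def slide_semilandmarks(aligned: np.ndarray, layout: LandmarkConfiguration,
                        n_iter: int = 3, gpa_tol: float = 1e-8):
    """Slide semi-landmarks along curve tangents to reduce bending energy.

    For each configuration the displacement of every semi-landmark along its
    local tangent is the closed-form minimizer of the TPS bending energy
    against the current consensus, scaled back (if necessary) so no point
    moves more than half its local inter-point spacing — sliding therefore
    never creates curve disorder, and because the objective is a convex
    quadratic the capped step still decreases it.  GPA is re-run after each
    pass.  Returns ``(aligned, consensus, energy_history)`` where the history
    holds (before, after) total bending energies per iteration, measured
    against that iteration's consensus.
    """
    X = aligned.copy()
    consensus = _unit(X.mean(axis=0))
    history = []
    for _ in range(n_iter):
        B = bending_energy_matrix(consensus)
        before = sum(bending_energy(x - consensus, B) for x in X)
        for i in range(X.shape[0]):
            semis, T, caps = _tangents(X[i], layout)
            if semis.size == 0:
                continue
            y = X[i] - consensus
            By = B @ y                                  # (k, 3)
            b = np.einsum("md,md->m", T, By[semis])
            # A_{ji} = sum_d t_{jd} B_{s_j s_i} t_{id} = (T T')_{ji} * B_{s_j s_i}
            A = (T @ T.T) * B[np.ix_(semis, semis)]
            d, *_ = np.linalg.lstsq(A, -b, rcond=None)
            over = np.abs(d) / np.where(caps > 0, caps, np.inf)
            scale = 1.0 / max(1.0, float(over.max())) if over.size else 1.0
            X[i][semis] += (scale * d)[:, None] * T
        after = sum(bending_energy(x - consensus, B) for x in X)
        history.append((before, after))
        X, consensus, _ = gpa(list(X), tol=gpa_tol)
    return X, consensus, history


# =====================================================================
# Shape axes
# =====================================================================
def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude entry positive."""
    V = V.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def pca(labels, aligned: np.ndarray, layout: LandmarkConfiguration | None = None) -> ShapeSpace:
    """Principal components of vectorized aligned coordinates.

    Eigen-decomposition of the sample covariance about the consensus; scores
    are centered data projected on the eigenvectors.  Axes with numerically
    zero variance are dropped; variance fractions sum to 1.
    """
    m = aligned.shape[0]
    if m < 2:
        raise ValueError("PCA needs at least 2 shapes")
    Xv = aligned.reshape(m, -1)
    mean = Xv.mean(axis=0)
    Xc = Xv - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (m - 1)
    keep = eigvals > max(eigvals.max(), 1.0) * 1e-12
    eigvals = eigvals[keep]
    V = _fix_signs(Vt[keep].T)
    scores = Xc @ V
    return ShapeSpace(
        labels=list(labels),
        aligned=aligned,
        consensus=mean.reshape(-1, 3),
        layout=layout,
        eigenvalues=eigvals,
        eigenvectors=V,
        variance_fraction=eigvals / eigvals.sum(),
        scores=scores,
        kind="pca",
    )


def ppca(labels, aligned: np.ndarray, tree: PhyloTree,
         layout: LandmarkConfiguration | None = None,
         C: np.ndarray | None = None) -> ShapeSpace:
    """Phylogenetic PCA (evolutionary covariance under Brownian motion).

    The GLS phylogenetic mean is ``a = (1'C^-1 1)^-1 1'C^-1 X`` and the
    evolutionary covariance ``(X - 1a)' C^-1 (X - 1a) / (n - 1)`` is
    eigen-decomposed; scores project the (GLS-)centered data on its
    eigenvectors.  ``C`` defaults to the Brownian covariance of ``tree`` in
    row order ``labels``; pass ``C=np.eye(n)`` to recover ordinary PCA.
    """
    labels = list(labels)
    m = aligned.shape[0]
    if set(labels) != set(tree.tip_labels()) or m != tree.n_tips:
        raise ValueError("shape rows must correspond 1:1 to tree tips")
    Xv = aligned.reshape(m, -1)
    if C is None:
        C = tree.vcv(order=labels)
    Ci = np.linalg.inv(C)
    one = np.ones(m)
    denom = one @ Ci @ one
    a = (one @ Ci @ Xv) / denom
    Xc = Xv - a
    R = Xc.T @ Ci @ Xc / (m - 1)
    eigvals, V = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, V = eigvals[order], V[:, order]
    keep = eigvals > max(eigvals.max(), 1.0) * 1e-12
    nkeep = min(int(keep.sum()), m - 1)
    eigvals, V = eigvals[:nkeep], _fix_signs(V[:, :nkeep])
    scores = Xc @ V
    return ShapeSpace(
        labels=labels,
        aligned=aligned,
        consensus=a.reshape(-1, 3),
        layout=layout,
        eigenvalues=eigvals,
        eigenvectors=V,
        variance_fraction=eigvals / eigvals.sum(),
        scores=scores,
        kind="ppca",
    )


def select_axes(space: ShapeSpace, cum_var: float = 0.99) -> pd.DataFrame:
    """Smallest leading set of axes reaching ``cum_var`` cumulative variance.

    Returns the first k score columns as a species x PC DataFrame.
    """
    if not 0 < cum_var <= 1:
        raise ValueError("cum_var must be in (0, 1]")
    frac = np.asarray(space.variance_fraction, dtype=float)
    cum = np.cumsum(frac)
    reached = np.flatnonzero(cum >= cum_var - 1e-12)
    k = int(reached[0]) + 1 if reached.size else frac.size
    return space.scores_frame().iloc[:, :k]
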