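"""Procrustes shape analysis and the parental discriminant shape axis.

Shape differences between bones are quantified in a generalized Procrustes
framework: every semilandmark configuration is scaled to unit centroid size,
translated to a common origin and optimally rotated (proper rotations only —
bacula are chiral).  During superimposition, semilandmarks may "slide"
within their local tangent plane to minimise the thin-plate-spline bending
energy against the consensus, relaxing the arbitrary placement of points
along the bone surface.  The result is a symmetric matrix of pairwise
Procrustes distances.

A single scalar shape score is then defined against the two parental
strains: the distance matrix is embedded by principal coordinates analysis
(classical MDS), a two-class linear discriminant is fit on the parental
specimens in that embedding, and every specimen is projected onto the
resulting axis (LD1).  The sign convention puts the first-listed parent at
lower scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .semilandmarks import SemilandmarkSet, centroid_size

_EIG_TOL = 1e-9


class ShapeError(ValueError):
    pass


def _as_config(obj) -> np.ndarray:
    coords = obj.coords if isinstance(obj, SemilandmarkSet) else np.asarray(obj)
    return np.asarray(coords, dtype=float)


def _normalize(coords: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    centred = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centred**2))
    if cs <= 0:
        raise ShapeError("configuration has zero centroid size")
    return centred / cs


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||a - b @ R.T|| for centred configs."""
    H = b.T @ a
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def opa(a, b) -> tuple[float, np.ndarray]:
    """Ordinary Procrustes analysis of two corresponding configurations.

    Both configurations are centred and scaled to unit centroid size, then
    ``b`` is optimally rotated onto ``a``.  Returns the Procrustes distance
    (Euclidean norm between the superimposed configurations) and the
    rotation applied to ``b``.
    """
    A = _normalize(_as_config(a))
    B = _normalize(_as_config(b))
    if A.shape != B.shape:
        raise ShapeError(f"configuration shapes differ: {A.shape} vs {B.shape}")
    R = optimal_rotation(A, B)
    return float(np.linalg.norm(A - B @ R.T)), R


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a 3D reference config.

    Uses the 3D kernel U(r) = -r (conditionally positive definite of the
    required order); the returned k x k matrix B is positive semidefinite
    and annihilates affine transforms, so sum_d y_d' B y_d measures the
    non-affine deformation from the reference to a target y.
    """
    X = np.asarray(reference, dtype=float)
    k = len(X)
    r = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    K = -r
    Q = np.hstack([np.ones((k, 1)), X])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    Linv = np.linalg.pinv(L)
    B = Linv[:k, :k]
    return 0.5 * (B + B.T)


def bending_energy(B: np.ndarray, target: np.ndarray) -> float:
    return float(np.einsum("id,ij,jd->", target, B, target))


def _tangent_directions(
    coords: np.ndarray, labels: list[tuple[int, str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent directions for sliding, estimated from neighbouring landmarks.

    Dorsal/ventral semilandmarks get two directions (along the slice and
    across slices); leftmost/rightmost get one (across slices, the slice
    tangent direction of the bone margin); tips are fixed.  Returns
    (landmark_index_per_direction, unit_direction_per_direction).
    """
    index = {lab: i for i, lab in enumerate(labels)}
    idx: list[int] = []
    dirs: list[np.ndarray] = []

    def neighbour_dir(i: int, lab_prev, lab_next) -> np.ndarray | None:
        p_prev = coords[index[lab_prev]] if lab_prev in index else coords[i]
        p_next = coords[index[lab_next]] if lab_next in index else coords[i]
        d = p_next - p_prev
        n = np.linalg.norm(d)
        return d / n if n > 1e-12 else None

    for i, (s, role) in enumerate(labels):
        if s < 0:  # tips never slide
            continue
        if role.startswith(("dorsal_", "ventral_")):
            base, line = role.rsplit("_", 1)
            line = int(line)
            within = neighbour_dir(i, (s, f"{base}_{line - 1}"), (s, f"{base}_{line + 1}"))
            across = neighbour_dir(i, (s - 1, role), (s + 1, role))
            for d in (within, across):
                if d is not None:
                    idx.append(i)
                    dirs.append(d)
        elif role in ("leftmost", "rightmost"):
            across = neighbour_dir(i, (s - 1, role), (s + 1, role))
            if across is not None:
                idx.append(i)
                dirs.append(across)
    return np.asarray(idx, dtype=int), np.asarray(dirs, dtype=float)


def _slide_config(
    Y: np.ndarray,
    B: np.ndarray,
    labels: list[tuple[int, str]],
    max_step_frac: float = 0.5,
) -> np.ndarray:
    """Slide semilandmarks along their tangent directions to reduce the
    bending energy of the thin-plate spline from the consensus to Y.

    The quadratic system is Tikhonov-damped (the bending-energy form is
    only semidefinite along near-affine direction combinations) and each
    landmark's slide is capped at ``max_step_frac`` of the median
    nearest-neighbour landmark spacing, keeping the semilandmarks on the
    scale of the surface they discretise.
    """
    j_idx, U = _tangent_directions(Y, labels)
    if len(j_idx) == 0:
        return Y
    BY = B @ Y  # k x 3
    rhs = np.einsum("qd,qd->q", U, BY[j_idx])
    G = B[np.ix_(j_idx, j_idx)] * (U @ U.T)
    lam = 1e-3 * np.trace(G) / len(G)
    a = np.linalg.solve(G + lam * np.eye(len(G)), -rhs)
    steps = np.zeros((len(Y), 3))
    np.add.at(steps, j_idx, U * a[:, None])
    # cap the slide at a fraction of the local landmark spacing
    d = np.linalg.norm(Y[:, None, :] - Y[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    spacing = float(np.median(d.min(axis=1)))
    norms = np.linalg.norm(steps, axis=1)
    cap = max_step_frac * spacing
    over = norms > cap
    if over.any():
        steps[over] *= (cap / norms[over])[:, None]
    Y_new = Y + steps
    if bending_energy(B, Y_new) > bending_energy(B, Y) + 1e-8:
        warnings.warn("sliding step did not reduce bending energy; skipped",
                      stacklevel=2)
        return Y
    return Y_new


@dataclass
class ShapeSpace:
    """Superimposed configurations, consensus and pairwise shape distances."""

    aligned_configs: np.ndarray  # n x k x 3, unit centroid size
    consensus: np.ndarray  # k x 3
    dist: np.ndarray  # n x n symmetric
    specimen_ids: list[str]
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def dist_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.specimen_ids, columns=self.specimen_ids)

    def index_of(self, specimen_id: str) -> int:
        try:
            return self.specimen_ids.index(specimen_id)
        except ValueError as exc:
            raise KeyError(f"specimen {specimen_id!r} not in shape space") from exc


def gpa(
    configs: list,
    slide: bool = False,
    max_iter: int = 200,
    tol: float = 1e-9,
    slide_iter: int = 3,
) -> ShapeSpace:
    """Generalized Procrustes analysis of many configurations.

    Iterates rotation to the consensus and consensus re-estimation until
    the consensus changes by less than ``tol``.  With ``slide=True`` the
    configurations must be :class:`SemilandmarkSet` (labels give the sliding
    topology); non-tip semilandmarks slide within their tangent planes to
    minimise bending energy against the consensus before re-superimposition.
    """
    if len(configs) < 2:
        raise ShapeError("gpa needs at least 2 configurations")
    ids = [
        c.specimen_id if isinstance(c, SemilandmarkSet) else f"config_{i}"
        for i, c in enumerate(configs)
    ]
    labels = None
    if slide:
        if not all(isinstance(c, SemilandmarkSet) for c in configs):
            raise ShapeError("slide=True requires SemilandmarkSet inputs")
        labels = configs[0].labels
    X = np.stack([_normalize(_as_config(c)) for c in configs])
    k = X.shape[1]
    if any(len(_as_config(c)) != k for c in configs):
        raise ShapeError("all configurations must share the landmark count")

    consensus = X[0].copy()
    converged = False
    for iteration in range(max_iter):
        for i in range(len(X)):
            R = optimal_rotation(consensus, X[i])
            X[i] = X[i] @ R.T
        if slide and iteration < slide_iter:
            B = bending_energy_matrix(consensus)
            for i in range(len(X)):
                slid = _slide_config(X[i], B, labels)
                X[i] = _normalize(slid)
                R = optimal_rotation(consensus, X[i])
                X[i] = X[i] @ R.T
        new_consensus = _normalize(X.mean(axis=0))
        change = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if change < tol and not (slide and iteration < slide_iter):
            converged = True
            break
    if not converged:
        warnings.warn(f"gpa did not converge in {max_iter} iterations", stacklevel=2)

    diff = X[:, None, :, :] - X[None, :, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=(2, 3)))
    dist = 0.5 * (dist + dist.T)
    np.fill_diagonal(dist, 0.0)
    return ShapeSpace(
        aligned_configs=X,
        consensus=consensus,
        dist=dist,
        specimen_ids=ids,
        converged=converged,
    )


def _pcoa(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Classical MDS of a distance matrix.

    Returns (eigvecs, eigvals, row means of D^2, grand mean of D^2) for the
    positive-eigenvalue components, sorted by decreasing eigenvalue.
    """
    D2 = np.asarray(D, dtype=float) ** 2
    n = len(D2)
    row_means = D2.mean(axis=1)
    grand = D2.mean()
    B = -0.5 * (D2 - row_means[:, None] - row_means[None, :] + grand)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > _EIG_TOL * max(eigvals.max(), 1.0)
    return eigvecs[:, keep], eigvals[keep], row_means, grand


@dataclass
class LD1Model:
    """Parental-anchored discriminant axis over a PCoA shape embedding."""

    fit_ids: list[str]
    eigvecs: np.ndarray  # n_fit x m (retained components)
    eigvals: np.ndarray  # m
    row_means: np.ndarray  # row means of squared fit distance matrix
    grand_mean: float
    coords: np.ndarray  # n_fit x m embedding of the fit specimens
    direction: np.ndarray  # m, discriminant axis in embedding space
    center: np.ndarray  # m, LDA centering point
    sign: float
    parental_means: dict  # group -> mean LD1 score
    parent_order: tuple[str, str]
    mode: str = "pcoa_lda"

    def score_coords(self, coords: np.ndarray) -> np.ndarray:
        return self.sign * ((coords - self.center) @ self.direction)


def fit_ld1(
    space: ShapeSpace,
    parental_labels: dict,
    var_explained: float = 0.95,
    mode: str = "pcoa_lda",
    shrinkage: str | float = "auto",
) -> LD1Model:
    """Fit the discriminant shape axis anchored on the two parental strains.

    ``parental_labels`` maps specimen id -> parental group name for parental
    specimens only (others omitted or mapped to None).  The full distance
    matrix is embedded by PCoA; the number of retained components is
    min(components explaining ``var_explained`` of the positive variance,
    n_parentals - 2).  A two-class LDA is fit on the parental specimens in
    that embedding; the sign is fixed so the first-listed parental group has
    the lower mean score.

    ``mode='distance_lda'`` instead uses distances to the parental specimens
    as features with a shrinkage-covariance LDA — an alternative reading of
    a discriminant analysis "on the distance matrix".
    """
    groups = {sid: g for sid, g in parental_labels.items() if g not in (None, "none")}
    order: list[str] = []
    for sid in space.specimen_ids:
        g = groups.get(sid)
        if g is not None and g not in order:
            order.append(g)
    if len(order) != 2:
        raise ShapeError(f"need exactly 2 parental groups, got {order}")
    p1, p2 = order
    members = {g: [sid for sid in space.specimen_ids if groups.get(sid) == g] for g in order}
    for g, mem in members.items():
        if len(mem) < 2:
            raise ShapeError(f"parental group {g!r} has {len(mem)} specimen(s); need >= 2")

    parental_ids = members[p1] + members[p2]
    par_rows = np.array([space.index_of(s) for s in parental_ids])
    y = np.array([p1] * len(members[p1]) + [p2] * len(members[p2]))

    if mode == "distance_lda":
        feats = space.dist[:, par_rows]
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(feats[par_rows], y)
        direction = lda.coef_[0]
        center = feats[par_rows].mean(axis=0)
        eigvecs = np.zeros((len(space.specimen_ids), 0))
        eigvals = np.zeros(0)
        coords = feats
        row_means = np.zeros(len(space.specimen_ids))
        grand = 0.0
    elif mode == "pcoa_lda":
        eigvecs, eigvals, row_means, grand = _pcoa(space.dist)
        frac = np.cumsum(eigvals) / eigvals.sum()
        m95 = int(np.searchsorted(frac, var_explained) + 1)
        m = max(1, min(m95, len(parental_ids) - 2, len(eigvals)))
        eigvecs, eigvals = eigvecs[:, :m], eigvals[:m]
        coords = eigvecs * np.sqrt(eigvals)
        # shrinkage-regularised within-class covariance: parental samples are
        # few relative to the embedding dimension, and an unshrunk estimate
        # makes the axis direction and scale unstable
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(coords[par_rows], y)
        direction = lda.coef_[0].copy()
        norm = np.linalg.norm(direction)
        if norm > 0:
            direction /= norm
        center = coords[par_rows].mean(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    raw = (coords - center) @ direction
    sign = 1.0
    if raw[par_rows[y == p1]].mean() > raw[par_rows[y == p2]].mean():
        sign = -1.0
    if np.isclose(raw[par_rows[y == p1]].mean(), raw[par_rows[y == p2]].mean()):
        raise ShapeError("parental groups are indistinguishable along LD1")
    model = LD1Model(
        fit_ids=list(space.specimen_ids),
        eigvecs=eigvecs,
        eigvals=eigvals,
        row_means=row_means,
        grand_mean=grand,
        coords=coords,
        direction=direction,
        center=center,
        sign=sign,
        parental_means={},
        parent_order=(p1, p2),
        mode=mode,
    )
    scores = model.score_coords(coords)
    model.parental_means = {
        p1: float(scores[par_rows[y == p1]].mean()),
        p2: float(scores[par_rows[y == p2]].mean()),
    }
    return model


def _embed_out_of_sample(model: LD1Model, d_to_fit: np.ndarray) -> np.ndarray:
    """Gower's formula: PCoA coordinates of a point from its distances to
    the fit specimens."""
    d2 = d_to_fit**2
    b = -0.5 * (d2 - model.row_means - d2.mean() + model.grand_mean)
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(model.eigvals)
    return (model.eigvecs.T @ b) * inv_sqrt


def project_ld1(model: LD1Model, space: ShapeSpace) -> pd.Series:
    """LD1 score for every specimen in ``space``.

    Specimens present at fit time reuse their fit-time embedding; others are
    embedded by the standard PCoA out-of-sample extension from their
    distances to the fit specimens (which must all be present in ``space``).
    """
    missing = set(model.fit_ids) - set(space.specimen_ids)
    if missing:
        raise KeyError(
            f"space is missing fit-time specimens: {sorted(missing)[:5]}"
        )
    fit_index = {sid: i for i, sid in enumerate(model.fit_ids)}
    scores: dict[str, float] = {}
    fit_rows_in_space = None
    for row, sid in enumerate(space.specimen_ids):
        if sid in fit_index:
            coords = model.coords[fit_index[sid]]
        elif model.mode == "distance_lda":
            if fit_rows_in_space is None:
                fit_rows_in_space = np.array([space.index_of(s) for s in model.fit_ids])
            # features are distances to the parental block of the fit set
            raise ShapeError(
                "distance_lda out-of-sample projection requires refit; use "
                "mode='pcoa_lda' for out-of-sample specimens"
            )
        else:
            if fit_rows_in_space is None:
                fit_rows_in_space = np.array([space.index_of(s) for s in model.fit_ids])
            coords = _embed_out_of_sample(model, space.dist[row, fit_rows_in_space])
        scores[sid] = float(model.score_coords(coords[None, :])[0])
    return pd.Series(scores, name="LD1")
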