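"""Contour deformation feature from shape-context matching.

The deformation between two cell contours is quantified by iterated
shape-context matching: each contour is resampled to ``n`` arc-length-equidistant
points, every point gets a log-polar histogram of the relative positions of the
other points, points are put in correspondence by the Hungarian algorithm on
the chi-squared histogram cost, and a regularized thin-plate-spline (TPS) warp
registers one contour onto the other.  The symmetric shape-context distance
recorded at each of ``L`` rounds forms the contour deformation feature
F_DCS = (D_SC^1, ..., D_SC^L).

Histograms are normalized by the mean pairwise point distance, so the feature
is invariant to translation and uniform scaling of both contours.  Rotation is
deliberately not normalized: the imaging geometry of tracked, stabilized cells
fixes the absolute horizontal axis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

# log-polar binning defaults: 5 radial x 12 angular bins, radial edges
# log-spaced between 1/8 and 2 times the mean pairwise distance
RADIAL_BINS = 5
ANGULAR_BINS = 12
R_INNER = 0.125
R_OUTER = 2.0


# ------------------------------------------------------------- resampling

def resample_contour(contour: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` points equally spaced by arc length.

    The arc-length origin is the polygon vertex with the smallest angle (in
    [0, 2pi), measured from the positive x axis) around the centroid, which
    makes the sampling canonical for matching.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("contour must be an (m, 2) array with m >= 3")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate contour: zero length")
    centroid = pts.mean(axis=0)
    ang = np.mod(np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0]),
                 2 * np.pi)
    # a vertex sitting numerically at 2*pi - eps is at angle ~0: unwrap so the
    # canonical start is stable under translation and scaling
    ang = np.where(2 * np.pi - ang < 1e-9, 0.0, ang)
    start = int(np.argmin(ang))
    pts = np.roll(pts, -start, axis=0)

    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("degenerate contour: zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * (total / n)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


# ---------------------------------------------------------- shape context

def shape_context(points: np.ndarray,
                  radial_bins: int = RADIAL_BINS,
                  angular_bins: int = ANGULAR_BINS,
                  r_inner: float = R_INNER,
                  r_outer: float = R_OUTER) -> np.ndarray:
    """Log-polar histogram h_i(k) = #{q != p_i : (q - p_i) in bin(k)} per point.

    Radial edges are log-spaced in [r_inner, r_outer] x mean pairwise distance;
    the innermost bin absorbs everything below its upper edge and points beyond
    the outermost edge are dropped.  Returns an (n, radial_bins * angular_bins)
    integer count matrix, flattened radial-major.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    d = cdist(pts, pts)
    mean_dist = d[np.triu_indices(n, k=1)].mean()
    if mean_dist == 0:
        raise ValueError("all points coincide")
    edges = np.geomspace(r_inner, r_outer, radial_bins)

    rel = pts[None, :, :] - pts[:, None, :]
    theta = np.mod(np.arctan2(rel[..., 1], rel[..., 0]), 2 * np.pi)
    # the 1e-9 bin-fraction epsilon absorbs floating-point jitter so that
    # proportional point sets (scale invariance) bin identically
    abin = (np.floor(theta * angular_bins / (2 * np.pi) + 1e-9).astype(int)
            % angular_bins)
    rbin = np.searchsorted(edges, (d / mean_dist) * (1.0 - 1e-12))
    ok = (rbin < radial_bins) & ~np.eye(n, dtype=bool)

    hist = np.zeros((n, radial_bins * angular_bins), dtype=np.int64)
    flat = rbin * angular_bins + abin
    for i in range(n):
        np.add.at(hist[i], flat[i][ok[i]], 1)
    return hist


def chi2_cost(h_i: np.ndarray, h_j: np.ndarray) -> float:
    """Chi-squared matching cost between two histograms; 0/0 terms contribute 0."""
    h_i = np.asarray(h_i, dtype=float)
    h_j = np.asarray(h_j, dtype=float)
    if h_i.shape != h_j.shape:
        raise ValueError("histogram binning mismatch")
    denom = h_i + h_j
    num = (h_i - h_j) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return 0.5 * float(terms.sum())


def chi2_cost_matrix(H1: np.ndarray, H2: np.ndarray) -> np.ndarray:
    """All-pairs chi-squared costs between the rows of H1 (n,K) and H2 (m,K)."""
    H1 = np.asarray(H1, dtype=float)
    H2 = np.asarray(H2, dtype=float)
    if H1.shape[1] != H2.shape[1]:
        raise ValueError("histogram binning mismatch")
    a = H1[:, None, :]
    b = H2[None, :, :]
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, (a - b) ** 2 / np.where(denom > 0, denom, 1.0),
                         0.0)
    return 0.5 * terms.sum(axis=2)


def hungarian(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal assignment minimizing the total cost H(pi) = sum C(p_i, q_pi(i))."""
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square")
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(cost.shape[0], dtype=int)
    perm[rows] = cols
    return perm, float(cost[rows, cols].sum())


# ----------------------------------------------------------------- TPS

@dataclasses.dataclass
class TpsTransform:
    """Thin-plate-spline map f(x) = a0 + A x + sum_i w_i U(|x - c_i|), U(r) = r^2 log r."""

    affine: np.ndarray        # (3, 2): rows = constant, x, y coefficients
    weights: np.ndarray       # (n, 2) warping coefficients
    control: np.ndarray       # (n, 2) control (source) points
    regularization: float

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        r = cdist(pts, self.control)
        K = _tps_kernel(r)
        ones = np.ones((len(pts), 1))
        return np.hstack([ones, pts]) @ self.affine + K @ self.weights


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(r > 0, r**2 * np.log(np.where(r > 0, r, 1.0)), 0.0)
    return out


def fit_tps(source: np.ndarray, target: np.ndarray,
            regularization: float = 0.0) -> TpsTransform:
    """Fit the TPS minimizing bending energy + residual at ``regularization``.

    With regularization 0 the transform interpolates the control points
    exactly; a singular system (e.g. collinear controls) raises LinAlgError.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must be matching (n, 2) arrays")
    n = len(src)
    K = _tps_kernel(cdist(src, src)) + regularization * np.eye(n)
    P = np.hstack([np.ones((n, 1)), src])
    L = np.zeros((n + 3, n + 3))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    sol = np.linalg.solve(L, rhs)
    return TpsTransform(affine=sol[n:], weights=sol[:n], control=src,
                        regularization=regularization)


# ------------------------------------------------------- distance & feature

def shape_distance(P: np.ndarray, Q: np.ndarray,
                   transform: TpsTransform | None = None,
                   **sc_kwargs) -> float:
    """Symmetric shape-context distance between point sets P and T(Q).

    D = 1/n sum_p min_q C(p, T(q)) + 1/m sum_q min_p C(p, T(q)) with C the
    chi-squared cost between log-polar histograms (the minimum is taken over
    the cost values).
    """
    TQ = transform(Q) if transform is not None else np.asarray(Q, dtype=float)
    C = chi2_cost_matrix(shape_context(P, **sc_kwargs),
                         shape_context(TQ, **sc_kwargs))
    return float(C.min(axis=1).mean() + C.min(axis=0).mean())


#: relative TPS regularization (scaled by squared mean pairwise distance)
TPS_REG_REL = 1e-3


def contour_deformation_feature(P_contour: np.ndarray, Q_contour: np.ndarray,
                                n: int = 100, L: int = 10,
                                reg_rel: float = TPS_REG_REL,
                                **sc_kwargs) -> np.ndarray:
    """F_DCS: shape-context distances over L rounds of matching + TPS warping.

    Round l records D_SC^l under the transform accumulated so far (identity
    for l = 1, so D_SC^1 is the raw symmetric shape-context distance of the
    resampled contours), then re-matches and applies a regularized TPS warp of
    Q towards P.  Identical contours give the all-zero vector.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    P = resample_contour(P_contour, n)
    Q = resample_contour(Q_contour, n)
    HP = shape_context(P, **sc_kwargs)
    D = np.zeros(L)
    Qc = Q
    for l in range(L):
        HQ = shape_context(Qc, **sc_kwargs)
        C = chi2_cost_matrix(HP, HQ)
        D[l] = float(C.min(axis=1).mean() + C.min(axis=0).mean())
        if l == L - 1:
            break
        if D[l] == 0.0:
            # every context already has an exact counterpart: the contours are
            # registered and all remaining distances stay zero
            break
        perm, _ = hungarian(C)
        d = cdist(Qc, Qc)
        mean_dist = d[np.triu_indices(len(Qc), k=1)].mean()
        reg = reg_rel * mean_dist**2
        try:
            T = fit_tps(Qc, _match_targets(P, perm), regularization=reg)
        except np.linalg.LinAlgError as exc:   # pragma: no cover - degenerate
            raise np.linalg.LinAlgError(
                f"TPS re-fit singular at iteration {l + 1}") from exc
        Qc = T(Qc)
    return D


def _match_targets(P: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Target positions for the TPS: P_i sits at matched source Q_perm(i)."""
    tgt = np.empty_like(P)
    tgt[perm] = P
    return tgt
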