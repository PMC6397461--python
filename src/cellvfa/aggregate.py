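"""Video-wide aggregation of frame-pair features by compact encoding.

A codebook (diagonal GMM for Fisher vectors, k-means for VLAD / H-VLAD) is
learned on training frame-pair features; a video's ordered feature sequence is
then encoded into a single vector:

* Fisher vector (FV): per GMM component, the soft-assignment-weighted first-
  and second-order residuals u_k, v_k; size 2 D' K, SSR + l2 normalized.
* VLAD-k: sum of residuals of each descriptor to its k nearest k-means
  centers; size D' K, intra (per-block l2) + SSR + l2 normalized.
* H-VLAD: per visual word, first / second / third order residuals between the
  assigned descriptors' statistics and the word's training statistics;
  size 3 D' K, intra + SSR + l2 normalized.

Temporal pyramid pooling (TPP) concatenates the encodings of the whole
sequence, its halves and its thirds (6 blocks), retaining coarse temporal
structure that the order-free encodings discard.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

#: GMM variance floor, relative to the mean global feature variance.  With
#: desk-scale training sets (a few hundred descriptors) a near-singleton
#: component's variance collapses, its standardized residuals (x - mu) / sigma
#: explode and after SSR + l2 normalization that block drowns every other
#: one; a substantial floor keeps the per-component scales commensurate.
VARIANCE_FLOOR_REL = 0.1


# ------------------------------------------------------------------- PCA

@dataclasses.dataclass
class PcaProjection:
    mean: np.ndarray          # (D,)
    components: np.ndarray    # (D', D) orthonormal rows

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components.T


def fit_pca(X: np.ndarray, n_components: int) -> PcaProjection:
    """Mean-centered orthonormal projection onto the top principal components."""
    X = np.asarray(X, dtype=float)
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature dimension")
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 training vectors")
    p = PCA(n_components=n_components, svd_solver="full").fit(X)
    return PcaProjection(mean=p.mean_, components=p.components_)


# -------------------------------------------------------------- codebooks

@dataclasses.dataclass
class GmmCodebook:
    weights: np.ndarray       # (K,)
    means: np.ndarray         # (K, D')
    variances: np.ndarray     # (K, D') diagonal
    pca: PcaProjection | None = None

    @property
    def K(self) -> int:
        return len(self.weights)


@dataclasses.dataclass
class KmeansCodebook:
    centers: np.ndarray       # (K, D')
    mu: np.ndarray            # (K, D') per-word training means
    sigma: np.ndarray         # (K, D') per-word training standard deviations
    gamma: np.ndarray         # (K, D') per-word training skewness
    pca: PcaProjection | None = None

    @property
    def K(self) -> int:
        return len(self.centers)


def fit_gmm(X: np.ndarray, K: int, seed: int,
            pca: PcaProjection | None = None) -> GmmCodebook:
    """Diagonal-covariance GMM codebook (EM with k-means initialization)."""
    X = np.asarray(X, dtype=float)
    if pca is not None:
        X = pca.transform(X)
    if K > len(X):
        raise ValueError(f"K={K} exceeds the {len(X)} training vectors")
    floor = VARIANCE_FLOOR_REL * max(float(X.var(axis=0).mean()), 1e-12)
    gmm = GaussianMixture(n_components=K, covariance_type="diag",
                          reg_covar=floor, random_state=seed,
                          max_iter=200, n_init=1).fit(X)
    return GmmCodebook(weights=gmm.weights_, means=gmm.means_,
                       variances=gmm.covariances_, pca=pca)


def fit_kmeans(X: np.ndarray, K: int, seed: int,
               pca: PcaProjection | None = None) -> KmeansCodebook:
    """K-means codebook with per-word first/second/third-order training statistics."""
    X = np.asarray(X, dtype=float)
    if pca is not None:
        X = pca.transform(X)
    if K > len(X):
        raise ValueError(f"K={K} exceeds the {len(X)} training vectors")
    km = KMeans(n_clusters=K, random_state=seed, n_init=10).fit(X)
    D = X.shape[1]
    mu = np.zeros((K, D))
    sigma = np.zeros((K, D))
    gamma = np.zeros((K, D))
    for k in range(K):
        Xk = X[km.labels_ == k]
        if len(Xk) == 0:
            continue
        mu[k] = Xk.mean(axis=0)
        var = ((Xk - mu[k]) ** 2).mean(axis=0)
        sigma[k] = np.sqrt(var)
        if len(Xk) > 2:
            m3 = ((Xk - mu[k]) ** 3).mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                gamma[k] = np.where(var > 0, m3 / np.where(var > 0, var, 1.0) ** 1.5,
                                    0.0)
    return KmeansCodebook(centers=km.cluster_centers_, mu=mu, sigma=sigma,
                          gamma=gamma, pca=pca)


# ------------------------------------------------------------ normalization

def ssr(z: np.ndarray) -> np.ndarray:
    """Signed square root (power normalization): z -> sign(z) sqrt(|z|)."""
    return np.sign(z) * np.sqrt(np.abs(z))


def l2_normalize(z: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(z)
    if n == 0:
        logger.warning("all-zero encoding left unnormalized")
        return z
    return z / n


def _intra_normalize(blocks: np.ndarray) -> np.ndarray:
    """Per-block l2 normalization; zero blocks stay zero."""
    norms = np.linalg.norm(blocks, axis=1, keepdims=True)
    return np.where(norms > 0, blocks / np.where(norms > 0, norms, 1.0), 0.0)


# --------------------------------------------------------------- encoders

def _gmm_posteriors(X: np.ndarray, gmm: GmmCodebook) -> np.ndarray:
    """Soft assignments q_ki (shape (K, N)) from the stored GMM parameters."""
    var = gmm.variances
    log_det = np.log(2 * np.pi * var).sum(axis=1)                   # (K,)
    diff = X[None, :, :] - gmm.means[:, None, :]                    # (K, N, D)
    maha = (diff**2 / var[:, None, :]).sum(axis=2)                  # (K, N)
    log_p = np.log(gmm.weights)[:, None] - 0.5 * (log_det[:, None] + maha)
    return np.exp(log_p - logsumexp(log_p, axis=0, keepdims=True))


def encode_fv(X: np.ndarray, gmm: GmmCodebook) -> np.ndarray:
    """Fisher vector of a feature sequence under a diagonal GMM.

    u_k = 1/(N sqrt(pi_k))   sum_i q_ki (x_i - mu_k) / sigma_k
    v_k = 1/(N sqrt(2 pi_k)) sum_i q_ki [((x_i - mu_k) / sigma_k)^2 - 1]

    concatenated as (u_1, v_1, ..., u_K, v_K), then SSR and global l2
    normalization.  Output length 2 D' K.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a nonempty (N, D) array")
    if gmm.pca is not None:
        X = gmm.pca.transform(X)
    N = len(X)
    q = _gmm_posteriors(X, gmm)                                     # (K, N)
    sd = np.sqrt(gmm.variances)
    blocks = []
    for k in range(gmm.K):
        z = (X - gmm.means[k]) / sd[k]
        u_k = (q[k][:, None] * z).sum(axis=0) / (N * np.sqrt(gmm.weights[k]))
        v_k = ((q[k][:, None] * (z**2 - 1.0)).sum(axis=0)
               / (N * np.sqrt(2.0 * gmm.weights[k])))
        blocks.extend([u_k, v_k])
    return l2_normalize(ssr(np.concatenate(blocks)))


def encode_vlad(X: np.ndarray, codebook: KmeansCodebook,
                k_nn: int = 5) -> np.ndarray:
    """VLAD-k: residuals of each descriptor to its k nearest centers.

    Per-block intra l2 normalization, then SSR, then global l2.  Length D' K.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a nonempty (N, D) array")
    if codebook.pca is not None:
        X = codebook.pca.transform(X)
    K = codebook.K
    if not 1 <= k_nn <= K:
        raise ValueError(f"k_nn must be in [1, {K}]")
    d2 = ((X[:, None, :] - codebook.centers[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argsort(d2, axis=1, kind="stable")[:, :k_nn]       # (N, k_nn)
    blocks = np.zeros_like(codebook.centers)
    for j in range(k_nn):
        ks = nearest[:, j]
        np.add.at(blocks, ks, X - codebook.centers[ks])
    return l2_normalize(ssr(_intra_normalize(blocks).ravel()))


def encode_hvlad(X: np.ndarray, codebook: KmeansCodebook) -> np.ndarray:
    """H-VLAD: first/second/third-order residuals per visual word.

    u_k = N_k (m_k - mu_k)
    v_k = 1/N_k sum (x_i - m_k)^2 - sigma_k^2
    s_k = skewness of assigned descriptors - gamma_k

    Empty words give zero blocks; the skewness residual is zeroed when it is
    undefined (N_k <= 2 or zero variance).  Concatenated as
    (u_1, v_1, s_1, ..., u_K, v_K, s_K); intra + SSR + global l2; length 3 D' K.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a nonempty (N, D) array")
    if codebook.pca is not None:
        X = codebook.pca.transform(X)
    K, D = codebook.centers.shape
    d2 = ((X[:, None, :] - codebook.centers[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    blocks = np.zeros((3 * K, D))
    for k in range(K):
        Xk = X[assign == k]
        Nk = len(Xk)
        if Nk == 0:
            continue
        m_k = Xk.mean(axis=0)
        blocks[3 * k] = Nk * (m_k - codebook.mu[k])
        m2 = ((Xk - m_k) ** 2).mean(axis=0)
        blocks[3 * k + 1] = m2 - codebook.sigma[k] ** 2
        if Nk > 2:
            m3 = ((Xk - m_k) ** 3).mean(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
            blocks[3 * k + 2] = np.where(m2 > 0, skew - codebook.gamma[k], 0.0)
    return l2_normalize(ssr(_intra_normalize(blocks).ravel()))


# ------------------------------------------------------------------- TPP

def tpp_windows(N: int) -> list[tuple[int, int]]:
    """The 6 temporal pyramid windows (whole, halves, thirds) as (start, stop).

    Contiguous near-equal partitions; when N is not divisible, the earlier
    windows receive the extra elements.
    """
    if N < 3:
        raise ValueError(
            f"temporal pyramid pooling needs at least 3 frame-pair features, "
            f"got {N}")
    windows = []
    for parts in (1, 2, 3):
        base, rem = divmod(N, parts)
        start = 0
        for j in range(parts):
            size = base + (1 if j < rem else 0)
            windows.append((start, start + size))
            start += size
    return windows


def tpp(X: np.ndarray, encode_fn) -> np.ndarray:
    """Concatenate encodings of the 6 pyramid windows; final global l2."""
    X = np.asarray(X, dtype=float)
    parts = [encode_fn(X[a:b]) for a, b in tpp_windows(len(X))]
    return l2_normalize(np.concatenate(parts))


def encode_video(X: np.ndarray, codebook, scheme: str = "fv",
                 k_nn: int = 5, use_tpp: bool = False) -> np.ndarray:
    """Encode one video's feature sequence with the chosen scheme (+ optional TPP)."""
    if scheme == "fv":
        enc = lambda Z: encode_fv(Z, codebook)
    elif scheme == "vlad":
        enc = lambda Z: encode_vlad(Z, codebook, k_nn=k_nn)
    elif scheme == "hvlad":
        enc = lambda Z: encode_hvlad(Z, codebook)
    elif scheme == "avgpool":
        # order-free average pooling of raw frame-pair features (baseline)
        enc = lambda Z: np.asarray(Z, float).mean(axis=0)
    else:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    return tpp(X, enc) if use_tpp else enc(np.asarray(X, float))


def fit_codebook(X: np.ndarray, scheme: str, K: int, seed: int,
                 pca: PcaProjection | None = None):
    if scheme == "fv":
        return fit_gmm(X, K, seed, pca=pca)
    if scheme in ("vlad", "hvlad"):
        return fit_kmeans(X, K, seed, pca=pca)
    if scheme == "avgpool":
        return None
    raise ValueError(f"unknown encoding scheme {scheme!r}")


# ------------------------------------------------------------ serialization

def save_codebook(path: str | Path, codebook, scheme: str, seed: int) -> None:
    """Single JSON bundle recording the scheme, seed and all parameters."""
    payload = {"scheme": scheme, "seed": seed}
    if isinstance(codebook, GmmCodebook):
        payload.update(kind="gmm", weights=codebook.weights.tolist(),
                       means=codebook.means.tolist(),
                       variances=codebook.variances.tolist())
    elif isinstance(codebook, KmeansCodebook):
        payload.update(kind="kmeans", centers=codebook.centers.tolist(),
                       mu=codebook.mu.tolist(), sigma=codebook.sigma.tolist(),
                       gamma=codebook.gamma.tolist())
    else:
        payload.update(kind="none")
    cb = codebook
    if cb is not None and cb.pca is not None:
        payload["pca"] = {"mean": cb.pca.mean.tolist(),
                          "components": cb.pca.components.tolist()}
    Path(path).write_text(json.dumps(payload))


def load_codebook(path: str | Path):
    payload = json.loads(Path(path).read_text())
    pca = None
    if "pca" in payload:
        pca = PcaProjection(mean=np.asarray(payload["pca"]["mean"]),
                            components=np.asarray(payload["pca"]["components"]))
    if payload["kind"] == "gmm":
        return GmmCodebook(weights=np.asarray(payload["weights"]),
                           means=np.asarray(payload["means"]),
                           variances=np.asarray(payload["variances"]), pca=pca)
    if payload["kind"] == "kmeans":
        return KmeansCodebook(centers=np.asarray(payload["centers"]),
                              mu=np.asarray(payload["mu"]),
                              sigma=np.asarray(payload["sigma"]),
                              gamma=np.asarray(payload["gamma"]), pca=pca)
    return None
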