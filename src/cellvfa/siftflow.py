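"""Dense SIFT descriptors, SIFT-flow estimation, and the appearance change field.

Cytoplasmic streaming between two frames is modeled as a dense integer
displacement field w = (u, v) matching per-pixel SIFT descriptors under the
truncated energy

    E(w) = sum_p min(||s1_p - s2_{p+w_p}||_1, t)
         + sum_p eta (|u_p| + |v_p|)
         + sum_{(p,q) 4-neighbors} min(alpha |u_p - u_q|, d)
                                 + min(alpha |v_p - v_q|, d).

The minimizer is approximated coarse-to-fine: the descriptor images are
average-pooled into a pyramid and, at each level, iterated conditional modes
(ICM) sweeps over a checkerboard update schedule move every pixel to the
displacement in a local search window that minimizes its local energy given
its neighbors.  Each sweep can only lower the energy, so the reported energy
is non-increasing across iterations and always equals :func:`flow_energy`
re-evaluated on the returned field.

The appearance change field is the per-pixel norm of the difference between
descriptors put in correspondence by the flow, capturing split / merge /
disappear events of intracellular cargo that movement alone cannot express.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

DESCRIPTOR_DIM = 128
_PATCH = 16          # descriptor support: 16x16 px
_CELL = 4            # 4x4 cells of 4x4 px
_ORIENT_BINS = 8


@dataclasses.dataclass(frozen=True)
class FlowParams:
    """Energy weights and optimizer controls for SIFT flow.

    Descriptors live on a [0, 255] scale, hence the 255 factors: ``eta``
    penalizes displacement magnitude, ``alpha`` weights the (per-component,
    truncated) smoothness, ``t`` and ``d`` truncate the data and smoothness
    terms.  The smoothness weight is set to a quarter of the weight commonly
    used for richly textured natural scenes (keeping the same alpha:d ratio):
    microscopy frames carry gradients only at the cell boundary and on
    intracellular granules, so a natural-scene smoothness weight overwhelms
    the sparse data term and collapses all motion to zero.  ``search_radius``
    is the per-level ICM move radius in pixels and ``pyramid_levels`` the
    number of coarse-to-fine levels (None: enough levels that the coarsest
    side is >= 8).
    """

    t: float = 40.0 * 255
    d: float = 10.0 * 255
    eta: float = 0.005 * 255
    alpha: float = 0.5 * 255
    search_radius: int = 2
    pyramid_levels: int | None = None
    iterations: int = 5
    # hard cap on |u|, |v| at full resolution (None: search_radius * 2^(levels-1))
    max_displacement: int | None = None

    def __post_init__(self) -> None:
        if min(self.t, self.d, self.eta, self.alpha) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


@dataclasses.dataclass
class FlowField:
    u: np.ndarray             # integer horizontal displacement per pixel
    v: np.ndarray             # integer vertical displacement per pixel
    energy: float             # E(w) of this field
    valid: np.ndarray         # bool mask: target p + w_p inside the image


# ------------------------------------------------------------- dense SIFT

def dense_sift(image: np.ndarray) -> np.ndarray:
    """Per-pixel 128-dim SIFT descriptor image, (H, W, 128) in [0, 255].

    Each descriptor covers a 16x16 neighborhood split into 4x4 cells of 4x4
    pixels with 8 orientation bins, filled with gradient-magnitude-weighted
    orientation histograms; borders are mirror-padded.  Descriptors are
    l2-normalized then scaled to [0, 255]; a gradient-free neighborhood gives
    the zero descriptor.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    h, w = img.shape
    if h < _PATCH or w < _PATCH:
        raise ValueError("image must be at least 16x16")

    half = _PATCH // 2
    pad = half + 1                       # +1 for central differences
    p = np.pad(img, pad, mode="reflect")
    gx = 0.5 * (p[1:-1, 2:] - p[1:-1, :-2])
    gy = 0.5 * (p[2:, 1:-1] - p[:-2, 1:-1])
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), 2 * np.pi)
    obin = np.minimum((theta * _ORIENT_BINS / (2 * np.pi)).astype(int),
                      _ORIENT_BINS - 1)

    ph, pw = mag.shape                   # h + 16, w + 16
    channels = np.zeros((_ORIENT_BINS, ph, pw))
    oy, ox = np.mgrid[0:ph, 0:pw]
    channels[obin.ravel(), oy.ravel(), ox.ravel()] = mag.ravel()

    # 4x4 box sums via cumulative sums: box[y, x] = sum over [y, y+4) x [x, x+4)
    cs = channels.cumsum(axis=1).cumsum(axis=2)
    cs = np.pad(cs, ((0, 0), (1, 0), (1, 0)))
    box = (cs[:, _CELL:, _CELL:] - cs[:, :-_CELL, _CELL:]
           - cs[:, _CELL:, :-_CELL] + cs[:, :-_CELL, :-_CELL])
    box = np.maximum(box, 0.0)        # cumsum cancellation can leave -1e-13

    desc = np.empty((h, w, DESCRIPTOR_DIM))
    k = 0
    for ci in range(_CELL):              # cell row
        for cj in range(_CELL):          # cell col
            y0, x0 = ci * _CELL, cj * _CELL          # cell origin in box coords
            block = box[:, y0:y0 + h, x0:x0 + w]     # (8, h, w)
            desc[..., k * _ORIENT_BINS:(k + 1) * _ORIENT_BINS] = (
                np.moveaxis(block, 0, -1))
            k += 1
    norms = np.linalg.norm(desc, axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        desc = np.where(norms > 0, desc / np.where(norms > 0, norms, 1.0) * 255.0,
                        0.0)
    return desc


# ----------------------------------------------------------------- energy

def flow_energy(s1: np.ndarray, s2: np.ndarray, u: np.ndarray, v: np.ndarray,
                params: FlowParams) -> float:
    """Exact evaluation of E(w); out-of-bounds targets are charged t."""
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    u = np.asarray(u)
    v = np.asarray(v)
    h, w = s1.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    tx, ty = xx + u, yy + v
    valid = (tx >= 0) & (tx < w) & (ty >= 0) & (ty < h)
    txc, tyc = np.clip(tx, 0, w - 1), np.clip(ty, 0, h - 1)
    diff = np.abs(s1 - s2[tyc, txc]).sum(axis=2)
    data = np.where(valid, np.minimum(diff, params.t), params.t).sum()
    disp = params.eta * (np.abs(u) + np.abs(v)).sum()
    smooth = 0.0
    for a in (u, v):
        smooth += np.minimum(params.alpha * np.abs(np.diff(a, axis=0)),
                             params.d).sum()
        smooth += np.minimum(params.alpha * np.abs(np.diff(a, axis=1)),
                             params.d).sum()
    return float(data + disp + smooth)


# --------------------------------------------------------------- optimizer

def _offset_cost(s1, s2, du, dv, t):
    """Data cost of the constant displacement (du, dv), via array slicing."""
    h, w = s1.shape[:2]
    out = np.full((h, w), t)
    y0, y1 = max(0, -dv), min(h, h - dv)
    x0, x1 = max(0, -du), min(w, w - du)
    if y0 < y1 and x0 < x1:
        diff = np.abs(s1[y0:y1, x0:x1]
                      - s2[y0 + dv:y1 + dv, x0 + du:x1 + du]).sum(axis=2)
        out[y0:y1, x0:x1] = np.minimum(diff, t)
    return out


class _CostVolume:
    """Lazily grown dense grid of constant-offset data costs for one level.

    ``grid[iu, iv]`` holds the data-cost map of the constant displacement
    (u0 + iu, v0 + iv); lookups of per-pixel candidate fields are then a
    single fancy-index gather.
    """

    def __init__(self, s1, s2, t):
        self.s1, self.s2, self.t = s1, s2, t
        self.cache: dict[tuple[int, int], np.ndarray] = {}
        h, w = s1.shape[:2]
        self.shape = (h, w)
        self._yy, self._xx = np.mgrid[0:h, 0:w]
        self.grid = None
        self.u0 = self.v0 = 0

    def offset(self, du: int, dv: int) -> np.ndarray:
        key = (du, dv)
        if key not in self.cache:
            self.cache[key] = _offset_cost(self.s1, self.s2, du, dv, self.t)
        return self.cache[key]

    def ensure(self, umin: int, umax: int, vmin: int, vmax: int) -> None:
        if (self.grid is not None and umin >= self.u0 and vmin >= self.v0
                and umax <= self.u0 + self.grid.shape[0] - 1
                and vmax <= self.v0 + self.grid.shape[1] - 1):
            return
        if self.grid is not None:
            umin = min(umin, self.u0)
            vmin = min(vmin, self.v0)
            umax = max(umax, self.u0 + self.grid.shape[0] - 1)
            vmax = max(vmax, self.v0 + self.grid.shape[1] - 1)
        nu, nv = umax - umin + 1, vmax - vmin + 1
        grid = np.empty((nu, nv) + self.shape)
        for iu in range(nu):
            for iv in range(nv):
                grid[iu, iv] = self.offset(umin + iu, vmin + iv)
        self.grid, self.u0, self.v0 = grid, umin, vmin

    def lookup(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Per-pixel data cost of a (possibly non-constant) candidate field."""
        self.ensure(int(u.min()), int(u.max()), int(v.min()), int(v.max()))
        return self.grid[u - self.u0, v - self.v0, self._yy, self._xx]


def _neighbor_stacks(a: np.ndarray):
    """Per-pixel neighbor values (4-connectivity) and an existence mask."""
    h, w = a.shape
    vals = np.zeros((4, h, w))
    mask = np.zeros((4, h, w), dtype=bool)
    vals[0, 1:, :], mask[0, 1:, :] = a[:-1, :], True     # up
    vals[1, :-1, :], mask[1, :-1, :] = a[1:, :], True    # down
    vals[2, :, 1:], mask[2, :, 1:] = a[:, :-1], True     # left
    vals[3, :, :-1], mask[3, :, :-1] = a[:, 1:], True    # right
    return vals, mask


def _icm_sweeps(s1, s2, u, v, params: FlowParams, sweeps: int,
                volume: "_CostVolume | None" = None,
                bound: int | None = None):
    """Checkerboard ICM: each pass moves one parity to its local optimum."""
    h, w = s1.shape[:2]
    if volume is None:
        volume = _CostVolume(s1, s2, params.t)
    if bound is None:
        bound = max(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    parity = (yy + xx) % 2
    r = params.search_radius
    offsets = list(itertools.product(range(-r, r + 1), repeat=2))
    for _ in range(sweeps):
        moved = False
        for par in (0, 1):
            sel = parity == par
            nu, numask = _neighbor_stacks(u)
            nv, _ = _neighbor_stacks(v)
            best_cost = np.full((h, w), np.inf)
            best_u = u.copy()
            best_v = v.copy()
            for du, dv in offsets:
                cu = np.clip(u + du, -bound, bound)
                cv = np.clip(v + dv, -bound, bound)
                cost = volume.lookup(cu, cv)
                cost = cost + params.eta * (np.abs(cu) + np.abs(cv))
                su = np.minimum(params.alpha * np.abs(cu[None] - nu), params.d)
                sv = np.minimum(params.alpha * np.abs(cv[None] - nv), params.d)
                cost = cost + (np.where(numask, su + sv, 0.0)).sum(axis=0)
                better = cost < best_cost - 1e-12
                best_cost = np.where(better, cost, best_cost)
                best_u = np.where(better, cu, best_u)
                best_v = np.where(better, cv, best_v)
            changed = sel & ((best_u != u) | (best_v != v))
            if changed.any():
                moved = True
                u = np.where(changed, best_u, u)
                v = np.where(changed, best_v, v)
        if not moved:
            break
    return u, v


def _pool2(s: np.ndarray) -> np.ndarray:
    """2x2 average pooling of a descriptor image (odd trailing row/col dropped)."""
    h, w = s.shape[:2]
    h2, w2 = h // 2, w // 2
    s = s[: 2 * h2, : 2 * w2]
    return 0.25 * (s[0::2, 0::2] + s[1::2, 0::2] + s[0::2, 1::2] + s[1::2, 1::2])


def _best_match_init(s1, s2, radius, t, center=(0, 0),
                     volume: "_CostVolume | None" = None):
    """Exhaustive per-pixel best data match within ``radius`` of ``center``
    (ignores smoothness)."""
    h, w = s1.shape[:2]
    if volume is None:
        volume = _CostVolume(s1, s2, t)
    best = np.full((h, w), np.inf)
    u = np.zeros((h, w), dtype=int)
    v = np.zeros((h, w), dtype=int)
    cu, cv = int(center[0]), int(center[1])
    for du, dv in itertools.product(range(-radius, radius + 1), repeat=2):
        du, dv = du + cu, dv + cv
        cost = volume.offset(du, dv)
        better = cost < best
        best = np.where(better, cost, best)
        u = np.where(better, du, u)
        v = np.where(better, dv, v)
    return u, v


def estimate_flow(s1: np.ndarray, s2: np.ndarray,
                  params: FlowParams = FlowParams()) -> FlowField:
    """Approximate minimizer of E(w) by coarse-to-fine checkerboard ICM.

    At the coarsest level the sweeps are started from both the zero field and
    the exhaustive best-data-match field, keeping whichever ends lower in
    energy.  The returned ``energy`` is the exact :func:`flow_energy` of the
    output, and it is non-increasing over the optimization.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("descriptor images must have the same shape")

    pyramid = [(s1, s2)]
    max_levels = params.pyramid_levels or 99
    while (len(pyramid) < max_levels
           and min(pyramid[-1][0].shape[:2]) >= 16):
        a, b = pyramid[-1]
        pyramid.append((_pool2(a), _pool2(b)))

    n_levels = len(pyramid)
    cap = (params.max_displacement if params.max_displacement is not None
           else params.search_radius * 2 ** (n_levels - 1))
    u = v = None
    for depth, (a, b) in enumerate(reversed(pyramid)):
        h, w = a.shape[:2]
        # per-level displacement bound: the full-resolution cap shrinks with
        # the downsampling factor, never below the search radius
        bound = max(params.search_radius, cap >> (n_levels - 1 - depth))
        vol = _CostVolume(a, b, params.t)
        cands = []
        if u is None:
            cands.append((np.zeros((h, w), int), np.zeros((h, w), int)))
            cands.append(_best_match_init(a, b, params.search_radius, params.t,
                                          volume=vol))
        else:
            u = np.clip(2 * np.repeat(np.repeat(u, 2, axis=0), 2, axis=1),
                        -bound, bound)[:h, :w]
            v = np.clip(2 * np.repeat(np.repeat(v, 2, axis=0), 2, axis=1),
                        -bound, bound)[:h, :w]
            if u.shape != (h, w):      # pyramid trimmed an odd row/col
                uu = np.zeros((h, w), int)
                vv = np.zeros((h, w), int)
                uu[: u.shape[0], : u.shape[1]] = u
                vv[: v.shape[0], : v.shape[1]] = v
                uu[u.shape[0]:, :] = uu[u.shape[0] - 1: u.shape[0], :]
                vv[u.shape[0]:, :] = vv[u.shape[0] - 1: u.shape[0], :]
                uu[:, u.shape[1]:] = uu[:, u.shape[1] - 1: u.shape[1]]
                vv[:, u.shape[1]:] = vv[:, u.shape[1] - 1: u.shape[1]]
                u, v = uu, vv
            cands.append((u, v))
            # escape route from collective coarse-level minima: re-search the
            # data term around the dominant upsampled displacement
            cu = int(np.clip(np.median(u), -bound + params.search_radius,
                             bound - params.search_radius))
            cv = int(np.clip(np.median(v), -bound + params.search_radius,
                             bound - params.search_radius))
            cands.append(_best_match_init(
                a, b, params.search_radius, params.t,
                center=(cu, cv), volume=vol))
        results = []
        for cu, cv in cands:
            ru, rv = _icm_sweeps(a, b, cu, cv, params, params.iterations,
                                 volume=vol, bound=bound)
            results.append((flow_energy(a, b, ru, rv, params), ru, rv))
        _, u, v = min(results, key=lambda x: x[0])

    energy = flow_energy(s1, s2, u, v, params)
    h, w = s1.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    valid = (xx + u >= 0) & (xx + u < w) & (yy + v >= 0) & (yy + v < h)
    return FlowField(u=u, v=v, energy=energy, valid=valid)


# ------------------------------------------------- appearance change field

def save_flow(path, flow: FlowField) -> None:
    """Store a flow field as a compressed 2-plane array container."""
    np.savez_compressed(path, u=flow.u, v=flow.v, energy=flow.energy,
                        valid=flow.valid)


def load_flow(path) -> FlowField:
    with np.load(path) as z:
        return FlowField(u=z["u"], v=z["v"], energy=float(z["energy"]),
                         valid=z["valid"])


def flow_to_rgb(flow: FlowField, max_magnitude: float | None = None) -> np.ndarray:
    """HSV flow-wheel rendering: hue = direction, saturation = magnitude."""
    from matplotlib.colors import hsv_to_rgb

    mag = np.hypot(flow.u, flow.v)
    if max_magnitude is None:
        max_magnitude = max(float(mag.max()), 1e-9)
    hsv = np.stack([
        np.mod(np.arctan2(flow.v, flow.u), 2 * np.pi) / (2 * np.pi),
        np.clip(mag / max_magnitude, 0, 1),
        np.ones_like(mag),
    ], axis=-1)
    return (hsv_to_rgb(hsv) * 255).astype(np.uint8)


def appearance_change_field(s1: np.ndarray, s2: np.ndarray, flow: FlowField,
                            norm: str = "l2") -> np.ndarray:
    """Per-pixel descriptor discrepancy ||s1_p - s2_{p+w_p}|| along the flow.

    Pixels whose flow target falls outside the image are set to 0 (and are
    already masked in ``flow.valid``).  ``norm`` is "l2" (default) or "l1".
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    h, w = s1.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    txc = np.clip(xx + flow.u, 0, w - 1)
    tyc = np.clip(yy + flow.v, 0, h - 1)
    diff = s1 - s2[tyc, txc]
    if norm == "l2":
        field = np.linalg.norm(diff, axis=2)
    elif norm == "l1":
        field = np.abs(diff).sum(axis=2)
    else:
        raise ValueError("norm must be 'l2' or 'l1'")
    return np.where(flow.valid, field, 0.0)
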