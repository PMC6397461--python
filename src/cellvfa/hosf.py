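"""Histograms of oriented SIFT flow (HOSF) and the combined frame-pair feature.

The movement field is summarized by binning each pixel's flow vector by its
angle from the horizontal axis into R equal sectors of [0, 2pi), weighted by
the flow magnitude (movement histogram, F_MDF) or by the appearance
discrepancy at that pixel (appearance histogram, F_ACF).  Zero-displacement
pixels carry no orientation and are skipped; histograms are restricted to the
(dilated) cell mask.  The frame-pair feature concatenates the contour
deformation feature with both histograms: F = (F_DCS, F_MDF, F_ACF).
"""

from __future__ import annotations

import numpy as np

from .siftflow import FlowField


def _flow_bins(u: np.ndarray, v: np.ndarray, R: int):
    ang = np.mod(np.arctan2(v, u), 2 * np.pi)
    return np.minimum((ang * R / (2 * np.pi)).astype(int), R - 1)


def _select(flow: FlowField, mask: np.ndarray | None):
    mag = np.hypot(flow.u, flow.v)
    sel = (mag > 0) & flow.valid
    if mask is not None:
        if mask.shape != flow.u.shape:
            raise ValueError("mask shape does not match flow field")
        sel &= mask.astype(bool)
    return sel, mag


def _maybe_l1(h: np.ndarray, normalize: bool) -> np.ndarray:
    if normalize and h.sum() > 0:
        return h / h.sum()
    return h


def orient_histogram_mdf(flow: FlowField, R: int,
                         mask: np.ndarray | None = None,
                         normalize: bool = False) -> np.ndarray:
    """Movement histogram: per angular bin, the summed flow magnitude.

    ``normalize`` switches on l1 normalization; by default histograms stay
    unnormalized and the encoding-level normalizations handle scale.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    sel, mag = _select(flow, mask)
    bins = _flow_bins(flow.u, flow.v, R)
    h = np.bincount(bins[sel].ravel(), weights=mag[sel].ravel(),
                    minlength=R).astype(float)
    return _maybe_l1(h, normalize)


def orient_histogram_acf(flow: FlowField, acf: np.ndarray, R: int,
                         mask: np.ndarray | None = None,
                         normalize: bool = False) -> np.ndarray:
    """Appearance histogram: binned by flow angle, weighted by descriptor discrepancy."""
    if R < 2:
        raise ValueError("R must be >= 2")
    acf = np.asarray(acf, dtype=float)
    if acf.shape != flow.u.shape:
        raise ValueError("appearance field shape does not match flow field")
    sel, _ = _select(flow, mask)
    bins = _flow_bins(flow.u, flow.v, R)
    h = np.bincount(bins[sel].ravel(), weights=acf[sel].ravel(),
                    minlength=R).astype(float)
    return _maybe_l1(h, normalize)


def combine_features(f_dcs: np.ndarray, f_mdf: np.ndarray,
                     f_acf: np.ndarray) -> np.ndarray:
    """Concatenate (F_DCS, F_MDF, F_ACF) into one frame-pair feature vector."""
    parts = []
    for name, part in (("f_dcs", f_dcs), ("f_mdf", f_mdf), ("f_acf", f_acf)):
        if part is None:
            raise ValueError(f"missing feature component {name}")
        part = np.asarray(part, dtype=float).ravel()
        if part.size == 0:
            raise ValueError(f"empty feature component {name}")
        parts.append(part)
    out = np.concatenate(parts)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite entries in combined feature")
    return out
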