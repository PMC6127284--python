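"""Pearson and Manders colocalization coefficients for two 3D channels.

Pearson's *r* measures voxel-wise correlation of the two signals inside the
analysis mask.  Manders' M1 is the fraction of channel-A signal lying in
voxels where channel B is above its threshold ("amount of A colocalised
with B"); M2 is the converse.  Thresholds default to an automatic
two-class (Otsu) split per channel; the raw (unthresholded, T = 0) variant
is available via ``thresholded=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

__all__ = ["ColocResult", "pearson", "manders", "coloc_analysis"]


@dataclass
class ColocResult:
    pearson_r: float
    manders_m1: float      # fraction of A signal in supra-threshold B
    manders_m2: float      # fraction of B signal in supra-threshold A
    threshold_a: float
    threshold_b: float
    n_voxels: int
    flags: list[str] = field(default_factory=list)


def _masked(chan_a, chan_b, mask):
    a = np.asarray(chan_a, dtype=float)
    b = np.asarray(chan_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share a shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask must match channel shape")
    return a[mask], b[mask]


def pearson(chan_a: np.ndarray, chan_b: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Voxel-wise Pearson correlation inside the mask (NaN if degenerate)."""
    a, b = _masked(chan_a, chan_b, mask)
    if a.size < 2:
        raise ValueError("need at least 2 masked voxels")
    da, db = a - a.mean(), b - b.mean()
    denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
    if denom == 0:
        warnings.warn("zero variance in a channel; Pearson undefined",
                      stacklevel=2)
        return float("nan")
    return float((da * db).sum() / denom)


def _auto_threshold(values: np.ndarray) -> float:
    if values.size == 0 or values.min() == values.max():
        return float(values.max()) if values.size else 0.0
    return float(threshold_otsu(values))


def manders(chan_a: np.ndarray, chan_b: np.ndarray,
            mask: np.ndarray | None = None,
            thresholds: tuple[float, float] | str = "otsu",
            thresholded: bool = True) -> tuple[float, float]:
    """Manders coefficients ``(M1, M2)``.

    ``M1 = Σ a over voxels with b > T_b / Σ a`` and symmetrically for M2,
    totals taken over the masked voxels.  ``thresholds`` is ``"otsu"`` or an
    explicit ``(T_a, T_b)`` pair; with ``thresholded=False`` both thresholds
    are zero (raw variant).
    """
    a, b = _masked(chan_a, chan_b, mask)
    if not thresholded:
        ta = tb = 0.0
    elif thresholds == "otsu":
        ta, tb = _auto_threshold(a), _auto_threshold(b)
    else:
        ta, tb = map(float, thresholds)
    tot_a, tot_b = a.sum(), b.sum()
    m1 = float(a[b > tb].sum() / tot_a) if tot_a > 0 else float("nan")
    m2 = float(b[a > ta].sum() / tot_b) if tot_b > 0 else float("nan")
    if tot_a <= 0 or tot_b <= 0:
        warnings.warn("zero total signal in a channel; Manders undefined",
                      stacklevel=2)
    return m1, m2


def coloc_analysis(chan_a: np.ndarray, chan_b: np.ndarray,
                   mask: np.ndarray | None = None,
                   thresholds: tuple[float, float] | str = "otsu",
                   thresholded: bool = True,
                   return_overlap_mask: bool = False):
    """Full two-channel colocalization analysis within a mask.

    Returns a :class:`ColocResult`; with ``return_overlap_mask`` also
    returns the both-channels-supra-threshold voxel mask (for overlay
    display; no statistic depends on it).
    """
    a, b = _masked(chan_a, chan_b, mask)
    flags = []
    try:
        r = pearson(chan_a, chan_b, mask)
    except ValueError:
        r, flags = float("nan"), ["pearson undefined"]
    if np.isnan(r) and "pearson undefined" not in flags:
        flags.append("pearson undefined")
    if not thresholded:
        ta = tb = 0.0
    elif thresholds == "otsu":
        ta, tb = _auto_threshold(a), _auto_threshold(b)
    else:
        ta, tb = map(float, thresholds)
    m1, m2 = manders(chan_a, chan_b, mask, thresholds=(ta, tb))
    if np.isnan(m1) or np.isnan(m2):
        flags.append("manders undefined")
    result = ColocResult(pearson_r=r, manders_m1=m1, manders_m2=m2,
                         threshold_a=ta, threshold_b=tb,
                         n_voxels=int(a.size), flags=flags)
    if return_overlap_mask:
        full_mask = (np.ones(np.shape(chan_a), dtype=bool) if mask is None
                     else np.asarray(mask, bool))
        overlap = (np.asarray(chan_a) > ta) & (np.asarray(chan_b) > tb) \
            & full_mask
        return result, overlap
    return result
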