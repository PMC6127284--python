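"""3D puncta segmentation, dendrite-normalised metrics and nanodomain clusters.

Mirrors the super-resolution (3D-SIM) quantifications: isosurface-style
segmentation of surface-receptor puncta with optional watershed splitting of
touching objects, density/volume metrics normalised to the dendritic
segment volume, and detection of scaffold nanodomain centres grouped into
clusters by single-linkage at a fixed linking distance.

All distances honour anisotropic voxel sizes (given per axis in μm,
z/y/x order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

__all__ = ["PunctaSet", "PunctaMetrics", "ClusterProfile", "segment_puncta",
           "puncta_metrics", "detect_nanodomains", "cluster_nanodomains",
           "dendrite_mask_from_cytoskeleton"]

_FULL_CONN = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity


@dataclass
class PunctaSet:
    """Labelled 3D objects with volumes and the parameters that made them."""

    label_image: np.ndarray
    table: pd.DataFrame          # label, n_voxels, volume_um3, z, y, x, peak
    voxel_size: tuple[float, float, float]
    params: dict = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return len(self.table)


@dataclass
class PunctaMetrics:
    """Per-segment metrics, all normalised to dendritic volume (μm³)."""

    puncta_density: float          # count / μm³ dendrite
    total_surface_volume: float    # μm³ puncta / μm³ dendrite
    mean_puncta_volume: float      # mean punctum μm³ / μm³ dendrite
    dendrite_volume_um3: float
    n_objects: int
    per_object: pd.DataFrame


@dataclass
class ClusterProfile:
    """Nanodomain centres grouped into clusters.

    ``histogram`` maps nanodomains-per-cluster to cluster count; singles are
    clusters of size 1.
    """

    centres: np.ndarray            # (n, 3) μm
    cluster_labels: np.ndarray     # (n,) component index per centre
    clusters: list[list[int]]      # member indices per cluster
    histogram: dict[int, int]
    single_nanodomain_density: float | None   # count / μm³, None without mask
    linking_distance: float


def _resolve_threshold(volume: np.ndarray, mask: np.ndarray,
                       threshold) -> float:
    if threshold == "otsu":
        vals = volume[mask]
        if vals.size == 0 or vals.min() == vals.max():
            return float(vals.max()) if vals.size else 0.0
        return float(threshold_otsu(vals))
    return float(threshold)


def _ellipsoid_footprint(radius_um: float,
                         voxel_size: tuple[float, float, float]) -> np.ndarray:
    r_vox = [max(1, int(np.ceil(radius_um / v))) for v in voxel_size]
    grids = np.meshgrid(*[np.arange(-r, r + 1) * v for r, v in
                          zip(r_vox, voxel_size)], indexing="ij")
    d2 = sum((g / radius_um) ** 2 for g in grids)
    return d2 <= 1.0


def segment_puncta(volume: np.ndarray, dendrite_mask: np.ndarray,
                   voxel_size: tuple[float, float, float],
                   threshold="otsu", min_volume: float | None = None,
                   split: bool = True, smoothing_sigma: float = 0.08,
                   seed_separation: float = 0.2) -> PunctaSet:
    """Segment supra-threshold puncta within the dendrite mask.

    Supra-threshold voxels are grouped by 26-connectivity; with ``split``,
    touching objects are divided by marker-based watershed seeded at local
    maxima of the Gaussian-smoothed volume (``smoothing_sigma`` μm, minimum
    seed separation ``seed_separation`` μm).  Objects smaller than
    ``min_volume`` μm³ (default: 8 voxels) are discarded.
    """
    volume = np.asarray(volume, dtype=float)
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    if volume.shape != dendrite_mask.shape:
        raise ValueError("volume and dendrite mask must share a shape")
    voxel_vol = float(np.prod(voxel_size))
    if min_volume is None:
        min_volume = 8 * voxel_vol

    thr = _resolve_threshold(volume, dendrite_mask, threshold)
    binary = (volume > thr) & dendrite_mask
    params = {"threshold": thr, "threshold_mode": threshold,
              "min_volume_um3": min_volume, "split": split,
              "smoothing_sigma_um": smoothing_sigma}

    if not binary.any():
        empty = pd.DataFrame(columns=["label", "n_voxels", "volume_um3",
                                      "z", "y", "x", "peak_intensity"])
        return PunctaSet(np.zeros_like(volume, dtype=np.int32), empty,
                         tuple(voxel_size), params)

    labels, _ = ndi.label(binary, structure=_FULL_CONN)
    if split:
        sigma_vox = [smoothing_sigma / v for v in voxel_size]
        smooth = ndi.gaussian_filter(volume, sigma_vox)
        fp = _ellipsoid_footprint(seed_separation, voxel_size)
        coords = peak_local_max(smooth, footprint=fp, labels=labels,
                                exclude_border=False)
        if len(coords):
            markers = np.zeros_like(labels)
            markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
            labels = watershed(-smooth, markers, mask=binary,
                               connectivity=_FULL_CONN)

    idx = np.arange(1, labels.max() + 1)
    counts = ndi.sum_labels(np.ones_like(labels), labels, idx)
    keep = idx[counts * voxel_vol >= min_volume - 1e-12]
    rows = []
    relabel = np.zeros(labels.max() + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        relabel[old] = new
    labels = relabel[labels]
    if len(keep):
        idx2 = np.arange(1, len(keep) + 1)
        counts2 = ndi.sum_labels(np.ones_like(labels), labels, idx2)
        peaks = ndi.maximum(volume, labels, idx2)
        cents = ndi.center_of_mass(volume, labels, idx2)
        for lab, nvox, pk, com in zip(idx2, counts2, peaks, cents):
            zc, yc, xc = [(c + 0.5) * v for c, v in zip(com, voxel_size)]
            rows.append({"label": int(lab), "n_voxels": int(nvox),
                         "volume_um3": float(nvox) * voxel_vol,
                         "z": zc, "y": yc, "x": xc,
                         "peak_intensity": float(pk)})
    table = pd.DataFrame(rows, columns=["label", "n_voxels", "volume_um3",
                                        "z", "y", "x", "peak_intensity"])
    return PunctaSet(labels.astype(np.int32), table, tuple(voxel_size), params)


def dendrite_mask_from_cytoskeleton(volume: np.ndarray,
                                    voxel_size: tuple[float, float, float],
                                    threshold="otsu",
                                    closing_radius: float = 0.3) -> np.ndarray:
    """Estimate the dendritic volume from a cytoskeleton channel.

    Thresholds the channel (Otsu by default) and closes gaps with an
    ellipsoidal structuring element of ``closing_radius`` μm, the usual
    stand-in when no explicit dendrite mask is supplied.
    """
    volume = np.asarray(volume, dtype=float)
    thr = _resolve_threshold(volume, np.ones_like(volume, dtype=bool),
                             threshold)
    binary = volume > thr
    if closing_radius > 0:
        selem = _ellipsoid_footprint(closing_radius, voxel_size)
        binary = ndi.binary_closing(binary, structure=selem)
    return binary


def puncta_metrics(puncta: PunctaSet, dendrite_mask: np.ndarray,
                   ) -> PunctaMetrics:
    """Density, total volume and mean punctum volume per dendritic volume.

    Only objects intersecting the dendrite mask contribute.  The mean
    punctum volume is itself divided by the dendritic volume, matching the
    per-segment normalisation used for all three reported metrics.
    """
    dendrite_mask = np.asarray(dendrite_mask, dtype=bool)
    voxel_vol = float(np.prod(puncta.voxel_size))
    dvol = float(dendrite_mask.sum()) * voxel_vol
    if dvol <= 0:
        raise ValueError("dendrite mask has zero volume")

    inside = np.unique(puncta.label_image[dendrite_mask])
    inside = inside[inside > 0]
    tab = puncta.table[puncta.table["label"].isin(inside)]
    n = len(tab)
    total = float(tab["volume_um3"].sum())
    mean_vol = float(tab["volume_um3"].mean()) if n else 0.0
    return PunctaMetrics(puncta_density=n / dvol,
                         total_surface_volume=total / dvol,
                         mean_puncta_volume=mean_vol / dvol,
                         dendrite_volume_um3=dvol, n_objects=n,
                         per_object=tab.reset_index(drop=True))


def detect_nanodomains(volume: np.ndarray,
                       voxel_size: tuple[float, float, float],
                       smoothing_sigma: float = 0.06,
                       min_separation: float = 0.15,
                       threshold="otsu") -> np.ndarray:
    """Detect nanodomain centres as smoothed local maxima.

    Maxima of the Gaussian-smoothed volume above the threshold are
    non-maximum-suppressed so that no two kept centres are closer than
    ``min_separation`` μm (anisotropy-aware).  Returns ``(n, 3)`` centres
    in μm (z, y, x).
    """
    volume = np.asarray(volume, dtype=float)
    sigma_vox = [smoothing_sigma / v for v in voxel_size]
    smooth = ndi.gaussian_filter(volume, sigma_vox)
    thr = _resolve_threshold(smooth, np.ones_like(volume, dtype=bool),
                             threshold)
    fp = _ellipsoid_footprint(min_separation, voxel_size)
    coords = peak_local_max(smooth, footprint=fp, threshold_abs=thr,
                            exclude_border=False)
    if len(coords) == 0:
        return np.empty((0, 3))
    centres = _refine_centres(smooth, coords, voxel_size, min_separation)
    # greedy suppression by true metric distance (footprint is voxel-grid)
    order = np.argsort(-smooth[tuple(coords.T)])
    kept: list[int] = []
    for i in order:
        if all(np.linalg.norm(centres[i] - centres[j]) >= min_separation
               for j in kept):
            kept.append(i)
    return centres[sorted(kept)]


def _refine_centres(smooth: np.ndarray, coords: np.ndarray,
                    voxel_size, radius: float) -> np.ndarray:
    """Sub-voxel centres: local intensity-weighted centroid around each peak.

    Removes the ±half-voxel quantisation of grid maxima, which otherwise
    dominates distances between closely spaced nanodomains.
    """
    voxel_size = np.asarray(voxel_size)
    r_vox = np.maximum(1, np.round(0.5 * radius / voxel_size).astype(int))
    out = np.empty((len(coords), 3))
    for i, c in enumerate(coords):
        lo = np.maximum(c - r_vox, 0)
        hi = np.minimum(c + r_vox + 1, smooth.shape)
        patch = smooth[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        w = patch - patch.min()
        if w.sum() <= 0:
            out[i] = (c + 0.5) * voxel_size
            continue
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                            indexing="ij")
        com = [float((g * w).sum() / w.sum()) for g in grids]
        out[i] = (np.asarray(com) + 0.5) * voxel_size
    return out


def cluster_nanodomains(centres: np.ndarray, linking_distance: float = 0.3,
                        dendrite_mask: np.ndarray | None = None,
                        voxel_size: tuple[float, float, float] | None = None,
                        mask_volume_um3: float | None = None) -> ClusterProfile:
    """Group nanodomain centres into single-linkage clusters.

    Clusters are the connected components of the graph joining centres
    within ``linking_distance`` μm.  The single-nanodomain density (size-1
    clusters per μm³) is reported when a dendrite volume is available,
    either directly (``mask_volume_um3``) or from a mask + voxel size.
    """
    centres = np.asarray(centres, dtype=float).reshape(-1, 3)
    n = len(centres)
    if n == 0:
        return ClusterProfile(centres, np.empty(0, dtype=int), [], {},
                              None, linking_distance)
    pairs = cKDTree(centres).query_pairs(linking_distance, output_type="ndarray")
    data = np.ones(len(pairs))
    graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]

    hist: dict[int, int] = {}
    for c in clusters:
        hist[len(c)] = hist.get(len(c), 0) + 1

    vol = mask_volume_um3
    if vol is None and dendrite_mask is not None and voxel_size is not None:
        vol = float(np.asarray(dendrite_mask, bool).sum()
                    * np.prod(voxel_size))
    density = (hist.get(1, 0) / vol) if vol else None
    return ClusterProfile(centres=centres, cluster_labels=labels,
                          clusters=clusters, histogram=hist,
                          single_nanodomain_density=density,
                          linking_distance=linking_distance)
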