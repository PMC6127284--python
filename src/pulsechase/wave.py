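"""Bin-wise wave analysis of pulse-chase movies.

The assay quantifies photoconverted (red) fluorescence spreading out of a
photoconversion ROI: the dendrite is divided into successive 5-μm bins on
either side of the ROI (bin zero), red intensity is summed per bin per
timepoint, and each value is normalised to the bin's area and to the
bin-zero intensity at time zero.  The result — the :class:`WaveMatrix` —
is the central derived object all velocity estimation operates on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .movie import Movie

__all__ = ["DendriteTrace", "BinGrid", "WaveMatrix",
           "extract_bins", "measure_bins", "normalise_wave", "compute_wave"]


@dataclass
class DendriteTrace:
    """Operator-supplied dendrite trace and photoconversion ROI.

    Parameters
    ----------
    points:
        ``(N, 2)`` polyline vertices in μm, image (x, y) coordinates,
        ordered from the proximal to the distal end.
    width:
        Dendrite width in μm — a scalar, or one value per vertex.
    roi_centre:
        Arc-length position of the ROI centre along the polyline, μm.
    roi_halfwidth:
        Half-length of the photoconversion ROI along the arc, μm.
    """

    points: np.ndarray
    width: float | np.ndarray
    roi_centre: float
    roi_halfwidth: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2:
            raise ValueError("trace needs at least 2 polyline points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("polyline arc length must strictly increase")
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])
        if np.isscalar(self.width):
            self.width = np.full(len(self.points), float(self.width))
        else:
            self.width = np.asarray(self.width, dtype=float)
            if len(self.width) != len(self.points):
                raise ValueError("need one width per vertex (or a scalar)")
        if (self.roi_centre - self.roi_halfwidth < -1e-9
                or self.roi_centre + self.roi_halfwidth > self.total_arc + 1e-9):
            raise ValueError("ROI footprint must lie within the traced extent")

    @property
    def total_arc(self) -> float:
        return float(self._arc[-1])

    def resample(self, step: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Densely resample to (points, arc positions, widths) at ``step`` μm."""
        s = np.arange(0.0, self.total_arc + step / 2, step)
        s[-1] = min(s[-1], self.total_arc)
        x = np.interp(s, self._arc, self.points[:, 0])
        y = np.interp(s, self._arc, self.points[:, 1])
        w = np.interp(s, self._arc, self.width)
        return np.column_stack([x, y]), s, w


@dataclass
class BinGrid:
    """Pixel-level assignment of a movie frame to arc-length bins.

    ``index_image`` maps every pixel to a bin code (−1 = outside the
    ribbon); ``bins`` lists, per (direction, label), the pixel count, area
    and truncation flag.  Bin labels are the distance in μm from the ROI
    edge to the bin's *outer* boundary, so "the 10-μm bin" spans (5, 10] μm
    beyond the ROI; bin zero is the ROI footprint itself.
    """

    bin_width: float
    pixel_size: float
    index_image: np.ndarray                 # (H, W) int codes, −1 outside
    bins: pd.DataFrame                      # direction, bin, code, n_pixels,
                                            # area_um2, truncated

    def area(self, direction: str, label: float) -> float:
        row = self._row(direction, label)
        return float(row["area_um2"])

    def mask(self, direction: str, label: float) -> np.ndarray:
        row = self._row(direction, label)
        return self.index_image == int(row["code"])

    def labels(self, direction: str, include_truncated: bool = False):
        sel = self.bins[self.bins["direction"] == direction]
        if not include_truncated:
            sel = sel[~sel["truncated"]]
        return list(sel["bin"])

    def _row(self, direction: str, label: float) -> pd.Series:
        sel = self.bins[(self.bins["direction"] == direction)
                        & (self.bins["bin"] == label)]
        if sel.empty:
            raise KeyError(f"no bin ({direction}, {label})")
        return sel.iloc[0]


def extract_bins(trace: DendriteTrace, shape: tuple[int, int],
                 pixel_size: float, bin_width: float = 5.0) -> BinGrid:
    """Tile 5-μm (by default) bins along the dendrite arc from the ROI edges.

    Pixels are assigned by nearest-arc-point lookup within the dendrite
    ribbon (perpendicular distance ≤ local half-width).  Bin intervals are
    half-open with the outer boundary included; a pixel exactly on a
    boundary goes to the more proximal bin.  Bins whose outer boundary
    exceeds the traced extent are flagged ``truncated`` and later excluded
    from velocity estimation.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    h, w = shape
    pts, arc, widths = trace.resample(step=pixel_size / 4.0)
    tree = cKDTree(pts)

    xs = (np.arange(w) + 0.5) * pixel_size
    ys = (np.arange(h) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = tree.query(centres, workers=-1)
    s = arc[idx]
    in_ribbon = dist <= widths[idx] / 2.0

    rel = s - trace.roi_centre
    code_img = np.full(h * w, -1, dtype=int)
    rows = []
    eps = 1e-9

    def add_bin(direction: str, label: float, sel: np.ndarray,
                truncated: bool, code: int) -> None:
        code_img[sel] = code
        npx = int(sel.sum())
        rows.append({"direction": direction, "bin": label, "code": code,
                     "n_pixels": npx, "area_um2": npx * pixel_size ** 2,
                     "truncated": truncated})

    code = 0
    zero_sel = in_ribbon & (np.abs(rel) <= trace.roi_halfwidth + eps)
    add_bin("zero", 0.0, zero_sel, False, code)
    code += 1

    for direction, d in (("distal", rel - trace.roi_halfwidth),
                         ("proximal", -rel - trace.roi_halfwidth)):
        extent = (trace.total_arc - trace.roi_centre - trace.roi_halfwidth
                  if direction == "distal"
                  else trace.roi_centre - trace.roi_halfwidth)
        n_bins = int(math.ceil(max(extent, 0.0) / bin_width - eps))
        if n_bins == 0:
            warnings.warn(f"trace shorter than one bin on the {direction} side",
                          stacklevel=2)
            continue
        for k in range(1, n_bins + 1):
            label = k * bin_width
            sel = in_ribbon & (d > (label - bin_width) + eps) & (d <= label + eps)
            truncated = label > extent + eps
            add_bin(direction, label, sel, truncated, code)
            code += 1

    bins = pd.DataFrame(rows)
    if int(bins.loc[bins["direction"] == "zero", "n_pixels"].iloc[0]) == 0:
        raise ValueError("ROI footprint contains no pixels")
    return BinGrid(bin_width=bin_width, pixel_size=pixel_size,
                   index_image=code_img.reshape(h, w), bins=bins)


def measure_bins(movie: Movie, grid: BinGrid,
                 background: float | np.ndarray | None = None) -> pd.DataFrame:
    """Sum background-subtracted intensity per bin per timepoint.

    ``background`` may be ``None`` (no subtraction), a constant per-pixel
    offset, or a boolean mask of off-cell pixels whose per-frame mean is
    subtracted.  Returns a tidy frame (direction, bin, time_s, raw) plus the
    per-frame background in ``df.attrs["background_per_frame"]``.
    """
    if grid.index_image.shape != movie.shape:
        raise ValueError("bin grid does not match movie frame shape")
    if (grid.bins["n_pixels"] == 0).any():
        empty = grid.bins[grid.bins["n_pixels"] == 0]
        raise ValueError("empty bin mask(s): "
                         + ", ".join(f"({r.direction}, {r.bin:g})"
                                     for r in empty.itertuples()))

    codes = grid.index_image.ravel()
    n_codes = int(codes.max()) + 1
    valid = codes >= 0

    if background is None:
        bg = np.zeros(movie.n_frames)
    elif isinstance(background, np.ndarray):
        if background.dtype != bool or background.shape != movie.shape:
            raise ValueError("background mask must be boolean, frame-shaped")
        if (background.ravel() & valid).any():
            raise ValueError("background region overlaps the dendrite bins")
        bg = movie.frames[:, background].mean(axis=1)
    else:
        bg = np.full(movie.n_frames, float(background))

    rows = []
    npx = np.bincount(codes[valid], minlength=n_codes)
    for ti, t in enumerate(movie.timepoints):
        flat = movie.frames[ti].ravel()
        sums = np.bincount(codes[valid], weights=flat[valid], minlength=n_codes)
        raw = sums - npx * bg[ti]
        for r in grid.bins.itertuples():
            rows.append({"direction": r.direction, "bin": r.bin,
                         "time_s": t, "raw": raw[r.code]})
    out = pd.DataFrame(rows)
    out.attrs["background_per_frame"] = bg
    return out


@dataclass
class WaveMatrix:
    """Doubly normalised bin × time fluorescence.

    ``value(b, t) = [raw(b, t)/A(b)] / [raw(0, 0)/A(0)]`` — intensity per
    unit dendritic area, relative to the ROI at the moment of
    photoconversion.  ``value(bin 0, t=0)`` is exactly 1.
    """

    table: pd.DataFrame          # direction, bin, time_s, value, truncated
    timepoints: np.ndarray
    normalisation: dict = field(default_factory=dict)

    def value(self, direction: str, label: float, time_s: float) -> float:
        sel = self.table[(self.table["direction"] == direction)
                         & (self.table["bin"] == label)
                         & (self.table["time_s"] == time_s)]
        if sel.empty:
            raise KeyError(f"no value at ({direction}, {label}, {time_s})")
        return float(sel["value"].iloc[0])

    def series(self, direction: str, label: float) -> pd.Series:
        sel = self.table[(self.table["direction"] == direction)
                         & (self.table["bin"] == label)].sort_values("time_s")
        if sel.empty:
            raise KeyError(f"no bin ({direction}, {label})")
        return pd.Series(sel["value"].to_numpy(), index=sel["time_s"].to_numpy())

    def pivot(self, direction: str) -> pd.DataFrame:
        sel = self.table[self.table["direction"] == direction]
        return sel.pivot(index="bin", columns="time_s", values="value")

    def labels(self, direction: str, include_truncated: bool = False):
        sel = self.table[self.table["direction"] == direction]
        if not include_truncated:
            sel = sel[~sel["truncated"]]
        return sorted(sel["bin"].unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WaveMatrix":
        table = pd.read_csv(path)
        if "truncated" not in table:
            table["truncated"] = False
        t = np.sort(table["time_s"].unique())
        return cls(table=table, timepoints=t)


def normalise_wave(raw: pd.DataFrame, grid: BinGrid) -> WaveMatrix:
    """Normalise raw bin sums to bin area and to bin zero at time zero."""
    t0 = raw["time_s"].min()
    ref_rows = raw[(raw["direction"] == "zero") & (raw["time_s"] == t0)]
    if ref_rows.empty:
        raise ValueError("raw table lacks bin zero at time zero")
    a0 = grid.area("zero", 0.0)
    ref = float(ref_rows["raw"].iloc[0]) / a0
    if ref <= 0:
        raise ValueError("no photoconverted signal in ROI "
                         "(bin zero at time zero is non-positive)")

    areas = {(r.direction, r.bin): r.area_um2 for r in grid.bins.itertuples()}
    trunc = {(r.direction, r.bin): r.truncated for r in grid.bins.itertuples()}
    table = raw.copy()
    table["value"] = [
        r.raw / areas[(r.direction, r.bin)] / ref for r in table.itertuples()
    ]
    table["truncated"] = [
        trunc[(r.direction, r.bin)] for r in table.itertuples()
    ]
    table = table.drop(columns=["raw"])
    table.attrs = {}   # provenance lives in the normalisation record
    norm = {
        "reference_density": ref,
        "areas_um2": {f"{k[0]}:{k[1]:g}": v for k, v in areas.items()},
        "background_per_frame": list(
            np.asarray(raw.attrs.get("background_per_frame", []))),
    }
    return WaveMatrix(table=table,
                      timepoints=np.sort(raw["time_s"].unique()),
                      normalisation=norm)


def compute_wave(movie: Movie, trace: DendriteTrace, bin_width: float = 5.0,
                 background: float | np.ndarray | None = None,
                 grid: BinGrid | None = None) -> WaveMatrix:
    """Full pipeline: bin extraction, measurement, normalisation.

    A precomputed ``grid`` may be supplied when many movies share the same
    geometry (e.g. simulation batches).
    """
    if grid is None:
        grid = extract_bins(trace, movie.shape, movie.pixel_size, bin_width)
    raw = measure_bins(movie, grid, background=background)
    return normalise_wave(raw, grid)
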