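"""Synthetic data generators.

Three generators provide ground-truth-known inputs for every analysis in
the package:

* :func:`simulate_pulse_chase` — a particle-based advection–diffusion
  simulation of a photoconverted receptor pool spreading bidirectionally
  along a dendrite, rendered as a PSF-blurred, Poisson-noisy movie.  The
  photoconverted pool is modelled as a mixture of a stationary fraction,
  a slow advective–diffusive majority (the endoplasmic-reticulum-associated
  pool, ~0.2 μm/s) and a fast, purely advective minority (receptor-carrying
  transport vesicles, ~0.82 μm/s).
* :func:`make_coloc_volume` — two-channel 3D volumes of ellipsoidal surface
  puncta (channel A) and clustered nanodomain spots (channel B) with a
  controlled co-placement fraction, for segmentation / colocalization tests.
* :func:`make_enrichment_universe` — a gene universe with differential
  expression planted at a configurable fold enrichment inside named loci.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .movie import Movie

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_pulse_chase",
    "straight_trace",
    "off_cell_background_mask",
    "Punctum",
    "VolumeSpec",
    "ColocVolume",
    "make_coloc_volume",
    "random_coloc_spec",
    "EnrichmentTruth",
    "make_enrichment_universe",
]

_POPULATIONS = ("stationary", "slow_distal", "slow_proximal",
                "fast_distal", "fast_proximal")


@dataclass
class SimulationConfig:
    """Parameters of the pulse-chase simulation.

    Defaults reproduce the acquisition of the assay this package
    quantifies: frames every 15 s for 3 min, a slow pool at 0.2 μm/s and a
    fast pool at 0.82 μm/s, bidirectional transport out of a 5-μm
    photoconversion ROI placed mid-dendrite.

    The motile pool is split 80/20 between slow and fast particles.  The
    slow pool departs immediately and advects with diffusion
    (``diffusion_slow``) — the bulk "crest".  Fast particles represent
    transport vesicles loaded and dispatched over time: each departs after
    an exponential delay of mean ``fast_departure_mean`` seconds and then
    advects at a constant speed, so the leading edge travels at exactly
    ``v_fast`` while distal bins stay occupied once reached.  An optional
    per-particle speed dispersion (``fast_velocity_cv``) is available.
    """

    n_particles: int = 2000
    frac_stationary: float = 0.30
    frac_slow_distal: float = 0.28
    frac_slow_proximal: float = 0.28
    frac_fast_distal: float = 0.07
    frac_fast_proximal: float = 0.07
    v_slow: float = 0.2            # μm/s
    v_fast: float = 0.82           # μm/s
    diffusion_slow: float = 0.05   # μm²/s
    fast_departure_mean: float = 30.0  # s, exponential loading delay
    fast_velocity_cv: float = 0.0  # relative SD of per-particle fast speeds
    dendrite_length: float = 100.0  # μm
    dendrite_width: float = 2.0     # μm
    roi_centre: float | None = None  # arc position, μm; default mid-dendrite
    roi_halfwidth: float = 2.5      # μm
    pixel_size: float = 0.1         # μm
    frame_interval: float = 15.0    # s
    duration: float = 180.0         # s
    psf_sigma: float = 0.15         # μm
    photons_per_particle: float = 50.0
    background_level: float = 10.0  # photons per pixel
    noise_on: bool = True
    # optional planted effect: extra stationary fluorescence centred at an
    # arc offset (μm, measured from the distal ROI edge), spread over ±2.5 μm
    depot_offset: float | None = None
    depot_particles: int = 0
    seed: int = 0

    @property
    def fractions(self) -> np.ndarray:
        return np.array([getattr(self, "frac_" + p) for p in _POPULATIONS])

    def validate(self) -> None:
        f = self.fractions
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("population fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"population fractions must sum to 1 (got {f.sum():.12g})")
        if not self.v_slow < self.v_fast:
            raise ValueError("v_slow must be smaller than v_fast")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame interval")

    @property
    def roi_centre_resolved(self) -> float:
        return (self.dendrite_length / 2.0 if self.roi_centre is None
                else self.roi_centre)

    @property
    def timepoints(self) -> np.ndarray:
        n = int(math.ceil(self.duration / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval


@dataclass
class GroundTruth:
    """Per-particle truth accompanying a simulated movie.

    ``trajectories`` holds the advection-only arc position of every particle
    at every frame (no Brownian term), so that regressing position on time
    over the frames after a particle's departure recovers its assigned
    velocity exactly.  ``positions`` holds the rendered positions including
    diffusion.
    """

    particles: pd.DataFrame          # population, direction, velocity,
                                     # departure_s, x0, y0
    trajectories: np.ndarray         # (n, T) advection-only arc positions, μm
    positions: np.ndarray            # (n, T) rendered arc positions, μm
    v_slow: float
    v_fast: float
    flags: dict = field(default_factory=dict)


def _population_labels(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Assign particles to populations with exact (largest-remainder) counts."""
    target = cfg.fractions * cfg.n_particles
    counts = np.floor(target).astype(int)
    remainder = cfg.n_particles - counts.sum()
    order = np.argsort(-(target - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(len(_POPULATIONS)), counts)
    return rng.permutation(labels)


def simulate_pulse_chase(cfg: SimulationConfig) -> tuple[Movie, GroundTruth]:
    """Simulate a photoconversion pulse-chase movie.

    Particles start uniformly inside the ROI footprint (the photoconverted
    pool) and follow ``x(t) = x0 ± v t`` plus, for the slow pool, a Brownian
    term with diffusion coefficient ``diffusion_slow``.  Each particle is
    rendered as a 2D Gaussian PSF on a straight, constant-width dendrite
    ribbon; Poisson shot noise and a uniform background are added when
    ``noise_on``.  Particles advecting past either dendrite tip are absorbed.

    Returns
    -------
    (movie, truth):
        The rendered :class:`~pulsechase.movie.Movie` and the
        :class:`GroundTruth` bookkeeping.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = cfg.timepoints
    n_frames = len(t)
    roi_c = cfg.roi_centre_resolved

    labels = _population_labels(cfg, rng)
    popnames = np.array(_POPULATIONS)[labels]
    n = cfg.n_particles

    x0 = rng.uniform(roi_c - cfg.roi_halfwidth, roi_c + cfg.roi_halfwidth, n)
    y0 = rng.uniform(0.0, cfg.dendrite_width, n)

    speed = np.zeros(n)
    speed[popnames == "slow_distal"] = cfg.v_slow
    speed[popnames == "slow_proximal"] = -cfg.v_slow
    for pop, sign in (("fast_distal", 1.0), ("fast_proximal", -1.0)):
        sel = popnames == pop
        m = int(sel.sum())
        if m:
            z = rng.standard_normal(m)
            if m > 1:
                z -= z.mean()  # pool-mean speed equals v_fast exactly
            speed[sel] = sign * cfg.v_fast * (1.0 + cfg.fast_velocity_cv * z)

    direction = np.where(speed > 0, "distal",
                         np.where(speed < 0, "proximal", "none"))

    departure = np.zeros(n)
    is_fast = np.isin(popnames, ("fast_distal", "fast_proximal"))
    if cfg.fast_departure_mean > 0 and is_fast.any():
        departure[is_fast] = rng.exponential(cfg.fast_departure_mean,
                                             int(is_fast.sum()))

    # planted depot: extra stationary signal at a fixed distal arc offset
    if cfg.depot_offset is not None and cfg.depot_particles > 0:
        nd = cfg.depot_particles
        centre = roi_c + cfg.roi_halfwidth + cfg.depot_offset
        x0 = np.concatenate([x0, rng.uniform(centre - 2.5, centre + 2.5, nd)])
        y0 = np.concatenate([y0, rng.uniform(0.0, cfg.dendrite_width, nd)])
        speed = np.concatenate([speed, np.zeros(nd)])
        popnames = np.concatenate([popnames, np.repeat("depot", nd)])
        direction = np.concatenate([direction, np.repeat("none", nd)])
        departure = np.concatenate([departure, np.zeros(nd)])
        n += nd

    moving_time = np.clip(t[None, :] - departure[:, None], 0.0, None)
    adv = x0[:, None] + speed[:, None] * moving_time

    pos = adv.copy()
    is_slow = np.isin(popnames, ("slow_distal", "slow_proximal"))
    if cfg.diffusion_slow > 0 and is_slow.any() and n_frames > 1:
        dt = np.diff(t)
        steps = rng.standard_normal((int(is_slow.sum()), n_frames - 1))
        steps *= np.sqrt(2.0 * cfg.diffusion_slow * dt)[None, :]
        pos[is_slow, 1:] += np.cumsum(steps, axis=1)

    # absorbing tips: a particle is removed once it leaves [0, L]
    inside = (pos >= 0.0) & (pos <= cfg.dendrite_length)
    alive = np.minimum.accumulate(inside, axis=1)
    any_absorbed = bool((~alive[:, -1]).any())

    frames = _render_frames(cfg, pos, np.repeat(y0[:, None], n_frames, axis=1),
                            alive)
    frames += cfg.background_level
    if cfg.noise_on:
        frames = rng.poisson(frames).astype(float)

    movie = Movie(frames=frames, pixel_size=cfg.pixel_size,
                  frame_interval=cfg.frame_interval, timepoints=t)

    distal_extent = cfg.dendrite_length - (roi_c + cfg.roi_halfwidth)
    proximal_extent = roi_c - cfg.roi_halfwidth
    flags = {
        "particles_absorbed": any_absorbed,
        "distal_bins_truncated_before_40um": distal_extent < 40.0,
        "proximal_bins_truncated_before_40um": proximal_extent < 40.0,
    }
    if flags["distal_bins_truncated_before_40um"]:
        warnings.warn("dendrite too short for complete distal 40-μm bins",
                      stacklevel=2)

    particles = pd.DataFrame({
        "population": popnames,
        "direction": direction,
        "velocity": speed,
        "departure_s": departure,
        "x0": x0,
        "y0": y0,
        "absorbed": ~alive[:, -1],
    })
    truth = GroundTruth(particles=particles, trajectories=adv, positions=pos,
                        v_slow=cfg.v_slow, v_fast=cfg.v_fast, flags=flags)
    return movie, truth


# ribbon is drawn with a 1-μm off-cell margin above and below
_PAD_UM = 1.0


def _frame_shape(cfg: SimulationConfig) -> tuple[int, int]:
    w = int(round(cfg.dendrite_length / cfg.pixel_size))
    h = int(round((cfg.dendrite_width + 2 * _PAD_UM) / cfg.pixel_size))
    return h, w


def _render_frames(cfg: SimulationConfig, x: np.ndarray, y: np.ndarray,
                   alive: np.ndarray) -> np.ndarray:
    """Stamp Gaussian PSFs onto each frame (vectorised over particles)."""
    h, w = _frame_shape(cfg)
    n_frames = x.shape[1]
    frames = np.zeros((n_frames, h, w))
    sig_px = cfg.psf_sigma / cfg.pixel_size
    r = max(2, int(math.ceil(4.0 * sig_px)))
    off = np.arange(-r, r + 1)
    amp = cfg.photons_per_particle / (2.0 * math.pi * sig_px ** 2)
    for ti in range(n_frames):
        sel = alive[:, ti]
        if not sel.any():
            continue
        px = x[sel, ti] / cfg.pixel_size - 0.5
        py = (y[sel, ti] + _PAD_UM) / cfg.pixel_size - 0.5
        cx = np.round(px).astype(int)
        cy = np.round(py).astype(int)
        gx = cx[:, None] + off[None, :]          # (m, k)
        gy = cy[:, None] + off[None, :]
        ex = np.exp(-((gx - px[:, None]) ** 2) / (2 * sig_px ** 2))
        ey = np.exp(-((gy - py[:, None]) ** 2) / (2 * sig_px ** 2))
        patch = amp * ey[:, :, None] * ex[:, None, :]   # (m, k, k)
        yy = np.broadcast_to(gy[:, :, None], patch.shape)
        xx = np.broadcast_to(gx[:, None, :], patch.shape)
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        np.add.at(frames[ti], (yy[ok], xx[ok]), patch[ok])
    return frames


def straight_trace(cfg: SimulationConfig):
    """Dendrite trace matching the simulated straight-ribbon geometry."""
    from .wave import DendriteTrace
    yc = _PAD_UM + cfg.dendrite_width / 2.0
    return DendriteTrace(
        points=np.array([[0.0, yc], [cfg.dendrite_length, yc]]),
        width=cfg.dendrite_width,
        roi_centre=cfg.roi_centre_resolved,
        roi_halfwidth=cfg.roi_halfwidth,
    )


def off_cell_background_mask(cfg: SimulationConfig) -> np.ndarray:
    """Boolean mask of pixels far enough from the ribbon to sample background.

    Uses the strip more than 4 PSF sigmas above the ribbon edge.
    """
    h, w = _frame_shape(cfg)
    ys = (np.arange(h) + 0.5) * cfg.pixel_size
    clear = _PAD_UM - 4.0 * cfg.psf_sigma
    mask = np.zeros((h, w), dtype=bool)
    mask[ys < clear, :] = True
    return mask


# ---------------------------------------------------------------------------
# 3D two-channel volumes


@dataclass
class Punctum:
    """An ellipsoidal blob: centre and radii in μm (z, y, x order)."""
    centre: tuple[float, float, float]
    radii: tuple[float, float, float]
    intensity: float
    channel: str  # "A" or "B"


@dataclass
class VolumeSpec:
    """Layout of a synthetic two-channel 3D volume.

    Channel A holds surface-receptor puncta; channel B holds scaffold
    nanodomain spots arranged in clusters (``cluster_layout``) plus any
    puncta listed with ``channel == "B"``.  ``coloc_fraction`` records the
    fraction of channel-A puncta that were co-placed with a channel-B
    punctum (bookkeeping for specs built by :func:`random_coloc_spec`).
    """

    shape: tuple[int, int, int]                      # voxels (z, y, x)
    voxel_size: tuple[float, float, float]           # μm per axis (z, y, x)
    puncta: list[Punctum] = field(default_factory=list)
    cluster_layout: list[list[tuple[float, float, float]]] = field(
        default_factory=list)
    coloc_fraction: float = 0.0
    nanodomain_radius: float = 0.12     # μm
    nanodomain_intensity: float = 120.0
    dendrite_box: tuple | None = None   # ((z0,z1),(y0,y1),(x0,x1)) voxels
    smoothing_sigma: float = 0.03       # μm, edge softening
    background: float = 0.0
    noise_on: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        extent = np.array(self.shape) * np.array(self.voxel_size)
        for p in self.puncta:
            if np.any(np.asarray(p.radii) <= 0):
                raise ValueError("punctum radii must be positive")
            if np.any(np.asarray(p.centre) < 0) or np.any(
                    np.asarray(p.centre) >= extent):
                raise ValueError("punctum centre outside the volume")
        for cluster in self.cluster_layout:
            for c in cluster:
                if np.any(np.asarray(c) < 0) or np.any(np.asarray(c) >= extent):
                    raise ValueError("nanodomain centre outside the volume")


@dataclass
class ColocVolume:
    """Rendered volume pair plus ground truth tables."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    dendrite_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    puncta_table: pd.DataFrame       # per punctum: channel, centre, volume...
    cluster_histogram: dict[int, int]
    overlap_fraction_a_in_b: float   # fraction of A signal inside B support
    overlap_fraction_b_in_a: float
    collapsed_puncta: int            # puncta sharing an identical centre


def _ellipsoid_mask(shape, voxel_size, centre, radii) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[
        (np.arange(s) + 0.5) * v for s, v in zip(shape, voxel_size)
    ], indexing="ij")
    d = (((zz - centre[0]) / radii[0]) ** 2
         + ((yy - centre[1]) / radii[1]) ** 2
         + ((xx - centre[2]) / radii[2]) ** 2)
    return d <= 1.0


def make_coloc_volume(spec: VolumeSpec) -> ColocVolume:
    """Render a two-channel volume and its ground truth.

    Puncta are rendered as hard ellipsoids of their intensity (softened by a
    small Gaussian blur) so that voxelised object volumes are well defined;
    nanodomains are small spheres of radius ``nanodomain_radius``.  Ground
    truth includes exact per-object voxel volumes, the planted cluster-size
    histogram and supra-zero overlap fractions between the channels.
    """
    from scipy import ndimage as ndi

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    vol_a = np.zeros(spec.shape)
    vol_b = np.zeros(spec.shape)
    voxel_vol = float(np.prod(spec.voxel_size))

    rows = []
    seen_centres: set[tuple] = set()
    collapsed = 0
    for i, p in enumerate(spec.puncta):
        key = (p.channel, tuple(np.round(p.centre, 9)))
        if key in seen_centres:
            collapsed += 1
        seen_centres.add(key)
        m = _ellipsoid_mask(spec.shape, spec.voxel_size, p.centre, p.radii)
        target = vol_a if p.channel == "A" else vol_b
        np.maximum(target, m * p.intensity, out=target)
        rows.append({"object": i, "channel": p.channel,
                     "z": p.centre[0], "y": p.centre[1], "x": p.centre[2],
                     "intensity": p.intensity,
                     "n_voxels": int(m.sum()),
                     "volume_um3": float(m.sum()) * voxel_vol})

    r = spec.nanodomain_radius
    for ci, cluster in enumerate(spec.cluster_layout):
        for c in cluster:
            m = _ellipsoid_mask(spec.shape, spec.voxel_size, c, (r, r, r))
            np.maximum(vol_b, m * spec.nanodomain_intensity, out=vol_b)
            rows.append({"object": len(rows), "channel": "B_nanodomain",
                         "z": c[0], "y": c[1], "x": c[2],
                         "intensity": spec.nanodomain_intensity,
                         "n_voxels": int(m.sum()),
                         "volume_um3": float(m.sum()) * voxel_vol,
                         "cluster": ci})

    sup_a, sup_b = vol_a > 0, vol_b > 0
    tot_a, tot_b = vol_a.sum(), vol_b.sum()
    frac_a = float(vol_a[sup_b].sum() / tot_a) if tot_a > 0 else float("nan")
    frac_b = float(vol_b[sup_a].sum() / tot_b) if tot_b > 0 else float("nan")

    if spec.smoothing_sigma > 0:
        sig = [spec.smoothing_sigma / v for v in spec.voxel_size]
        vol_a = ndi.gaussian_filter(vol_a, sig)
        vol_b = ndi.gaussian_filter(vol_b, sig)
    vol_a += spec.background
    vol_b += spec.background
    if spec.noise_on:
        vol_a = rng.poisson(vol_a).astype(float)
        vol_b = rng.poisson(vol_b).astype(float)

    mask = np.ones(spec.shape, dtype=bool)
    if spec.dendrite_box is not None:
        mask[:] = False
        (z0, z1), (y0, y1), (x0, x1) = spec.dendrite_box
        mask[z0:z1, y0:y1, x0:x1] = True

    hist: dict[int, int] = {}
    for cluster in spec.cluster_layout:
        hist[len(cluster)] = hist.get(len(cluster), 0) + 1

    return ColocVolume(channel_a=vol_a, channel_b=vol_b, dendrite_mask=mask,
                       voxel_size=spec.voxel_size,
                       puncta_table=pd.DataFrame(rows),
                       cluster_histogram=hist,
                       overlap_fraction_a_in_b=frac_a,
                       overlap_fraction_b_in_a=frac_b,
                       collapsed_puncta=collapsed)


def random_coloc_spec(n_puncta: int = 20,
                      coloc_fraction: float = 0.5,
                      cluster_sizes: tuple[int, ...] = (1, 1, 2, 3),
                      shape: tuple[int, int, int] = (32, 128, 128),
                      voxel_size: tuple[float, float, float] = (0.1, 0.05, 0.05),
                      punctum_radius: float = 0.3,
                      punctum_intensity: float = 100.0,
                      min_gap: float = 0.9,
                      seed: int = 0) -> VolumeSpec:
    """Build a :class:`VolumeSpec` with randomly placed, well-separated objects.

    Channel-A puncta are spheres of ``punctum_radius``; a planted fraction of
    them (``coloc_fraction``, realised exactly by count) receives a co-placed
    channel-B punctum.  Nanodomain clusters of the requested sizes are laid
    out with intra-cluster spacing of ~0.25 μm and inter-object gaps of at
    least ``min_gap``.
    """
    rng = np.random.default_rng(seed)
    extent = np.array(shape) * np.array(voxel_size)
    margin = punctum_radius + 0.2

    def draw_centre(existing: list, gap: float) -> tuple[float, float, float]:
        for _ in range(10000):
            c = rng.uniform(margin, extent - margin)
            if all(np.linalg.norm(c - np.asarray(e)) >= gap for e in existing):
                return tuple(c)
        raise RuntimeError("could not place objects with the requested gap")

    anchors: list[tuple[float, float, float]] = []
    puncta: list[Punctum] = []
    n_coloc = int(round(coloc_fraction * n_puncta))
    coloc_flags = np.zeros(n_puncta, dtype=bool)
    coloc_flags[rng.permutation(n_puncta)[:n_coloc]] = True
    for i in range(n_puncta):
        c = draw_centre(anchors, min_gap)
        anchors.append(c)
        rr = (punctum_radius,) * 3
        puncta.append(Punctum(c, rr, punctum_intensity, "A"))
        if coloc_flags[i]:
            puncta.append(Punctum(c, rr, punctum_intensity, "B"))

    layout: list[list[tuple[float, float, float]]] = []
    step = 0.25
    for size in cluster_sizes:
        for _ in range(10000):
            anchor = np.asarray(draw_centre(anchors, min_gap + step * size))
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            members = [anchor + step * j * d for j in range(size)]
            if all(np.all(m >= margin) and np.all(m <= extent - margin)
                   for m in members):
                break
        else:
            raise RuntimeError("could not place a cluster inside the volume")
        anchors.extend(tuple(m) for m in members)
        layout.append([tuple(m) for m in members])

    return VolumeSpec(shape=shape, voxel_size=voxel_size, puncta=puncta,
                      cluster_layout=layout, coloc_fraction=n_coloc / n_puncta
                      if n_puncta else 0.0, seed=seed)


# ---------------------------------------------------------------------------
# gene universe with planted locus enrichment


@dataclass
class EnrichmentTruth:
    """Recipe for a gene universe with planted locus enrichment.

    ``loci`` maps locus names to gene counts; locus gene sets are disjoint
    random subsets of the universe.  Differentially expressed genes are
    drawn without replacement with sampling weight ``planted_fold_enrichment``
    for genes inside loci and 1 elsewhere, so the in-locus DE rate is the
    planted fold times the background rate (in expectation) while the total
    DE count is exact.
    """

    universe_size: int = 22753
    n_de: int = 1256
    loci: dict[str, int] = field(default_factory=lambda: {
        f"locus_{i:03d}": 5 for i in range(20)})
    planted_fold_enrichment: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.universe_size <= 0 or not 0 <= self.n_de <= self.universe_size:
            raise ValueError("need 0 <= n_de <= universe_size")
        if sum(self.loci.values()) > self.universe_size:
            raise ValueError("loci cannot exceed the universe")
        if self.planted_fold_enrichment < 0:
            raise ValueError("fold enrichment must be non-negative")


def make_enrichment_universe(
        truth: EnrichmentTruth,
) -> tuple[list[str], list[str], dict[str, list[str]]]:
    """Return ``(universe, de_genes, loci)`` realising the planted recipe."""
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    universe = [f"G{i:05d}" for i in range(truth.universe_size)]

    order = rng.permutation(truth.universe_size)
    loci: dict[str, list[str]] = {}
    pos = 0
    in_locus = np.zeros(truth.universe_size, dtype=bool)
    for name, size in truth.loci.items():
        idx = order[pos:pos + size]
        loci[name] = sorted(universe[i] for i in idx)
        in_locus[idx] = True
        pos += size

    w = np.where(in_locus, truth.planted_fold_enrichment, 1.0)
    if w.sum() == 0:
        raise ValueError("all sampling weights are zero")
    # effective per-gene DE probability must stay a probability
    p_bg = truth.n_de / (truth.universe_size
                         + (truth.planted_fold_enrichment - 1.0)
                         * int(in_locus.sum()))
    if truth.planted_fold_enrichment * p_bg > 1.0:
        warnings.warn("planted fold drives in-locus DE probability above 1; "
                      "enrichment will saturate", stacklevel=2)
    de_idx = rng.choice(truth.universe_size, size=truth.n_de, replace=False,
                        p=w / w.sum())
    de_genes = sorted(universe[i] for i in de_idx)
    return universe, de_genes, loci
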