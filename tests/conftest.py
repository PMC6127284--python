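import numpy as np
import pandas as pd
import pytest

import pulsechase as pc


@pytest.fixture(scope="session")
def ev_config():
    """Factory for the packaged empty-vector simulation parameters."""
    return pc.empty_vector_config


@pytest.fixture(scope="session")
def quiet_config():
    """Small, noise-free, diffusion-free config for fast deterministic tests."""
    def make(**overrides):
        base = dict(n_particles=300, noise_on=False, diffusion_slow=0.0,
                    fast_departure_mean=0.0, background_level=0.0, seed=11)
        base.update(overrides)
        return pc.empty_vector_config(**base)
    return make


def make_wave(series_by_bin, timepoints, direction="distal"):
    """Build a WaveMatrix directly from {bin label: values} (unit tests)."""
    rows = []
    for (d, b), vals in series_by_bin.items():
        for t, v in zip(timepoints, vals):
            rows.append({"direction": d, "bin": float(b), "time_s": float(t),
                         "value": float(v), "truncated": False})
    table = pd.DataFrame(rows)
    return pc.WaveMatrix(table=table, timepoints=np.asarray(timepoints,
                                                            dtype=float))


def advecting_wave(v, timepoints, bins=(5, 10, 15, 20, 25, 30, 35, 40),
                   slug_width=5.0, direction="distal"):
    """Analytic wave of a rigid slug advecting at v μm/s out of a 5-μm ROI.

    value(b, t) = overlap of the slug [v t − w, v t] (μm beyond the ROI
    edge) with bin (b − 5, b].  Independent of the rendering pipeline.
    """
    series = {}
    for b in bins:
        vals = []
        for t in timepoints:
            lo, hi = v * t - slug_width, v * t
            vals.append(max(0.0, min(hi, b) - max(lo, b - 5.0)))
        series[(direction, float(b))] = vals
    return make_wave(series, timepoints)


def streaming_wave(v, timepoints, bins=(5, 10, 15, 20, 25, 30, 35, 40),
                   delays=tuple(range(0, 61, 5)), direction="distal"):
    """Analytic wave of slugs departing the ROI at staggered delays.

    Emulates ongoing vesicle dispatch: the leading edge travels at v while
    bins stay occupied once reached (superposition of delayed rigid slugs).
    """
    series = {}
    for b in bins:
        vals = []
        for t in timepoints:
            total = 0.0
            for d in delays:
                lo = v * max(t - d, 0.0) - 5.0
                hi = v * max(t - d, 0.0)
                total += max(0.0, min(hi, b) - max(lo, b - 5.0))
            vals.append(total / len(delays))
        series[(direction, float(b))] = vals
    return make_wave(series, timepoints)


@pytest.fixture(scope="session")
def coloc_volume():
    spec = pc.random_coloc_spec(n_puncta=10, coloc_fraction=0.5,
                                cluster_sizes=(1, 1, 2, 3), seed=3)
    return spec, pc.make_coloc_volume(spec)
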