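"""pulsechase: quantification of dendritic receptor transport and synaptic
puncta organisation.

The package implements, over synthetic or user-supplied imaging data:

* a particle-based simulator of photoconversion pulse-chase movies and of
  3D two-channel puncta volumes with known ground truth (:mod:`.synth`);
* the bin-wise wave analysis of pulse-chase movies (:mod:`.wave`);
* crest (time-to-peak) and leading-edge transport velocity estimators and
  the two-population classification (:mod:`.velocity`);
* 3D puncta segmentation, dendrite-normalised metrics and nanodomain
  cluster profiling (:mod:`.puncta`);
* Pearson/Manders colocalization (:mod:`.coloc`);
* group-comparison statistics and locus enrichment (:mod:`.stats`).
"""

from importlib import resources

from .movie import Movie
from .synth import (SimulationConfig, GroundTruth, simulate_pulse_chase,
                    straight_trace, off_cell_background_mask,
                    VolumeSpec, Punctum, ColocVolume, make_coloc_volume,
                    random_coloc_spec, EnrichmentTruth,
                    make_enrichment_universe)
from .wave import (DendriteTrace, BinGrid, WaveMatrix, extract_bins,
                   measure_bins, normalise_wave, compute_wave)
from .velocity import (VelocityEstimate, PopulationSummary, peak_velocity,
                       edge_velocity, estimate_velocities,
                       classify_populations)
from .puncta import (PunctaSet, PunctaMetrics, ClusterProfile, segment_puncta,
                     puncta_metrics, detect_nanodomains, cluster_nanodomains,
                     dendrite_mask_from_cytoskeleton)
from .coloc import ColocResult, pearson, manders, coloc_analysis
from .stats import (group_compare, paired_wave_test, locus_enrichment,
                    EnrichmentResult, dunn_posthoc)

__version__ = "0.1.0"


def empty_vector_config(**overrides) -> SimulationConfig:
    """The packaged empty-vector (control) simulation parameters."""
    import yaml
    text = (resources.files("pulsechase") / "configs"
            / "empty_vector.yaml").read_text()
    data = yaml.safe_load(text)
    data.update(overrides)
    return SimulationConfig(**data)
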