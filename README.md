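# pulsechase

Quantification of dendritic receptor transport from photoconversion
pulse-chase imaging, with companion analyses for super-resolution synaptic
puncta and for gene-set locus enrichment.

## Who this is for

Labs that track a tagged receptor pool (e.g. GluN1 fused to a
photoconvertible protein such as Dendra2) after photoconverting it inside a
dendritic region of interest (ROI), and that quantify the resulting red
fluorescence "wave" in successive 5-μm bins along the dendrite.  The same
study design typically includes 3D-SIM imaging of surface receptor puncta,
PSD95 nanodomain clusters and receptor–scaffold colocalization, plus
RNA-seq-derived gene lists tested for enrichment in disease-associated
loci; all of those quantifications are included.

## The model and the estimators

After photoconversion at *t* = 0 the labelled pool spreads bidirectionally.
The dendrite is divided into 5-μm bins on each side of the ROI (bin zero),
and the doubly normalised wave matrix is

```
W(b, t) = [ F(b, t) / A(b) ] / [ F(0, 0) / A(0) ]
```

where `F` is background-subtracted summed intensity and `A` the bin area,
so `W(0, 0) = 1` by construction.  Two per-neuron velocity estimators act
on `W`:

* **crest (time-to-peak) velocity** — for near bins *b* ∈ {10, 15} μm,
  `v = b / argmax_t W(b, t)`; tracks the slow bulk of the pool
  (ER-associated receptor, ~0.2 μm/s in control neurons);
* **leading-edge velocity** — for far bins *b* ∈ {25, 30, 35, 40} μm,
  `v = b / t_appear(b)`, with appearance the first time `W` exceeds its
  *t* = 0 baseline by 3 robust noise SDs for two consecutive frames; tracks
  the fastest minority (transport vesicles, ~0.82 μm/s in controls).

A paired test on the per-neuron (crest, edge) samples decides whether the
data support two kinematically distinct populations.  A particle-based
advection–diffusion simulator (`pulsechase.synth`) generates movies with
known ground truth for validation, alongside generators for 3D two-channel
puncta volumes and gene universes with planted locus enrichment.

## Worked example

```python
import pulsechase as pc

cfg = pc.empty_vector_config(seed=1)          # 0.2 / 0.82 μm/s two-pool mix
movie, truth = pc.simulate_pulse_chase(cfg)   # 13 frames, 15 s apart
wave = pc.compute_wave(movie, pc.straight_trace(cfg),
                       background=pc.off_cell_background_mask(cfg))
est = pc.estimate_velocities(wave, direction="distal")
print(est.peak_velocity, est.edge_velocity)
```

prints

```
0.2111111111111111 0.736111111111111
```

i.e. this neuron's crest velocity is 0.211 μm/s (the slow pool, configured
at 0.2 — the 10-μm bin peaked at 45 s and the 15-μm bin at 75 s) and its
leading-edge velocity is 0.736 μm/s (the fast pool, configured at 0.82;
the 15-s frame interval quantises appearance times upward, biasing single
neurons slightly low).  Across 20 neurons the means recover both
configured velocities within a few percent (see below).

The other analyses follow the same pattern:

```python
spec = pc.random_coloc_spec(n_puncta=20, coloc_fraction=0.5, seed=1)
vol = pc.make_coloc_volume(spec)
puncta = pc.segment_puncta(vol.channel_a, vol.dendrite_mask, vol.voxel_size)
metrics = pc.puncta_metrics(puncta, vol.dendrite_mask)
coloc = pc.coloc_analysis(vol.channel_a, vol.channel_b, vol.dendrite_mask)
```

A `pulsechase` command-line interface wraps every step
(`pulsechase simulate pulse-chase`, `pulsechase wave`,
`pulsechase velocity`, `pulsechase puncta`, `pulsechase nanodomains`,
`pulsechase coloc`, `pulsechase stats-compare`, `pulsechase enrich`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

simulates 20 pulse-chase movies from the packaged empty-vector parameter
file, runs the full wave→velocity pipeline on each, and writes the
across-neuron mean crest velocity (`t1`, μm/s) and mean leading-edge
velocity (`t2`, μm/s) — the two control-condition transport velocities the
pipeline is designed to measure.

See `docs/methods.md` for the simulation model, parameter defaults and
numerical choices.
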