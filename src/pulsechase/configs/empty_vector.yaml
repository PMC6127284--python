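# Pulse-chase simulation parameters for the empty-vector (control) condition:
# slow pool 0.2 um/s, fast pool 0.82 um/s, frames every 15 s for 3 min,
# 5-um photoconversion ROI mid-way along a 100-um dendrite.
n_particles: 2000
frac_stationary: 0.30
frac_slow_distal: 0.28
frac_slow_proximal: 0.28
frac_fast_distal: 0.07
frac_fast_proximal: 0.07
v_slow: 0.2
v_fast: 0.82
diffusion_slow: 0.05
fast_departure_mean: 30.0
fast_velocity_cv: 0.0
dendrite_length: 100.0
dendrite_width: 2.0
roi_centre: null
roi_halfwidth: 2.5
pixel_size: 0.1
frame_interval: 15.0
duration: 180.0
psf_sigma: 0.15
photons_per_particle: 50.0
background_level: 10.0
noise_on: true
seed: 0
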