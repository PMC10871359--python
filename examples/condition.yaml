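# Example smfretq pipeline configuration: one simulated condition.
# Defaults mirror the acquisition and analysis conventions the pipeline
# is built around; every key can be overridden here or on the CLI.

output_dir: smfretq_out
condition: demo
seed: 7
frame_interval: 0.1          # seconds per frame (100-ms frames, 10 fps)

simulation:
  state_names: [splayed, compact, super-compact]
  state_fret: [0.35, 0.50, 0.70]     # low / medium / high FRET states
  rate_matrix:                       # 1/s, row -> column; diagonal ignored
    - [0.0, 0.6, 0.0]
    - [0.6, 0.0, 0.4]
    - [0.0, 0.8, 0.0]
  n_movies: 4                        # at least 4 movies per condition
  traces_per_movie: 100
  n_frames: 600
  total_intensity: 1000.0            # photons/frame from the dye pair
  donor_bleach_tau: 40.0             # s
  acceptor_bleach_tau: 25.0          # s
  background_mean: 200.0             # photons/frame/channel
  read_noise_sd: 20.0

selection:
  min_fret_lifetime_frames: 50       # trace passes only if lifetime > 50
  max_total_intensity_cv: 0.15
  max_anticorrelation_r: -0.2

histogram:
  bin_width: 0.02                    # display histograms, bin size 0.02
  n_display_frames: 50               # first 50 frames of each trace
  fret_min: -0.1
  fret_max: 1.0
  min_traces: 20                     # sparse movies pooled below this
  max_combine: 3                     # at most 3 movies pooled per group

fit:
  fixed_means: [0.3, 0.5, 0.7]       # component means held fixed
  initial_amplitude: 0.05
  initial_sigma: 0.01
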