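# Methods

## Scope and data model

smfretq analyzes camera-based smFRET recordings of single surface-attached
molecules carrying one donor and one acceptor dye. The measurement model
throughout is:

* a molecule occupies one of K discrete conformational states, each with a
  fixed FRET efficiency; transitions form a continuous-time Markov chain;
* while both dyes emit, the detected donor and acceptor intensities are
  I·(1−E) and I·E for a per-pair photon budget I — photons are
  redistributed between channels, not created or destroyed (γ = 1, no
  spectral corrections by default; `compute_fret` accepts optional γ and
  donor-leak parameters);
* each dye photobleaches irreversibly after a single-exponential lifetime;
  after the acceptor dies the donor recovers to I, after the donor dies
  both channels fall to background;
* camera counts are Poisson (signal + background) plus Gaussian read noise
  at unit gain; traces are background-subtracted.

## Synthetic data generator

`simulate_state_path` is an exact-event (Gillespie) simulation; per-frame
efficiencies are the dwell-time-weighted average of the state efficiencies
over the 100-ms exposure, so a frame straddling a fast transition reports
an intermediate value. This within-frame averaging, not per-frame state
sampling, is what broadens real histograms and the analysis is tested
against it. Paths default to starting from the stationary distribution of
the rate matrix.

Defaults (all configurable): frame interval 0.1 s; three states at
E = 0.35/0.50/0.70 interconverting at 0.4–0.8 s⁻¹ (dwell times of roughly
one to two seconds, so transitions are frequent on a 30–60 s trace while
frames remain mostly pure); photon budget 1000 photons/frame/pair;
background 200 photons/frame/channel; read noise 20; donor and acceptor
bleaching lifetimes 40 s and 25 s; four movies per condition. Rates are
free parameters of the simulator — the analysis nowhere depends on them.
Per-channel SNR is defined as the signal at E = 0.5 (I/2) over the channel
noise SD; `fixtures.photophysics_for_snr` solves the read noise needed to
hit a target SNR, and benchmark conditions use SNR 10.

Ground truth (state path, bleach frames, frame-weighted occupancy over the
FRET-alive segment) is emitted alongside every synthetic trace and is never
recomputed downstream.

Movies are rendered with pixel-integrated (erf) Gaussian PSFs whose
per-frame integrated intensity equals the trace value, on a constant-mean
background with shot and read noise; 16-bit TIFF output with a JSON ground
truth sidecar. The generator does **not** emulate: sCMOS pixel-dependent
noise maps, stage drift, nonlinear channel warping, triplet photophysics,
spectral crosstalk beyond a single donor-leak fraction, or overlapping
spots. Passing tests therefore validate the analysis logic under
shot-noise-limited, well-separated-spot conditions, not robustness to
those instrument artifacts.

## Extraction

Spots are local maxima of the average of the first 10 frames, thresholded
at background + 5 robust SDs (median/MAD). Non-maximum suppression keeps
the brightest peak within a merge radius (default 2.5 px — noise can split
a broad PSF into several maxima); remaining peaks closer than the minimum
separation are *both* discarded, because overlapping apertures corrupt
photometry. Centroids are refined by background-subtracted intensity
weighting in a small window. Channel pairing applies an explicit affine
transform (identity, translation, or solved from ≥3 fiducial pairs); there
is no automatic registration. Photometry is the aperture sum minus the
annulus median times the aperture pixel count, per frame and channel
(defaults: aperture 3 px, annulus 5–8 px, matched to a ~1.2 px PSF; the
benchmarks use wider radii for their 2.5 px PSF). Annulus-median background
estimation adds noise proportional to the aperture area — the dominant
fidelity limit at low peak SNR.

## Trace selection

The classic manual criteria are made quantitative. Change points are found
by recursive binary segmentation on a piecewise-constant least-squares
cost, with a BIC-like penalty 2σ̂²·log n; σ̂ is the median absolute first
difference divided by 0.6745·√2, which steps and slow dynamics barely
perturb. Steps smaller than 4σ̂ are ignored.

Classifying steps as photobleaching rather than conformational exploits
three invariances of one-donor/one-acceptor FRET:

* **Donor steps.** The total intensity I_D + I_A is flat under both
  conformational dynamics and acceptor-side losses, so every downward step
  of the total is a donor-side loss. Exactly one such step, landing at
  background, is required.
* **Acceptor bleach.** A drop of the acceptor channel to ~zero (1.5σ̂ on a
  15-frame post-step mean, or a tenth of the channel's peak) while the
  donor persists. Blink-off excursions also land at zero and are counted,
  so blinking traces are rejected — intended behavior.
* **Partial acceptor loss** (two-acceptor molecules). Losing one of two
  FRET-coupled acceptors multiplies the apparent efficiency by the
  surviving acceptor's share, compressing the whole level set at once.
  Candidate split points (efficiency change points, acceptor-intensity
  drops, and a coarse grid) are tested with windows of ≥75 frames on both
  sides; a candidate is flagged when the efficiency statistics *undercut
  the conformational level-ratio floor*: neighbouring conformational
  states in this regime sit at level ratios ≳0.7, so a post/pre ratio of
  the lowest sustained level or of the upper tail (q95) below 0.62, or a
  sustained post level below 0.9× a well-sampled pre bottom level with the
  post top capped below 0.9× the pre top, cannot be produced by occupancy
  shifts between windows.

Known limitation: compression by a share approaching the conformational
level ratio (~0.7), or realizations whose pre-drop window never samples
the bottom state, are information-theoretically ambiguous from a single
trace; a fraction of a percent of two-acceptor molecules with comparable
shares evade the filter, and exactly equal-share loss whose compressed top
collides with the uncompressed bottom level is undetectable in principle.
In the noise-free limit the change-point penalty degenerates and the
classifier's false-positive channel is no longer monotone in noise, which
is why the monotonicity property is asserted from a weak noise floor
upward.

FRET lifetime is the frame count until the first bleach of either dye, and
the >50-frame criterion is strict. Total-intensity CV is taken over the
pre-donor-bleach segment; anti-correlation is the Pearson r of the two
channels over the FRET-alive segment (uninformative afterwards). Traces in
which a dye never visibly bleaches are rejected — single-step bleaching
cannot be verified. Defaults (CV ≤ 0.15, r ≤ −0.2, ≥20 frames for the
correlation) accept noise-free ideal traces and reject the canonical
violators; all are config-exposed.

## Histograms and statistics

Only the FRET-alive segment contributes. Each trace contributes at most its
first 50 efficiency values to its movie's display histogram (uniform 0.02
bins over [−0.1, 1.0); 55 bins; out-of-range values are clipped into the
terminal bins so mass is conserved; frames with non-positive total are
dropped). Negative bins absorb noise around E ≈ 0. Every counted frame has
equal weight. Movies with fewer than 20 accepted traces (low expression)
are pooled greedily with adjacent sparse movies, never more than three per
group. The condition histogram is the per-bin mean of the per-movie
histograms with SEM = SD/√m across the m movies (zero for a single movie,
flagged in the manifest); the SEM is across movies, not across traces.
Quartiles are read off the cumulative histogram as the center of the first
bin strictly exceeding 25/50/75% of the counts, per movie, and averaged
into the condition values — so a condition quartile need not lie on a bin
center.

## Trimodal occupancy fit

The condition histogram is fit by three Gaussians with fixed means
(defaults 0.3/0.5/0.7) and a single shared σ, by bounded nonlinear least
squares over (A₁, A₂, A₃, σ) from the prescribed start A = 0.05,
σ = 0.01 (trust-region reflective, tolerances 1e−12, amplitudes ≥ 0,
σ ∈ (1e−4, 0.5]). With fixed means and one σ the model is identifiable —
no component permutation is possible — and the default start reaches the
same optimum as a 100-restart multistart on the benchmark mixtures.
Amplitudes are bounded below by zero because negative component mass is
meaningless and destabilizes the area ratio. Component areas use composite
Simpson's rule on the histogram's own bin-center grid (extended by one
step when the point count is even); occupancies are each area as a
percentage of the trimodal total. Because σ is shared, occupancy
percentages equal amplitude ratios up to finite-domain truncation; both
are reported and the Simpson ratio is primary. Non-convergence returns the
best fit with a warning flag rather than raising. A per-component-width
variant and per-movie fitting are deliberately not defaults: the shared
width matches the single-σ component form, and the condition-average
histogram is the default fit target.

## Pipeline and reproducibility

One master seed spawns independent per-movie and per-trace streams
(`numpy` SeedSequence), making every output byte-reproducible; the run
manifest echoes the config and the SHA-256 digest of every artifact, and
running stages separately produces artifacts identical to `run-all`.
Configuration is a single YAML file validated before any stage runs;
unknown keys are rejected with an aggregated error.

## Benchmark problem sizes

The shipped benchmarks use 4 movies × 200 traces × 600 frames for
end-to-end occupancy recovery (recovers a 60/30/10 stationary mixture
within ~2 points at SNR 10), 500 traces for selection
sensitivity/specificity, 200 hundred-frame traces for the change-point
oracle comparison, a 20-spot 100-frame movie for extraction, and 40
replicate 500-s paths for Gillespie stationarity — sizes at which the
stochastic tolerances used in the tests (±5 occupancy points, ≥90%
sensitivity, r > 0.99) hold with comfortable margin.
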