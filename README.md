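# smfretq

Quantification pipeline for single-molecule FRET (smFRET) recordings of
conformational dynamics, of the kind acquired on a two-channel TIRF
microscope at ~10 fps: surface-attached molecules each carrying one donor
and one acceptor dye, interconverting between a few discrete conformational
states with distinct FRET efficiencies.

The package covers the whole chain from raw movies (or pre-extracted
traces) to state-occupancy percentages:

1. **Trace extraction** — spot detection on a time-averaged image
   (median/MAD thresholding, sub-pixel centroids), donor/acceptor channel
   pairing by an explicit affine registration, and circular-aperture
   photometry with an annulus-median local background.
2. **Automated trace selection** — penalized change-point detection turns
   the classic manual curation criteria into reproducible filters: exactly
   one photobleaching step per fluorophore, constant total fluorescence
   (CV ≤ 0.15), global donor–acceptor anti-correlation (Pearson r ≤ −0.2),
   and FRET lifetime > 50 frames.
3. **Histogramming** — apparent efficiency E = I_A/(I_A + I_D) per frame;
   per-movie display histograms from each trace's first 50 FRET-alive
   frames (bin width 0.02); sparse movies pooled up to 3 at a time;
   per-bin mean ± SEM across movies; median and quartiles as the center of
   the first bin whose cumulative fraction exceeds 25/50/75%.
4. **Occupancy decomposition** — nonlinear least squares of a trimodal
   Gaussian with fixed means (0.3, 0.5, 0.7 by default) and one shared
   width, starting from A = 0.05 and σ = 0.01:

       f(E) = Σₙ Aₙ · exp(−(E − μₙ)² / 2σ²)

   The area under each component (composite Simpson's rule on the
   histogram grid) is reported as a percentage of the area under the
   trimodal sum — the occupancy of the low/medium/high-FRET state.

A first-class synthetic-data module generates ground-truth test data:
continuous-time Markov (Gillespie) state paths with within-frame averaging,
single-exponential photobleaching of each dye, optional acceptor blinking,
Poisson shot noise + Gaussian read noise, and rendered two-channel TIFF
movies with pixel-integrated Gaussian PSFs.

## Worked example

```sh
smfretq run-all -c examples/condition.yaml -o demo_out
```

simulates four movies of 100 molecules (three states at E = 0.35/0.50/0.70,
interconverting at 0.4–0.8 s⁻¹, 600 frames at 10 fps), runs selection,
histogramming and the occupancy fit, and prints:

```
accepted 212 traces
quartiles (q25, q50, q75): 0.36, 0.48, 0.53
state occupancy (low, mid, high): 27.6%, 48.5%, 23.9%
```

About half of the simulated traces survive the selection filters (the rest
bleach too early or never bleach inside the recording). The median
efficiency of 0.48 reflects the mostly-compact stationary mixture, and the
occupancy percentages quantify the mass the trimodal fit assigns to each
conformational class. All artifacts (per-movie trace TSVs, selection
report, histograms with SEM, fit JSON, run manifest with file digests) land
in `demo_out/`.

The same stages are available as `simulate`, `extract`, `select`,
`histogram`, `fit` and `report` subcommands, and as plain functions
(`smfretq.pipeline`, `smfretq.selection`, `smfretq.histograms`,
`smfretq.occupancy`) for notebook use.

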