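# tacsim

Simulation and offline analysis of closed-loop, phase-locked, intermittent
tACS-EEG sessions.

The package has two halves:

* **A generative simulator** of full experimental sessions: 31-channel 10-20
  EEG (no Oz/Cz) at a configurable sampling rate, a per-subject alpha source
  with individual alpha frequency (IAF) and eyes-closed > eyes-open
  amplitude, 10 alternating EO/EC blocks of 50 trials (1 s pre / 1 s
  stimulation / 1 s post, jittered 333-666 ms inter-trial interval, 25
  in-phase + 25 anti-phase per block), an optional huge stimulation artifact
  confined to the stimulation interval, and a parameterized, phase-independent
  transient post-stimulation alpha suppression with exponential recovery whose
  expected percent modulation has a closed form
  (`tacsim.expected_post_modulation`).
* **The offline analysis chain**: 500-ms pre/post windows with 100-ms guard
  trims, 5-40 Hz zero-phase Butterworth filtering, detrended zero-padded
  (512-sample) FFT power averaged over IAF +/- 1 Hz, POz / 9-channel
  parieto-occipital-cluster sources, leave-one-trial-out cross-validated CSP
  components (CSPpre / CSPpost), overlapping post-stimulation time bins,
  condition-mean spectra, and from-first-principles repeated-measures
  statistics (within-subject ANOVA with Greenhouse-Geisser correction,
  Bonferroni adjustment, generalized eta squared, Cohen's d_z, marginal
  means, linear time-bin contrasts).

A simulated closed-loop controller (`tacsim.closedloop`) reproduces the
online side: IAF estimation from EC/EO resting spectra, 250-ms Hilbert-based
phase estimation, latency-compensated phase forecasting, and synthesis of
the 1 mA peak-to-peak in-/anti-phase stimulation sinusoid.

## Command line

```sh
# simulate a cohort and write BrainVision triplets + events TSV + ground truth
tacsim simulate --subjects 5 --seed 1 --out data/

# analyze previously written recordings
tacsim analyze --data data/ --out analysis/

# one-shot: simulate + closed loop + analysis + statistics
tacsim full --config config.yaml --seed 7 --out run1/

# summarize a finished run
tacsim report --out run1/
```

The config file is a flat YAML mapping; keys are the fields of
`SimulationConfig` (srate, n_blocks, trials_per_block, suppression_depth,
suppression_tau, noise_amp, ...) plus analysis options (nfft, csp_gamma,
latency, use_true_iaf, write_recordings). `tacsim full` writes per-trial
power and modulation tables, CSP topographies, condition spectra, the three
repeated-measures ANOVA tables (TIME x STATE x STIMULATION per source;
BLOCK x STATE x STIMULATION and TIMEBIN x STATE x STIMULATION on CSPpre
modulations), time-bin linear contrasts, a ground-truth-recovery report, and
a `manifest.json` with the config hash and per-stage wall times. Reruns with
the same config and seed are byte-identical; every table carries the config
hash in `#` header comments.

## Conventions

* EEG in microvolts; stimulation current in mA.
* Sample indices are 0-based; all intervals are half-open `[onset, offset)`.
* Phases are cosine phases (0 rad at the signal maximum) wrapped to
  (-pi, pi].
* FFT window power is `|X_k|^2 / nfft`, one-sided without doubling; all
  downstream comparisons are scale-invariant and the convention is pinned by
  a brute-force DFT oracle test.

## Layout

| module                | contents                                             |
|-----------------------|------------------------------------------------------|
| `tacsim.montage`      | fixed 31-channel layout and POC cluster              |
| `tacsim.simulate`     | session scheduler, subject/cohort simulator, artifact injection, suppression oracle |
| `tacsim.closedloop`   | IAF estimation, phase estimation/forecast, stimulation waveforms, session replay |
| `tacsim.power`        | interval extraction, filtering, window power, sources, modulation, spectra |
| `tacsim.csp`          | covariances, CSP eigenproblem, leave-one-trial-out components, topographies |
| `tacsim.stats`        | RM-ANOVA, GG epsilon, Bonferroni, marginal means, contrasts, Cohen's d |
| `tacsim.io`           | BrainVision triplet reader/writer, TSV/JSON tables   |
| `tacsim.pipeline`     | run orchestration, config, manifest                  |
| `tacsim.cli`          | `tacsim` console entry point                         |
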