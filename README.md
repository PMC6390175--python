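# facesim

Similarity-space analysis of dynamic faces: physical form and motion
similarity measures computed from landmark-annotated videos, categorical and
perceptual model matrices, pattern-similarity matrices from evoked and
time-frequency multichannel (MEG-style) responses, and the full RSA
statistics chain — Spearman / partial Spearman over matrix cells, Fisher
r-to-z, per-participant map smoothing, group one-sample t, threshold-free
cluster enhancement (TFCE) and participant sign-flip permutation correction.

Because the original stimuli and recordings are not distributable, the
package ships first-class synthetic generators that emulate every input with
controllable planted structure: 179-landmark dynamic face videos
(identity-specific neutral configurations, feature-localized expression
trajectories, global rigid head motion), pairwise similarity judgment
tables, and sensor epochs whose spatial-pattern geometry inside a chosen
time/frequency window follows a planted model similarity matrix.

## Layout

| module                  | contents |
|-------------------------|----------|
| `facesim.landmarks`     | landmark frames/videos, pairwise-distance configuration vectors, configural-form similarity matrices |
| `facesim.motion`        | fiducial-triangle affine rigid correction, landmark flow, feature averaging, motion-pattern similarity matrices |
| `facesim.similarity`    | similarity-matrix type, categorical/judgment/response-pattern matrices, canonical lower-triangle vectorization |
| `facesim.meg`           | epoch container, artifact rejection, evoked averaging, Morlet time-frequency power (factor 7), log-ratio baseline, responsive-channel selection |
| `facesim.rsa`           | Spearman & partial Spearman, Fisher z, Butterworth/Gaussian smoothing, group t maps, TFCE, sign-flip permutation correction, end-to-end `rsa_scan` |
| `facesim.simulate`      | face-set, judgment and epoch generators with planted ground truth |
| `facesim.pipeline`      | config handling, stage orchestration, behavioral RSA planned comparisons, sensor RSA runner, result tables |
| `facesim.io`            | TSV/JSON/npy readers and writers for every artifact |
| `facesim.cli`           | `facesim` command-line interface |

## CLI

```sh
# generate synthetic videos, judgments and epochs
facesim simulate --seed 1 --out runs/sim

# physical similarity matrices from landmark videos on disk
facesim physical --videos runs/sim/videos --out runs/physical

# Spearman correlations among the six test matrices (13 planned comparisons)
facesim behavioral-rsa --sim-dir runs/sim --out runs/behavioral.tsv

# sensor-level RSA: time-frequency or evoked scans with TFCE permutation
facesim meg-rsa --sim-dir runs/sim --analysis tf --models identity,configural_form \
    --controls configural_form:identity --n-permutations 1000 --out runs/rsa

facesim report --results-dir runs/rsa
```

Every run writes a manifest (config hash, decided parameters, library
versions) next to its outputs; identical configs reproduce identical
results. YAML config files (see `facesim.pipeline.default_config`) override
any parameter, e.g. the scan band (`analysis.freq_lo/freq_hi`), smoothing
kernels, artifact thresholds or permutation count.

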