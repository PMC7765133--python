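# somnofuse

Simultaneous EEG–fMRI analysis of disturbed sleep, built around the study
design used to characterise NREM parasomnia (disorders of arousal):
in-scanner EEG is cleaned of MR gradient and cardiac artifacts, windowed
relative band power is computed with multitaper spectra, awakening (A)
and transition-to-sleep (T) epochs and band-limited power (BLP) drive
EEG-informed general linear models of the BOLD signal, and patient and
control groups are compared by nonparametric electrode-space statistics
and by the signed intersection of their thresholded activation maps.

The study data this workflow was designed for are clinical recordings
that are not publicly deposited, so the package ships a first-class
synthetic-cohort generator: every effect the analysis is meant to find
(group spectral differences during awakening epochs, region x band BOLD
coupling signs, resting networks, artifact structure) is planted with
known ground truth, which makes every stage testable end to end. The
package is aimed at researchers developing or validating EEG–fMRI sleep
pipelines and at anyone who needs a fully controlled sandbox for
mass-univariate EEG-informed fMRI analysis.

## What it computes

**EEG cleaning.** The gradient artifact is removed by average artifact
subtraction (AAS): volume-locked epochs minus a template estimated from
the other epochs, with an optional PCA residual basis. The cardiac
(ballistocardiographic) artifact is removed by an optimal basis set
(OBS): beat-locked epochs are decomposed by PCA and the leading
components refitted per beat, with the per-beat scale solved jointly
across channels. Eye artifacts are removed by zeroing ICA components
correlated with a blink reference; signals are then band-passed
0.5–30 Hz, notch filtered, and referenced to the mastoid average.

**Spectra.** Multitaper (DPSS) band power in delta (0.5–4.5 Hz), theta
(4.5–8.5 Hz), alpha (8.5–13 Hz) and beta (13–30 Hz), normalised by the
four-band total so each (channel, window) carries relative shares that
sum to one.

**Group statistics on electrodes.** Per-channel two-sample t statistics
between patients and controls, clustered over a position-derived sensor
adjacency; each cluster's summed t is referred to a Monte-Carlo null of
the maximal cluster statistic over group relabelings. The most
significant cluster selects the electrodes for the BLP regressors.

**EEG-informed GLM.** Per voxel and subject,

```
y = X beta + eps
```

with design columns `[A | T | BLP_alpha | BLP_theta | BLP_delta |
6 motion | initial wake | intercept]`; condition boxcars and BLP series
are convolved with a canonical double-gamma HRF. Second-level one-sample
t-maps per group are thresholded at uncorrected p = 0.01 (0.05 fallback)
with a minimum-cluster-extent rule, and the two groups are compared by
the signed intersection of their thresholded maps — a descriptive
overlap, not a significance statement.

## Worked example

Simulate the default cohort (8 controls, 9 patients, 32 channels,
300 s sessions at TR = 1 s) and test the planted awakening-epoch alpha
difference:

```python
from somnofuse import CohortSpec
from somnofuse.group_stats import (cluster_permutation_test, electrode_adjacency,
                                   default_distance_threshold, select_electrodes)
from somnofuse.synth import sensor_positions, simulate_band_share_tables

spec = CohortSpec(seed=1)
tables = simulate_band_share_tables(spec, state="A")
positions, labels = sensor_positions(spec.n_channels)
adjacency = electrode_adjacency(positions, default_distance_threshold(positions))
result = cluster_permutation_test(
    tables["control"][:, :, 2],       # relative alpha power, subjects x channels
    tables["patient"][:, :, 2],
    adjacency, n_perm=1000, seed=0)
best = result.most_significant()
print(f"most significant cluster: p = {best.monte_carlo_p:.3f}, "
      f"{len(best.members)} electrodes, summed t = {best.statistic:.1f}")
members, _ = select_electrodes(result)
print("selected electrodes:", [labels[i] for i in members])
print("planted electrodes: ", [labels[i] for i in tables["planted_electrodes"]])
```

prints

```
most significant cluster: p = 0.001, 11 electrodes, summed t = -42.5
selected electrodes: ['E2', 'E4', 'E7', 'E10', 'E12', 'E15', 'E20', 'E22', 'E23', 'E25', 'E28']
planted electrodes:  ['E7', 'E15', 'E20', 'E12', 'E2', 'E23', 'E10', 'E28', 'E25', 'E4']
```

The cluster is significant (patients carry more relative alpha during
awakening epochs, hence the negative summed t for control − patient) and
its members recover the ten planted electrodes plus one neighbour.

The full flow — simulation, artifact removal, spectra, electrode
statistics, first/second-level maps, thresholding, intersections, QC —
runs from the command line:

```
somnofuse run --config run.yaml --out runs/demo --seed 1
```

and writes t-maps (NIfTI), cluster/region tables (TSV), EEG and BOLD
hypothesis reports keyed H1–H27, a coupling-sign table, a QC report and
a provenance manifest into the run directory.

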