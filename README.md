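# rotaspike

Spike-train and kinematics analysis for single-neuron recordings made under
**head-fixed passive rotation** — the preparation used to study
head-direction (HD) coding in parahippocampal cortex (e.g. the presubiculum),
where the animal sits head-fixed on a platform that the experimenter rotates
clockwise and counterclockwise while a single LED is video-tracked at 25 Hz.

It is written for systems neuroscientists who have sorted spike times, LED
tracking and (optionally) waveform snippets per cell, and want the standard
battery of per-cell statistics with permutation-based significance:

* **Kinematics** from the LED trace: 600 ms boxcar smoothing, least-squares
  circle fit for the rotation centre, head angle θ, angular velocity
  ω = Δθ/dt and acceleration α = dω/dt on the 40 ms frame grid, linear-speed
  movement mask (rest ⇔ LED speed ≤ 1 cm/s), and direction-inversion counts.
* **HD tuning**: 36-bin occupancy-normalised tuning curves over movement
  frames; the HD index as the mean resultant (Rayleigh) vector length
  R = |Σᵢ rᵢ e^{jθᵢ}| / Σᵢ rᵢ of the binned curve; significance from 1000
  rigid circular time-shifts of the whole spike train (HD cell ⇔ index >
  95th percentile of the null; "strong" HD ⇔ index > 0.8 and p < 0.01);
  split-half stability as the Pearson r between half-session curves.
* **Theta rhythmicity**: spike autocorrelogram (10 ms bins, ±0.5 s), theta
  index = mean spectral power within 1 Hz of the 4–12 Hz peak ÷ mean power
  over 1–50 Hz; significance from per-spike random time-shifts (cells with
  ≤ 20 spikes are excluded with a reason code).
* **Speed modulation**: Pearson correlation between the per-frame firing
  rate and |ω| over movement frames, with the rigid-shift null; rest versus
  rotation firing rates.
* **Spike features**: peak-to-trough time, half-width, negativity amplitude
  from averaged waveforms (20 kHz); bursting index (fraction of spikes with
  preceding ISI < 6 ms); fast-spiking classification (narrow spike AND high
  rate).
* **Group statistics**: two-sided Mann-Whitney U and Fisher's exact test for
  layer/cell-type comparisons.
* A **synthetic session generator** (rotation schedules with inversions and
  rest blocks; inhomogeneous-Poisson spike trains with von Mises HD tuning,
  sinusoidal theta modulation and linear speed gain; biphasic waveform
  templates) so the full pipeline is exercisable and testable without any
  recordings.

## Worked example

```python
import rotaspike as rs

spec = rs.SessionSpec(duration_s=180.0, n_inversions=5, seed=3)
cells = {
    "l3_hd":    rs.CellSpec(base_rate_hz=4.0, kappa=4.0, preferred_dir_rad=1.0, seed=1),
    "l2_theta": rs.CellSpec(base_rate_hz=6.0, theta_freq_hz=8.0, theta_depth=0.8, seed=2),
    "fs_speed": rs.CellSpec(base_rate_hz=15.0, speed_gain=8.0,
                            celltype_label="fs", seed=3),
}
session = rs.generate_session(
    spec, cells,
    layers={"l3_hd": "L3", "l2_theta": "L2", "fs_speed": "unknown"},
)
model = rs.RotationSession.from_synthetic(session)
results = model.fit(seed=0)       # returns a SessionResults
print(results.summary())
```

prints

```
Passive-rotation session: 3 cells, 180 s (144 s movement, 5 inversions, mean |omega| 1.08 rad/s)
 cell_id   layer  n_spikes  mean_rate_hz  hd_index  hd_p  stability_r  theta_index  theta_p  speed_score  speed_p  bursting_index  peak_to_trough_ms  is_hd  is_strong_hd  is_theta_rhythmic  is_speed_modulated  is_fs
fs_speed unknown      3702        20.567     0.021 0.358        0.030        1.901    0.474        0.097    0.001           0.084               0.25  False         False              False                True   True
l2_theta      L2      1057         5.872     0.038 0.380        0.072        8.893    0.001        0.003    0.387           0.042               0.80  False         False               True               False  False
   l3_hd      L3       788         4.378     0.870 0.001        0.987        1.715    0.538        0.025    0.305           0.049               0.80   True          True              False               False  False
```

Each simulated cell is recovered as its intended functional class: the
von Mises-tuned cell (`l3_hd`) is a strong HD cell (index 0.87, shuffle
p = 0.001, split-half stability 0.99), the 8 Hz-modulated cell is
theta-rhythmic (theta index 8.9 at p = 0.001), and the fast-spiking cell is
speed-modulated (p = 0.001) with a narrow 0.25 ms spike. `results.table()`
gives the same content as a `DataFrame`, `results.to_json()` a deterministic
machine-readable report, and `results.layer_comparisons()` the
Mann-Whitney/Fisher comparison set between layers.

The same pipeline runs from the shell:

```sh
rotaspike simulate -o session_dir --duration 180 --seed 3
rotaspike analyze session_dir --seed 0
```

which writes `report.json`, `cells.csv` (one row per cell) and, when two
layers are present, `layer_comparisons.json`.

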