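# msbdyn

Analysis of **multisynaptic bouton (MSB) synapses** in two-channel
fluorescence image stacks of dendrites — for neurobiologists quantifying
synapse configurations and spine dynamics in dissociated neuron cultures,
and for anyone who needs a fully ground-truthed synthetic testbed for such
pipelines.

A presynaptic bouton normally contacts one dendritic spine; an MSB contacts
two or more. `msbdyn` covers the whole quantitative chain around this
observation:

- **Synthetic scenes** (`msbdyn.synthetic`): parametric dendrites with
  spines, boutons, and per-frame spine-volume trajectories, renderable into
  calibrated T-Z-C-Y-X stacks — every downstream stage is testable against
  known truth, no data download needed.
- **Image operators** (`msbdyn.imageops`): outlier despeckling, z-projection,
  puncta and spine-head segmentation, integrated density
  (mean brightness × area).
- **Profile census** (`msbdyn.profiles`): contact detection
  (abutting/overlapping regions), MSB vs single profile classification, the
  converse "opposite" profile, and the live-imaging MSB spine-pair rule
  (shared bouton, head distance < 1.3 µm, heads angled towards or parallel).
- **Pair geometry** (`msbdyn.geometry`): head-to-head distances between
  centres of mass, towards/parallel/away orientation, spine density, random
  adjacent control pairs.
- **Dominance dynamics** (`msbdyn.dynamics`): the core statistic. For a
  spine pair tracked hourly, with the dominant spine preselected by higher
  mean integrated density over a 15-h window,

  ```
  DiffIndex(t) = (IntDen_Dom(t) − IntDen_Nondom(t)) / (IntDen_Dom(t) + IntDen_Nondom(t))
  ```

  and the OLS slope of DiffIndex vs time is the **dominance rate**
  (ΔDiffIndex/h), with R² measuring trend strength. MSB pairs diverge fast
  (≈ 0.042/h); single-bouton (SSB) neighbor pairs drift near zero
  (≈ 0.002/h) — a ~21-fold separation.
- **Statistics** (`msbdyn.stats`): one-tailed two-sample t, exact
  small-sample two-tailed Mann–Whitney U, and χ² (goodness-of-fit and
  contingency), implemented from first principles, α = 0.05.

See `docs/methods.md` for the model, parameter defaults, and limitations.

## Worked example

`examples/` holds one short script per capability. For instance, pair
dynamics (`python examples/03_pair_dynamics.py`):

```
one MSB pair, first frames (time, IntDen_Dom, IntDen_Nondom, DiffIndex):
   0.0     21034     20198  +0.020
   1.0     22451     21511  +0.021
   2.0     24235     20760  +0.077
   3.0     24517     18928  +0.129
  fitted rate +0.0415 ΔDiffIndex/h (truth +0.0407), R² 0.979
class  n  rate_mean  rate_sd  r2_mean  r2_sd
  msb 50     0.0411   0.0046   0.9736 0.0156
  ssb 50     0.0020   0.0083   0.3974 0.2875
rate fold (MSB/SSB): 20.7; one-tailed t p = 1.9e-50
```

The table reads: across 50 simulated pairs per class at the default
conditions (16 hourly frames, 5% intensity noise), fitted dominance rates
recover the class means — MSB pairs drift apart ~21× faster than SSB
neighbor pairs, and the one-tailed t test confirms the separation. The
other scripts simulate and render a scene (`01`), run the fixed-image
profile census and the geometry statistics (`02`), and execute the full
stack-to-report pipeline with truth-recovery scoring (`04`).

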