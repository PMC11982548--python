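# beeal — honeybee antennal-lobe network simulator

`beeal` is a biophysical simulator of early olfactory processing in the
honeybee antennal lobe (AL), built for studying how plasticity of the
*inhibitory* AL network reshapes odor representations during appetitive
learning.  It targets researchers in computational neuroscience and
olfaction who want a tested, scriptable implementation of:

* a conductance-based AL network — 100 Hodgkin-Huxley projection
  neurons (PNs) and 280 local interneurons (LNs) in 20 glomeruli, with
  fast GABA_A, slow G-protein-coupled inhibition and nicotinic
  excitation, integrated with RK4 at 0.04 ms in a compiled (numba)
  kernel;
* reward-gated facilitation of inhibitory synapses — presynaptic
  (associative) facilitation during rewarded odors and postsynaptic
  (nonassociative) facilitation during habituated odors, each spike
  adding dF=0.15 to a multiplier that decays back to 1 with τ=30 s;
* percept-structured odor inputs — odors as mixtures of "pure chemical"
  percepts with Gaussian activation profiles, including floral-blend
  odors whose percept widths equal chemical proportions and gas-sensor-
  derived pulse inputs;
* the representation analyses of the study design — binned-spike-count
  correlations, PCA trajectories, LFP, and the contrast-enhancement
  regression of per-percept change in activity on the uniqueness index

      UI = (act_rew − act_hab) / act_hab,
      Δact = (act_diff − act_naive) / act_naive;

* a graph-convolutional analog of the circuit (16 sensor nodes + 1
  reward node, H(l+1) = h(A·H(l)·W(l)), Adam/cross-entropy in plain
  numpy) with the same layer-wise contrast analysis.

The headline phenomenon: after differential conditioning (one odor
class rewarded, one habituated), inhibition restructures so that PNs of
percepts *unique* to rewarded odors keep or increase their firing while
PNs of *shared* percepts are suppressed — pushing the two odor classes
apart in coding space (contrast enhancement, pattern separation).

## Worked example

Train a reduced AL network (8 glomeruli, 12 × 1 s presentations) with
differential conditioning and measure how the correlation between
rewarded-class and habituated-class PN representations changes:

```python
from beeal.experiments import conditioning_study, SMALL_SCALE

frame = conditioning_study(seed=1, modes=("both",), include_shuffled=True,
                           scale=SMALL_SCALE)
print(frame[["condition", "between", "within"]].round(3).to_string(index=False))
```

```
condition  between  within
    naive    0.547   0.926
     both    0.472   0.877
 shuffled    0.546   0.914
```

Reading: in the naive network the two odor classes (3 active percepts
each, 2 shared) are strongly correlated (0.547).  Differential
conditioning (`both`: associative + nonassociative facilitation)
decorrelates them (0.472) while within-class similarity falls less
(0.926 → 0.877) — learned pattern separation.  Re-shuffling the trained
weights over the same connections (`shuffled`, identical weight
distribution, destroyed structure) abolishes the effect (0.546):
decorrelation comes from *where* inhibition grew, not from how much.

The GCN analog on synthetic gas-sensor features:

```python
from beeal.odors import synthetic_sensor_dataset, zscore_sensor_features
from beeal.gcn import train_gcn, gcn_contrast_analysis

feat, lab = synthetic_sensor_dataset(seed=7)
featz = zscore_sensor_features(feat)
model, info = train_gcn(featz, lab, seed=7)
res = gcn_contrast_analysis(model, featz, lab)
print(f"held-out accuracy {info['accuracy']:.3f}; "
      f"contrast slope {res.slope:.2f} (R^2 {res.r_squared:.2f})")
```

```
held-out accuracy 0.972; contrast slope 9.00 (R^2 0.62)
```

Sensor nodes unique to the rewarded odor group increase their activation
from layer 1 to layer 2 while shared nodes decrease — the same contrast-
enhancement strategy the biophysical network learns.

A `beeal` command-line interface wraps the same machinery
(`beeal build / train / test / envexp / analyze / sweep / gcn / fixture`);
records are written as HDF5, analysis tables as CSV.  See
`docs/methods.md` for the model equations, parameters, calibration and
problem-size choices.

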