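# Methods

## The model

`beeal` simulates the honeybee antennal lobe (AL) as a conductance-based
network of 100 excitatory projection neurons (PNs) and 280 inhibitory
local interneurons (LNs).  Each cell is a single compartment with
Hodgkin-Huxley currents of the form I = g·m^M·h^N·(V−E):

* PN: fast Na (g=90 mS/cm²), delayed-rectifier K (10), transient A-type K
  (10), low-threshold Ca I_T (2), hyperpolarization-activated cation I_h
  (0.02), leak (0.01, E=−70 mV) and K-leak (0.012, E=−95 mV).
* LN: Na (100), K (10), Ca (1.75), leak (0.05) and K-leak (0.018); no I_A
  or I_h.

E_Na=50 mV, E_K=−95 mV, E_Ca=140 mV for all cells.  Intracellular Ca
follows d[Ca]/dt = −A·I_T − (Ca−Ca_∞)/τ with A=5.2·10⁻⁵ mM·cm²/(ms·µA),
τ=5 ms, Ca_∞=2.4·10⁻⁴ mM.  Total capacitances (2.9·10⁻⁴ µF PN,
1.43·10⁻⁴ µF LN) are reconciled with the mS/cm² conductances by an
implicit membrane area (2.9·10⁻⁴ / 1.43·10⁻⁴ cm²), i.e. a specific
capacitance of 1 µF/cm²; all internal arithmetic is in specific units.

### Gating kinetics

The steady-state and relaxation-time curves x_∞(V), τ_x(V) are not fixed
by the parameter set above; we use the AL model lineage this network
derives from: Traub-type Na/K rate functions with a −50 mV shift, the
Huguenard A-current, the Destexhe low-threshold Ca current and the
McCormick h-current for PNs.  For LNs the Ca current uses the
depolarized-activation LN variant of the same lineage
(m_∞ midpoint −20 mV, inactivation midpoint −25 mV): with the
thalamic-style low-threshold kinetics the LN becomes a rebound burster
with a near-zero rheobase, every LN fires for every odor, and the
odor-specific structure of the inhibitory plasticity (the basis of all
results here) is lost.  The curves live in a sampled `KineticsTable`
(0.05 mV grid, linear interpolation) shared by the reference
implementation and the compiled integrator, so alternative kinetics can
be dropped in wholesale.

### Synapses

PN→LN is nicotinic (E=0 mV, α=1/ms, β=0.2/ms, transmitter: 0.5 mM square
pulse of 0.3 ms per presynaptic spike).  LN→PN and LN→LN are fast GABA_A
(E=−70 mV, α=10/ms, β=0.2/ms, transmitter: sigmoid of presynaptic
voltage, midpoint −20 mV, slope 1.5 mV); LN→PN additionally carries slow
G-protein-coupled inhibition (r₁=0.5, r₂=0.0013, r₃=0.1, r₄=0.033,
K=100 µM⁴, E=−95 mV) on the same adjacency.  Kinetic state is kept per
presynaptic neuron (the transmitter depends only on the presynaptic
cell); per-edge strength is base conductance × facilitation.

The printed class conductances (0.02 µS LN→LN, 0.015 µS LN→PN fast,
0.02 µS LN→PN slow, 0.3 µS PN→LN; large network 0.024/0.019/0.075 µS)
are interpreted as per-target class totals: each edge carries
g_class / n_afferents(postsynaptic cell), divided by the postsynaptic
membrane area.  This is the normalization convention of the source model
family and keeps the total synaptic conductance of a cell independent of
its random in-degree.

### Network geometry

20 glomeruli of 5 PNs + 12 unipolar LNs, plus 40 multipolar LNs.
Directed edges are independent Bernoulli draws: PN→uniLN 0.4,
PN→multiLN 0.4, uniLN→PN 0.5 (0 within its own glomerulus), uniLN→uniLN
0.4 (0 within glomerulus), uniLN→multiLN 0.3, multiLN→PN 0.3,
multiLN→multiLN 0.1, multiLN→uniLN 0.4; no PN→PN edges.  The 4×-scaled
variant (400 PN / 1120 LN) uses uniform p=0.125 for all three classes.
Smaller networks for testing keep the same per-glomerulus composition
and probabilities with fewer glomeruli.

### Odors and inputs

Seven percepts tile the PN population in contiguous blocks; a percept
drives its block with a Gaussian profile centered on the block's central
neuron, with standard deviation = width × span/2.  Unipolar LNs receive
the mean profile value of their glomerulus's PNs; multipolar LNs receive
35% of the mean unipolar drive.  Each activated neuron receives a
current pulse rising with τ=66.7 ms for 500 ms and decaying with
τ=200 ms, scaled by its profile amplitude, plus per-step Gaussian noise.

Input amplitudes are calibration parameters, not printed quantities.
They were chosen once so that (i) the untrained network shows
odor-evoked PN firing (at least half of the PNs in activated percepts
spike during the pulse) and odor-locked LFP oscillations, and (ii) PN
and LN firing is sparse (~5-15 Hz active-cell rates).  Sparseness
matters because facilitation increments are per spike (dF=0.15): at
30-50 Hz the multipliers saturate within a few presentations and wash
out the odor-specific structure of the learned weights.  Defaults:
PN peak 5.0 µA/cm², LN peak 2.5 µA/cm², noise SD 0.15 µA/cm², odor onset
200 ms into each presentation.

Blend odors (PH/PP experiment) set each percept's width equal to the
chemical's proportion of the blend, with the seventh percept inactive.
The actual blend compositions are not available, so the generator uses
synthetic proportion templates emulating two floral varieties (rewarded
PH weighted toward early percepts, the first component pinned at the
printed 0.372; habituated PP weighted toward later percepts) with
per-odor lognormal within-variety variation (σ=0.25) renormalized to
sum to 1.  The six blends are a *fixed* odor panel — identical across
simulation seeds, as a panel of measured blends would be — so
seed-to-seed spread reflects network realization and noise, not input
resampling.  Sensor-
derived odors map each sensor's (ΔR, ema_max, ema_min) features to pulse
(height, rise τ, decay τ) ∝ (ΔR, 1/ema_max, 1/ema_min); the synthetic
sensor generator emulates the 16-sensor × 8-feature × 6-odor schema with
designed rewarded-selective, habituated-selective and shared sensor
groups plus Gaussian repetition jitter.

### Plasticity

Each LN→PN (fast and slow jointly) and LN→LN synapse carries a
multiplier F ≥ 1.  During rewarded presentations every presynaptic LN
spike adds dF_pre=0.15 to F of all that LN's outgoing inhibitory edges
(associative rule); during habituated presentations every postsynaptic
spike adds dF_post=0.15 to F of all inhibitory edges onto the spiking
cell (nonassociative rule).  Between updates F decays as
1+(F−1)e^(−Δt/τ) with τ=30 s, applied lazily from per-edge timestamps —
numerically identical to continuous decay for this rule and free of
per-step cost.  The same decay is the forgetting mechanism of the
environment experiments.  Any spike within a presentation counts (the
rule is gated by the odor's class, not by the stimulus window), and
increments are uncapped.  Training = 30 presentations × 2 s in
randomized order balanced over the two classes; weights are frozen
(g·F at the training-end clock) for all test-phase trials.

### Integration

Classical RK4 at dt=0.04 ms over the packed state vector (V, 8 gating
variables, Ca per neuron; O_ACh, O_GABA, R, G per presynaptic neuron),
compiled with numba.  Aggregate synaptic conductances (weight-matrix ×
open-fraction products) are evaluated once per step from start-of-step
states while the driving force (V−E) is evaluated at every stage; the
kinetic states evolve on ≥5 ms timescales, so the step-frozen
conductance perturbs voltage traces far below the noise floor.  Gates
and open fractions are clamped to [0,1] after each step; Ca and G are
kept positive.  Spikes are upward 0 mV crossings with a 2 ms refractory;
facilitation fires at the crossing step.  Noise is one Gaussian draw per
neuron per step, held across stages.  Non-finite state aborts with the
offending variable named.

### Analyses

Representations are PN × time-bin matrices of spike counts over the
500 ms stimulation window (100 ms bins; 40 ms for PCA), normalized by
the trial's grand sum.  Similarity is the per-bin Pearson correlation of
PN vectors averaged over bins; zero-variance bins are skipped and
counted, not imputed.  Per-percept activation is the mean PN firing rate
of the percept's block over the window, averaged over trials; the
uniqueness index is (act_rew−act_hab)/act_hab from naive responses, the
change in activity is (act_diff−act_naive)/act_naive for rewarded odors,
and contrast enhancement is their OLS regression (two-sided t on the
slope).  Units with zero denominators are excluded and reported through
the regression's unit count.  The LFP is the mean PN voltage sampled at
1 ms.

### GCN analog

16 sensor nodes + 1 reward node; sensor-sensor edges are 1 with no
self-loops (so a node's aggregation, the group sum minus its own value,
preserves per-sensor identity), and the reward node's edges are +1/−1
per training sample and 0 at test.  Two graph-convolution layers
H(l+1)=ReLU(A·H(l)·W(l)) (8→8→4 features) feed a flattened two-layer
head (68→64→2).  Cross-entropy is minimized with Adam (lr 0.01,
20 epochs), with forward, backward and optimizer written directly in
numpy.  Because a train-only label signal would be exploited as a
shortcut that vanishes at test time, the reward edges are dropped for a
random half of training samples, forcing the sensor pathway to carry the
classification.  Layer-wise contrast analysis treats layer-1 node
activations (feature means) as the untrained circuit and layer-2 as the
trained one, with the same UI/change regression as the biophysical
model; the layer change is reported as a plain difference.

## Problem sizes

Full-protocol simulations of the 380-neuron network take minutes per
training run, so the package defines scale bundles that preserve the
architecture, connection statistics, plasticity rule and the ratio of
forgetting time constant to training duration (τ_F = total training
time / 2, which equals the printed 30 s at the reference protocol):

* reference / acceptance (used by `scripts/acceptance.py`): 20
  glomeruli (100 PN / 280 LN), full 30 × 2 s protocol, 4 seeds, 1
  frozen-weight test trial per odor — trained-state responses are
  reproducible to ~3 decimals across test noise, so seed-to-seed
  realization dominates the spread and extra trials add little;
* directional tests: 8-10 glomeruli, 12-16 × 1 s presentations, 1 test
  trial per odor, 2-3 seeds; environment experiments use 4 odors per
  class (the reference protocol uses 10) and an 8-percept tiling, since
  two disjoint environments of 3-percept classes overlapping by two
  cannot be embedded in 7 percepts.

## What the synthetic data does and does not show

The generators emulate the *structure* of the study's inputs — percept
mixtures with controlled overlap, blend proportions, the gas-sensor
feature schema — with documented defaults where the study's exact values
are unavailable (width sets, blend compositions, sensor templates).
Passing tests therefore demonstrate the circuit mechanisms (selective
facilitation, decorrelation, contrast enhancement, forgetting-driven
relearning) on inputs with realistic statistics; they do not certify
performance on the measured blend compositions or the real drift-dataset
recordings, and absolute correlation values depend on the synthetic
width distributions.

## Known limitations

* The associative (presynaptic-only) rule produces a modest
  decorrelation here rather than none; the dissociation is expressed as
  its effect being well under half of the nonassociative rule's.
* In the two-environment reversal cases (3 and 4), the recovery of the
  old-pair correlation after training with a reversed reward structure
  is small at test scale and is asserted as a pooled direction over both
  cases.
* Multi-compartment morphology, temperature dependence, channel noise,
  synaptic depression and gap junctions are out of scope; LN spikes are
  modeled as full Na spikes.
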