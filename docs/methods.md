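# Methods

## Model

### Nucleus dynamics

Every circular component ("nucleus") is a neural-mass-style rate unit:

```
ε dx/dt = α + β · (1/(1+S)) · Σᵢ Eᵢ wᵢ uᵢ − γ · Σⱼ Iⱼ − x
o       = φ atan(x),  φ = 1/atan(1)
```

Assumptions built into this form:

* a population's state is captured by one scalar activation; spatial
  structure within a nucleus is ignored;
* excitation and subtractive inhibition combine linearly, while shunting
  inhibition acts divisively on the excitatory term only (the factor
  `1/(1+S)`), reflecting the distinct receptor dynamics the three
  connection kinds stand for;
* with the averaging defaults `β = 1/N`, `γ = 1/M`, the aggregate
  excitatory term stays in [0, 1] for inputs in [0, 1] regardless of
  fan-in, so adding connections never destabilizes a unit.  When a unit
  has no inputs of a class, that term is zero (no 0/0 from the averaging
  default);
* the output nonlinearity is odd and bounded; `φ = 1/atan(1)` makes a
  unit activation produce a unit output, so a chain of nuclei neither
  amplifies nor attenuates a unit signal at equilibrium.  `|o| < φ·π/2 = 2`
  always.  Activations are not clamped: negative activations produce
  negative outputs symmetrically, and consumers that need non-negative
  signals (shunting aggregation, the plant's muscle drives) rectify at
  zero on their side.

### Integration and scheduling

First-order explicit Euler with a fixed step, `dt = 0.01` s by default
against a shared nucleus time constant `ε = 0.1` s (ten steps per time
constant).  `dt > ε` is rejected rather than warned: the explicit scheme
overshoots there, and all stability reasoning presumes stable stepping.
Fixed-step integration (rather than adaptive) keeps the simulator
compatible with real-time, robot-facing use of the same models.

Every connection is delayed by an integer number of ticks, minimum one.
Each tick, all connections are read, all components are stepped, and all
fresh outputs are written back to the delay buffers.  Because reads only
ever see previous-tick outputs, the schedule is synchronous and
deterministic with no update-order ambiguity — this replaces
rendezvous-style parallel execution with an equivalent, reproducible
serial schedule.  Halving `dt` preserves equilibria exactly and changes
transients with first-order convergence (verified in the test suite),
and the behavioral orderings below are invariant under `dt` halving.

### Synaptic gain adaptation

Each excitatory synapse carries a slow gain `u` (initially 1) modeling
receptor up/down-regulation: an exponential moving average of the raw
input (`tau_e = 2` s) drives `u' = clip(u + (dt/tau_u)(setpoint − u·avg),
0.25, 4)` with `setpoint = 1`, so `u = 1` is a fixed point at unit
average input, persistent weak input up-regulates, and saturated input
down-regulates.  The input average is initialized at the setpoint —
synapses are assumed to start at their adapted equilibrium — which makes
the unit-gain fixed point exact from the first tick.

`tau_u = 600` s.  The functional requirement is that adaptation be slow
relative to entire behavioral episodes, including multi-trial training
runs of 30–60 s; at 600 s, gain drift stays below ~10 % over any shipped
experiment while remaining visible over long exposures (dark adaptation
of the light reflex is a real, if slow, consequence of the rule).  The
exact functional form of receptor regulation is a design choice; only
its direction and slow timescale are constrained.

## The pupil network

18 components: 15 nuclei and three functional (algebraic) units, plus an
iris plant.  The connection graph is data (`pupilsim/data/pupil.model`),
a provisional reconstruction from the standard anatomy of pupil control;
revising it requires no code change.  Key structure:

* parasympathetic constriction: `R → PTA → EWpg → CG → sphincter`
  (4 hops);
* sympathetic dilation: `AMY → LH → DMH → IML → SCG → dilator` (5 hops,
  with `DMH → PVN → IML` as a parallel relay).  The one-hop excess over
  the constriction chain — both chains pass four integrating nuclei — is
  the structural source of dilation being slower than constriction.  The
  quantitative lag equals the per-hop delay; only the ordering is
  asserted, since no reference value for the ratio is fixed here;
* modulation: `AMY → LC`, `LC —(shunting)→ EWpg` implements the
  fear-inhibited light reflex divisively; `R → SCN → VLPO —| LC` holds LC
  down under bright light;
* recognition: `R → LGN → Cortex` (identity + surprise) and the
  subcortical `R → SC → PULV → AMY` salience route;
* learning: only the cerebellar (`Cortex → CB`) and amygdalar
  (`PULV → AMY`) afferents are plastic; every other weight is exactly 1
  and is verified bitwise after every simulation.

Receptor annotations on edges (`nAChR`, `a2`, ...) are carried as
metadata only; the computational kind (excitatory / inhibitory /
shunting) is what the simulator interprets.

### Functional components

**Cortex.** Stimulus identity is symbolic: the protocol's `identity`
channel is an index into a fixed identity set (default 16), standing in
for object recognition, which is out of scope.  The cortex outputs the
one-hot identity and a surprise signal `0.6^k` after `k` prior exposures
(counted per contiguous presentation episode).  Novelty is per-identity
and never forgotten — no spontaneous recovery is modeled.

**Cerebellum.** Learns the conditioned light response.  The
cortico-cerebellar connection carries the identity trace with a delay of
4 ticks (simulation variant) or a tapped delay line at offsets
{2,4,6,8,10} (robot variant, `cb_taps`); weights per (identity, tap)
follow the delta rule `Δw = η·trace·(US − prediction)` with `η = 0.1`
per paired tick, clipped at zero, using the `us_light` brightness flash
as the teaching signal.  Credit lands on the tap whose delay matches the
CS–US interval, which is what produces the inter-stimulus-interval
tuning of conditioning: the tuning curve peaks at the configured
cerebellar delay (0.04 s by default).

**Amygdala.** Learns signed stimulus valence into separate positive and
negative channels (magnitudes in [0, 1], `η = 0.1` per tick while the
stimulus and a non-zero `valence` teaching signal are present) but
reports arousal as the *sum of magnitudes* plus surprise — hence equal
arousal for equally-trained positive and negative stimuli.  The symbolic
identity and valence arrive as external channels; the `arousal` channel
is a direct probe input used by the timing experiment.  The `PULV → AMY`
edge is carried structurally (plastic, initial weight 0) as the
anatomical substrate of that association.

**Iris plant.** `diameter = clip(d_rest − g_s·sphincter + g_d·dilator,
d_min, d_max)` with `d_rest = 4.0` mm, range [2.0, 8.0] mm and gains
`g_s = g_d = 3.0` mm per unit drive — within the physiological pupil
range; only ordering-type claims depend on these numbers.  Negative
drives are rectified (muscles cannot be pushed).  The plant is an
actuator, not a model component: it exists because a simulation needs
diameters in millimetres where a robot would drive pupil servos.

## Stimulus protocols

Protocols are deterministic per-tick channel bundles (`light`,
`us_light`, `identity`, `valence`, `arousal`) serializable to CSV.  They
emulate experimental timelines — light steps, CS–US pairings, novelty
sequences, fear–light compounds — not sensory physics: there is no image
rendering, no photoreceptor adaptation, no noise.  Consequently, passing
the behavioral suite shows that the *circuit structure* produces the
qualitative phenomena, not that the model fits any empirical trace.

Defaults: reflex protocols use a dark baseline; novelty/emotion
protocols hold ambient light at 0.3 so dilation has headroom in both
directions.  Conditioning uses 0.03 s CS and US pulses (sharp ISI
tuning; long pulses would flatten the overlap across neighbouring ISIs)
with 1.5 s trial spacing.  The fear experiment familiarizes the CS with
ten neutral exposures before aversive pairing, because a *novel* CS
arouses by itself and would contaminate the untrained null control; its
light probe is 0.5 intensity with a 1.0 s CS lead so the CS-driven
dilation has plateaued before the light arrives, and the reflex is
measured as the dip below the immediately pre-light baseline within the
light-on window in both matched conditions.

## Response metrics

From each diameter trace: baseline (mean over a pre-onset window),
signed peak deviation (negative = constriction), latency (first crossing
of 10 % of the peak deviation, linearly interpolated between ticks),
time to peak, and half-recovery time.  Flat traces report zero amplitude
and no latency.  The 10 % threshold and interpolation are measurement
choices of this package.

## Population runs

`population_run` draws named parameters from per-parameter distributions
(constant, uniform, or normal), builds one network per draw with
deterministic per-run seeds spawned from the master seed, and aggregates
a metric function over runs (default: light-reflex amplitude and
latency).  Zero-variance distributions reproduce a single individual
exactly.

## Structural validation

`compare_to_reference` compares the model's directed component graph to
a TSV edge list after name normalization (leaf names, optionally an
alias table): directed-edge Jaccard index, missing/extra edge diffs, and
a Spearman rank correlation of per-node total degree.  Comparison is on
unweighted directed edges; kinds and weights appear in the diff detail
only.  Graph-edit distances and automatic connectome extraction are out
of scope.

## Known limitations

* The edge list is a provisional anatomical reconstruction; receptor
  types per edge and some hypothalamic projection directions are not
  settled, which is why the graph lives in a data file.
* Recognition is symbolic; the matrix retina/cortex coding of the
  original architecture is not exercised.
* The cerebellar and amygdalar learning rules are minimal delta-rule
  stand-ins chosen to reproduce the qualitative phenomena; no claim is
  made about their biological fidelity.
* Validation is by qualitative ordering (amplitudes, latencies, lags),
  not by fitting empirical pupil traces; no human dataset is reproduced
  here.
* The dilation/contraction lag equals one hop-delay by construction;
  its empirical magnitude is not calibrated.
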