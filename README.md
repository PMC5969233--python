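# ctnet — corticothalamic network simulations of structural damage

`ctnet` simulates MEG-like resting-state alpha activity on a structural
brain network with a corticothalamic mean-field model, applies graded
*virtual lesions* — white-matter (between-region), cortical and thalamic
(within-region) damage — and quantifies the functional consequences with
phase-locking connectivity and minimum-spanning-tree network topology. It
is aimed at computational neuroscientists studying how neurodegeneration
(multiple-sclerosis-like white- and grey-matter loss in particular)
reshapes functional connectivity and network organisation.

## The model

Each network node is a *unit* of four neuronal populations — cortical
excitatory (e), cortical inhibitory (i), thalamic relay (s), thalamic
reticular (r). Population a's mean membrane potential V_a obeys

    D V_a(t) = Σ_b ν_ab · φ_b(t),
    D = (1/αβ) d²/dt² + (1/α + 1/β) d/dt + 1,

with synaptic gains ν_ab (mV·s), rise/decay rates β, α, and the firing
sigmoid Q(V) = Q_max / (1 + exp(−(V−θ)/σ)). The excitatory field φ_e is
damped as (1/γ² d²/dt² + 2/γ d/dt + 1) φ_e = Q_e. Thalamus and cortex
exchange input with a 40 ms loop delay τ_ct; units are coupled e→e over a
78×78 (configurable) structural adjacency A with distance-dependent axonal
delays τ_jn and global gain ε:

    network input to unit j = ε (1/N) Σ_n A_jn φ_e,n(t − τ_jn).

Zero-mean Gaussian white noise drives the relay population only. The
delayed stochastic system is integrated with Euler–Maruyama at dt = 1e-4 s;
the first 2 s (20,000 samples) are discarded. The corticothalamic loop
resonance makes the alpha band (8–13 Hz) the dominant rhythm of the
excitatory output, which is the model's MEG-like observable.

Outcome measures per simulation: alpha-band **mean activity** (band-limited
power), **mean PLV** (phase-locking value over all region pairs), and, from
the maximum spanning tree of the PLV matrix, **diameter** (integration) and
**leaf fraction** (segregation).

Damage experiments scale, linearly over iterations and from empirical
maxima: predilection-site white-matter edges (up to 14%), per-region
intracortical gains ν_ee, ν_ei, ν_ie, ν_ii (up to the region's
cortical-thickness loss), or the intrathalamic gains ν_sr, ν_rs (up to 11%,
the relative thalamic volume loss 1 − 18.50/20.78).

## Worked example

```python
from ctnet import (ModelParameters, calibrate_alpha, generate_connectome,
                   generate_damage_maps)
from ctnet.damage import DamageSchedule, run_experiment

connectome = generate_connectome(n_regions=40, edge_density=0.15, seed=1)
maps = generate_damage_maps(connectome, seed=2)
params = ModelParameters()

print(calibrate_alpha(params, connectome, seed=5))
# {'peak_frequency': 9.5, 'in_band': True}

schedule = DamageSchedule(kind="thalamic", maps=maps, n_iterations=10)
traj = run_experiment(schedule, params, connectome, n_realizations=5,
                      base_seed=42)
agg = traj.to_aggregate_frame()
print(agg[["fraction_of_max", "mean_plv_mean", "diameter_mean"]].round(3))
```

which prints (mean over 5 stochastic realizations per damage level):

```
   fraction_of_max  mean_plv_mean  diameter_mean
0            0.000          0.139           14.2
3            0.333          0.152           15.0
6            0.667          0.392           19.8
9            1.000          0.422           23.0
```

(abridged to every third iteration). Read: as intrathalamic inhibition
weakens, alpha-band synchrony rises from its resting level (0.14) to 0.42,
and the spanning-tree diameter grows from 14 to 23 hops — the functional network loses integration while overall
connectivity *increases*. The same pipeline with `kind="white_matter"`
shows the opposite activity trend: alpha power falls monotonically as
structural edges weaken.

A CLI mirrors the library: `ctnet generate`, `ctnet simulate`,
`ctnet experiment` (see `--help`).

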