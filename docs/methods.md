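# Methods

## Model

Each of N network nodes is a corticothalamic *unit* with four neural-mass
populations: cortical excitatory (e) and inhibitory (i), thalamic relay (s)
and reticular (r). The mean membrane potential of population a in unit j is
driven by synaptically filtered firing input,

    D V_a,j = Σ_b ν_ab · (input from b),
    D = (1/αβ) d²/dt² + (1/α + 1/β) d/dt + 1,

with the population sigmoid Q(V) = Q_max / (1 + exp(−(V − θ)/σ)) and
damped-field dynamics (1/γ² d²/dt² + 2/γ d/dt + 1) φ_e = Q_e for the
propagating excitatory output. The within-unit wiring is: e receives
{ν_ee φ_e, ν_ei Q_i, ν_es Q_s(t−τ_ct)}; i receives {ν_ie φ_e, ν_ii Q_i and
the same delayed relay input with gain ν_es as printed in the source
equations (a separate ν_is is available behind the `use_nu_is` switch)};
s receives {ν_se φ_e(t−τ_ct), ν_sr Q_r, noise}; r receives
{ν_re φ_e(t−τ_ct), ν_rs Q_s}. Between units only e→e coupling exists, with
gain ε/N on the binary structural adjacency and per-edge delays
τ_jn = distance/velocity. Spatially continuous field dynamics are not
modelled (the Laplacian term is zero): each unit is a point process in
space, and all spatial structure enters through the network.

Noise is a zero-mean, unit-variance Gaussian white process χ(t) entering
only the relay equation as ν_n·σ_n·αβ·χ(t); in the Euler–Maruyama update it
contributes with the usual √dt scaling. Since α, β and ν_n are constants,
the overall noise scale is the single free amplitude σ_n.

## Default parameters

Rates and potentials: Q_max = 250 s⁻¹, θ = 15 mV, σ = 6 mV, α = 50 s⁻¹,
β = 200 s⁻¹, γ = 100 s⁻¹, τ_ct = 40 ms, dt = 1e-4 s, σ_n = 1e-3,
conduction velocity 10 m/s (config; never stated for this class of study,
within the physiological range of myelinated association fibres).

The gain table ν_ab was *designed*, not copied: the resting-state values in
the lineage of this model are specified as dimensionless loop gains, and we
solved for the ν_ab (given the sigmoid) that realise

    G_ee = 4, G_ei = −6, G_ese = 4, G_esre = −2.8, G_srs = −0.6

at operating rates (Q_e, Q_i, Q_s, Q_r) = (15, 15, 15, 40) s⁻¹, with the
self-consistency conditions of the noise-free fixed point closing the
system. Two constraints shaped the choice within the published range of
these gains:

1. **Alpha resonance.** The 2×40 ms corticothalamic loop with these gains
   puts the dominant pole of the linearised noise→φ_e transfer near 9 Hz.
   The shipped defaults are gated by `calibrate_alpha`, which simulates,
   averages Welch spectra over regions and checks that the dominant peak
   above 2 Hz falls in 8–13 Hz.
2. **Branch persistence under damage.** Mean-field models of this family
   are multistable: a saturated high-firing equilibrium coexists with the
   physiological low-firing branch, and parameter changes that disinhibit
   the cortex (exactly what cortical grey-matter damage does) can fold the
   low branch away, slamming the simulation to the saturation rail. The
   default gains were required, by explicit continuation in the damage
   fraction, to keep the low-firing equilibrium in existence under the full
   cortical (≤18% regional) and thalamic (11%) damage ranges.

The inhibitory gain ν_ei is strengthened relative to a single isolated
unit so that the additional excitatory drive arriving over the network
(ε/N · Σ A φ_e ≈ 0.09 mV·s of effective e→e gain at the default density)
is balanced at the operating point. ε = 0.64 places the baseline network
just below its synchronization onset — the standard near-critical working
point for resting-state whole-brain models — where the PLV matrix is
structured but not saturated and both increases and decreases of effective
gain are visible in the outcome measures.

## Numerics

The second-order operators are reduced to first-order pairs; states are
advanced by Euler–Maruyama at dt = 1e-4 s (halving dt changes a 1 s
deterministic trajectory by well under first-order tolerance; a test
asserts the convergence order). Delays are rounded to the nearest multiple
of dt and served from ring buffers holding φ_e (network and τ_ct lags) and
Q_s (τ_ct lag); the buffer depth exceeds the maximum delay by one row so a
write for t+1 can never alias a read at the maximum lag. History for t < 0
is the noise-free steady state found by root-finding with continuation from
the uncoupled system (tracking the low-firing branch); if damage has folded
that branch away, the last point on the branch is used as a nearby initial
condition — the discarded 2 s transient absorbs the difference. The
compiled (numba) kernel is verified against a transparent numpy reference
integration, including the noise stream, in the test suite. Non-finite
states abort with the step index and a parameter dump; inside experiment
loops such cells are recorded as failed and skipped by the aggregates.

Output is the excitatory field of every region, decimated to 1 kHz (the
synaptic and damping filters leave negligible power near the new Nyquist
frequency).

## Observables

The output is band-passed to 8–13 Hz with a zero-phase Hamming FIR filter
(two-sided `filtfilt`; 3.3·fs/2 taps, i.e. a 2 Hz transition band, so the
5 Hz-wide pass band reaches unit gain). One filter length is trimmed from
each end before any statistic. Mean activity is the variance of the
filtered signal averaged over regions (equal to band-integrated spectral
power; a Welch-integral variant is available and rank-agrees). PLV uses
analytic-signal phases: PLV(j,k) = |⟨exp i(φ_j−φ_k)⟩| over the trimmed
window, one window per simulation (no epoching). With ~11 s of valid data
and a 5 Hz bandwidth the PLV floor for independent signals is ≈ 0.1; all
reported baseline values sit above this floor and the null level is checked
against a Monte-Carlo oracle in the tests.

Network topology uses the spanning tree over the *strongest* connections
(maximum spanning tree of PLV; the convention of the MEG minimum-spanning-
tree literature, equivalent to the MST of 1−PLV), built by Kruskal with
exact lexicographic tie-breaking. Diameter is reported in hops
(unnormalised); leaf fraction as a proportion of nodes.

## Synthetic substrate

No published structural matrix is shipped. The generator emulates the gross
organisation of atlas-based cortical networks: regions are placed in two
mirrored hemispheric blocks (left x < 0), and edges are taken in order of
log-normally jittered Euclidean distance under a per-node degree cap, which
yields the short-range-dominated connectivity and narrow degree
distribution characteristic of parcellation-scale structural networks, plus
a guaranteed-connected Euclidean MST backbone. Adjacency is binary. What
this does *not* emulate: true fibre geometry, interhemispheric homotopic
connectivity, weighted streamline counts, and hub architecture — so tests
passing on this substrate show the damage-response *shapes* are generic to
the model class, not that they are quantitatively those of any specific
empirical network.

Damage maps: predilection-site edges are sampled with probability
proportional to edge length (default 30% of edges), emulating the
periventricular concentration of white-matter lesions; the cortical atrophy
map draws per-region maximal fractional losses uniformly from 2–15%,
consistent with relative cortical-thickness reductions reported in
longstanding disease; the thalamic maximum is 0.11 = 1 − 18.50/20.78 from
published patient/control volume means.

## Experiments and statistics

Each schedule is linear in damage fraction from 0 to its maximum (white
matter 14% on masked edges; cortical: regional atrophy map; thalamic: 11%),
always scaling the original baseline value so the final iteration lands
exactly on the maximum. Iterations default to 20 (the figure-style axis);
the test and acceptance runs use 10 iterations × 8 realizations × 16 s at
40 regions to fit a single-CPU budget (the integer-valued tree diameter in
particular needs more than a handful of realizations per iteration for a
stable baseline) — the curve shapes, not their axis
lengths, are the object of interest. Every (iteration, realization) cell
has a seed derived from (base seed, iteration, realization) via
`SeedSequence`, so iteration 0 is identical across schedule kinds by
construction and every cell is independently reproducible.

Curve statistics: Spearman rank correlation of the per-iteration mean
against iteration with a permutation p-value; an inverted-U detector that
fires when an interior maximum exceeds both endpoints by half the mean
across-realization SD; and a departure fraction — the damage fraction at
which a curve first leaves a ±2 SD band around its baseline.

## Observed behaviour and known limitations

Under the defaults, cortical and thalamic damage raise alpha activity and
mean PLV (cortical more strongly, with a plateau), and both raise the tree
diameter and lower the leaf fraction — the functional network loses
integration and segregation while connectivity increases. White-matter
damage lowers activity strictly monotonically and lowers PLV slightly.

Two discrepancies with the qualitative template this study family reports
are documented rather than hidden:

* **No inverted-U for white-matter damage.** In this implementation, mean
  PLV declines monotonically (by a few percent) along the white-matter
  schedule, at every baseline we examined — deep subcritical, near-onset,
  partially synchronized — and at conduction velocities from 2 to 10 m/s.
  The initial *rise* in connectivity reported for mild white-matter damage
  evidently requires ingredients this synthetic configuration lacks
  (plausibly the weighted empirical connectome's community structure, or an
  operating point whose long-range delayed inputs are net-desynchronizing).
  The detector and its test are implemented as specified and report the
  absence honestly.
* **White-matter topology effects are weak and not in the template
  direction.** With damage confined to 30% of edges at ≤14%, the total
  coupling change is ~4%; at the reduced test scale the spanning-tree
  diameter ends slightly *below* and the leaf fraction slightly *above*
  baseline — within about one realization SD, but consistently so. The
  grey-matter topology effects, by contrast, are large, robust and in the
  reported direction (diameter up, leaf fraction down).

Other limitations: grey-matter demyelination (within-unit delays),
conduction-velocity heterogeneity, task dynamics, and any forward model to
sensors are out of scope; thalamic output is never used as an observable;
the saturated high-firing branch of the mean-field family is a model
artifact whose avoidance constrains, as described above, how far damage
schedules may push the system.
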