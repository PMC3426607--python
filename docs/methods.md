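# Methods

## The model

`flyal` implements a multi-scale model of the insect antennal lobe (AL),
the first olfactory relay of the fly brain. The AL is organized into
glomerular channels: all olfactory receptor neurons (ORNs) expressing one
receptor class converge on one glomerulus, whose projection neurons (PNs)
carry the odor code downstream while excitatory and inhibitory local
neurons (LNEs, LNIs) mediate lateral interactions. The package's central
question is the functional role of two coexisting forms of short-term
depression at the ORN output synapse:

* **vesicle depletion** — feedforward: every ORN spike releases a fraction
  `p_ves` of the remaining pool, which recovers with time constant `tau_D`;
* **presynaptic inhibition** — feedback: LNIs deposit GABA on the ORN
  terminal, suppressing release with strength `s_pre`.

Both act through one release efficacy per ORN terminal,

    eta = (1 - D) * exp(-s_pre * A_pre),        0 <= eta <= 1,

with `D` the depleted fraction (jump `p_ves (1 - D)` per ORN spike, decay
`tau_D`) and `A_pre` the summed GABA-A + GABA-B conductance at the
terminal. The exponential form is a modeling choice (the two mechanisms
must combine multiplicatively, stay bounded, and remain independently
scannable); its consequences are insensitive to the precise saturating
shape.

### Point-neuron network

Every neuron is a single-compartment Hodgkin–Huxley model with the
classical 1952 squid-axon sodium/potassium kinetics in the −65 mV rest
convention (C = 1 µF/cm², gNa = 120, gK = 36, gL = 0.3 mS/cm², ENa = 50,
EK = −77, VL = −54.4 mV). Integration is fixed-step RK4 at dt = 0.02 ms;
spike times are linearly interpolated 0 mV upcrossings; a ±200 mV guard
aborts with diagnostics. Halving dt moves spike times of a driven 500 ms
trace by well under 0.5 ms.

Synapses release instantaneously on presynaptic spikes into three
conductance channels: fast excitation (decay σ_E = 9 ms), GABA-A
(σ_A = 12 ms) and GABA-B (two-stage filter, rise 100 ms / decay 300 ms).
IPSCs onto PNs split roughly 50/50 between fast and slow components in
current contribution (the slow weight is scaled by the ratio of the filter
areas). ORN somata receive no synaptic conductances; LNI→ORN edges act
only on the terminal efficacy.

The default architecture is 5 glomeruli × (60 ORN, 6 PN, 6 LNE, 6 LNI).
Connectivity is Erdős–Rényi per class pair: each ordered pair connects
independently with a probability depending only on (pre-class, post-class,
same/different glomerulus). ORNs and PNs project only within their own
glomerulus; LNEs/LNIs project laterally. The LNE→PN intra-glomerular
probability is 0.20 (direct LN→PN contacts are rare), while LNE→PN
inter-glomerular connectivity is denser (0.50) so lateral excitation
reaches most glomerulus pairs.

### Input

Each ORN receives Poisson input events filtered through a causal 2 ms
exponential kernel into a stimulus current. Background rate is 350 Hz with
kernel strength 1.2 µA/cm² per event (ORN background firing ≈ 1–2 Hz, low
but nonzero). An odor is a vector of peak extra rates over the glomerular
channels, ramped with a 100 ms onset constant and a slower 300 ms offset
constant; concentration scales the same channel vector. Peak odor rates of
~4000 Hz saturate the PN response. The two noise sources across trials are
the Poisson input realization and a ±5 mV uniform jitter of the initial
membrane potentials; both are controlled by one per-trial seed, keyed by
(base seed, odor name, trial index) so panel order is irrelevant.

### Calibration of unconstrained defaults

Most of the model's numerical constants are not pinned down by external
constraints, so the
default coupling strengths are this package's own calibration, chosen once
so that a single parameter set satisfies the classical benchmark
constraints simultaneously:

1. high ORN→PN convergence (p = 0.8 over 60 ORNs) with ORN→PN weight 0.05,
   so PNs receive strong, reliable input right after odor onset;
2. enough ORN-synapse depression (`p_ves` = 0.2, `tau_D` = 300 ms,
   `s_pre` = 0.5 by default) that the PN firing-rate curve saturates and
   the PN PSTH peaks before the ORN PSTH;
3. lateral connectivity sparse enough that background activity shows no
   network oscillation, yet strong enough that PNs respond more broadly
   than their ORN class (undriven-glomerulus PNs respond to odors driving
   the other glomeruli).

The depression constants deserve a note: with a slower vesicle pool
(e.g. `tau_D` = 500 ms) the background depletion level rises enough that
the margin between the strength of a single background EPSP and the
sustained saturated drive collapses; the PN then operates in a
fluctuation-driven regime during odors and its spiking becomes *less*
regular as drive grows, contradicting the mean-driven picture the model is
meant to illustrate. `tau_D` = 300 ms with `p_ves` ≈ 0.2 keeps the odor
drive mean-driven (PN conductance ≈ 0.2 mS/cm², comfortably above the
conductance rheobase ≈ 0.13) while background EPSPs stay mostly
subthreshold. Where no constraint reaches a constant at all (logistic
steepness, persistence times of the discrete-state model, the spike
detection threshold), round conventional values are used and exposed in
configuration.

### Variance coding (hypothesis 1)

In the saturated regime the time-averaged release per terminal approaches
the ceiling `1/(p_ves tau_D)` events/s regardless of ORN rate, so the mean
PN conductance is pinned while its *fluctuations* shrink as the rate
grows: the stimulus is coded in the variance, not the mean. The analyzable
cartoon (conductance-based integrate-and-fire PN driven by depressing
Poisson ORN synapses) makes this exact: D and G are jump–decay shot-noise
processes and their stationary moments, including the G–D cross-moment,
follow in closed form from the moment ODEs (no Gaussian or decoupling
approximation; the Gaussian description is an interpretation valid at high
rates). The mean conductance saturates at `g sigma_G / (rho tau_D)` while
its standard deviation decays toward zero. Downstream, a high-threshold
Kenyon-cell readout fires on spike clusters but not on regular input of
equal mean rate, so the regularity itself is decodable — and in the full
network, classifier accuracy from spike counts *plus* pairwise
correlations exceeds counts alone on a saturating odor panel, with the gap
shrinking as total depression is removed.

### Reliability–sensitivity tradeoff (hypothesis 2)

Networks with the same mean PN rate can realize it with different mixes of
the two depression mechanisms: a **type-A** network (presynaptic
inhibition dominated) is sensitive but unreliable; a **type-B** network
(vesicle depletion dominated) is reliable but less sensitive. The package
probes this three ways:

* the full network is scanned over a (p_ves, s_pre) grid with matched
  seeds and fixed wiring; iso-rate contours of the mean PN spike count are
  extracted by marching squares (scikit-image, bilinear interpolation) and
  trial-to-trial count standard deviation is profiled along them (see the
  limitations: at desk scale the reliability gradient is dominated by the
  rheobase distance and runs opposite to the type-A/type-B expectation);
* discriminability of two similar odors (the weighted-vote classifier, see
  below) is profiled along the same contours at a long (400 ms) and a
  short (80 ms) observation window: the long-window optimum sits toward
  type-A, the short-window optimum toward type-B;
* the 2-LNI cartoon makes the tradeoff exact: two phase oscillators
  dv/dt = i (1 − d) that freeze each other for `tau_f` after each spike.
  Unfrozen-time accounting yields closed-form rates
  f_A = a(1 − b·tau_f)/(1 − a·b·tau_f²) (a, b the depressed speeds), and
  the return-map analysis yields exactly two ISI atoms per neuron,
  separated by tau_f, with masses fixed by the mean. Along the iso-rate
  (tau_f, d) family, ISI variance and the rate separation |f_A − f_B| both
  grow with tau_f.

### Odor discrimination

The decoder estimates, per PN and odor, a discrete distribution of spike
counts from training trials (Laplace pseudo-count 1; continuous features
such as pairwise correlations are digitized into 12 uniform bins fit on
training data). Each PN votes for the odor under which its observed count
is more likely, weighted by the log information ratio
log((h + s)/(e + s)) of its hit and error rates. k-way tasks run all
pairwise contests and take the majority; ties count as incorrect.
Evaluation is leave-one-trial-out with the whole trial layer held out
across odors, which keeps the null calibration at chance. The Gaussian
signal-to-noise analysis gives the matching theory: the best linear
classifier errs with probability
½ erfc(|Δµ| / (2√2 √(σ̄²/M + σ_η²))), verified against a Monte-Carlo
optimal-threshold classifier.

### Discrete-state Markov analysis

Each ORN–LNI pair carries three binary variables (v firing, d depletion,
a presynaptic inhibition); per time step, with input c ~ Bernoulli(λ):
v fires from 0 with probability c·P0·ℓ(γ(1−d−a))/ℓ(γ) (logistic reduction,
γ = 4, P0 = 0.5) and returns with probability 1/τ_on (τ_on = 2); d sets
with probability p·c and recovers at 1/τ_off (τ_off = 6); a sets with
probability 1 − exp(−S Σ_j A[j,k] v_j) and recovers at 1/τ_off. The
1 − exp(−·) form is chosen for smoothness in S and in every edge weight,
which is what makes *exact* operator differentiation possible. The exact
joint operator (dense, 8^N states) is built for N ≤ 4; equilibrium comes
from the eigen-problem with a power-iteration polish, firing rates and ISI
distributions from path sums with a 1e−12 tail truncation.

The subnetwork expansion Taylor-expands the firing rate and the iso-rate
ISI variance in the edge strengths around the uncoupled network, with the
vesicle parameter co-varied to hold the target rate fixed. All
coefficients are exact directional derivatives computed by second-order
forward Taylor (jet) propagation through the operator, the equilibrium
solve and the ISI path sums — finite differences are kept only as a
cross-check. Terms are motif-tagged (autapse, in-edge, fan-in, chain). In
the low-drive regime (λ ≈ 0.3) the motif signs reproduce the qualitative
story: foreign in-edges raise ISI variance (and sensitivity) along the
iso-rate family, an autapse lowers it. For an autapse-bearing LNI in an
Erdős–Rényi network the expansion predicts a critical in-degree K* (the
point where in-edge contributions outweigh the autapse), hence a critical
network size N_crit(κ) = min{N : P(Binomial(N−1, κ) ≥ K*) ≥ 75%},
non-increasing in the sparsity κ; the prediction is confirmed by exact
operators at N ≤ 3.

## Synthetic data

The fixture generators (Poisson, periodic, two-atom, bursty,
correlated-pair via common-mother thinning, Gaussian-count separable odor
panels) produce spike datasets whose rate, ISI structure, count
correlation and class separability are known by construction and stored in
metadata. They emulate the *statistical* shapes the analyses must resolve,
not AL biophysics: passing tests on them validates the statistics and the
decoder, while the engine-level tests validate the network model itself.
What they do not capture — odor-specific temporal structure beyond the
stereotyped ramp, inhibitory ORN responses, correlated trial-to-trial
drifts — bounds what any green test says about real recordings.

## Problem sizes and numerics

Test and acceptance runs use desk-scale reductions chosen as the smallest
systems in which each effect is unambiguous: a 2-glomerulus network at
full ORN convergence (60 ORNs, 6 PN/LNE/LNI per glomerulus) for the
hypothesis-level checks, a 3×3 (p_ves, s_pre) grid with 8 matched-seed
trials per odor, 3-glomerulus networks for lateral-interaction protocols,
and N ≤ 3 exact operators for the Markov checks. The full 5-glomerulus
default remains the package default for interactive use. Determinism is
end-to-end: identical (configuration, seed) reproduce bit-identical spike
tables. Degenerate cases are flagged rather than silently zeroed:
undefined CVs are NaN, constant response vectors are excluded from rank
correlations with a reported count, constant maps refuse contour
extraction, and the 2-LNI model raises a regime error when the freeze
window exceeds the faster neuron's period.

## Known limitations

* At desk scale, the reliability gradient along iso-rate contours of the
  HH-network depression scan runs *opposite* to the expected
  type-A-unreliable / type-B-reliable ordering: because the sustained PN
  conductance scales inversely with `p_ves`, the heavy-depletion end of
  any matched-rate contour sits near the classical HH neuron's type-II
  conductance rheobase and is fluctuation-driven, hence noisy. The
  corresponding acceptance check is deliberately left failing rather than
  redefined; the tradeoff itself is established exactly by the 2-LNI
  cartoon and the discrete-state Markov analysis, and the
  observation-window dependence of the discriminability optimum (short
  windows favor type-B, long windows type-A) does hold in the full
  network.
* The PN-PN versus PN-ORN rank-correlation contrast (same-glomerulus PN
  pairs correlating more strongly across odors than PN-ORN pairs) is not
  resolvable at desk scale in this calibration: with a
  shared-signal-plus-independent-noise response structure the two means
  differ by less than the estimation noise of small panels, and raising
  the lateral excitation enough to separate them injects correlated noise
  that degrades the reliability and discriminability structure of the
  depression scan. The package therefore verifies the robust form of the
  broad-tuning claim — undriven-glomerulus PNs respond to odors driving
  other glomeruli while their own ORNs stay at background — and exposes
  the rank-correlation histograms for larger-scale runs.

* Beyond the documented configuration constants (census, input rate,
  wiring band, synaptic time scales), quantitative targets for the
  emergent dynamics are not available, so validation is structural and
  qualitative: closed-form/oracle equivalences, monotonicities, sign
  patterns and benchmark orderings.
* The classical HH neuron enters depolarization block above a synaptic
  conductance of ≈ 1 mS/cm², so a network with *no* ORN-synapse
  depression silences its PNs under strong odors rather than saturating;
  scans therefore start at small nonzero depression.
* The weighted-vote classifier's discrete histograms are data-hungry;
  with few trials its accuracies carry binomial noise of order 0.1, which
  sets the resolution of the discriminability maps.
* The discrete-state exact analysis is capped at N = 4 pairs (8^N
  states); larger networks are reached only through the expansion plus
  motif counting.
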