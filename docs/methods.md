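# Methods

## The model

`mdynemo` models a multichannel, zero-mean envelope time series
x_t ∈ R^{Nc} as Gaussian with a time-varying covariance that factorises
into power and functional-connectivity (FC) parts:

    x_t ~ N(0, C_t),      C_t = G_t F_t G_t,

where G_t is diagonal with positive entries (per-channel standard
deviations — "power") and F_t is a unit-diagonal positive-definite
correlation matrix ("FC"). Each factor is a convex mixture of a small
basis of spatial *modes*:

    G_t = Σ_j α_jt E_j        (J1 diagonal matrices E_j, positive diagonal)
    F_t = Σ_j β_jt R_j        (J2 correlation matrices R_j)

The mixing weights α_t, β_t are softmaxes of two latent logit sequences
θ_t¹, θ_t². Crucially the two sequences are *separate*: power and FC may
follow different dynamics, with the single-dynamic model (one sequence
mixing full covariance matrices) as a special case. A recurrent prior
ties them together without coupling them: an LSTM consumes the
concatenated logit history of both dynamics and emits, through
per-dynamic linear heads with a softplus scale link, the conditional
Gaussian p(θ_t^k | θ_{1:t−1}^{1,2}).

### Inference

The posterior is amortised and mean-field: a bidirectional LSTM over the
data sequence produces per-time-point Gaussian factors q(θ_t^k) =
N(m_t^k, (s_t^k)²) through per-dynamic linear heads. Training minimises
the variational free energy per sequence,

    L = − E_q[ Σ_t log N(x_t | 0, C_t(θ)) ]  +  Σ_{t=2}^{T} Σ_k KL(q(θ_t^k) ‖ p(θ_t^k | θ_{1:t−1})),

with one reparameterised posterior sample for the likelihood term and
the Gaussian KL in closed form. The KL sum starts at t = 2 — the prior
is conditional-only, so the first time step's posterior is unpenalised —
and recurrent state is reset at every sequence boundary. Sessions are
cut into non-overlapping sequences of `sequence_length` (default 200)
samples that never span a session boundary; trailing remainders are
dropped for training but covered during inference by a final overlapping
window, so inferred mixing time courses have the full session length.

Optimisation is Adam over shuffled mini-batches. Three stabilisation
devices are used, all config-exposed or automatic: a linear KL anneal
over `kl_anneal_epochs` (the likelihood term shapes the observation
model before the temporal prior bites); `n_random_starts` independent
restarts keeping the best final loss (default 10); and a K-means warm
start of the observation model. The warm start exists because mixture
models of this kind exhibit a characteristic collapse when all modes
start near the static solution: whichever dynamic's likelihood signal
is picked up first gets fully resolved while two modes of the other
dynamic merge, and the optimiser rarely escapes (the collapsed optimum
has a clearly worse loss, so restart selection does catch it, at the
price of several extra runs). Clustering 100-sample window standard
deviations and correlations with K-means and initialising each E_j/R_j
from its cluster's statistics starts the modes distinct and roughly
aligned with real covariance regimes; empirically this removes the
collapse and cuts convergence time by about 3×. The windowed estimates
are far too coarse to constitute the answer — the fixed-window baseline
demonstrably fails on fast dynamics — they only break the symmetry. If
the data cannot support windowing (too short, degenerate), the
initialisation falls back to a noisy copy of the static solution.

Because no deep-learning framework is assumed, the LSTMs, heads and
optimiser are implemented on `autograd`-traced numpy; the Gaussian
log-likelihood is a custom primitive whose vector–Jacobian product,
∂/∂C · Σ log N(x|0,C) = ½(C⁻¹xxᵀC⁻¹ − C⁻¹), is supplied analytically.
This keeps a desk-scale fit (20 channels, ~13k samples) in the
single-digit minutes on one CPU.

### Parameter constraints

* Power diagonals: softplus of unconstrained values (plus 1e-8), smooth
  and total.
* Correlation modes: an unconstrained square factor's lower triangle L
  gives M = LLᵀ + 10⁻⁶ I, normalised to R = D^{−1/2} M D^{−1/2} with
  D = diag(M) — unit-diagonal and positive-definite for any input.
* Posterior/prior scales: softplus plus a 10⁻⁶ floor.
* Positive-definiteness is always certified by Cholesky; 10⁻⁶ is the
  jitter/eigenvalue floor throughout.

### PCA-incorporated variant

Full-rank PCA (orthonormal W, rows = eigenvectors of the concatenated
data covariance) can be folded into the likelihood: the model evaluates
N(x̃_t | 0, W C_t Wᵀ) on projected data x̃ = Wx while the modes E_j, R_j
stay in the original channel space, so their interpretation survives the
rotation. Since |det W| = 1 the likelihood value is unchanged — a
property the test suite asserts.

### Dual estimation

Session-level modes come from freezing the group model's temporal side:
the amortised posterior supplies the session's mixing coefficients
(posterior means, for determinism), and only the observation parameters
are re-optimised on that session's likelihood. With J = 1 this reduces
to the sample standard deviation / correlation, which the tests verify.

## The simulator

Ground truth is generated from the hidden-Markov analogue of the model:
two Markov chains (uniform initial state, `stay_prob` on the transition
diagonal, remainder uniform) select the active power and FC mode with
hard one-hot mixing, and x_t is drawn from the implied Gaussian. A
`shared_dynamics` flag makes the two chains literally identical — the
control world where the model must *not* report distinct dynamics.
Defaults: 20 channels, 3 power + 3 FC states, stay probability 0.98
(mean lifetime 50 samples, i.e. 200 ms at 250 Hz), 4 sessions of 12,800
samples. Random modes: log-normal power diagonals and
correlation-normalised low-rank-factor FC matrices, with separation
scales (`mode_separation`, `fc_separation`) controlling how distinct the
modes are; the defaults give between-mode correlation-profile
similarity around 0.3 and mean absolute off-diagonals around 0.25,
which we consider representative of parcel-level envelope data. Task
variants force a designated chain into a designated state for a window
after each stimulus onset, independently per trial with a configurable
probability; the forcing stream is separate from the sampling stream so
a probability-0 task is bit-identical to rest.

What the simulator does *not* emulate: oscillatory (pre-envelope)
signals, spectral structure, measurement noise, inter-subject spatial
variability, or soft mode mixtures. A green recovery test therefore
establishes that the inference machinery identifies hard-switching
covariance dynamics at realistic SNR — not that it handles every
property of real recordings.

## Preprocessing

Fixed stage order (each stage optional, order immutable): 5th-order
Butterworth band-pass 1–45 Hz applied forward–backward (zero phase) →
Hilbert amplitude envelope → 25-sample moving average (trimmed, length
T − 24) → per-session z-transform → optional full-rank PCA fit on
session-concatenated data. PCA is a *group* projection (the generative
model is shared across sessions); eigenvector sign is fixed by making
each row's largest-magnitude entry positive.

## Baseline and statistics

* **Sliding window**: per-window channel standard deviations and
  upper-triangle correlations (window 500 samples, step 10), K-means on
  each feature set separately (k-means++, 10 restarts), giving separate
  power and FC state sequences. Features sit at window centres;
  Hungarian assignment on the confusion matrix handles label matching.
* **Renormalisation**: mixing weights are reweighted by each mode's
  overall magnitude — mean E_j diagonal for power, mean |off-diagonal|
  of R_j for FC — and re-normalised to the simplex, so a time course
  reads as contribution to total variance/correlation.
* **Mode matching**: mean-centred cosine similarity plus Hungarian
  assignment; significance from a max-statistic permutation test that
  permutes the spatial elements of each map in one set (preserves value
  distributions, breaks correspondence, controls FWER over all pairs).
* **Coupling**: per-session Pearson correlations between α and β time
  courses, Fisher-z transformed; group inference by random sign flips
  of session z-matrices with a max-|mean| statistic. Task-vs-rest
  coupling change uses the same engine on per-session z differences.
* **Evoked GLM**: two levels. First level per session — OLS of
  baseline-corrected (pre-stimulus mean subtracted per trial) epoched
  time courses on condition indicators, combined by contrast vectors.
  Second level — one-sample t across sessions per (time, mode) cell,
  max-|t| sign-flip null, FWER-corrected p-values; epochs span −0.5 s to
  +2 s around onsets. All permutation p-values use the add-one
  estimator; default 1,000 permutations.
* **Network recalculation**: given a fixed mixing m, per-mode
  covariances solve the elementwise least squares
  min Σ_t ‖x_t x_tᵀ − Σ_j m_jt C_j‖²_F, then are split into power
  (sqrt diagonal) and correlation parts.

## Numerical and design choices

* First-level GLM uses separate condition-indicator regressors with
  contrast vectors (the alternative, contrast coding, is equivalent for
  the tested contrasts).
* Group statistics treat sessions as exchangeable units.
* Degenerate inputs: constant channels are rejected by standardisation;
  near-constant data trigger a "degenerate fit" warning rather than a
  crash; non-PD covariances are reported with the offending time index.
* Training defaults: hidden width 64, learning rate 10⁻³, batch 32.
  The acceptance-scale experiments in the test suite use width 32 and
  learning rate 5·10⁻³, which converge in ~70 epochs on the reduced
  simulations; these are time-budget choices, not tuned thresholds.
* Divergence guard: a restart aborts if its epoch loss exceeds ten
  times the magnitude of the first epoch's loss.

## Known limitations

* Mean-field posteriors underestimate temporal posterior correlations;
  mixing time courses are point summaries (posterior-mean softmax).
* The likelihood primitive inverts every C_t on the backward pass;
  beyond ~100 channels a low-rank or time-batched scheme would be
  needed.
* Model selection over the numbers of modes is out of scope; the mode
  counts are configuration.
* The simulator's hard one-hot mixing makes recovery well-posed; soft
  ground-truth mixtures would weaken identifiability of individual
  modes.
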