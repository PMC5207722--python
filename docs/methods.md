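# Methods

## The model

`sigbnet` implements a mass-action ODE model of the σ^B general-stress
network of *Bacillus subtilis*: the partner-switching core (σ^B, the
anti-σ factor RsbW, the anti-anti-σ factor RsbV, and a lumped stress
phosphatase P), the autoregulated *sigB* operon, and two extensions
that add competition for core RNA polymerase.

Explicit species (all μM): free σ^B, RsbW monomer, RsbW₂ dimer, RsbV,
RsbV~P, the complexes RsbW₂·σ^B, RsbW₂·RsbV, RsbW₂·(RsbV)₂ and
RsbV~P·P.  Elementary reactions: RsbW dimerization; association /
dissociation of RsbW₂ with RsbV (two steps) and with σ^B; RsbV
phosphorylation inside the RsbW₂ complexes (rate k_k); partner
displacement (RsbV attacking RsbW₂·σ^B); phosphatase binding and
catalysis (k_p); uniform first-order degradation/dilution k_deg of
every species; and operon production of σ^B : RsbW : RsbV at
1 : λ_W : λ_V with firing rate

    v_B = v0 (1 + f σ/(K + σ)),    σ = free σ^B.

Free phosphatase is eliminated by the conservation [P] = P_T(t) −
[RsbV~P·P], with P_T(t) an external input; the subtraction is clamped
at zero (activations are possible only while P_T decreases faster than
the complex can dissolve; they are not observed under the inputs used
here).  The right-hand side is assembled term by term from the
reactions, with an explicit RsbW-monomer equation, so the total
concentrations obey d[B_T]/dt = v_B − k_deg[B_T] (and the λ-scaled
analogues) exactly; the unit tests verify this identity against an
independent integration of the closed-form total ODEs.

Default rate constants: diffusion-limited association 3600 μM⁻¹hr⁻¹
with 5 nM complex affinities (dissociation 18 hr⁻¹), displacement
rates 1800, k_k = 36 hr⁻¹, k_p = 180 hr⁻¹, k_deg = 0.7 hr⁻¹ (≈1 hr
doubling), v0 = 0.4 μM hr⁻¹, f = 30, K = 0.2 μM, λ_W = 4, λ_V = 4.5.
k_deg is an ordinary parameter; the ramp-encoding analysis uses 0.72
hr⁻¹ (and 0.36 / 1.44 hr⁻¹) with v0 rescaled proportionally so that
steady-state totals stay approximately fixed (dilution also enters the
post-translational balance, so the invariance is within ~10%, not
exact).

Integration uses LSODA with rtol 1e-8 / atol 1e-10 μM for
deterministic runs and rtol 1e-6 / atol 1e-9 for stochastic ensembles
(the input noise dominates the local truncation error at that
setting).  Steady states are found by integrating 200/k_deg hours from
an empty cell and refining with a Powell-hybrid root solve; the
convergence criterion is ‖rhs‖∞ < 1e-8 μM hr⁻¹.  The refined root is
discarded (the integrated endpoint kept) if it leaves the nonnegative
orthant, which happens only for pathological parameter sets.

## Decoupling analysis

The loop is cut into the post-translational response F_P (free σ^B vs
B_T at fixed P_T, computed by firing the operon at a constant rate v so
that B_T = v/k_deg and the W/V totals stay in the λ ratios) and the
transcriptional response F_T (closed form).  The curve is parameterized
by v, which is monotone in B_T, so folds in σ^B never fold the scan;
continuation software is unnecessary.  The closed-loop steady state is
recovered as a Brent root of v_B(F_P(v/k_deg)) − v on [v0, v0(1+f)] and
agrees with the full-model steady state to 1e-4 relative (tested).

The logarithmic gain LG_P = d log σ / d log B_T is a centered
difference with a 1% log-space step, computed either on a stored curve
(log–log interpolation; exact for power laws) or by two flanking
fixed-v steady-state solves where precision matters.

### Feedback regions

A (λ_W, λ_V) pair is classified at a reference phosphatase
P_T = 0.5 μM (the stressed-condition mean used throughout):

* **III (non-responsive)** if free σ^B never exceeds 15% of B_T
  anywhere along the post-translational curve — the strong-binding
  releasable fraction is ≈ (2 + λ_V − λ_W)/2, so this floor implements
  the analytic upper boundary λ_W = 2 + λ_V: the measured fraction
  drops from ≥0.22 at the line to ≤0.12 one λ_W-unit above it.  A
  |LG_P| ≤ 0.05 dead zone also maps to III.
* **I (positive feedback)** if LG_P > +0.05 at the closed-loop state.
* **II (negative feedback)** if LG_P < −0.05.

A pure LG_P-sign rule cannot place the II/III boundary: zero-order
titration keeps LG_P ≈ −2 one full unit above the strong-binding line,
where the network is already non-responsive in absolute terms
(excursions < 0.02 μM).

The companion dynamical call `is_pulsing` requires a step-response
excursion ≥ 0.03 μM (the geometric midpoint between the excursion
scales measured on the two sides of the region II/III transition,
0.047 vs 0.02 μM) that relaxes back by ≥ 15% of its height.  With
these definitions an 8×8 grid gives pulsing ⟺ region II exactly, and
both region boundaries lie within one grid cell of the analytic lines.

Adaptation is quantified as |σ_final − σ_initial| / pulse amplitude,
because pre-stress free σ^B is nearly zero (≈6 nM) and a ratio test on
it would be meaningless.  At the defaults the step response returns to
within 3% of baseline; the experimentally measured synthesis-ratio
pairs (λ_W = 2.9, λ_V = 1.7 and 2.4, 2.65) pulse but adapt imperfectly
(9.5% and 25%).

### Pulsing threshold

The pulsing threshold P_T* is the smallest step amplitude whose σ^B
excursion exceeds 1% of the pre-step B_T, found by bisection.  The
printed strong-binding approximation
v0·k_k(λ_W/2 − 1 − λ_W·k_deg/k_k)/(k_p/k_deg) is evaluated verbatim
and used only for trend directions (its printed form is dimensionally
ambiguous); the numeric threshold is checked to move in the same
direction under changes of v0, λ_W and k_p.

## Stochastic phosphatase input

Energy-stress phosphatase fluctuates as a gamma-distributed
Ornstein–Uhlenbeck shot-noise process: Poisson bursts (frequency a per
cell cycle), exponentially distributed burst sizes (mean b μM), and
exponential relaxation at rate γ between bursts.  The per-cell-cycle
convention is kept exact by setting γ = 1/cell_cycle (default 1 hr⁻¹,
matching the ≈1 hr doubling time): the stationary law is then
Gamma(shape = a, scale = b) with mean exactly a·b.  Tying γ to the
cell cycle rather than to k_deg keeps the mean law exact; the two
rates differ by 0.7 vs 1.0 hr⁻¹ and none of the encoding results
depend on the distinction.  Sampling is pathwise-exact on a uniform
grid (default dt = 0.005 hr): per step, Poisson-many bursts arrive at
uniform offsets and are decayed by the remaining fraction of the step;
the initial value is drawn from the stationary law.  Trajectories are
pre-computed and linearly interpolated inside the ODE solver.

`sweep_mean` produces burst-parameter families of prescribed
stationary means: size modulation scales b at fixed a; frequency
modulation scales a at fixed b.

## Pulse analysis

Pulses are local maxima (scipy `find_peaks`) with a minimum prominence
(default 5% of the signal range) and ≥ 0.5 hr separation; amplitude is
peak minus the preceding minimum.  The encoding sweeps detect and
measure pulses on the σ^B-dependent promoter-activity signal σ/(K+σ)
(operon affinity K = 0.2 μM) with a deterministic absolute prominence
— 5% of the reference step response's activity excursion (0.043) — so
that detection is identical across stress levels, modulation modes and
seeds; a data-dependent threshold (a fraction of the observed sweep
range) couples the statistics to the single largest excursion in the
ensemble and makes fitted exponents seed-fragile.  The saturating
occupancy transform is part of the design: it compresses the
large-excursion regime, which keeps frequency-modulated amplitudes
flat, while expanding the small-pulse regime, which preserves the
linear amplitude growth under size modulation.  Headline ensemble
statistics are stable to ±2× changes of both detection thresholds
(tested).

A caveat on the frequency-vs-mean-phosphatase Hill exponent: the
detection threshold trades off two encoding signatures.  A large
threshold (e.g. 0.25 μM on the free-σ^B channel) censors the
low-stress toe and steepens the frequency curve (fitted exponents
4–6), but it also removes the small pulses that carry the linear
amplitude growth; a small threshold preserves amplitudes but admits
small events that flatten the frequency curve (exponents ~2–3).  No
single threshold produces both a frequency exponent ≳5 and a ~5-fold
linear amplitude span in this generator; the default favors the
amplitude-encoding signatures, so the frequency exponent reported by
the acceptance pipeline is ~2–3 rather than ~5.6 while the
amplitude-side statistics match the published behavior.

Hill fits y = ymax·xⁿ/(Kⁿ+xⁿ) use multi-start least squares (log-space
starts over n ∈ [0.3, 10] and K across the data range); ties break to
the lowest n.  Noiseless recovery is exact to optimizer tolerance for
n ∈ [0.5, 8] (tested).

σ^B target promoter activity is the occupancy σ/(K_target+σ) of a
regulon promoter with K_target = 1 μM — weaker than the operon's
0.2 μM and inside the typical σ-promoter range — so that pulse peaks
(0.3–1.4 μM free σ^B) do not saturate the reporter; with the operon
affinity every expression dose–response flattens to an exponent near
one.  "Target expression" is this activity low-pass filtered at k_deg
(a stable reporter protein diluted by growth), time-averaged after a
2 hr burn-in, and reported as induction above the unstressed baseline
(0.006) so the dose–response starts at zero.  Burst-encoding
conditions: size modulation holds the burst frequency at 4 per cell
cycle and scales b; frequency modulation holds b = 0.25 μM and scales
a; eight mean-phosphatase levels from 0.1 to 0.8 μM.

## Ramp-rate encoding

For a linear-ramp input rising to 0.5 μM over duration T_ramp, the
pulse amplitude decreases monotonically with T_ramp; the half-maximal
duration K_ramp is extracted per k_deg by fitting the amplitude drop
(A(0) − A(T)) with a rising Hill form.  K_ramp is strictly monotone
across k_deg ∈ {0.36, 0.72, 1.44} hr⁻¹ (tested), reflecting the
separation between the input-limited post-translational rise and the
k_deg-limited transcriptional shutoff.

## RNA-polymerase competition

The mechanistic σ^A/σ^B model adds reversible holoenzyme formation
(σ^B and σ^A with core polymerase; affinities 1.2 and 0.02 μM),
holoenzyme–promoter binding (0.1 μM, 0.05 μM of σ^B promoter sites),
and production fired from the promoter-bound holoenzyme at
v0·f/p_B_tot per μM of complex plus the unconditioned basal flux v0.
Only free σ^B partner-switches (holoenzyme and anti-σ binding use
overlapping interfaces).  σ^B-containing holoenzyme species degrade at
k_deg, destroying the σ^B moiety and returning polymerase (and
promoter) to their free pools, so A_T and RNApol_tot remain the fixed
constants the analysis varies.  Total-σ^B bookkeeping
(d[B_T]/dt = v_B − k_deg[B_T] with holoenzyme forms included) is exact
and tested.

K_sigB — the free σ^B needed for half-maximal target expression — is
computed on a clamped-σ equilibrium partition of polymerase and rises
steeply with A_T (0.012 μM without competitor, 0.11 at A_T = 9, 1.2 at
A_T = 12 μM as A_T crosses RNApol_tot = 10 μM) and with a second
stress σ.

## Three-σ phenomenological model

Post-translational release of each stress σ is collapsed into the
printed form σ_free = S_T/(1 + (S_T/K)^nb / P^mb) (K = 5 μM; negative
feedback nb = 7, mb = 5; positive variant nb = 0, mb = 3).  Only the
two totals B_T, W_T evolve (production − dilution, exactly as the
mechanistic totals do); the titration and the RNApol/promoter binding
partition are quasi-static and solved by nested scalar root finding at
each evaluation.  An explicit-binding formulation was rejected because
polymerase surrendered by a collapsing σ^W module flows back into free
σ^W and buffers away the competition effects the model exists to
expose.

Two constants are rescaled to this model's concentration regime (σ
totals of order 10 μM rather than 1 μM): the σ^A–RNApol affinity is
0.8 μM (still stronger than the stress σ's 1.2 μM) and the
holoenzyme–promoter affinity 3 μM.  With the full model's nM-scale
values, σ^A would act as an effectively perfect polymerase buffer
(compliance ∝ A_T·K_A/(K_A+R)² ≈ 30× the stress-σ pools') and every
promoter would saturate, extinguishing the transcriptional feedback;
no qualitative conclusion of the reduced model survives that regime.
Neighboring constants (±50%) give the same qualitative behavior.
Partition deltas (ΔRpol-σ^A, ΔRpol-σ^W) are referenced to the
smallest P_B on the scanned grid.

## Synthetic-data conditions and what they do not emulate

The generator reproduces the study conditions: step and ramp inputs,
and gamma-OU burst ensembles.  It does not emulate extrinsic noise in
the σ^B operon itself, cell-to-cell parameter variability, cell
division, or upstream stressosome dynamics (RsbX is excluded); pulse
statistics here characterize the network's response to phosphatase
noise only, and passing tests say nothing about those other noise
sources in real cells.

Ensemble sizes: encoding sweeps use 20 traces × 10 h (2 h burn-in) per
mean-phosphatase level with eight levels; the amplitude-CDF
comparisons pool 50 traces at the two compared levels.  These sizes
put Monte-Carlo error comfortably inside the tolerances asserted in
the acceptance suite.

## Known limitations

* The clamp [P] = max(P_T − [VPP], 0) momentarily violates mass
  balance if P_T drops faster than the complex can dissociate; inputs
  here never do.
* Hill exponents fitted to dose–response windows are effective,
  window-dependent quantities; they are meaningful only together with
  the stated sweep range.
* The three-σ model's binding constants are regime-rescaled (above);
  its outputs are qualitative orderings, not quantitative μM
  predictions.
* `half_max_K_sigB` uses the equilibrium partition, not the dynamic
  model; during fast pulses the instantaneous K_sigB can differ.
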