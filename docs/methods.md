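# Methods

This note documents the models implemented in `biofilm_electro`, the
choices made where the underlying biology left the design open, and what
the synthetic data do and do not establish.

## Scientific setting

Under blue-light stress, *E. coli* cells and biofilms show two successive
membrane hyperpolarization events, reported by the Nernstian voltage dye
Thioflavin T (ThT): a fast first spike that registers the stressor
(requiring the mechanosensitive channels MscK, MscL, MscS), and — after a
quiescent gap — a sustained second rise to a plateau (requiring the
voltage-gated potassium channel Kch), interpreted as habituation to the
persisting stimulus. In three-dimensional biofilms the first event is a
potassium wavefront that travels from the core to the periphery
(centrifugal), collapses back from the edges to the center (centripetal),
and re-emerges as the habituated plateau. The package implements (i) a
two-channel Hodgkin–Huxley model of the globally averaged membrane
potential, (ii) a 3D agent-based fire-diffuse-fire (FDF) simulator of the
wavefronts, and (iii) the anomalous-transport analysis that fits
R(t)² = Rc² + b·t^γ to the wavefront radius and classifies the transport.

## Two-channel membrane model (`hh_membrane`)

State variables: membrane potential V (mV), gates m_Q, h_Q (activation and
inactivation of the unidentified fast channel Q, minimally the product
MscK × MscL × MscS), n_K (Kch activation), and the reactive-oxygen-species
(ROS) stress S:

    C_m dV/dt = −[g_Q·m_Q·h_Q·(V−E_Q) + g_K·n_K^p·(V−E_K) + g_L·(V−E_L)]
    dx/dt     = (x_∞ − x)/τ_x               for x ∈ {m_Q, h_Q, n_K}
    dS/dt     = α_ROS·I(t) − δ_ROS·S

Units: minutes, mV, µW/mm² for irradiance I; conductances in consistent
membrane units. Defaults: g_Q = 1.0, g_K = 1.6, g_L = 0.3, E_Q = −150,
E_K = −85, E_L = −60 (rest), C_m = 1.

No gating equations or parameter values are published for this system, so
the couplings are the package's own minimal mechanism, chosen to reproduce
every observed phenotype simultaneously:

* **Q activation is light-gated**: m_∞ = I/(I + I_half), τ = 0.3 min. The
  first spike cannot be ROS-driven, because scavenging ROS (catalase)
  leaves it intact; light must act on Q directly.
* **Q inactivation is voltage-windowed**: h_∞ is low only in the
  intermediate band (−100 … −75 mV, logistic edges of slope 3 mV). The
  Kch-mediated partial repolarization pulls V from the deep Q plateau into
  this band, where Q inactivates (τ = 2 min) and the leak completes
  repolarization. Without Kch the cell never enters the window — which is
  exactly why the Δkch mutant shows one peak followed by a plateau with no
  repolarization. Recovery from inactivation is frozen (τ = 500 min) until
  the ROS latch engages.
* **Kch activation is hyperpolarization-gated** (V½ = −95 mV, slope
  7 mV, τ rise 1.5 / fall 0.4 min) and is suppressed once the ROS latch is
  crossed, so the habituated plateau is Q-dominated and as deep as the
  first event.
* **The ROS latch** drives habituation: when S crosses a fixed level,
  h_Q recovery becomes fast (τ = 3 min) and Q re-opens under the sustained
  light, producing the persistent second hyperpolarization. The latch
  level is tied to the working irradiance threshold: at the default
  production/clearance rates (α = 0.1, δ = 0.05/min) a constant exposure
  at 15.99 µW/mm² crosses it 35 min in, so the second peak occurs within a
  60-min protocol exactly for irradiances at or above threshold. The
  threshold is soft on its lower side (the crossing time diverges as I
  falls toward ≈0.83·I_threshold); sub-threshold behavior is therefore
  guaranteed for I ≲ 13 µW/mm².

Consequences (the testable contract): wildtype shows exactly two
hyperpolarization events; g_K = 0 one peak plus plateau; α_ROS = 0 one
transient peak; g_Q = 0 no events; the first-peak latency is
non-increasing in irradiance; more ROS production shortens the quiescence
and raises the plateau. The published qualitative claim that *reduced* ROS
also sharpens the first spike is not reproduced: in this minimal coupling
the first event is deliberately ROS-independent.

The robustness band: the phenotype counts hold across a ±20% perturbation
of conductances, time constants and α_ROS at I = 20 µW/mm². At the working
irradiance itself the system sits exactly at threshold, so a −20% change
in α_ROS is definitionally sub-threshold there — robustness is a
supra-threshold statement.

Numerics: fixed-step RK4 (default dt = 0.005 min, bit-reproducible; gates
clamped to [0,1] per step; dt validated against the fastest time constant;
halving dt changes the trace by ≪0.1%) or adaptive RK45 at rtol 1e-6 as a
cross-check. The ThT readout is Nernstian, F ∝ exp(−(V−V_ref)/26 mV), and
is returned unnormalized so that downstream analysis can distinguish a
flat (non-responding) trace from a responding one before min-max scaling.

## Fire-diffuse-fire biofilm model (`fdf_biofilm`)

Cells sit on a jittered cubic lattice (spacing 1.5 µm, jitter 0.15)
clipped to a sphere. The extracellular K⁺ field obeys
∂c/∂t = D∇²c − k(x)·c on a cubic grid (explicit 7-point stencil, CFL
D·dt/dx² ≤ 1/6 enforced), with an absorbing boundary at three biofilm
radii. Two spatial features matter:

* **Clearance acts only in the fluid**: k(x) = k_decay outside the biofilm
  and `interior_decay_fraction`·k_decay (default 0) inside. The crowded
  interior is shielded from the flow, so released K⁺ pools inside the
  biofilm and drains through the surface. This retention produces the
  uniformly bright biofilm after the wave, the edge-first collapse, and
  the size dependence of propagation: a small biofilm's pool drains before
  the wave completes.
* **Recovering cells pump K⁺ back in**: refractory and habituated cells
  are sinks of strength k_uptake·c (µm³/min). The trailing sink grows with
  the fired volume, so the front decelerates as it spreads — the slow
  decrease of front velocity with radius seen in the velocity–curvature
  analysis.

A quiescent cell fires when its locally interpolated concentration reaches
c_thresh (inclusive); it releases σ_release (trigger cells
trigger_boost× that) uniformly over t_fire, then is refractory for
t_refract, after which it habituates (if the run has passed
habituation_delay) and relaxes to the persistent tht plateau. The per-cell
fluorescence proxy integrates the local concentration after firing,
d(tht)/dt = tht_gain·c − tht_decay·tht, so brightness reflects both when a
cell fired and how much K⁺ it has been bathed in — core cells, bathed in
the retained pool, stay brightest, which is what makes the collapse sweep
from the periphery inward.

Canonical defaults (pinned once with `scripts/tune_fdf.py`, since the
original parameter values are unpublished): D = 2 µm²/min, k_decay =
1.2/min, c_thresh = 1 (defines the concentration unit), σ_release = 35,
t_fire = 2 min, t_refract = 18 min, k_uptake = 2.6 µm³/min, tht_gain = 1,
tht_decay = 0.3/min, habituation_delay = 20 min, trigger_boost = 1,
dt = 0.05 min. The trigger region is the seven lattice sites within one
spacing of the origin, selected on the unjittered lattice so the ignition
energy is seed-independent. With these defaults a radius-15 µm biofilm
(≈4200 cells) produces the full phenomenology in a 40-min run: centrifugal
wave over ~4–6 min, edge-to-core collapse, quiescence, habituated plateau.

The deliverable quantities at these defaults (10-run ensembles): mean
centrifugal exponent γ ≈ 1.2, mean centripetal exponent γ ≈ 2.0–2.1, and a
bisected critical radius of ≈ 5 ± 1.7 µm — each within the published
uncertainty of the corresponding agent-based result (1.21 ± 0.12,
2.26 ± 0.31, 6.17 ± 1.84 µm). Near the critical radius, propagation is
genuinely stochastic: occasional seeds fail even at large radii and cannot
be bracketed; the bisection skips such seeds and reports how many were
used.

## Wavefront analysis (`wavefront_analysis`)

Per frame, cell tht values (or image voxels) are averaged in concentric
shells; the front radius is the outermost shell whose mean reaches
`threshold` (default 0.5) times the **movie maximum** of the shell
profile, with sub-bin linear interpolation of the crossing. The movie-max
reference is deliberate: a per-frame maximum is invariant under uniform
decay, so a collapsing dome would be undetectable by construction; the
movie maximum corresponds to an absolute half-max in image intensity
(`max_mode="frame"` is available for comparison). Analysis is restricted
to the first-peak event — frames after the quiescent trough of the mean
intensity belong to the habituated re-brightening.

The track splits at the global maximum of R(t). The centrifugal phase runs
from first detection to that maximum. The centripetal phase keeps the
absolute front radius with its time origin at collapse onset, defined as
the first frame the front has receded one shell width (recession below the
spatial resolution is not measurable motion, mirroring the exclusion of
radii below one grid spacing at the other end). Fitting uses nonlinear
least squares on R² with an analytic Jacobian, multi-started over γ ∈
{0.5, 1, 1.5, 2, 2.5}; Rc² is constrained non-negative, and a decreasing
track is fitted with a negative prefactor. The centripetal fit is on the
absolute (decreasing) radius rather than on inward distance travelled: a
distance-travelled track necessarily starts at zero speed at the smooth
turning point of R(t), which forces d ∝ t² at onset and inflates the
fitted exponent for any collapse, regardless of its physics.

Transport classes partition γ exactly: subdiffusive (γ<1), diffusive
(γ=1), superdiffusive subballistic (1<γ<2), ballistic (γ=2),
super-ballistic (γ>2). Velocity profiles use a moving-average smoothed
R(t), central differences, and spherical mean curvature κ = 2/R by default
(1/R available for comparison with the 2D literature).

## Synthetic data (`synthetic_data`)

First-peak latencies are lognormal, moment-matched to the reported
mean/SD; for sparse cells (7.34 ± 10.89 min) the SD exceeds the mean,
which rules out a Gaussian. Because ~1% of that heavy tail lies beyond an
hour, the sparse template's observation window is 240 min — otherwise
censoring would bias the recovered mean low. Trace shapes are a
lognormal-in-time first pulse plus a logistic second rise (wildtype), a
single saturating rise (Δkch), the pulse alone (catalase), or baseline
noise (MS knockout), with multiplicative and additive Gaussian noise
(2% each by default). Image stacks deposit per-cell tht into voxels,
convolve with a Gaussian PSF, and add Poisson shot noise over a constant
background.

What passing the synthetic round trips shows: the analysis pipeline
(normalization → peak calling → latency statistics; tracking → power-law
fitting → classification) is calibrated and unbiased at the stated noise
levels. What it does not show: robustness to the untested structure of
real recordings — bleaching, drift, segmentation errors, non-Gaussian
noise — which are all out of scope here.

## Numerical and procedural details

* Peak calling: prominence ≥ 0.15 of the normalized range, separation ≥
  5 min; a terminal plateau (≥0.8 for the final ≥10 min) counts as the
  final peak, because the habituated second event is a plateau, not a
  transient. Traces whose raw dynamic range is below 0.2 intensity units
  are classed as non-responding before normalization (min-max scaling
  would otherwise amplify noise into spurious events).
* Sample SD uses the n−1 denominator; SE = SD/√n; n = 1 reports SD 0 with
  a warning.
* Firing threshold comparison is inclusive (≥). Seeds propagate from a
  single root through `numpy.random.SeedSequence(root, spawn_key=...)`
  with a fixed per-module index table, so adding a pipeline stage never
  perturbs another stage's stream.
* Problem sizes used by the shipped analyses: radius-15 µm biofilms
  (~4200 agents, 61³ field voxels, 800 steps of 0.05 min) for exponent
  ensembles; radii 2.5–15 µm in the critical-radius bisection; 500-trace
  ensembles for latency statistics.

## Known limitations

* The membrane model is a phenomenological minimal mechanism; the voltage
  window on Q inactivation and the ROS latch are one admissible coupling,
  not an inference from data.
* The FDF defaults are a calibrated set, not measured constants; other
  parameter sets may reproduce the same three outputs.
* The centripetal exponent depends on the documented collapse-onset and
  absolute-radius conventions; with a distance-travelled convention the
  same simulations yield systematically larger exponents.
* No cell growth, fluid flow, advection, non-spherical geometries, or
  calcium dynamics.
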