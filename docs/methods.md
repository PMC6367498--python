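# Methods

This note documents the model behind `crtsim`: its equations,
assumptions, default parameters, numerical choices, and what the
synthetic data generator does and does not emulate.

## Synthetic activation maps

The study the package reproduces used contact electrograms from 112
sites (52 LV free wall, 50 RV free wall, 7 RV-septal, 3 LV-septal) in
dogs with AV block paced from the RV apex and the LV basal
posterolateral epicardium. Those recordings are not available, so the
`activation` module generates surrogate maps with the same structure.

Segments are nodes of abstract 2-D lattices (one per wall) joined at the
septal insertions; the only quantity kept per segment is its geodesic
path length to each pacing site. Activation under a delay pair is the
earliest arrival over the captured sources at conduction velocity
`v_cond` (0.8 mm/ms); a site loses capture when the contralateral
wavefront arrives before its own stimulus (strict `<`; an exact tie — a
measure-zero case — counts as capture for both).

Two asymmetries reproduce the experiment's left/right differences:

* the LV free-wall lattice is larger and slower (`wall_scale` 1.5), so
  RV-only pacing leaves the LVFW late on average (VEU ≈ +38 ms) while
  LV-only pacing leaves the RVFW late by more (VEU ≈ −47 ms);
* a wavefront that has crossed into the *contralateral* free wall
  propagates slowed by `cross_slow` (1.3): without Purkinje
  pre-excitation, spread there is predominantly transmural
  cell-to-cell. Each pacing site therefore has its own distance field
  (the contralateral wall's internal edges scaled); this is what makes
  RV free-wall activation *more* dispersed under LV pacing, as mapped
  experimentally, instead of being compacted by fusion.

The septal RV side attaches apically to the RV free wall (the RV apex
pacing site sits at that corner), while the LV side of the septum is
reachable over its whole height. Consequences, all deliberate: the
septum is activated early whenever the RV is paced; the LV site, far
from the insertions, reaches the septum and RV late; and the LVFW's
mean self-activation (≈ +35 ms after its stimulus) lags the septum's
(≈ +17 ms), which is what places the LV contractility optimum at a
*slight* LV pre-excitation rather than exactly simultaneous pacing.

With these constraints satisfied the single-site total activation times
end up at ≈ 110 ms (RV-only) and ≈ 125 ms (LV-only) — somewhat longer
than the ~80–100 ms originally aimed for. Shorter lattices could not
simultaneously hold the VEU calibration targets and the optimum
location; the longer times were accepted as the price of the
centroid-lag mechanism.

Measurement noise is emulated by per-segment Gaussian jitter (SD 3 ms,
clipped at ±3 SD, floored so no segment precedes the earliest captured
stimulus), and a cohort of six virtual dogs perturbs the per-wall scales
(SD 5%). RNG substreams are spawned from one root seed with numpy's
`SeedSequence` in fixed dog-major order, so any subset of settings is
reproducible. The *generic* pattern per setting sorts each dog's times
within each mechanical wall and takes the elementwise median — valid
because patches within a wall are mechanically interchangeable.

What the generator does **not** emulate: electrogram morphology and
deflection detection, true 3-D geometry, His–Purkinje physiology,
breathing-related variability, per-dog electrode placement error beyond
a global wall scale. Tests passing on these maps show the *pipeline*
behaves as in the study; they cannot validate conduction physics.

## Myofiber stress

Natural fiber strain ε relates to patch midwall area by
`ε = ½ ln(A_m/A_ref)`; sarcomere length is `l_s = l_ref e^ε`. Total
fiber stress is active + passive:

* passive: `σ_p = k_pas (exp(c_pas (l_s/l_pas0 − 1)) − 1)` above the
  slack length `l_pas0`, continued linearly (slope-matched) below it;
* active: `σ_a = σ_act · f_L(l_s) · g(τ)` with
  `f_L = max(0, (l_s − l_act0)/(l_ref − l_act0))`, a sin² twitch
  `g = sin²(π τ/t_w)` for `0 ≤ τ ≤ t_w`, and a length-dependent
  duration `t_w = t_w,ref + k_tw (l_s − l_ref)`.

The forms are phenomenological and smooth (`g(0) = g(t_w) = 0`), chosen
by this package; the calibration procedure fixes the scale factors.
Defaults (ventricles): σ_act 60 kPa, l_ref 2.0 µm, l_act0 1.58 µm,
l_pas0 1.8 µm, k_pas 1.5 kPa, c_pas 12, t_w,ref 180 ms, k_tw
120 ms/µm. Atria: σ_act 30 kPa, t_w,ref 120 ms, l_act0 1.51 µm.

Why these values: with the reference areas below, the tuned canine
baseline then operates at EDV ≈ 100 mL and ESV ≈ 35 mL per ventricle
with arterial pressure ≈ 73/49 mmHg (the measured baseline was 70/45);
the steep `f_L` (l_act0 1.58) gives the length-dependent activation that
makes stroke volume preload-sensitive while `k_tw` keeps dP/dt_max
comparatively preload-*insensitive* — the discrepancy between the two
indices is a central observation of the study. The passive stiffness
damps the systolic pre-stretch of late-activated patches; much softer
values roughly double the dyssynchrony sensitivity of LV dP/dt_max.

## Walls, TriSeg and chambers

Each wall is a thick spherical shell treated with the thin-shell
tension–stress relation `T_m = σ_f (V_w/A_m)` and Laplace's law
`Δp = 2 T_m c_m`. A wall's patches share one tension: given the wall's
total midwall area, the solver iterates a linearisation of each patch's
tension–area relation (with adaptive under-relaxation) until the patch
tensions agree to 1e-8 relative and areas sum exactly to the target.

The three ventricular walls are spherical caps spanning a common
junction ring (radius `y_m`); the septal cap volume `V_m,S` and `y_m`
are solved by a 2-D Newton iteration that balances the tension
components at the ring. Cavity pressures follow from the free walls'
tensions and curvatures. The thin-shell choice preserves the causal
chain stress → tension → pressure with closed-form geometry; its cost is
quantified by the septal-consistency diagnostic
`|(p_LV − p_RV) − Δp_SEPT| / max(|p|)` ≤ 5 %, asserted in the tests.

The septum is one mechanical wall of 10 patches (7 + 3 from the two
septal electrode groups) owned by neither free wall. Atria are
single-patch spheres (no atrial mapping data exists to subdivide them),
activated at t = 0 of every cycle. The pericardium adds
`p_peri = p0 exp((V_heart − V_ref)/(s V_ref))` (defaults 0.4 mmHg,
650 mL, s = 0.12; a weak constraint, enabled by default and exposed as a
flag — whether the original simulations used one is not stated).

Wall geometry defaults (tissue volume / reference midwall area): LVFW
87 mL / 95 cm², septum 38 mL / 48 cm², RVFW 30 mL / 110 cm², LA
8 mL / 70 cm², RA 6 mL / 70 cm² — a human-sized reference heart, which
the study itself used with canine activation and canine hemodynamic
targets.

## Circulation and integration

Eight volume states (four chambers, systemic/pulmonary arteries and
veins) close the loop; compartment pressures are `(V − V_0)/C`, flows
`Δp/R`, and the four valves are quasi-static one-way resistors — no
inertance and no regurgitation, because the acceptance surface is
dP/dt_max and stroke volume, not flow waveforms. The valve opening is
regularised with a C¹ quadratic knee over the first ~0.5 mmHg of
forward gradient so beat metrics converge cleanly when the step is
refined. Vascular defaults: r_sys 1.1 (tuned), r_pulm 0.09, venous
return resistances 0.06 mmHg·s/mL, compliances 2.4 / 25 / 6 / 5
mL/mmHg (systemic art/ven, pulmonary art/ven); the fairly stiff venous
pools speed the beat-to-beat preload redistribution that follows a
pacing switch.

Integration: fixed-step RK4, dt = 1 ms, no adaptive stepping
(bit-reproducibility over speed); the TriSeg and wall solves are
warm-started across stages and steps. Blood volume is conserved to
round-off (< 1e-9 mL/beat) because the flow bookkeeping is exactly
antisymmetric. Activation-map switches take effect at beat boundaries;
twitch tails that cross the cycle boundary wrap modulo the cycle.
dP/dt_max is the maximum centred difference of the pressure trace over a
fixed ±3 ms window (mirroring the finite bandwidth of catheter dP/dt),
with the discrete peak refined by a parabolic vertex; halving dt moves
the key beat metrics by < 0.5 %.

Failure handling: negative volumes and non-finite states abort with the
offending compartment named; a TriSeg divergence triggers one dt/2
retry of the beat. The TriSeg Newton uses finite-difference Jacobians
with relative steps of 1e-4 (well above the inner solves' 1e-8 noise
floor), a best-candidate backtracking line search, step limiting, and up
to three starts (warm, symmetric, symmetric with cold patch areas).

## Protocol

`tune_vasculature` alternates a venous-pressure-aware multiplicative
update of r_sys against MAP with a secant update of blood volume against
CO (volume steps clamped to ±250 mL — larger instantaneous withdrawals
can transiently deflate the heart into a fully slack state where the
septal equilibrium is ill-conditioned). `calibrate_contractility`
scales LV-side (LVFW + septum) and RV-side peak active stress toward the
measured baseline dP/dt_max medians, re-tuning after each change.

The sweep runs each of the 100 settings independently from the same
converged baseline with resistance and blood volume frozen; "beat 1" is
the first complete cycle using the new map. Relative changes are
`100 (x − x_base)/x_base` against the baseline steady state. For
settings that pace both ventricles the "AV delay" is defined as the
delay of the first-paced ventricle, `min(A-LV, A-RV)`; VV delay is
`A-RV − A-LV` (positive = LV pre-excitation). The VEU sign convention
is `mean LVFW − mean RVFW` activation time, positive when the LV free
wall is late.

Problem sizes: the full sweep is ~700 simulated beats (100 settings × ≤
10 beats to steady state at 0.1 % stroke-volume tolerance), a few
minutes on one CPU with the compiled kernels; tuning plus calibration is
~300 beats more.

## Known limitations

* **Cardiac output's AV-delay sensitivity is understated.** With purely
  one-way valves, a mistimed atrial kick cannot leak back through the
  mitral valve (diastolic regurgitation), which is the dominant
  long-AV-delay penalty in vivo. The model still shows the correct
  ordering along the AV axis (CO largest at first-paced delays of
  50–70 ms, monotonically falling toward 230 ms, peak ≈ +5 % against
  the reported "up to 9 %"), but across the whole grid the VV-driven CO
  variation is of comparable size, so CO is not unambiguously more
  AV- than VV-sensitive here. The corresponding acceptance test is left
  failing rather than weakened.
* Relative dP/dt_max responses are larger than measured (LV optimum
  ≈ +57 % vs ≈ +25 %): the synthetic baseline is electrically somewhat
  more handicapped than the median dog, and the multipatch model has no
  passive scar/heterogeneity to blunt resynchronization. Directions,
  optima locations and orderings — the quantities the study rests on —
  are reproduced.
* No autonomic regulation (deliberately, as in the study), no
  respiratory variation, no blood inertia, no long-term remodeling.
* The septum's transmural activation delay is a single lattice edge;
  intramural electrophysiology is out of scope.
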