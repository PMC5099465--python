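# Methods

## The model in one paragraph

A schematic patch of peripheral retina is modelled as four arteriole/venule
(A/V) sectors side by side: vertical boundary vessels alternating arteriole
— venule every 300 µm, joined at the top by a peripheral shunt vessel, with
ten horizontal capillary rungs per sector. The tissue between vessels is a
5 µm lattice of Mueller cells and other retinal cells. Steady network blood
flow, a steady oxygen tension field and a steady VEGF field are computed for
the current occlusion state; once per model week every open capillary draws
a Bernoulli occlusion trial whose probability increases with local VEGF and
decreases with its blood speed. Occlusions are irreversible and each
committed batch triggers a re-equilibration. Laser burns convert viable
cells into non-consuming, non-synthesising tissue clamped to a
choroid-coupled oxygen tension — standing oxygen sources that locally lift
the inter-vessel oxygen trough above the hypoxia threshold and thereby
silence the VEGF feedback.

## Geometry

| parameter | default | note |
|---|---|---|
| A/V centreline distance | 300 µm | band length default equals it |
| sector length | 770 µm | calibrated so the N = 4 band pattern burns 0.26 of the two treated sectors (120 000 / 462 000 µm²); a multiple of the lattice spacing |
| sectors | 4, middle two treated | outer sectors provide boundary realism |
| capillary rungs | 10 per sector (77 µm pitch) | keeps every interstitial cell within ~40 µm of a capillary, so the intact network is fully normoxic |
| lattice spacing | 5 µm | every sweep burn dimension (multiples of 20 µm) rasterises exactly; 20 µm minimum burn = 4 sites |
| vessel diameters | arteriole 20, venule 25, shunt 18, capillary 10 µm | |
| cell sizes | Mueller 24 µm, other 21 µm (nominal) | deterministic interleaved block tiling snapped to the lattice |
| capillary tortuosity | 3 | hydraulic length = 3 × straight length; see below |

Real peripheral retinal capillaries meander; modelling them as straight
rungs with their geometric length would understate their hydraulic
resistance. The tortuosity factor raises capillary resistance (viscosity
stays a constant 2 mPa·s; no Fåhræus–Lindqvist correction), which pushes
flow onto the shunt pathway and yields the observed velocity ordering —
every arteriole, venule and shunt segment faster than every capillary.

## Hemodynamics

Poiseuille conductance G = πd⁴/(128 µL_hydraulic), Kirchhoff solve with
Dirichlet pressures at arteriole inlets (40 mmHg) and venule outlets
(20 mmHg). Occluded segments are removed from the conductance matrix;
components disconnected from all boundary nodes get zero flow. The sparse
solve agrees with a dense reference solve to 1e-10 relative and conserves
mass to 1e-9 relative.

## Oxygen

Intravascular: blood enters arteriole inlets at 50 mmHg and relaxes toward
the perivascular tissue mean with decay exponent w·πd·L/Q per segment
(w = 64 µm/s of wall area — wall flux scales with perimeter). Segments are
processed in descending node-pressure order, which is a topological order of
steady flow, so the march is direct. Perimeter scaling matters for the
venous trend: after a sector infarcts, the venule outlet pO₂ falls (the
remaining venous blood equilibrates toward the colder perivascular tissue),
rather than rising with the shunt-dominated flow.

Tissue: D∇²P − M(x,P) = 0 with D = 1500 µm²/s and zeroth-order consumption
M = 31 mmHg/s on viable cells, ramped linearly to zero below 2 mmHg (keeps
the discrete operator an M-matrix; the converged field is non-negative and
bounded by the largest source). Vessel sites of flowing segments are
Dirichlet-clamped to the local intravascular tension; burned sites to the
choroid-coupled tension `choroid_po2 = 50` mmHg. Zero-flux outer boundary. The coupled vessel-march/tissue fixed point iterates to a maximum
site change below 1e-6 mmHg; the sparse LU is refactorised only when the
Dirichlet or cutoff pattern changes, so one equilibration costs one
factorisation plus cheap triangular solves.

Calibration targets (all enforced by tests):

* intact network: zero hypoxic sites; mid-sector trough 16.1 mmHg, between
  the hypoxia threshold (15 mmHg, a named config knob) and 1.2 × threshold
  ("only slightly above threshold") — this is what makes any capillary loss
  immediately hypoxia-generating;
* a single mid-sector occlusion produces a non-empty hypoxic patch
  (~0.035 of the treated region);
* adding any burn raises the tension pointwise everywhere.

## VEGF

Screened diffusion D_V∇²V − kV + σ = 0 with D_V = 100 µm²/s, k = 0.05 s⁻¹
(screening length ≈ 45 µm). Synthesis: basal 1 on normoxic Mueller sites
(the permissively elevated diabetic baseline), 45 on hypoxic Mueller sites;
binary gating at the hypoxia threshold (a graded ramp was considered and
left out — the threshold picture is what the landscape argument uses).
An extra first-order sink (0.6 s⁻¹) on large-vessel wall sites represents
the denser endothelial mass of arteriole/venule/shunt walls; it attenuates
VEGF crossing a boundary-vessel column (the barrier that confines ischemia
to one sector) without damping the rung-to-rung relay inside a sector.
Fields are reported normalised to the basal steady level σ_basal/k; only
this ratio enters the occlusion probability. The matrix is constant for a
given geometry, so its factorisation is computed once per process.

## Occlusion probability

p = p_max · Vⁿ/(Vⁿ + V₅₀ⁿ) · exp(−v/v_s) per week, with p_max = 1.0,
V₅₀ = 2.2 (basal-normalised), n = 8, v_s = 4000 µm/s. Large vessels are
excluded from the sweep by default (their velocities alone put them below
1e-4 per week). The constants were calibrated jointly so that

* the intact network produces no spontaneous occlusion over 3 model years
  (basal V ≈ 0.5 ⇒ p ≈ 1e-6/week per capillary);
* a seeded occlusion relays to adjacent rungs (77 µm away) at p ≈ 0.1–0.3
  per week, filling the sector in well under 144 weeks in most replicates;
* the plume cannot recruit capillaries across an oxygenated band or across
  an arteriole/venule.

## Burns

Dots sit one lattice site off the vessel walls, count fixed by the density
label (3N dots, area-matched to N bands at the reference 100 µm edge),
evenly spaced per column with equal end margins — so the realised inter-dot
gap is (770 − nS)/(n + 1): 117.5, 132.5, 147.5, 162.5, 177.5 µm for
S = 100…20 at N = 4. Bands span the A/V distance (or are centred mid-sector
when shortened) and are evenly spaced along the sector. Rasterisation
rounds each rectangle edge to the nearest lattice line (the per-axis
overlap-majority rule with deterministic tie-breaks), so realised areas are
close to, but not exactly, the requested ones — edge cells live or die by
majority overlap. The PRP comparator is arithmetic: 0.28 of the retina
burned plus untreated-style progression on the remaining 0.72.

## What the experiments show

Under the defaults, the emergent protection radius of a burn is ~55 µm and
of a vessel wall ~25–30 µm. That geometry reproduces the pattern-efficacy
picture: N = 4 bands and dots (0.26 burn fraction) hold ischemia at the
seed-patch level; N = 2 is partial; thinning bands to 20 µm or shortening
them to 50 µm leaves the median ischemia "more or less unchanged" while
cutting burned area by 80 %, making the shortened centred band the best
total (burn + ischemia ≈ 0.12 vs 0.49 for the PRP estimate); and the
dot-size sweep crosses its efficacy transition between S = 80 (gap
132.5 µm, holds) and S = 60 (gap 147.5 µm, escapes) — the critical gap of
~140 µm. S = 60 outcomes are genuinely bimodal (a transition point): whether
a replicate escapes depends on where the seed lands relative to the dot
rows. For that reason "holding" is classified on both the median and the
upper quartile of final ischemia (≤1.5× and ≤2.5× the seed-only level,
respectively), the quartiles being exactly what replicate box plots report.

## Problem sizes and replicate counts

Replicate experiments use seeds base_seed + r and are bit-reproducible.
The test suite runs the stochastic reproductions at: untreated 12
replicates, N = 4 band/dot 8, band width/length sweeps 6 per configuration,
dot-size sweep 10 per S; the acceptance script uses 16 per S. A full
156-week cascade costs ~5–8 s (one sparse refactorisation per event week);
a blocked run ~1–3 s.

## What the generator does not emulate

The synthetic retina is a periodic ladder, not the irregular capillary bed
seen in real peripheral-retina histology: capillary paths are straight rungs with a
tortuosity factor, there is no capillary-free zone around the arteriole,
and the third dimension (choroid/photoreceptor oxygen profiles, hemoglobin
saturation) is absorbed into effective constants. VEGF stands in for the
whole cytokine balance; the leukostasis mechanism is black-boxed inside the
probability function. Physical transport constants are calibration
parameters constrained only by the qualitative targets above, so passing
tests demonstrate the mechanism and the pattern geometry arguments, not
quantitative prediction for a real retina. Reperfusion, neovascularisation,
macular edema and burn healing are out of scope.

## Numerical notes

Oxygen convergence tolerance 1e-6 mmHg, cap 200 iterations (typical: 80
cold, 5–30 warm-started); the below-cutoff consumption set is frozen at half
the iteration cap to prevent chatter. Ties in the node-pressure ordering are
broken by node id; zero-flow segments are skipped by the march and their
sites are plain tissue. Hypoxia is a strict `<` comparison at the threshold.
Quantiles use linear interpolation (NumPy default, type 7). All randomness
flows through `numpy.random.default_rng(seed)`; the event log is
reproducible bit-exactly from (config, seed).
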