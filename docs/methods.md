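# Methods

## Model

The glomerulus is a directed multigraph of capillary segments between
nodes, with a single afferent entry and a single efferent exit. The
afferent and efferent arterioles are lumped resistors R_A and R_E
(mmHg·min/nL) connecting the entry node to the mean arterial pressure
(MAP) and the exit node to a fixed downstream pressure. Each segment
carries length L, diameter D and wall thickness t; flow directions are
not part of the anatomy — they emerge from the solved pressure field.

Within a segment, axial Poiseuille flow couples to transmural Starling
filtration. Writing the leak strength as a² = R/(R_f L²) — R the
Poiseuille resistance 128µL/(πD⁴), R_f the filtration resistance — the
axial pressure obeys the transmission-line equation d²p/dx² − a²p =
−a²p_BS with the nodal pressures as boundary values. Its cosh/sinh
solution, its integrals (mean transmural pressure, cumulative
filtration), and the end flows are all closed-form; the end flows are
linear in the nodal pressures, so whole-network blood-volume
conservation is one symmetric linear system per iteration. For numerical
stability the hyperbolic terms are evaluated in exponentially scaled
form, so the profile stays finite for arbitrarily large aL (physiological
values are aL ≈ 0.01–0.3).

R_f balances the transmural pressure against the oncotic gradient
(the equation in the README); the oncotic pressure within a segment is
evaluated pointwise from the protein concentration profile C(x) =
C_in·Q_plasma(0)/Q_plasma(x) of the previous iterate, with the two
integrals taken in closed form where available and by fixed 16-point
Gauss–Legendre quadrature otherwise. Local reabsorption (Π exceeding the
transmural pressure pointwise) is allowed; only a segment whose *whole*
net filtration pressure integral is non-positive is clamped
non-filtering (R_f at 10⁹ mmHg·min/nL). Near filtration equilibrium the
reciprocal parametrisation g = 1/R_f ∈ [0, kπLD] is the iterated
variable: it is bounded and smooth where R_f diverges.

## Constitutive laws

The source anatomy/physiology literature specifies the *existence* of
three empirical relations but not their coefficients, so each sits
behind a configurable coefficient block (`rheology` section of the run
config, echoed into every run log):

* **Oncotic pressure**: Landis–Pappenheimer cubic Π = 2.1C + 0.16C² +
  0.009C³ (mmHg, C in g/dL).
* **Apparent viscosity**: the Pries–Neuhaus–Gaehtgens in-vitro tube-flow
  law for relative viscosity vs diameter and discharge hematocrit
  (Fåhræus–Lindqvist minimum near capillary calibre), multiplied by a
  plasma viscosity rising linearly with protein, 0.9 + 0.0614·C cP
  (≈1.25 cP at 5.7 g/dL). The hematocrit and protein used per segment
  are the mean of the inlet and outlet values.
* **Phase separation**: the Pries empirical logit law (A =
  −6.96 ln(Dα/Dβ)/D_f, B = 1 + 6.98(1−H)/D_f, X₀ = 0.4/D_f). The law is
  binary; at nodes with more than two outflows it is applied
  sequentially in descending flow order, which preserves erythrocyte
  volume. When the law would push a slow daughter past the hematocrit
  cap (0.95), the excess erythrocyte flux is redistributed to the other
  daughters so conservation stays exact. The feeding diameter at the
  entry node is the afferent arteriole's (default 20 µm).

Protein is not filtered (sieving coefficient 0); protein mass and
erythrocyte volume are conserved at every node and along every segment.

## Fixed-point solver

Each outer iteration: (1) solve the nodal linear system; (2) orient
segments by solved flow sign and propagate hematocrit/protein through
the flow field in topological order (pressure-descending order if the
instantaneous flow digraph has a cycle); (3) update µ and g per segment.
Initialisation is the impermeable, inlet-composition state (a = 0, µ
from H_in, C_in), which guarantees a well-posed first linear solve.
Convergence requires the maximum change of g (scaled by each segment's
conductance ceiling kπLD) and of µ (relative) to fall below 1e-6, with
at most 400 iterations.

Updates are under-relaxed (factor 0.5 by default) with adaptive
deepening while residuals rise and recovery while they fall; the
transported composition is damped with the same factor, since routing at
bifurcations can otherwise flip-flop across the plasma-skimming
threshold. Two deterministic fallbacks handle stiff cases: a retry under
heavy constant damping (factor 0.08, 4× the iteration budget), and —
when a shallow limit cycle persists — acceptance of the cycle-averaged
state. Such cycles are genuine properties of the discrete routing map
(phase separation near threshold coupled to hematocrit-dependent
viscosity admits no exact fixed point, a known behaviour of
microvascular network models); the accepted state is self-consistent to
better than 5e-3 and is always flagged in `solution.warnings`. Identical
inputs always produce identical output.

Whole-glomerulus summaries: SNGFR is the sum of segment filtration
rates, computed from the solved end flows so the identity SNGFR =
ΣCSGFR = plasma inflow − plasma outflow holds to machine precision; Q_A
is *plasma* flow (micropuncture convention), converted from blood flow
with the inlet hematocrit; P_GC is the length-weighted mean of the
segment mean pressures (unweighted and flow-weighted alternatives behind
`pgc_mode`).

## Fitting

Per condition, MAP is an input and three parameters are fitted: (R_A,
R_E) to (P_GC, Q_A) by a trust-region quasi-Newton root-find on
log-resistances (bounds 1e-4–1e3 mmHg·min/nL, seeded by two-resistor
algebra), then k to SNGFR by bracketing bisection on log k, alternating
until all three targets agree within 0.5 % (their printed precision).
The stages decouple because the capillary network's own resistance is
small next to R_A and R_E, so k barely moves P_GC and Q_A; one or two
passes suffice. The k bracket expands upward from 1e-4 only as far as
the target requires — very large k drives the bed to filtration
equilibrium, a stiff regime with no physiological counterpart. Every
solve inside the fit is cold-started so all probes land on the same
deterministic solution branch as the final verification solve.

Published fitted parameter values from comparable studies are treated as
reference metadata, not targets: fitted resistances and conductivity are
properties of the particular network realisation.

## Synthetic networks

The generator emulates the scale and architecture of the reconstructed
rat glomerulus used in the source anatomy: three lobules branching off a
shared afferent node and coalescing into a shared efferent node, exactly
320 segments and 193 nodes by default. Each lobule is a ladder of levels
(widths ramping 1, 2, 4, 6, 8, then mirrored) with base edges
guaranteeing through-flow for every node and seeded extra anastomoses up
to the exact edge count. Geometry is lognormal — diameter median 7 µm
(σ 0.25), length median 50 µm (σ 0.4), capillary-scale defaults chosen
in the absence of published distributions — with a Murray's-law calibre
factor ((peak width / local width)^⅓) widening the few root/outlet
segments that carry a whole lobule's flow, keeping the internal pressure
drop realistic. Wall thickness is uniform 0.2 µm (assumed; hoop-stress
magnitudes scale as 1/t, so only cross-condition hoop ratios are
robust). A `lobule_bias` knob scales per-lobule diameters to induce the
flow-favoured-lobule pattern deliberately.

What the generator does *not* emulate: the true degree distribution,
lobule sizes, 3-D embedding and diameter–length correlations of a real
glomerulus. Tests passing on these networks therefore validate the
solver, the inverse machinery and directional cross-condition claims —
not absolute stress magnitudes, which also depend on the assumed wall
thickness.

`generate_observations` forward-simulates known (R_A, R_E, k) into
(P_GC, Q_A, SNGFR) "observations" (optionally with multiplicative
Gaussian noise) for parameter-recovery testing; noise-free observations
must recover the generating parameters within the fit tolerance, and do.

## Defaults that are conventions, not data

Bowman's-space pressure 14 mmHg and downstream pressure 15 mmHg are
model constants; afferent hematocrit 0.5 and plasma protein 5.7 g/dL are
rat-micropuncture conventions (not printed in the hemodynamic source)
and are echoed in every run header. The four packaged conditions (Sham,
Sham + NF449, AngII, AngII + NF449) carry the micropuncture MAP, P_GC,
Q_A and SNGFR values as fit targets.

## Problem sizes used in the checks

The test suite exercises the full 320/193 network for the
four-condition fits, the conservation suite and the directional stress
comparisons; oracle-equivalence checks (monolithic nonlinear solve vs
fixed point) run on 3–6-segment chains and diamonds where every coupled
equation can be written down independently; parameter recovery runs on
ten 40-segment generated networks. The acceptance script fits all four
conditions on the full-scale network.

## Known limitations

* Steady state only: no pulsatility, no vessel compliance, no
  autoregulatory feedback.
* Diameter is axially uniform per segment; protein sieving is zero.
* Hoop-stress magnitudes inherit the assumed uniform wall thickness.
* The discrete routing limit cycles described above mean a handful of
  operating points are resolved to ~1e-3 rather than 1e-6
  self-consistency (always flagged).
* The phase-separation, viscosity and oncotic coefficient sets are
  literature defaults, configurable but not re-fitted here.
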