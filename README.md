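# glomflow

Blood flow, plasma filtration and mechanical stress in glomerular
capillary networks.

## The problem

The glomerulus filters plasma water across the walls of a tangled network
of a few hundred capillaries fed by the afferent arteriole (AA) and
drained by the efferent arteriole (EA). Hypertension, and the vasoactive
systems that respond to it (angiotensin II, purinergic P2X receptors on
arteriolar smooth muscle), change the arteriolar resistances and with
them the pressures, flows and *mechanical stresses* — endothelial shear
and circumferential "hoop" stress — felt by every capillary. Those
stresses are not measurable in vivo per capillary; an anatomically
explicit network model is the only way to map them.

`glomflow` is for renal physiologists and modellers who want to
(i) simulate steady-state hemodynamics in a capillary graph with leaky
(filtering) vessels, (ii) fit the unmeasured parameters — afferent and
efferent arteriolar resistances R_A, R_E and wall hydraulic conductivity
k — to micropuncture data (glomerular capillary pressure P_GC, plasma
flow Q_A, single-nephron GFR), and (iii) compare per-capillary stress
maps across experimental conditions.

## The model

Each capillary of length L and diameter D is a leaky transmission line.
With x the axial coordinate, p_BS the Bowman's-space pressure and R, R_f
the Poiseuille and filtration resistances of the segment, the wall leak
turns the axial pressure into

    d²p/dx² − a² p = −a² p_BS,      a² = R/(R_f L²) = 128 µ/(π D⁴ R_f L),

solved in closed form (cosh/sinh) between the nodal pressures. The
filtration resistance is balanced against the local Starling forces,

    R_f = ∫(p − p_BS) dx / [ k π L D ∫(p − p_BS − Π) dx ],

where the colloid osmotic pressure Π(C) is a cubic in the plasma protein
concentration C, which itself rises along each capillary as protein-free
water is filtered (dQ/dx = −(p − p_BS)/(L R_f)). Blood viscosity µ(D, H,
C) follows the empirical in-vitro tube-flow law, with erythrocytes routed
at bifurcations by the empirical phase-separation law. Conservation of
blood volume at every node (∑Q = 0, with the AA/EA as lumped resistors
between MAP and a fixed downstream pressure) closes the system; a
fixed-point iteration alternates the linear nodal solve with R_f and µ
updates until both converge. Per capillary, the model then reports the
filtration rate CSGFR, the wall shear stress τ = 32 µ ⟨|Q|⟩/(π D³), and
the Laplace hoop stress σ = D ⟨p − p_BS⟩/(2 t).

All internal arithmetic runs in a (µg, s, µm) working-unit system to keep
every quantity far from floating-point underflow; inputs and outputs are
in the customary reported units (mmHg, nL/min, cP, dyn/cm², kPa).

## Worked example

```python
from glomflow import GlomerulusModel

model = GlomerulusModel.from_generator(seed=1)   # 320 capillaries, 193 nodes
res = model.fit_named_condition("Sham")          # fit R_A, R_E, k
print(res.summary())
```

prints

```
Condition fit: Sham
==============================================
  MAP (input)                   119.7 mmHg
  fitted R_A                   0.2438 mmHg·min/nL
  fitted R_E                   0.0916 mmHg·min/nL
  fitted k                  2.460e-05 nL/min/mmHg/µm²
----------------------------------------------
  quantity      target    achieved   rel.err
  P_GC   mmHg      46.9      46.81  1.91e-03
  Q_A  nL/min     125.8     125.92  9.16e-04
  SNGFR nL/min     38.8      38.80  1.30e-12
----------------------------------------------
  outer passes 1; solver iterations 46; segments clamped 183/320
  hematocrit_in=0.5, protein_in=5.7 g/dL (conventions, not data)
```

The fitted resistances reproduce the Sham micropuncture state: a mean
capillary pressure of ≈47 mmHg, plasma flow ≈126 nL/min, and a
single-nephron GFR of 38.8 nL/min; "clamped" counts capillaries that sit
at filtration equilibrium (no net filtration), a physiological feature of
the normotensive state. `res.stress_report()` then gives the
per-capillary shear/hoop table, and `glomflow.run_study` (or the
`glomflow study` CLI) fits all four packaged conditions — Sham and
angiotensin-II hypertension, each with and without the P2X1 antagonist
NF449 — and writes fitted-parameter, stress and Welch-test comparison
CSVs plus stress-map figures.

A command-line interface mirrors the library:

```bash
glomflow generate --seed 1 --out network.csv
glomflow solve --network network.csv --map 110 --k 2e-5 --ra 0.4 --re 0.2
glomflow fit --condition Sham
glomflow study --seed 1 --out study_out
```

## Layout

| module | contents |
|---|---|
| `glomflow.model` | `GlomerulusModel` / `ConditionFitResults` facade |
| `glomflow.units` | working-unit conversions, physiological constants |
| `glomflow.network` | network data model, validation, CSV/JSON/GraphML I/O |
| `glomflow.rheology` | viscosity, oncotic pressure, phase separation, mixing |
| `glomflow.mechanics` | single-capillary closed forms |
| `glomflow.solver` | nodal assembly, fixed-point loop, k fitting |
| `glomflow.fitting` | resistance/conductivity fits, conditions table |
| `glomflow.stress` | shear/hoop stresses, Welch comparisons, maps |
| `glomflow.synthetic` | seeded network generator, observation generator |
| `glomflow.study`, `glomflow.cli` | study driver and CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and numerical choices.
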