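# arterywall

An integrative, single-segment simulation model of resistance-artery
biomechanics and adaptation, for researchers in vascular physiology and
cardiovascular modeling who want to study how small arteries keep
themselves in a functional, stable state while adapting to pressure,
flow and vasoactive agents.

## The model

A small artery segment is described by five state variables:

| symbol      | meaning                                           |
|-------------|---------------------------------------------------|
| ε           | matrix strain (midwall distension from slack)     |
| A           | smooth-muscle tone, 0–1                           |
| sp          | SMC span (fraction of circumference per cell)     |
| r_m,slack   | slack midwall radius of the matrix                |
| wCSA        | wall cross-sectional area                         |

Three stress-bearing elements lie in parallel across the wall — passive
matrix (bi-exponential stress–strain law σ_p(ε)), active SMC filaments
(bell-shaped length–stress capacity σ̂_a(l) scaled by tone A) and a steep
cytoskeletal stretch brake σ_c(l) — each covering one third of the wall
area, so the mean wall stress is

    σ = af_p σ_p(ε) + af_a A σ̂_a(l) + af_c σ_c(l),  l = sp · 2π r_m.

The load side is the Laplace relation σ_eq = P·r_i/h and Poiseuille wall
shear τ = 4ηQ/(π r_i³). Five first-order processes couple them:

1. **mechanics** — dε/dt = k_mech (σ_eq − σ): strain follows the load;
2. **tone** — dA/dt = k_tone (A_eq − A), with set-point
   A_eq = Hill(σ + CON; σ₅₀, h_c) · [1 − ecf·Hill(τ + DIL; τ₅₀, h_d)]:
   the myogenic response driven by wall stress and equipotent
   constrictors, reduced by shear- and dilator-mediated relaxation;
3. **SMC plasticity** — d(sp)/dt = k_span (l_ref − l) l/l_ref: cells
   reposition so their length returns to a reference;
4. **eutrophic remodeling** — d(r_m,slack)/dt = k_slack r_m,slack
   (β ε − α A): strain drives outward, tone inward reorganization of the
   existing matrix;
5. **growth** — d(wCSA)/dt = k_growth wCSA (σ − σ_ref): slow trophic
   change of wall mass toward a reference stress.

Switching processes off (setting rate constants to zero) gives the model
hierarchy `MECH`, `FUNCT`, `PLAST`, `REMOD`, `GROWTH` and the software
knockouts `FUNCTKO`, `PLASTKO`, `REMODKO`.

At any stable full-model steady state the rate laws pin σ = σ_ref,
l = l_ref, A = A_eq, σ = P·r_i/h and βε = αA — the vessel regulates wall
stress and shear stress simultaneously, keeps intermediate tone (radius
reserve), and keeps active and passive biomechanics matched.

## Worked example

```python
import arterywall as aw

ss = aw.find_steady_state(aw.DEFAULT_INPUTS)   # 80 mmHg, 0.25 µL/s
print(ss.verdict)
for k, v in ss.derived.items():
    print(k, v)
```

prints (formatted, clinical units):

```
verdict          : stable
inner radius     : 67.89 um
tone             : 0.367
SMC length       : 80.00 um
slack inner rad. : 49.60 um
wall CSA         : 12126 um^2
wall stress      : 30.0 kPa
wall shear       : 35.60 dyn/cm^2
radius reserve   : 1.418
tension match    : 0.995
```

The vessel settles at intermediate tone with wall stress at the growth
reference (30 kPa) and SMC length at its plasticity reference (80 µm).
Radius reserve (fully dilated over actual radius, 1.42) quantifies the
vasodilatory margin; tension match ≈ 1 means the radius of peak active
stress capacity coincides with the passive radius at 100 mmHg.

Typical experiments:

```python
# chronic pressure step: radius and tone fully restored, wall thickens
ts = aw.step_response("GROWTH", {"P": aw.units.mmhg(100)})

# sensitivity of all steady-state outputs to key adaptation parameters
sm = aw.sensitivity_matrix()          # ±5% central differences
print(sm.table.round(3))

# chronic dilators: steady-state shear falls so that tau + DIL is
# conserved (~35.6 dyn/cm²); beyond that total the radius runs away
scan = aw.dilator_shear_sum_scan()
```

The same protocols are exposed on the command line:

```bash
arterywall steady-state --pressure 100 --out ss.json
arterywall simulate --variant REMOD --out trajectory.csv
arterywall sensitivity --out table.json
arterywall scan-dilator --out scan.csv
```

## Acceptance script

`scripts/acceptance.py` recomputes the model's parameter-sensitivity
entries from scratch: it solves the full-model steady state (stiff BDF
integration from the canonical vessel, then Newton polishing) at ±5%
perturbations of endothelial function, reference SMC length, the
strain-remodeling weight and the reference growth stress, forms the
central-difference sensitivities of the steady-state outputs, and writes
one JSON entry per target:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The model is fully deterministic; the seed only fixes the (unused) numpy
random state.

## Layout

- `src/arterywall/mechanics.py` — constitutive laws, geometry, Laplace/shear
- `src/arterywall/regulation.py` — tone set-point, rate laws, variant masks
- `src/arterywall/engine.py` — stiff integration, steady states, stability verdicts
- `src/arterywall/protocols.py` — pressure–radius curves, step responses, maps, sensitivity, dilator scan
- `src/arterywall/config.py`, `io.py`, `cli.py` — YAML config, CSV/JSON output, CLI
- `docs/methods.md` — model assumptions, numerical choices, limitations
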