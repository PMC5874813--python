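# ecollim

Analytical design toolkit for electron-beam applicator collimation systems.

Electron applicators ("cones") on a medical linear accelerator shape the
therapeutic electron field with a stack of square shielding frames
("trimmers") mounted below the X-ray jaws. Trimmers made thick and wide
enough to stop every scattered electron are unnecessarily heavy, and heavy
applicators are a genuine ergonomic problem for radiotherapy staff.
`ecollim` implements the analytic machinery needed to design trimmers that
are just heavy enough: an in-air Gaussian penumbra model, rule-based trimmer
cross-section generation, exact frame-mass integration, and grid-search
optimization of trimmer positions and edge placements under an in-field
flatness constraint. It is aimed at medical physicists studying collimation
design trade-offs (weight vs flatness vs leakage) for 6–20 MeV beams.

## Model

Off-axis fluence at a plane below a collimator edge is an error-function
penumbra,

    OAR(E, x) = ½ · [1 − erf( x / (√2 σ_x(E)) )],

where `x` is measured from the divergent projection of the upstream edge and
the Gaussian width combines in-air multiple scattering with the projected
virtual-source width σ_SW:

    σ_x² = T_air(E) · [ z′(z−z′)²/4 + (z−z′)³/3 ] + σ_SW² · ((z−z′)/z′)²,

with `z′`, `z` the distances of the upstream and downstream planes from the
virtual source (94 cm above isocenter) and
`T_air(E) = 0.00554·E^−1.78 rad²/cm`. The first bracket is the Fermi–Eyges
in-gap term plus the conditional angular spread pencil beams carry into the
gap; the air-scatter form is injectable (`ElectronBeamModel(air_term=...)`)
because published design formulas differ in this term.

Design rules built on this model:

* **inner edges** of each trimmer sit at a prescribed OAR of the upstream
  component's 6-MeV penumbra (95% for pure shielding designs; lowered per
  trimmer when flatness allows), solved bottom-up from the field size at
  isocenter;
* **outer edges** are beveled: at each energy, the stopping thickness
  `t(E) = 0.53 cm · R(E)/R(20 MeV)` of the tungsten-alloy frame
  (9.6 g/cm² full thickness) extends to that energy's outer-OAR anchor
  (2% for plain bevels, interpolated 2→48% for the final bevel shapes);
* **mass** is the mitered-corner perimeter integral of the cross-section,
  checked against a voxelized oracle;
* **jaw schedules** interpolate the OAR at the upper trimmer inner edge
  linearly in energy (e.g. 96.5% at 6 MeV → 55% at 20 MeV).

The five-stage pipeline (`run_design_pipeline`) chains the staged weight
reductions — bevel, plane optimization, inner-edge placement, jaw schedule,
thickness/bevel-shape adjustment — for a family of 6×6 … 25×25 cm²
applicators and emits a weight ledger, jaw schedules and fabrication-facing
cross-section profiles.

## Worked example

```sh
$ ecollim design --applicator 10 --applicator 20 --out design_report
  10x10 cm^2: 4.04 kg, flatness margin +0.0184 (pass)
  20x20 cm^2: 5.33 kg, flatness margin +0.0125 (pass)
wrote 5 files to design_report
```

The two numbers per line are the final total trimmer mass after the full
five-stage chain and the 6-MeV analytical flatness margin (relative fluence
at 2 cm inside the field edge may drop at most 0.02 below the central axis;
a positive margin passes). `design_report/weight_ledger.csv` holds one row
per stage:

```
applicator,stage,mass_kg,step_reduction_pct,cumulative_reduction_pct
10.0,initial,7.587,,0.0
10.0,bevel,6.074,19.94,19.94
...
10.0,thickness_bevel,4.037,29.65,46.79
```

i.e. the un-beveled shielding design for the 10×10 cm² applicator weighs
7.59 kg and the staged modifications cut it by 47% to 4.04 kg. The same
chain is available as a library:

```python
import ecollim as ec
machine, beam, mat = ec.MachineGeometry(), ec.ElectronBeamModel(), ec.TrimmerMaterial()
design = ec.build_applicator(10.0, machine, beam, mat,
                             trimmer_z=(66.0, 79.0, 95.0),
                             inner_oars={"lower": .95, "middle": .96, "upper": .965})
print(design.total_trimmer_mass)          # kg
print(design.mass_report.per_trimmer())   # per-frame breakdown
```

Other CLI entry points: `ecollim optimize-z` (isomass grid search over
trimmer plane positions), `ecollim optimize-oars` (five-parameter inner-edge
optimization under the flatness constraint), `ecollim calibrate-jaws`
(jaw-plane heights from physical vs isocenter-projected jaw settings) and
`ecollim report`.

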