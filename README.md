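# pterolaunch

Muscle moment-arm analysis of the three hypothesised pterosaur take-off
motions — bipedal burst, bipedal countermotion and quadrupedal launch —
for a medium-sized (5 m wingspan) ornithocheiraean musculoskeletal model.

Whether pterosaurs launched bipedally like birds or quadrupedally by
vaulting onto their forelimbs is a long-standing question in vertebrate
palaeobiomechanics. One quantitative handle on it is *leverage*: the
muscle moment arms available to each limb during each hypothesised
take-off motion. This package implements that analysis as a tested,
reusable pipeline:

- a **skeletal model** as a tree of rigid segments joined by 3-DOF
  rotational joints (X = long-axis rotation, positive = pronation;
  Y = flexion–extension, positive = extension; Z = ab/adduction,
  positive = adduction), carrying a 43-row muscle roster with MTU
  multiplicities and extant-phylogenetic-bracket inference grades;
- **muscle-path routing** through via points and cylindrical wrapping
  surfaces (tangent-line + geodesic construction, lengths in closed form);
- **virtual-work (tendon-excursion) moment arms**,
  `MA = -∂L/∂q`, by central finite difference, verified against an
  independent perpendicular-distance oracle and the pulley theorem;
- **take-off kinematics**: one-second sequences interpolated
  (shape-preserving cubic) from key poses, with style-specific phase
  structure (burst: crouch / ankle-lifted / launch; countermotion:
  countermotion / launch; quadrupedal: crouch / vault / launch) and
  per-coordinate launch-applicability intervals;
- a **Monte Carlo error model**: each moment-arm value v is perturbed
  v·(1+u), u ~ U(−0.2, +0.2), for 1000 trials, summarised by mean and SD;
- **directional summation**: per coordinate, same-signed (per-frame)
  muscle arms are summed into extensor/flexor, adductor/abductor and
  internal/external-rotator group traces — the headline leverage
  statistic — plus mean-across-muscles and extensors-only variants.

The specimen-derived skeletal geometry is not redistributable, so the
package ships a clearly-labelled **synthetic stand-in** model whose
roster, tree topology, joint conventions and sequence structure follow
the study design; user-supplied model files (YAML schema, or a minimal
OpenSim `.osim` subset) slot in unchanged. Fossil-specific moment-arm
magnitudes are therefore out of scope here; every structural and
statistical property of the pipeline is testable without them.

## Worked example

```python
from pterolaunch import MonteCarloConfig, make_quadruped_toy
from pterolaunch.pipeline import run_takeoff_analysis

model, sequences = make_quadruped_toy(seed=1)
result = run_takeoff_analysis(
    model, sequences, n_frames=101,
    mc=MonteCarloConfig(fraction=0.20, n_trials=1000, seed=1),
)
for style, sr in sorted(result.styles.items()):
    print(f"{style}: launch-applicable extensor total at launch "
          f"{sr.extensors_only[-1]:.4f} m")
```

prints

```
bipedal_burst: launch-applicable extensor total at launch 0.3747 m
bipedal_countermotion: launch-applicable extensor total at launch 0.3894 m
quadrupedal: launch-applicable extensor total at launch 0.5798 m
```

i.e. on the stand-in geometry the quadrupedal motion ends launch with the
largest summed extensor moment arms among the coordinates its launch limb
can actually exploit — the forelimb from vault onset — because the
forelimb musculature both outnumbers and out-levers the hindlimb set.
(The magnitudes are properties of the synthetic stand-in, not of the
fossil.)

The same analysis as a script sequence, each step writing its tables
under `results/`:

```sh
python analysis/01_build_model.py            # model + MTU bookkeeping
python analysis/02_build_kinematics.py       # the three 1-s sequences
python analysis/03_trace_moment_arms.py      # per-MTU virtual-work arms
python analysis/04_summarise_with_uncertainty.py  # MC + directional sums + figures
python analysis/05_compare_takeoff_styles.py # style comparison table
```

A `pterolaunch` CLI (`validate`, `make-toy`, `kinematics`, `moment-arms`,
`montecarlo`, `report`, `run-all`) wraps the same library calls.

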