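# dynasite

Dynamic active-site mapping for protein conformational ensembles, built
around the type-3 dicopper active site of human tyrosinase (Tyr), the
enzyme that initiates melanin biosynthesis and whose missense variants
cause oculocutaneous albinism type 1 (OCA1).

The package is for structural bioinformaticians who want to turn short MD
ensembles (or synthetic stand-ins with known ground truth) into
residue-level statements about substrate recognition and mutation impact:

- **Per-residue metrics** over an ensemble: RMSD at fixed analysis ticks,
  RMSF, dynamic cross-correlation matrices (DCCM), non-bonded heavy-atom
  contact counts, Shrake–Rupley SASA with side-chain exposure ratios, and
  5-state secondary-structure fractions (H/G/E/T/C).
- **Ligand-interaction detection and pose triage**: geometric hydrogen
  bonds, hydrophobic contacts and π–π stacking; the dicopper validity rule
  (a hydroxyl/carbonyl oxygen within 4.0 Å of CuA or CuB, oriented toward
  the site); energy-ranked greedy pose clustering at 5.0 Å heavy-atom RMSD;
  bound/unbound calls over trajectories.
- **Interaction-set algebra**: per-substrate residue sets with persistence,
  reduced to a universal core (engaged by every substrate), substrate-
  specific positions, and shared subsets.
- **Mutation-impact scoring**: Δ-metrics (mutant − wild type), stabilization
  labels (increases in RMSD/RMSF/SASA destabilizing; decreases in contacts
  and DCCM coupling destabilizing), perturbation summaries over a variant
  panel, and a group-level disruption score with the anchoring-region vs
  gating-loop ratio.
- **Seeded generators** for every input: ideal backbones (α-helix, 3₁₀,
  β-strand, antiparallel sheet), correlated Gaussian ensembles with exact
  DCCM/RMSF ground truth, a toy dicopper site, bound/escaping ligand
  trajectories, and variant panels with prescribed group effect sizes.

## Core quantities

For residue displacement deviations Δr_i about the time mean (after
rigid-body superposition on a fit selection),

    DCCM:  C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)
    RMSF:  RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)

SASA uses Shrake–Rupley quadrature (960 golden-spiral points, 1.4 Å water
probe) with an embedded vdW table (C 1.70, N 1.55, O 1.52, S 1.80,
Cu 1.40 Å).  Secondary structure uses the classic backbone H-bond energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with bonds at
E < −0.5.  The disruption score sign-adjusts each Δ so positive means
destabilizing, normalizes by the wild-type magnitude, then averages
metrics → variants → residues → group, and reports the ratio of the
anchoring region (K334, E345, F347) to the gating loop (M374–F386).

## Worked example

```python
import numpy as np
from dynasite.synthetic_data import (
    FluctuationSpec, VariantPanelSpec, gen_gaussian_ensemble,
    gen_ideal_structure, gen_variant_panel, tyrosinase_fixtures,
)
from dynasite.metrics import dccm, per_residue_rmsf
from dynasite.structmodel import SelectionSpec
from dynasite.delta_analysis import disruption_score

# a 20 ns / 0.25 ns ensemble with two correlated blocks and a rigid core
ref = gen_ideal_structure("coil", 30, with_cb=False)
mobile = [f"A{i}" for i in range(1, 21)]
spec = FluctuationSpec(
    sigma={lab: 0.5 for lab in mobile},
    blocks=[(mobile[:10], 0.8), (mobile[10:], 0.8)],
    n_frames=80, stride_ns=0.25, seed=1,
)
ens = gen_gaussian_ensemble(ref, spec)
print(f"frames: {ens.n_frames}, span: {ens.span_ns} ns")

core = SelectionSpec(atom_names=frozenset({"CA"}), residue_range=(21, 30),
                     include_hetero=False)
rmsf = per_residue_rmsf(ens, fit_spec=core)
print(f"mean mobile RMSF: {rmsf[mobile].mean():.2f} A "
      f"(sigma*sqrt(3) = {0.5 * np.sqrt(3):.2f} A)")
C = dccm(ens, fit_spec=core).to_frame()
intra = C.loc[mobile[:10], mobile[:10]].values[np.triu_indices(10, 1)]
print(f"intra-block DCCM: {intra.mean():.2f}")

# mutation-impact scoring over the 23-residue active-site universe
fx = tyrosinase_fixtures()
groups = {"anchoring_334_347": list(fx.anchoring_group),
          "gating_374_386": list(fx.gating_group)}
panel = VariantPanelSpec(
    universe=list(fx.interacting_residues),
    group_effects={"anchoring_334_347": (groups["anchoring_334_347"], 0.34),
                   "gating_374_386": (groups["gating_374_386"], 0.20)},
    noise_cv=0.10, n_variants=25, seed=1,
)
_, deltas = gen_variant_panel(panel)
report = disruption_score(deltas, groups)
for name, score in report.group_scores.items():
    print(f"{name}: {score:.3f}")
print(f"disruption ratio: {report.ratio:.2f}")
```

Output:

```
frames: 80, span: 20.0 ns
mean mobile RMSF: 0.89 A (sigma*sqrt(3) = 0.87 A)
intra-block DCCM: 0.82
anchoring_334_347: 0.341
gating_374_386: 0.200
disruption ratio: 1.71
```

The 80-frame ensemble matches the 20 ns / 0.25 ns sampling convention; the
measured RMSF and DCCM sit on their analytic targets (σ√3 and the
prescribed block correlation); and the 25-variant panel with 10%
multiplicative noise recovers group disruption scores near the prescribed
effect sizes (0.34 and 0.20), giving an anchoring-to-gating susceptibility
ratio of ~1.7.

## Command line

One subcommand per pipeline stage, with the study's printed defaults
(contact 5.0 Å, O–Cu 4.0 Å, cluster 5.0 Å, probe 1.4 Å, H-bond tolerances
0.4 Å / 20°, save stride 0.25 ns, analysis stride 1.0 ns):

```
dynasite simulate --mode bound --out sim --seed 1 --frames 20 --save-stride 1.0
dynasite metrics  --input sim/bound.pdb --out wt.tsv --save-stride 1.0
dynasite map      --input sim/bound.pdb --out map.json --save-stride 1.0
dynasite delta    --table-a wt.tsv --table-b mut.tsv --out delta.tsv
dynasite disrupt  --wildtype wt.tsv --variant v1.tsv --variant v2.tsv --out d.json
```

Exit codes: 0 success, 2 validation error, 1 runtime error.  Every output
embeds the parameters and seed that produced it.

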