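# Methods

This note documents the models, conventions and numerical choices behind
`dynasite`, in the order the pipeline uses them.

## Coordinate model and trajectory convention

Structures are ordered atom lists grouped into residues keyed by
`(chain, author residue number, insertion code)`; all reporting uses author
numbering so labels match the literature convention for the tyrosinase
active site (H180 … H390).  Coordinates are Å throughout.  PDB I/O is
delegated to gemmi; a pre-scan of ATOM/HETATM coordinate columns reports
the offending line number for malformed records.  Altloc policy: keep the
highest-occupancy conformer, ties broken by altloc letter, giving a
deterministic single-conformer model.

Multi-MODEL files become ensembles under the saved-snapshot convention:
the first MODEL is the frame at `t = stride` (t = 0 is the reference
topology, not a saved frame), so a 20 ns run saved every 0.25 ns carries
80 frames.  A count of "81 snapshots" in some bookkeeping styles includes
the t = 0 reference; this package consistently excludes it.  Analysis-time
metrics are sampled at 1 ns ticks by taking the nearest saved frame, ties
resolved toward the earlier frame.

## Superposition and the rigid-core fit

Kabsch superposition (SVD, proper rotation enforced by determinant
correction) requires at least three non-collinear fit points.  All dynamic
metrics superpose frames before measuring; the fit selection is a
parameter, Cα by default.

A consequence worth making explicit: Kabsch translation removal subtracts
the per-frame mean displacement of the *fit atoms*.  If the fit set is
itself dominated by correlated flexible blocks, that subtraction injects
spurious negative cross-correlations between blocks (a centering
artifact).  The recommended — and tested — usage is therefore to fit on a
rigid core (residues with low mobility) and compute DCCM/RMSF on the
mobile selection.  This mirrors standard MD practice of aligning on a
stable domain, and it is what makes block-correlation recovery on the
Gaussian generator exact.

## Per-residue metrics

- **RMSD**: at each 1 ns tick, superpose globally on the fit selection,
  then compute each residue's heavy-atom RMSD to the reference.  Heavy
  atoms (not just Cα) are used for the deviation so side-chain remodeling
  registers.  Both the per-interval series and the time average are
  reported.
- **RMSF**: `sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` over superposed frames, averaged over
  each residue's selected atoms.  For isotropic per-coordinate noise of
  std σ this converges to σ√3.
- **DCCM**: normalized displacement-vector covariance.  Residues with zero
  positional variance get NaN (missing), never 0 — a zero would falsely
  read as "uncorrelated".  The per-residue scalar `dccm_residue_score` is
  the mean correlation of a residue to a partner set excluding itself; the
  canonical partner set is the 23-residue interaction list, so the scalar
  reads as active-site coupling.
- **Contacts**: heavy-atom pairs between a residue and the rest within
  5.0 Å, excluding covalently linked pairs (the peptide C(i)–N(i+1) link).
  Atom-pair counting is the default; distinct-partner-residue counting is
  available via `count_partners=True` since trajectory-analysis tools
  differ on this convention.
- **SASA**: Shrake–Rupley with a deterministic golden-spiral quadrature
  (default 960 points; 4000 points brings two-sphere overlap within 1% of
  the spherical-cap closed form).  Probe 1.4 Å; embedded vdW radii
  C 1.70, N 1.55, O 1.52, S 1.80, Cu 1.40, H 1.20, P 1.80, Se 1.90 Å.
  Hydrogens carry no area and do not occlude.
- **Exposure ratio**: side-chain SASA over a per-residue-type random-coil
  reference, ×100, unclamped (a clamped display variant exists).  The
  reference table is *synthetic*: computed once with this package's SASA
  routine on generator-built extended Gly-X-Gly tripeptides in which the
  side chain is represented by its β-carbon (Cα for glycine), then frozen
  in source.  Under that proxy all non-Gly residues share one reference
  area (56.10 Ų; Gly 26.67 Ų).  This keeps the ratio internally
  consistent for generator-built structures; it is *not* calibrated for
  full-side-chain models, where a residue-type-specific table from an
  all-atom reference should be substituted.
- **Secondary structure**: reduced 5-state assignment (H, G, E, T, C)
  from backbone H-bond energies, `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH
  − 1/r_CN)` kcal/mol, bond when E < −0.5.  Two consecutive n-turns at
  offset 4 (3) make H (G); parallel/antiparallel bridge patterns make E
  (single bridges are folded into E rather than a separate B state);
  isolated turns make T; priority H > G > E > T > C.  Amide hydrogens
  absent from heavy-atom-only files are inferred at 1.01 Å from N along
  the direction opposing the bisector of the N–CA and N–C(prev) bonds.
  Residues missing backbone atoms are labeled C with a warning.  π-helix,
  bend and chirality classes are out of scope.

## Interaction detection and pose triage

Hydrogen bonds use base criteria of 3.0 Å donor–acceptor distance and
140° donor-H-acceptor angle, relaxed by the configured tolerances
(defaults 0.4 Å and 20°, i.e. accept ≤ 3.4 Å and ≥ 120°); boundaries are
inclusive wherever a cutoff is printed with ≤/≥.  When a donor has no
explicit hydrogen the angle criterion is treated as satisfied, which keeps
heavy-atom-only models usable at the cost of some permissiveness.
Hydrophobic contacts are apolar(C,S)–apolar pairs within 5.0 Å, one record
per residue per frame at the minimum distance.  π–π stacking compares
SVD-fitted ring planes: parallel at inter-plane angle ≤ 30°, T-shaped in
[60°, 120°]; protein rings come from an embedded name table
(Phe/Tyr/Trp/His), ligand rings from the substrate templates.

Ligand chemistry is template-based, no general perception: four idealized
substrate templates (codes TYS = L-tyrosine, LDO = L-DOPA, DHC = DHICA,
DHI = DHI) annotate ring atoms, hydroxyl/carbonyl oxygens, donors and
acceptors.  Codes are three characters to fit the PDB residue-name field.

A pose is catalytically plausible when (a) some hydroxyl/carbonyl oxygen
lies within 4.0 Å (inclusive) of CuA or CuB and (b) the ring-centroid→
oxygen vector has positive projection on the centroid→Cu-midpoint vector
(oxygen points into the site).  Pose clustering is greedy and
energy-ranked at 5.0 Å ligand heavy-atom RMSD without re-superposition
(fixed receptor frame, standard docking practice).

Bound/unbound classification over an ensemble defaults to the O–Cu
distance reading of the "≤ 4.0 Å deviation" rule (min qualifying-oxygen
distance to either copper at every analysis frame); an alternative
positional-deviation criterion (ligand-centroid displacement from the
reference pose) is available because the wording admits both readings,
and the criterion used is recorded in the result.  On single-frame
ensembles the default criterion agrees with pose validity's distance
clause by construction.

The interaction map admits residues with records in more than
`min_persistence` of analysis frames; the default 0 means a single frame
suffices, because active-site engagement is reported "to varying degrees"
across a trajectory, and persistence fractions are always recorded so
stricter thresholds are reproducible.  Copper-coordinating histidines that
frame the site without touching the ligand (H211, H390) can be
force-included via an explicit allow-list; forced entries are flagged.
Universal/specific/shared classification partitions the residue union
exactly.  Copper-proximity annotation labels each residue by nearer copper
(min heavy-atom distance), "both" within a 1.0 Å margin.

## Comparative analytics

Δ-metrics are always B − A on shared residues; missing values propagate.
Sign convention: increases in RMSD, RMSF, SASA (and exposure) are
destabilizing; decreases in contacts and DCCM coupling are destabilizing.
The neutral band is 1% of the wild-type magnitude (absolute floor 1e-9)
so floating-point dust is never labeled as signal.

The group disruption score needs commensuration across metrics with
different units; the choice here is relative change: each Δ is
sign-adjusted so positive = destabilizing, then divided by the wild-type
magnitude for that residue and metric.  Where a wild-type value is zero
the fallback is a z-score against the wild-type spread of that metric
across the residue universe (unit denominator if the spread is also
zero).  Magnitudes are then averaged metrics → variants → residues →
group; the ratio of the first to the second group score is the
susceptibility ratio.  The construction makes the score dimensionless and
invariant to rescaling any metric by a positive constant — the reported
ratio would change under a different commensuration (e.g. raw Δ or global
z-scores), which is why the settings are embedded in every report.

Significance uses Student's (pooled-variance) two-sample t on per-interval
RMSD series, two-tailed, with stars at p < 0.05/0.01/0.001; Welch's
variant is available behind a flag.  Zero-variance degenerate cases:
equal means → (t=0, p=1); unequal means → infinite-t flagged.  No
multiple-testing correction is applied, matching the upstream protocol.
Pearson R² and the two normalizations (UMS in [0,1] → percent; foldability
as percent of the reference maximum 19, values above 100 flagged) are
direct.  Conservation classes per ungapped reference position:
`conserved_distant` when a column is identical across all rows,
`conserved_vertebrate` when identical across vertebrate-tagged rows,
else `not_conserved`; gaps and ambiguity codes break identity
(conservative calls).

## Synthetic generators: what they emulate, and what they do not

The generators reproduce the statistical structure the metrics assume,
with exact ground truth:

- `gen_gaussian_ensemble` draws per-residue displacement 3-vectors from a
  multivariate normal with block correlation structure, the three axes
  independent; side-chain atoms follow their residue's displacement
  rigidly.  Ground truth: DCCM = block ρ, RMSF = σ√3.  PSD of the implied
  correlation matrix is validated at construction.  Default run length
  80 frames at 0.25 ns (20 ns).
- `gen_ideal_structure` builds backbones from canonical internal
  coordinates (NeRF chain extension; bond lengths within 0.02 Å of
  canonical values; α: φ=−57°, ψ=−47°; 3₁₀: −49°, −26°; strand: −139°,
  135°; coil is polyproline-II-like, which forms no H-bond pattern).  The
  antiparallel sheet places a partner strand via a rigid transform
  calibrated once (for a 10-residue strand) to put every narrow-pair
  backbone H-bond at canonical energy, carried to other lengths through
  the strand's exact screw symmetry.
- `gen_toy_active_site` arranges two coppers 3.5 Å apart, each flanked by
  three histidine-like residues (ND1 ≈ 2.1 Å from its copper) numbered
  after the canonical coordinating histidines, plus a bridging O₂
  placeholder; the +x corridor past CuB is left open for ligand approach.
- `gen_ligand_trajectory` starts the template's anchor oxygen 3.2 Å from
  CuB on that corridor.  Bound mode adds Gaussian jitter *clipped at 2σ*,
  so the ground-truth bound call can never flip on a tail event; escape
  mode adds a linear drift making the O–Cu distance at 0-based frame k
  exactly `3.2 + (k+1)·drift`, so the first failing frame has a closed
  form.
- `gen_variant_panel` draws per-residue destabilization magnitudes as
  `effect × lognormal` (unit-mean, CV as configured — lognormal keeps
  magnitudes positive), writes them into a metric table with wild-type
  value 1.0 and the destabilizing sign per metric, so the recovered
  magnitude equals the drawn effect exactly.  Groups must be disjoint and
  inside the universe.

What passing tests on these generators shows: the estimators are unbiased
and correctly normalized on data that satisfies their assumptions, and
the pipeline's bookkeeping (strides, persistence, set algebra, nested
means) is exact.  What they do not show: behavior on real MD output —
anharmonic and collective motions, correlated axes, solvent effects,
conformational transitions, imperfect superposition cores, or ligand
flexibility.  Conclusions about real trajectories still require real
trajectories.

Fixed study conditions used throughout tests and the acceptance script:
20 ns at 0.25 ns save stride (80 frames), 1 ns analysis ticks, σ = 0.5 Å,
block ρ = 0.8, ligand start 3.2 Å with a 4.0 Å cutoff, 25-variant panels
with group effects 0.34/0.20 and 10% noise CV.  Estimator-recovery checks
use 2000 frames (RMSF) and 5000 frames (DCCM) — sizes at which the
estimators' sampling error is comfortably inside the documented
tolerances — and a 60-residue chain with a 20-residue rigid core.

## Known limitations

- The exposure-ratio reference is the Cβ-proxy table described above, not
  an all-atom random-coil reference.
- H-bond detection without explicit hydrogens skips the angle criterion.
- Secondary-structure assignment is the reduced 5-state scheme, not a
  full DSSP reimplementation.
- No periodic-boundary imaging: ensembles are assumed whole and imaged.
- Docking energies are consumed, never computed; UMS and foldability
  values are consumed from tables.
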