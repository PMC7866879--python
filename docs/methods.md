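# Methods

This note documents the models and procedures implemented in `varimpact`,
the parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where more than one
reasonable option existed.

## Structures and selections

PDB files are parsed with author numbering preserved — variant sites in the
literature are cited in author numbers, so nothing is renumbered. Alternate
locations are resolved to the highest-occupancy conformer (first wins on a
tie). Hydrogens are kept if present but excluded from the `heavy` selection
preset; all metrics default to heavy or backbone scopes. Modified polymer
residues (trimethyl-lysine: M3L/MLY/MLZ) are treated as chain residues;
ligands and metals remain hetero groups addressed by residue name.
Multi-model PDB is the portable trajectory dialect; binary trajectories can
be read through MDAnalysis when it is available.

## Static perturbation

`local_perturbation` selects the residues whose heavy atoms lie within
10 Å (default) of the mutated residue's heavy atoms, excludes the mutated
residue itself (its side chain differs by construction), and computes the
backbone RMSD plus the mean per-atom displacement over that shell. Both the
local and global scores default to *non-superposed* RMSD: wild-type and
variant models derive from one energy-minimised starting structure and are
already co-registered, so a Kabsch fit would only hide genuine displacement;
`superpose=True` is available when the inputs are independently placed.
A `mask_residues` option drops residues (e.g. homology-rebuilt loops) from
the shell; nothing is masked by default.

Atom pairing between structures matches on (chain, residue number,
insertion code, atom name); at positions where the residue type differs the
side-chain atoms are excluded automatically, so a mutation never produces a
spurious pairing error.

## Solvent-accessible and buried surface

SASA is computed with the Shrake–Rupley construction: each atom's sphere is
inflated by the probe radius (1.4 Å) and sampled with a 960-point
golden-spiral grid; a point survives if no neighbouring inflated sphere
covers it. A point lying exactly on a neighbour's sphere is claimed by the
lower atom index, so coincident duplicate atoms do not double-count. The
bundled radii are C 1.70, N 1.55, O 1.52, S 1.80, H 1.09, Zn 1.39, with a
1.80 Å default for anything else; the table is a plain CSV and fully
overridable, since published surface areas rarely state their radii set.
Polar surface sums N and O atoms (S counts as nonpolar), configurable.

Buried surface between two parts of a complex is
ΔSASA = SASA(A) + SASA(B) − SASA(AB), reported under both the `per_side`
(Δ/2, the default) and `total` conventions because published interface areas
use either without saying so. The identity `total = 2 × per_side` and the
polar + nonpolar decomposition are exact by construction and tested.

## Trajectory metrics

The analysis protocol assumes replicate simulations (10 replicates of 1000
frames at 10 ps in the full-scale design) and uses only the production
window — the last half of the frames — for every statistic, by which point
a relaxing system has typically reached its plateau.

**Drift.** Each frame is Kabsch-superposed onto the replicate's initial
structure and the RMSD recorded; the replicate summary is the median over
the window. **Outlier replicates** are excluded before averaging: replicate
*i* is flagged when |medianᵢ − median of medians| > k · (1.4826·MAD), with
k = 3.5 (the usual modified-z-score cutoff) and at most 2 of 10 removed,
worst first. The raw-MAD variant at k ≈ 2.5 flags ~2σ replicates, which are
not "clear" outliers — with 6–10 replicates it regularly discarded
perfectly typical members of the set — hence the consistency-scaled form.
If every replicate is flagged the set is returned unchanged with a warning.
The variant's drift score is the median of the pooled windowed RMSD across
retained replicates minus the baseline (the mean of the benign-control
sets' statistics by default; a wild-type baseline is a flag away).

**Flexibility.** Frames are superposed over the backbone onto the window
mean (one refinement pass — superpose to frame 0, re-mean, superpose to the
mean), then RMSF per atom is the root-mean-square distance to the atom's
mean position, averaged per residue over its Cα by default (heavy-atom
scope available). Replicate sets average per-replicate profiles over
retained replicates. Five comparison statistics are computed between
wild-type and variant profiles; the headline score is the mean absolute
per-residue difference, which unlike correlations is sensitive to uniform
elevations. Predicted B-factors use B = (8π²/3)·RMSF²; mobility classes use
< 0.7 Å (still) and > 1.0 Å (mobile), boundaries mapping to intermediate.

## Essential dynamics

PCA diagonalises the covariance of the superposed coordinate fluctuations,
Λ = TᵀCT, with eigenvalues sorted descending and each eigenvector's sign
fixed by making its largest-magnitude component positive (outputs are then
reproducible across BLAS implementations). With fewer frames than
coordinates the decomposition is rank-deficient; a warning is emitted but
the leading components are still meaningful. Porcupine vectors average the
eigenvector's per-atom components over each residue and scale by
√eigenvalue, giving an RMS displacement amplitude in Å. The free-energy
landscape is −ln(count/count_max) in kT over a 50×50 histogram of
(PC1, PC2); empty bins are masked, never filled with pseudo-counts, so the
occupied minimum is exactly 0. PCA is fitted on the wild type and variants
are cross-projected; the per-PC shift is the difference of projection
medians plus a histogram overlap coefficient. These shifts are *reported
but not classified* by default: distribution shifts along individual PCs
proved too noisy a verdict source relative to the other layers, so they
serve as supporting evidence only.

## pKa shifts

Tables of per-residue pKa (computed externally at pH 7, or synthetic) are
compared residue-by-residue over the shared titratable set
(ASP/GLU/HIS/LYS/ARG/CYS/TYR). "Both directions" is implemented as
separately reported positive and negative sums whose magnitudes add to the
headline total — the only reading consistent with one signed heatmap plus
one scalar per variant. Residues present in only one table, and always the
mutation site itself, are excluded and listed: a titratable gained or lost
at the site would trivially dominate the total, and the method is after
indirect, environment-mediated effects. The heatmap matrix distinguishes
missing (excluded) entries from true zeros, and orders residues by number
descending. Weak spots are residues with |Δ| above a threshold in at least
a minimum number of variants.

## Interaction energies

Nonbonded energies between disjoint atom groups sum Coulomb and
Lennard-Jones terms per pair within a 12 Å plain-truncation cutoff:
elec = 332.0637·qᵢqⱼ/(ε(r)·r) and vdW = ε_ij[(r_min/r)¹² − 2(r_min/r)⁶],
with geometric-mean well depths and additive r_min/2. The solvent model is
the distance-dependent dielectric ε(r) = D·r with D = 80, which makes the
electrostatics decay as r⁻²; the specification of such models in the
literature is often ambiguous between this and a constant ε = 80, so both
modes exist and D is configurable. The bundled parameter table is a small
set of plausible charges and LJ parameters for backbone atoms, common side
chain tips, Fe²⁺/Zn²⁺, a 2-oxoglutarate analogue and trimethyl-lysine, with
wildcard fallbacks — it is sufficient for deltas and orderings, and no
claim is made that absolute energies reproduce any particular force field.
The scored quantity is the variant-minus-wild-type windowed mean; positive
(weakened binding) beyond τ = 0.5 kcal/mol is destabilizing, negative
beyond −τ stabilizing. In classification the metric enters as
`higher_is_worse`, so stabilizing deltas carry zero badness.

## Classification

Per metric, an orientation maps values to badness: `higher_is_worse` clips
negatives to zero, `magnitude_is_worse` takes |value|. b_max is the largest
benign-control badness; labels are benign (≤ b_max), VUS (≤ 2·b_max),
damaging (beyond). Boundaries are inclusive downward so a benign control
always labels itself benign. A degenerate calibration (b_max below the
floor, default 10⁻⁶ in the metric's units) is replaced by the floor and
logged — for metrics whose benign deltas can be all-negative (energies) a
floor on the scale of the metric's noise is the sensible configuration.
Layers aggregate by worst metric label (a majority mode exists but is not
the default); the overall call is damaging if any layer is damaging, benign
if all layers are benign, otherwise VUS. External columns (folding ΔΔG) and
whole external layers (sequence predictors) join through the same registry.

A property worth knowing: the twice-rule's specificity depends strongly on
the benign panel size. With benign badness behaving as half-normal noise,
the max of only 3 controls is itself noisy, and a null query lands beyond
2·b_max in some layer roughly a quarter of the time under the any-layer
rule; with a 10-control panel the false-positive rate drops to a few
percent. The recovery tests therefore validate the rule's discrimination on
a 10-control panel; applications with 3 controls should read borderline
"damaging" calls in a single layer with care.

## Synthetic generator

The generator emulates the statistical structure the metrics consume, not
the physics. Toy chains place ideal N/CA/C/O backbones with ~3.8 Å Cα
spacing (helix, strand, or seeded smooth coil). Ensembles are
reference + i.i.d. Gaussian noise per coordinate (σ = 0.25–0.3 Å per
coordinate, giving per-residue RMSF ≈ σ√3 ≈ 0.45–0.52 Å, the scale seen in
stable folded domains), optionally plus sinusoidal collective modes along
seeded unit directions confined to residue windows, mean-shift offsets for
static perturbation, σ-multiplier windows for flexibility effects, and
σ-inflated outlier replicates. Because frames are temporally independent,
anything about autocorrelation, convergence, or kinetics is outside what
passing tests demonstrate; distributional metrics (medians, RMSF, PCA,
histograms) are exercised faithfully. Variant effect sizes default to the
ranges reported for real benign and disease variants (drift +8.1–16.4 %
damaging vs +2.7–6.7 % benign; flexibility +12–19.6 % vs +5.7–6.0 %; pKa
weak-spot shifts 0.5–1.5 pH units at three residues vs 0.02 noise), so the
demonstration cohort reproduces the qualitative separation at desk scale:
the pipeline demo runs 10 variants × 6 replicates × 150 frames over a
40-residue chain, and the recovery experiments use 80–500 frames — sizes
chosen so the full suite and the acceptance script each complete in well
under a minute of compute while keeping Monte-Carlo noise far from the
planted effects.

In the score-table generator, benign controls and planted-benign queries
draw half-normal null badness of scale s and planted-damaging queries
receive 6s badness in at least one layer. The multiple 6 is chosen from the
rule's operating characteristic: a query at badness m·s is called damaging
when m·s > 2·b_max, and with 3 controls P(b_max < 3s) ≈ 0.99 at m = 6,
whereas m = 3 would be recovered only ~65 % of the time — by design the
planted effects are clear, as in the real cohort where damaging variants
typically exceed the controls severalfold.

## Known limitations

- No real force-field sampling, solvent, or kinetics; synthetic ensembles
  are temporally uncorrelated by construction.
- Absolute interaction energies and SASA depend on the bundled parameter
  and radii tables; only deltas, decompositions and orderings are claimed.
- The published buried-surface worked example needs the crystal complex
  coordinates (PDB 3AVR), which are not redistributed with the package.
- pKa tables are inputs; nothing here computes pKa from structure.
- Sequence-layer labels are external inputs; no predictor is bundled.
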