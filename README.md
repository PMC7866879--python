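# varimpact

Multi-layer structural and dynamical impact assessment of missense variants.

Sequence-based pathogenicity predictors disagree with each other and miss
variants whose damage is mechanistic rather than evolutionary. This package
implements a complementary, structure-grounded workflow of the kind used to
dissect missense variants in the catalytic domain of the histone demethylase
KDM6A (UTX), where rare substitutions cause Kabuki syndrome: score each
variant at several mechanistic *layers* — static structure perturbation, the
electrostatic environment (pKa shifts), conformational dynamics, and
enzyme–partner interaction energies — calibrate thresholds on variants of
known benign effect, and combine the layers into an overall
benign / VUS / damaging call.

The package consumes inputs that an external molecular-mechanics stack
normally produces (energy-minimised structures, trajectory ensembles,
per-residue pKa tables, folding-energy columns) and provides a synthetic
generator with planted ground truth that stands in for that stack, so the
whole workflow runs and is testable on a laptop.

## The scored quantities

For a variant *v* against the wild type *w*:

- **Local perturbation** — backbone RMSD over the residues within a 10 Å
  shell of the mutation site (site excluded), from energy-minimised
  structures; plus the global backbone RMSD.
- **pKa shift total** — per shared titratable residue,
  Δᵢ = pKaᵥ(i) − pKa_w(i); positive and negative shifts are summed
  separately and the headline score is Σ|Δᵢ|. Titratables lost or gained at
  the mutation site itself are excluded, so only indirect effects count.
- **Structural drift** — per replicate trajectory, the RMSD from the initial
  structure per frame; the variant statistic is the median over the pooled
  production window (last 500 of 1000 frames by default) of the retained
  replicates, scored as the *median difference* from the benign-control
  baseline. Replicates that clearly deviate from their set of 10 are
  excluded first (modified z-score on replicate medians, at most 2 of 10).
- **Flexibility change** — per-residue RMSF about the production-window mean
  structure; the score is mean |RMSF_w − RMSFᵥ| over residues
  (Spearman/Pearson, signed mean difference and absolute residual sum are
  also reported). RMSF converts to a predicted temperature factor via
  B = (8π²/3)·RMSF² for comparison with crystallographic B-factors, and
  residues classify as still (< 0.7 Å), intermediate, or mobile (> 1.0 Å).
- **Essential dynamics** — PCA of the coordinate covariance (Λ = TᵀCT),
  porcupine vectors per residue, free-energy landscapes
  F = −kT·ln(ρ/ρ_max) over (PC1, PC2), and per-PC median shifts of a
  variant's projections (reported, not classified).
- **Interaction energies** — per-frame nonbonded energy between the enzyme
  and a partner group (substrate peptide, methylated lysine, cofactor,
  metal sites): elec = 332.0637·qᵢqⱼ/(ε(r)·r) with a distance-dependent
  dielectric ε(r) = D·r (D = 80 by default), plus a 6-12 Lennard-Jones term;
  scored as the variant-minus-wild-type change in the windowed mean.
- **Classification** — per metric, values map to a non-negative "badness";
  b_max is the worst benign control. Badness ≤ b_max ⇒ benign,
  ≤ 2·b_max ⇒ VUS, beyond ⇒ damaging. A layer takes the worst label of its
  metrics; a variant damaging in *any* layer is damaging overall, one benign
  in *every* layer is benign, anything else is a VUS.

## Worked example

Run the packaged synthetic cohort — 3 benign controls, 2 damaging controls
and 5 query variants with realistic effect sizes (RMSF elevated 12–19.6 %
for damaging variants vs 5.7–6 % for benign ones, pKa weak-spot shifts of
0.5–1.5 pH units, weakened partner charges) — end to end:

```sh
varimpact run --seed 1 --outdir out/
```

prints (abridged):

```
Variant impact ledger
========================================================================
                structure       pka  dynamics substrate_zn   overall              role
benign_ctrl_1      benign    benign    benign       benign    benign    benign_control
benign_ctrl_2      benign    benign    benign       benign    benign    benign_control
benign_ctrl_3      benign    benign    benign       benign    benign    benign_control
damaging_ctrl_1  damaging  damaging  damaging     damaging  damaging  damaging_control
damaging_ctrl_2  damaging  damaging  damaging     damaging  damaging  damaging_control
query_1          damaging  damaging  damaging     damaging  damaging             query
...
Calibration (benign-control b_max; VUS bound = 2 x b_max):
  local_rmsd: b_max=0.01155, vus_bound=0.02309
  pka_total_abs: b_max=0.341, vus_bound=0.6819
  rmsd_median_diff: b_max=0.001749, vus_bound=0.003499
...
Replicate exclusions:
  wild_type/rep6: median RMSD 1.519 Å deviates 0.907 Å from set median 0.612 Å (> 3.5 x MAD 0.013 Å)
```

Reading it: every planted-damaging variant exceeds twice the worst
benign-control score in at least one layer and is called damaging; the
benign controls sit at or below their own calibration by construction; and
the one deliberately σ-inflated replicate per set is caught and excluded
before any averaging. `out/` holds the score table, ledger, pKa heatmap
matrix, calibration record and this report.

Individual stages are available both as library functions
(`varimpact.local_perturbation`, `varimpact.rmsd_score`, `varimpact.pca`,
`varimpact.shift_profile`, `varimpact.build_ledger`, ...) and as
file-oriented subcommands (`simulate-fixtures`, `perturbation`, `dynamics`,
`pca`, `pka-shift`, `energy`, `classify`, `report`), so externally computed
columns — a FoldX-style folding ΔΔG, sequence-predictor labels, real pKa
tables — can be injected at any point.

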