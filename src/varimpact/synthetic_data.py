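"""Synthetic-data generators with known ground truth.

Every input the assessment pipeline consumes can be generated here: toy
backbone structures, Gaussian fluctuation ensembles with planted
region-specific effects and collective modes, replicate sets with inflated
outlier replicates, pKa tables with planted weak-spot shifts, small charged
atom systems with known interaction energies, and score tables emulating the
benign-control calibration design.  All generators are pure functions of
their parameters and a seed.

Default effect sizes follow the study conditions the pipeline is built for:
variant replicate sets elevate RMSF by ~12–19.6% against ~5.7–6.0% for
benign controls, and the RMSD drift by ~8.1–16.4% against ~2.7–6.7%.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_dynamics import Ensemble, ReplicateSet
from .impact_classify import MetricSpec, ScoreTable
from .pka_shift import TITRATABLE, PkaTable
from .structure_io import Atom, ResidueKey, Structure

__all__ = [
    "EnsembleSpec",
    "VariantEffectSpec",
    "make_structure",
    "make_variant_structure",
    "make_ensemble",
    "make_pka_tables",
    "make_interaction_ensembles",
    "make_score_table",
]

#: Residue types cycled along generated chains; includes every titratable
#: type so pKa tables are non-trivial.
_SEQUENCE = (
    "ALA ASP LEU GLU GLY HIS SER LYS VAL ARG "
    "THR CYS ILE TYR ALA GLU PHE LYS ASN ASP"
).split()

#: Canonical model-compound pKa values per titratable type.
CANONICAL_PKA = {
    "ASP": 3.65,
    "GLU": 4.25,
    "HIS": 6.00,
    "LYS": 10.53,
    "ARG": 12.48,
    "CYS": 8.30,
    "TYR": 10.07,
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Conditions of a replicate ensemble: 10 replicates of 1000 frames at
    10 ps by default, per-coordinate Gaussian fluctuations of σ Å."""

    n_residues: int = 40
    geometry: str = "helix"
    sigma: float = 0.3
    modes: tuple[tuple[tuple[int, int], float], ...] = ()  # ((lo, hi), amplitude Å)
    n_frames: int = 1000
    frame_interval: float = 10.0
    n_replicates: int = 10
    n_outliers: int = 0
    outlier_inflation: float = 2.5
    seed: int = 0


@dataclass(frozen=True)
class VariantEffectSpec:
    """Planted effects of one variant, all relative to the wild type."""

    label: str
    site_resseq: int | None = None
    new_resname: str = "ALA"
    rmsf_multiplier: float = 1.0
    rmsf_window: tuple[int, int] | None = None  # None = whole chain
    mean_shift: float = 0.0  # Å, applied in mean_shift_window
    mean_shift_window: tuple[int, int] | None = None
    pka_weak_spots: tuple[tuple[int, float], ...] = ()  # (resseq, Δ)
    charge_scale: float = 1.0  # partner-group charge scaling
    truth: str = "benign"


def _backbone_offsets(tangent: np.ndarray, normal: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "N": -1.2 * tangent + 0.3 * normal,
        "CA": np.zeros(3),
        "C": 1.2 * tangent + 0.3 * normal,
        "O": 1.2 * tangent + 1.5 * normal,
    }


def make_structure(
    n_residues: int = 40,
    geometry: str = "helix",
    seed: int = 0,
    chain: str = "A",
) -> Structure:
    """An ideal toy backbone (N, CA, C, O per residue) with CA–CA spacing of
    ~3.8 Å; ``helix`` winds a canonical helix, ``strand`` extends, ``coil``
    follows a seeded smooth random walk.  Deterministic per seed."""
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    ca = np.zeros((n_residues, 3))
    if geometry == "helix":
        i = np.arange(n_residues)
        theta = np.deg2rad(100.0) * i
        ca[:, 0] = 2.3 * np.cos(theta)
        ca[:, 1] = 2.3 * np.sin(theta)
        ca[:, 2] = 1.5 * i
    elif geometry == "strand":
        i = np.arange(n_residues)
        ca[:, 0] = 3.7947 * i
        ca[:, 1] = 0.2 * (-1.0) ** i
    elif geometry == "coil":
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(1, n_residues):
            direction = direction + 0.4 * rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            ca[i] = ca[i - 1] + 3.8 * direction
    else:
        raise ValueError(f"unknown geometry preset {geometry!r}")
    atoms: list[Atom] = []
    keys: list[ResidueKey] = []
    serial = 1
    for i in range(n_residues):
        lo = ca[max(i - 1, 0)]
        hi = ca[min(i + 1, n_residues - 1)]
        tangent = hi - lo
        tangent /= np.linalg.norm(tangent)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(tangent @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        normal = np.cross(tangent, ref)
        normal /= np.linalg.norm(normal)
        resname = _SEQUENCE[i % len(_SEQUENCE)]
        key = ResidueKey(chain=chain, resseq=i + 1, icode="", resname=resname)
        for name, offset in _backbone_offsets(tangent, normal).items():
            atoms.append(
                Atom(serial=serial, name=name, element=name[0], coords=ca[i] + offset)
            )
            keys.append(key)
            serial += 1
    return Structure(atoms, keys, title=f"synthetic {geometry} chain")


def _window_mask(structure: Structure, window: tuple[int, int] | None) -> np.ndarray:
    if window is None:
        return np.ones(len(structure), dtype=bool)
    lo, hi = window
    return np.array([lo <= k.resseq <= hi for k in structure.residue_keys])


def make_variant_structure(wt: Structure, effect: VariantEffectSpec) -> Structure:
    """The variant's energy-minimised-structure analogue: the wild-type
    backbone with the planted mean shift applied in its window and the
    residue type replaced at the mutation site."""
    coords = wt.coords.copy()
    if effect.mean_shift:
        mask = _window_mask(wt, effect.mean_shift_window)
        coords[mask] += np.array([effect.mean_shift, 0.0, 0.0])
    out = wt.with_coords(coords)
    if effect.site_resseq is not None:
        new_keys = []
        for key in out.residue_keys:
            if key.resseq == effect.site_resseq:
                key = ResidueKey(key.chain, key.resseq, key.icode, effect.new_resname)
            new_keys.append(key)
        out.residue_keys = new_keys
    out.title = f"synthetic variant {effect.label}"
    return out


def _mode_direction(n_atoms: int, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    direction = np.zeros((n_atoms, 3))
    direction[mask] = rng.standard_normal((int(mask.sum()), 3))
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("planted mode window selects no atoms")
    return direction / norm


def make_ensemble(
    structure: Structure,
    spec: EnsembleSpec,
    effect: VariantEffectSpec | None = None,
) -> ReplicateSet:
    """A replicate set of Gaussian fluctuation ensembles around the (variant-
    shifted) reference, with planted collective modes and outlier replicates.

    Frames are reference + i.i.d. Gaussian noise (σ per coordinate, scaled by
    the variant's multiplier inside its window) + sinusoidal collective modes
    along seeded unit directions.  The last ``n_outliers`` replicates get σ
    inflated by ``outlier_inflation``.  The ground-truth record is attached
    to the returned set as ``truth``.
    """
    label = effect.label if effect is not None else "wild_type"
    base = structure if effect is None else make_variant_structure(structure, effect)
    ref = base.coords
    n_atoms = ref.shape[0]
    sigma = np.full(n_atoms, float(spec.sigma))
    if effect is not None and effect.rmsf_multiplier != 1.0:
        mask = _window_mask(base, effect.rmsf_window)
        sigma[mask] *= effect.rmsf_multiplier
    root = np.random.default_rng(spec.seed)
    mode_dirs = [
        _mode_direction(n_atoms, _window_mask(base, window), root)
        for window, _ in spec.modes
    ]
    ensembles = []
    outlier_ids = []
    for rep in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, rep, zlib.crc32(label.encode())])
        rep_sigma = sigma.copy()
        rep_id = f"rep{rep + 1}"
        if rep >= spec.n_replicates - spec.n_outliers:
            rep_sigma = rep_sigma * spec.outlier_inflation
            outlier_ids.append(rep_id)
        noise = rng.standard_normal((spec.n_frames, n_atoms, 3)) * rep_sigma[None, :, None]
        frames = ref[None, :, :] + noise
        for (window, amplitude), direction in zip(spec.modes, mode_dirs):
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(spec.n_frames)
            coeff = amplitude * np.sin(2 * np.pi * t / max(spec.n_frames / 3, 2) + phase)
            frames = frames + coeff[:, None, None] * direction[None, :, :]
        ensembles.append(
            Ensemble(
                frames,
                base,
                frame_interval=spec.frame_interval,
                replicate_id=rep_id,
                label=label,
            )
        )
    window = slice(spec.n_frames // 2, spec.n_frames)
    rset = ReplicateSet(ensembles, production_window=window, label=label)
    rset.truth = {
        "sigma": float(spec.sigma),
        "outlier_replicates": outlier_ids,
        "label": label,
        "effect": effect,
    }
    return rset


def titratable_residues(structure: Structure) -> list[ResidueKey]:
    return [k for k in structure.residues() if k.resname in TITRATABLE]


def make_pka_tables(
    structure: Structure,
    effects: list[VariantEffectSpec],
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[PkaTable, dict[str, PkaTable]]:
    """Wild-type and per-variant pKa tables over the structure's titratable
    residues.  The wild type takes canonical model-compound values; every
    variant adds N(0, noise_sd²) scatter; variants with planted weak spots
    additionally shift those residues by their stated Δ."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    residues = titratable_residues(structure)
    if not residues:
        raise ValueError("structure has no titratable residues")
    wt = PkaTable(
        {k: CANONICAL_PKA[k.resname] for k in residues}, provenance="synthetic"
    )
    tables: dict[str, PkaTable] = {}
    for i, effect in enumerate(effects):
        rng = np.random.default_rng([seed, i])
        values = {
            k: v + rng.normal(0.0, noise_sd) if noise_sd > 0 else v
            for k, v in wt.values.items()
        }
        planted = dict(effect.pka_weak_spots)
        for key in list(values):
            if key.resseq in planted:
                values[key] += planted[key.resseq]
        # the mutation site loses/gains its titratable group
        if effect.site_resseq is not None:
            values = {k: v for k, v in values.items() if k.resseq != effect.site_resseq}
            if effect.new_resname in TITRATABLE:
                site = ResidueKey(
                    residues[0].chain, effect.site_resseq, "", effect.new_resname
                )
                values[site] = CANONICAL_PKA[effect.new_resname]
        if not values:
            raise ValueError("variant table would be empty")
        tables[effect.label] = PkaTable(values, provenance="synthetic")
    return wt, tables


def make_interaction_ensembles(
    effects: list[VariantEffectSpec],
    n_frames: int = 100,
    jitter: float = 0.02,
    seed: int = 0,
):
    """A minimal enzyme/partner two-group system with known energies.

    Group A ("enzyme", chain E) and group B ("partner", chain P) each hold a
    few charged LJ atoms ~4 Å apart.  A variant scales the partner-facing
    charges by its ``charge_scale``, so weakened (scale < 1) binding gives a
    positive, destabilizing interaction-energy delta by construction.
    Returns (ensembles by label, group selections, params builder).
    """
    from .energetics import NonbondedParams
    from .structure_io import Selection

    # closest cross-group pair sits at the LJ minimum (r = 4.0 = rmin sum)
    # and the charge pattern is net attractive, so the reference complex is
    # bound (total < 0) and scaling the partner charges down weakens it
    positions_a = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]])
    positions_b = np.array([[5.5, 0.0, 0.0], [7.0, 0.0, 0.0], [5.5, 1.5, 0.0]])

    def build(charge_scale: float = 1.0) -> NonbondedParams:
        table = {
            ("ENZ", "Q1"): (-1.0, 0.12, 1.7),
            ("ENZ", "Q2"): (-0.6, 0.10, 2.0),
            ("ENZ", "Q3"): (0.5, 0.10, 2.0),
            ("PRT", "P1"): (1.0 * charge_scale, 0.12, 1.7),
            ("PRT", "P2"): (0.7 * charge_scale, 0.10, 2.0),
            ("PRT", "P3"): (-0.4 * charge_scale, 0.10, 2.0),
        }
        return NonbondedParams(table=table)

    atoms, keys = [], []
    for i, pos in enumerate(positions_a):
        atoms.append(Atom(serial=i + 1, name=f"Q{i + 1}", element="O", coords=pos))
        keys.append(ResidueKey("E", 1, "", "ENZ"))
    for i, pos in enumerate(positions_b):
        atoms.append(Atom(serial=i + 4, name=f"P{i + 1}", element="N", coords=pos))
        keys.append(ResidueKey("P", 1, "", "PRT"))
    template = Structure(atoms, keys)
    ref = template.coords

    ensembles = {}
    specs = [VariantEffectSpec(label="wild_type")] + list(effects)
    for i, effect in enumerate(specs):
        rng = np.random.default_rng([seed, i])
        frames = ref[None, :, :] + rng.standard_normal((n_frames, ref.shape[0], 3)) * jitter
        ensembles[effect.label] = (
            Ensemble(frames, template, replicate_id="rep1", label=effect.label),
            build(effect.charge_scale),
        )
    group_a = Selection(chains=frozenset({"E"}), atom_names=None)
    group_b = Selection(chains=frozenset({"P"}), atom_names=None)
    return ensembles, group_a, group_b


def make_score_table(
    n_benign: int = 3,
    n_damaging: int = 5,
    benign_scale: float = 1.0,
    damaging_multiple: float = 6.0,
    layers: tuple[str, ...] = ("structure", "pka", "dynamics"),
    seed: int = 0,
    n_benign_queries: int = 0,
    metrics_per_layer: int = 2,
) -> tuple[ScoreTable, dict[str, str]]:
    """A score table emulating the control-calibrated design: benign controls
    (and planted-benign queries) draw half-normal null badness of scale
    ``benign_scale``; each planted-damaging query gets badness
    ``damaging_multiple × benign_scale`` in at least one randomly chosen
    layer and null badness elsewhere.  Returns (table, truth labels)."""
    if n_benign < 1:
        raise ValueError("need at least one benign control")
    rng = np.random.default_rng(seed)
    metric_names = []
    metrics: dict[str, MetricSpec] = {}
    for layer in layers:
        count = 1 if layer == "pka" else metrics_per_layer
        for j in range(count):
            name = f"{layer}_m{j + 1}"
            metric_names.append(name)
            metrics[name] = MetricSpec(layer=layer, orientation="higher_is_worse")
    rows, roles, truth = {}, {}, {}

    def null_row():
        return np.abs(rng.normal(0.0, benign_scale, size=len(metric_names)))

    for i in range(n_benign):
        name = f"benign_ctrl_{i + 1}"
        rows[name] = null_row()
        roles[name] = "benign_control"
        truth[name] = "benign"
    for i in range(n_benign_queries):
        name = f"benign_query_{i + 1}"
        rows[name] = null_row()
        roles[name] = "query"
        truth[name] = "benign"
    for i in range(n_damaging):
        name = f"damaging_query_{i + 1}"
        row = null_row()
        layer = layers[rng.integers(len(layers))]
        for m, metric in enumerate(metric_names):
            if metrics[metric].layer == layer:
                row[m] = damaging_multiple * benign_scale
        rows[name] = row
        roles[name] = "query"
        truth[name] = "damaging"
    values = pd.DataFrame.from_dict(rows, orient="index", columns=metric_names)
    return ScoreTable(values=values, metrics=metrics, roles=roles), truth
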