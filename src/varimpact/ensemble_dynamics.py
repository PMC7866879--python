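"""Trajectory-ensemble metrics: RMSD drift, per-residue RMSF, replicate
outlier exclusion and the comparison statistics used for variant scoring.

The analysis protocol mirrors a replicate-simulation design: each variant is
sampled by several independent replicates recorded at a fixed frame interval;
only the production window (by default the last half of the frames, once the
system has relaxed) enters any statistic; replicates whose RMSD drift clearly
deviates from the rest of their set are excluded before averaging; and
variant impact is scored against benign-control baselines via the median
RMSD difference and the mean absolute per-residue RMSF difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .geometry import kabsch
from .structure_io import ResidueKey, Selection, Structure, read_pdb

__all__ = [
    "Ensemble",
    "ReplicateSet",
    "RmsfProfile",
    "ensemble_from_structures",
    "load_ensemble",
    "rmsd_series",
    "median_rmsd",
    "exclude_outlier_replicates",
    "rmsd_score",
    "rmsf",
    "rmsf_compare",
    "bfactor_agreement",
    "classify_mobility",
]

BOLTZMANN_B_FACTOR = 8.0 * np.pi**2 / 3.0  # B = (8π²/3)·RMSF²


@dataclass
class Ensemble:
    """A stack of frames over a fixed atom selection.

    ``template`` carries atom metadata (names, residues) for selections;
    ``frames`` is an F x N x 3 coordinate array in Å.
    """

    frames: np.ndarray
    template: Structure
    frame_interval: float = 10.0  # ps
    replicate_id: str = "rep1"
    label: str = "wild_type"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be F x N x 3")
        if self.frames.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if self.frames.shape[1] != len(self.template):
            raise ValueError("frame atom count does not match template")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def atom_index(self) -> list[tuple[ResidueKey, str]]:
        return [(key, atom.name) for key, atom in self.template]

    def indices(self, selection: Selection | None) -> np.ndarray:
        if selection is None:
            return np.arange(len(self.template))
        return np.asarray(selection.indices(self.template), dtype=int)

    def frame_structure(self, i: int) -> Structure:
        return self.template.with_coords(self.frames[i])


@dataclass
class ReplicateSet:
    """Replicate ensembles of one system plus the production window and the
    record of excluded replicates."""

    ensembles: list[Ensemble]
    production_window: slice | None = None
    excluded: dict[str, str] = field(default_factory=dict)
    label: str = "wild_type"

    def __post_init__(self) -> None:
        if not self.ensembles:
            raise ValueError("empty replicate set")
        n = self.ensembles[0].frames.shape[1]
        if any(e.frames.shape[1] != n for e in self.ensembles):
            raise ValueError("replicates must share the atom space")
        if self.production_window is None:
            f = self.ensembles[0].n_frames
            self.production_window = slice(f // 2, f)

    @property
    def retained(self) -> list[Ensemble]:
        return [e for e in self.ensembles if e.replicate_id not in self.excluded]


@dataclass
class RmsfProfile:
    """Per-residue RMSF in Å, keyed by residue."""

    values: dict[ResidueKey, float]
    atom_scope: str = "calpha"
    label: str = ""

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values.values()):
            raise ValueError("RMSF values must be non-negative")

    def by_position(self) -> dict[tuple, float]:
        return {key.position: v for key, v in self.values.items()}

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()))


def ensemble_from_structures(
    structures: list[Structure],
    frame_interval: float = 10.0,
    replicate_id: str = "rep1",
    label: str = "wild_type",
) -> Ensemble:
    """Build an Ensemble from the models of a multi-model PDB."""
    if len(structures) < 2:
        raise ValueError("need at least 2 models")
    template = structures[0]
    frames = np.stack([s.coords for s in structures])
    return Ensemble(frames, template, frame_interval, replicate_id, label)


def load_ensemble(path: str | Path, **kw) -> Ensemble:
    """Read a multi-model PDB as an Ensemble."""
    return ensemble_from_structures(read_pdb(path, model_policy="all"), **kw)


def load_trajectory(topology: str | Path, trajectory: str | Path, **kw) -> Ensemble:
    """Read a binary trajectory (DCD/XTC/...) with a PDB topology via
    MDAnalysis; heavy atoms only, in topology order."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    sel = u.select_atoms("not name H*")
    template = read_pdb(topology)
    frames = np.stack([sel.positions.copy() for _ in u.trajectory])
    heavy = [i for i, (_, a) in enumerate(template) if not a.is_hydrogen]
    template = Structure(
        [template.atoms[i] for i in heavy], [template.residue_keys[i] for i in heavy]
    )
    return Ensemble(frames, template, **kw)


# ---------------------------------------------------------------------------
# RMSD drift
# ---------------------------------------------------------------------------


def rmsd_series(
    ensemble: Ensemble,
    reference: Structure | None = None,
    selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) from the reference (frame 0 by default), each frame
    Kabsch-superposed onto the reference over the selection first."""
    idx = ensemble.indices(selection)
    if idx.size == 0:
        raise ValueError("selection resolves to no atoms in the ensemble")
    if reference is None:
        ref_coords = ensemble.frames[0][idx]
    else:
        if len(reference) != len(ensemble.template):
            raise ValueError("reference atom count does not match ensemble")
        ref_coords = reference.coords[idx]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        out[f] = kabsch(ensemble.frames[f][idx], ref_coords).rmsd
    return out


def median_rmsd(series: np.ndarray, production_window: slice | None = None) -> float:
    series = np.asarray(series, dtype=float)
    window = series[production_window] if production_window is not None else series
    if window.size == 0:
        raise ValueError("empty production window")
    return float(np.median(window))


def _replicate_medians(
    replicate_set: ReplicateSet, selection: Selection | None = None
) -> dict[str, float]:
    out = {}
    for ens in replicate_set.ensembles:
        series = rmsd_series(ens, selection=selection)
        out[ens.replicate_id] = median_rmsd(series, replicate_set.production_window)
    return out


def exclude_outlier_replicates(
    replicate_set: ReplicateSet,
    k: float = 3.5,
    max_excluded: int = 2,
    selection: Selection | None = None,
) -> ReplicateSet:
    """Flag replicates whose production-window median RMSD clearly deviates
    from the rest of the set, removing at most ``max_excluded`` (worst
    first).  A replicate is flagged when |median_i − median of medians|
    exceeds k times the consistency-scaled MAD (1.4826·MAD, the robust
    normal-sd estimate); k = 3.5 is the usual modified-z-score cutoff, so
    only genuinely deviant replicates are dropped.  If every replicate is
    flagged the set is returned unchanged with a warning recorded."""
    if len(replicate_set.ensembles) < 3:
        raise ValueError("need at least 3 replicates for outlier detection")
    medians = _replicate_medians(replicate_set, selection)
    values = np.array(list(medians.values()))
    center = np.median(values)
    mad = 1.4826 * np.median(np.abs(values - center))
    deviations = {rid: abs(v - center) for rid, v in medians.items()}
    flagged = sorted(
        (rid for rid, d in deviations.items() if d > k * mad),
        key=lambda rid: -deviations[rid],
    )
    result = ReplicateSet(
        ensembles=list(replicate_set.ensembles),
        production_window=replicate_set.production_window,
        excluded=dict(replicate_set.excluded),
        label=replicate_set.label,
    )
    if len(flagged) == len(medians):
        result.excluded["__warning__"] = (
            "all replicates flagged as outliers; exclusion refused"
        )
        return result
    for rid in flagged[:max_excluded]:
        result.excluded[rid] = (
            f"median RMSD {medians[rid]:.3f} Å deviates {deviations[rid]:.3f} Å "
            f"from set median {center:.3f} Å (> {k} x MAD {mad:.3f} Å)"
        )
    return result


def _pooled_median(
    replicate_set: ReplicateSet, selection: Selection | None = None
) -> float:
    pooled = []
    for ens in replicate_set.retained:
        series = rmsd_series(ens, selection=selection)
        pooled.append(series[replicate_set.production_window])
    if not pooled:
        raise ValueError("no retained replicates")
    return float(np.median(np.concatenate(pooled)))


def rmsd_score(
    variant_set: ReplicateSet,
    baseline_sets: list[ReplicateSet],
    selection: Selection | None = None,
) -> dict:
    """Median-difference RMSD score of a variant against a baseline.

    The variant statistic is the median of the pooled production-window RMSD
    across retained replicates; the baseline is the mean of the baseline
    sets' statistics (typically the benign controls).  Outlier exclusion is
    assumed to have been applied already.
    """
    if not baseline_sets:
        raise ValueError("empty baseline")
    variant_stat = _pooled_median(variant_set, selection)
    baseline_stats = [_pooled_median(b, selection) for b in baseline_sets]
    baseline = float(np.mean(baseline_stats))
    diff = variant_stat - baseline
    return {
        "variant_median": variant_stat,
        "baseline_median": baseline,
        "median_diff": diff,
        "percent_change": 100.0 * diff / baseline if baseline else float("nan"),
    }


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


def _superpose_to_mean(
    frames: np.ndarray, fit_idx: np.ndarray, iterations: int = 1
) -> np.ndarray:
    """Superpose frames over fit_idx onto frame 0, then once (iterated) onto
    the running mean structure; returns superposed copies of all atoms."""
    out = frames.copy()
    ref = out[0][fit_idx]
    for f in range(out.shape[0]):
        sup = kabsch(out[f][fit_idx], ref)
        out[f] = sup.apply(out[f])
    for _ in range(iterations):
        mean = out[:, fit_idx, :].mean(axis=0)
        for f in range(out.shape[0]):
            sup = kabsch(out[f][fit_idx], mean)
            out[f] = sup.apply(out[f])
    return out


def _rmsf_single(
    ensemble: Ensemble,
    window: slice,
    selection: Selection,
    fit_selection: Selection,
) -> dict[ResidueKey, float]:
    sel_idx = ensemble.indices(selection)
    fit_idx = ensemble.indices(fit_selection)
    if sel_idx.size == 0 or fit_idx.size == 0:
        raise ValueError("empty selection for RMSF")
    frames = ensemble.frames[window]
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames in the production window")
    fitted = _superpose_to_mean(frames, fit_idx)
    mean = fitted.mean(axis=0)
    sq = ((fitted - mean) ** 2).sum(axis=2)  # F x N squared distance to mean
    atom_rmsf = np.sqrt(sq.mean(axis=0))
    per_residue: dict[ResidueKey, list[float]] = {}
    keys = ensemble.template.residue_keys
    for i in sel_idx:
        per_residue.setdefault(keys[i], []).append(atom_rmsf[i])
    return {key: float(np.mean(v)) for key, v in per_residue.items()}


def rmsf(
    ensemble_or_set: Ensemble | ReplicateSet,
    selection: Selection | None = None,
    fit_selection: Selection | None = None,
    production_window: slice | None = None,
) -> RmsfProfile:
    """Per-residue RMSF (Å) about the mean structure of the production
    window.  Frames are superposed onto the window-mean structure over the
    fit selection (backbone, one refinement pass); the per-residue value is
    the mean over the residue's selected atoms (Cα by default).  For a
    replicate set, per-replicate profiles over retained replicates are
    averaged."""
    selection = selection if selection is not None else Selection.calpha()
    fit_selection = fit_selection if fit_selection is not None else Selection.backbone()
    if isinstance(ensemble_or_set, ReplicateSet):
        rset = ensemble_or_set
        window = rset.production_window
        profiles = [
            _rmsf_single(e, window, selection, fit_selection) for e in rset.retained
        ]
        if not profiles:
            raise ValueError("no retained replicates")
        keys = profiles[0].keys()
        values = {
            key: float(np.mean([p[key] for p in profiles])) for key in keys
        }
        scope = selection.atom_names if isinstance(selection.atom_names, str) else "custom"
        return RmsfProfile(values, atom_scope=scope, label=rset.label)
    ens = ensemble_or_set
    window = (
        production_window
        if production_window is not None
        else slice(0, ens.n_frames)
    )
    values = _rmsf_single(ens, window, selection, fit_selection)
    scope = selection.atom_names if isinstance(selection.atom_names, str) else "custom"
    return RmsfProfile(values, atom_scope=scope, label=ens.label)


def rmsf_compare(wt: RmsfProfile, variant: RmsfProfile) -> dict:
    """All candidate flexibility-comparison metrics between two profiles.

    The headline score is ``avg_abs_diff`` — the mean over residues of
    |RMSF_wt − RMSF_variant| — selected over Spearman/Pearson correlation,
    average (signed, wt − variant) difference and the absolute residual sum.
    ``percent_elevation`` is the relative change of the mean RMSF.
    """
    wt_map = wt.by_position()
    var_map = variant.by_position()
    shared = [p for p in wt_map if p in var_map]
    if not shared:
        raise ValueError("no shared residues")
    a = np.array([wt_map[p] for p in shared])
    b = np.array([var_map[p] for p in shared])
    diff = a - b
    out = {
        "avg_abs_diff": float(np.mean(np.abs(diff))),
        "avg_diff": float(np.mean(diff)),
        "abs_residual_sum": float(np.sum(np.abs(diff))),
        "percent_elevation": (
            100.0 * (b.mean() - a.mean()) / a.mean() if a.mean() else float("nan")
        ),
        "n_shared": len(shared),
    }
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues for correlation metrics")
    out["pearson"] = float(stats.pearsonr(a, b).statistic)
    out["spearman"] = float(stats.spearmanr(a, b).statistic)
    return out


def bfactor_agreement(profile: RmsfProfile, structure: Structure) -> dict:
    """Agreement between simulated flexibility and crystallographic
    temperature factors: predicted B = (8π²/3)·RMSF², correlated against the
    per-residue mean of the crystal B-factors."""
    prof = profile.by_position()
    crystal: dict[tuple, list[float]] = {}
    for key, atom in structure:
        if key.position in prof and not atom.is_hetero:
            crystal.setdefault(key.position, []).append(atom.b_factor)
    shared = sorted(crystal.keys() & prof.keys())
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues")
    rmsf_vals = np.array([prof[p] for p in shared])
    predicted_b = BOLTZMANN_B_FACTOR * rmsf_vals**2
    observed_b = np.array([np.mean(crystal[p]) for p in shared])
    if np.allclose(predicted_b, 0):
        raise ValueError("all-zero RMSF profile: correlation undefined")
    return {
        "pearson": float(stats.pearsonr(predicted_b, observed_b).statistic),
        "spearman": float(stats.spearmanr(predicted_b, observed_b).statistic),
        "predicted_b": dict(zip(shared, predicted_b.tolist())),
    }


def classify_mobility(
    profile: RmsfProfile, still_cut: float = 0.7, mobile_cut: float = 1.0
) -> dict[ResidueKey, str]:
    """Label residues still (< 0.7 Å), mobile (> 1.0 Å) or intermediate;
    boundary values map to intermediate."""
    out = {}
    for key, value in profile.values.items():
        if value < still_cut:
            out[key] = "still"
        elif value > mobile_cut:
            out[key] = "mobile"
        else:
            out[key] = "intermediate"
    return out
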