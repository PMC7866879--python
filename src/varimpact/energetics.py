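"""Nonbonded (van der Waals + electrostatic) interaction energies between an
enzyme and named partner groups, per frame over a trajectory.

The electrostatic term uses an implicit solvent model with a
distance-dependent dielectric, ε(r) = D·r (default D = 80); a constant
dielectric ε = D is also available.  The Lennard-Jones term uses the
ε/r_min parameterisation with geometric-mean well depths and additive
r_min/2 combination.  Absolute energies from the small bundled parameter
table are not claimed to reproduce any particular force field's values;
variant-minus-wild-type deltas and their signs are the scored quantities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .ensemble_dynamics import Ensemble
from .structure_io import Selection, Structure

__all__ = [
    "NonbondedParams",
    "InteractionSeries",
    "pair_energy",
    "group_energy",
    "interaction_series",
    "interaction_delta",
    "load_params",
]

COULOMB_CONSTANT = 332.0637  # kcal·Å/(mol·e²)


@dataclass
class NonbondedParams:
    """Per-atom charges and LJ parameters keyed by (resname, atom name); a
    ``*`` resname row matches any residue and a (``*``, ``*``) row is the
    global fallback."""

    table: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )
    dielectric_model: str = "distance_dependent"
    dielectric_factor: float = 80.0
    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.dielectric_model not in {"distance_dependent", "constant"}:
            raise ValueError("dielectric_model must be distance_dependent|constant")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for key, (_, eps, rmin_half) in self.table.items():
            if eps < 0 or rmin_half <= 0:
                raise ValueError(f"invalid LJ parameters for {key}")

    def lookup(self, resname: str, atom_name: str) -> tuple[float, float, float]:
        for key in ((resname, atom_name), ("*", atom_name), (resname, "*"), ("*", "*")):
            if key in self.table:
                return self.table[key]
        raise KeyError(f"no nonbonded parameters for ({resname}, {atom_name})")


def load_params(path: str | Path | None = None, **overrides) -> NonbondedParams:
    """Load a parameter table (bundled defaults when ``path`` is None)."""
    if path is None:
        text = resources.files("varimpact.data").joinpath("nonbonded.csv").read_text()
    else:
        text = Path(path).read_text()
    table = {}
    for row in csv.DictReader(text.splitlines()):
        table[(row["resname"], row["atom"])] = (
            float(row["charge"]),
            float(row["epsilon"]),
            float(row["rmin_half"]),
        )
    return NonbondedParams(table=table, **overrides)


@dataclass
class InteractionSeries:
    elec: np.ndarray  # kcal/mol per frame
    vdw: np.ndarray
    partner: str = "custom"
    production_window: slice | None = None

    @property
    def total(self) -> np.ndarray:
        return self.elec + self.vdw

    def windowed(self) -> np.ndarray:
        if self.production_window is None:
            return self.total
        return self.total[self.production_window]

    @property
    def mean(self) -> float:
        return float(self.windowed().mean())

    @property
    def sd(self) -> float:
        return float(self.windowed().std(ddof=1)) if self.windowed().size > 1 else 0.0


def _dielectric(r: np.ndarray, params: NonbondedParams) -> np.ndarray:
    if params.dielectric_model == "distance_dependent":
        return params.dielectric_factor * r
    return np.full_like(r, params.dielectric_factor)


def pair_energy(
    atom_i: tuple[str, str],
    atom_j: tuple[str, str],
    r: float,
    params: NonbondedParams,
) -> dict:
    """Electrostatic + LJ energy (kcal/mol) of one atom pair at distance
    ``r`` Å.  Atoms are (resname, atom name) keys into the parameter table.

    elec = 332.0637·qᵢqⱼ/(ε(r)·r); vdW = ε_ij[(r_min/r)¹² − 2(r_min/r)⁶]
    with ε_ij the geometric mean and r_min,ij the sum of r_min/2 halves.
    Both terms are zero beyond the cutoff.
    """
    if r <= 0:
        raise ValueError("zero or negative interatomic distance")
    qi, eps_i, rh_i = params.lookup(*atom_i)
    qj, eps_j, rh_j = params.lookup(*atom_j)
    if r > params.cutoff:
        return {"elec": 0.0, "vdw": 0.0}
    eps_r = float(_dielectric(np.asarray(r, dtype=float), params))
    elec = COULOMB_CONSTANT * qi * qj / (eps_r * r)
    eps_ij = np.sqrt(eps_i * eps_j)
    rmin = rh_i + rh_j
    ratio6 = (rmin / r) ** 6
    vdw = eps_ij * (ratio6**2 - 2.0 * ratio6)
    return {"elec": float(elec), "vdw": float(vdw)}


def _group_params(
    structure: Structure, selection: Selection, params: NonbondedParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[int]]:
    idx = selection.indices(structure)
    q = np.empty(len(idx))
    eps = np.empty(len(idx))
    rh = np.empty(len(idx))
    coords = np.empty((len(idx), 3))
    for n, i in enumerate(idx):
        key = structure.residue_keys[i]
        atom = structure.atoms[i]
        q[n], eps[n], rh[n] = params.lookup(key.resname, atom.name)
        coords[n] = atom.coords
    return coords, q, eps, rh, idx


def _energy_from_arrays(ca, qa, ea, ra, cb, qb, eb, rb, params) -> tuple[float, float]:
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    if np.any(d == 0):
        raise ValueError("coincident atoms between groups (r = 0)")
    within = d <= params.cutoff
    if not np.any(within):
        return 0.0, 0.0
    eps_r = _dielectric(d, params)
    elec = COULOMB_CONSTANT * np.outer(qa, qb) / (eps_r * d)
    rmin = ra[:, None] + rb[None, :]
    ratio6 = (rmin / d) ** 6
    vdw = np.sqrt(np.outer(ea, eb)) * (ratio6**2 - 2.0 * ratio6)
    return float(elec[within].sum()), float(vdw[within].sum())


def group_energy(
    structure: Structure,
    group_a: Selection,
    group_b: Selection,
    params: NonbondedParams,
) -> dict:
    """Sum of pair energies over the a x b atom pairs within the cutoff;
    symmetric in its group arguments."""
    ca, qa, ea, ra, idx_a = _group_params(structure, group_a, params)
    cb, qb, eb, rb, idx_b = _group_params(structure, group_b, params)
    if set(idx_a) & set(idx_b):
        raise ValueError("groups overlap")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty group selection")
    elec, vdw = _energy_from_arrays(ca, qa, ea, ra, cb, qb, eb, rb, params)
    return {"elec": elec, "vdw": vdw, "total": elec + vdw}


def interaction_series(
    ensemble: Ensemble,
    group_a: Selection,
    group_b: Selection,
    params: NonbondedParams,
    production_window: slice | None = None,
    partner: str = "custom",
) -> InteractionSeries:
    """Per-frame group interaction energy over a trajectory, with the
    production-window mean/s.d. exposed on the result."""
    template = ensemble.template
    _, qa, ea, ra, idx_a = _group_params(template, group_a, params)
    _, qb, eb, rb, idx_b = _group_params(template, group_b, params)
    if set(idx_a) & set(idx_b):
        raise ValueError("groups overlap")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty group selection")
    idx_a = np.asarray(idx_a)
    idx_b = np.asarray(idx_b)
    elec = np.empty(ensemble.n_frames)
    vdw = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        elec[f], vdw[f] = _energy_from_arrays(
            ensemble.frames[f][idx_a], qa, ea, ra,
            ensemble.frames[f][idx_b], qb, eb, rb,
            params,
        )
    if production_window is None:
        production_window = slice(ensemble.n_frames // 2, ensemble.n_frames)
    return InteractionSeries(elec, vdw, partner, production_window)


def interaction_delta(
    variant_series: InteractionSeries,
    wt_series: InteractionSeries,
    tau: float = 0.5,
) -> dict:
    """Variant-minus-wild-type change in mean interaction energy.

    A positive delta (weaker binding) beyond +τ kcal/mol is destabilizing, a
    delta below −τ stabilizing, anything in between (boundaries included)
    neutral.
    """
    if variant_series.partner != wt_series.partner:
        raise ValueError(
            f"partner mismatch: {variant_series.partner} vs {wt_series.partner}"
        )
    delta = variant_series.mean - wt_series.mean
    if delta > tau:
        direction = "destabilizing"
    elif delta < -tau:
        direction = "stabilizing"
    else:
        direction = "neutral"
    return {"delta_mean": delta, "direction": direction, "partner": wt_series.partner}
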