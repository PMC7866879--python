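"""Rigid-body superposition, structural-perturbation scores and solvent
accessible / buried surface area.

The perturbation scores quantify how far a variant's energy-minimised
structure departs from the wild type: globally over all backbone atoms, and
locally over the residues within a 10 Å shell of the mutation site.  Both
structures derive from one common starting model, so they are already
co-registered and the default is a direct (non-superposed) RMSD; a flag
enables Kabsch superposition first.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    BACKBONE_NAMES,
    ResidueKey,
    Selection,
    Structure,
    residues_within,
)

__all__ = [
    "SuperpositionResult",
    "SasaReport",
    "kabsch",
    "rmsd_between",
    "match_atoms",
    "local_perturbation",
    "sasa",
    "buried_surface",
    "load_radii",
]

#: Elements counted as polar in surface decompositions (S is nonpolar here,
#: matching the common convention; override via the ``polar_elements``
#: arguments).
POLAR_ELEMENTS = frozenset({"N", "O"})


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the rotation/translation minimising the RMSD, with the reflection
    corrected via the sign of the smallest singular value so that
    det(rotation) = +1.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N x 3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    h = mob_c.T @ ref_c
    if np.linalg.matrix_rank(h) < 2:
        raise ValueError("degenerate geometry: points are (near-)collinear")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = mob_c @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref_c) ** 2, axis=1))))
    translation = reference.mean(axis=0) - mobile.mean(axis=0) @ rot.T
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def match_atoms(
    struct_a: Structure,
    struct_b: Structure,
    selection: Selection | None = None,
) -> tuple[np.ndarray, np.ndarray, list[tuple[ResidueKey, str]]]:
    """Pair atoms between two structures by (chain, resseq, icode, atom name).

    Residues whose type differs between the structures (mutated residues)
    contribute only backbone atoms, so a variant side chain never produces a
    spurious mismatch.  Returns (coords_a, coords_b, matched_labels).
    """
    def collect(struct: Structure) -> dict[tuple, tuple[str, np.ndarray]]:
        out = {}
        for key, atom in struct:
            if selection is not None and not selection.matches(key, atom):
                continue
            out[(key.position, atom.name)] = (key.resname, atom.coords)
        return out

    map_a = collect(struct_a)
    map_b = collect(struct_b)
    pos_resname_b = {key.position: key.resname for key, _ in struct_b}
    coords_a, coords_b, labels = [], [], []
    unmatched = []
    for slot, (resname_a, ca) in map_a.items():
        if slot not in map_b:
            # a side-chain atom of a mutated residue is absent by construction
            if pos_resname_b.get(slot[0], resname_a) != resname_a and slot[1] not in BACKBONE_NAMES:
                continue
            unmatched.append(slot)
            continue
        resname_b, cb = map_b[slot]
        if resname_a != resname_b and slot[1] not in BACKBONE_NAMES:
            continue  # mutated side chain: excluded by construction
        coords_a.append(ca)
        coords_b.append(cb)
        labels.append(slot)
    # atoms only in b, excluding mutated side chains
    pos_resname_a = {}
    for key, _ in struct_a:
        pos_resname_a[key.position] = key.resname
    for slot, (resname_b, _) in map_b.items():
        if slot in map_a:
            continue
        if pos_resname_a.get(slot[0]) != resname_b and slot[1] not in BACKBONE_NAMES:
            continue
        unmatched.append(slot)
    if unmatched:
        raise ValueError(
            "atom pairing failed; unmatched atoms: "
            + ", ".join(f"{p[0]}/{p[1]}{p[2]}:{name}" for p, name in sorted(unmatched)[:10])
        )
    if not coords_a:
        raise ValueError("no atoms matched between structures")
    return np.array(coords_a), np.array(coords_b), labels


def rmsd_between(
    struct_a: Structure,
    struct_b: Structure,
    selection: Selection | None = None,
    superpose: bool = False,
) -> float:
    """RMSD between two structures over a selection (backbone by default
    usage), with optional Kabsch superposition first."""
    ca, cb, _ = match_atoms(struct_a, struct_b, selection)
    if superpose:
        return kabsch(cb, ca).rmsd
    return float(np.sqrt(np.mean(np.sum((ca - cb) ** 2, axis=1))))


def local_perturbation(
    wt: Structure,
    variant: Structure,
    site: ResidueKey,
    radius: float = 10.0,
    superpose: bool = False,
    mask_residues: set[int] | None = None,
) -> dict:
    """Backbone RMSD over the residues within ``radius`` Å of the mutation
    site (site excluded), plus the mean per-atom backbone displacement.

    Shell membership uses heavy-atom minimum distances in the wild type.
    ``mask_residues`` drops the given residue numbers from the shell (e.g.
    loop regions that were rebuilt by homology rather than observed).
    """
    shell = residues_within(wt, site, radius, atom_scope="heavy")
    if mask_residues:
        shell = {k for k in shell if k.resseq not in mask_residues}
    if not shell:
        raise ValueError(f"no residues within {radius} Å of {site}; radius too small")
    sel = Selection.residues(shell, atom_names="backbone")
    ca, cb, _ = match_atoms(wt, variant, sel)
    if superpose:
        sup = kabsch(cb, ca)
        cb = sup.apply(cb)
    disp = np.linalg.norm(ca - cb, axis=1)
    return {
        "rmsd": float(np.sqrt(np.mean(disp**2))),
        "mean_disp": float(np.mean(disp)),
        "n_residues": len(shell),
    }


def global_perturbation(
    wt: Structure, variant: Structure, superpose: bool = False
) -> float:
    """Backbone RMSD over the entire chain."""
    return rmsd_between(wt, variant, Selection.backbone(), superpose=superpose)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley)
# ---------------------------------------------------------------------------


def load_radii(path: str | Path | None = None) -> dict[str, float]:
    """Element → van der Waals radius (Å).  The bundled table carries the
    common values (C 1.70, N 1.55, O 1.52, S 1.80) plus a ``default`` row."""
    if path is None:
        source = resources.files("varimpact.data").joinpath("radii.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    radii: dict[str, float] = {}
    for row in csv.DictReader(text.splitlines()):
        radii[row["element"]] = float(row["radius"])
    return radii


@dataclass
class SasaReport:
    total: float
    per_atom: np.ndarray
    polar: float
    nonpolar: float
    probe_radius: float


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    structure: Structure,
    probe: float = 1.4,
    sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    polar_elements: frozenset[str] = POLAR_ELEMENTS,
    include_hydrogens: bool = False,
) -> SasaReport:
    """Numerical solvent-accessible surface area (Shrake–Rupley).

    Each heavy atom is inflated by the probe radius and sampled with a fixed
    quasi-uniform sphere grid; a sample point is accessible when no other
    inflated atom covers it.  ``polar`` sums N and O atoms, ``nonpolar`` the
    rest (C, S, metals).
    """
    if radii is None:
        radii = load_radii()
    default = radii.get("default")
    entries = [
        (key, atom)
        for key, atom in structure
        if include_hydrogens or not atom.is_hydrogen
    ]
    if not entries:
        raise ValueError("no atoms to compute SASA for")
    coords = np.array([a.coords for _, a in entries])
    r = np.empty(len(entries))
    for i, (_, atom) in enumerate(entries):
        if atom.element in radii:
            r[i] = radii[atom.element]
        elif default is not None:
            r[i] = default
        else:
            raise KeyError(f"no radius for element {atom.element!r} and no default")
    inflated = r + probe
    pts = _sphere_points(sphere_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    per_atom = np.zeros(len(entries))
    for i in range(len(entries)):
        neighbors = [
            j
            for j in tree.query_ball_point(coords[i], max_reach)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < inflated[i] + inflated[j]
        ]
        surface = coords[i] + inflated[i] * pts
        if neighbors:
            nb_coords = coords[neighbors]
            nb_r2 = inflated[neighbors] ** 2
            d2 = ((surface[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            # strictly inside a neighbour occludes; a point exactly on a
            # neighbour's inflated sphere is claimed by the lower atom index
            # so coincident duplicate atoms do not double-count
            eps = 1e-9
            inside = d2 < nb_r2[None, :] - eps
            boundary = np.abs(d2 - nb_r2[None, :]) <= eps
            earlier = np.array([j < i for j in neighbors])
            occluded = inside | (boundary & earlier[None, :])
            frac = (~occluded.any(axis=1)).mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * inflated[i] ** 2
    polar_mask = np.array([a.element in polar_elements for _, a in entries])
    polar = float(per_atom[polar_mask].sum())
    total = float(per_atom.sum())
    return SasaReport(
        total=total,
        per_atom=per_atom,
        polar=polar,
        nonpolar=total - polar,
        probe_radius=probe,
    )


def buried_surface(
    complex_structure: Structure,
    part_a: Selection,
    part_b: Selection,
    convention: str = "per_side",
    probe: float = 1.4,
    sphere_points: int = 960,
    radii: dict[str, float] | None = None,
) -> dict:
    """Surface area buried at the interface between two parts of a complex.

    Δ = SASA(a alone) + SASA(b alone) − SASA(complex); the ``per_side``
    convention (default) divides by two, ``total`` reports the full Δ.
    Polar/nonpolar components follow the SASA element classification.
    """
    if convention not in {"per_side", "total"}:
        raise ValueError("convention must be 'per_side' or 'total'")
    sub_a = complex_structure.select(part_a)
    sub_b = complex_structure.select(part_b)
    ids_a = {id(atom) for atom in sub_a.atoms}
    ids_b = {id(atom) for atom in sub_b.atoms}
    if ids_a & ids_b:
        raise ValueError("part_a and part_b selections overlap")
    joint = Structure(
        atoms=sub_a.atoms + sub_b.atoms,
        residue_keys=sub_a.residue_keys + sub_b.residue_keys,
    )
    kw = dict(probe=probe, sphere_points=sphere_points, radii=radii)
    rep_a = sasa(sub_a, **kw)
    rep_b = sasa(sub_b, **kw)
    rep_ab = sasa(joint, **kw)
    factor = 0.5 if convention == "per_side" else 1.0
    buried = (rep_a.total + rep_b.total - rep_ab.total) * factor
    polar = (rep_a.polar + rep_b.polar - rep_ab.polar) * factor
    return {
        "buried": buried,
        "polar": polar,
        "nonpolar": buried - polar,
        "convention": convention,
    }
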