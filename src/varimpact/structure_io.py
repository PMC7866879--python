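"""PDB structure reading/writing and atom/residue selection primitives.

Coordinates are in Å throughout. Author (PDB) residue numbering is canonical:
residues are addressed by (chain, resseq, icode) exactly as deposited, with no
renumbering, because variant sites in the literature are cited in author
numbers (e.g. C1153 of the KDM6A catalytic domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "ResidueKey",
    "Structure",
    "Selection",
    "PdbParseError",
    "read_pdb",
    "write_pdb",
    "residues_within",
    "BACKBONE_NAMES",
]

#: Backbone atom names (protein main chain).
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
#: Modified polymer residues treated as part of the chain, not as ligands
#: (trimethyl-lysine as found at H3K27me3).
_MODIFIED_AA = frozenset({"M3L", "MLZ", "MLY"})


class PdbParseError(ValueError):
    """Malformed fixed-width PDB record; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Author-numbered residue identity: (chain, resseq, icode, resname)."""

    chain: str
    resseq: int
    icode: str = ""
    resname: str = ""

    @property
    def position(self) -> tuple[str, int, str]:
        """Identity without the residue type — what a mutation preserves."""
        return (self.chain, self.resseq, self.icode)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chain}/{self.resname}{self.resseq}{self.icode}"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    alt_loc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            self.element = infer_element(self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name when the element column
    is absent.  Handles two-letter metals (FE, ZN, ...) and the common
    convention that a leading digit marks a hydrogen (e.g. ``1HB``)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    two = name[:2].upper()
    if two in {"FE", "ZN", "MG", "MN", "NA", "CL", "CA", "NI", "CU", "BR", "SE"}:
        # CA is ambiguous (calcium vs alpha carbon); alpha carbon is written
        # " CA " with a leading space in real files, so a bare "CA" arriving
        # here from a polymer record is treated as carbon by callers that
        # know the residue; default to the metal only for hetero use.
        if two == "CA":
            return "C"
        return two[0] + two[1].lower()
    return name[0].upper()


@dataclass
class Structure:
    """An ordered list of atoms grouped by residue.

    ``residue_keys[i]`` is the residue of ``atoms[i]``; atom order is stable
    under round-trip through :func:`write_pdb` / :func:`read_pdb`.
    """

    atoms: list[Atom] = field(default_factory=list)
    residue_keys: list[ResidueKey] = field(default_factory=list)
    model_id: int = 1
    title: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.residue_keys):
            raise ValueError("atoms and residue_keys must be parallel")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[tuple[ResidueKey, Atom]]:
        return iter(zip(self.residue_keys, self.atoms))

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]).reshape(-1, 3)

    def residues(self) -> list[ResidueKey]:
        """Unique residue keys in order of first appearance."""
        seen: dict[ResidueKey, None] = {}
        for key in self.residue_keys:
            seen.setdefault(key, None)
        return list(seen)

    def residue_atoms(self, key: ResidueKey) -> list[Atom]:
        return [a for k, a in self if k == key]

    def find_residue(self, chain: str, resseq: int, icode: str = "") -> ResidueKey:
        for key in self.residue_keys:
            if key.position == (chain, resseq, icode):
                return key
        raise KeyError(f"no residue {chain}/{resseq}{icode}")

    def select(self, selection: "Selection") -> "Structure":
        """Subsetting preserves the parent atom order."""
        idx = selection.indices(self)
        return Structure(
            atoms=[self.atoms[i] for i in idx],
            residue_keys=[self.residue_keys[i] for i in idx],
            model_id=self.model_id,
            title=self.title,
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError("coordinate array shape mismatch")
        new_atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(new_atoms, list(self.residue_keys), self.model_id, self.title)


@dataclass(frozen=True)
class Selection:
    """A predicate over (ResidueKey, Atom).

    ``atom_names`` may be an explicit set or one of the presets ``backbone``
    ({N, CA, C, O}), ``calpha`` ({CA}) or ``heavy`` (all non-hydrogens).
    Composition of selections (:meth:`__and__`) is intersection.
    """

    chains: frozenset[str] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | str | None = "heavy"
    include_hetero: bool = False

    @staticmethod
    def backbone(**kw) -> "Selection":
        return Selection(atom_names="backbone", **kw)

    @staticmethod
    def calpha(**kw) -> "Selection":
        return Selection(atom_names="calpha", **kw)

    @staticmethod
    def heavy(**kw) -> "Selection":
        return Selection(atom_names="heavy", **kw)

    @staticmethod
    def residues(keys: Iterable[ResidueKey], atom_names="heavy") -> "ResidueSetSelection":
        return ResidueSetSelection(frozenset(k.position for k in keys), atom_names)

    def matches(self, key: ResidueKey, atom: Atom) -> bool:
        if atom.is_hetero and not self.include_hetero:
            return False
        if self.chains is not None and key.chain not in self.chains:
            return False
        if self.residue_ranges is not None:
            if not any(lo <= key.resseq <= hi for lo, hi in self.residue_ranges):
                return False
        return _name_matches(self.atom_names, atom)

    def indices(self, structure: Structure) -> list[int]:
        return [i for i, (k, a) in enumerate(structure) if self.matches(k, a)]

    def __and__(self, other: "Selection") -> "CompositeSelection":
        return CompositeSelection((self, other))


def _name_matches(atom_names, atom: Atom) -> bool:
    if atom_names is None:
        return True
    if atom_names == "heavy":
        return not atom.is_hydrogen
    if atom_names == "backbone":
        return atom.name in BACKBONE_NAMES and not atom.is_hydrogen
    if atom_names == "calpha":
        return atom.name == "CA" and not atom.is_hydrogen
    if isinstance(atom_names, str):
        raise ValueError(f"unknown atom-name preset {atom_names!r}")
    return atom.name in atom_names


@dataclass(frozen=True)
class ResidueSetSelection(Selection):
    """Selection restricted to an explicit set of residue positions."""

    positions: frozenset[tuple[str, int, str]] = frozenset()

    def __init__(self, positions, atom_names="heavy", include_hetero=False):
        object.__setattr__(self, "chains", None)
        object.__setattr__(self, "residue_ranges", None)
        object.__setattr__(self, "atom_names", atom_names)
        object.__setattr__(self, "include_hetero", include_hetero)
        object.__setattr__(self, "positions", frozenset(positions))

    def matches(self, key: ResidueKey, atom: Atom) -> bool:
        if key.position not in self.positions:
            return False
        if atom.is_hetero and not self.include_hetero:
            return False
        return _name_matches(self.atom_names, atom)


@dataclass(frozen=True)
class CompositeSelection(Selection):
    parts: tuple[Selection, ...] = ()

    def __init__(self, parts):
        object.__setattr__(self, "chains", None)
        object.__setattr__(self, "residue_ranges", None)
        object.__setattr__(self, "atom_names", None)
        object.__setattr__(self, "include_hetero", True)
        object.__setattr__(self, "parts", tuple(parts))

    def matches(self, key: ResidueKey, atom: Atom) -> bool:
        return all(p.matches(key, atom) for p in self.parts)


# ---------------------------------------------------------------------------
# PDB fixed-width I/O
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> tuple[ResidueKey, Atom]:
    if len(line.rstrip("\n")) < 54:
        raise PdbParseError("ATOM/HETATM record shorter than coordinate fields", lineno)
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        alt_loc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
        b_factor = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except ValueError as exc:
        raise PdbParseError(f"malformed field ({exc})", lineno) from None
    is_hetero = line.startswith("HETATM")
    if element:
        element = element[0].upper() + element[1:].lower()
    elif not is_hetero and name == "CA":
        element = "C"
    else:
        element = infer_element(name)
    key = ResidueKey(chain=chain, resseq=resseq, icode=icode, resname=resname)
    atom = Atom(
        serial=serial,
        name=name,
        element=element,
        coords=np.array([x, y, z]),
        alt_loc=alt_loc,
        occupancy=min(max(occupancy, 0.0), 1.0),
        b_factor=b_factor,
        is_hetero=is_hetero and resname not in _MODIFIED_AA,
    )
    return key, atom


def _resolve_altlocs(pairs: list[tuple[ResidueKey, Atom]]) -> list[tuple[ResidueKey, Atom]]:
    """Keep one location per (residue, atom name): highest occupancy, first on tie."""
    best: dict[tuple, int] = {}
    order: list[tuple] = []
    for i, (key, atom) in enumerate(pairs):
        slot = (key.position, key.resname, atom.name)
        if slot not in best:
            best[slot] = i
            order.append(slot)
        elif pairs[i][1].occupancy > pairs[best[slot]][1].occupancy:
            best[slot] = i
    return [pairs[best[s]] for s in order]


def read_pdb(path: str | Path, model_policy: str = "first"):
    """Read a PDB file.

    Parameters
    ----------
    path : str or Path
    model_policy : {'first', 'all'}
        ``'first'`` returns a single :class:`Structure` (the first MODEL, or
        the whole file when no MODEL records are present); ``'all'`` returns a
        list with one Structure per MODEL.
    """
    if model_policy not in {"first", "all"}:
        raise ValueError("model_policy must be 'first' or 'all'")
    path = Path(path)
    models: list[list[tuple[ResidueKey, Atom]]] = []
    model_ids: list[int] = []
    current: list[tuple[ResidueKey, Atom]] = []
    current_id = 1
    title_parts: list[str] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
            elif rec == "MODEL ":
                if current:
                    models.append(current)
                    model_ids.append(current_id)
                    current = []
                try:
                    current_id = int(line[10:14])
                except ValueError:
                    current_id = len(models) + 1
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                model_ids.append(current_id)
                current = []
                in_model = False
                if model_policy == "first" and models:
                    break
            elif rec == "TITLE ":
                title_parts.append(line[10:].rstrip())
    if current or not models:
        if current:
            models.append(current)
            model_ids.append(current_id if in_model else 1)
    title = " ".join(title_parts).strip()
    structures = []
    for pairs, mid in zip(models, model_ids):
        if not pairs:
            continue
        pairs = _resolve_altlocs(pairs)
        structures.append(
            Structure(
                atoms=[a for _, a in pairs],
                residue_keys=[k for k, _ in pairs],
                model_id=mid,
                title=title,
            )
        )
    if not structures:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    if model_policy == "first":
        return structures[0]
    return structures


def _format_atom_line(key: ResidueKey, atom: Atom) -> str:
    if len(atom.name) > 4:
        raise ValueError(f"atom name {atom.name!r} longer than 4 characters")
    record = "HETATM" if atom.is_hetero else "ATOM  "
    # atom-name column convention: names of <4 chars start in column 14
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.coords
    if max(abs(x), abs(y), abs(z)) >= 10000:
        raise ValueError("coordinate out of fixed-width range")
    return (
        f"{record}{atom.serial:>5d} {name}{atom.alt_loc or ' ':1s}"
        f"{key.resname:>3s} {key.chain[:1]:1s}{key.resseq:>4d}{key.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structure: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write one Structure, or a sequence as a multi-model PDB."""
    multi = not isinstance(structure, Structure)
    structures = list(structure) if multi else [structure]
    if not structures or any(len(s) == 0 for s in structures):
        raise ValueError("cannot write an empty structure")
    lines: list[str] = []
    if structures[0].title:
        lines.append(f"TITLE     {structures[0].title}")
    for i, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {i:>4d}")
        for key, atom in s:
            lines.append(_format_atom_line(key, atom))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def residues_within(
    structure: Structure,
    site: ResidueKey,
    radius: float,
    atom_scope: str = "heavy",
) -> set[ResidueKey]:
    """Residues whose scoped atoms come within ``radius`` Å of the site
    residue's scoped atoms (minimum pairwise distance); the site itself is
    excluded from the returned set.

    This is the 10 Å neighbourhood used for local-perturbation scoring around
    a mutation site.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if atom_scope not in {"heavy", "calpha"}:
        raise ValueError("atom_scope must be 'heavy' or 'calpha'")

    def in_scope(atom: Atom) -> bool:
        if atom_scope == "calpha":
            return atom.name == "CA"
        return not atom.is_hydrogen

    site_coords = np.array(
        [a.coords for k, a in structure if k.position == site.position and in_scope(a)]
    )
    if site_coords.size == 0:
        raise KeyError(f"site residue {site} not found (or has no scoped atoms)")
    other = [(k, a) for k, a in structure if k.position != site.position and in_scope(a)]
    if not other:
        return set()
    other_coords = np.array([a.coords for _, a in other])
    tree = cKDTree(other_coords)
    hits = tree.query_ball_point(site_coords, r=radius)
    result: set[ResidueKey] = set()
    for hit_list in hits:
        for j in hit_list:
            result.add(other[j][0])
    return result
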