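"""Aggregation of per-residue pKa tables into variant shift profiles.

pKa tables are produced externally (a Poisson–Boltzmann or empirical
calculator, at pH 7.0) or by the synthetic generator; this module only
compares them.  For each variant, the per-residue shift Δ = pKa(variant) −
pKa(wild type) is taken over the shared titratable residues, the positive
and negative shifts are summed separately (the "both directions" reading)
and their magnitudes added into one total.  Titratable residues lost or
gained at the mutation site itself would dominate the sum trivially and are
always excluded, so only indirect electrostatic-environment effects are
scored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import ResidueKey

__all__ = [
    "TITRATABLE",
    "PkaTable",
    "ShiftProfile",
    "read_pka_table",
    "write_pka_table",
    "shift_profile",
    "weak_spots",
    "heatmap_matrix",
]

#: Residue types with a titratable side chain.
TITRATABLE = frozenset({"ASP", "GLU", "HIS", "LYS", "ARG", "CYS", "TYR"})


@dataclass
class PkaTable:
    values: dict[ResidueKey, float]
    provenance: str = "external"
    ph: float = 7.0

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if key.resname not in TITRATABLE:
                raise ValueError(f"{key}: {key.resname} is not a titratable type")
            if not np.isfinite(v):
                raise ValueError(f"{key}: pKa must be finite")

    def by_position(self) -> dict[tuple, tuple[ResidueKey, float]]:
        return {key.position: (key, v) for key, v in self.values.items()}


def read_pka_table(path: str | Path, provenance: str = "external", ph: float = 7.0) -> PkaTable:
    """Read a delimited table with columns chain, resseq, resname, pka."""
    values = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            key = ResidueKey(
                chain=row["chain"],
                resseq=int(row["resseq"]),
                icode=row.get("icode", "") or "",
                resname=row["resname"],
            )
            values[key] = float(row["pka"])
    return PkaTable(values, provenance, ph)


def write_pka_table(table: PkaTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["chain", "resseq", "icode", "resname", "pka"])
        for key in sorted(table.values):
            writer.writerow(
                [key.chain, key.resseq, key.icode, key.resname, f"{table.values[key]:.4f}"]
            )


@dataclass
class ShiftProfile:
    """Per-residue pKa shifts of one variant relative to the wild type."""

    deltas: dict[ResidueKey, float]
    excluded_sites: list[ResidueKey] = field(default_factory=list)
    variant: str = ""

    @property
    def positive_sum(self) -> float:
        return float(sum(d for d in self.deltas.values() if d > 0))

    @property
    def negative_sum(self) -> float:
        return float(sum(d for d in self.deltas.values() if d < 0))

    @property
    def total_abs(self) -> float:
        return float(sum(abs(d) for d in self.deltas.values()))


def shift_profile(
    wt: PkaTable,
    variant: PkaTable,
    mutation_site: ResidueKey | None = None,
    variant_name: str = "",
) -> ShiftProfile:
    """Per-residue Δ = pKa(variant) − pKa(wild type) over shared residues.

    Residues present in only one table (lost or gained titratables) are
    excluded and listed, as is the mutation site itself regardless.
    """
    wt_map = wt.by_position()
    var_map = variant.by_position()
    site_pos = mutation_site.position if mutation_site is not None else None
    deltas: dict[ResidueKey, float] = {}
    excluded: list[ResidueKey] = []
    for pos in sorted(wt_map.keys() | var_map.keys(), key=lambda p: (p[0], p[1], p[2])):
        in_wt, in_var = pos in wt_map, pos in var_map
        key = (wt_map.get(pos) or var_map.get(pos))[0]
        if pos == site_pos or not (in_wt and in_var):
            excluded.append(key)
            continue
        deltas[key] = var_map[pos][1] - wt_map[pos][1]
    if not deltas:
        raise ValueError("no shared titratable residues after exclusions")
    return ShiftProfile(deltas, excluded, variant_name)


def weak_spots(
    profiles: dict[str, ShiftProfile],
    threshold: float = 0.25,
    min_variants: int = 2,
) -> list[dict]:
    """Residues recurrently perturbed across variants: |Δ| ≥ threshold in at
    least ``min_variants`` profiles, sorted by hit count then max |Δ|."""
    if not profiles:
        raise ValueError("no profiles")
    hits: dict[tuple, dict] = {}
    for name, profile in profiles.items():
        for key, d in profile.deltas.items():
            if abs(d) >= threshold:
                rec = hits.setdefault(
                    key.position, {"residue": key, "count": 0, "max_abs": 0.0}
                )
                rec["count"] += 1
                rec["max_abs"] = max(rec["max_abs"], abs(d))
    found = [r for r in hits.values() if r["count"] >= min_variants]
    return sorted(found, key=lambda r: (-r["count"], -r["max_abs"]))


def heatmap_matrix(profiles: dict[str, ShiftProfile]) -> pd.DataFrame:
    """Variants x titratable-residues matrix of signed Δ, columns ordered by
    residue number descending; excluded residues appear as NaN (missing),
    never as zero."""
    universe: dict[tuple, ResidueKey] = {}
    for profile in profiles.values():
        for key in profile.deltas:
            universe.setdefault(key.position, key)
        for key in profile.excluded_sites:
            universe.setdefault(key.position, key)
    ordered = sorted(universe.values(), key=lambda k: (-k.resseq, k.chain, k.icode))
    columns = [str(k) for k in ordered]
    data = []
    for name, profile in profiles.items():
        by_pos = {k.position: d for k, d in profile.deltas.items()}
        data.append([by_pos.get(k.position, np.nan) for k in ordered])
    return pd.DataFrame(data, index=list(profiles), columns=columns)
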