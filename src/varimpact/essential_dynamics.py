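"""Essential dynamics: covariance PCA of conformational ensembles, porcupine
vectors, bidimensional free-energy landscapes and per-PC distribution shifts.

The coordinate-fluctuation covariance matrix C is diagonalised by an
orthogonal transformation T, Λ = TᵀCT: the columns of T are the collective
motion eigenvectors (PC1, PC2, ...) and the diagonal of Λ their variances in
Å².  PCA is fitted on the wild-type ensemble and variant ensembles are
cross-projected onto the common reference frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_dynamics import Ensemble, ReplicateSet, _superpose_to_mean
from .structure_io import ResidueKey, Selection, Structure

__all__ = ["PCAResult", "FelGrid", "pca", "project", "porcupine", "fel", "pc_shift"]

KB_KCAL = 0.0019872041  # kcal/mol/K, for kT -> kcal/mol conversion


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, Å²
    eigenvectors: np.ndarray  # 3N x 3N, columns orthonormal
    mean_coords: np.ndarray  # N x 3
    covariance_trace: float
    atom_index: list[tuple[ResidueKey, str]]

    @property
    def n_atoms(self) -> int:
        return self.mean_coords.shape[0]


@dataclass
class FelGrid:
    free_energy: np.ndarray  # kT units; masked bins are nan
    mask: np.ndarray  # True where the bin is empty
    x_edges: np.ndarray
    y_edges: np.ndarray
    temperature: float = 300.0

    @property
    def masked_fraction(self) -> float:
        return float(self.mask.mean())

    def in_kcal_per_mol(self) -> np.ndarray:
        return self.free_energy * KB_KCAL * self.temperature


def _gather_frames(
    ensemble_or_set: Ensemble | ReplicateSet, selection: Selection
) -> tuple[np.ndarray, list[tuple[ResidueKey, str]], Structure]:
    if isinstance(ensemble_or_set, ReplicateSet):
        rset = ensemble_or_set
        template = rset.ensembles[0].template
        idx = np.asarray(selection.indices(template), dtype=int)
        frames = np.concatenate(
            [e.frames[rset.production_window] for e in rset.retained]
        )
    else:
        template = ensemble_or_set.template
        idx = np.asarray(selection.indices(template), dtype=int)
        frames = ensemble_or_set.frames
    if idx.size == 0:
        raise ValueError("selection resolves to no atoms")
    atom_index = [(template.residue_keys[i], template.atoms[i].name) for i in idx]
    return frames[:, idx, :], atom_index, template


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-magnitude component positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def pca(
    ensemble_or_set: Ensemble | ReplicateSet,
    selection: Selection | None = None,
    superpose: bool = True,
) -> PCAResult:
    """Eigendecomposition of the coordinate-fluctuation covariance matrix
    over the selected atoms (Cα by default), after superposing the frames to
    their mean (same protocol as the RMSF computation).  ``superpose=False``
    analyses the raw coordinates, for frames that are already co-registered
    by construction."""
    selection = selection if selection is not None else Selection.calpha()
    frames, atom_index, _ = _gather_frames(ensemble_or_set, selection)
    f, n, _ = frames.shape
    fitted = _superpose_to_mean(frames, np.arange(n)) if superpose else frames
    x = fitted.reshape(f, 3 * n)
    mean = x.mean(axis=0)
    dev = x - mean
    if np.allclose(dev, 0):
        raise ValueError("degenerate ensemble: zero variance")
    if f <= 3 * n:
        warnings.warn(
            f"only {f} frames for {3 * n} coordinates; covariance is rank-deficient",
            stacklevel=2,
        )
    cov = dev.T @ dev / f
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = _fix_signs(evecs[:, order])
    return PCAResult(
        eigenvalues=evals,
        eigenvectors=evecs,
        mean_coords=mean.reshape(n, 3),
        covariance_trace=float(np.trace(cov)),
        atom_index=atom_index,
    )


def project(
    ensemble_or_set: Ensemble | ReplicateSet,
    pca_result: PCAResult,
    k: int = 3,
    selection: Selection | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Project frames onto the first ``k`` eigenvectors (F x k).  Frames are
    superposed onto the PCA mean structure so that cross-projections of a
    second ensemble live in the same reference frame."""
    selection = selection if selection is not None else Selection.calpha()
    frames, atom_index, _ = _gather_frames(ensemble_or_set, selection)
    if [name for _, name in atom_index] != [name for _, name in pca_result.atom_index] or len(
        atom_index
    ) != pca_result.n_atoms:
        raise ValueError("ensemble atoms do not match the PCA atom space")
    from .geometry import kabsch

    out = np.empty((frames.shape[0], k))
    vecs = pca_result.eigenvectors[:, :k]
    mean_flat = pca_result.mean_coords.reshape(-1)
    for f in range(frames.shape[0]):
        if superpose:
            sup = kabsch(frames[f], pca_result.mean_coords)
            moved = sup.apply(frames[f])
        else:
            moved = frames[f]
        out[f] = (moved.reshape(-1) - mean_flat) @ vecs
    return out


def porcupine(
    pca_result: PCAResult, component: int, structure: Structure | None = None
) -> list[dict]:
    """Per-residue motion vectors of one principal component.

    For each residue, the eigenvector's per-atom 3-vectors are averaged over
    the residue's atoms and scaled by sqrt(eigenvalue) (an RMS displacement
    amplitude, Å); the origin is the residue's mean coordinate.  Rendered
    externally as cones whose length encodes motion magnitude.
    """
    if not 1 <= component <= pca_result.eigenvalues.size:
        raise ValueError("component out of range")
    vec = pca_result.eigenvectors[:, component - 1].reshape(-1, 3)
    scale = float(np.sqrt(max(pca_result.eigenvalues[component - 1], 0.0)))
    per_res: dict[ResidueKey, list[int]] = {}
    for i, (key, _) in enumerate(pca_result.atom_index):
        per_res.setdefault(key, []).append(i)
    rows = []
    for key, idx in per_res.items():
        direction = vec[idx].mean(axis=0)
        origin = pca_result.mean_coords[idx].mean(axis=0)
        rows.append(
            {
                "residue": key,
                "origin": origin,
                "vector": direction * scale,
                "magnitude": float(np.linalg.norm(direction) * scale),
            }
        )
    return rows


def fel(
    projections: np.ndarray,
    bins: int = 50,
    temperature: float = 300.0,
) -> FelGrid:
    """Bidimensional free-energy landscape over (PC1, PC2).

    F_bin = −ln(count / count_max) in kT units; the minimum over occupied
    bins is exactly 0 and empty bins are masked, never extrapolated.
    """
    projections = np.asarray(projections, dtype=float)
    if projections.size == 0:
        raise ValueError("no frames to histogram")
    if projections.ndim != 2 or projections.shape[1] < 2:
        raise ValueError("projections must be F x 2 (or wider)")
    counts, x_edges, y_edges = np.histogram2d(
        projections[:, 0], projections[:, 1], bins=bins
    )
    mask = counts == 0
    free = np.full_like(counts, np.nan)
    occupied = ~mask
    free[occupied] = -np.log(counts[occupied] / counts.max())
    return FelGrid(free, mask, x_edges, y_edges, temperature)


def _overlap_coefficient(a: np.ndarray, b: np.ndarray, bins: int = 40) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges, density=False)
    pb, _ = np.histogram(b, bins=edges, density=False)
    return float(np.minimum(pa / pa.sum(), pb / pb.sum()).sum())


def pc_shift(
    wt: Ensemble | ReplicateSet,
    variant: Ensemble | ReplicateSet,
    k: int = 3,
    selection: Selection | None = None,
    pca_result: PCAResult | None = None,
    superpose: bool = True,
) -> dict:
    """Distributional shift of a variant's essential-dynamics projections
    with respect to the wild type.  PCA is fitted on the wild type (unless
    supplied) and both ensembles are projected onto the first ``k`` PCs;
    per PC the median difference (variant − wild type) and the histogram
    overlap coefficient are reported."""
    selection = selection if selection is not None else Selection.calpha()
    if pca_result is None:
        pca_result = pca(wt, selection, superpose=superpose)
    proj_wt = project(wt, pca_result, k, selection, superpose=superpose)
    proj_var = project(variant, pca_result, k, selection, superpose=superpose)
    shifts, overlaps = [], []
    for i in range(k):
        shifts.append(float(np.median(proj_var[:, i]) - np.median(proj_wt[:, i])))
        overlaps.append(_overlap_coefficient(proj_wt[:, i], proj_var[:, i]))
    return {"shift": shifts, "overlap": overlaps, "pca": pca_result}
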