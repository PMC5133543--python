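"""Posterior-ensemble analytics: superposition, RMSD profiles, PCA.

The thinned posterior sample is analyzed as a collection of Cartesian
structures sharing one atom ordering: Kabsch superposition (SVD with a
reflection guard), an iterative mean structure, global and per-residue RMSD
(backbone N/CA/C'; side-chain CB/CG*/CD*/CE* plus side-chain nitrogens),
principal component analysis of the superposed coordinates, and seeded
subsampling for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molecule import CartesianStructure, build_coordinates

__all__ = [
    "Ensemble",
    "PCAResult",
    "backbone_selection",
    "sidechain_selection",
    "kabsch_superpose",
    "mean_structure",
    "rmsd_to_mean",
    "per_residue_rmsd",
    "pca_ensemble",
    "subsample",
]

BACKBONE_ATOMS = ("N", "CA", "C")
# side-chain heavy atoms of the per-residue RMSD profile: beta through
# epsilon carbons and side-chain nitrogens (zeta atoms deliberately not
# included in this selection)
_SIDECHAIN_PREFIXES = ("CB", "CG", "CD", "CE")
_SIDECHAIN_N = ("ND", "NE", "NZ", "NH")


@dataclass
class Ensemble:
    """Ordered conformer collection with per-member log posteriors."""

    structures: list  # of CartesianStructure, shared atom ordering
    log_posteriors: np.ndarray

    def __post_init__(self):
        self.log_posteriors = np.asarray(self.log_posteriors, dtype=float)
        if len(self.structures) != len(self.log_posteriors):
            raise ValueError("one log posterior per structure required")
        if self.structures:
            names = self.structures[0].template.atom_names
            for s in self.structures[1:]:
                if s.template.atom_names != names:
                    raise ValueError("members must share atom ordering")

    def __len__(self):
        return len(self.structures)

    @property
    def template(self):
        return self.structures[0].template

    def coords(self) -> np.ndarray:
        """(n_members, n_atoms, 3) coordinate stack."""
        return np.stack([s.coords for s in self.structures])

    @classmethod
    def from_posterior_states(cls, states) -> "Ensemble":
        return cls([build_coordinates(st.conformer) for st in states],
                   np.array([st.log_posterior for st in states]))


@dataclass
class PCAResult:
    components: np.ndarray          # (n_components, 3 * n_selected)
    explained_variance_ratio: np.ndarray
    projections: np.ndarray         # (n_members, n_components)


def backbone_selection(template) -> np.ndarray:
    return np.array([k for k, n in enumerate(template.atom_names)
                     if n in BACKBONE_ATOMS], dtype=int)


def sidechain_selection(template, residue_1based: int | None = None
                        ) -> np.ndarray:
    def is_side(n):
        return (n[:2] in _SIDECHAIN_PREFIXES or n[:2] in _SIDECHAIN_N)

    idx = [k for k, n in enumerate(template.atom_names) if is_side(n)]
    if residue_1based is not None:
        idx = [k for k in idx
               if int(template.atom_res[k]) + 1 == residue_1based]
    return np.array(idx, dtype=int)


def _resolve_selection(template, selection):
    if selection is None or (isinstance(selection, str)
                             and selection == "backbone"):
        return backbone_selection(template)
    if isinstance(selection, str) and selection == "sidechain":
        return sidechain_selection(template)
    return np.asarray(selection, dtype=int)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection=None):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``mobile``/``reference`` are (n_atoms, 3) arrays; ``selection`` (index
    array) restricts the fit.  Returns ``(rotation, translation, rmsd)``
    with a proper rotation (det = +1, reflections guarded) minimizing the
    RMSD over the selected atoms; apply as ``mobile @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = (np.arange(len(mobile)) if selection is None
           else np.asarray(selection, dtype=int))
    A = mobile[sel]
    B = reference[sel]
    if len(A) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    A0 = A - ca
    B0 = B - cb
    s = np.linalg.svd(A0, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) atom selection")
    H = A0.T @ B0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def mean_structure(ensemble: Ensemble, selection=None,
                   tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Iterative mean: superpose all members on the current mean (over the
    selection), re-average, repeat until the mean moves < ``tol`` A."""
    sel = _resolve_selection(ensemble.template, selection)
    coords = ensemble.coords()
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = []
        for c in coords:
            R, t, _ = kabsch_superpose(c, mean, sel)
            aligned.append(c @ R.T + t)
        new_mean = np.mean(aligned, axis=0)
        delta = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if delta < tol:
            break
    return mean


def rmsd_to_mean(ensemble: Ensemble, selection="backbone") -> float:
    """Average Kabsch RMSD of the members to the iterative mean."""
    sel = _resolve_selection(ensemble.template, selection)
    mean = mean_structure(ensemble, sel)
    vals = [kabsch_superpose(s.coords, mean, sel)[2]
            for s in ensemble.structures]
    return float(np.mean(vals))


def per_residue_rmsd(ensemble: Ensemble, reference: CartesianStructure,
                     mode: str = "backbone"):
    """Per-residue RMSD (and member sd) to a reference structure.

    All members are first superposed globally on the reference backbone;
    per residue, the RMSD over the mode-selected atoms of that residue is
    averaged over members.  Residues with no selected atoms (glycine in
    side-chain mode) report NaN.
    """
    if mode not in ("backbone", "sidechain"):
        raise ValueError("mode must be 'backbone' or 'sidechain'")
    tpl = ensemble.template
    nres = len(tpl.sequence)
    bb = backbone_selection(tpl)
    aligned = []
    for s in ensemble.structures:
        R, t, _ = kabsch_superpose(s.coords, reference.coords, bb)
        aligned.append(s.coords @ R.T + t)
    values = np.full(nres, np.nan)
    sds = np.full(nres, np.nan)
    for r in range(1, nres + 1):
        if mode == "backbone":
            sel = np.array([k for k in bb
                            if int(tpl.atom_res[k]) + 1 == r], dtype=int)
        else:
            sel = sidechain_selection(tpl, r)
        if len(sel) == 0:
            continue
        member_rmsds = [
            float(np.sqrt(np.mean(np.sum(
                (c[sel] - reference.coords[sel])**2, axis=1))))
            for c in aligned
        ]
        values[r - 1] = np.mean(member_rmsds)
        sds[r - 1] = np.std(member_rmsds)
    return values, sds


def pca_ensemble(ensemble: Ensemble, selection="backbone",
                 n_components: int = 5) -> PCAResult:
    """PCA of the superposed, flattened selected coordinates.

    Members are superposed on the iterative mean first; projections are
    centered; components are orthonormal and variance fractions
    non-increasing.
    """
    from sklearn.decomposition import PCA

    sel = _resolve_selection(ensemble.template, selection)
    mean = mean_structure(ensemble, sel)
    X = []
    for s in ensemble.structures:
        R, t, _ = kabsch_superpose(s.coords, mean, sel)
        X.append(((s.coords @ R.T + t)[sel]).ravel())
    X = np.asarray(X)
    n_components = min(n_components, max(1, min(X.shape) - 1))
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(X)
    return PCAResult(components=pca.components_,
                     explained_variance_ratio=pca.explained_variance_ratio_,
                     projections=proj)


def subsample(ensemble: Ensemble, fraction: float, seed: int = 0) -> Ensemble:
    """Uniformly subsample floor(fraction * N) members without replacement,
    preserving the original order; deterministic per seed."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(ensemble)
    keep = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=keep, replace=False))
    return Ensemble([ensemble.structures[i] for i in idx],
                    ensemble.log_posteriors[idx])
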