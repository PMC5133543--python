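"""Polypeptide model in torsion space.

A conformer is parameterized by its rotatable torsions (backbone phi/psi and
side-chain chi1/chi2; the peptide bond omega is fixed trans at 180 deg).
Bond lengths, bond angles and all remaining torsions are held at template
values from an embedded geometry table measured on ideal residue templates,
so Cartesian coordinates follow deterministically by sequential
internal-to-Cartesian (NeRF) placement: the first residue spans a canonical
frame (N at the origin, CA on +x, C' in the xy-plane) and every later atom
is placed from a reference triple by bond length, bond angle and dihedral.

The module also provides the inverse (torsion measurement), uniform random
conformers, and a simplified physical prior energy

    E = k_rep * sum_nonbonded max(0, r_min_ij - r_ij)^2
        + k_tor * sum_torsions (1 + cos 3 theta)

i.e. soft-core steric repulsion between heavy atoms plus a threefold
staggering potential, in units of k_B T at the reference temperature.  It
plays the role of conformational prior information for the Bayesian
refinement; it is not a molecular-mechanics force field.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import _kernels
from .formats_io import AMINO1TO3, AtomRecord

__all__ = [
    "GeometryTable",
    "ChainTemplate",
    "TorsionConformer",
    "CartesianStructure",
    "PriorParams",
    "build_coordinates",
    "measure_torsions",
    "prior_energy",
    "random_conformer",
    "dihedral_angle",
]

# backbone internal coordinates (trans peptide), Angstrom / degrees
BB = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231, "N_H": 1.010,
    "ANG_N_CA_C": 111.0, "ANG_CA_C_N": 116.2, "ANG_C_N_CA": 121.7,
    "ANG_CA_C_O": 120.8, "ANG_C_N_H": 119.5, "ANG_CA_N_H": 118.0,
    "OMEGA": 180.0,
}

# solvent dielectric constant of bulk water; recorded for reference, the
# surrogate prior carries no electrostatic term that would consume it
SOLVENT_DIELECTRIC = 78.5

# repulsive core radii per element (Angstrom)
CORE_RADII = {"H": 1.00, "C": 1.55, "N": 1.40, "O": 1.35}
RMIN_SCALE = 0.85   # fraction of the radius sum for general pairs
RMIN_SCALE_14 = 0.70  # reduced for atoms three bonds apart

# ring-closure bonds absent from the build tree
EXTRA_BONDS = {
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "HIS": [("NE2", "CE1")],
    "TRP": [("NE1", "CE2"), ("CZ3", "CH2")],
}


@dataclass(frozen=True)
class _AtomSpec:
    name: str
    parent: str
    grand: str
    ggrand: str
    bond: float
    angle: float  # degrees
    tor_name: str | None  # CHI1 / CHI2 / None
    tor_offset: float  # degrees (the full torsion if tor_name is None)


class GeometryTable:
    """Per-residue-type internal-coordinate templates (embedded data file)."""

    def __init__(self, atoms: dict, chi_defs: dict):
        self.atoms = atoms       # residue type -> list of _AtomSpec
        self.chi_defs = chi_defs  # residue type -> {CHI1: (a,b,c,d), ...}

    @classmethod
    @functools.lru_cache(maxsize=1)
    def load(cls) -> "GeometryTable":
        text = (resources.files("incellfold") / "data" / "geometry.txt").read_text()
        atoms: dict = {}
        chi: dict = {}
        res = None
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "RESIDUE":
                res = parts[1]
                atoms[res] = []
                chi[res] = {}
            elif parts[0] == "T":
                chi[res][parts[1]] = tuple(parts[2:6])
            elif parts[0] == "A":
                name, parent, grand, ggrand = parts[1:5]
                bond, ang = float(parts[5]), float(parts[6])
                kind, val = parts[7].split(":")
                tor_name = None if kind == "FIXED" else kind
                atoms[res].append(_AtomSpec(name, parent, grand, ggrand,
                                            bond, ang, tor_name, float(val)))
        return cls(atoms, chi)

    def supported(self):
        return sorted(self.atoms)

    def residue_atoms(self, residue_type: str):
        if residue_type not in self.atoms:
            raise KeyError(f"unsupported residue type {residue_type!r}")
        backbone = ["N", "CA", "C", "O", "H"]
        return backbone + [a.name for a in self.atoms[residue_type]]


def _normalize_sequence(sequence):
    """Accept 1-letter string or iterable of 3-letter codes."""
    if isinstance(sequence, str) and sequence.isalpha() and \
            all(c.upper() in AMINO1TO3 for c in sequence):
        return tuple(AMINO1TO3[c.upper()] for c in sequence)
    seq = tuple(str(s).upper() for s in sequence)
    table = GeometryTable.load()
    for s in seq:
        if s not in table.atoms:
            raise KeyError(f"unsupported residue type {s!r}")
    return seq


class ChainTemplate:
    """Compiled array representation of a sequence for the build kernels."""

    def __init__(self, sequence):
        self.sequence = _normalize_sequence(sequence)
        table = GeometryTable.load()
        nres = len(self.sequence)

        names: list[str] = []      # atom names
        res_of: list[int] = []     # 0-based residue index per atom
        index: dict = {}           # (res0, name) -> atom index
        ref_a, ref_b, ref_c = [], [], []
        bond, angle, tor_base, tor_idx = [], [], [], []

        # torsion vector layout
        self.torsion_names: list[tuple[int, str]] = []  # (res 1-based, name)
        tmap: dict = {}
        for i, rt in enumerate(self.sequence):
            if i > 0:
                tmap[(i, "PHI")] = len(self.torsion_names)
                self.torsion_names.append((i + 1, "PHI"))
            tmap[(i, "PSI")] = len(self.torsion_names)
            self.torsion_names.append((i + 1, "PSI"))
            for chi in sorted(table.chi_defs[rt]):
                tmap[(i, chi)] = len(self.torsion_names)
                self.torsion_names.append((i + 1, chi))
        self.torsion_index = {(r, n): k for k, (r, n) in
                              enumerate(self.torsion_names)}

        def add(name, res, a, b, c, bl, ang, base, tidx):
            index[(res, name)] = len(names)
            names.append(name)
            res_of.append(res)
            ref_a.append(a)
            ref_b.append(b)
            ref_c.append(c)
            bond.append(bl)
            angle.append(np.radians(ang))
            tor_base.append(np.radians(base))
            tor_idx.append(tidx)

        for i, rt in enumerate(self.sequence):
            if i == 0:
                add("N", 0, -1, -1, -1, 0.0, 0.0, 0.0, -1)
                add("CA", 0, -1, -1, -1, BB["N_CA"], 0.0, 0.0, -1)
                add("C", 0, -1, -1, -1, BB["CA_C"], BB["ANG_N_CA_C"], 0.0, -1)
            else:
                pN, pCA, pC = (index[(i - 1, "N")], index[(i - 1, "CA")],
                               index[(i - 1, "C")])
                add("N", i, pN, pCA, pC, BB["C_N"], BB["ANG_CA_C_N"],
                    0.0, tmap[(i - 1, "PSI")])
                add("CA", i, pCA, pC, index[(i, "N")], BB["N_CA"],
                    BB["ANG_C_N_CA"], BB["OMEGA"], -1)
                add("C", i, pC, index[(i, "N")], index[(i, "CA")],
                    BB["CA_C"], BB["ANG_N_CA_C"], 0.0, tmap[(i, "PHI")])
            iN, iCA, iC = index[(i, "N")], index[(i, "CA")], index[(i, "C")]
            add("O", i, iN, iCA, iC, BB["C_O"], BB["ANG_CA_C_O"],
                180.0, tmap[(i, "PSI")])
            if i == 0:
                add("H", 0, iC, iCA, iN, BB["N_H"], BB["ANG_CA_N_H"],
                    180.0, -1)
            else:
                add("H", i, index[(i - 1, "CA")], index[(i - 1, "C")], iN,
                    BB["N_H"], BB["ANG_C_N_H"], 0.0, -1)
            for spec in table.atoms[rt]:
                tidx = (-1 if spec.tor_name is None
                        else tmap[(i, spec.tor_name)])
                add(spec.name, i, index[(i, spec.ggrand)],
                    index[(i, spec.grand)], index[(i, spec.parent)],
                    spec.bond, spec.angle, spec.tor_offset, tidx)

        self.atom_names = names
        self.atom_res = np.array(res_of, dtype=np.int64)  # 0-based
        self.index = index
        self.n_atoms = len(names)
        self.n_torsions = len(self.torsion_names)
        self.ref_a = np.array(ref_a, dtype=np.int64)
        self.ref_b = np.array(ref_b, dtype=np.int64)
        self.ref_c = np.array(ref_c, dtype=np.int64)
        self.bond = np.array(bond)
        self.angle = np.array(angle)
        self.tor_base = np.array(tor_base)
        self.tor_idx = np.array(tor_idx, dtype=np.int64)
        self.elements = np.array([n[0] for n in names])

        self._build_measure_defs(table)
        self._build_pairs()

    # -- torsion measurement ------------------------------------------------
    def _build_measure_defs(self, table):
        quads = []
        offs = []
        nres = len(self.sequence)
        for res1, name in self.torsion_names:
            i = res1 - 1
            ix = self.index
            if name == "PHI":
                quads.append((ix[(i - 1, "C")], ix[(i, "N")],
                              ix[(i, "CA")], ix[(i, "C")]))
                offs.append(0.0)
            elif name == "PSI":
                if i + 1 < nres:
                    quads.append((ix[(i, "N")], ix[(i, "CA")],
                                  ix[(i, "C")], ix[(i + 1, "N")]))
                    offs.append(0.0)
                else:  # last residue: via the carbonyl O, shifted by 180
                    quads.append((ix[(i, "N")], ix[(i, "CA")],
                                  ix[(i, "C")], ix[(i, "O")]))
                    offs.append(180.0)
            else:
                a, b, c, d = table.chi_defs[self.sequence[i]][name]
                quads.append((ix[(i, a)], ix[(i, b)], ix[(i, c)], ix[(i, d)]))
                offs.append(0.0)
        self.measure_quads = np.array(quads, dtype=np.int64)
        self.measure_offsets = np.array(offs)

    # -- nonbonded pair list ------------------------------------------------
    def _build_pairs(self):
        n = self.n_atoms
        adj = [set() for _ in range(n)]

        def link(i, j):
            adj[i].add(j)
            adj[j].add(i)

        for k in range(n):
            if self.ref_c[k] >= 0:
                link(k, int(self.ref_c[k]))
        link(self.index[(0, "N")], self.index[(0, "CA")])
        link(self.index[(0, "CA")], self.index[(0, "C")])
        for i, rt in enumerate(self.sequence):
            for a, b in EXTRA_BONDS.get(rt, ()):
                link(self.index[(i, a)], self.index[(i, b)])

        # graph distances up to 3 bonds
        dist3 = {}
        for s in range(n):
            frontier = {s}
            seen = {s: 0}
            for d in (1, 2, 3):
                nxt = set()
                for u in frontier:
                    for v in adj[u]:
                        if v not in seen:
                            seen[v] = d
                            nxt.add(v)
                frontier = nxt
            dist3[s] = seen

        heavy = [k for k in range(n) if self.elements[k] != "H"]
        pi, pj, rmin = [], [], []
        radii = {e: CORE_RADII[e] for e in CORE_RADII}
        for a_pos, i in enumerate(heavy):
            for j in heavy[a_pos + 1:]:
                d = dist3[i].get(j, 4)
                if d <= 2:
                    continue
                contact = radii[self.elements[i]] + radii[self.elements[j]]
                scale = RMIN_SCALE_14 if d == 3 else RMIN_SCALE
                pi.append(i)
                pj.append(j)
                rmin.append(scale * contact)
        self.pair_i = np.array(pi, dtype=np.int64)
        self.pair_j = np.array(pj, dtype=np.int64)
        self.pair_rmin = np.array(rmin)

    def build(self, torsions_deg: np.ndarray) -> np.ndarray:
        """Cartesian coordinates (n_atoms, 3) for a torsion vector (deg)."""
        t = np.radians(np.asarray(torsions_deg, dtype=float))
        if t.shape != (self.n_torsions,):
            raise ValueError(
                f"expected {self.n_torsions} torsions, got {t.shape}"
            )
        return _kernels.nerf_build(self.ref_a, self.ref_b, self.ref_c,
                                   self.bond, self.angle, self.tor_base,
                                   self.tor_idx, t)

    def measure(self, coords: np.ndarray) -> np.ndarray:
        """Torsion vector (deg, in (-180, 180]) from coordinates."""
        q = self.measure_quads
        d = dihedral_angle(coords[q[:, 0]], coords[q[:, 1]],
                           coords[q[:, 2]], coords[q[:, 3]])
        out = d - self.measure_offsets
        return -((-out + 180.0) % 360.0 - 180.0)  # wrap into (-180, 180]

    def atom_index(self, residue_index_1based: int, atom_name: str) -> int:
        key = (residue_index_1based - 1, atom_name)
        if key not in self.index:
            raise KeyError(
                f"atom {atom_name} of residue {residue_index_1based} "
                f"({self.sequence[residue_index_1based - 1]}) not in model"
            )
        return self.index[key]


@functools.lru_cache(maxsize=64)
def get_template(sequence: tuple) -> ChainTemplate:
    return ChainTemplate(sequence)


@dataclass
class TorsionConformer:
    """A polypeptide state: sequence plus rotatable-torsion values (deg)."""

    sequence: tuple
    angles: np.ndarray

    def __post_init__(self):
        self.sequence = _normalize_sequence(self.sequence)
        self.angles = np.asarray(self.angles, dtype=float)
        tpl = self.template
        if self.angles.shape != (tpl.n_torsions,):
            raise ValueError(
                f"sequence {''.join(s[0] for s in self.sequence)} needs "
                f"{tpl.n_torsions} torsions, got {self.angles.shape}"
            )

    @property
    def template(self) -> ChainTemplate:
        return get_template(self.sequence)

    def get(self, residue_index_1based: int, name: str) -> float:
        return float(self.angles[
            self.template.torsion_index[(residue_index_1based, name.upper())]])

    def replace(self, residue_index_1based: int, name: str,
                value: float) -> "TorsionConformer":
        a = self.angles.copy()
        a[self.template.torsion_index[(residue_index_1based, name.upper())]] = value
        return TorsionConformer(self.sequence, a)


@dataclass
class CartesianStructure:
    """Cartesian coordinates with atom metadata (one model)."""

    sequence: tuple
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        self.sequence = _normalize_sequence(self.sequence)
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def template(self) -> ChainTemplate:
        return get_template(self.sequence)

    @property
    def atoms(self) -> list:
        tpl = self.template
        return [
            AtomRecord(k + 1, tpl.atom_names[k],
                       self.sequence[tpl.atom_res[k]],
                       int(tpl.atom_res[k]) + 1,
                       float(self.coords[k, 0]), float(self.coords[k, 1]),
                       float(self.coords[k, 2]))
            for k in range(tpl.n_atoms)
        ]

    @classmethod
    def from_atom_records(cls, records) -> "CartesianStructure":
        by_res: dict = {}
        for r in records:
            by_res.setdefault(r.residue_index, r.residue_type)
        seq = tuple(by_res[k] for k in sorted(by_res))
        tpl = get_template(_normalize_sequence(seq))
        coords = np.full((tpl.n_atoms, 3), np.nan)
        for r in records:
            try:
                k = tpl.atom_index(r.residue_index, r.atom_name)
            except KeyError:
                continue  # tolerate extra atoms (e.g. terminal oxygens)
            coords[k] = (r.x, r.y, r.z)
        if np.isnan(coords).any():
            missing = [tpl.atom_names[k] for k in
                       np.where(np.isnan(coords[:, 0]))[0][:5]]
            raise ValueError(f"missing atoms in records: {missing}")
        return cls(seq, coords)


@dataclass
class PriorParams:
    """Parameters of the simplified physical prior (k_B T units)."""

    k_rep: float = 1.0    # per Angstrom^2
    k_tor: float = 0.2
    dielectric: float = SOLVENT_DIELECTRIC  # recorded; unused (no GB term)


def build_coordinates(conformer: TorsionConformer) -> CartesianStructure:
    """Deterministic torsion-to-Cartesian build in the canonical frame."""
    tpl = conformer.template
    return CartesianStructure(conformer.sequence, tpl.build(conformer.angles))


def measure_torsions(structure: CartesianStructure) -> TorsionConformer:
    """Measure all rotatable torsions (IUPAC sign convention, (-180, 180])."""
    tpl = structure.template
    return TorsionConformer(structure.sequence,
                            tpl.measure(structure.coords))


def prior_energy(structure: CartesianStructure,
                 params: PriorParams | None = None) -> float:
    """Soft-core heavy-atom repulsion plus threefold torsion staggering."""
    params = params or PriorParams()
    tpl = structure.template
    torsions = np.radians(tpl.measure(structure.coords))
    return float(_kernels.prior_energy_arrays(
        structure.coords, torsions, tpl.pair_i, tpl.pair_j, tpl.pair_rmin,
        params.k_rep, params.k_tor))


def random_conformer(sequence, seed: int = 0) -> TorsionConformer:
    """Torsions i.i.d. uniform on (-180, 180], deterministic per seed."""
    seq = _normalize_sequence(sequence)
    tpl = get_template(seq)
    rng = np.random.default_rng(seed)
    angles = 180.0 - rng.random(tpl.n_torsions) * 360.0  # uniform (-180, 180]
    return TorsionConformer(seq, angles)


def dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral (deg) of four points, IUPAC convention; vectorized."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    if np.any((np.linalg.norm(v, axis=-1) < 1e-9) |
              (np.linalg.norm(w, axis=-1) < 1e-9)):
        raise ValueError("degenerate dihedral: collinear atoms")
    return np.degrees(np.arctan2(y, x))
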