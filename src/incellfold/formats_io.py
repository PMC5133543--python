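"""Readers and writers for the file formats the pipeline exchanges.

Conventions
-----------
* Residue numbering is 1-based everywhere; sampling-grid indices are 0-based.
* Peak lists are whitespace-separated XEASY-style tables:
  ``peak_id  pos_1 ... pos_D  intensity  spectrum_id``.
* Shift lists follow the CYANA ``.prot`` layout:
  ``id  shift  error  atom_name  residue_index`` (residue type is carried in
  an optional trailing column; ``read_shift_list`` accepts both).
* Distance restraints use CYANA-style ``.upl`` rows; ambiguous restraints are
  encoded as several rows sharing a trailing ``#group`` tag.
* Dihedral restraints use ``.aco`` rows: residue, residue type, angle name,
  lower, upper (degrees).
* Coordinates use fixed-column PDB ``ATOM`` records with ``MODEL``/``ENDMDL``
  for ensembles.

All parsers raise :class:`ParseError` (with the offending line number) rather
than silently skipping malformed rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "ParseError",
    "ValidationError",
    "PeakRecord",
    "ShiftRecord",
    "RestraintRecord",
    "DihedralRestraint",
    "AtomRecord",
    "read_peak_list",
    "write_peak_list",
    "read_shift_list",
    "write_shift_list",
    "read_upl",
    "write_upl",
    "read_aco",
    "write_aco",
    "read_pdb_models",
    "write_pdb_models",
    "read_schedule",
    "write_schedule",
]

AMINO3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
AMINO1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
AMINO3TO1 = {v: k for k, v in AMINO1TO3.items()}


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed records violate a format invariant."""


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass(frozen=True)
class PeakRecord:
    """One cross peak of a (2D or 3D) spectrum peak list."""

    peak_id: int
    positions: tuple  # chemical shifts in ppm, one per dimension
    intensity: float
    spectrum_id: str = "spec"

    def __post_init__(self):
        if len(self.positions) not in (2, 3):
            raise ValidationError(
                f"peak {self.peak_id}: expected 2 or 3 dimensions, "
                f"got {len(self.positions)}"
            )
        if not all(_finite(p) for p in self.positions) or not _finite(self.intensity):
            raise ValidationError(f"peak {self.peak_id}: non-finite field")


@dataclass(frozen=True)
class ShiftRecord:
    """An assigned chemical shift for one atom."""

    residue_index: int  # 1-based
    residue_type: str  # 3-letter code
    atom_name: str
    shift: float  # ppm

    def __post_init__(self):
        rt = self.residue_type.upper()
        rt = AMINO1TO3.get(rt, rt)
        if rt not in AMINO3:
            raise ValidationError(f"unknown residue type {self.residue_type!r}")
        object.__setattr__(self, "residue_type", rt)
        if not _finite(self.shift):
            raise ValidationError(
                f"non-finite shift for {rt} {self.residue_index} {self.atom_name}"
            )


@dataclass(frozen=True)
class RestraintRecord:
    """A (possibly ambiguous) distance restraint.

    ``options`` is a tuple of atom-pair assignments
    ``((res_i, atom_i), (res_j, atom_j))``; an unambiguous restraint has one.
    """

    options: tuple
    upper_bound: float  # Angstrom
    lower_bound: float = 0.0
    spectrum_id: str = ""
    peak_id: int = -1
    intensity: float = float("nan")  # source-peak intensity, if any

    def __post_init__(self):
        if not self.options:
            raise ValidationError("restraint with no atom-pair options")
        if not (0.0 <= self.lower_bound <= self.upper_bound):
            raise ValidationError(
                f"inverted bounds: lower {self.lower_bound} > upper {self.upper_bound}"
            )

    @property
    def range_class(self) -> str:
        from .noe_restraints import classify_range  # local to avoid cycle

        (ri, _), (rj, _) = self.options[0]
        return classify_range(ri, rj)


@dataclass(frozen=True)
class DihedralRestraint:
    """An allowed interval for a named backbone/side-chain torsion."""

    residue_index: int
    residue_type: str
    angle_name: str  # PHI, PSI, CHI1, ...
    lower: float  # degrees
    upper: float

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValidationError(
                f"inverted dihedral bounds for {self.angle_name} "
                f"{self.residue_index}: {self.lower} > {self.upper}"
            )


@dataclass
class AtomRecord:
    """One atom of a Cartesian model."""

    serial: int
    atom_name: str
    residue_type: str
    residue_index: int
    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(_finite(v) for v in (self.x, self.y, self.z)):
            raise ValidationError(
                f"non-finite coordinate for atom {self.atom_name} "
                f"{self.residue_index}"
            )


# ---------------------------------------------------------------------------
# peak lists


def write_peak_list(records, path, dialect: str = "tsv") -> None:
    if dialect not in ("xeasy", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("# peak_id  positions(ppm)  intensity  spectrum_id\n")
        for r in records:
            pos = "  ".join(f"{p:.4f}" for p in r.positions)
            fh.write(f"{r.peak_id}  {pos}  {r.intensity:.6g}  {r.spectrum_id}\n")


def read_peak_list(path, dialect: str = "tsv"):
    if dialect not in ("xeasy", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (5, 6):  # id + 2or3 positions + I + label
                raise ParseError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(parts)}"
                )
            try:
                peak_id = int(parts[0])
                positions = tuple(float(p) for p in parts[1:-2])
                intensity = float(parts[-2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field ({exc})")
            records.append(
                PeakRecord(peak_id, positions, intensity, spectrum_id=parts[-1])
            )
    return records


# ---------------------------------------------------------------------------
# shift lists (.prot-style)


def write_shift_list(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id  shift  error  atom  residue  residue_type\n")
        for i, r in enumerate(records, start=1):
            fh.write(
                f"{i}  {r.shift:.4f}  0.000  {r.atom_name}  "
                f"{r.residue_index}  {r.residue_type}\n"
            )


def read_shift_list(path):
    records = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ParseError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(parts)}"
                )
            try:
                shift = float(parts[1])
                atom = parts[3]
                res = int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed field ({exc})")
            rtype = parts[5] if len(parts) == 6 else "ALA"
            key = (res, atom)
            if key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate shift entry for residue "
                    f"{res} atom {atom}"
                )
            seen.add(key)
            records.append(ShiftRecord(res, rtype, atom, shift))
    return records


# ---------------------------------------------------------------------------
# distance (.upl) and dihedral (.aco) restraints


def write_upl(restraints, path) -> None:
    """Write restraints; ambiguous ones expand to one row per option
    sharing a ``#g<n>`` group tag in the final column."""
    with open(path, "w") as fh:
        fh.write("# res_i type_i atom_i  res_j type_j atom_j  upper  [lower] [#group]\n")
        group = 0
        for r in restraints:
            tag = ""
            if len(r.options) > 1:
                group += 1
                tag = f"  #g{group}"
            for (ri, ai), (rj, aj) in r.options:
                fh.write(
                    f"{ri} XXX {ai}  {rj} XXX {aj}  "
                    f"{r.upper_bound:.2f}  {r.lower_bound:.2f}{tag}\n"
                )


def read_upl(path):
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            group = None
            if parts and parts[-1].startswith("#g"):
                group = parts[-1]
                parts = parts[:-1]
            if len(parts) not in (7, 8):
                raise ParseError(
                    f"{path}:{lineno}: expected 7 or 8 columns, got {len(parts)}"
                )
            try:
                ri, ai = int(parts[0]), parts[2]
                rj, aj = int(parts[3]), parts[5]
                upper = float(parts[6])
                lower = float(parts[7]) if len(parts) == 8 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed field ({exc})")
            if lower > upper:
                raise ValidationError(
                    f"{path}:{lineno}: lower bound {lower} exceeds upper {upper}"
                )
            rows.append((group, ((ri, ai), (rj, aj)), upper, lower, lineno))

    restraints = []
    i = 0
    while i < len(rows):
        group, opt, upper, lower, _ = rows[i]
        if group is None:
            restraints.append(RestraintRecord((opt,), upper, lower))
            i += 1
            continue
        options = [opt]
        j = i + 1
        while j < len(rows) and rows[j][0] == group:
            options.append(rows[j][1])
            j += 1
        restraints.append(RestraintRecord(tuple(options), upper, lower))
        i = j
    return restraints


def write_aco(restraints, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue  type  angle  lower  upper (deg)\n")
        for r in restraints:
            fh.write(
                f"{r.residue_index}  {r.residue_type}  {r.angle_name}  "
                f"{r.lower:.1f}  {r.upper:.1f}\n"
            )


def read_aco(path):
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(
                    f"{path}:{lineno}: expected 5 columns, got {len(parts)}"
                )
            try:
                rec = DihedralRestraint(
                    int(parts[0]), parts[1], parts[2].upper(),
                    float(parts[3]), float(parts[4]),
                )
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise ValidationError(f"{path}:{lineno}: {exc}")
                raise ParseError(f"{path}:{lineno}: malformed field ({exc})")
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# PDB coordinates


def _format_atom_line(a: AtomRecord) -> str:
    # PDB v3.3 ATOM record, columns checked in the test-suite byte-offset test
    name = a.atom_name
    # element-left-justified names start in column 14 unless 4 chars long
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {a.serial:5d} {name_field} {a.residue_type:>3s} A"
        f"{a.residue_index:4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {name[0]:>2s}"
    )


def write_pdb_models(models, path) -> None:
    """Write one or more models (lists of :class:`AtomRecord`) to a PDB file."""
    single = len(models) == 1
    with open(path, "w") as fh:
        for imodel, atoms in enumerate(models, start=1):
            if not single:
                fh.write(f"MODEL     {imodel:4d}\n")
            for a in atoms:
                fh.write(_format_atom_line(a) + "\n")
            fh.write("TER\n")
            if not single:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_models(path):
    """Read all models of a PDB file as lists of :class:`AtomRecord`."""
    models = []
    current: list[AtomRecord] = []
    seen: set = set()
    last_res = None

    def _flush():
        nonlocal current, seen, last_res
        if current:
            models.append(current)
        current, seen, last_res = [], set(), None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                _flush()
            elif rec == "ENDMDL":
                _flush()
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    rtype = line[17:20].strip()
                    rindex = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad ATOM record ({exc})")
                key = (rindex, name)
                if key in seen:
                    raise ValidationError(
                        f"{path}:{lineno}: duplicate atom {name} in residue {rindex}"
                    )
                seen.add(key)
                if last_res is not None and rindex < last_res:
                    warnings.warn(
                        f"{path}:{lineno}: non-monotonic residue numbering "
                        f"({rindex} after {last_res})"
                    )
                last_res = rindex
                current.append(AtomRecord(serial, name, rtype, rindex, x, y, z))
    _flush()
    return models


# ---------------------------------------------------------------------------
# sampling schedules (nuslist-style)


def write_schedule(schedule, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# grid {schedule.n1} x {schedule.n2}\n")
        for i, j in schedule.sorted_points():
            fh.write(f"{i} {j}\n")


def read_schedule(path, n1: int | None = None, n2: int | None = None):
    """Read a schedule file; grid sizes come from the header comment unless
    given explicitly."""
    from .nus_maxent import SamplingSchedule

    points = []
    seen = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 4 and parts[0] == "grid" and parts[2] == "x":
                    n1 = n1 or int(parts[1])
                    n2 = n2 or int(parts[3])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 indices")
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed index ({exc})")
            if (i, j) in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate point ({i}, {j})")
            seen.add((i, j))
            points.append((i, j))
    if n1 is None or n2 is None:
        raise ValidationError(f"{path}: grid size missing (no header, none given)")
    for i, j in points:
        if not (0 <= i < n1 and 0 <= j < n2):
            raise ValidationError(f"{path}: point ({i}, {j}) outside {n1}x{n2} grid")
    return SamplingSchedule(n1=n1, n2=n2, points=frozenset(points))


# ---------------------------------------------------------------------------
# time-domain data and spectrum grids (documented text formats)


def write_fid(data, path) -> None:
    """Sampled time-domain points: header + one line per point
    ``i j re im`` (0-based grid indices, complex value)."""
    with open(path, "w") as fh:
        fh.write(f"# grid {data.schedule.n1} x {data.schedule.n2}\n")
        if data.noise_sigma is not None:
            fh.write(f"# noise_sigma {float(data.noise_sigma)!r}\n")
        for (i, j), v in zip(data.schedule.sorted_points(), data.values):
            fh.write(f"{i} {j} {float(v.real)!r} {float(v.imag)!r}\n")


def read_fid(path):
    from .nus_maxent import SamplingSchedule, TimeDomainData
    import numpy as np

    n1 = n2 = None
    noise = None
    points, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 4 and parts[0] == "grid":
                    n1, n2 = int(parts[1]), int(parts[3])
                elif len(parts) == 2 and parts[0] == "noise_sigma":
                    noise = float(parts[1])
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 'i j re im'")
            try:
                points.append((int(parts[0]), int(parts[1])))
                values.append(complex(float(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed field ({exc})")
    if n1 is None:
        raise ValidationError(f"{path}: missing grid header")
    order = sorted(range(len(points)), key=lambda k: points[k])
    sched = SamplingSchedule(n1=n1, n2=n2, points=frozenset(points))
    return TimeDomainData(schedule=sched,
                          values=np.array([values[k] for k in order]),
                          noise_sigma=noise)


def write_spectrum(spectrum, path) -> None:
    """Real intensity grid with axis metadata header, row per i-index."""
    ax1, ax2 = spectrum.axes
    with open(path, "w") as fh:
        fh.write(f"# shape {spectrum.intensities.shape[0]} "
                 f"{spectrum.intensities.shape[1]}\n")
        for d, ax in (("1", ax1), ("2", ax2)):
            fh.write(f"# axis{d} size {ax.size} sw_hz {ax.sw_hz!r} "
                     f"obs_mhz {ax.obs_mhz!r} carrier_ppm {ax.carrier_ppm!r}\n")
        for row in spectrum.intensities:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_spectrum(path):
    from .nus_maxent import Axis, Spectrum
    import numpy as np

    axes = {}
    rows = []
    shape = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "shape":
                    shape = (int(parts[1]), int(parts[2]))
                elif parts and parts[0].startswith("axis"):
                    kv = dict(zip(parts[1::2], parts[2::2]))
                    axes[parts[0]] = Axis(size=int(kv["size"]),
                                          sw_hz=float(kv["sw_hz"]),
                                          obs_mhz=float(kv["obs_mhz"]),
                                          carrier_ppm=float(kv["carrier_ppm"]))
                continue
            try:
                rows.append([float(v) for v in line.split()])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed row ({exc})")
    grid = np.array(rows)
    if shape is not None and grid.shape != shape:
        raise ValidationError(f"{path}: grid shape {grid.shape} != header {shape}")
    if "axis1" not in axes or "axis2" not in axes:
        raise ValidationError(f"{path}: missing axis metadata")
    return Spectrum(grid, (axes["axis1"], axes["axis2"]))
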