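"""NOESY peak interpretation: shift matching, network support, calibration.

A NOESY cross peak at proton shifts ``(w1, w2)`` is assigned by exhaustive
chemical-shift matching: every ordered pair of assigned protons whose shifts
match both dimensions within tolerance (0.04 ppm for 1H; 0.4 ppm would apply
to heavy dimensions) becomes an assignment option.  Ambiguity is retained and
carried into the restraint as a multi-option record contributing through the
ambiguous effective distance

    r_eff = ( sum_options r^-6 )^(-1/6).

Spurious long-range options are pruned by a network-support filter: an
option linking residues (i, j) with |i - j| >= 2 is kept only if enough
other peaks link neighboring residue pairs (within +-1 on both sides), a
simplified form of network anchoring.

Calibration converts intensities to upper distance bounds through the
isolated-spin-pair relation I = C / r^6; the constant is either given or
chosen so the median calibrated distance equals a target (4.0 A by default),
and bounds are clipped to [2.4, 6.0] A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import PeakRecord, RestraintRecord, ShiftRecord
from .molecule import CartesianStructure

__all__ = [
    "AssignmentCandidate",
    "CalibrationModel",
    "RestraintSet",
    "match_assignments",
    "network_filter",
    "auto_calibration_constant",
    "calibrate",
    "classify_range",
    "effective_distance",
    "target_function",
]

TOL_H_DEFAULT = 0.04     # ppm, proton dimensions
TOL_HEAVY_DEFAULT = 0.4  # ppm, 13C/15N dimensions
CAL_D_MIN = 2.4          # A, van der Waals contact
CAL_D_MAX = 6.0          # A, NOE detection limit
CAL_TARGET_MEDIAN = 4.0  # A, auto-calibration target
DIHEDRAL_WEIGHT = 0.0025  # A^2 per deg^2 in the target function


@dataclass
class AssignmentCandidate:
    """A peak with its surviving assignment options.

    Each option is ``(((res_i, atom_i), (res_j, atom_j)), deviations)`` with
    per-dimension shift deviations in ppm.
    """

    peak: PeakRecord
    options: list

    @property
    def unassigned(self) -> bool:
        return len(self.options) == 0

    def residue_pairs(self):
        out = set()
        for (pair, _dev) in self.options:
            (ri, _), (rj, _) = pair
            out.add((min(ri, rj), max(ri, rj)))
        return out


@dataclass
class CalibrationModel:
    """I = C / r^6 calibration for one spectrum."""

    spectrum_id: str
    constant: float  # C, intensity * A^6
    d_min: float = CAL_D_MIN
    d_max: float = CAL_D_MAX

    def __post_init__(self):
        if self.constant <= 0:
            raise ValueError("calibration constant must be > 0")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")

    def distance(self, intensity: float) -> float:
        return float(np.clip((self.constant / intensity) ** (1.0 / 6.0),
                             self.d_min, self.d_max))


@dataclass
class RestraintSet:
    """Calibrated distance restraints with provenance."""

    restraints: list  # of RestraintRecord

    def __len__(self):
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, k):
        return self.restraints[k]

    def count_by_class(self) -> dict:
        out = {"intra": 0, "sequential": 0, "medium": 0, "long": 0}
        for r in self.restraints:
            (ri, _), (rj, _) = r.options[0]
            out[classify_range(ri, rj)] += 1
        return out


def match_assignments(peaks, shifts, tol_h: float = TOL_H_DEFAULT,
                      tol_heavy: float = TOL_HEAVY_DEFAULT):
    """Exhaustive shift matching of 2D 1H-1H peaks against a shift table.

    An option is included iff the shifts of both protons lie within
    ``tol_h`` of the respective peak dimensions.  Peaks with no matching
    pair are returned with an empty option list (flagged unassigned).
    """
    if tol_h <= 0 or tol_heavy <= 0:
        raise ValueError("tolerances must be > 0")
    protons = [s for s in shifts if s.atom_name.startswith("H")]
    out = []
    for p in peaks:
        if len(p.positions) != 2:
            raise ValueError(
                f"peak {p.peak_id}: only 2D 1H-1H peak lists are matched "
                "(3D spectra are reduced to classed 2D lists upstream)"
            )
        w1, w2 = p.positions
        m1 = [(s, abs(s.shift - w1)) for s in protons
              if abs(s.shift - w1) <= tol_h]
        m2 = [(s, abs(s.shift - w2)) for s in protons
              if abs(s.shift - w2) <= tol_h]
        options = []
        for s1, d1 in m1:
            for s2, d2 in m2:
                if (s1.residue_index, s1.atom_name) == \
                        (s2.residue_index, s2.atom_name):
                    continue
                pair = ((s1.residue_index, s1.atom_name),
                        (s2.residue_index, s2.atom_name))
                options.append((pair, (d1, d2)))
        out.append(AssignmentCandidate(peak=p, options=options))
    return out


def network_filter(candidates, min_support: int = 1):
    """Drop long-range options lacking support from neighboring contacts.

    An option linking residues (i, j) with |i - j| >= 2 survives only if at
    least ``min_support`` *other* candidates contain an option linking a
    residue pair within +-1 of (i, j) on both sides.  ``min_support = 0``
    is the identity.
    """
    if min_support < 0:
        raise ValueError("min_support must be >= 0")
    if min_support == 0:
        return candidates
    pair_sets = [c.residue_pairs() for c in candidates]
    out = []
    for k, cand in enumerate(candidates):
        kept = []
        for (pair, dev) in cand.options:
            (ri, _), (rj, _) = pair
            i, j = min(ri, rj), max(ri, rj)
            if j - i < 2:
                kept.append((pair, dev))
                continue
            support = sum(
                1 for m, ps in enumerate(pair_sets)
                if m != k and any(abs(i - i2) <= 1 and abs(j - j2) <= 1
                                  for (i2, j2) in ps)
            )
            if support >= min_support:
                kept.append((pair, dev))
        out.append(AssignmentCandidate(peak=cand.peak, options=kept))
    return out


def auto_calibration_constant(intensities,
                              target_median: float = CAL_TARGET_MEDIAN) -> float:
    """C such that the median calibrated distance equals ``target_median``."""
    arr = np.asarray([i for i in intensities if i > 0], dtype=float)
    if arr.size == 0:
        raise ValueError("no positive intensities to calibrate on")
    return float(np.median(arr) * target_median**6)


def calibrate(candidates, model: CalibrationModel) -> RestraintSet:
    """Turn assigned peaks into upper-bound distance restraints.

    Ambiguous candidates become one restraint carrying all options;
    non-positive intensities are skipped with a warning; unassigned peaks
    are ignored.
    """
    import warnings

    restraints = []
    for cand in candidates:
        if cand.unassigned:
            continue
        if cand.peak.intensity <= 0:
            warnings.warn(
                f"peak {cand.peak.peak_id} ({cand.peak.spectrum_id}): "
                "non-positive intensity, skipped"
            )
            continue
        upper = model.distance(cand.peak.intensity)
        restraints.append(RestraintRecord(
            options=tuple(pair for (pair, _dev) in cand.options),
            upper_bound=upper,
            lower_bound=0.0,
            spectrum_id=cand.peak.spectrum_id,
            peak_id=cand.peak.peak_id,
            intensity=cand.peak.intensity,
        ))
    return RestraintSet(restraints)


def classify_range(res_i: int, res_j: int) -> str:
    """Sequence-separation class: intra / sequential / medium (2-4) / long (>=5)."""
    d = abs(res_i - res_j)
    if d == 0:
        return "intra"
    if d == 1:
        return "sequential"
    if d <= 4:
        return "medium"
    return "long"


def effective_distance(structure: CartesianStructure, options) -> float:
    """Ambiguity-weighted effective distance (sum r^-6)^(-1/6) in Angstrom."""
    if not options:
        raise ValueError("restraint with no options")
    tpl = structure.template
    s = 0.0
    for (ri, ai), (rj, aj) in options:
        d = structure.coords[tpl.atom_index(ri, ai)] - \
            structure.coords[tpl.atom_index(rj, aj)]
        s += float(np.dot(d, d)) ** -3
    return s ** (-1.0 / 6.0)


def target_function(structure: CartesianStructure, restraints,
                    dihedrals=(), dihedral_weight: float = DIHEDRAL_WEIGHT
                    ) -> float:
    """Sum of squared restraint violations (Angstrom^2).

    Distance terms: max(0, r_eff - upper)^2 + max(0, lower - r_eff)^2.
    Dihedral terms: squared angular distance (deg) to the allowed interval,
    scaled by ``dihedral_weight`` (A^2/deg^2).
    """
    t = 0.0
    for r in restraints:
        reff = effective_distance(structure, r.options)
        if reff > r.upper_bound:
            t += (reff - r.upper_bound) ** 2
        elif reff < r.lower_bound:
            t += (r.lower_bound - reff) ** 2
    if dihedrals:
        from .molecule import measure_torsions

        conf = measure_torsions(structure)
        for d in dihedrals:
            theta = conf.get(d.residue_index, d.angle_name)
            if d.lower <= theta <= d.upper:
                continue
            dlo = min(abs(theta - d.lower), 360.0 - abs(theta - d.lower))
            dhi = min(abs(theta - d.upper), 360.0 - abs(theta - d.upper))
            t += dihedral_weight * min(dlo, dhi) ** 2
    return t


def compile_restraints(template, restraints):
    """Flatten a restraint collection into kernel arrays.

    Returns a dict with option atom-index arrays (``opt_i/opt_j`` plus the
    ``[start, end)`` slice per restraint), bounds, log intensities and the
    per-restraint spectrum index (with the spectrum-id list).
    """
    opt_i, opt_j, starts, ends = [], [], [], []
    lower, upper, log_i, spec_idx = [], [], [], []
    spec_ids: list[str] = []
    for r in restraints:
        starts.append(len(opt_i))
        for (ri, ai), (rj, aj) in r.options:
            opt_i.append(template.atom_index(ri, ai))
            opt_j.append(template.atom_index(rj, aj))
        ends.append(len(opt_i))
        lower.append(r.lower_bound)
        upper.append(r.upper_bound)
        if r.spectrum_id not in spec_ids:
            spec_ids.append(r.spectrum_id)
        spec_idx.append(spec_ids.index(r.spectrum_id))
        log_i.append(np.log(r.intensity) if r.intensity > 0 else np.nan)
    return {
        "opt_i": np.array(opt_i, dtype=np.int64),
        "opt_j": np.array(opt_j, dtype=np.int64),
        "opt_start": np.array(starts, dtype=np.int64),
        "opt_end": np.array(ends, dtype=np.int64),
        "lower": np.array(lower),
        "upper": np.array(upper),
        "log_intensity": np.array(log_i),
        "spectrum_index": np.array(spec_idx, dtype=np.int64),
        "spectrum_ids": spec_ids,
    }


def compile_dihedrals(template, dihedrals,
                      weight: float = DIHEDRAL_WEIGHT):
    """Flatten dihedral interval restraints into kernel arrays."""
    idx, lo, hi = [], [], []
    for d in dihedrals:
        idx.append(template.torsion_index[(d.residue_index,
                                           d.angle_name.upper())])
        lo.append(d.lower)
        hi.append(d.upper)
    return {
        "dih_idx": np.array(idx, dtype=np.int64),
        "dih_lo": np.array(lo),
        "dih_hi": np.array(hi),
        "dih_weight": weight,
    }
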