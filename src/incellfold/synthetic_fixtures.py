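"""Synthetic ground-truth scenarios for every pipeline stage.

Real in-cell NOESY data are not distributable, so tests run on generated
scenarios with known answers: a preset reference fold (torsion table
embedded), a chemical-shift table with controllable proton degeneracy, NOE
peak lists with intensities following I = C / r^6 under multiplicative
log-normal noise, and non-uniformly sampled time-domain planes built from
decaying complex sinusoids.

The presets were designed in torsion space so that the repulsive prior is
exactly zero and each fold has at least ten proton pairs under 5 A that are
five or more residues apart (the long-range contacts that define a fold):

* ``hairpin12`` - a 12-mer two-stranded beta hairpin with a type-I' turn;
* ``helix16``   - a 16-mer alpha helix (residues 1-9 at exactly
  (-60, -45)) packed against a C-terminal extended segment;
* ``mixed20``   - a 20-mer alpha/beta fold: helix 1-8 followed by a
  beta hairpin 11-20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import PeakRecord, RestraintRecord, ShiftRecord
from .molecule import (CartesianStructure, TorsionConformer,
                       build_coordinates, get_template, _normalize_sequence)
from .noe_restraints import RestraintSet
from .nus_maxent import SamplingSchedule, TimeDomainData

__all__ = [
    "PRESETS",
    "SpectrumSpec",
    "FidComponent",
    "Scenario",
    "make_reference_structure",
    "simulate_shift_table",
    "simulate_noe_peaks",
    "simulate_fid",
    "make_scenario",
]

NOE_MAX_DISTANCE = 5.5  # A; longer proton pairs give no observable peak

# preset torsion tables: residue (1-based) -> {angle name: degrees}
_HAIRPIN12 = {
    "sequence": "KTVSINGKTVSE",
    "angles": {
        1: {"PSI": 135.0, "CHI1": -60.0, "CHI2": 180.0},
        2: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        3: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        4: {"PHI": -122.0, "PSI": 143.0, "CHI1": 60.0},
        5: {"PHI": -122.0, "PSI": 127.0, "CHI1": -60.0, "CHI2": 180.0},
        6: {"PHI": 52.0, "PSI": 22.0, "CHI1": -60.0, "CHI2": 180.0},
        7: {"PHI": 90.0, "PSI": 0.0},
        8: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0, "CHI2": 180.0},
        9: {"PHI": -130.0, "PSI": 135.0, "CHI1": 175.0},
        10: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        11: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        12: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0, "CHI2": 180.0},
    },
}

_HELIX16 = {
    "sequence": "AEKLSAKIGELAKVLT",
    "angles": {
        1: {"PSI": -45.0},
        2: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        3: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        4: {"PHI": -60.0, "PSI": -45.0, "CHI1": 175.0, "CHI2": 90.0},
        5: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0},
        6: {"PHI": -60.0, "PSI": -45.0},
        7: {"PHI": -60.0, "PSI": -45.0, "CHI1": -82.0, "CHI2": 52.0},
        8: {"PHI": -60.0, "PSI": -45.0, "CHI1": -90.0, "CHI2": -90.0},
        9: {"PHI": -60.0, "PSI": -45.0},
        10: {"PHI": -76.0, "PSI": -4.0, "CHI1": -60.0, "CHI2": 180.0},
        11: {"PHI": 74.0, "PSI": 16.0, "CHI1": -60.0, "CHI2": 180.0},
        12: {"PHI": -114.0, "PSI": 151.0},
        13: {"PHI": -138.0, "PSI": 135.0, "CHI1": 60.0, "CHI2": 180.0},
        14: {"PHI": -130.0, "PSI": 135.0, "CHI1": -175.0},
        15: {"PHI": -130.0, "PSI": 135.0, "CHI1": 90.0, "CHI2": 180.0},
        16: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
    },
}

_MIXED20 = {
    "sequence": "AEKLSAKIGNKTVSINGKTV",
    "angles": {
        1: {"PSI": -45.0},
        2: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        3: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        4: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        5: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0},
        6: {"PHI": -60.0, "PSI": -45.0},
        7: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        8: {"PHI": -60.0, "PSI": -45.0, "CHI1": -60.0, "CHI2": 180.0},
        9: {"PHI": -82.0, "PSI": 0.0},
        10: {"PHI": -120.0, "PSI": 140.0, "CHI1": -175.0, "CHI2": 180.0},
        11: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0, "CHI2": 180.0},
        12: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        13: {"PHI": -122.0, "PSI": 135.0, "CHI1": 60.0},
        14: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        15: {"PHI": 60.0, "PSI": 22.0, "CHI1": -60.0, "CHI2": 180.0},
        16: {"PHI": 82.0, "PSI": 0.0, "CHI1": -60.0, "CHI2": 180.0},
        17: {"PHI": -130.0, "PSI": 135.0},
        18: {"PHI": -130.0, "PSI": 135.0, "CHI1": 60.0, "CHI2": 180.0},
        19: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
        20: {"PHI": -130.0, "PSI": 135.0, "CHI1": -60.0},
    },
}

PRESETS = {"hairpin12": _HAIRPIN12, "helix16": _HELIX16, "mixed20": _MIXED20}

# chemical-shift statistics per proton class: (mean ppm, sd ppm)
_SHIFT_STATS = {
    "H_amide": (8.3, 0.5),
    "HA": (4.4, 0.35),
    "HB": (1.9, 0.4),
    "HG": (1.4, 0.35),
    "HD": (1.5, 0.45),
    "HE": (2.9, 0.4),
    "H_arom": (7.0, 0.4),
    "H_other": (1.0, 0.3),
    "N": (119.0, 4.0),
}
_AROMATIC = {"PHE", "TYR", "HIS", "TRP"}


def make_reference_structure(name: str) -> TorsionConformer:
    """Deterministic, clash-free preset conformer (see module docstring)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    preset = PRESETS[name]
    seq = _normalize_sequence(preset["sequence"])
    tpl = get_template(seq)
    angles = np.zeros(tpl.n_torsions)
    for k, (r, n) in enumerate(tpl.torsion_names):
        angles[k] = preset["angles"][r].get(n, 180.0)
    return TorsionConformer(seq, angles)


def _proton_class(residue_type: str, atom_name: str) -> str:
    if atom_name == "H":
        return "H_amide"
    if atom_name.startswith("HA"):
        return "HA"
    if residue_type in _AROMATIC and atom_name[:2] in (
            "HD", "HE", "HZ", "HH") and residue_type != "HIS":
        return "H_arom"
    if residue_type == "HIS" and atom_name[:2] in ("HD", "HE"):
        return "H_arom"
    for cls in ("HB", "HG", "HD", "HE"):
        if atom_name.startswith(cls):
            return cls
    return "H_other"


def simulate_shift_table(sequence, seed: int = 0,
                         degeneracy_fraction: float = 0.0):
    """Chemical shifts per atom with controllable proton degeneracy.

    Proton shifts are drawn from per-class normal ranges; with
    ``degeneracy_fraction = 0`` all pairwise proton differences are forced
    above the matching tolerance (0.04 ppm) by iterative resampling plus a
    deterministic spreading pass, so assignment is unambiguous by
    construction.  A positive fraction instead forces that fraction of
    protons into near-degenerate pairs (within 0.02 ppm).
    """
    seq = _normalize_sequence(sequence)
    tpl = get_template(seq)
    rng = np.random.default_rng(seed)

    records = []
    proton_rows = []  # indices into records
    for k in range(tpl.n_atoms):
        name = tpl.atom_names[k]
        res1 = int(tpl.atom_res[k]) + 1
        rtype = seq[res1 - 1]
        if name.startswith("H"):
            mu, sd = _SHIFT_STATS[_proton_class(rtype, name)]
            proton_rows.append(len(records))
            records.append(ShiftRecord(res1, rtype, name,
                                       float(rng.normal(mu, sd))))
        elif name == "N":
            mu, sd = _SHIFT_STATS["N"]
            records.append(ShiftRecord(res1, rtype, name,
                                       float(rng.normal(mu, sd))))

    tol = 0.04
    shifts = np.array([records[i].shift for i in proton_rows])

    if degeneracy_fraction <= 0:
        # resample collisions, then spread any leftovers deterministically
        for _ in range(200):
            order = np.argsort(shifts)
            bad = [order[i + 1] for i in range(len(order) - 1)
                   if shifts[order[i + 1]] - shifts[order[i]] <= tol]
            if not bad:
                break
            for b in bad:
                rec = records[proton_rows[b]]
                mu, sd = _SHIFT_STATS[_proton_class(rec.residue_type,
                                                    rec.atom_name)]
                shifts[b] = rng.normal(mu, sd)
        else:
            order = np.argsort(shifts)
            for i in range(1, len(order)):
                lo = shifts[order[i - 1]] + tol * 1.05
                if shifts[order[i]] < lo:
                    shifts[order[i]] = lo
    else:
        n_pairs = int(round(degeneracy_fraction * len(proton_rows) / 2.0))
        idx = rng.choice(len(proton_rows), size=2 * n_pairs, replace=False)
        for a, b in zip(idx[:n_pairs], idx[n_pairs:]):
            shifts[b] = shifts[a] + float(rng.uniform(-0.02, 0.02))

    for row, i in enumerate(proton_rows):
        r = records[i]
        records[i] = ShiftRecord(r.residue_index, r.residue_type,
                                 r.atom_name, float(shifts[row]))
    return records


@dataclass(frozen=True)
class SpectrumSpec:
    """One simulated NOESY class: which proton pairs it observes and its
    calibration constant / noise."""

    spectrum_id: str
    proton_class: str  # 'n15' (amide), 'c13' (carbon-bound), 'all'
    constant: float    # C, intensity * A^6
    sigma: float       # sd of ln intensity noise


def _pair_class(name_i: str, name_j: str) -> str:
    return "n15" if (name_i == "H" or name_j == "H") else "c13"


def simulate_noe_peaks(structure: CartesianStructure, shifts,
                       spectra_spec, seed: int = 0):
    """NOE peak lists per spectrum plus the exact truth restraint set.

    Every proton pair closer than 5.5 A produces one cross peak in the
    spectrum of its class, at the two protons' shifts, with intensity
    ``C_s / r^6 * eps`` where ``ln eps ~ N(0, sigma_s^2)``.  The returned
    truth set holds one unambiguous restraint per peak whose upper bound is
    the exact distance.
    """
    rng = np.random.default_rng(seed)
    tpl = structure.template
    shift_of = {(s.residue_index, s.atom_name): s.shift for s in shifts}
    protons = [k for k in range(tpl.n_atoms) if tpl.elements[k] == "H"]

    peaks: dict = {s.spectrum_id: [] for s in spectra_spec}
    truths: dict = {s.spectrum_id: [] for s in spectra_spec}
    for a, i in enumerate(protons):
        for j in protons[a + 1:]:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            if d > NOE_MAX_DISTANCE:
                continue
            ni, nj = tpl.atom_names[i], tpl.atom_names[j]
            ri, rj = int(tpl.atom_res[i]) + 1, int(tpl.atom_res[j]) + 1
            cls = _pair_class(ni, nj)
            for spec in spectra_spec:
                if spec.proton_class not in (cls, "all"):
                    continue
                intensity = spec.constant / d**6 * float(
                    np.exp(rng.normal(0.0, spec.sigma))) if spec.sigma > 0 \
                    else spec.constant / d**6
                pid = len(peaks[spec.spectrum_id]) + 1
                peaks[spec.spectrum_id].append(PeakRecord(
                    peak_id=pid,
                    positions=(shift_of[(ri, ni)], shift_of[(rj, nj)]),
                    intensity=intensity,
                    spectrum_id=spec.spectrum_id,
                ))
                truths[spec.spectrum_id].append(RestraintRecord(
                    options=(((ri, ni), (rj, nj)),),
                    upper_bound=d, lower_bound=0.0,
                    spectrum_id=spec.spectrum_id, peak_id=pid,
                    intensity=intensity,
                ))
                break  # a pair belongs to exactly one spectrum
    truth_all = RestraintSet([r for s in spectra_spec
                              for r in truths[s.spectrum_id]])
    return peaks, truth_all


@dataclass(frozen=True)
class FidComponent:
    """One decaying complex sinusoid: frequency in bins, decay per sample."""

    k1: float
    k2: float
    amplitude: float = 1.0
    decay1: float = 0.0
    decay2: float = 0.0


def simulate_fid(components, n1: int, n2: int,
                 schedule: SamplingSchedule | None = None,
                 noise_sigma: float = 0.0, seed: int = 0) -> TimeDomainData:
    """Complex 2D decaying sinusoids sampled on a schedule, plus noise.

    The value at grid point (t1, t2) is
    ``sum_c a_c exp(2 pi i (k1 t1/n1 + k2 t2/n2)) exp(-(d1 t1 + d2 t2))``
    plus i.i.d. complex Gaussian noise with per-component standard
    deviation ``noise_sigma``.
    """
    if schedule is None:
        pts = [(i, j) for i in range(n1) for j in range(n2)]
        schedule = SamplingSchedule(n1=n1, n2=n2, points=frozenset(pts),
                                    fraction=1.0)
    pts = np.array(schedule.sorted_points(), dtype=float)
    vals = np.zeros(len(pts), dtype=complex)
    for c in components:
        phase = 2j * np.pi * (c.k1 * pts[:, 0] / n1 + c.k2 * pts[:, 1] / n2)
        damp = np.exp(-(c.decay1 * pts[:, 0] + c.decay2 * pts[:, 1]))
        vals = vals + c.amplitude * np.exp(phase) * damp
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vals = vals + noise_sigma * (rng.normal(size=len(pts))
                                     + 1j * rng.normal(size=len(pts)))
    return TimeDomainData(schedule=schedule, values=vals,
                          noise_sigma=noise_sigma if noise_sigma > 0 else None)


@dataclass
class Scenario:
    """A complete synthetic study with known ground truth."""

    name: str
    seed: int
    conformer: TorsionConformer
    structure: CartesianStructure
    shifts: list
    spectra: list            # of SpectrumSpec
    peaks: dict              # spectrum_id -> list of PeakRecord
    truth_restraints: RestraintSet
    nus_data: TimeDomainData

    @property
    def sequence(self):
        return self.conformer.sequence


def make_scenario(preset: str = "hairpin12", seed: int = 0,
                  degeneracy_fraction: float = 0.0,
                  noise_sigma: float = 0.0,
                  constants=(1.0e5, 2.0e5)) -> Scenario:
    """Scenario with one amide and one carbon-class NOESY spectrum.

    ``noise_sigma`` is the sd of the log-normal intensity noise (0 gives
    exactly invertible intensities); ``constants`` are the true calibration
    constants of the two spectra.  Regeneration with the same arguments is
    bit-identical.
    """
    conformer = make_reference_structure(preset)
    structure = build_coordinates(conformer)
    shifts = simulate_shift_table(conformer.sequence, seed=seed,
                                  degeneracy_fraction=degeneracy_fraction)
    spectra = [
        SpectrumSpec("noesy_n15", "n15", constants[0], noise_sigma),
        SpectrumSpec("noesy_c13", "c13", constants[1], noise_sigma),
    ]
    peaks, truth = simulate_noe_peaks(structure, shifts, spectra, seed=seed + 1)
    schedule_pts = None  # default 25% pseudo-random schedule
    from .nus_maxent import generate_schedule

    sched = generate_schedule(48, 22, 0.25, seed=seed)
    fid = simulate_fid(
        [FidComponent(12.0, 5.0, 40.0, 0.04, 0.06),
         FidComponent(30.0, 14.0, 25.0, 0.05, 0.05),
         FidComponent(7.0, 17.0, 15.0, 0.04, 0.04)],
        48, 22, schedule=sched, noise_sigma=0.5, seed=seed + 2)
    return Scenario(
        name=preset, seed=seed, conformer=conformer, structure=structure,
        shifts=shifts, spectra=spectra, peaks=peaks, truth_restraints=truth,
        nus_data=fid,
    )
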