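"""File-format readers/writers: round trips, layouts, validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from incellfold import formats_io as fio
from incellfold.nus_maxent import SamplingSchedule

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


# -- peak lists -------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.tuples(finite, finite, finite), min_size=0, max_size=8))
def test_peak_list_round_trip(tmp_path_factory, rows):
    path = tmp_path_factory.mktemp("peaks") / "p.list"
    records = [fio.PeakRecord(i + 1, (round(a, 4), round(b, 4)),
                              float(np.float32(i)), "spec1")
               for i, (a, b, _c) in enumerate(rows)]
    fio.write_peak_list(records, path)
    back = fio.read_peak_list(path)
    assert len(back) == len(records)
    for r, b in zip(records, back):
        assert b.peak_id == r.peak_id
        assert b.positions == pytest.approx(r.positions, abs=1e-4)
        assert b.spectrum_id == r.spectrum_id


def test_peak_list_documented_column_layout(tmp_path):
    p = tmp_path / "p.list"
    p.write_text("1  7.82  4.31  153000.0  noesy15N\n")
    (rec,) = fio.read_peak_list(p)
    assert rec.peak_id == 1
    assert rec.positions == (7.82, 4.31)
    assert rec.intensity == 153000.0
    assert rec.spectrum_id == "noesy15N"


def test_peak_list_comments_only_and_errors(tmp_path):
    p = tmp_path / "p.list"
    p.write_text("# a comment\n\n# another\n")
    assert fio.read_peak_list(p) == []
    p.write_text("1  bad  4.31  1.0  s\n")
    with pytest.raises(fio.ParseError, match=":1"):
        fio.read_peak_list(p)
    p.write_text("1  4.31  1.0\n")
    with pytest.raises(fio.ParseError):
        fio.read_peak_list(p)


# -- shift lists ------------------------------------------------------------

def test_shift_list_round_trip_and_duplicates(tmp_path):
    recs = [fio.ShiftRecord(i, "ALA", n, 4.0 + 0.1 * i)
            for i, n in enumerate(["HA", "HB1", "H", "N", "CA"], start=1)]
    path = tmp_path / "s.prot"
    fio.write_shift_list(recs, path)
    assert fio.read_shift_list(path) == recs

    path.write_text("1 4.31 0.0 HA 3 ALA\n2 4.20 0.0 HA 3 ALA\n")
    with pytest.raises(fio.ValidationError, match="duplicate"):
        fio.read_shift_list(path)


def test_shift_list_hand_parse(tmp_path):
    p = tmp_path / "s.prot"
    p.write_text("12  4.310  0.000  HA  3\n")
    (rec,) = fio.read_shift_list(p)
    assert (rec.residue_index, rec.atom_name, rec.shift) == (3, "HA", 4.310)


def test_shift_record_unknown_residue():
    with pytest.raises(fio.ValidationError, match="unknown residue"):
        fio.ShiftRecord(1, "XXX", "HA", 4.0)


# -- restraints -------------------------------------------------------------

def test_upl_hand_parse(tmp_path):
    p = tmp_path / "r.upl"
    p.write_text("3 ALA HA  9 LYS HN  4.50\n")
    (r,) = fio.read_upl(p)
    assert r.upper_bound == 4.5
    assert r.options == (((3, "HA"), (9, "HN")),)


def test_upl_round_trip_mixed_ambiguity(tmp_path):
    rs = [
        fio.RestraintRecord((((1, "HA"), (5, "H")),), 4.0),
        fio.RestraintRecord((((2, "HB2"), (7, "H")),
                             ((2, "HB3"), (7, "H"))), 5.5, 1.8),
        fio.RestraintRecord((((3, "HA"), (9, "H")),), 3.2, 2.4),
    ]
    path = tmp_path / "m.upl"
    fio.write_upl(rs, path)
    back = fio.read_upl(path)
    assert [(r.options, r.upper_bound, r.lower_bound) for r in back] == \
        [(r.options, r.upper_bound, r.lower_bound) for r in rs]


def test_upl_bound_inversion(tmp_path):
    p = tmp_path / "r.upl"
    p.write_text("3 ALA HA  9 LYS HN  2.00  4.00\n")
    with pytest.raises(fio.ValidationError, match="bound"):
        fio.read_upl(p)


def test_aco_hand_parse_and_round_trip(tmp_path):
    p = tmp_path / "d.aco"
    p.write_text("5 VAL PHI  -120.0  -60.0\n")
    (r,) = fio.read_aco(p)
    assert (r.residue_index, r.angle_name, r.lower, r.upper) == \
        (5, "PHI", -120.0, -60.0)
    out = tmp_path / "d2.aco"
    fio.write_aco([r], out)
    assert fio.read_aco(out) == [r]
    p.write_text("5 VAL PHI  -60.0  -120.0\n")
    with pytest.raises(fio.ValidationError):
        fio.read_aco(p)


# -- PDB --------------------------------------------------------------------

def _toy_model(n=3, shift=0.0):
    atoms = []
    serial = 1
    for r in range(1, n + 1):
        for name in ("N", "CA", "C"):
            atoms.append(fio.AtomRecord(serial, name, "ALA", r,
                                        1.234 + serial + shift,
                                        -2.5 + 0.1 * serial, 3.75))
            serial += 1
    return atoms


def test_pdb_round_trip_coordinates(tmp_path):
    path = tmp_path / "m.pdb"
    model = _toy_model()
    fio.write_pdb_models([model], path)
    (back,) = fio.read_pdb_models(path)
    for a, b in zip(model, back):
        assert (b.atom_name, b.residue_index) == (a.atom_name, a.residue_index)
        assert (b.x, b.y, b.z) == pytest.approx((a.x, a.y, a.z), abs=1e-3)


def test_pdb_multi_model(tmp_path):
    path = tmp_path / "e.pdb"
    fio.write_pdb_models([_toy_model(shift=0.01 * k) for k in range(20)], path)
    assert len(fio.read_pdb_models(path)) == 20


def test_pdb_fixed_column_layout(tmp_path):
    """Byte offsets of the ATOM record match the PDB v3 fixed-width layout
    (cross-checked against gemmi's parser)."""
    path = tmp_path / "c.pdb"
    atoms = [fio.AtomRecord(1, "CA", "ALA", 7, 1.234, -5.678, 90.123)]
    fio.write_pdb_models([atoms], path)
    line = path.read_text().splitlines()[0]
    assert line[0:6] == "ATOM  "
    assert line[12:16].strip() == "CA"
    assert line[17:20] == "ALA"
    assert line[22:26] == "   7"
    assert line[30:38] == "   1.234"
    assert line[38:46] == "  -5.678"
    assert line[46:54] == "  90.123"
    gemmi = pytest.importorskip("gemmi")
    stg = gemmi.read_pdb(str(path))
    at = stg[0][0][0][0]
    assert (at.pos.x, at.pos.y, at.pos.z) == pytest.approx(
        (1.234, -5.678, 90.123))
    assert at.name == "CA"


def test_pdb_nonmonotonic_residues_warn(tmp_path):
    path = tmp_path / "w.pdb"
    atoms = [fio.AtomRecord(1, "CA", "ALA", 5, 0, 0, 0),
             fio.AtomRecord(2, "CA", "GLY", 3, 1, 1, 1)]
    fio.write_pdb_models([atoms], path)
    with pytest.warns(UserWarning, match="non-monotonic"):
        fio.read_pdb_models(path)


# -- schedules --------------------------------------------------------------

def test_schedule_round_trip_264(tmp_path):
    from incellfold.nus_maxent import generate_schedule

    sched = generate_schedule(48, 22, 0.25, seed=4)
    path = tmp_path / "s.nus"
    fio.write_schedule(sched, path)
    back = fio.read_schedule(path)
    assert back.points == sched.points
    assert len(back) == 264


def test_schedule_full_grid_and_errors(tmp_path):
    pts = frozenset((i, j) for i in range(4) for j in range(4))
    sched = SamplingSchedule(n1=4, n2=4, points=pts)
    path = tmp_path / "f.nus"
    fio.write_schedule(sched, path)
    lines = [l for l in path.read_text().splitlines()
             if l and not l.startswith("#")]
    assert len(lines) == 16

    path.write_text("# grid 4 x 4\n1 1\n1 1\n")
    with pytest.raises(fio.ValidationError, match="duplicate"):
        fio.read_schedule(path)
    path.write_text("# grid 4 x 4\n9 1\n")
    with pytest.raises(fio.ValidationError, match="outside"):
        fio.read_schedule(path)


# -- fid / spectrum ---------------------------------------------------------

def test_fid_and_spectrum_round_trip(tmp_path):
    from incellfold.nus_maxent import Axis, Spectrum
    from incellfold.synthetic_fixtures import FidComponent, simulate_fid

    fid = simulate_fid([FidComponent(3, 2, 5.0, 0.02, 0.02)], 8, 8,
                       noise_sigma=0.3, seed=1)
    path = tmp_path / "p.fid"
    fio.write_fid(fid, path)
    back = fio.read_fid(path)
    assert back.schedule.points == fid.schedule.points
    assert np.allclose(back.values, fid.values)
    assert back.noise_sigma == fid.noise_sigma

    spec = Spectrum(np.arange(12.0).reshape(3, 4),
                    (Axis(3), Axis(4, sw_hz=1200.0)))
    spath = tmp_path / "s.txt"
    fio.write_spectrum(spec, spath)
    back = fio.read_spectrum(spath)
    assert np.array_equal(back.intensities, spec.intensities)
    assert back.axes[1].sw_hz == 1200.0
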