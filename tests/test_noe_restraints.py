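"""Shift matching, network support, calibration, target function."""

import numpy as np
import pytest

from incellfold import molecule as mol
from incellfold import noe_restraints as nr
from incellfold.formats_io import PeakRecord, RestraintRecord, ShiftRecord


def _shifts():
    return [
        ShiftRecord(3, "ALA", "HA", 4.20),
        ShiftRecord(9, "LYS", "H", 8.10),
        ShiftRecord(5, "VAL", "HA", 4.20),   # degenerate with res 3 HA
        ShiftRecord(7, "GLY", "H", 7.50),
    ]


def test_match_exact_peak_contains_true_pair():
    peak = PeakRecord(1, (4.20, 8.10), 100.0)
    (cand,) = nr.match_assignments([peak], _shifts())
    pairs = [p for (p, _d) in cand.options]
    assert ((3, "HA"), (9, "H")) in pairs


def test_match_tolerance_excludes_beyond_004():
    peak = PeakRecord(1, (4.25, 8.10), 100.0)  # 0.05 ppm off every HA
    (cand,) = nr.match_assignments([peak], _shifts(), tol_h=0.04)
    assert all(a != "HA" for ((_, a), _b), _d in
               [(o[0], o[1]) for o in cand.options]) or cand.unassigned


def test_match_degenerate_cross_product():
    """Two degenerate shifts in dimension 1, one in dimension 2 ->
    exactly the options of the exhaustive cross product."""
    peak = PeakRecord(1, (4.20, 8.10), 100.0)
    (cand,) = nr.match_assignments([peak], _shifts())
    # dim1 matches HA(3) and HA(5); dim2 matches H(9) only
    assert len(cand.options) == 2
    assert {p[0][0] for (p, _d) in cand.options} == {3, 5}


def test_match_unassigned_flagged():
    peak = PeakRecord(1, (2.00, 3.00), 50.0)
    (cand,) = nr.match_assignments([peak], _shifts())
    assert cand.unassigned


# -- network filter ---------------------------------------------------------

def _cand(peak_id, res_i, res_j):
    return nr.AssignmentCandidate(
        PeakRecord(peak_id, (1.0, 2.0), 10.0),
        [(((res_i, "HA"), (res_j, "H")), (0.0, 0.0))])


def test_network_filter_identity_at_zero():
    cands = [_cand(1, 2, 9), _cand(2, 3, 4)]
    assert nr.network_filter(cands, 0) is cands


def test_network_filter_removes_lone_long_range():
    cands = [_cand(1, 2, 9), _cand(2, 3, 4)]  # no support near (2, 9)
    out = nr.network_filter(cands, 1)
    assert out[0].unassigned
    assert not out[1].unassigned  # |3-4| < 2 always kept


def test_network_filter_mutual_support():
    """Three contacts within +-1 of each other support one another."""
    cands = [_cand(1, 3, 9), _cand(2, 4, 9), _cand(3, 3, 10)]
    out = nr.network_filter(cands, 2)
    assert all(not c.unassigned for c in out)
    # exhaustive support count oracle: each pair is within +-1 of both others
    for k, c in enumerate(cands):
        (i, _), (j, _) = c.options[0][0]
        support = sum(
            1 for m, o in enumerate(cands) if m != k
            for (p, _d) in o.options
            if abs(min(p[0][0], p[1][0]) - min(i, j)) <= 1
            and abs(max(p[0][0], p[1][0]) - max(i, j)) <= 1)
        assert support == 2


# -- calibration ------------------------------------------------------------

def test_calibration_distance_formula():
    model = nr.CalibrationModel("s", constant=64.0, d_min=0.5, d_max=10.0)
    assert model.distance(1.0) == pytest.approx(2.0)


def test_calibration_clipping():
    model = nr.CalibrationModel("s", constant=64.0)  # defaults [2.4, 6.0]
    assert model.distance(64.0) == 2.4   # raw distance 1.0, clipped up
    assert model.distance(1e-9) == 6.0   # very weak peak, clipped down


def test_auto_calibration_median_target():
    rng = np.random.default_rng(3)
    intensities = rng.uniform(10.0, 500.0, size=7)
    C = nr.auto_calibration_constant(intensities, target_median=4.0)
    model = nr.CalibrationModel("s", C, d_min=0.1, d_max=99.0)
    dists = sorted(model.distance(i) for i in intensities)
    assert dists[3] == pytest.approx(4.0)  # median of 7


def test_calibrate_skips_nonpositive_intensity():
    cands = [
        nr.AssignmentCandidate(PeakRecord(1, (1.0, 2.0), -5.0),
                               [(((1, "HA"), (2, "H")), (0, 0))]),
        nr.AssignmentCandidate(PeakRecord(2, (1.0, 2.0), 64.0),
                               [(((1, "HA"), (3, "H")), (0, 0))]),
    ]
    model = nr.CalibrationModel("s", 64.0)
    with pytest.warns(UserWarning, match="non-positive"):
        rset = nr.calibrate(cands, model)
    assert len(rset) == 1


def test_calibrate_keeps_ambiguity():
    cands = [nr.AssignmentCandidate(
        PeakRecord(1, (1.0, 2.0), 10.0),
        [(((1, "HA"), (5, "H")), (0, 0)), (((2, "HA"), (5, "H")), (0, 0))])]
    (r,) = nr.calibrate(cands, nr.CalibrationModel("s", 100.0))
    assert len(r.options) == 2


# -- range classes ----------------------------------------------------------

@pytest.mark.parametrize("i,j,cls", [
    (5, 5, "intra"), (5, 6, "sequential"), (6, 5, "sequential"),
    (3, 5, "medium"), (3, 7, "medium"), (3, 8, "long"), (3, 9, "long"),
])
def test_classify_range(i, j, cls):
    assert nr.classify_range(i, j) == cls


# -- effective distance and target function ---------------------------------

@pytest.fixture(scope="module")
def toy_structure():
    return mol.build_coordinates(mol.random_conformer("AKLVE", 12))


def test_effective_distance_single(toy_structure):
    opts = (((1, "HA"), (3, "HA")),)
    tpl = toy_structure.template
    d = np.linalg.norm(toy_structure.coords[tpl.atom_index(1, "HA")]
                       - toy_structure.coords[tpl.atom_index(3, "HA")])
    assert nr.effective_distance(toy_structure, opts) == pytest.approx(d)


def test_effective_distance_symmetric_pair():
    """Two options at identical distance give r * 2^(-1/6)."""
    s = mol.build_coordinates(mol.random_conformer("AKLVE", 12))
    tpl = s.template
    opt = ((1, "HA"), (3, "HA"))
    r = nr.effective_distance(s, (opt,))
    assert nr.effective_distance(s, (opt, opt)) == \
        pytest.approx(r * 2 ** (-1 / 6))


def test_effective_distance_3_and_6():
    """Analytic case: options at 3.0 and 6.0 A -> about 2.992 A."""
    expected = (3.0**-6 + 6.0**-6) ** (-1 / 6)
    assert expected == pytest.approx(2.992, abs=5e-4)
    s = mol.build_coordinates(mol.random_conformer("AKLVE", 12))
    tpl = s.template
    # synthetic coordinates: move two atom copies is impractical; check the
    # formula through the kernel compiler instead
    from incellfold._kernels import effective_distances

    coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 6.0, 0]])
    out = effective_distances(
        coords, np.array([0, 0], dtype=np.int64),
        np.array([1, 2], dtype=np.int64),
        np.array([0], dtype=np.int64), np.array([2], dtype=np.int64))
    assert out[0] == pytest.approx(expected, abs=1e-12)


def test_target_function_values(toy_structure):
    opts = (((1, "HA"), (3, "HA")),)
    d = nr.effective_distance(toy_structure, opts)
    sat = RestraintRecord(opts, upper_bound=d + 1.0)
    assert nr.target_function(toy_structure, [sat]) == 0.0
    viol = RestraintRecord(opts, upper_bound=max(d - 0.5, 0.1))
    assert nr.target_function(toy_structure, [viol]) == pytest.approx(0.25)
    viol2 = RestraintRecord(opts, upper_bound=max(d - 0.3, 0.1))
    viol3 = RestraintRecord(opts, upper_bound=max(d - 0.4, 0.1))
    assert nr.target_function(toy_structure, [viol2, viol3]) == \
        pytest.approx(0.09 + 0.16)


def test_target_self_consistency(hairpin_scenario):
    """Restraints generated from a structure's own distances give target 0."""
    assert nr.target_function(hairpin_scenario.structure,
                              hairpin_scenario.truth_restraints) == 0.0


def test_target_monotone_in_tightening(toy_structure):
    opts = (((1, "HA"), (4, "HA")),)
    d = nr.effective_distance(toy_structure, opts)
    uppers = np.linspace(max(d - 2.0, 0.1), d + 1.0, 10)
    targets = [nr.target_function(
        toy_structure, [RestraintRecord(opts, upper_bound=u)])
        for u in uppers]
    assert all(a >= b for a, b in zip(targets, targets[1:]))


def test_ambiguity_never_increases_violation(toy_structure):
    opts1 = (((1, "HA"), (5, "HA")),)
    opts2 = opts1 + (((2, "HA"), (5, "HA")),)
    u = 2.0
    t1 = nr.target_function(toy_structure, [RestraintRecord(opts1, u)])
    t2 = nr.target_function(toy_structure, [RestraintRecord(opts2, u)])
    assert t2 <= t1


def test_dihedral_interval_violation():
    from incellfold.formats_io import DihedralRestraint

    seq = "AKLVE"
    tpl = mol.get_template(mol._normalize_sequence(seq))
    conf = mol.TorsionConformer(seq, np.full(tpl.n_torsions, 180.0))
    s = mol.build_coordinates(conf)
    ok = DihedralRestraint(2, "LYS", "PHI", 170.0, 190.0 - 360.0 + 360.0)
    within = nr.target_function(s, [], dihedrals=[
        DihedralRestraint(2, "LYS", "PHI", 170.0, 180.0)])
    assert within == 0.0
    viol = nr.target_function(s, [], dihedrals=[
        DihedralRestraint(2, "LYS", "PHI", -60.0, 60.0)],
        dihedral_weight=1.0)
    # 180 deg is 120 deg from the nearest interval edge
    assert viol == pytest.approx(120.0**2)
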