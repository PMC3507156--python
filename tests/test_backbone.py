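import numpy as np
import pytest

from triadcore.backbone import (
    assign_secondary_structure,
    backbone_dihedrals,
    classify_ramachandran,
    correct_dihedral_outliers,
    count_ss_elements,
    ramachandran_report,
)
from triadcore.structure_io import extract_ca_trace
from triadcore.synthetic import (
    build_backbone_from_dihedrals,
    make_ideal_ca_trace,
    perturb_with_core,
)

from conftest import random_rigid_transform

HELIX = (-57.0, -47.0)
SHEET = (-139.0, 135.0)


def _roundtrip_error(angles):
    st = build_backbone_from_dihedrals(angles)
    records, skipped = backbone_dihedrals(st, "A")
    assert skipped == 0
    errs = []
    for k, rec in enumerate(records):
        if rec.phi is not None:
            errs.append(abs(rec.phi - angles[k][0]))
        if rec.psi is not None:
            errs.append(abs(rec.psi - angles[k][1]))
    return max(errs)


def test_uniform_helix_angles_round_trip():
    assert _roundtrip_error([HELIX] * 20) < 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_random_angle_lists_round_trip(seed):
    rng = np.random.default_rng(seed)
    angles = [tuple(a) for a in rng.uniform(-179.9, 179.9, size=(30, 2))]
    assert _roundtrip_error(angles) < 1e-6


def test_terminal_residues_have_undefined_angles():
    st = build_backbone_from_dihedrals([HELIX, HELIX])
    records, _ = backbone_dihedrals(st, "A")
    assert records[0].phi is None and records[0].psi is not None
    assert records[1].phi is not None and records[1].psi is None


def test_dihedrals_invariant_under_rigid_transform():
    angles = [HELIX] * 10 + [SHEET] * 10
    st = build_backbone_from_dihedrals(angles)
    base, _ = backbone_dihedrals(st, "A")
    rot, trans = random_rigid_transform(np.random.default_rng(3))
    moved, _ = perturb_with_core(st, np.ones(20, bool), 0.0, 0.0,
                                 rigid=(rot, trans), seed=0)
    after, _ = backbone_dihedrals(moved, "A")
    for a, b in zip(base, after):
        if a.phi is not None:
            assert b.phi == pytest.approx(a.phi, abs=1e-9)
        if a.psi is not None:
            assert b.psi == pytest.approx(a.psi, abs=1e-9)


def test_canonical_conformations_are_most_favoured():
    assert classify_ramachandran(*HELIX) == "most_favoured"
    assert classify_ramachandran(*SHEET) == "most_favoured"


def test_forbidden_corner_is_disallowed():
    assert classify_ramachandran(58.0, -130.0) == "disallowed"


def test_report_counts_planted_region_memberships():
    # angles planted at cell centers of each of the four grid levels
    from triadcore.backbone import _grid

    grid = _grid()
    picks = {}
    for grade in "FAGD":
        for i in range(36):
            for j in range(36):
                if grid[i][j] == grade:
                    picks[grade] = (-175.0 + 10 * i, -175.0 + 10 * j)
                    break
            if grade in picks:
                break
    angles = ([picks["F"]] * 5 + [picks["A"]] * 4 + [picks["G"]] * 3
              + [picks["D"]] * 2)
    st = build_backbone_from_dihedrals(angles)
    records, _ = backbone_dihedrals(st, "A")
    # drop termini (undefined angles) and replant exact values
    complete = [r for r in records if r.phi is not None and r.psi is not None]
    for rec, ang in zip(complete, angles[1:-1]):
        rec.phi, rec.psi = ang
    report = ramachandran_report(complete)
    planted = angles[1:-1]
    expect = {
        "most_favoured": sum(a == picks["F"] for a in planted),
        "additionally_allowed": sum(a == picks["A"] for a in planted),
        "generously_allowed": sum(a == picks["G"] for a in planted),
        "disallowed": sum(a == picks["D"] for a in planted),
    }
    assert report.counts == expect
    assert report.n_assessed == len(planted)


def test_all_helix_chain_reports_hundred_percent_favoured():
    st = build_backbone_from_dihedrals([HELIX] * 50)
    records, _ = backbone_dihedrals(st, "A")
    report = ramachandran_report(records)
    assert report.percentages["most_favoured"] == 100.0
    assert report.counts["disallowed"] == 0
    assert sum(report.percentages.values()) == pytest.approx(100.0, abs=0.1)


def test_glycine_and_proline_are_excluded():
    st = build_backbone_from_dihedrals([HELIX] * 10, residue_names=["GLY"] * 10)
    records, _ = backbone_dihedrals(st, "A")
    report = ramachandran_report(records)
    assert report.n_assessed == 0
    assert report.n_excluded == 10


def test_outlier_correction_clears_generous_and_disallowed():
    rng = np.random.default_rng(5)
    angles = [tuple(a) for a in rng.uniform(-179.9, 179.9, size=(60, 2))]
    corrected = correct_dihedral_outliers(angles)
    st = build_backbone_from_dihedrals(corrected)
    records, _ = backbone_dihedrals(st, "A")
    report = ramachandran_report(records)
    assert report.counts["generously_allowed"] == 0
    assert report.counts["disallowed"] == 0
    assert report.n_assessed == 58  # all but the two termini


def test_ideal_helix_trace_assigns_helix():
    trace = extract_ca_trace(make_ideal_ca_trace([("helix", 20)]), "A")
    states = assign_secondary_structure(trace.coords)
    assert states.count("H") >= 16
    assert "E" not in states


def test_ideal_strand_trace_assigns_strand():
    trace = extract_ca_trace(make_ideal_ca_trace([("strand", 12)]), "A")
    states = assign_secondary_structure(trace.coords)
    assert states.count("E") >= 8
    assert "H" not in states


def test_helix_loop_helix_counts_two_elements():
    trace = extract_ca_trace(
        make_ideal_ca_trace([("helix", 8), ("loop", 4), ("helix", 8)]), "A"
    )
    summary = count_ss_elements(assign_secondary_structure(trace.coords))
    assert summary.n_helices == 2
    assert summary.n_strands == 0


def test_assignment_invariant_under_rigid_transform():
    st = make_ideal_ca_trace([("helix", 10), ("loop", 4), ("strand", 8)])
    trace = extract_ca_trace(st, "A")
    base = assign_secondary_structure(trace.coords)
    rot, trans = random_rigid_transform(np.random.default_rng(8))
    assert assign_secondary_structure(trace.coords @ rot.T + trans) == base


def test_short_runs_relabelled_to_coil():
    summary = count_ss_elements("HHHHHCCCEEE")
    assert (summary.n_helices, summary.n_strands) == (1, 1)
    summary = count_ss_elements("HHHCC", min_helix=4)
    assert summary.n_helices == 0
    assert summary.states == "CCCCC"


def test_planted_topology_counts_recovered():
    topo = []
    for _ in range(12):
        topo += [("helix", 8), ("loop", 4)]
    for _ in range(8):
        topo += [("strand", 6), ("loop", 4)]
    trace = extract_ca_trace(make_ideal_ca_trace(topo), "A")
    summary = count_ss_elements(assign_secondary_structure(trace.coords))
    assert (summary.n_helices, summary.n_strands) == (12, 8)


def test_trace_too_short_rejected():
    with pytest.raises(ValueError):
        assign_secondary_structure(np.zeros((4, 3)))
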