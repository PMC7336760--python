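"""Pore geometry, contacts, distances, and superposition."""

import numpy as np
import pytest

from cysloopvar import (
    ToyChannelSpec,
    classify_permeation,
    compare_profiles,
    contacts,
    gen_toy_pentamer,
    kabsch_rmsd,
    pore_axis,
    pore_profile,
    read_structure,
    residue_distance,
)
from cysloopvar.structure3d import Atom, Chain, IonConstants, Residue, Structure3D
from cysloopvar.synthetic import write_toy_pdb

from conftest import station_radius


def _rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


# ---------------------------------------------------------------------------
# axis detection


def test_pore_axis_of_ideal_bundle_is_z(toy_channel):
    _, st, _ = toy_channel
    origin, direction = pore_axis(st)
    angle = np.degrees(np.arccos(abs(direction @ np.array([0, 0, 1.0]))))
    assert angle < 1.0
    assert np.allclose(origin[:2], 0.0, atol=1e-9)


def test_pore_axis_follows_rigid_rotation():
    rot = _rotation([1, 2, 0.5], 0.9)
    spec = ToyChannelSpec(rotation=tuple(map(tuple, rot)), translation=(4.0, -1.0, 2.0))
    st, _ = gen_toy_pentamer(spec)
    _, direction = pore_axis(st)
    expected = np.array([0, 0, 1.0]) @ rot
    angle = np.degrees(np.arccos(min(1.0, abs(direction @ expected))))
    assert angle < 1.0


def test_pore_axis_rejects_too_few_chains(toy_channel):
    _, st, _ = toy_channel
    single = Structure3D("one", chains=st.chains[:1])
    with pytest.raises(ValueError):
        pore_axis(single)


# ---------------------------------------------------------------------------
# pore profiles


def test_profile_matches_analytic_radii(toy_channel):
    _, st, analytic = toy_channel
    prof = pore_profile(st, pore_axis(st))
    for z, expected_radius in analytic:
        assert station_radius(prof, (0, 0, z)) == pytest.approx(expected_radius, abs=0.05)


def test_profile_minimum_is_at_the_constriction(toy_channel):
    _, st, analytic = toy_channel
    prof = pore_profile(st, pore_axis(st))
    min_radius, _ = prof.min_radius()
    assert min_radius == pytest.approx(min(r for _, r in analytic), abs=0.05)


def test_profile_with_mutated_ring():
    spec = ToyChannelSpec(mutation_mask={1: 1.0})
    st, analytic = gen_toy_pentamer(spec)
    prof = pore_profile(st, pore_axis(st))
    assert analytic[1][1] == pytest.approx(0.8)
    assert station_radius(prof, (0, 0, analytic[1][0])) == pytest.approx(0.8, abs=0.05)


def test_profile_invariant_under_rigid_motion(toy_channel):
    _, st, analytic = toy_channel
    rot = _rotation([0.3, -1, 2], 1.1)
    moved, _ = gen_toy_pentamer(ToyChannelSpec(rotation=tuple(map(tuple, rot)), translation=(7.0, 3.0, -5.0)))
    prof = pore_profile(moved, pore_axis(moved))
    for z, expected_radius in analytic:
        world = np.array([0, 0, z]) @ rot + np.array([7.0, 3.0, -5.0])
        assert station_radius(prof, world) == pytest.approx(expected_radius, abs=0.05)


def test_fixed_axis_mode_stays_on_axis(toy_channel):
    _, st, analytic = toy_channel
    prof = pore_profile(st, pore_axis(st), refine_center=False)
    for z, expected_radius in analytic:
        # exact C5 symmetry: the axis point is already the optimum
        assert station_radius(prof, (0, 0, z)) == pytest.approx(expected_radius, abs=1e-6)


# ---------------------------------------------------------------------------
# permeation classes


@pytest.mark.parametrize(
    "radius,label",
    [
        (1.60, "blocked"),
        (1.80, "blocked"),
        (1.81, "dehydrated-Cl-only"),
        (3.19, "dehydrated-Cl-only"),
        (3.2, "hydrated-Cl-passable"),
        (3.55, "hydrated-Cl-passable"),
    ],
)
def test_classification_thresholds(radius, label):
    assert classify_permeation(radius) == label


def test_classification_is_monotone_step_function():
    order = {"blocked": 0, "dehydrated-Cl-only": 1, "hydrated-Cl-passable": 2}
    labels = [order[classify_permeation(r)] for r in np.linspace(0, 6, 200)]
    assert labels == sorted(labels)


def test_negative_radius_rejected():
    with pytest.raises(ValueError):
        classify_permeation(-0.1)


def test_ion_constants():
    ions = IonConstants()
    assert (ions.cl_pauling_radius, ions.cl_hydrated_radius) == (1.81, 3.2)


# ---------------------------------------------------------------------------
# profile comparison


def test_identical_profiles_have_zero_deltas(toy_channel):
    _, st, _ = toy_channel
    axis = pore_axis(st)
    prof = pore_profile(st, axis)
    table = compare_profiles(prof, {"same": prof})
    assert np.allclose(table["delta_A"], 0.0)
    assert not table["flagged"].any()


def test_mutant_narrows_exactly_at_the_mutated_ring(toy_channel):
    _, st, analytic = toy_channel
    axis = pore_axis(st)
    wt = pore_profile(st, axis)
    mut_st, _ = gen_toy_pentamer(ToyChannelSpec(mutation_mask={1: 0.7}))
    mut = pore_profile(mut_st, axis, step_size=wt.step_size)
    table = compare_profiles(wt, {"mut": mut}, report_threshold=0.3)
    by_step = table.set_index("step_A")
    # stations: rings at z = 0, 6, 12 map to s = -6, 0, 6 around the centroid
    assert by_step.loc[0.0, "delta_A"] == pytest.approx(-0.7, abs=0.05)
    assert by_step.loc[0.0, "flagged"]
    # the unmutated outer rings keep their radii
    assert by_step.loc[-6.0, "delta_A"] == pytest.approx(0.0, abs=0.05)
    assert by_step.loc[6.0, "delta_A"] == pytest.approx(0.0, abs=0.05)


def test_monotone_narrowing_with_increasing_mutation_load(toy_channel):
    _, st, _ = toy_channel
    axis = pore_axis(st)
    radii = []
    for decrement in (0.0, 0.5, 1.0):
        mut_st, _ = gen_toy_pentamer(ToyChannelSpec(mutation_mask={1: decrement}))
        prof = pore_profile(mut_st, axis)
        radii.append(station_radius(prof, (0, 0, 6.0)))
    assert radii[0] > radii[1] > radii[2]


def test_mismatched_steps_rejected(toy_channel):
    _, st, _ = toy_channel
    axis = pore_axis(st)
    a = pore_profile(st, axis, step_size=3.0)
    b = pore_profile(st, axis, step_size=2.0)
    with pytest.raises(ValueError):
        compare_profiles(a, {"bad": b})


# ---------------------------------------------------------------------------
# contacts and distances


def _two_atom_structure(d, elements=("C", "C"), chains=("A", "B")):
    def make_chain(cid, num, element, x):
        res = Residue(number=num, name="TST", atoms=[Atom(f"{element}1", element, np.array([x, 0.0, 0.0]))])
        return Chain(chain_id=cid, subunit_role="", residues=[res])

    if chains[0] == chains[1]:
        c = Chain(
            chain_id=chains[0],
            subunit_role="",
            residues=[
                Residue(1, "TST", [Atom(f"{elements[0]}1", elements[0], np.array([0.0, 0, 0]))]),
                Residue(2, "TST", [Atom(f"{elements[1]}1", elements[1], np.array([d, 0, 0]))]),
            ],
        )
        return Structure3D("toy2", [c])
    return Structure3D(
        "toy2",
        [make_chain(chains[0], 1, elements[0], 0.0), make_chain(chains[1], 2, elements[1], d)],
    )


def test_carbon_pair_within_vdw_margin_is_contact():
    cset = contacts(_two_atom_structure(3.5))
    assert len(cset) == 1
    c = cset.contacts[0]
    assert c.kind == "vdw"
    assert c.inter_subunit


def test_carbon_pair_beyond_cutoff_is_no_contact():
    assert len(contacts(_two_atom_structure(4.2))) == 0


def test_no_pair_classified_as_hbond():
    cset = contacts(_two_atom_structure(2.9, elements=("N", "O")))
    assert len(cset) == 1
    assert cset.contacts[0].kind == "hbond"


def test_intra_chain_contact_not_inter_subunit():
    cset = contacts(_two_atom_structure(3.5, chains=("A", "A")))
    assert len(cset) == 1
    assert not cset.contacts[0].inter_subunit


def test_contacts_symmetric_lookup():
    cset = contacts(_two_atom_structure(3.5))
    assert cset.between(("A", 1), ("B", 2)) == cset.between(("B", 2), ("A", 1))
    assert len(cset.between(("A", 1), ("B", 2))) == 1


def test_residue_distance_self_is_zero_by_convention():
    st = _two_atom_structure(7.0)
    assert residue_distance(st, ("A", 1), ("A", 1), "min-heavy") == 0.0
    assert residue_distance(st, ("A", 1), ("A", 1), "ca") == 0.0


def test_residue_distance_missing_ca_errors():
    st = _two_atom_structure(7.0)
    with pytest.raises(ValueError, match="CA"):
        residue_distance(st, ("A", 1), ("B", 2), "ca")


def test_residue_distance_min_heavy():
    st = _two_atom_structure(7.0)
    assert residue_distance(st, ("A", 1), ("B", 2), "min-heavy") == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# Kabsch superposition


def _quaternion_rmsd(a, b):
    """Horn's quaternion method, as an independent oracle."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sxx = a.T @ b
    k = np.zeros((4, 4))
    k[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    k[0, 1] = k[1, 0] = sxx[1, 2] - sxx[2, 1]
    k[0, 2] = k[2, 0] = sxx[2, 0] - sxx[0, 2]
    k[0, 3] = k[3, 0] = sxx[0, 1] - sxx[1, 0]
    k[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    k[1, 2] = k[2, 1] = sxx[0, 1] + sxx[1, 0]
    k[1, 3] = k[3, 1] = sxx[2, 0] + sxx[0, 2]
    k[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    k[2, 3] = k[3, 2] = sxx[1, 2] + sxx[2, 1]
    k[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    msd = (np.sum(a**2) + np.sum(b**2) - 2 * lam) / len(a)
    return np.sqrt(max(msd, 0.0))


def test_kabsch_identity_and_rigid_invariance():
    rng = np.random.default_rng(17)
    a = rng.normal(size=(10, 3))
    rmsd, rot, t = kabsch_rmsd(a, a)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    moved = a @ _rotation([1, 1, 1], 0.8) + np.array([3.0, -2.0, 5.0])
    rmsd2, rot2, t2 = kabsch_rmsd(a, moved)
    assert rmsd2 == pytest.approx(0.0, abs=1e-9)
    assert np.linalg.det(rot2) == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(a @ rot2 + t2, moved, atol=1e-9)


def test_kabsch_matches_quaternion_oracle():
    rng = np.random.default_rng(23)
    for _ in range(20):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        rmsd, _, _ = kabsch_rmsd(a, b)
        assert rmsd == pytest.approx(_quaternion_rmsd(a, b), abs=1e-9)


def test_kabsch_is_symmetric():
    rng = np.random.default_rng(29)
    a = rng.normal(size=(8, 3))
    b = rng.normal(size=(8, 3))
    assert kabsch_rmsd(a, b)[0] == pytest.approx(kabsch_rmsd(b, a)[0], abs=1e-9)


def test_kabsch_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        kabsch_rmsd(line, line)


# ---------------------------------------------------------------------------
# structure I/O


def test_pdb_round_trip_of_toy_channel(tmp_path, toy_channel):
    _, st, analytic = toy_channel
    path = write_toy_pdb(st, tmp_path / "toy.pdb")
    loaded = read_structure(path, chain_roles={"A": "toy"})
    assert len(loaded.chains) == 5
    assert loaded.chain("A").subunit_role == "toy"
    n_atoms = sum(len(r.atoms) for c in loaded.chains for r in c.residues)
    assert n_atoms == 15
    prof = pore_profile(loaded, pore_axis(loaded))
    for z, expected_radius in analytic:
        assert station_radius(prof, (0, 0, z)) == pytest.approx(expected_radius, abs=0.05)


def test_unknown_chain_in_role_map_errors(tmp_path, toy_channel):
    _, st, _ = toy_channel
    path = write_toy_pdb(st, tmp_path / "toy.pdb")
    with pytest.raises(ValueError, match="unknown"):
        read_structure(path, chain_roles={"Z": "toy"})


ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40 10.00           C
ATOM      3  CA  ALA A   2       3.000   0.000   0.000  1.00 10.00           C
ATOM      4  H   ALA A   2       3.500   0.000   0.000  1.00 10.00           H
END
"""


def test_altloc_keeps_highest_occupancy_and_drops_hydrogens(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    st = read_structure(p)
    res1 = st.chain("A").residue(1)
    assert len(res1.atoms) == 1
    assert res1.atoms[0].altloc == "A"
    assert np.allclose(res1.atoms[0].xyz, [0, 0, 0])
    res2 = st.chain("A").residue(2)
    assert [a.element for a in res2.atoms] == ["C"]
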