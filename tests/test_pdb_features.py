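"""Structural descriptors against analytic limits and brute-force oracles."""

import math
import textwrap

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cleavecrf import pdb_features as pf
from cleavecrf import synthetic


def single_atom_structure(element="C"):
    atom = pf.Atom(name="CA", element=element, coord=np.zeros(3))
    res = pf.Residue("A", 1, "", "A", [atom])
    return pf.Structure("one", {"A": [res]})


def transformed(structure, rotation, translation):
    chains = {}
    for cid, residues in structure.chains.items():
        new = []
        for r in residues:
            atoms = [
                pf.Atom(a.name, a.element, rotation @ a.coord + translation,
                        a.bfactor, a.occupancy, a.serial)
                for a in r.atoms
            ]
            new.append(pf.Residue(r.chain_id, r.seq_number, r.insertion_code,
                                  r.aa, atoms))
        chains[cid] = new
    return pf.Structure(structure.id, chains, structure.experiment)


# ---------------------------------------------------------------------------
# parsing


SMALL_PDB = textwrap.dedent("""\
    HEADER    HYDROLASE                               01-JAN-20   TEST
    EXPDTA    X-RAY DIFFRACTION
    ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
    ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 20.00           C
    ATOM      3  C   ALA A   1      10.799   5.118  -4.303  1.00 30.00           C
    ATOM      4  O   ALA A   1       9.659   4.805  -4.653  1.00 10.00           O
    ATOM      5  CA AGLY A   2       9.000   5.000  -3.000  0.40 12.00           C
    ATOM      6  CA BGLY A   2       9.100   5.100  -3.100  0.60 12.00           C
    ATOM      7  CA  SER B   1       0.000   0.000   0.000  1.00 15.00           C
    HETATM    8  O   HOH A 101       0.000  20.000   0.000  1.00 20.00           O
    END
""")


def test_parse_pdb_roundtrip_of_generated_fixture(tmp_path, mixed_structure):
    path = tmp_path / "fix.pdb"
    synthetic.write_pdb(mixed_structure, path)
    parsed = pf.parse_pdb(path, chain="A")
    assert len(parsed.chains["A"]) == 30
    assert [r.seq_number for r in parsed.chains["A"]] == list(range(1, 31))
    assert parsed.experiment == "X-RAY DIFFRACTION"
    orig = mixed_structure.atom_coords()
    np.testing.assert_allclose(parsed.atom_coords(), orig, atol=1.5e-3)


def test_parse_pdb_chain_selection_and_errors(tmp_path):
    path = tmp_path / "small.pdb"
    path.write_text(SMALL_PDB)
    st = pf.parse_pdb(path, chain="B")
    assert list(st.chains) == ["B"]
    assert len(st.chains["B"]) == 1
    with pytest.raises(pf.ChainNotFoundError):
        pf.parse_pdb(path, chain="Z")
    with pytest.raises(FileNotFoundError):
        pf.parse_pdb(tmp_path / "missing.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(pf.PDBParseError):
        pf.parse_pdb(empty)


def test_parse_pdb_altloc_and_het_handling(tmp_path):
    path = tmp_path / "small.pdb"
    path.write_text(SMALL_PDB)
    st = pf.parse_pdb(path, chain="A")
    assert len(st.chains["A"]) == 2  # water excluded
    gly = st.chains["A"][1]
    assert len(gly.atoms) == 1  # altlocs collapsed
    assert gly.atoms[0].occupancy == pytest.approx(0.6)  # highest kept
    np.testing.assert_allclose(gly.atoms[0].coord, [9.1, 5.1, -3.1])


# ---------------------------------------------------------------------------
# SASA


def test_isolated_atom_sasa_matches_sphere_area():
    st = single_atom_structure()
    area = pf.compute_sasa(st)[0]
    exact = 4 * math.pi * (1.70 + 1.4) ** 2
    assert abs(area - exact) / exact < 0.02


def test_distant_atoms_do_not_occlude():
    a1 = pf.Atom("CA", "C", np.zeros(3))
    a2 = pf.Atom("CA", "C", np.array([100.0, 0, 0]))
    st = pf.Structure(
        "two",
        {"A": [pf.Residue("A", 1, "", "A", [a1]),
               pf.Residue("A", 2, "", "A", [a2])]},
    )
    areas = pf.compute_sasa(st)
    exact = 4 * math.pi * (1.70 + 1.4) ** 2
    np.testing.assert_allclose(areas.sum(), 2 * exact, rtol=0.02)


def caged_structure():
    """A central atom fully enclosed by a dense shell of atoms."""
    shell = 3.0
    pts = pf._sphere_points(80) * shell
    residues = [pf.Residue("A", 1, "", "A",
                           [pf.Atom("C1", "C", np.zeros(3))])]
    cage_atoms = [pf.Atom(f"C{i}", "C", p) for i, p in enumerate(pts)]
    residues.append(pf.Residue("A", 2, "", "A", cage_atoms))
    return pf.Structure("cage", {"A": residues}), shell


def test_enclosed_atom_has_zero_sasa_verified_by_direct_occlusion():
    st, shell = caged_structure()
    areas = pf.compute_sasa(st)
    # direct check: every quadrature point of the central atom lies inside
    # some cage atom's solvent sphere
    probe = 1.4
    r_c = 1.70 + probe
    pts = pf._sphere_points(960) * r_c
    cage = st.atom_coords()[1:]
    d = np.linalg.norm(pts[:, None, :] - cage[None, :, :], axis=2)
    assert (d.min(axis=1) < r_c).all()
    assert areas[0] == 0.0


def test_residue_accessibility_partition_and_gly_convention(mixed_structure):
    sasa = pf.compute_sasa(mixed_structure)
    abs_acc, rel_acc = pf.residue_accessibility(mixed_structure, sasa)
    # all = side + main within additive tolerance
    np.testing.assert_allclose(abs_acc[:, 0], abs_acc[:, 1] + abs_acc[:, 2],
                               atol=1e-6)
    # side = polar + nonpolar
    np.testing.assert_allclose(abs_acc[:, 1], abs_acc[:, 3] + abs_acc[:, 4],
                               atol=1e-6)
    assert (abs_acc >= 0).all()
    # glycine: CA counted as side chain
    g_atom = pf.Atom("CA", "C", np.zeros(3))
    gly = pf.Structure("g", {"A": [pf.Residue("A", 1, "", "G", [g_atom])]})
    g_abs, g_rel = pf.residue_accessibility(gly, pf.compute_sasa(gly))
    assert g_abs[0, 1] > 0 and g_abs[0, 2] == 0
    # unknown residue type: absolute present, relative missing
    x_atom = pf.Atom("CA", "C", np.zeros(3))
    unk = pf.Structure("x", {"A": [pf.Residue("A", 1, "", "X", [x_atom])]})
    u_abs, u_rel = pf.residue_accessibility(unk, pf.compute_sasa(unk))
    assert u_abs[0, 0] > 0 and np.isnan(u_rel[0, 0])


# ---------------------------------------------------------------------------
# secondary structure


def test_helix_assignment_with_hbond_energy_oracle(helix_structure):
    ss8, ss3 = pf.assign_secondary_structure(helix_structure)
    assert all(s == "H" for s in ss3[2:18])
    # oracle: i -> i+4 backbone H-bond energies below the cutoff
    residues = helix_structure.chains["A"]
    bb = pf._backbone(residues)
    H = pf._impute_amide_h(bb)
    for i in range(1, 14):
        donor = i + 4
        e = pf._HB_Q1Q2F * (
            1 / np.linalg.norm(bb["O"][i] - bb["N"][donor])
            + 1 / np.linalg.norm(bb["C"][i] - H[donor])
            - 1 / np.linalg.norm(bb["O"][i] - H[donor])
            - 1 / np.linalg.norm(bb["C"][i] - bb["N"][donor])
        )
        assert e < -0.5


def test_antiparallel_pair_is_strand():
    pair = synthetic.build_antiparallel_pair()
    ss8, ss3 = pf.assign_secondary_structure(pair)
    paired = [i for i, s in enumerate(ss3) if s == "E"]
    assert len(paired) >= 4
    assert any(i < 8 for i in paired) and any(i >= 8 for i in paired)


def test_short_chain_is_coil():
    atoms = [pf.Atom("CA", "C", np.array([float(i), 0, 0])) for i in range(2)]
    st = pf.Structure(
        "s", {"A": [pf.Residue("A", i + 1, "", "A", [a])
                    for i, a in enumerate(atoms)]}
    )
    ss8, ss3 = pf.assign_secondary_structure(st)
    assert ss3 == ["L", "L"]


# ---------------------------------------------------------------------------
# torsions


def test_helix_torsions_match_construction(helix_structure):
    phi, psi = pf.backbone_torsions(helix_structure)
    assert np.isnan(phi[0]) and np.isnan(psi[-1])
    np.testing.assert_allclose(phi[1:-1], -57.0, atol=2.0)
    np.testing.assert_allclose(psi[1:-1], -47.0, atol=2.0)
    finite = np.concatenate([phi[1:], psi[:-1]])
    assert ((finite > -180) & (finite <= 180)).all()


def test_chain_break_gives_missing_angles():
    a = synthetic.build_backbone([("helix", 6)], seed=0)
    b = synthetic.build_backbone([("helix", 6)], seed=0)
    shifted = transformed(b, np.eye(3), np.array([100.0, 0, 0]))
    residues = a.chains["A"] + [
        pf.Residue("A", r.seq_number + 6, "", r.aa, r.atoms)
        for r in shifted.chains["A"]
    ]
    st = pf.Structure("broken", {"A": residues})
    phi, psi = pf.backbone_torsions(st)
    assert np.isnan(psi[5]) and np.isnan(phi[6])
    assert not np.isnan(phi[5]) and not np.isnan(psi[6])


def test_degenerate_dihedral_warns_and_returns_nan():
    with pytest.warns(UserWarning, match="degenerate"):
        ang = pf.dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])
    assert np.isnan(ang)


# ---------------------------------------------------------------------------
# half-sphere exposure


def hse_bruteforce(structure, radius=13.0):
    """Independent O(n^2) double loop over residues."""
    chains = list(structure.chains.values())
    flat = [(ci, i, r) for ci, ch in enumerate(chains) for i, r in enumerate(ch)]
    out = {k: [] for k in ("cn", "hseau", "hsead", "hsebu", "hsebd")}
    cbs = []
    for ci, i, r in flat:
        cb = r.atom("CB")
        if cb is not None:
            cbs.append(cb.coord)
        else:
            n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
            cbs.append(pf.ideal_cb(n.coord, ca.coord, c.coord)
                       if n and ca and c else None)
    for idx, (ci, i, r) in enumerate(flat):
        ca = r.atom("CA").coord
        chain = chains[ci]
        d = np.zeros(3)
        for j in (i - 1, i + 1):
            if 0 <= j < len(chain) and chain[j].atom("CA") is not None:
                d += ca - chain[j].atom("CA").coord
        dir_a = d / np.linalg.norm(d) if np.linalg.norm(d) > 1e-9 else None
        dir_b = None
        if cbs[idx] is not None:
            dir_b = cbs[idx] - ca
            dir_b = dir_b / (np.linalg.norm(dir_b) + 1e-12)
        cn = au = ad = bu = bd = 0
        for jdx, (cj, j, r2) in enumerate(flat):
            if jdx == idx:
                continue
            ca2 = r2.atom("CA").coord
            if np.linalg.norm(ca2 - ca) < radius:
                cn += 1
                if dir_a is None or np.dot(ca2 - ca, dir_a) > 0:
                    au += 1
                else:
                    ad += 1
            if cbs[jdx] is not None and np.linalg.norm(cbs[jdx] - ca) < radius:
                if dir_b is None or np.dot(cbs[jdx] - ca, dir_b) > 0:
                    bu += 1
                else:
                    bd += 1
        for k, v in zip(("cn", "hseau", "hsead", "hsebu", "hsebd"),
                        (cn, au, ad, bu, bd)):
            out[k].append(v)
    return {k: np.array(v) for k, v in out.items()}


def test_hse_matches_bruteforce_and_partition(mixed_structure):
    hse = pf.half_sphere_exposure(mixed_structure)
    ref = hse_bruteforce(mixed_structure)
    for k in hse:
        np.testing.assert_array_equal(hse[k], ref[k])
    np.testing.assert_array_equal(hse["hseau"] + hse["hsead"], hse["cn"])


def test_hse_single_residue_all_zero():
    st = single_atom_structure()
    hse = pf.half_sphere_exposure(st)
    for k in ("cn", "hseau", "hsead", "hsebu", "hsebd"):
        assert hse[k][0] == 0


# ---------------------------------------------------------------------------
# depth and protrusion


def test_depth_index_exposed_zero_and_caged_distance():
    st, shell = caged_structure()
    sasa = pf.compute_sasa(st)
    dpx = pf.depth_index(st, sasa)
    # every exposed atom has depth 0
    assert (dpx[sasa > 0] == 0).all()
    # central atom: distance to nearest exposed atom, by direct computation
    coords = st.atom_coords()
    exposed = coords[sasa > 0]
    expected = np.linalg.norm(exposed, axis=1).min()
    assert dpx[0] == pytest.approx(expected)


def test_depth_index_surface_structure_all_zero(helix_structure):
    sasa = pf.compute_sasa(helix_structure)
    if (sasa > 0).all():
        dpx = pf.depth_index(helix_structure, sasa)
        np.testing.assert_array_equal(dpx, 0.0)


def test_protrusion_isolated_atom_closed_form():
    st = single_atom_structure()
    cx = pf.protrusion_index(st)[0]
    v_sphere = 4 / 3 * math.pi * 10.0**3
    assert cx == pytest.approx((v_sphere - 20.1) / 20.1)


def test_protrusion_dense_cluster_floors_at_zero():
    # enough atoms inside the sphere that V_int saturates
    n_side = 12
    grid = np.array(
        [[x, y, z] for x in range(n_side) for y in range(n_side)
         for z in range(n_side)],
        dtype=float,
    ) * 1.8
    center = grid.mean(axis=0)
    atoms = [pf.Atom(f"C{i}", "C", p) for i, p in enumerate(grid)]
    st = pf.Structure("dense", {"A": [pf.Residue("A", 1, "", "A", atoms)]})
    cx = pf.protrusion_index(st)
    central = int(np.argmin(np.linalg.norm(grid - center, axis=1)))
    assert cx[central] == pytest.approx(0.0)


def test_protrusion_matches_neighbor_count_formula(mixed_structure):
    cx = pf.protrusion_index(mixed_structure)
    coords = mixed_structure.atom_coords()
    v_sphere = 4 / 3 * math.pi * 10.0**3
    for i in range(0, len(coords), 7):
        count = int(np.sum(np.linalg.norm(coords - coords[i], axis=1) <= 10.0))
        v_int = min(count * 20.1, v_sphere)
        assert cx[i] == pytest.approx((v_sphere - v_int) / v_int)


# ---------------------------------------------------------------------------
# hydrogen bonds, B-factor, packing


def test_hbonds_distant_pair_zero_and_helix_interior_bonded(helix_structure):
    a = synthetic.build_backbone([("helix", 2)], seed=0)
    far = transformed(synthetic.build_backbone([("helix", 2)], seed=0),
                      np.eye(3), np.array([50.0, 0, 0]))
    st = pf.Structure("far", {"A": a.chains["A"], "B": far.chains["A"]})
    assert pf.hydrogen_bond_counts(st).sum() == 0
    counts = pf.hydrogen_bond_counts(helix_structure)
    assert (counts[4:16] >= 1).all()


def test_hbond_counted_for_both_partners():
    helix = synthetic.build_backbone([("helix", 8)], seed=0)
    counts = pf.hydrogen_bond_counts(helix)
    # each bond adds one to the donor and one to the acceptor residue
    bb = pf._backbone(helix.chains["A"])
    H = pf._impute_amide_h(bb)
    total_bonds = 0
    n = len(helix.chains["A"])
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 2 or np.isnan(H[i]).any():
                continue
            d = np.linalg.norm(bb["N"][i] - bb["O"][j])
            if d < 3.9:
                v1 = bb["N"][i] - H[i]
                v2 = bb["O"][j] - H[i]
                cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if math.degrees(math.acos(np.clip(cos, -1, 1))) > 90:
                    total_bonds += 1
    assert counts.sum() == 2 * total_bonds


def test_bfactor_mean_and_packing_closed_form():
    atoms = [
        pf.Atom("N", "N", np.array([0.0, 0, 0]), bfactor=10.0),
        pf.Atom("CA", "C", np.array([1.5, 0, 0]), bfactor=20.0),
        pf.Atom("C", "C", np.array([2.5, 1, 0]), bfactor=30.0),
    ]
    st = pf.Structure("b", {"A": [pf.Residue("A", 1, "", "A", atoms)]})
    bmean, packing = pf.bfactor_and_packing(st)
    assert bmean[0] == pytest.approx(20.0)
    assert packing[0] == pytest.approx(3 / (4 / 3 * math.pi * 8.0**3))


def test_packing_matches_bruteforce(mixed_structure):
    _, packing = pf.bfactor_and_packing(mixed_structure)
    coords = mixed_structure.atom_coords()
    v = 4 / 3 * math.pi * 8.0**3
    for ri, res in enumerate(mixed_structure.residues()):
        centroid = res.coords().mean(axis=0)
        count = int(np.sum(np.linalg.norm(coords - centroid, axis=1) <= 8.0))
        assert packing[ri] == pytest.approx(count / v)


# ---------------------------------------------------------------------------
# rigid-motion invariance


def test_descriptors_invariant_under_rigid_motion(mixed_structure):
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    t = np.array([11.0, -5.0, 23.0])
    moved = transformed(mixed_structure, rot, t)

    sasa_a = pf.compute_sasa(mixed_structure)
    sasa_b = pf.compute_sasa(moved)
    assert abs(sasa_a.sum() - sasa_b.sum()) / sasa_a.sum() < 0.01

    hse_a = pf.half_sphere_exposure(mixed_structure)
    hse_b = pf.half_sphere_exposure(moved)
    for k in hse_a:
        np.testing.assert_array_equal(hse_a[k], hse_b[k])

    np.testing.assert_allclose(
        pf.protrusion_index(mixed_structure), pf.protrusion_index(moved),
        atol=1e-6,
    )
    pa, _ = pf.backbone_torsions(mixed_structure)
    pb, _ = pf.backbone_torsions(moved)
    np.testing.assert_allclose(pa[1:], pb[1:], atol=1e-6)
    _, pk_a = pf.bfactor_and_packing(mixed_structure)
    _, pk_b = pf.bfactor_and_packing(moved)
    np.testing.assert_allclose(pk_a, pk_b, atol=1e-9)


def test_descriptor_table_has_fixed_columns(mixed_structure):
    df = pf.descriptors_table(mixed_structure)
    assert len(df) == 30
    for col in ("ss3", "phi", "psi", "cn", "dpx", "cx", "hbonds",
                "bfactor_mean", "packing", "sasa_all", "rsa_all"):
        assert col in df.columns
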