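"""Interface features: interaction counts, delta-SASA, hydrophobicity,
surface tension, superposition RMSD and feature-vector assembly."""

import numpy as np
import pytest

from ppaffinity.features import (
    FeatureOptions,
    InteractionCriteria,
    MissingCovariateError,
    build_feature_vector,
    compute_interactions,
    delta_sasa,
    feature_table,
    hydrophobicity_score,
    interface_rmsd,
    kabsch_superpose,
    surface_tension,
)
from ppaffinity.features import _hydrophobicity_table, _tension_table
from ppaffinity.sasa import vdw_radius
from ppaffinity.simulate import generate_toy_complex
from ppaffinity.structures import AffinityRecord, AssayMethod, AtomRecord, ComplexEntry, parse_complex

from conftest import random_entry

CRITERIA = InteractionCriteria()


def _entry(atoms):
    return ComplexEntry("FIX1", frozenset({"A"}), frozenset({"B"}), atoms)


# --------------------------------------------------------------------------
# independent naive classifier used as the oracle (plain loops, no trees)

_POS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
        ("HIS", "ND1"), ("HIS", "NE2")}
_NEG = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_RINGS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_APOLAR_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}


def _oracle_counts(entry, criteria=CRITERIA):
    rec = [a for a in entry.group_atoms("receptor") if a.element != "H" and not a.is_hetero]
    lig = [a for a in entry.group_atoms("ligand") if a.element != "H" and not a.is_hetero]

    def rings(atoms):
        found = []
        residues = {}
        for i, a in enumerate(atoms):
            if a.residue_name in _RINGS and a.atom_name in _RINGS[a.residue_name]:
                residues.setdefault((a.chain_id, a.residue_seq, a.residue_name), []).append(i)
        for (c, s, rn), idx in residues.items():
            if {atoms[i].atom_name for i in idx} == _RINGS[rn]:
                centroid = np.mean([[atoms[i].x, atoms[i].y, atoms[i].z] for i in idx], axis=0)
                found.append((centroid, set(idx)))
        return found

    counts = dict.fromkeys(
        ["disulfide", "salt_bridge", "hydrogen_bond", "cation_pi", "aromatic",
         "hydrophobic", "vdw_contact"], 0)
    excl = set()
    for ca, ia in rings(rec):
        for cb, ib in rings(lig):
            if np.linalg.norm(ca - cb) <= criteria.aromatic:
                counts["aromatic"] += 1
                excl |= {(i, j) for i in ia for j in ib}
    for i, a in enumerate(rec):
        if (a.residue_name, a.atom_name) in _POS:
            for cb, ib in rings(lig):
                if np.linalg.norm([a.x - cb[0], a.y - cb[1], a.z - cb[2]]) <= criteria.cation_pi:
                    counts["cation_pi"] += 1
                    excl |= {(i, j) for j in ib}
    for j, b in enumerate(lig):
        if (b.residue_name, b.atom_name) in _POS:
            for ca, ia in rings(rec):
                if np.linalg.norm([b.x - ca[0], b.y - ca[1], b.z - ca[2]]) <= criteria.cation_pi:
                    counts["cation_pi"] += 1
                    excl |= {(i, j) for i in ia}

    def apolar(a):
        return a.element == "C" and a.atom_name not in ("C", "CA") and a.residue_name in _APOLAR_RES

    for i, a in enumerate(rec):
        for j, b in enumerate(lig):
            d = np.linalg.norm([a.x - b.x, a.y - b.y, a.z - b.z])
            ka, kb = (a.residue_name, a.atom_name), (b.residue_name, b.atom_name)
            if ka == ("CYS", "SG") and kb == ("CYS", "SG") and d <= criteria.disulfide:
                counts["disulfide"] += 1
            elif d <= criteria.salt_bridge and (
                (ka in _POS and kb in _NEG) or (ka in _NEG and kb in _POS)
            ):
                counts["salt_bridge"] += 1
            elif d <= criteria.hydrogen_bond and a.element in "NO" and b.element in "NO":
                counts["hydrogen_bond"] += 1
            elif (i, j) in excl:
                continue
            elif d <= criteria.hydrophobic and apolar(a) and apolar(b):
                counts["hydrophobic"] += 1
            elif d <= vdw_radius(a.element) + vdw_radius(b.element) + criteria.vdw_slack:
                counts["vdw_contact"] += 1
    return counts


class TestInteractions:
    def test_single_backbone_hbond(self):
        atoms = [
            AtomRecord(1, "N", "N", "GLY", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "O", "O", "GLY", 1, "B", 2.9, 0.0, 0.0),
        ]
        counts = compute_interactions(_entry(atoms))
        assert counts["hydrogen_bond"] == 1
        assert sum(counts.values()) == 1

    def test_distant_chains_have_no_contacts(self):
        atoms = [
            AtomRecord(1, "N", "N", "GLY", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "O", "O", "GLY", 1, "B", 50.0, 0.0, 0.0),
        ]
        assert sum(compute_interactions(_entry(atoms)).values()) == 0

    def test_salt_bridge_takes_precedence_over_hbond(self):
        atoms = [
            AtomRecord(1, "NZ", "N", "LYS", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "OD1", "O", "ASP", 1, "B", 3.2, 0.0, 0.0),
        ]
        counts = compute_interactions(_entry(atoms))
        assert counts["salt_bridge"] == 1 and counts["hydrogen_bond"] == 0

    def test_random_fixture_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            entry = random_entry(rng, n_per_chain=50, box=12.0)
            assert compute_interactions(entry) == _oracle_counts(entry)

    def test_unknown_element_warned_and_excluded(self):
        atoms = [
            AtomRecord(1, "N", "N", "GLY", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "XX", "XQ", "UNK", 1, "B", 3.0, 0.0, 0.0),
            AtomRecord(3, "O", "O", "GLY", 2, "B", 2.9, 0.0, 0.0),
        ]
        with pytest.warns(UserWarning, match="XQ"):
            counts = compute_interactions(_entry(atoms))
        assert counts["hydrogen_bond"] == 1


class TestPlantedComplexes:
    def test_planted_truth_recovered(self, rng):
        classes = ["hydrogen_bond", "salt_bridge", "disulfide", "hydrophobic",
                   "vdw_contact", "aromatic", "cation_pi"]
        for _ in range(20):
            spec = {c: int(rng.integers(0, 3)) for c in rng.choice(classes, 3, replace=False)}
            pdb, truth = generate_toy_complex(spec)
            entry = parse_complex(pdb, {"A"}, {"B"})
            assert compute_interactions(entry) == truth

    def test_separated_chains_have_no_contacts_and_no_burial(self):
        pdb, truth = generate_toy_complex({"hydrogen_bond": 2}, extra_separation=100.0)
        entry = parse_complex(pdb, {"A"}, {"B"})
        assert sum(compute_interactions(entry).values()) == 0
        assert sum(truth.values()) == 0
        ds = delta_sasa(entry, n_points=240)
        assert abs(ds["delta_sasa"]) < 1e-6

    def test_intermediate_separation_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_complex({"hydrogen_bond": 1}, extra_separation=3.0)


class TestDeltaSasa:
    def test_contacting_chains_bury_area(self):
        pdb, _ = generate_toy_complex({"hydrogen_bond": 1})
        entry = parse_complex(pdb, {"A"}, {"B"})
        ds = delta_sasa(entry, n_points=240)
        assert ds["delta_sasa"] < 0
        assert ds["sasa_complex"] == pytest.approx(
            ds["sasa_receptor"] + ds["sasa_ligand"] + ds["delta_sasa"], abs=1e-9
        )

    def test_two_sphere_burial_matches_cap_area(self):
        # one carbon per chain at 2.0 A: buried area is two spherical caps
        atoms = [
            AtomRecord(1, "CA", "C", "GLY", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "CA", "C", "GLY", 1, "B", 2.0, 0.0, 0.0),
        ]
        ds = delta_sasa(_entry(atoms))
        r = 1.7 + 1.4
        h = r - 1.0  # cap height at equal radii, d = 2
        analytic = -2.0 * (2.0 * np.pi * r * h)
        assert ds["delta_sasa"] == pytest.approx(analytic, rel=0.02)


def _residue_chain(resnames, chain="A", spacing=8.0):
    """One CB-like atom per residue, far enough apart that all are surface."""
    return [
        AtomRecord(i + 1, "CB", "C", rn, i + 1, chain, i * spacing, 0.0, 0.0)
        for i, rn in enumerate(resnames)
    ]


class TestHydrophobicity:
    def test_ile_surface_more_hydrophobic_than_asp(self):
        ile = hydrophobicity_score(_residue_chain(["ILE"] * 5))
        asp = hydrophobicity_score(_residue_chain(["ASP"] * 5))
        assert ile > asp

    def test_single_residue_is_end_modulated_table_value(self):
        table = _hydrophobicity_table()
        score = hydrophobicity_score(_residue_chain(["TRP"]))
        assert score == pytest.approx(table["TRP"] - 0.05)

    def test_random_sequence_matches_table_mean(self, rng):
        table = _hydrophobicity_table()
        names = list(table)
        seq = [names[i] for i in rng.integers(0, len(names), 20)]
        expected = np.mean(
            [table[rn] + (-0.05 if i in (0, 19) else 0.0) for i, rn in enumerate(seq)]
        )
        assert hydrophobicity_score(_residue_chain(seq)) == pytest.approx(expected)

    def test_shipped_table_within_documented_envelope(self):
        values = list(_hydrophobicity_table().values())
        assert min(values) - 0.05 >= -1.05
        assert max(values) <= 2.05

    def test_empty_residue_set_raises(self):
        with pytest.raises(ValueError):
            hydrophobicity_score([])


class TestSurfaceTension:
    def test_all_buried_sums_to_zero(self):
        atoms = _residue_chain(["ALA", "GLY"])
        assert surface_tension(atoms, surface_threshold=1e9) == 0.0

    def test_single_residue_equals_atomic_sum(self):
        element_tab, overrides = _tension_table()
        atoms = [
            AtomRecord(1, "CB", "C", "ASP", 1, "A", 0.0, 0.0, 0.0),
            AtomRecord(2, "OD1", "O", "ASP", 1, "A", 1.3, 0.0, 0.0),
        ]
        expected = element_tab["C"] + overrides["ASP"]["OD1"]
        assert surface_tension(atoms) == pytest.approx(expected)

    def test_random_fixture_matches_summation_oracle(self, rng):
        entry = random_entry(rng, n_per_chain=25, box=14.0)
        element_tab, overrides = _tension_table()
        from ppaffinity.sasa import sasa_by_residue

        per_res = sasa_by_residue(entry.atoms)
        surface = {k for k, v in per_res.items() if v > 5.0}
        expected = 0.0
        for a in entry.atoms:
            if (a.chain_id, a.residue_seq) in surface:
                ov = overrides.get(a.residue_name, {}).get(a.atom_name)
                expected += ov if ov is not None else element_tab.get(a.element, 0.0)
        assert surface_tension(entry) == pytest.approx(expected)


def _quaternion_rmsd(bound, unbound):
    """Horn's quaternion superposition, an independent oracle for Kabsch."""
    b = bound - bound.mean(axis=0)
    u = unbound - unbound.mean(axis=0)
    m = u.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = (u**2).sum() + (b**2).sum()
    return np.sqrt(max(e0 - 2.0 * lam, 0.0) / len(b))


class TestInterfaceRmsd:
    def test_identical_coordinates_give_zero(self, rng):
        xyz = rng.uniform(0, 10, (6, 3))
        assert interface_rmsd(xyz, xyz.copy()) == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_removed(self, rng):
        xyz = rng.uniform(0, 10, (6, 3))
        assert interface_rmsd(xyz, xyz + np.array([5.0, 0, 0])) == pytest.approx(0.0, abs=1e-9)

    def test_rotation_plus_translation_removed(self, rng):
        xyz = rng.uniform(0, 10, (8, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.linalg.det(q)
        assert interface_rmsd(xyz, xyz @ q.T + 3.0) == pytest.approx(0.0, abs=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        bound = rng.uniform(0, 10, (4, 3))
        unbound = bound.copy()
        unbound[2] += np.array([2.0, 0.0, 0.0])
        assert interface_rmsd(bound, unbound) == pytest.approx(
            _quaternion_rmsd(bound, unbound), abs=1e-8
        )
        for _ in range(5):
            b = rng.uniform(0, 10, (10, 3))
            u = b + rng.normal(0, 0.8, (10, 3))
            assert interface_rmsd(b, u) == pytest.approx(_quaternion_rmsd(b, u), abs=1e-8)

    def test_mapping_subsets_pairs(self, rng):
        xyz = rng.uniform(0, 10, (6, 3))
        mapping = [(0, 0), (2, 2), (4, 4), (5, 5)]
        assert interface_rmsd(xyz, xyz + 1.0, mapping) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_or_collinear_raise(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            interface_rmsd(line[:2], line[:2])
        with pytest.raises(ValueError):
            interface_rmsd(line, line + 0.5)

    def test_kabsch_returns_proper_rotation(self, rng):
        a = rng.uniform(0, 5, (6, 3))
        r, t, moved = kabsch_superpose(a, a[:, [1, 0, 2]] * np.array([1, 1, -1]))
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def toy_entry():
    pdb, _ = generate_toy_complex({"hydrogen_bond": 1, "hydrophobic": 1})
    entry = parse_complex(pdb, {"A"}, {"B"}, complex_id="TOY1")
    entry.resolution = 2.1
    entry.cryst_temperature = 290.0
    entry.cryst_ph = 7.0
    return entry


@pytest.fixture(scope="module")
def affinity():
    return AffinityRecord(
        "TOY1", 8.2, AssayMethod.ITC, assay_temperature=298.0, assay_ph=7.4
    )


class TestFeatureVector:
    def test_full_covariate_block(self, toy_entry, affinity):
        opts = FeatureOptions(
            cryst_conditions=True, resolution=True, assay_conditions=True,
            assay_method=True, n_points=120,
        )
        fv = build_feature_vector(toy_entry, affinity, opts)
        for col in ("cryst_temp", "cryst_pH", "resolution", "assay_temp", "assay_pH"):
            assert col in fv.values
        assert fv.values["assay_ITC"] == 1.0
        assert fv.values["assay_SPR"] == 0.0
        assert fv.values["assay_INHIBITION"] == 0.0

    def test_missing_covariate_raises_for_dropping(self, toy_entry):
        bare = AffinityRecord("TOY1", 8.2)  # no assay temperature
        with pytest.raises(MissingCovariateError):
            build_feature_vector(
                toy_entry, bare, FeatureOptions(assay_conditions=True, n_points=120)
            )

    def test_column_order_deterministic(self, toy_entry, affinity):
        opts = FeatureOptions(assay_method=True, n_points=120)
        a = feature_table([build_feature_vector(toy_entry, affinity, opts)]).to_csv()
        b = feature_table([build_feature_vector(toy_entry, affinity, opts)]).to_csv()
        assert a == b
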