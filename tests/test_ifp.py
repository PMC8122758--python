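import math

import numpy as np
import pytest

from plifdet import fixtures
from plifdet.ifp import (
    AromaticRing,
    AtomTyping,
    Donor,
    GeomThresholds,
    InteractionType,
    bit_to_descriptor,
    descriptor_residue_rank,
    descriptor_type_code,
    detect_bits,
    fingerprint_pose,
    type_ligand_pose,
    type_protein_residue,
)
from plifdet.structio import ResidueRef, Structure

from .conftest import make_atom


# ---------------------------------------------------------------------------
# Independent brute-force detector (plain math, no shared geometry helpers)
# ---------------------------------------------------------------------------

def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _angle(a, b, c):
    v1 = [a[i] - b[i] for i in range(3)]
    v2 = [c[i] - b[i] for i in range(3)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    cosang = sum(x * y for x, y in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _brute_hbond(donor, acceptor, thr):
    if _dist(donor.heavy.coords, acceptor.coords) > thr.hbond_dmax:
        return False
    if donor.hydrogens:
        return any(_angle(donor.heavy.coords, h.coords, acceptor.coords)
                   >= thr.hbond_angle_min for h in donor.hydrogens)
    if donor.neighbor_centroid is None:
        return True
    d = [donor.heavy.coords[i] - donor.neighbor_centroid[i] for i in range(3)]
    norm = math.sqrt(sum(x * x for x in d))
    if norm < 1e-9:
        return True
    ph = [donor.heavy.coords[i] + d[i] / norm for i in range(3)]
    return _angle(donor.heavy.coords, ph, acceptor.coords) >= thr.pseudo_angle_min


def brute_force_bits(res_typing, lig_typing, thr):
    """All-pairs enumeration of the seven detectors, written independently."""
    bits = [0] * 7
    for pa in res_typing.hydrophobic_atoms:
        for la in lig_typing.hydrophobic_atoms:
            if _dist(pa.coords, la.coords) <= thr.hydrophobic_dmax:
                bits[0] = 1
    for pr in res_typing.aromatic_rings:
        for lr in lig_typing.aromatic_rings:
            if _dist(pr.centroid, lr.centroid) <= thr.aromatic_dmax:
                cosang = abs(sum(x * y for x, y in zip(pr.normal, lr.normal)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang <= thr.f2f_angle_max:
                    bits[1] = 1
                elif ang <= thr.e2f_angle_max:
                    bits[2] = 1
    for d in res_typing.donors:
        for a in lig_typing.acceptors:
            if _brute_hbond(d, a, thr):
                bits[3] = 1
    for d in lig_typing.donors:
        for a in res_typing.acceptors:
            if _brute_hbond(d, a, thr):
                bits[4] = 1
    for c in res_typing.cations:
        for an in lig_typing.anions:
            if _dist(c, an) <= thr.ionic_dmax:
                bits[5] = 1
    for an in res_typing.anions:
        for c in lig_typing.cations:
            if _dist(an, c) <= thr.ionic_dmax:
                bits[6] = 1
    return np.array(bits, dtype=np.uint8)


def _random_ring(rng, center):
    basis, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    u, v = basis[:, 0], basis[:, 1]
    atoms = []
    for k in range(6):
        theta = math.radians(60 * k)
        pos = center + 1.39 * (math.cos(theta) * u + math.sin(theta) * v)
        atoms.append(make_atom(pos, serial=k + 1))
    normal = np.cross(u, v)
    return AromaticRing(atoms, np.asarray(center, dtype=float),
                        normal / np.linalg.norm(normal))


def _random_typing(rng, n_items=3, spread=8.0):
    t = AtomTyping()
    pts = lambda: rng.uniform(-spread, spread, size=3)  # noqa: E731
    for _ in range(rng.integers(0, n_items + 1)):
        t.hydrophobic_atoms.append(make_atom(pts()))
    for _ in range(rng.integers(0, 2)):
        t.aromatic_rings.append(_random_ring(rng, pts()))
    for _ in range(rng.integers(0, n_items + 1)):
        heavy = make_atom(pts(), element="O")
        hs = [make_atom(heavy.coords + rng.normal(0, 0.6, 3), element="H")
              for _ in range(rng.integers(0, 2))]
        anchor = heavy.coords + rng.normal(0, 1.0, 3) if rng.random() < 0.8 else None
        t.donors.append(Donor(heavy, hs, neighbor_centroid=anchor))
    for _ in range(rng.integers(0, n_items + 1)):
        t.acceptors.append(make_atom(pts(), element="O"))
    for _ in range(rng.integers(0, 2)):
        t.cations.append(pts())
    for _ in range(rng.integers(0, 2)):
        t.anions.append(pts())
    return t


class TestDetectBits:
    def test_parallel_rings_face_to_face(self):
        r1 = AromaticRing([], np.zeros(3), np.array([0.0, 0.0, 1.0]))
        r2 = AromaticRing([], np.array([0.0, 0.0, 3.6]), np.array([0.0, 0.0, 1.0]))
        bits = detect_bits(AtomTyping(aromatic_rings=[r1]),
                           AtomTyping(aromatic_rings=[r2]))
        assert list(bits) == [0, 1, 0, 0, 0, 0, 0]

    def test_perpendicular_rings_edge_to_face(self):
        r1 = AromaticRing([], np.zeros(3), np.array([0.0, 0.0, 1.0]))
        r2 = AromaticRing([], np.array([0.0, 0.0, 3.6]), np.array([1.0, 0.0, 0.0]))
        bits = detect_bits(AtomTyping(aromatic_rings=[r1]),
                           AtomTyping(aromatic_rings=[r2]))
        assert list(bits) == [0, 0, 1, 0, 0, 0, 0]

    def test_angle_exactly_30_is_face_to_face(self):
        # closed upper bound on the interplanar angle
        n2 = np.array([math.sin(math.radians(30)), 0.0, math.cos(math.radians(30))])
        r1 = AromaticRing([], np.zeros(3), np.array([0.0, 0.0, 1.0]))
        r2 = AromaticRing([], np.array([0.0, 0.0, 3.6]), n2)
        bits = detect_bits(AtomTyping(aromatic_rings=[r1]),
                           AtomTyping(aromatic_rings=[r2]))
        assert list(bits) == [0, 1, 0, 0, 0, 0, 0]

    def test_empty_typings_zero_bits(self):
        assert detect_bits(AtomTyping(), AtomTyping()).sum() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_randomized_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        thr = GeomThresholds()
        for _ in range(50):
            rt, lt = _random_typing(rng), _random_typing(rng)
            np.testing.assert_array_equal(
                detect_bits(rt, lt, thr), brute_force_bits(rt, lt, thr))

    def test_donor_acceptor_role_swap_symmetry(self):
        # protein donor vs ligand acceptor (bit 4) equals bit 5 of the
        # swapped configuration
        heavy = make_atom([0, 0, 0], element="N")
        h = make_atom([1.0, 0, 0], element="H")
        donor = Donor(heavy, [h])
        acceptor = make_atom([2.9, 0, 0], element="O")
        b_pd = detect_bits(AtomTyping(donors=[donor]),
                           AtomTyping(acceptors=[acceptor]))
        b_pa = detect_bits(AtomTyping(acceptors=[acceptor]),
                           AtomTyping(donors=[donor]))
        assert b_pd[3] == 1 and b_pd.sum() == 1
        assert b_pa[4] == 1 and b_pa.sum() == 1

    @pytest.mark.parametrize("seed", range(3))
    def test_shrinking_distance_thresholds_never_sets_new_bits(self, seed):
        rng = np.random.default_rng(seed)
        default = GeomThresholds()
        tighter = GeomThresholds(hydrophobic_dmax=3.5, hbond_dmax=3.0,
                                 hbond_angle_min=150.0, pseudo_angle_min=150.0,
                                 ionic_dmax=4.0, aromatic_dmax=4.0)
        for _ in range(30):
            rt, lt = _random_typing(rng), _random_typing(rng)
            loose = detect_bits(rt, lt, default)
            tight = detect_bits(rt, lt, tighter)
            assert np.all(tight <= loose)


class TestProteinTyping:
    def test_asp_anion_at_carboxylate_midpoint_no_donors(self):
        atoms = fixtures.make_residue("ASP", 1)
        typing = type_protein_residue(atoms, nobb=True)
        assert len(typing.anions) == 1
        od = [a.coords for a in atoms if a.name in ("OD1", "OD2")]
        np.testing.assert_allclose(typing.anions[0], np.mean(od, axis=0))
        assert typing.donors == []
        assert len(typing.acceptors) == 2

    def test_gly_nobb_empty(self):
        typing = type_protein_residue(fixtures.make_residue("GLY", 1), nobb=True)
        assert not (typing.hydrophobic_atoms or typing.aromatic_rings
                    or typing.donors or typing.acceptors
                    or typing.cations or typing.anions)

    def test_gly_backbone_donor_acceptor_without_nobb(self):
        typing = type_protein_residue(fixtures.make_residue("GLY", 1), nobb=False)
        assert len(typing.donors) == 1 and typing.donors[0].heavy.name == "N"
        assert len(typing.acceptors) == 1 and typing.acceptors[0].name == "O"

    def test_trp_two_rings_with_newell_normals(self):
        # independent plane fit: Newell's method over the ring polygon
        typing = type_protein_residue(fixtures.make_residue("TRP", 1))
        assert len(typing.aromatic_rings) == 2
        for ring in typing.aromatic_rings:
            coords = [a.coords for a in ring.atoms]
            n = np.zeros(3)
            for i, p in enumerate(coords):
                q = coords[(i + 1) % len(coords)]
                n += np.cross(p, q)
            n /= np.linalg.norm(n)
            angle = math.degrees(math.acos(min(1.0, abs(float(np.dot(n, ring.normal))))))
            assert angle < 1.0

    def test_unknown_residue_hydrophobic_only_with_warning(self, caplog):
        atoms = fixtures.make_residue("ALA", 1)
        for a in atoms:
            a.residue_name = "XXX"
        with caplog.at_level("WARNING"):
            typing = type_protein_residue(atoms, nobb=True)
        assert "unknown residue" in caplog.text
        # nobb strips the backbone first; only the side-chain carbon remains
        assert [a.name for a in typing.hydrophobic_atoms] == ["CB"]

    def test_his_cationic_only_on_request(self):
        atoms = fixtures.make_residue("HIS", 1)
        assert type_protein_residue(atoms).cations == []
        assert len(type_protein_residue(atoms, his_cationic=True).cations) == 1


class TestLigandTyping:
    def _benzene(self):
        atoms = []
        for k in range(6):
            theta = math.radians(60 * k)
            atoms.append(make_atom([1.39 * math.cos(theta),
                                    1.39 * math.sin(theta), 0.0], serial=k + 1))
        return Structure(atoms)

    def test_benzene_one_ring_six_hydrophobic(self):
        typing = type_ligand_pose(self._benzene())
        assert len(typing.aromatic_rings) == 1
        assert len(typing.hydrophobic_atoms) == 6
        assert typing.acceptors == [] and typing.cations == [] and typing.anions == []

    def test_methylammonium_single_cation(self):
        n = np.array([0.0, 0.0, 0.0])
        atoms = [
            make_atom(n, element="N", serial=1),
            make_atom([0.94, 0.33, 0.0], element="H", serial=2),
            make_atom([-0.47, 0.33, 0.82], element="H", serial=3),
            make_atom([-0.47, 0.33, -0.82], element="H", serial=4),
            make_atom([0.0, -1.49, 0.0], element="C", serial=5),
        ]
        typing = type_ligand_pose(Structure(atoms))
        assert len(typing.cations) == 1
        np.testing.assert_allclose(typing.cations[0], n)
        assert typing.anions == [] and typing.hydrophobic_atoms == []

    def test_acetate_anion_center_and_two_acceptors(self):
        atoms = [
            make_atom([0.0, 0.0, 0.0], element="C", serial=1),    # methyl
            make_atom([0.0, 1.52, 0.0], element="C", serial=2),   # carboxyl C
            make_atom([-1.09, 2.29, 0.0], element="O", serial=3),
            make_atom([1.09, 2.29, 0.0], element="O", serial=4),
        ]
        typing = type_ligand_pose(Structure(atoms))
        assert len(typing.anions) == 1
        np.testing.assert_allclose(typing.anions[0], [0.0, 2.29, 0.0])
        assert len(typing.acceptors) == 2
        # methyl carbon bonded only to carbon stays hydrophobic
        assert [a.serial for a in typing.hydrophobic_atoms] == [1]

    def test_missing_element_is_error(self):
        atom = make_atom([0, 0, 0])
        atom.element = "C"
        s = Structure([atom])
        s.atoms[0].element = ""
        with pytest.raises(ValueError, match="element"):
            type_ligand_pose(s)


class TestFingerprintPose:
    def test_far_pose_all_zero(self):
        toy = fixtures.make_toy_complex(
            [fixtures.PlantedInteractionSpec(InteractionType.IONIC_PROTEIN_ANION)])
        far_atoms = [make_atom(a.coords + np.array([50.0, 0, 0]), element=a.element,
                               serial=a.serial) for a in toy.pose_set.poses[0].atoms]
        fp = fingerprint_pose(toy.receptor, toy.residue_list, Structure(far_atoms))
        assert fp.bits.sum() == 0

    def test_planted_salt_bridge_sets_single_anion_bit(self):
        specs = [fixtures.PlantedInteractionSpec(InteractionType.HYDROPHOBIC),
                 fixtures.PlantedInteractionSpec(InteractionType.IONIC_PROTEIN_ANION)]
        toy = fixtures.make_toy_complex(specs, seed=11)
        fp = fingerprint_pose(toy.receptor, toy.residue_list, toy.pose_set.poses[0])
        # Asp is residue rank 2: its anion bit is (2-1)*7 + 7 = 14
        asp_bits = [k for k in fp.set_indices() if k > 7]
        assert asp_bits == [14]

    def test_missing_residue_is_error(self):
        toy = fixtures.make_toy_complex(
            [fixtures.PlantedInteractionSpec(InteractionType.HYDROPHOBIC)])
        bogus = toy.residue_list + [ResidueRef("A", 99, "GLY")]
        with pytest.raises(ValueError, match="A:GLY99"):
            fingerprint_pose(toy.receptor, bogus, toy.pose_set.poses[0])

    def test_nobb_removes_backbone_hbond(self):
        # ligand amine donating to a Gly backbone carbonyl: visible only
        # when backbone atoms participate
        receptor = Structure(fixtures.make_residue("GLY", 1))
        o = [a for a in receptor.atoms if a.name == "O"][0]
        n = o.coords + np.array([0.0, -2.9, 0.0])
        pose = Structure([
            make_atom(n, element="N", serial=1),
            make_atom(n + (o.coords - n) / np.linalg.norm(o.coords - n),
                      element="H", serial=2),
            make_atom(n + np.array([0.0, -1.49, 0.0]), element="C", serial=3),
        ])
        refs = [ResidueRef("A", 1, "GLY")]
        with_bb = fingerprint_pose(receptor, refs, pose, nobb=False)
        without_bb = fingerprint_pose(receptor, refs, pose, nobb=True)
        assert list(with_bb.bits) == [0, 0, 0, 0, 1, 0, 0]
        assert without_bb.bits.sum() == 0

    def test_bit_text_serialization(self):
        toy = fixtures.make_toy_complex(
            [fixtures.PlantedInteractionSpec(InteractionType.AROMATIC_EDGE_TO_FACE)])
        fp = fingerprint_pose(toy.receptor, toy.residue_list, toy.pose_set.poses[0])
        assert fp.to_text() == "0010000"


class TestBitToDescriptor:
    def _refs(self, n):
        return [ResidueRef("A", i + 1, "ALA") for i in range(n)]

    def test_index_63_is_ninth_residue_protein_anion(self):
        refs = self._refs(12)
        residue, itype = bit_to_descriptor(63, refs)
        assert residue == refs[8]  # 9th residue
        assert itype is InteractionType.IONIC_PROTEIN_ANION

    def test_index_207_is_thirtieth_residue_protein_donor(self):
        refs = self._refs(40)
        residue, itype = bit_to_descriptor(207, refs)
        assert residue == refs[29]
        assert itype is InteractionType.HBOND_PROTEIN_DONOR

    @pytest.mark.parametrize("k", [0, -3, 85])
    def test_out_of_range_rejected(self, k):
        with pytest.raises(ValueError):
            bit_to_descriptor(k, self._refs(12))

    def test_all_reference_indices_map_to_printed_types(self, table1):
        for record in table1.records:
            assert descriptor_type_code(record.descriptor_index) == int(record.interaction)

    def test_reference_ranks_increase_with_sequence_number(self, table1):
        for receptor, indices in table1.descriptor_lists.items():
            recs = [r for r in table1.records if r.receptor == receptor]
            ranks = [descriptor_residue_rank(k) for k in indices]
            numbers = [r.residue.residue_number for r in recs]
            assert ranks == sorted(ranks)
            assert all(r2 > r1 or (r2 == r1)
                       for r1, r2 in zip(ranks, ranks[1:]))
            # residue ranks must co-vary with residue sequence numbers
            assert numbers == sorted(numbers)
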