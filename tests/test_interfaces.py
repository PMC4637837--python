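import math

import numpy as np
import pytest

from supramol.assembly import ComplexModel, PlacedSubunit
from supramol.config import DEFAULT
from supramol.elements import build_element_dataset
from supramol.fixtures import (
    FixtureSpec,
    make_chain,
    make_dimer_model,
    make_toy_complex,
    make_two_partner_model,
)
from supramol.interfaces import (
    VDW_RADII,
    buried_area,
    classify_alternative_partners,
    collapse_homologous,
    detect_interfaces,
    flag_indirect,
    residue_sasa,
    sasa,
    type_interfaces,
)
from supramol.network import cluster_subnetworks
from supramol.assembly import build_all_models
from supramol.sequences import ProteinEntry
from supramol.structures_io import AtomRecord, ChainStructure, Residue, RigidTransform, apply_transform

from _oracles import dense_sasa


def _single_residue_chain(aa="G", atoms=None):
    atoms = atoms or [AtomRecord("CA", "C", [0.0, 0.0, 0.0])]
    return ChainStructure("A", [Residue(1, aa, atoms)])


class TestSasa:
    def test_isolated_residue_matches_dense_oracle(self, helix30):
        got = residue_sasa(helix30)
        want = dense_sasa([helix30])
        for seq, area in got.items():
            assert area == pytest.approx(want[(0, seq)], rel=0.02)

    def test_lone_atom_is_full_sphere(self):
        chain = _single_residue_chain()
        area = residue_sasa(chain)[1]
        r = VDW_RADII["C"] + DEFAULT.sasa_probe
        assert area == pytest.approx(4 * math.pi * r * r, rel=1e-6)

    def test_fully_caged_residue_has_zero_area(self):
        # surround one atom with a dense shell of cage atoms
        i = np.arange(80) + 0.5
        phi = math.pi * (3.0 - math.sqrt(5.0)) * i
        z = 1.0 - 2.0 * i / 80
        r = np.sqrt(1.0 - z * z)
        shell = np.column_stack([r * np.cos(phi), r * np.sin(phi), z]) * 2.5
        cage = ChainStructure("B", [Residue(1, "X", [
            AtomRecord("C", "C", p) for p in shell])])
        center = _single_residue_chain()
        areas = sasa([center, cage])
        assert areas[(0, 1)] == 0.0

    def test_additivity_for_distant_chains(self, helix30):
        far = apply_transform(helix30, RigidTransform(np.eye(3), np.array([200.0, 0, 0])))
        iso = residue_sasa(helix30)
        both = sasa([helix30, far])
        for seq, area in iso.items():
            assert both[(0, seq)] == pytest.approx(area, abs=1e-9)

    def test_neighbours_only_reduce_area(self, star_pipeline):
        model = star_pipeline["models"][0]
        hub = model.subunits[0]
        iso = residue_sasa(hub.chain)
        group = sasa([s.chain for s in model.subunits])
        for seq, area in iso.items():
            assert group[(0, seq)] <= area + 1e-9


class TestBuriedArea:
    def test_disjoint_subunits_bury_nothing(self, helix30):
        far = apply_transform(helix30, RigidTransform(np.eye(3), np.array([120.0, 0, 0])))
        far.source_protein = "B"
        model = ComplexModel(model_id="m", subunits=[
            PlacedSubunit("A", "A", helix30, None, "A", RigidTransform.identity()),
            PlacedSubunit("B", "B", far, None, "B", RigidTransform.identity()),
        ])
        area_a, area_b, res_a, res_b = buried_area(model, "A", "B")
        assert area_a == 0.0 and area_b == 0.0
        assert res_a == set() and res_b == set()

    def test_planted_contact_matches_dense_oracle(self):
        model = make_dimer_model(400.0, seed=5)
        a = model.subunit("D001").chain
        b = model.subunit("D002").chain
        area_a, area_b, res_a, res_b = buried_area(model, "D001", "D002")
        iso_a = dense_sasa([a])
        both = dense_sasa([a, b])
        oracle_a = sum(iso_a[(0, s)] - both[(0, s)] for (c, s) in both if c == 0)
        assert area_a == pytest.approx(oracle_a, rel=0.02)
        assert res_a and res_b

    def test_sides_roughly_symmetric_for_compact_contacts(self):
        for seed in (1, 2, 3):
            model = make_dimer_model(380.0, seed=seed)
            area_a, area_b, _, _ = buried_area(model, "D001", "D002")
            assert abs(area_a - area_b) / max(area_a, area_b) < 0.25


class TestDetectInterfaces:
    def test_area_threshold_family(self):
        """Contacts burying well under / over 250 A^2 classify exactly."""
        for target, expected in [(150, 0), (200, 0), (320, 1), (400, 1), (500, 1)]:
            model = make_dimer_model(float(target), seed=target)
            assert len(detect_interfaces(model)) == expected

    def test_hub_with_independent_patches_has_two_interfaces(self):
        model = make_two_partner_model(180.0)
        ifaces = detect_interfaces(model)
        hub_ifaces = [f for f in ifaces if "H001" in (f.subunit_a, f.subunit_b)]
        assert len(hub_ifaces) == 2
        for f in hub_ifaces:
            assert not f.alternative_partners

    @pytest.mark.parametrize("gamma,expect_alt", [
        (180.0, False), (150.0, False), (120.0, True), (90.0, True), (60.0, True),
    ])
    def test_overlap_rule_follows_shared_area_oracle(self, gamma, expect_alt):
        """Sites merge at >=10% shared buried area, stay distinct below."""
        model = make_two_partner_model(gamma)
        ifaces = detect_interfaces(model)
        pairs = {frozenset((f.subunit_a, f.subunit_b)): f for f in ifaces}
        f1 = pairs[frozenset(("H001", "H002"))]
        f2 = pairs[frozenset(("H001", "H003"))]
        # oracle: shared buried area fraction from dense sampling
        hub = model.subunit("H001").chain
        iso = dense_sasa([hub], n_points=4000)
        losses = []
        for other in ("H002", "H003"):
            both = dense_sasa([hub, model.subunit(other).chain], n_points=4000)
            losses.append({s: iso[(0, s)] - both[(0, s)]
                           for (c, s) in both if c == 0
                           and iso[(0, s)] - both[(0, s)] > 0.1})
        shared = sum(min(losses[0][r], losses[1][r])
                     for r in set(losses[0]) & set(losses[1]))
        frac = shared / min(sum(losses[0].values()), sum(losses[1].values()))
        assert (frac >= 0.10) == expect_alt, f"gamma={gamma} oracle frac={frac:.3f}"
        got_alt = "H003" in f1.alternative_partners
        assert got_alt == expect_alt
        assert ("H002" in f2.alternative_partners) == expect_alt


@pytest.fixture(scope="module")
def ring_annotated():
    """Ring with a dropped interaction (suggested) and a dropped structure
    (predicted), fully typed."""
    b = make_toy_complex(FixtureSpec(seed=71, n_proteins=5, topology="ring",
                                     drop_interaction=((0, 4),)))
    elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
    net = cluster_subnetworks(elements)[0]
    model = build_all_models(net, elements)[0]
    ifaces = type_interfaces(model, b.interactions, elements)
    return b, elements, model, ifaces


class TestTypeInterfaces:
    def test_element_joined_pairs_are_experimental(self, ring_annotated):
        b, elements, model, ifaces = ring_annotated
        by_pair = {frozenset((f.subunit_a, f.subunit_b)): f.type for f in ifaces}
        assert by_pair[frozenset(("P001", "P002"))] == "experimental"
        assert by_pair[frozenset(("P004", "P005"))] == "experimental"

    def test_unrecorded_contact_is_model_suggested(self, ring_annotated):
        b, elements, model, ifaces = ring_annotated
        by_pair = {frozenset((f.subunit_a, f.subunit_b)): f.type for f in ifaces}
        assert by_pair[frozenset(("P001", "P005"))] == "model_suggested"

    def test_recorded_contact_without_template_is_model_predicted(self):
        b = make_toy_complex(FixtureSpec(seed=72, n_proteins=5, topology="ring",
                                         drop_structure=((0, 4),)))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        model = build_all_models(net, elements)[0]
        ifaces = type_interfaces(model, b.interactions, elements)
        by_pair = {frozenset((f.subunit_a, f.subunit_b)): f.type for f in ifaces}
        assert by_pair[frozenset(("P001", "P005"))] == "model_predicted"

    def test_types_partition_interfaces(self, ring_annotated):
        _, _, _, ifaces = ring_annotated
        assert all(f.type in ("experimental", "model_predicted", "model_suggested")
                   for f in ifaces)


class TestFlagIndirect:
    def test_complete_table_over_path_flags_non_adjacent(self):
        b = make_toy_complex(FixtureSpec(seed=73, n_proteins=4, topology="complete"))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        model = build_all_models(net, elements)[0]
        assert model.size == 4
        flags = dict((pair, direct) for pair, direct, _ in
                     flag_indirect(model, b.interactions))
        # oracle: independent dense-sampling buried area with the 250 A^2 rule
        protein_chain = {s.protein: s.chain for s in model.subunits}
        for pair, direct in flags.items():
            ca, cb = protein_chain[pair[0]], protein_chain[pair[1]]
            iso_a = dense_sasa([ca], n_points=2000)
            iso_b = dense_sasa([cb], n_points=2000)
            both = dense_sasa([ca, cb], n_points=2000)
            loss_a = sum(iso_a[(0, s)] - both[(0, s)] for (c, s) in both if c == 0)
            loss_b = sum(iso_b[(0, s)] - both[(1, s)] for (c, s) in both if c == 1)
            assert direct == (max(loss_a, loss_b) > 250.0), (pair, loss_a, loss_b)

    def test_direct_indirect_partition_recorded_pairs(self):
        b = make_toy_complex(FixtureSpec(seed=74, n_proteins=5, topology="complete"))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        model = build_all_models(net, elements)[0]
        flags = flag_indirect(model, b.interactions)
        placed = {s.protein for s in model.subunits}
        recorded = [r for r in b.interactions
                    if r.acc_a in placed and r.acc_b in placed]
        assert len(flags) == len(recorded)
        n_indirect = sum(1 for _, direct, _ in flags if not direct)
        assert n_indirect >= 1  # ring geometry cannot realize all recorded contacts


class TestCollapseHomologous:
    def _two_dimer_model(self, ident_high):
        rng = np.random.default_rng(99)
        from supramol.fixtures import _distinct_sequence, _mutated_to_identity

        seq_a = _distinct_sequence(rng, 30, [], DEFAULT)
        seq_b = _distinct_sequence(rng, 30, [seq_a], DEFAULT)
        if ident_high:
            seq_c = _mutated_to_identity(seq_a, 0.6)
            seq_d = _mutated_to_identity(seq_b, 0.6)
        else:
            seq_c = _distinct_sequence(rng, 30, [seq_a, seq_b], DEFAULT)
            seq_d = _distinct_sequence(rng, 30, [seq_a, seq_b, seq_c], DEFAULT)
        m1 = make_dimer_model(400.0, seed=1)
        chains = {}
        names = ["PA", "PB", "PC", "PD"]
        seqs = [seq_a, seq_b, seq_c, seq_d]
        subs = []
        shift = np.array([0.0, 80.0, 0.0])
        for i, (name, seq) in enumerate(zip(names, seqs)):
            base = m1.subunits[i % 2].chain
            chain = base.copy()
            for ri, res in enumerate(chain.residues):
                res.aa = seq[ri]
                if i >= 2:
                    for atom in res.atoms:
                        atom.coords = atom.coords + shift
            subs.append(PlacedSubunit(name, name, chain, None, name,
                                      RigidTransform.identity()))
        model = ComplexModel(model_id="m", subunits=subs)
        proteins = {n: ProteinEntry(n, s) for n, s in zip(names, seqs)}
        return model, proteins

    def test_homologous_pairs_collapse(self):
        model, proteins = self._two_dimer_model(ident_high=True)
        ifaces = detect_interfaces(model)
        assert len(ifaces) == 2
        reps = collapse_homologous(ifaces, proteins, model)
        assert len(reps) == 1

    def test_unrelated_pairs_unchanged(self):
        model, proteins = self._two_dimer_model(ident_high=False)
        ifaces = detect_interfaces(model)
        assert len(ifaces) == 2
        reps = collapse_homologous(ifaces, proteins, model)
        assert len(reps) == 2


class TestClassifyAlternativePartners:
    def test_three_way_classification(self):
        rng = np.random.default_rng(5)
        from supramol.fixtures import _distinct_sequence, _mutated_to_identity

        seq_a = _distinct_sequence(rng, 30, [], DEFAULT)
        seq_hom = _mutated_to_identity(seq_a, 0.6)
        seq_fold = _distinct_sequence(rng, 30, [seq_a, seq_hom], DEFAULT)
        seq_diff = _distinct_sequence(rng, 30, [seq_a, seq_hom, seq_fold], DEFAULT)
        chains = {
            "A": make_chain("A", seq_a, "helix"),
            "HOM": make_chain("HOM", seq_hom, "helix"),
            "FOLD": make_chain("FOLD", seq_fold, "helix"),
            "DIFF": make_chain("DIFF", seq_diff, "extended"),
        }
        proteins = {k: ProteinEntry(k, c.sequence) for k, c in chains.items()}
        records = [("X", "A", "HOM"), ("X", "A", "FOLD"), ("X", "A", "DIFF")]
        counts = classify_alternative_partners(records, chains, proteins)
        assert counts == {"homologous": 1, "same_fold": 1, "different_fold": 1}
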