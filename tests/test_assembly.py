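import json

import numpy as np
import pytest

from supramol.assembly import (
    ComplexModel,
    PlacedSubunit,
    build_all_models,
    clash,
    grow_model,
    select_anchor,
)
from supramol.config import DEFAULT
from supramol.elements import build_element_dataset
from supramol.fixtures import FixtureSpec, make_chain, make_toy_complex
from supramol.network import cluster_subnetworks
from supramol.structures_io import RigidTransform, apply_transform

from test_network import stub_element


def _placed(chain, sid=None):
    sid = sid or chain.source_protein or "S"
    return PlacedSubunit(subunit_id=sid, protein=sid, chain=chain,
                         introduced_by=None, anchor=sid,
                         transform=RigidTransform.identity())


class TestClash:
    def test_far_candidate_no_clash(self, helix30):
        far = apply_transform(helix30, RigidTransform(np.eye(3), np.array([80.0, 0, 0])))
        assert clash([_placed(helix30, "A")], far) is False

    def test_exact_overlay_clashes(self, helix30):
        assert clash([_placed(helix30, "A")], helix30.copy()) is True

    @pytest.mark.parametrize("n_close,expected", [(8, False), (12, True)])
    def test_pair_budget_boundary(self, helix30, n_close, expected):
        """Candidate engineered to have exactly n_close CA pairs below 3 A."""
        cand = helix30.copy()
        for i, res in enumerate(cand.residues):
            shift = np.array([0.5, 0.0, 0.0]) if i < n_close else np.array([50.0, 0, 0])
            for atom in res.atoms:
                atom.coords = atom.coords + shift
        # brute-force oracle count
        from scipy.spatial.distance import cdist

        count = int((cdist(cand.ca_coords(), helix30.ca_coords()) < DEFAULT.clash_dist).sum())
        assert count == n_close
        assert clash([_placed(helix30, "A")], cand) is expected


class TestSelectAnchor:
    def _model(self, order):
        subs = [_placed(make_chain(p, "A" * 16, "helix"), p) for p in order]
        return ComplexModel(model_id="m", subunits=subs)

    def test_highest_degree_wins(self):
        nets = cluster_subnetworks([stub_element("A", "B"), stub_element("A", "C"),
                                    stub_element("A", "D")])
        model = self._model(["B", "A", "C"])
        assert select_anchor(model, nets[0], set()) == "A"

    def test_exhausted_falls_back_to_placement_order(self):
        nets = cluster_subnetworks([stub_element("A", "B"), stub_element("A", "C")])
        model = self._model(["A", "C", "B"])  # C placed before B, same degree
        assert select_anchor(model, nets[0], {"A"}) == "C"

    def test_all_exhausted_terminates(self):
        nets = cluster_subnetworks([stub_element("A", "B")])
        model = self._model(["A", "B"])
        assert select_anchor(model, nets[0], {"A", "B"}) is None


@pytest.fixture(scope="module")
def clash_star():
    """Star with two leaves planted on the same hub site."""
    b = make_toy_complex(FixtureSpec(seed=61, n_proteins=4, topology="star",
                                     clash_pairs=((1, 2),)))
    elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
    nets = cluster_subnetworks(elements)
    return b, elements, nets[0]


class TestGrowModel:
    def test_star_recovers_all_subunits(self, star_pipeline):
        b = star_pipeline["bundle"]
        net = star_pipeline["nets"][0]
        model = grow_model("P001", net, star_pipeline["elements"])
        assert sorted(model.proteins) == ["P001", "P002", "P003", "P004"]
        assert model.validate_no_clashes()

    def test_clash_yields_smaller_model_and_alternative_record(self, clash_star):
        b, elements, net = clash_star
        model = grow_model("P001", net, elements)
        assert model.size == 3
        assert len(model.alternative_records) == 1
        owner, pa, pb = model.alternative_records[0]
        assert owner == "P001" and {pa, pb} == {"P002", "P003"}

    def test_single_edge_subnetwork_is_seed_dimer(self):
        b = make_toy_complex(FixtureSpec(seed=62, n_proteins=2, topology="path"))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        model = grow_model("P001", net, elements)
        assert model.size == 2
        assert all(s.anchor == s.subunit_id for s in model.subunits)

    def test_rejected_superposition_is_logged_not_placed(self):
        b = make_toy_complex(FixtureSpec(seed=63, n_proteins=3, topology="path",
                                         misfold_edges=((1, 2),)))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        model = grow_model("P001", net, elements)
        assert model.size == 2  # the misfolded template cannot anchor P003
        assert any(r["reason"] == "gate" for r in model.rejections)

    def test_non_seed_subunits_anchor_on_placed_subunits(self, star_pipeline):
        model = grow_model("P002", star_pipeline["nets"][0], star_pipeline["elements"])
        ids_in_order = []
        for su in model.subunits:
            if su.anchor != su.subunit_id:
                assert su.anchor in ids_in_order
            ids_in_order.append(su.subunit_id)

    def test_unknown_start_rejected(self, star_pipeline):
        with pytest.raises(ValueError):
            grow_model("NOPE", star_pipeline["nets"][0], star_pipeline["elements"])


class TestBuildAllModels:
    def test_path_dedups_to_single_model(self):
        b = make_toy_complex(FixtureSpec(seed=64, n_proteins=3, topology="path"))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        models = build_all_models(net, elements)
        assert len(models) == 1
        assert models[0].size == 3

    def test_incompatible_halves_survive_dedup(self):
        b = make_toy_complex(FixtureSpec(seed=65, n_proteins=3, topology="two_blocks",
                                         clash_pairs=((1, 2),)))
        elements, _ = build_element_dataset(b.interactions, b.proteins, b.library)
        net = cluster_subnetworks(elements)[0]
        models = build_all_models(net, elements)
        assert len(models) == 2
        protein_sets = {frozenset(m.proteins) for m in models}
        assert protein_sets == {frozenset({"P001", "P002"}), frozenset({"P001", "P003"})}

    def test_degree_and_random_modes_agree_on_mean_size(self, clash_star):
        b, elements, net = clash_star
        degree_sizes = [m.size for m in build_all_models(net, elements, mode="degree")]
        random_means = []
        for seed in range(10):
            sizes = [m.size for m in build_all_models(net, elements,
                                                      mode="random", seed=seed)]
            random_means.append(np.mean(sizes))
        assert abs(np.mean(degree_sizes) - np.mean(random_means)) < 0.5

    def test_random_mode_reproducible_per_seed(self, clash_star):
        b, elements, net = clash_star
        a = build_all_models(net, elements, mode="random", seed=3)
        c = build_all_models(net, elements, mode="random", seed=3)
        assert [m.proteins for m in a] == [m.proteins for m in c]
        for ma, mc in zip(a, c):
            for sa, sc in zip(ma.subunits, mc.subunits):
                np.testing.assert_array_equal(sa.chain.ca_coords(), sc.chain.ca_coords())

    def test_models_sorted_by_size_and_clash_free(self, clash_star):
        b, elements, net = clash_star
        models = build_all_models(net, elements)
        sizes = [m.size for m in models]
        assert sizes == sorted(sizes, reverse=True)
        assert all(m.validate_no_clashes() for m in models)


class TestDeterminism:
    def test_degree_mode_provenance_is_byte_identical(self, tmp_path, star_pipeline):
        from supramol.structures_io import write_complex

        b = star_pipeline["bundle"]
        net = star_pipeline["nets"][0]
        blobs = []
        for run in (1, 2):
            model = grow_model("P001", net, star_pipeline["elements"])
            d = tmp_path / f"run{run}"
            d.mkdir()
            p = d / "model.pdb"
            write_complex(model, p)
            blobs.append(p.read_bytes() +
                         p.with_suffix(".pdb.provenance.json").read_bytes())
        assert blobs[0] == blobs[1]
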