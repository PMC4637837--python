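"""Iterative growth of complex models by superposing shared subunits.

Given a modelable sub-network and its template elements, a model is grown
from a starting protein: the seed element places the first two subunits,
then, repeatedly, the placed subunit with the highest interaction degree
anchors further placements.  For every unused element incident to the
anchor's protein, the element's shared-protein chain is structurally
superposed onto the anchor; the placement is kept only if it clears the
identity/TM-score acceptance gate and does not sterically clash with the
subunits already placed.  A clash means the two partners compete for the
same site on the anchor, and is recorded as an alternative interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .config import DEFAULT, Config
from .elements import PPIElement
from .network import SubNetwork
from .structures_io import ChainStructure, RigidTransform, apply_transform
from .superpose import SuperpositionResult, accept_superposition, structure_align

__all__ = [
    "PlacedSubunit",
    "ComplexModel",
    "clash",
    "select_anchor",
    "grow_model",
    "build_all_models",
]


@dataclass
class PlacedSubunit:
    subunit_id: str
    protein: str
    chain: ChainStructure            # coordinates in the model frame
    introduced_by: Optional[PPIElement]
    anchor: str                      # subunit_id of the anchoring subunit
    transform: RigidTransform        # template frame -> model frame
    template_chain: Optional[ChainStructure] = None  # untransformed template


@dataclass
class ComplexModel:
    model_id: str
    subunits: List[PlacedSubunit] = field(default_factory=list)
    alternative_records: List[Tuple[str, str, str]] = field(default_factory=list)
    start_subunit: str = ""
    subnetwork_ref: str = ""
    joined_pairs: Set[Tuple[str, str]] = field(default_factory=set)
    rejections: List[dict] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.subunits)

    @property
    def proteins(self) -> List[str]:
        return [s.protein for s in self.subunits]

    def subunit(self, subunit_id: str) -> PlacedSubunit:
        for s in self.subunits:
            if s.subunit_id == subunit_id:
                return s
        raise KeyError(subunit_id)

    def template_entries(self) -> Set[str]:
        return {s.chain.source_entry for s in self.subunits}

    def validate_no_clashes(self, cfg: Config = DEFAULT) -> bool:
        """Post-hoc re-check that no placed pair violates the clash predicate."""
        for i, a in enumerate(self.subunits):
            for b in self.subunits[i + 1:]:
                if _close_pair_count(a.chain, b.chain, cfg) >= cfg.clash_max_pairs:
                    return False
        return True


def _close_pair_count(a: ChainStructure, b: ChainStructure, cfg: Config) -> int:
    ca_a = a.ca_coords()
    ca_b = b.ca_coords()
    ca_a = ca_a[np.all(np.isfinite(ca_a), axis=1)]
    ca_b = ca_b[np.all(np.isfinite(ca_b), axis=1)]
    if len(ca_a) == 0 or len(ca_b) == 0:
        return 0
    return int((cdist(ca_a, ca_b) < cfg.clash_dist).sum())


def clash(existing: Sequence[PlacedSubunit], candidate: ChainStructure,
          cfg: Config = DEFAULT) -> bool:
    """True iff the candidate overlaps the placed subunits.

    The predicate counts candidate-vs-existing C-alpha pairs closer than
    the clash distance, over all placed subunits; reaching the pair budget
    means the candidate cannot occupy the site.
    """
    total = 0
    for su in existing:
        total += _close_pair_count(candidate, su.chain, cfg)
        if total >= cfg.clash_max_pairs:
            return True
    return False


def _clash_partner(existing: Sequence[PlacedSubunit], candidate: ChainStructure,
                   cfg: Config) -> Optional[PlacedSubunit]:
    """The placed subunit contributing the most close pairs (the blocker)."""
    best, best_n = None, 0
    for su in existing:
        n = _close_pair_count(candidate, su.chain, cfg)
        if n > best_n:
            best, best_n = su, n
    return best


def select_anchor(model: ComplexModel, net: SubNetwork,
                  exhausted: Set[str]) -> Optional[str]:
    """Highest-degree placed subunit not yet exhausted as an anchor.

    Ties are broken by placement order, then accession.  Returns None when
    every placed subunit has been exhausted (assembly terminates).
    """
    if not model.subunits:
        raise ValueError("cannot select an anchor in an empty model")
    candidates = [
        (idx, su) for idx, su in enumerate(model.subunits)
        if su.subunit_id not in exhausted
    ]
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-net.degree.get(t[1].protein, 0), t[0], t[1].protein))
    return candidates[0][1].subunit_id


def _place_seed(model: ComplexModel, elem: PPIElement, start: str) -> None:
    ident = RigidTransform.identity()
    acc_a, acc_b = elem.interaction.acc_a, elem.interaction.acc_b
    homodimer = acc_a == acc_b
    first, second = (acc_a, acc_b) if (start == acc_a or homodimer) else (acc_b, acc_a)
    ids = (first, second + "_2") if homodimer else (first, second)
    chains = (elem.chain_for(first), elem.chain_b if homodimer else elem.chain_for(second))
    for sid, acc, chain in zip(ids, (first, second), chains):
        placed = chain.copy()
        placed.source_protein = acc
        model.subunits.append(PlacedSubunit(
            subunit_id=sid, protein=acc, chain=placed,
            introduced_by=elem, anchor=sid, transform=ident,
            template_chain=chain,
        ))
    model.joined_pairs.add(elem.interaction.pair)


def grow_model(
    start: str,
    net: SubNetwork,
    elements: Sequence[PPIElement],
    mode: str = "degree",
    seed: int = 0,
    cfg: Config = DEFAULT,
    _align_cache: Optional[dict] = None,
) -> ComplexModel:
    """Grow one complex model from a starting protein of the sub-network.

    mode="degree" follows the highest-interaction-degree anchor ordering;
    mode="random" replaces it by a seeded random ordering of the placed,
    non-exhausted subunits.  Every element is consumed at most once, which
    guarantees termination; each protein node is placed at most once.
    """
    if start not in net.nodes:
        raise ValueError(f"start protein {start} not in sub-network {net.net_id}")
    if mode not in ("degree", "random"):
        raise ValueError("mode must be 'degree' or 'random'")
    rng = np.random.default_rng(seed)
    model = ComplexModel(model_id=f"{net.net_id}:{start}", start_subunit=start,
                         subnetwork_ref=net.net_id)
    incident = {
        n: sorted((e for (a, b), e in net.edges if n in (a, b)),
                  key=lambda e: (e.partner_of(n), e.template_entry))
        for n in net.nodes
    }
    seed_candidates = incident[start]
    if not seed_candidates:
        raise ValueError(f"{start} has no templated edge")
    # seed with the start node's highest-degree edge, ties by accession order
    seed_elem = sorted(seed_candidates,
                       key=lambda e: (-net.degree.get(e.partner_of(start), 0),
                                      e.partner_of(start)))[0]
    _place_seed(model, seed_elem, start)
    used: Set[int] = {id(seed_elem)}
    placed_proteins: Set[str] = set(model.proteins)
    exhausted: Set[str] = set()
    while True:
        if mode == "degree":
            anchor_id = select_anchor(model, net, exhausted)
        else:
            pool = sorted(s.subunit_id for s in model.subunits
                          if s.subunit_id not in exhausted)
            anchor_id = None if not pool else pool[int(rng.integers(len(pool)))]
        if anchor_id is None:
            break
        anchor = model.subunit(anchor_id)
        for elem in incident.get(anchor.protein, []):
            if id(elem) in used:
                continue
            used.add(id(elem))
            partner = elem.partner_of(anchor.protein)
            if partner in placed_proteins:
                model.joined_pairs.add(elem.interaction.pair)
                continue
            shared_tmpl = elem.chain_for(anchor.protein)
            try:
                # superpositions between raw template chains are reusable
                # across growth attempts: identity and TM-score are frame
                # invariant, and the placement transform composes with the
                # anchor's own placement
                if _align_cache is not None and anchor.template_chain is not None:
                    key = (id(elem), anchor.protein, id(anchor.template_chain))
                    if key not in _align_cache:
                        _align_cache[key] = structure_align(
                            shared_tmpl, anchor.template_chain, cfg)
                    raw = _align_cache[key]
                    sup = SuperpositionResult(
                        transform=anchor.transform.compose(raw.transform),
                        rmsd=raw.rmsd, tmscore=raw.tmscore,
                        n_matched=raw.n_matched,
                        identity_struct=raw.identity_struct,
                        norm_length=raw.norm_length,
                    )
                else:
                    sup = structure_align(shared_tmpl, anchor.chain, cfg)
            except ValueError as exc:
                model.rejections.append({
                    "anchor": anchor.protein, "partner": partner,
                    "reason": f"alignment: {exc}",
                })
                continue
            if not accept_superposition(sup.identity_struct, sup.tmscore, cfg):
                model.rejections.append({
                    "anchor": anchor.protein, "partner": partner,
                    "reason": "gate", "identity": round(sup.identity_struct, 4),
                    "tmscore": round(sup.tmscore, 4),
                })
                continue
            new_tmpl = elem.chain_for(partner)
            candidate = apply_transform(new_tmpl, sup.transform)
            candidate.source_protein = partner
            if clash(model.subunits, candidate, cfg):
                blocker = _clash_partner(model.subunits, candidate, cfg)
                model.alternative_records.append(
                    (anchor.protein,
                     blocker.protein if blocker else anchor.protein,
                     partner)
                )
                model.rejections.append({
                    "anchor": anchor.protein, "partner": partner,
                    "reason": "clash",
                    "blocker": blocker.protein if blocker else None,
                })
                continue
            model.subunits.append(PlacedSubunit(
                subunit_id=partner, protein=partner, chain=candidate,
                introduced_by=elem, anchor=anchor_id, transform=sup.transform,
                template_chain=new_tmpl,
            ))
            placed_proteins.add(partner)
            model.joined_pairs.add(elem.interaction.pair)
        exhausted.add(anchor_id)
    return model


def build_all_models(
    net: SubNetwork,
    elements: Sequence[PPIElement],
    mode: str = "degree",
    seed: int = 0,
    cfg: Config = DEFAULT,
) -> List[ComplexModel]:
    """Grow a model from every node, deduplicate, sort by size descending.

    Two models are duplicates when their protein multisets and their
    element-joined pair sets coincide; the first (from the smallest start
    accession) representative is kept.
    """
    models = []
    align_cache: dict = {}
    for start in sorted(net.nodes):
        try:
            models.append(grow_model(start, net, elements, mode, seed, cfg,
                                     _align_cache=align_cache))
        except ValueError:
            continue
    seen = set()
    unique: List[ComplexModel] = []
    for m in sorted(models, key=lambda m: (-m.size, m.start_subunit)):
        key = (tuple(sorted(m.proteins)), frozenset(m.joined_pairs))
        if key in seen:
            continue
        seen.add(key)
        unique.append(m)
    return unique
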