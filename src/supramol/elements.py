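"""Template selection: the binary-complex element dataset.

For every interaction in the *complex* category, the pair of co-determined
chains with the highest average sequence identity to the two partners is
selected as the template ("element") used during assembly.  Target
sequences are mapped onto template chains by alignment; no comparative
remodeling is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .config import DEFAULT, Config
from .sequences import (
    AlignmentResult,
    InteractionRecord,
    ProteinEntry,
    align_pair,
    find_homologues,
)
from .structures_io import ChainStructure

__all__ = ["PPIElement", "select_element", "build_element_dataset", "element_dataset_to_json"]


@dataclass
class PPIElement:
    """A template binary complex mapped onto an interacting protein pair."""

    interaction: InteractionRecord
    template_entry: str
    chain_a: ChainStructure
    chain_b: ChainStructure
    ident_a: float
    ident_b: float
    mapping_a: AlignmentResult  # target residue -> template residue, side A
    mapping_b: AlignmentResult

    def __post_init__(self):
        if self.chain_a.source_entry != self.chain_b.source_entry:
            raise ValueError("element chains must be co-determined (same entry)")

    @property
    def average_identity(self) -> float:
        return 0.5 * (self.ident_a + self.ident_b)

    def chain_for(self, accession: str) -> ChainStructure:
        if accession == self.interaction.acc_a:
            return self.chain_a
        if accession == self.interaction.acc_b:
            return self.chain_b
        raise KeyError(accession)

    def mapping_for(self, accession: str) -> AlignmentResult:
        if accession == self.interaction.acc_a:
            return self.mapping_a
        if accession == self.interaction.acc_b:
            return self.mapping_b
        raise KeyError(accession)

    def partner_of(self, accession: str) -> str:
        if accession == self.interaction.acc_a:
            return self.interaction.acc_b
        if accession == self.interaction.acc_b:
            return self.interaction.acc_a
        raise KeyError(accession)


Candidate = Tuple[ChainStructure, ChainStructure, AlignmentResult, AlignmentResult]


def select_element(rec: InteractionRecord, candidates: Sequence[Candidate]) -> Optional[PPIElement]:
    """Pick the candidate chain pair with the highest average identity.

    Ties are broken lexicographically by (template entry, chain A id,
    chain B id) so the choice is deterministic and auditable.
    """
    if not candidates:
        return None
    best = min(
        candidates,
        key=lambda c: (
            -(c[2].identity_fraction + c[3].identity_fraction) / 2.0,
            c[0].source_entry,
            c[0].chain_id,
            c[1].chain_id,
        ),
    )
    ca, cb, ma, mb = best
    return PPIElement(
        interaction=rec,
        template_entry=ca.source_entry,
        chain_a=ca,
        chain_b=cb,
        ident_a=ma.identity_fraction,
        ident_b=mb.identity_fraction,
        mapping_a=ma,
        mapping_b=mb,
    )


def _candidates_for(
    rec: InteractionRecord,
    proteins: Dict[str, ProteinEntry],
    library: Sequence[ChainStructure],
    min_identity: Optional[float],
    cfg: Config,
) -> List[Candidate]:
    hits_a = find_homologues(proteins[rec.acc_a], library, min_identity, cfg)
    hits_b = hits_a if rec.acc_a == rec.acc_b else find_homologues(
        proteins[rec.acc_b], library, min_identity, cfg)
    by_entry_b: Dict[str, List] = {}
    for chain, res in hits_b:
        by_entry_b.setdefault(chain.source_entry, []).append((chain, res))
    cands: List[Candidate] = []
    for chain_a, res_a in hits_a:
        for chain_b, res_b in by_entry_b.get(chain_a.source_entry, []):
            if chain_b.chain_id == chain_a.chain_id:
                continue  # a template dimer needs two distinct chains
            cands.append((chain_a, chain_b, res_a, res_b))
    return cands


def build_element_dataset(
    interactions: Sequence[InteractionRecord],
    proteins: Dict[str, ProteinEntry],
    library: Sequence[ChainStructure],
    min_identity: Optional[float] = None,
    cfg: Config = DEFAULT,
) -> Tuple[List[PPIElement], Dict[str, int]]:
    """Classify every interaction and build one element per complex pair.

    Returns the element list (in input interaction order, deduplicated by
    unordered pair) and the tally over the four categories.
    """
    from .sequences import classify_interaction

    tally = {"complex": 0, "independent": 0, "one_sided": 0, "unknown": 0}
    elements: List[PPIElement] = []
    seen_pairs = set()
    for rec in interactions:
        if rec.pair in seen_pairs:
            continue
        seen_pairs.add(rec.pair)
        category = classify_interaction(rec, proteins, library, min_identity, cfg)
        tally[category] += 1
        if category != "complex":
            continue
        cands = _candidates_for(rec, proteins, library, min_identity, cfg)
        elem = select_element(rec, cands)
        if elem is not None:
            elements.append(elem)
        else:  # pragma: no cover - complex category implies candidates exist
            tally["complex"] -= 1
            tally["independent"] += 1
    return elements, tally


def element_dataset_to_json(elements: Sequence[PPIElement]) -> str:
    records = []
    for e in elements:
        records.append({
            "acc_a": e.interaction.acc_a,
            "acc_b": e.interaction.acc_b,
            "source_id": e.interaction.source_id,
            "template_entry": e.template_entry,
            "chain_a": e.chain_a.chain_id,
            "chain_b": e.chain_b.chain_id,
            "ident_a": round(e.ident_a, 6),
            "ident_b": round(e.ident_b, 6),
            "mapping_a": e.mapping_a.aligned_pairs,
            "mapping_b": e.mapping_b.aligned_pairs,
        })
    return json.dumps(records, indent=1, sort_keys=True)
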