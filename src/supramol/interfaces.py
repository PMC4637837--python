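"""Solvent accessibility, buried-area interface detection and typing.

Solvent-accessible surface area (SASA) is computed with the Shrake-Rupley
rolling-probe method (probe 1.4 A, 960 sphere points per atom, standard
van der Waals radii).  The interface between two subunits is the area each
loses on complexation; a contact is reported as an interface when the
larger of the two per-subunit buried areas exceeds 250 A^2.  Interfaces on
one subunit that share at least 10% of their buried area are one
alternative-capable site; below 10% they are distinct sites.

Interface types follow provenance: *experimental* when the subunit pair is
covered by a structural template element, *model-predicted* when the pair
is only recorded in the interaction table, *model-suggested* when it
appears in neither.  A recorded interaction whose partners share no
detected interface in the model is flagged *indirect*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .config import DEFAULT, Config
from .assembly import ComplexModel
from .sequences import InteractionRecord, ProteinEntry, align_pair
from .structures_io import ChainStructure

__all__ = [
    "Interface",
    "sasa",
    "residue_sasa",
    "buried_area",
    "detect_interfaces",
    "type_interfaces",
    "flag_indirect",
    "collapse_homologous",
    "classify_alternative_partners",
    "VDW_RADII",
]

#: van der Waals radii (A), Chothia-style values keyed by element symbol
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "SE": 1.90, "P": 1.80, "H": 1.20,
}
DEFAULT_RADIUS = 1.70


@dataclass
class Interface:
    subunit_a: str
    subunit_b: str
    residues_a: Set[int]
    residues_b: Set[int]
    area_a: float
    area_b: float
    type: str = ""                 # experimental | model_predicted | model_suggested
    direct: bool = True
    alternative_partners: Set[str] = field(default_factory=set)
    # per-residue buried area on each side, used for overlap computations
    loss_a: Dict[int, float] = field(default_factory=dict)
    loss_b: Dict[int, float] = field(default_factory=dict)

    @property
    def max_area(self) -> float:
        return max(self.area_a, self.area_b)

    def side(self, subunit_id: str) -> Tuple[Set[int], float, Dict[int, float]]:
        if subunit_id == self.subunit_a:
            return self.residues_a, self.area_a, self.loss_a
        if subunit_id == self.subunit_b:
            return self.residues_b, self.area_b, self.loss_b
        raise KeyError(subunit_id)

    def other(self, subunit_id: str) -> str:
        if subunit_id == self.subunit_a:
            return self.subunit_b
        if subunit_id == self.subunit_b:
            return self.subunit_a
        raise KeyError(subunit_id)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Nearly uniform unit-sphere sampling (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(chains: Sequence[ChainStructure], cfg: Config = DEFAULT,
         n_points: Optional[int] = None) -> Dict[Tuple[int, int], float]:
    """Per-residue solvent-accessible area of a chain group.

    Returns a map (chain_index, residue seq_index) -> area in A^2.
    Residues without atoms get area 0.  Chains shield each other, so
    computing a pair in one call yields in-complex accessibilities.
    """
    n_pts = n_points or cfg.sasa_points
    sphere = _fibonacci_sphere(n_pts)
    coords, radii, owner = [], [], []
    areas: Dict[Tuple[int, int], float] = {}
    for ci, chain in enumerate(chains):
        for res in chain.residues:
            areas[(ci, res.seq_index)] = 0.0
            for atom in res.atoms:
                if not atom.is_heavy:
                    continue
                coords.append(atom.coords)
                radii.append(VDW_RADII.get(atom.element.upper(), DEFAULT_RADIUS))
                owner.append((ci, res.seq_index))
    if not coords:
        return areas
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    probe = cfg.sasa_probe
    ext = radii + probe
    tree = cKDTree(coords)
    max_ext = ext.max()
    for i in range(len(coords)):
        neigh = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                 if j != i]
        pts = sphere * ext[i] + coords[i]
        if neigh:
            nc = coords[neigh]
            nr = ext[neigh]
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 > (nr * nr)[None, :]).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[owner[i]] += 4.0 * math.pi * ext[i] ** 2 * frac
    return areas


def residue_sasa(chain: ChainStructure, cfg: Config = DEFAULT,
                 n_points: Optional[int] = None) -> Dict[int, float]:
    """Isolated-chain per-residue SASA keyed by seq_index."""
    return {seq: a for (_, seq), a in sasa([chain], cfg, n_points).items()}


def buried_area(
    model: ComplexModel,
    a: str,
    b: str,
    cfg: Config = DEFAULT,
    iso_cache: Optional[Dict[str, Dict[int, float]]] = None,
) -> Tuple[float, float, Set[int], Set[int]]:
    """Buried area and interfacial residues of the subunit pair (a, b).

    area_x = SASA(x alone) - SASA(x with the other subunit present);
    residues losing more than the per-residue threshold are interfacial.
    """
    if iso_cache is None:
        iso_cache = {}
    iface = _pair_buried(model, a, b, cfg, iso_cache)
    return iface.area_a, iface.area_b, iface.residues_a, iface.residues_b


def _pair_buried(model, a, b, cfg, iso_cache) -> Interface:
    su_a, su_b = model.subunit(a), model.subunit(b)
    for su in (su_a, su_b):
        if su.subunit_id not in iso_cache:
            iso_cache[su.subunit_id] = residue_sasa(su.chain, cfg)
    pair = sasa([su_a.chain, su_b.chain], cfg)
    loss_a, loss_b = {}, {}
    for (ci, seq), area in pair.items():
        iso = iso_cache[(su_a if ci == 0 else su_b).subunit_id][seq]
        loss = iso - area
        if loss > cfg.interface_residue_min_loss:
            (loss_a if ci == 0 else loss_b)[seq] = loss
    return Interface(
        subunit_a=a, subunit_b=b,
        residues_a=set(loss_a), residues_b=set(loss_b),
        area_a=sum(loss_a.values()), area_b=sum(loss_b.values()),
        loss_a=loss_a, loss_b=loss_b,
    )


def _min_ca_distance(a: ChainStructure, b: ChainStructure) -> float:
    ca_a = a.ca_coords()
    ca_b = b.ca_coords()
    ca_a = ca_a[np.all(np.isfinite(ca_a), axis=1)]
    ca_b = ca_b[np.all(np.isfinite(ca_b), axis=1)]
    if len(ca_a) == 0 or len(ca_b) == 0:
        return math.inf
    return float(cdist(ca_a, ca_b).min())


def detect_interfaces(model: ComplexModel, cfg: Config = DEFAULT) -> List[Interface]:
    """All subunit pairs burying more than the interface threshold.

    On each subunit, interfaces to different partners sharing at least the
    overlap fraction of buried area (shared area over the smaller side)
    are flagged as one alternative-capable site: each member interface
    gains the others' partners in ``alternative_partners``.  Partners
    rejected by clash during assembly are merged in from the assembly
    record (they compete for the anchor's site by construction).
    """
    results: List[Interface] = []
    ids = [s.subunit_id for s in model.subunits]
    iso_cache: Dict[str, Dict[int, float]] = {}
    contact_cut = 2.0 * (DEFAULT_RADIUS + cfg.sasa_probe) + 8.0
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if _min_ca_distance(model.subunit(a).chain, model.subunit(b).chain) > contact_cut:
                continue
            iface = _pair_buried(model, a, b, cfg, iso_cache)
            if iface.max_area > cfg.interface_min_area:
                results.append(iface)
    # overlap-based alternative-site merging, per subunit
    for sid in ids:
        mine = [f for f in results if sid in (f.subunit_a, f.subunit_b)]
        for x in range(len(mine)):
            for y in range(x + 1, len(mine)):
                fa, fb = mine[x], mine[y]
                _, area_a, loss_a = fa.side(sid)
                _, area_b, loss_b = fb.side(sid)
                shared = sum(min(loss_a[r], loss_b[r]) for r in set(loss_a) & set(loss_b))
                denom = min(area_a, area_b)
                if denom > 0 and shared / denom >= cfg.interface_overlap_frac:
                    fa.alternative_partners.add(fb.other(sid))
                    fb.alternative_partners.add(fa.other(sid))
    # clash-rejected partners recorded during assembly
    placed = {s.protein: s.subunit_id for s in model.subunits}
    for owner, kept, rejected in model.alternative_records:
        owner_id = placed.get(owner)
        kept_id = placed.get(kept)
        if owner_id is None:
            continue
        for f in results:
            if {f.subunit_a, f.subunit_b} == {owner_id, kept_id}:
                f.alternative_partners.add(rejected)
    return results


def type_interfaces(
    model: ComplexModel,
    interactions: Sequence[InteractionRecord],
    elements: Sequence,
    interfaces: Optional[List[Interface]] = None,
    cfg: Config = DEFAULT,
) -> List[Interface]:
    """Annotate detected interfaces as experimental / predicted / suggested."""
    if interfaces is None:
        interfaces = detect_interfaces(model, cfg)
    element_pairs = {e.interaction.pair for e in elements}
    interaction_pairs = {r.pair for r in interactions}
    protein_of = {s.subunit_id: s.protein for s in model.subunits}
    for f in interfaces:
        pair = tuple(sorted((protein_of[f.subunit_a], protein_of[f.subunit_b])))
        if pair in element_pairs:
            f.type = "experimental"
        elif pair in interaction_pairs:
            f.type = "model_predicted"
        else:
            f.type = "model_suggested"
    return interfaces


def flag_indirect(
    model: ComplexModel,
    interactions: Sequence[InteractionRecord],
    interfaces: Optional[List[Interface]] = None,
    cfg: Config = DEFAULT,
) -> List[Tuple[Tuple[str, str], bool, str]]:
    """Direct/indirect flags for recorded interactions among placed subunits.

    A recorded pair is direct iff its subunits share a detected interface;
    the detection method rides along for method-wise indirect-rate reports.
    """
    if interfaces is None:
        interfaces = detect_interfaces(model, cfg)
    protein_of = {s.subunit_id: s.protein for s in model.subunits}
    contact_pairs = {
        tuple(sorted((protein_of[f.subunit_a], protein_of[f.subunit_b])))
        for f in interfaces
    }
    placed = set(protein_of.values())
    out = []
    for rec in interactions:
        if rec.acc_a in placed and rec.acc_b in placed:
            out.append((rec.pair, rec.pair in contact_pairs, rec.detection_method))
    return out


def collapse_homologous(
    interfaces: Sequence[Interface],
    proteins: Dict[str, ProteinEntry],
    model: ComplexModel,
    cfg: Config = DEFAULT,
) -> List[Interface]:
    """Group interfaces between mutually homologous protein pairs.

    Interfaces (P, Q) and (R, S) are redundant when P~R and Q~S (or P~S
    and Q~R) at above-threshold identity on both sides; one representative
    per group is returned, in input order.
    """
    protein_of = {s.subunit_id: s.protein for s in model.subunits}

    def ident(p: str, q: str) -> float:
        if p == q:
            return 1.0
        if p not in proteins or q not in proteins:
            return 0.0
        return align_pair(proteins[p], proteins[q], cfg).identity_fraction

    n = len(interfaces)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        pi = protein_of[interfaces[i].subunit_a], protein_of[interfaces[i].subunit_b]
        for j in range(i + 1, n):
            pj = protein_of[interfaces[j].subunit_a], protein_of[interfaces[j].subunit_b]
            same = (
                (ident(pi[0], pj[0]) > cfg.min_identity and ident(pi[1], pj[1]) > cfg.min_identity)
                or
                (ident(pi[0], pj[1]) > cfg.min_identity and ident(pi[1], pj[0]) > cfg.min_identity)
            )
            if same:
                parent[find(j)] = find(i)
    reps = []
    seen = set()
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen.add(root)
            reps.append(interfaces[i])
    return reps


def classify_alternative_partners(
    records: Sequence[Tuple[str, str, str]],
    chains: Dict[str, ChainStructure],
    proteins: Dict[str, ProteinEntry],
    cfg: Config = DEFAULT,
) -> Dict[str, int]:
    """Why do two partners compete for one site?  Homology, fold, or neither.

    For each alternative record (owner, partner_a, partner_b) the two
    partners are compared: *homologous* when sequence identity exceeds the
    homologue threshold, else *same_fold* when their structures superpose
    with TM-score > 0.5, else *different_fold*.
    """
    from .superpose import structure_align

    counts = {"homologous": 0, "same_fold": 0, "different_fold": 0}
    for _, pa, pb in records:
        label = "different_fold"
        if pa in proteins and pb in proteins:
            if align_pair(proteins[pa], proteins[pb], cfg).identity_fraction > cfg.min_identity:
                label = "homologous"
        if label == "different_fold" and pa in chains and pb in chains:
            try:
                sup = structure_align(chains[pa], chains[pb], cfg)
                tm = sup.tmscore
            except ValueError:
                # no sequence correspondence: fall back to positional
                # register pairing, enough to separate gross fold classes
                from .superpose import tm_score

                ca, cb = chains[pa], chains[pb]
                n = min(len(ca), len(cb))
                if n >= 4:
                    tm = tm_score(ca, cb, [(i, i) for i in range(1, n + 1)], len(cb))
                else:
                    tm = 0.0
            if tm > 0.5:
                label = "same_fold"
        counts[label] += 1
    return counts
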