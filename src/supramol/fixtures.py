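"""Deterministic synthetic data with known ground truth.

The generator builds toy multi-subunit complexes out of idealized
poly-alanine-geometry chains (full N/CA/C/O/CB backbones built with ideal
bond geometry) arranged so that every intended contact buries a chosen
surface area.  Each ground-truth dimer is emitted as a separate synthetic
"crystal" entry in its own random rigid frame, so assembly must rediscover
the complex by superposing shared subunits.  The accompanying sequence,
interaction and variant tables can deliberately disagree with the
structures — extra edges without contacts (indirect interactions), edges
without templates (model-predicted interfaces), contacts without recorded
interactions (model-suggested interfaces), and mutually exclusive
placements (alternative interfaces) — so every annotation path is
exercised against a known answer.

Everything is a pure function of the seed; regenerating is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import DEFAULT, Config
from .sequences import InteractionRecord, ProteinEntry, align_pair
from .structures_io import (
    AtomRecord,
    ChainStructure,
    Residue,
    RigidTransform,
    apply_transform,
    write_chains,
)

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_chain",
    "make_toy_complex",
    "random_rigid_transform",
    "synthetic_assignments",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: conservative substitute (positive or near-zero BLOSUM62 score) per residue,
#: used to dial planted homologue identities without destroying alignability
CONSERVATIVE_SUB = {
    "A": "S", "R": "K", "N": "D", "D": "E", "C": "A", "Q": "E", "E": "D",
    "G": "A", "H": "Y", "I": "V", "L": "M", "K": "R", "M": "L", "F": "Y",
    "P": "T", "S": "T", "T": "S", "W": "Y", "Y": "F", "V": "I",
}

# ideal backbone geometry (angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.5, 110.4

_FOLD_TORSIONS = {
    "helix": (-57.0, -47.0),
    "extended": (-120.0, 120.0),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF atom placement: position d from internal coordinates."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -math.cos(angle),
        math.sin(angle) * math.cos(torsion),
        math.sin(angle) * math.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_trace(n_res: int, fold: str) -> List[Dict[str, np.ndarray]]:
    phi, psi = _FOLD_TORSIONS[fold]
    omega = 180.0
    res: List[Dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0]) @ np.eye(3)
    res.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n_res):
        prev = res[-1]
        N = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        CA = _place(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, omega)
        C = _place(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": N, "CA": CA, "C": C})
    for i, r in enumerate(res):
        if i + 1 < len(res):
            nxt = res[i + 1]["N"]
            r["O"] = _place(nxt, r["CA"], r["C"], _B_C_O, _A_CA_C_O, 180.0)
        else:
            r["O"] = _place(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        r["CB"] = _place(r["C"], r["N"], r["CA"], _B_CA_CB, _A_N_CA_CB, 122.55)
    return res


def _orient_to_z(points_by_res: List[Dict[str, np.ndarray]]) -> List[Dict[str, np.ndarray]]:
    """Center the chain and align its end-to-end CA vector with +z."""
    cas = np.array([r["CA"] for r in points_by_res])
    centroid = cas.mean(axis=0)
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))
    return [{k: R @ (p - centroid) for k, p in r.items()} for r in points_by_res]


def _assemble_bundle(n_res: int) -> List[Dict[str, np.ndarray]]:
    """Three-helix bundle in one chain: tight triangular packing.

    Deliberately ignores the chemistry of the connecting segments — the
    point is a compact fold with genuinely buried residues.
    """
    per = n_res // 3
    rest = n_res - 2 * per
    spacing = 8.2  # angstrom between helix axes; tight, to bury core residues
    positions = [
        np.array([0.0, 0.0, 0.0]),
        np.array([spacing, 0.0, 0.0]),
        np.array([spacing / 2.0, spacing * math.sqrt(3) / 2.0, 0.0]),
    ]
    out: List[Dict[str, np.ndarray]] = []
    for h, count in enumerate((per, per, rest)):
        helix = _orient_to_z(_backbone_trace(count, "helix"))
        flip = np.diag([1.0, -1.0, -1.0]) if h == 1 else np.eye(3)
        for r in helix:
            out.append({k: flip @ p + positions[h] for k, p in r.items()})
    return out


def make_chain(accession: str, sequence: str, fold: str = "helix",
               chain_id: str = "A", entry: str = "truth") -> ChainStructure:
    """Build an idealized chain with the given sequence tags.

    fold: "helix" (straight alpha-helix), "extended" (beta-strand
    geometry), or "bundle3" (compact three-helix bundle with a buried
    core).  The chain is centered at the origin with its long axis on z.
    """
    n = len(sequence)
    if fold == "bundle3":
        trace = _assemble_bundle(n)
        cas = np.array([r["CA"] for r in trace])
        centroid = cas.mean(axis=0)
        trace = [{k: p - centroid for k, p in r.items()} for r in trace]
    elif fold in _FOLD_TORSIONS:
        trace = _orient_to_z(_backbone_trace(n, fold))
    else:
        raise ValueError(f"unknown fold {fold!r}")
    residues = []
    for i, (aa, r) in enumerate(zip(sequence, trace), start=1):
        atoms = [
            AtomRecord("N", "N", r["N"]),
            AtomRecord("CA", "C", r["CA"]),
            AtomRecord("C", "C", r["C"]),
            AtomRecord("O", "O", r["O"]),
            AtomRecord("CB", "C", r["CB"]),
        ]
        residues.append(Residue(seq_index=i, aa=aa, atoms=atoms))
    return ChainStructure(chain_id=chain_id, residues=residues,
                          source_entry=entry, source_protein=accession)


def random_rigid_transform(rng: np.random.Generator,
                           max_shift: float = 60.0) -> RigidTransform:
    """Uniformly random proper rotation plus a bounded random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(Q, t)


def _shift(chain: ChainStructure, offset: np.ndarray) -> ChainStructure:
    return apply_transform(chain, RigidTransform(np.eye(3), np.asarray(offset, float)))


def _rotate_z(chain: ChainStructure, theta: float) -> ChainStructure:
    c, s = math.cos(theta), math.sin(theta)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return apply_transform(chain, RigidTransform(R, np.zeros(3)))


def _pair_buried_area(chain_a: ChainStructure, chain_b: ChainStructure,
                      cfg: Config, n_points: int = 480) -> float:
    from .interfaces import sasa

    iso_a = sasa([chain_a], cfg, n_points)
    iso_b = sasa([chain_b], cfg, n_points)
    both = sasa([chain_a, chain_b], cfg, n_points)
    lost_a = sum(iso_a[(0, s)] - both[(0, s)] for (c, s) in both if c == 0)
    lost_b = sum(iso_b[(0, s)] - both[(1, s)] for (c, s) in both if c == 1)
    return max(lost_a, lost_b)


@lru_cache(maxsize=64)
def _calibrated_separation(len_a: int, fold_a: str, len_b: int, fold_b: str,
                           target_area: float) -> float:
    """Axis separation (along x) burying `target_area` between two chains.

    Buried area decreases monotonically with separation, so bisection on a
    poly-alanine pair converges; sequences do not enter the geometry.
    """
    cfg = DEFAULT
    a = make_chain("calA", "A" * len_a, fold_a)
    b0 = make_chain("calB", "A" * len_b, fold_b)
    lo, hi = 6.5, 20.0
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        area = _pair_buried_area(a, _shift(b0, [mid, 0.0, 0.0]), cfg)
        if abs(area - target_area) / target_area < 0.02:
            return mid
        if area > target_area:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_proteins: int = 4
    topology: str = "star"          # star | path | ring | complete | two_blocks
    chain_length: int = 30
    contact_area: float = 400.0     # target buried area per planted contact, A^2
    clash_pairs: Tuple[Tuple[int, int], ...] = ()   # leaf/node index pairs sharing a site
    identity_ladder: Tuple[float, ...] = ()         # planted homologue identities for protein 0
    variant_plan: Optional[Dict[str, Dict[str, int]]] = None  # class -> env -> count
    misfold_edges: Tuple[Tuple[int, int], ...] = ()  # edges whose template shared chain is misfolded
    extra_interactions: Tuple[Tuple[int, int], ...] = ()  # recorded pairs without contact
    drop_structure: Tuple[Tuple[int, int], ...] = ()      # contact edges without a crystal
    drop_interaction: Tuple[Tuple[int, int], ...] = ()    # contact edges absent from the table
    disordered_tail: int = 6
    hub_fold: str = "helix"


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    proteins: Dict[str, ProteinEntry]
    truth_chains: Dict[str, ChainStructure]       # complex-frame ground truth
    entries: Dict[str, List[ChainStructure]]      # synthetic crystal entries
    interactions: List[InteractionRecord]
    variants: List["object"]
    variant_truth: Dict[Tuple[str, int], str]     # (accession, position) -> environment
    structural_edges: List[Tuple[str, str]]
    clash_pairs: List[Tuple[str, str, str]]       # (owner, kept-site partner, duplicate)
    homologue_identities: Dict[str, float]        # planted ladder entry -> identity

    @property
    def library(self) -> List[ChainStructure]:
        return [c for chains in self.entries.values() for c in chains]

    def accession(self, index: int) -> str:
        return f"P{index + 1:03d}"

    def write(self, out_dir) -> Dict[str, Path]:
        """Write crystals, FASTA, interaction TSV and variant TSV to disk."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}
        for entry_id, chains in sorted(self.entries.items()):
            p = out / f"{entry_id}.pdb"
            write_chains(chains, p, entry_name=entry_id)
            paths[entry_id] = p
        fasta = out / "proteins.fasta"
        with open(fasta, "w") as fh:
            for acc in sorted(self.proteins):
                fh.write(f">{acc}\n{self.proteins[acc].sequence}\n")
        paths["fasta"] = fasta
        itab = out / "interactions.tsv"
        with open(itab, "w") as fh:
            fh.write("acc_a\tacc_b\tdetection_method\tsource_id\n")
            for rec in self.interactions:
                fh.write(f"{rec.acc_a}\t{rec.acc_b}\t{rec.detection_method}\t{rec.source_id}\n")
        paths["interactions"] = itab
        vtab = out / "variants.tsv"
        with open(vtab, "w") as fh:
            fh.write("accession\tposition\tref_aa\talt_aa\tvar_class\n")
            for v in self.variants:
                fh.write(f"{v.accession}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t{v.var_class}\n")
        paths["variants"] = vtab
        return paths


def _distinct_sequence(rng: np.random.Generator, length: int,
                       existing: Sequence[str], cfg: Config) -> str:
    """A random sequence with no above-threshold similarity to `existing`."""
    for _ in range(60):
        seq = "".join(rng.choice(list(AA20), size=length))
        ok = True
        for other in existing:
            res = align_pair(seq, other, cfg)
            if res.identity_fraction > cfg.min_identity - 0.03:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError("could not draw a dissimilar sequence")  # pragma: no cover


def _mutated_to_identity(seq: str, target: float) -> str:
    """Substitute evenly spaced positions to reach ~target identity."""
    n = len(seq)
    n_mut = round((1.0 - target) * n)
    if n_mut <= 0:
        return seq
    idx = np.linspace(1, n - 2, n_mut).round().astype(int)
    out = list(seq)
    for i in sorted(set(idx.tolist())):
        out[i] = CONSERVATIVE_SUB.get(out[i], "A")
    return "".join(out)


def _topology_edges(topology: str, n: int) -> List[Tuple[int, int]]:
    if topology in ("star", "two_blocks"):
        return [(0, k) for k in range(1, n)]
    if topology == "path":
        return [(k, k + 1) for k in range(n - 1)]
    if topology in ("ring", "complete"):
        edges = [(k, k + 1) for k in range(n - 1)]
        if n > 2:
            edges.append((0, n - 1))
        return edges
    raise ValueError(f"unknown topology {topology!r}")


def _layout(spec: FixtureSpec, chains: Dict[int, ChainStructure],
            folds: Dict[int, str], cfg: Config) -> Dict[int, ChainStructure]:
    """Place ground-truth subunits so that every edge buries ~contact_area."""
    n = spec.n_proteins
    L = spec.chain_length

    def sep(i: int, j: int) -> float:
        return _calibrated_separation(L, folds[i], L, folds[j], spec.contact_area)

    placed: Dict[int, ChainStructure] = {}
    topo = spec.topology
    if topo in ("star", "two_blocks"):
        placed[0] = chains[0]
        leaves = list(range(1, n))
        clash_dups = {j for _, j in spec.clash_pairs}
        slots = [k for k in leaves if k not in clash_dups]
        angles = {}
        n_slots = max(len(slots), 1)
        if n_slots > 1 and 2.0 * math.pi / n_slots < math.radians(60):
            raise ValueError("too many star leaves for clash-free placement")
        for s_idx, k in enumerate(slots):
            angles[k] = 2.0 * math.pi * s_idx / n_slots
        for i, j in spec.clash_pairs:
            angles[j] = angles[i]  # duplicate occupies the same hub site
        for k in leaves:
            d = sep(0, k)
            placed[k] = _rotate_z(_shift(chains[k], [d, 0.0, 0.0]), angles[k])
    elif topo == "path":
        x = 0.0
        placed[0] = chains[0]
        for k in range(1, n):
            x += sep(k - 1, k)
            placed[k] = _shift(chains[k], [x, 0.0, 0.0])
    elif topo in ("ring", "complete"):
        d = sep(0, 1)
        R = d / (2.0 * math.sin(math.pi / n))
        for k in range(n):
            theta = 2.0 * math.pi * k / n
            placed[k] = _shift(chains[k], [R * math.cos(theta), R * math.sin(theta), 0.0])
    else:
        raise ValueError(f"unknown topology {topo!r}")
    return placed


def make_toy_complex(spec: FixtureSpec, cfg: Config = DEFAULT) -> FixtureBundle:
    """Generate one ground-truth complex and its (im)perfect observations."""
    from .variants import VariantRecord

    if spec.n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    accs = [f"P{k + 1:03d}" for k in range(n)]

    folds = {k: "helix" for k in range(n)}
    folds[0] = spec.hub_fold
    sequences: Dict[int, str] = {}
    existing: List[str] = []
    for k in range(n):
        seq = _distinct_sequence(rng, spec.chain_length, existing, cfg)
        sequences[k] = seq
        existing.append(seq)

    base = {k: make_chain(accs[k], sequences[k], folds[k], chain_id="A")
            for k in range(n)}
    placed = _layout(spec, base, folds, cfg)
    truth_chains = {accs[k]: placed[k] for k in range(n)}

    edges_idx = _topology_edges(spec.topology, n)
    if spec.topology == "two_blocks" and not spec.clash_pairs:
        raise ValueError("two_blocks requires clash_pairs")
    drop_struct = {tuple(sorted(e)) for e in spec.drop_structure}
    drop_inter = {tuple(sorted(e)) for e in spec.drop_interaction}
    misfold = {tuple(sorted(e)) for e in spec.misfold_edges}

    entries: Dict[str, List[ChainStructure]] = {}
    t_idx = 0
    for i, j in edges_idx:
        key = tuple(sorted((i, j)))
        if key in drop_struct or key in drop_inter:
            continue
        t_idx += 1
        entry_id = f"T{t_idx:03d}"
        transform = random_rigid_transform(rng)
        if key in misfold:
            # non-superposable shared-subunit geometry: same sequences, wrong fold
            wrong = make_chain(accs[i], sequences[i], "extended", chain_id="A")
            cj = make_chain(accs[j], sequences[j], folds[j], chain_id="B")
            pair = [wrong, _shift(cj, [11.0, 0.0, 0.0])]
        else:
            pair = [truth_chains[accs[i]].copy(), truth_chains[accs[j]].copy()]
            pair[0].chain_id, pair[1].chain_id = "A", "B"
        out_pair = []
        for chain in pair:
            moved = apply_transform(chain, transform)
            moved.source_entry = entry_id.lower()
            moved.source_protein = None
            out_pair.append(moved)
        entries[entry_id] = out_pair

    # planted homologue ladder for protein 0: single-chain entries
    homologue_identities: Dict[str, float] = {}
    for li, ident in enumerate(spec.identity_ladder):
        entry_id = f"H{li + 1:03d}"
        mseq = _mutated_to_identity(sequences[0], ident)
        chain = make_chain(f"{accs[0]}_hom{li + 1}", mseq, folds[0], chain_id="A")
        moved = apply_transform(chain, random_rigid_transform(rng))
        moved.source_entry = entry_id.lower()
        moved.source_protein = None
        entries[entry_id] = [moved]
        homologue_identities[entry_id.lower()] = ident

    # interaction table: structural edges (minus dropped) plus extras
    interactions: List[InteractionRecord] = []
    methods = ("two hybrid", "x-ray crystallography", "anti bait coip",
               "cosedimentation")
    src = 0
    table_pairs = [tuple(sorted(e)) for e in edges_idx
                   if tuple(sorted(e)) not in drop_inter]
    if spec.topology == "complete":
        table_pairs = sorted({(i, j) for i in range(n) for j in range(i + 1, n)})
    for i, j in sorted(set(table_pairs) | {tuple(sorted(e)) for e in spec.extra_interactions}):
        src += 1
        method = methods[src % len(methods)]
        interactions.append(InteractionRecord(accs[i], accs[j], method, f"IX{src:04d}"))

    # extra sequence-only proteins give one-sided / unknown categories a home
    proteins = {
        accs[k]: ProteinEntry(
            accs[k],
            sequences[k] + "".join(rng.choice(list(AA20), size=spec.disordered_tail)),
        )
        for k in range(n)
    }

    variants, variant_truth = _plant_variants(spec, accs, truth_chains, proteins,
                                              edges_idx, cfg, rng)
    clash_named = [(accs[0], accs[i], accs[j]) if spec.topology in ("star", "two_blocks")
                   else (accs[i], accs[i], accs[j])
                   for i, j in spec.clash_pairs]
    return FixtureBundle(
        spec=spec,
        proteins=proteins,
        truth_chains=truth_chains,
        entries=entries,
        interactions=interactions,
        variants=variants,
        variant_truth=variant_truth,
        structural_edges=[(accs[i], accs[j]) for i, j in edges_idx],
        clash_pairs=clash_named,
        homologue_identities=homologue_identities,
    )


def _plant_variants(spec, accs, truth_chains, proteins, edges_idx, cfg, rng):
    from .interfaces import residue_sasa, sasa
    from .variants import MAX_ACCESSIBILITY, VariantRecord

    variants: List = []
    truth: Dict[Tuple[str, int], str] = {}
    if not spec.variant_plan:
        return variants, truth

    acc0 = accs[0]
    chain0 = truth_chains[acc0]
    iso = residue_sasa(chain0, cfg)
    # interface residues of protein 0, over all its structural edges
    iface_res: set = set()
    for i, j in edges_idx:
        if 0 not in (i, j):
            continue
        other = accs[j] if i == 0 else accs[i]
        pair = sasa([chain0, truth_chains[other]], cfg)
        for (ci, s), area in pair.items():
            if ci == 0 and iso[s] - area > cfg.interface_residue_min_loss:
                iface_res.add(s)
    rel = {s: iso[s] / MAX_ACCESSIBILITY.get(chain0.residues[s - 1].aa, 200.0)
           for s in iso}
    pools = {
        "interface": sorted(iface_res),
        "interior": sorted(s for s, r in rel.items() if r < 0.8 * cfg.buried_rel_acc),
        "surface": sorted(s for s, r in rel.items()
                          if r > 2.0 * cfg.buried_rel_acc and s not in iface_res),
        "disordered": list(range(len(chain0) + 1, len(proteins[acc0].sequence) + 1)),
    }
    for var_class, env_counts in sorted(spec.variant_plan.items()):
        for env, count in sorted(env_counts.items()):
            pool = pools.get(env, [])
            if not pool:
                raise ValueError(f"no candidate residues for environment {env!r}")
            for c in range(count):
                pos = pool[c % len(pool)]
                ref = proteins[acc0].sequence[pos - 1]
                alt = CONSERVATIVE_SUB.get(ref, "A")
                variants.append(VariantRecord(acc0, pos, ref, alt, var_class))
                truth[(acc0, pos)] = env
    return variants, truth


def _as_model(chains: Dict[str, ChainStructure], model_id: str):
    from .assembly import ComplexModel, PlacedSubunit

    subs = [
        PlacedSubunit(subunit_id=acc, protein=acc, chain=chain,
                      introduced_by=None, anchor=acc,
                      transform=RigidTransform.identity())
        for acc, chain in chains.items()
    ]
    return ComplexModel(model_id=model_id, subunits=subs)


def make_dimer_model(target_area: float, chain_length: int = 30, seed: int = 0,
                     cfg: Config = DEFAULT):
    """Hand-assembled dimer burying ~target_area on each side.

    Used to probe the interface area threshold with a controlled family of
    contact sizes.
    """
    rng = np.random.default_rng(seed)
    seq_a = _distinct_sequence(rng, chain_length, [], cfg)
    seq_b = _distinct_sequence(rng, chain_length, [seq_a], cfg)
    sep = _calibrated_separation(chain_length, "helix", chain_length, "helix",
                                 target_area)
    a = make_chain("D001", seq_a, "helix")
    b = _shift(make_chain("D002", seq_b, "helix"), [sep, 0.0, 0.0])
    return _as_model({"D001": a, "D002": b}, f"dimer{int(target_area)}")


def make_two_partner_model(gamma_deg: float, hub_length: int = 48,
                           partner_length: int = 24, contact_area: float = 350.0,
                           seed: int = 0, cfg: Config = DEFAULT):
    """Hub with two partners at azimuths +/- gamma/2 around its axis.

    The angular separation dials how much of the two hub-side patches is
    shared: 180 degrees puts the partners on opposite faces (independent
    sites), small angles make them compete for one site.
    """
    rng = np.random.default_rng(seed)
    seqs = []
    for L in (hub_length, partner_length, partner_length):
        seqs.append(_distinct_sequence(rng, L, seqs, cfg))
    sep = _calibrated_separation(hub_length, "helix", partner_length, "helix",
                                 contact_area)
    hub = make_chain("H001", seqs[0], "helix")
    half = math.radians(gamma_deg) / 2.0
    p1 = _rotate_z(_shift(make_chain("H002", seqs[1], "helix"), [sep, 0, 0]), half)
    p2 = _rotate_z(_shift(make_chain("H003", seqs[2], "helix"), [sep, 0, 0]), -half)
    return _as_model({"H001": hub, "H002": p1, "H003": p2},
                     f"twopartner{int(gamma_deg)}")


def synthetic_assignments(seed: int, n_variants: int = 2000,
                          interface_enrichment: float = 3.0):
    """Synthetic environment assignments with a planted interface effect.

    Half the variants are (benign) polymorphisms drawn from a background
    environment distribution; the other half are disease variants whose
    interface probability is multiplied by the enrichment factor.  Used to
    exercise the enrichment statistics with a known effect size.
    """
    from .variants import EnvironmentAssignment, VariantRecord

    rng = np.random.default_rng(seed)
    envs = ["interface", "surface", "interior", "disordered"]
    base = np.array([0.05, 0.50, 0.25, 0.20])
    enriched = base.copy()
    enriched[0] *= interface_enrichment
    enriched /= enriched.sum()
    out = []
    for i in range(n_variants):
        cls = "polymorphism" if i % 2 == 0 else "disease"
        p = base if cls == "polymorphism" else enriched
        env = envs[int(rng.choice(4, p=p))]
        var = VariantRecord("PSYN", i + 1, "A", "S", cls)
        out.append(EnvironmentAssignment(
            var, env, "model_suggested" if env == "interface" else None, "synthetic"))
    return out
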