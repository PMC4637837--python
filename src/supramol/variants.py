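"""Model extrapolation and variant-to-environment mapping.

Amino-acid variants are mapped onto complex models and classified into
four molecular environments: *disordered* (no modeled coordinates),
*interior* (relative accessibility below 0.1 on the isolated subunit),
*interface* (member of a detected interface's residue set, carrying that
interface's subtype), and *surface* (everything else exposed).  Models are
first extrapolated to homologous subunit combinations: each subunit may be
substituted by any homologue above the identity threshold, and the
Cartesian product of per-subunit choices enumerates the model variants.

Enrichment of a variant class (e.g. disease) in an environment relative to
a baseline class (e.g. polymorphism) is assessed per cell by a chi-square
test against the expectation under the baseline distribution, and by a
one-sided hypergeometric test for category-membership enrichment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .assembly import ComplexModel
from .config import DEFAULT, Config
from .interfaces import Interface, detect_interfaces, residue_sasa
from .sequences import ProteinEntry, align_pair

__all__ = [
    "VariantRecord",
    "EnvironmentAssignment",
    "ModelVariant",
    "MAX_ACCESSIBILITY",
    "read_variants",
    "extrapolate_models",
    "classify_environment",
    "map_variants",
    "enrichment_tests",
    "hypergeom_pvalue",
    "environment_table",
]

VAR_CLASSES = ("polymorphism", "disease", "unclassified")
ENVIRONMENTS = ("interface", "surface", "interior", "disordered")
SUBTYPE_PRIORITY = ("experimental", "model_predicted", "model_suggested")

#: theoretical maximum accessibility of residue X in a Gly-X-Gly tripeptide
#: (Tien et al. 2013, theoretical column), A^2
MAX_ACCESSIBILITY = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
    "X": 200.0,
}


@dataclass(frozen=True)
class VariantRecord:
    accession: str
    position: int            # 1-based in the protein sequence
    ref_aa: str
    alt_aa: str
    var_class: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("variant position must be >= 1")
        if self.var_class not in VAR_CLASSES:
            raise ValueError(f"var_class must be one of {VAR_CLASSES}")


@dataclass
class EnvironmentAssignment:
    variant: VariantRecord
    environment: str
    interface_subtype: Optional[str] = None
    model_id: str = ""

    def __post_init__(self):
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment}")
        if (self.interface_subtype is not None) != (self.environment == "interface"):
            raise ValueError("interface_subtype present iff environment is interface")


@dataclass
class ModelVariant:
    """One homologue combination of a base model's subunits."""

    base: ComplexModel
    assigned: Dict[str, str]   # subunit_id -> accession occupying it

    @property
    def is_original(self) -> bool:
        return all(self.base.subunit(sid).protein == acc
                   for sid, acc in self.assigned.items())


def read_variants(path) -> List[VariantRecord]:
    """TSV reader: accession, position, ref AA, alt AA, class."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("accession"):
                continue
            acc, pos, ref, alt, cls = line.split("\t")[:5]
            out.append(VariantRecord(acc, int(pos), ref, alt, cls))
    return out


def extrapolate_models(
    model: ComplexModel,
    homologue_map: Dict[str, Sequence[str]],
) -> List[ModelVariant]:
    """All homologue combinations of a model's subunits.

    ``homologue_map`` lists, per accession, the homologues that may stand
    in for it (above-threshold identity).  The original protein is always
    a choice, so a model whose subunits have 2, 3 and 3 homologues
    (originals included) yields 18 combinations; an empty or missing list
    means the subunit admits only its original protein.
    """
    choices: List[List[Tuple[str, str]]] = []
    for su in model.subunits:
        alts = list(homologue_map.get(su.protein) or [su.protein])
        if su.protein not in alts:
            alts = [su.protein] + alts
        choices.append([(su.subunit_id, acc) for acc in alts])
    return [ModelVariant(base=model, assigned=dict(combo))
            for combo in itertools.product(*choices)]


def _position_to_residue(protein_seq: str, chain, position: int,
                         cfg: Config) -> Optional[int]:
    """Map a 1-based protein position onto a chain residue seq_index.

    Gapped or unaligned positions return None (disordered by convention).
    """
    aln = align_pair(protein_seq, chain.sequence, cfg)
    col = aln.query_to_subject.get(position)
    if col is None:
        return None
    return chain.residues[col - 1].seq_index


def classify_environment(
    model: ComplexModel,
    subunit_id: str,
    position: int,
    protein_seq: str,
    interfaces: Optional[List[Interface]] = None,
    cfg: Config = DEFAULT,
    _sasa_cache: Optional[Dict[str, Dict[int, float]]] = None,
) -> Tuple[str, Optional[str]]:
    """Environment (and interface subtype) of one sequence position.

    Order of precedence: unmapped/coordinate-less -> disordered; relative
    accessibility on the isolated subunit < threshold -> interior; member
    of a detected interface residue set -> interface; otherwise surface.
    """
    su = model.subunit(subunit_id)
    if position < 1 or position > len(protein_seq):
        raise IndexError(f"position {position} beyond sequence of length {len(protein_seq)}")
    seq_index = _position_to_residue(protein_seq, su.chain, position, cfg)
    if seq_index is None:
        return "disordered", None
    residue = next(r for r in su.chain.residues if r.seq_index == seq_index)
    if not residue.has_coordinates:
        return "disordered", None
    if _sasa_cache is not None and subunit_id in _sasa_cache:
        iso = _sasa_cache[subunit_id]
    else:
        iso = residue_sasa(su.chain, cfg)
        if _sasa_cache is not None:
            _sasa_cache[subunit_id] = iso
    rel = iso.get(seq_index, 0.0) / MAX_ACCESSIBILITY.get(residue.aa, 200.0)
    if rel < cfg.buried_rel_acc:
        return "interior", None
    if interfaces is None:
        interfaces = detect_interfaces(model, cfg)
    for f in interfaces:
        if subunit_id in (f.subunit_a, f.subunit_b):
            residues, _, _ = f.side(subunit_id)
            if seq_index in residues:
                return "interface", f.type or "experimental"
    return "surface", None


def map_variants(
    variants: Sequence[VariantRecord],
    models: Sequence[ComplexModel],
    proteins: Dict[str, ProteinEntry],
    interfaces_by_model: Optional[Dict[str, List[Interface]]] = None,
    homologue_map: Optional[Dict[str, Sequence[str]]] = None,
    cfg: Config = DEFAULT,
) -> List[EnvironmentAssignment]:
    """Map each variant onto every model (and extrapolated combination).

    A variant hitting several models is counted once: interface placements
    win (with subtype priority experimental > model-predicted >
    model-suggested), then interior, then surface, then disordered.
    """
    if interfaces_by_model is None:
        interfaces_by_model = {m.model_id: detect_interfaces(m, cfg) for m in models}
    sasa_caches: Dict[str, Dict] = {m.model_id: {} for m in models}
    env_rank = {"interface": 0, "interior": 1, "surface": 2, "disordered": 3}
    sub_rank = {s: i for i, s in enumerate(SUBTYPE_PRIORITY)}
    out: List[EnvironmentAssignment] = []
    for var in variants:
        if var.accession not in proteins:
            continue
        seq = proteins[var.accession].sequence
        if var.position > len(seq):
            continue
        best: Optional[Tuple[int, int, str, Optional[str], str]] = None
        for model in models:
            occupancies = [(su.subunit_id, su.protein) for su in model.subunits]
            if homologue_map:
                extra = {
                    su.subunit_id for su in model.subunits
                    if var.accession in (homologue_map.get(su.protein) or [])
                }
                occupancies += [(sid, var.accession) for sid in sorted(extra)]
            for sid, occupant in occupancies:
                if occupant != var.accession:
                    continue
                env, subtype = classify_environment(
                    model, sid, var.position, seq,
                    interfaces=interfaces_by_model[model.model_id], cfg=cfg,
                    _sasa_cache=sasa_caches[model.model_id],
                )
                key = (env_rank[env], sub_rank.get(subtype, 9), env, subtype, model.model_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            _, _, env, subtype, model_id = best
            out.append(EnvironmentAssignment(var, env, subtype, model_id))
    return out


def environment_table(assignments: Sequence[EnvironmentAssignment]) -> pd.DataFrame:
    """Counts per variant class x environment (interface split by subtype)."""
    cols = ["interface_experimental", "interface_model_predicted",
            "interface_model_suggested", "surface", "interior", "disordered"]
    table = pd.DataFrame(0, index=list(VAR_CLASSES), columns=cols)
    for a in assignments:
        col = (f"interface_{a.interface_subtype}" if a.environment == "interface"
               else a.environment)
        table.loc[a.variant.var_class, col] += 1
    table["total"] = table.sum(axis=1)
    return table


def hypergeom_pvalue(n_population: int, n_success: int, n_draw: int,
                     k_observed: int) -> float:
    """One-sided (enrichment) hypergeometric tail probability P[X >= k]."""
    return float(stats.hypergeom.sf(k_observed - 1, n_population, n_success, n_draw))


def enrichment_tests(
    assignments: Sequence[EnvironmentAssignment],
    baseline_class: str = "polymorphism",
) -> pd.DataFrame:
    """Per-environment enrichment of each class against the baseline class.

    For each non-baseline class and environment the expected count under
    the baseline's environment distribution is compared with the observed
    count by a 1-df chi-square test, plus a one-sided hypergeometric test
    on the corresponding 2x2 table.  Cells whose baseline margin is zero
    are skipped with a notice row.
    """
    classes = {a.variant.var_class for a in assignments}
    if len(classes) < 2 or baseline_class not in classes:
        raise ValueError("need the baseline class and at least one other class")

    def env_counts(cls: str) -> Dict[str, int]:
        c = dict.fromkeys(ENVIRONMENTS, 0)
        for a in assignments:
            if a.variant.var_class == cls:
                c[a.environment] += 1
        return c

    base = env_counts(baseline_class)
    base_total = sum(base.values())
    rows = []
    for cls in sorted(classes - {baseline_class}):
        obs = env_counts(cls)
        cls_total = sum(obs.values())
        for env in ENVIRONMENTS:
            if base_total == 0 or cls_total == 0:
                continue
            expected = cls_total * base[env] / base_total
            if base[env] == 0 and obs[env] == 0:
                rows.append({"var_class": cls, "environment": env,
                             "observed": 0, "expected": 0.0,
                             "p_value": np.nan, "test": "skipped_zero_margin"})
                continue
            if expected in (0.0, float(cls_total)):
                chi_p = np.nan
            else:
                chi_p = float(stats.chisquare(
                    [obs[env], cls_total - obs[env]],
                    [expected, cls_total - expected]).pvalue)
            hyp_p = hypergeom_pvalue(
                n_population=base_total + cls_total,
                n_success=base[env] + obs[env],
                n_draw=cls_total,
                k_observed=obs[env],
            )
            rows.append({"var_class": cls, "environment": env,
                         "observed": obs[env], "expected": expected,
                         "p_value": chi_p, "test": "chi2"})
            rows.append({"var_class": cls, "environment": env,
                         "observed": obs[env], "expected": expected,
                         "p_value": hyp_p, "test": "hypergeometric"})
    return pd.DataFrame(rows)
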