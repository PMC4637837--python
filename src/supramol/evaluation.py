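"""Virtual blind test of assembled models against experimental references.

A model is a blind-test case when it was assembled from elements of at
least two different template entries and an experimental reference complex
contains homologues of all compared subunits: the model then predicts the
relative placement of subunits the reference never saw together with their
template.  Accuracy is measured as whole-complex C-alpha RMSD and, per
predicted subunit, as the ligand-RMSD analogue used in docking assessment:
the common subunits are superposed and the RMSD of the predicted subunit
is read off without re-fitting.  CAPRI-style classes apply: <=1 A high,
<=5 A medium, <=10 A acceptable, else incorrect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .assembly import ComplexModel
from .config import DEFAULT, Config
from .sequences import align_pair
from .structures_io import ChainStructure
from .superpose import kabsch

__all__ = [
    "BlindTestResult",
    "BlindCase",
    "capri_class",
    "eligible_blind_cases",
    "blind_rmsd",
]

CAPRI_BOUNDS = ((1.0, "high"), (5.0, "medium"), (10.0, "acceptable"))


def capri_class(rmsd: float, atol: float = 1e-9) -> str:
    """Accuracy class with closed upper bounds at 1, 5 and 10 A.

    `atol` absorbs floating-point noise exactly at a boundary, so a
    measured 1 + 1e-12 A displacement still counts as the boundary class.
    """
    if rmsd < 0:
        raise ValueError("rmsd must be non-negative")
    for bound, label in CAPRI_BOUNDS:
        if rmsd <= bound + atol:
            return label
    return "incorrect"


@dataclass
class BlindTestResult:
    model_id: str
    overall_rmsd: float
    subunit_rmsds: Dict[str, float]
    capri_classes: Dict[str, str]

    def __post_init__(self):
        if self.overall_rmsd < 0 or any(v < 0 for v in self.subunit_rmsds.values()):
            raise ValueError("rmsd values must be non-negative")


@dataclass
class BlindCase:
    model: ComplexModel
    reference: Dict[str, ChainStructure]   # protein accession -> reference chain
    predicted_subunits: List[str]          # subunit ids whose placement was inferred


def _predicted_subunits(model: ComplexModel) -> List[str]:
    """Subunits whose template entry differs from their anchor's entry.

    The seed pair is co-determined by construction; a subunit introduced by
    an element from another entry is an inference the reference can test.
    """
    entry_of = {s.subunit_id: s.chain.source_entry for s in model.subunits}
    out = []
    for su in model.subunits:
        if su.anchor == su.subunit_id:
            continue  # seed subunit
        if entry_of[su.subunit_id] != entry_of.get(su.anchor):
            out.append(su.subunit_id)
    return out


def eligible_blind_cases(
    models: Sequence[ComplexModel],
    references: Sequence[Dict[str, ChainStructure]],
    min_common: int = 3,
) -> List[BlindCase]:
    """Pair multi-entry models with references covering their subunits."""
    cases = []
    for model in models:
        if len(model.template_entries()) < 2:
            continue
        predicted = _predicted_subunits(model)
        if not predicted:
            continue
        for ref in references:
            if all(s.protein in ref for s in model.subunits) and len(model.subunits) >= min_common:
                cases.append(BlindCase(model=model, reference=ref,
                                       predicted_subunits=predicted))
                break
    return cases


def _matched_coords(model_chain: ChainStructure, ref_chain: ChainStructure,
                    cfg: Config) -> Tuple[np.ndarray, np.ndarray]:
    aln = align_pair(model_chain.sequence, ref_chain.sequence, cfg)
    m_ca, r_ca = model_chain.ca_coords(), ref_chain.ca_coords()
    mov, fix = [], []
    for i, j in aln.aligned_pairs:
        a, b = m_ca[i - 1], r_ca[j - 1]
        if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
            mov.append(a)
            fix.append(b)
    return np.asarray(mov), np.asarray(fix)


def blind_rmsd(case: BlindCase, cfg: Config = DEFAULT) -> BlindTestResult:
    """Whole-complex RMSD plus per-predicted-subunit ligand RMSD."""
    per_subunit: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for su in case.model.subunits:
        ref_chain = case.reference.get(su.protein)
        if ref_chain is None:
            continue
        mov, fix = _matched_coords(su.chain, ref_chain, cfg)
        if len(mov):
            per_subunit[su.subunit_id] = (mov, fix)
    all_mov = np.vstack([v[0] for v in per_subunit.values()])
    all_fix = np.vstack([v[1] for v in per_subunit.values()])
    if len(all_mov) < 3:
        raise ValueError("fewer than 3 matched residues for whole-complex fit")
    _, overall = kabsch(all_mov, all_fix)
    subunit_rmsds: Dict[str, float] = {}
    classes: Dict[str, str] = {}
    for sid in case.predicted_subunits:
        if sid not in per_subunit:
            continue
        common_mov = np.vstack([v[0] for k, v in per_subunit.items() if k != sid])
        common_fix = np.vstack([v[1] for k, v in per_subunit.items() if k != sid])
        if len(common_mov) < 3:
            raise ValueError(f"fewer than 3 residues in the fitting set for {sid}")
        t, _ = kabsch(common_mov, common_fix)
        mov, fix = per_subunit[sid]
        diff = t.apply(mov) - fix
        r = float(np.sqrt((diff * diff).sum() / len(mov)))
        subunit_rmsds[sid] = r
        classes[sid] = capri_class(r)
    return BlindTestResult(
        model_id=case.model.model_id,
        overall_rmsd=overall,
        subunit_rmsds=subunit_rmsds,
        capri_classes=classes,
    )
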