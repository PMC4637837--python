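"""Rigid-body superposition, TM-score, and the assembly acceptance gate.

Kabsch's SVD solution gives the least-squares optimal proper rotation for a
matched point set.  The TM-score of a residue correspondence,

    TM = (1/L_n) * sum_i 1 / (1 + (d_i / d0)^2),
    d0 = 1.24 * (L_n - 15)^(1/3) - 1.8   (floored at 0.5 A),

is maximized over rigid superpositions by the usual fragment-seeded
iterative search.  A candidate superposition during assembly is accepted
when the structure-based sequence identity and TM-score clear a two-band
gate: identity above 30% requires TM > 0.5, identity within 25-30%
requires the stricter TM > 0.6, and identity below 25% is never accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import DEFAULT, Config
from .sequences import align_pair
from .structures_io import ChainStructure, RigidTransform

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "tm_d0",
    "tm_score",
    "structure_align",
    "accept_superposition",
]


@dataclass
class SuperpositionResult:
    transform: RigidTransform      # maps the moving chain onto the fixed chain
    rmsd: float                    # over matched C-alpha pairs, angstrom
    tmscore: float
    n_matched: int
    identity_struct: float         # identity over structurally matched pairs
    norm_length: int = 0           # chain length used to normalize the TM-score

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if not 0.0 < self.tmscore <= 1.0:
            raise ValueError("tmscore must be in (0,1]")
        if self.n_matched < 3:
            raise ValueError("need at least 3 matched pairs")


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> Tuple[RigidTransform, float]:
    """Optimal proper rigid motion mapping `moving` onto `fixed`.

    Returns the transform and the minimized RMSD.  A reflection-only
    optimum is corrected to a proper rotation by flipping the smallest
    singular direction.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("point sets must have equal shape")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return RigidTransform(R, t), rmsd


def tm_d0(norm_length: int) -> float:
    """Length-dependent distance scale of the TM-score, floored at 0.5 A."""
    if norm_length > 15:
        d0 = 1.24 * (norm_length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_value(mov: np.ndarray, fix: np.ndarray, t: RigidTransform,
              d0: float, norm_length: int) -> float:
    d2 = ((t.apply(mov) - fix) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d2 / (d0 * d0))).sum() / norm_length)


def _tm_refine(mov: np.ndarray, fix: np.ndarray, seed: np.ndarray,
               d0: float, norm_length: int, max_iter: int = 20
               ) -> Tuple[float, RigidTransform]:
    """Iterative inclusion-set refinement from a seed subset of pairs."""
    n = len(mov)
    sel = seed
    best_tm, best_t = 0.0, None
    prev: Optional[frozenset] = None
    for _ in range(max_iter):
        t, _ = kabsch(mov[sel], fix[sel])
        tm = _tm_value(mov, fix, t, d0, norm_length)
        if tm > best_tm:
            best_tm, best_t = tm, t
        d = np.sqrt(((t.apply(mov) - fix) ** 2).sum(axis=1))
        cut = d0
        new = np.where(d < cut)[0]
        while len(new) < 3 and cut < 100.0:
            cut += 0.5
            new = np.where(d < cut)[0]
        key = frozenset(new.tolist())
        if key == prev:
            break
        prev = key
        sel = new
    return best_tm, best_t


def tm_score(
    moving: ChainStructure,
    fixed: ChainStructure,
    pairs: Sequence[Tuple[int, int]],
    norm_length: int,
    seed_starts: str = "all",
    return_transform: bool = False,
):
    """TM-score of a residue correspondence, maximized over superpositions.

    `pairs` are 1-based (moving_index, fixed_index) residue pairs; the score
    is normalized by `norm_length`.  The search seeds the refinement from
    every contiguous fragment of at least 4 matched pairs, so the reported
    score is the full fragment-seeded optimum rather than a heuristic
    subset of seeds.
    """
    if not pairs:
        raise ValueError("no matched pairs")
    mov_ca = moving.ca_coords()
    fix_ca = fixed.ca_coords()
    mov, fix = [], []
    for i, j in pairs:
        a, b = mov_ca[i - 1], fix_ca[j - 1]
        if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
            mov.append(a)
            fix.append(b)
    mov, fix = np.asarray(mov), np.asarray(fix)
    n = len(mov)
    if n < 3:
        raise ValueError("fewer than 3 matched pairs with coordinates")
    d0 = tm_d0(norm_length)
    lengths = range(min(4, n), n + 1)
    best_tm, best_t = 0.0, None
    for frag in lengths:
        for s in range(0, n - frag + 1):
            seed = np.arange(s, s + frag)
            tm, t = _tm_refine(mov, fix, seed, d0, norm_length)
            if tm > best_tm:
                best_tm, best_t = tm, t
    if return_transform:
        return best_tm, best_t
    return best_tm


def structure_align(a: ChainStructure, b: ChainStructure,
                    cfg: Config = DEFAULT) -> SuperpositionResult:
    """Sequence-guided structural superposition of chain `a` onto chain `b`.

    The residue correspondence comes from local sequence alignment; it is
    refined by iterative superposition with outlier rejection (pairs beyond
    2*d0 are dropped and the fit repeated, up to 10 rounds).  The returned
    identity is computed over the structurally retained pairs, and the
    TM-score is normalized by the length of the fixed (anchor) chain.
    """
    if len(a) < 15 or len(b) < 15:
        raise ValueError("structure_align requires chains of >= 15 residues")
    aln = align_pair(a.sequence, b.sequence, cfg)
    if not aln.aligned_pairs:
        raise ValueError("sequence alignment is empty")
    a_ca, b_ca = a.ca_coords(), b.ca_coords()
    pairs = [(i, j) for i, j in aln.aligned_pairs
             if np.all(np.isfinite(a_ca[i - 1])) and np.all(np.isfinite(b_ca[j - 1]))]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 aligned residues with coordinates")
    norm_length = len(b)
    d0 = tm_d0(norm_length)
    kept = list(pairs)
    transform = None
    rmsd = 0.0
    for _ in range(10):
        mov = np.array([a_ca[i - 1] for i, _ in kept])
        fix = np.array([b_ca[j - 1] for _, j in kept])
        transform, rmsd = kabsch(mov, fix)
        d = np.sqrt(((transform.apply(mov) - fix) ** 2).sum(axis=1))
        keep_mask = d <= 2.0 * d0
        if keep_mask.sum() < 3 or keep_mask.all():
            break
        kept = [p for p, k in zip(kept, keep_mask) if k]
    matches = sum(1 for i, j in kept if a.sequence[i - 1] == b.sequence[j - 1])
    identity_struct = matches / len(kept)
    tm = tm_score(a, b, pairs, norm_length)
    return SuperpositionResult(
        transform=transform,
        rmsd=rmsd,
        tmscore=tm,
        n_matched=len(kept),
        identity_struct=identity_struct,
        norm_length=norm_length,
    )


def accept_superposition(identity_struct: float, tmscore: float,
                         cfg: Config = DEFAULT) -> bool:
    """Two-band acceptance gate on a candidate superposition.

    True iff identity > 30% with TM-score > 0.5, or identity within
    [25%, 30%] with TM-score > 0.6.  Identity below 25% is never accepted.
    Identity exactly 0.30 falls in the stricter band; exactly 0.25 is
    admitted to it.
    """
    if not (0.0 <= identity_struct <= 1.0 and 0.0 <= tmscore <= 1.0):
        raise ValueError("identity and tmscore must be fractions in [0,1]")
    if identity_struct > cfg.accept_hi_id:
        return tmscore > cfg.accept_hi_tm
    if identity_struct >= cfg.accept_min_id:
        return tmscore > cfg.accept_lo_tm
    return False
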