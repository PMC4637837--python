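"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different algorithmic route from the code
under test: quaternion (Horn) superposition instead of SVD, brute-force
dense sampling instead of the production SASA grid, textbook dynamic
programming instead of the aligner library, explicit enumeration instead
of closed-form distributions.
"""

from __future__ import annotations

import math
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def horn_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    P = np.asarray(moving, float)
    Q = np.asarray(fixed, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    Sxx = P0.T @ Q0
    S = Sxx
    N = np.array([
        [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
        [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
        [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
        [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
    ])
    lam = np.linalg.eigvalsh(N)[-1]
    e0 = (P0 * P0).sum() + (Q0 * Q0).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / len(P))
    return math.sqrt(msd)


def gotoh_local_score(a: str, b: str, gap_open: float = 11.0,
                      gap_extend: float = 1.0) -> float:
    """Textbook affine-gap local alignment (Gotoh) best score."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def rescore_alignment(a: str, b: str, pairs: Sequence[Tuple[int, int]],
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score of an explicit alignment path (pairs are 1-based, increasing)."""
    score = 0.0
    for k, (i, j) in enumerate(pairs):
        score += _BLOSUM62[a[i - 1], b[j - 1]]
        if k:
            gi = i - pairs[k - 1][0] - 1
            gj = j - pairs[k - 1][1] - 1
            for g in (gi, gj):
                if g > 0:
                    score -= gap_open + (g - 1) * gap_extend
    return score


def _ring_lattice(n_points: int) -> np.ndarray:
    """Equal-area latitude-ring sphere sampling (deterministic)."""
    n_rings = max(3, int(round(math.sqrt(n_points * math.pi / 4.0))))
    pts = []
    for i in range(n_rings):
        theta = math.pi * (i + 0.5) / n_rings
        n_phi = max(1, int(round(n_points * math.sin(theta) * math.pi / (2.0 * n_rings))))
        for j in range(n_phi):
            phi = 2.0 * math.pi * (j + 0.5) / n_phi
            pts.append([math.sin(theta) * math.cos(phi),
                        math.sin(theta) * math.sin(phi),
                        math.cos(theta)])
    return np.asarray(pts)


def dense_sasa(chains, n_points: int = 10000, probe: float = 1.4,
               radii: Dict[str, float] = None, seed: int = 0
               ) -> Dict[Tuple[int, int], float]:
    """Brute-force SASA: dense stratified ring lattice, no spatial index."""
    from supramol.interfaces import DEFAULT_RADIUS, VDW_RADII

    radii = radii or VDW_RADII
    sphere = _ring_lattice(n_points)
    n_points = len(sphere)
    coords, rads, owner = [], [], []
    areas: Dict[Tuple[int, int], float] = {}
    for ci, chain in enumerate(chains):
        for res in chain.residues:
            areas[(ci, res.seq_index)] = 0.0
            for atom in res.atoms:
                if not atom.is_heavy:
                    continue
                coords.append(atom.coords)
                rads.append(radii.get(atom.element.upper(), DEFAULT_RADIUS))
                owner.append((ci, res.seq_index))
    coords = np.asarray(coords)
    ext = np.asarray(rads) + probe
    n_atoms = len(coords)
    for i in range(n_atoms):
        pts = sphere * ext[i] + coords[i]
        # plain distance prefilter (no spatial index): only atoms whose
        # extended spheres can intersect atom i's can cover its points
        d_atoms = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.where((d_atoms < ext[i] + ext) & (np.arange(n_atoms) != i))[0]
        covered = np.zeros(n_points, dtype=bool)
        for j in neigh:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            covered |= d2 <= ext[j] ** 2
        areas[owner[i]] += 4.0 * math.pi * ext[i] ** 2 * (~covered).mean()
    return areas


def flood_fill_components(nodes: Sequence[str],
                          edges: Sequence[Tuple[str, str]]) -> List[Set[str]]:
    """Connected components by explicit breadth-first flood fill."""
    adj: Dict[str, Set[str]] = {n: set() for n in nodes}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: Set[str] = set()
    comps = []
    for n in adj:
        if n in seen:
            continue
        comp = set()
        stack = [n]
        while stack:
            cur = stack.pop()
            if cur in comp:
                continue
            comp.add(cur)
            stack.extend(adj[cur] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for a hypergeometric draw, by explicit mass enumeration."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def tm_score_exhaustive(mov: np.ndarray, fix: np.ndarray, norm_length: int,
                        max_iter: int = 30) -> float:
    """TM-score maximized over every contiguous fragment seed (length >= 4).

    Independent of the production search: its own Kabsch-free quaternion
    superposition (Horn rotation) and its own inclusion-set iteration.
    """
    mov = np.asarray(mov, float)
    fix = np.asarray(fix, float)
    n = len(mov)
    if norm_length > 15:
        d0 = max(0.5, 1.24 * (norm_length - 15) ** (1.0 / 3.0) - 1.8)
    else:
        d0 = 0.5

    def horn_transform(P, Q):
        P0 = P - P.mean(axis=0)
        Q0 = Q - Q.mean(axis=0)
        S = P0.T @ Q0
        N4 = np.array([
            [S[0, 0] + S[1, 1] + S[2, 2], S[1, 2] - S[2, 1], S[2, 0] - S[0, 2], S[0, 1] - S[1, 0]],
            [S[1, 2] - S[2, 1], S[0, 0] - S[1, 1] - S[2, 2], S[0, 1] + S[1, 0], S[2, 0] + S[0, 2]],
            [S[2, 0] - S[0, 2], S[0, 1] + S[1, 0], -S[0, 0] + S[1, 1] - S[2, 2], S[1, 2] + S[2, 1]],
            [S[0, 1] - S[1, 0], S[2, 0] + S[0, 2], S[1, 2] + S[2, 1], -S[0, 0] - S[1, 1] + S[2, 2]],
        ])
        w, V = np.linalg.eigh(N4)
        q = V[:, -1]
        q0, q1, q2, q3 = q
        R = np.array([
            [q0*q0+q1*q1-q2*q2-q3*q3, 2*(q1*q2-q0*q3), 2*(q1*q3+q0*q2)],
            [2*(q1*q2+q0*q3), q0*q0-q1*q1+q2*q2-q3*q3, 2*(q2*q3-q0*q1)],
            [2*(q1*q3-q0*q2), 2*(q2*q3+q0*q1), q0*q0-q1*q1-q2*q2+q3*q3],
        ])
        t = Q.mean(axis=0) - R @ P.mean(axis=0)
        return R, t

    def tm_of(R, t):
        d2 = ((mov @ R.T + t - fix) ** 2).sum(axis=1)
        return float((1.0 / (1.0 + d2 / (d0 * d0))).sum() / norm_length)

    best = 0.0
    for frag in range(4, n + 1):
        for s in range(0, n - frag + 1):
            sel = np.arange(s, s + frag)
            prev = None
            for _ in range(max_iter):
                R, t = horn_transform(mov[sel], fix[sel])
                best = max(best, tm_of(R, t))
                d = np.sqrt(((mov @ R.T + t - fix) ** 2).sum(axis=1))
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
    return best
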