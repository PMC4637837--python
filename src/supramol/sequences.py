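"""Pairwise sequence comparison and interaction categorization.

Interacting protein pairs are compared against the chains of a structure
library by exact local alignment (Smith-Waterman, BLOSUM62, gap 11/1) and
sorted into four categories: *complex* (homologues of both partners were
co-determined in one structure entry and can template the interaction),
*independent* (both partners have homologous structures, but never together),
*one_sided*, and *unknown*.  Identity is computed over aligned columns only;
coverage is deliberately not a filter at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .config import DEFAULT, Config
from .structures_io import ChainStructure

__all__ = [
    "ProteinEntry",
    "AlignmentResult",
    "InteractionRecord",
    "align_pair",
    "find_homologues",
    "classify_interaction",
    "read_fasta",
    "read_interactions",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

CATEGORIES = ("complex", "independent", "one_sided", "unknown")


@dataclass(frozen=True)
class ProteinEntry:
    accession: str
    sequence: str
    organism: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: invalid residues {sorted(bad)}")


@dataclass
class AlignmentResult:
    identity_fraction: float
    aligned_pairs: List[Tuple[int, int]]  # 1-based (query, subject) pairs
    score: float

    def __post_init__(self):
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction out of [0,1]")

    @property
    def query_to_subject(self) -> Dict[int, int]:
        return dict(self.aligned_pairs)


@dataclass(frozen=True)
class InteractionRecord:
    acc_a: str
    acc_b: str
    detection_method: str = ""
    source_id: str = ""

    def __post_init__(self):
        if not self.acc_a or not self.acc_b:
            raise ValueError("interaction accessions must be non-empty")

    @property
    def pair(self) -> Tuple[str, str]:
        """Unordered pair identity: (A, B) == (B, A)."""
        return tuple(sorted((self.acc_a, self.acc_b)))


_ALIGNER = None


def _aligner(cfg: Config) -> Align.PairwiseAligner:
    global _ALIGNER
    key = (cfg.gap_open, cfg.gap_extend)
    if _ALIGNER is None or _ALIGNER[0] != key:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -cfg.gap_open
        aligner.extend_gap_score = -cfg.gap_extend
        _ALIGNER = (key, aligner)
    return _ALIGNER[1]


def align_pair(query, subject, cfg: Config = DEFAULT) -> AlignmentResult:
    """Best local alignment of two sequences.

    Accepts ProteinEntry or plain strings.  Alignments scoring below the
    score floor are treated as no alignment (identity 0, no pairs): a short
    spurious local hit between unrelated sequences carries no homology
    signal.  Identity is identical columns over aligned (gap-free) columns.
    """
    qseq = query.sequence if hasattr(query, "sequence") else str(query)
    sseq = subject.sequence if hasattr(subject, "sequence") else str(subject)
    if not qseq or not sseq:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(cfg)
    alns = aligner.align(qseq.replace("X", "A"), sseq.replace("X", "A"))
    try:
        best = alns[0]
    except IndexError:
        return AlignmentResult(0.0, [], 0.0)
    if best.score < cfg.score_floor:
        return AlignmentResult(0.0, [], float(best.score))
    pairs: List[Tuple[int, int]] = []
    matches = 0
    for (qs, qe), (ss, se) in zip(*best.aligned):
        for k in range(int(qe) - int(qs)):
            qi, si = int(qs) + k, int(ss) + k
            pairs.append((qi + 1, si + 1))
            if qseq[qi] == sseq[si]:
                matches += 1
    if not pairs:
        return AlignmentResult(0.0, [], float(best.score))
    return AlignmentResult(matches / len(pairs), pairs, float(best.score))


def find_homologues(
    query: ProteinEntry,
    library: Sequence[ChainStructure],
    min_identity: Optional[float] = None,
    cfg: Config = DEFAULT,
) -> List[Tuple[ChainStructure, AlignmentResult]]:
    """All library chains with identity strictly above the threshold.

    Sorted by identity descending (ties by entry then chain ID for a
    deterministic order).  Coverage is not a filter.
    """
    thr = cfg.min_identity if min_identity is None else min_identity
    if not 0.0 <= thr <= 1.0:
        raise ValueError("min_identity must be in [0,1]")
    hits = []
    for chain in library:
        if not chain.sequence:
            continue
        res = align_pair(query.sequence, chain.sequence, cfg)
        if res.identity_fraction > thr:
            hits.append((chain, res))
    hits.sort(key=lambda h: (-h[1].identity_fraction, h[0].source_entry, h[0].chain_id))
    return hits


def classify_interaction(
    rec: InteractionRecord,
    proteins: Dict[str, ProteinEntry],
    library: Sequence[ChainStructure],
    min_identity: Optional[float] = None,
    cfg: Config = DEFAULT,
) -> str:
    """Assign one of the four categories to an interaction record.

    complex     homologues of both partners are co-determined chains of a
                single structure entry (for a self-interaction: two distinct
                homologous chains in one entry, a homodimer template)
    independent both partners have homologues, never co-determined
    one_sided   exactly one partner has a homologue
    unknown     neither does
    """
    for acc in (rec.acc_a, rec.acc_b):
        if acc not in proteins:
            raise KeyError(f"no sequence for accession {acc}")
    hits_a = find_homologues(proteins[rec.acc_a], library, min_identity, cfg)
    if rec.acc_a == rec.acc_b:
        hits_b = hits_a
    else:
        hits_b = find_homologues(proteins[rec.acc_b], library, min_identity, cfg)
    if not hits_a and not hits_b:
        return "unknown"
    if not hits_a or not hits_b:
        return "one_sided"
    by_entry_a: Dict[str, set] = {}
    for chain, _ in hits_a:
        by_entry_a.setdefault(chain.source_entry, set()).add(chain.chain_id)
    for chain, _ in hits_b:
        ids_a = by_entry_a.get(chain.source_entry)
        if ids_a and (ids_a - {chain.chain_id}):
            return "complex"
    return "independent"


def read_fasta(path) -> Dict[str, ProteinEntry]:
    """Load protein sequences keyed by accession (first token of the header)."""
    entries: Dict[str, ProteinEntry] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        entries[acc] = ProteinEntry(accession=acc, sequence=str(rec.seq).upper())
    return entries


def read_interactions(path) -> List[InteractionRecord]:
    """Read a MITAB-style TSV (acc_a, acc_b, detection_method, source_id).

    A header line starting with '#' or 'acc_a' is skipped; duplicate
    unordered pairs are kept (they may differ in detection method).
    """
    records: List[InteractionRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("acc_a"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed interaction line: {line!r}")
            acc_a, acc_b = parts[0].strip(), parts[1].strip()
            method = parts[2].strip() if len(parts) > 2 else ""
            source = parts[3].strip() if len(parts) > 3 else ""
            records.append(InteractionRecord(acc_a, acc_b, method, source))
    return records
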