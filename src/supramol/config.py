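"""Tunable thresholds for the modeling pipeline.

Every cutoff used by the assembly, interface and variant-mapping stages is a
field here, so a run can be reproduced from its configuration alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class Config:
    # sequence comparison
    min_identity: float = 0.25      # homologue threshold (strict >)
    gap_open: float = 11.0          # Smith-Waterman gap open penalty
    gap_extend: float = 1.0         # gap extension penalty
    score_floor: float = 25.0       # local alignments scoring below this are discarded

    # superposition acceptance gate
    accept_hi_id: float = 0.30      # identity above this: TM-score must exceed accept_hi_tm
    accept_hi_tm: float = 0.5
    accept_lo_tm: float = 0.6       # identity in [min_identity, accept_hi_id]: stricter TM gate
    accept_min_id: float = 0.25

    # steric clash predicate during assembly
    clash_max_pairs: int = 10       # >= this many close C-alpha pairs is a clash
    clash_dist: float = 3.0         # angstrom

    # solvent accessible surface area
    sasa_probe: float = 1.4         # angstrom, water probe
    sasa_points: int = 960          # sphere sample points per atom

    # interface detection
    interface_min_area: float = 250.0   # angstrom^2, on the larger of the two sides
    interface_overlap_frac: float = 0.10  # shared-area fraction merging two sites
    interface_residue_min_loss: float = 0.1  # angstrom^2 lost to count a residue as interfacial

    # variant environment classification
    buried_rel_acc: float = 0.1     # relative accessibility below this is interior

    def with_(self, **kw) -> "Config":
        return replace(self, **kw)


DEFAULT = Config()
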