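# Methods

This note records the model behind `supramol`, the parameter choices that
matter, what the synthetic benchmarks do and do not emulate, and the
numerical conventions a maintainer would need to reproduce or modify the
results.

## Model and assumptions

The central assumption is rigid-body transferability of binary
interfaces: if a dimeric structure exists for homologues of an
interacting pair, the relative orientation of the two chains can be
carried, unchanged, into a larger assembly by superposing shared
subunits. No comparative (homology) remodeling of the subunit chains is
performed — target sequences are mapped onto template chains by
alignment, and template coordinates are used as-is. Consequences:

- model quality is bounded by template quality and by the rigidity
  assumption; conformational changes on complexation are invisible;
- a model is a set of placed chains plus provenance (which element
  introduced which subunit, anchored on what, with what transform), so
  every interface statistic is reproducible from the output alone;
- assembly terminates: each element is consumed at most once per model
  and each network node is placed at most once, so fibrous/periodic
  growth cannot occur by construction.

Anchor selection is degree-greedy (highest interaction degree within the
sub-network, ties by placement order then accession), matching the
intuition that well-connected subunits offer the most superposition
opportunities. A seeded random anchor ordering is available as a control;
on the bundled benchmarks both orderings give the same mean model size.

Homodimer edges (self-interactions) are retained and may seed a model
with two copies of one protein; they are otherwise consumed without
placement, since each network node admits one copy. Distinct homologous
proteins are distinct nodes and assemble normally.

## Acceptance gate

A superposition introducing a subunit is accepted iff

| structure-based identity | TM-score required |
|---|---|
| > 0.30 | > 0.5 |
| 0.25 – 0.30 (inclusive) | > 0.6 |
| < 0.25 | never |

Identity exactly 0.30 falls in the stricter band; 0.25 is admitted to it.
The TM-score is normalized by the anchor (fixed) chain length; the
normalization choice is recorded per superposition in provenance. The
structural aligner is sequence-guided (local alignment for the
correspondence, iterative Kabsch with 2·d₀ outlier rejection, ≤ 10
rounds) rather than a full structural-alignment search; the TM-score it
reports is the optimum over all contiguous fragment seeds (length ≥ 4)
with inclusion-set refinement, which on the test fixtures coincides with
an exhaustive-seed reference to < 1e-6. Numerical agreement with the
TM-align program is not promised — only the score definition above.

## Thresholds and parameters

All are fields of `supramol.config.Config`:

- `min_identity = 0.25` (strict >): homologue retrieval and element
  assignment. Coverage is deliberately not filtered; quality control
  happens at the superposition step instead, because templates are often
  domain fragments.
- Alignment: Smith–Waterman, BLOSUM62, gap open 11 / extend 1 — the
  classic protein local-alignment parameterization. `score_floor = 25`
  (≈ 5 consecutive identities) discards spurious short local hits that
  would otherwise register as high-identity micro-alignments; identity is
  identical columns over aligned (gap-free) columns.
- Clash: ≥ 10 candidate-vs-placed Cα pairs under 3.0 Å. Chosen to
  tolerate loop-level brushes while rejecting core overlap; both numbers
  are config keys, and all clash/gate rejections are logged with scores.
- SASA: Shrake–Rupley, probe 1.4 Å, 960 golden-spiral points per atom,
  vdW radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å. At 960 points the
  per-residue discretization error on the benchmark folds is ≲ 1.5%
  against a ~10⁴-point dense-sampling reference.
- Interfaces: reported when max(buried_A, buried_B) > 250 Å² (the larger
  side, since buried areas are near-symmetric for compact contacts);
  a residue is interfacial when it loses > 0.1 Å². Overlap fraction
  between two sites on one subunit = shared buried area / smaller
  interface area; ≥ 10% merges them into one alternative-capable site.
- Variants: interior means relative accessibility < 0.1 on the isolated
  subunit, using the Tien et al. (2013) theoretical Gly-X-Gly maxima;
  classification precedence is disordered → interior → interface →
  surface (a buried residue stays interior even if the site is
  interfacial, matching the accessibility-first convention). A variant
  hitting several models counts once, interface placements first, with
  subtype priority experimental > model-predicted > model-suggested.
- CAPRI-style classes close their upper bounds (≤ 1 / ≤ 5 / ≤ 10 Å) with
  a 1e-9 Å tolerance so boundary displacements classify as the boundary
  class.

## Interface typing

A detected interface is *experimental* when the subunit pair possesses a
structure element (whether or not that element performed the placement),
*model-predicted* when the pair appears only in the interaction table,
*model-suggested* otherwise. A recorded interaction whose subunits share
no detected interface is *indirect*; indirect rates are reported per
detection method. Redundant interfaces between mutually homologous pairs
(> 25% identity on both sides, either orientation) collapse to one
representative. Alternative-partner pairs are classified as homologous
(identity > 25%), same fold (TM > 0.5; for partners with no sequence
correspondence a positional register pairing is used, sufficient for the
gross fold classes of the synthetic chains), or different fold.

## Synthetic benchmarks

`supramol.fixtures` builds complexes from idealized chains: full
N/CA/C/O/CB backbones generated by internal-coordinate chain growth with
ideal bond geometry (φ/ψ = −57/−47 for helices, −120/120 for extended
chains; a three-helix bundle variant packs helix axes 8.2 Å apart to
create genuinely buried residues). Subunits are laid out on star, path or
ring topologies; the separation between contacting chains is calibrated
by bisection so each planted contact buries a requested area (default
400 Å², reproduced within 10% by an independent dense-sampling check).
Every ground-truth dimer is emitted as its own "crystal" entry in a
random rigid frame, so assembly must rediscover the complex through
superposition. Deliberate disagreements exercise each annotation path:

- two leaves on one hub site → clash → alternative interface;
- interaction-table edges without contacts (e.g. a complete-graph table
  over a ring/path complex) → indirect flags;
- a contact edge missing from the table → model-suggested interface;
- a contact edge with no crystal → model-predicted interface;
- mutated-copy library entries at planted identities → homologue
  retrieval and threshold behavior;
- a mis-folded template shared chain → gate rejection;
- variants planted in measured interface / surface / interior /
  disordered-tail positions.

Sequences are random 20-letter strings drawn with rejection so that
distinct proteins share no above-threshold local identity; planted
homologues substitute evenly spaced positions with conservative
(positive-BLOSUM) replacements so the full-length alignment survives
while identity drops to the target. Everything is a pure function of the
seed; regeneration is byte-identical.

What the toys do not emulate — side-chain chemistry, conformational
heterogeneity, domain fragments, noisy/partial templates, realistic
interface shapes and energetics. Passing tests therefore demonstrate the
correctness of the machinery (alignment, superposition, gates, areas,
statistics, determinism) under conditions where the right answer is
known, not predictive accuracy on real proteomes.

Benchmark sizes: ground-truth recovery uses 25 seeded complexes of 3–8
subunits over mixed topologies; the enrichment power check uses 2,000
synthetic variants (half benign, half disease, interface probability
tripled for disease) over 100 seeds; oracle agreement uses 1,000 random
point sets (superposition) and 50 fixture residues (SASA). These sizes
give stable pass/fail behavior at desk scale while each stage remains
exercised end-to-end.

## Numerical conventions and edge cases

- Kabsch uses SVD with a determinant correction, so a reflection-only
  optimum returns the best proper rotation; degenerate inputs (< 3
  points, length mismatch) raise.
- Multi-model structure files contribute model 1 only; alternate
  locations keep the highest-occupancy conformer; MSE reads as M, other
  non-standard residues as X with atoms retained; hydrogens, waters and
  ligands are excluded.
- Output chain IDs are remapped A, B, C, … in subunit insertion order
  (62 IDs; beyond that a named overflow error), making repeated runs
  diffable; JSON outputs sort keys.
- Model deduplication across starting points is by (protein multiset,
  element-joined pair set).
- Zero-margin cells in enrichment tables are skipped with a notice row
  rather than dividing by zero; χ² is per-cell (1 df) against the
  baseline-class distribution, hypergeometric tests are one-sided tails.
- Variant densities per interface area are reported without a
  significance claim; the appropriate comparison test for that quantity
  is not settled.

## Known limitations

- The structural aligner requires a sequence correspondence; remote
  same-fold/different-sequence relationships are out of reach (affects
  only the alternative-partner fold classification, where a positional
  fallback stands in).
- One template per interaction: runners-up are recorded in provenance
  but not assembled as alternates.
- Interface residue definition is area-loss-based; distance-based
  definitions would differ near the 0.1 Å² cutoff.
- The clash predicate is Cα-only; side-chain-level steric analysis is
  out of scope for poly-alanine-geometry templates.
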