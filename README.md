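# supramol

Template-based assembly and annotation of multi-subunit protein complex
models ("supramolecules") from a structure library and a protein–protein
interaction (PPI) network.

Experimental structure determination lags far behind interaction
detection: interactome databases record orders of magnitude more binary
interactions than there are co-crystallized complexes. `supramol` closes
part of that gap for structural biologists and interactome annotators by
(1) extracting *structure elements* — experimentally determined binary
complexes whose chains are homologous to a recorded interacting pair —
and (2) stitching those dimeric templates into multi-subunit models by
iterative superposition of shared subunits. The resulting models
distinguish direct from indirect interactions, simultaneous from
alternative (mutually exclusive) interfaces, and expose interfaces that
no experiment has yet observed, onto which amino-acid variants can be
mapped.

## Method

**Templates.** For each recorded interaction (A, B), library chains with
sequence identity > 25% (Smith–Waterman, BLOSUM62, gap 11/1; identity over
aligned columns, coverage not filtered) are retrieved for both partners.
If homologues A′ and B′ are co-determined in one entry, the pair with the
highest average identity ½(id_A + id_B) becomes the element templating
that edge. Edges with elements are clustered by single linkage; each
connected component is a *modelable sub-network*.

**Assembly.** From a starting protein, the seed element places two
subunits. Repeatedly, the placed subunit with the largest interaction
degree anchors new placements: for each unused element incident to the
anchor's protein, the element's shared chain A″ is superposed onto the
placed A′ (Kabsch least squares on the sequence-aligned Cα pairs with
outlier rejection), carrying the partner chain into the model. The
superposition is accepted when

    id > 30% and TM > 0.5,   or   25% ≤ id ≤ 30% and TM > 0.6,

where TM is the fragment-seeded optimum of
TM = (1/L)·Σᵢ 1/(1 + (dᵢ/d₀)²), d₀ = 1.24·(L−15)^⅓ − 1.8 (floor 0.5 Å),
normalized by the anchor length L. A placement whose chain overlaps an
existing subunit (≥ 10 Cα pairs under 3 Å) is discarded and recorded as an
*alternative interface*: the two partners compete for one site.

**Interfaces.** Buried surface area per subunit pair is computed by
Shrake–Rupley SASA (probe 1.4 Å, 960 points/atom); a contact is an
interface when the larger side buries > 250 Å². Interfaces on one subunit
sharing ≥ 10% of buried area are one alternative-capable site. Each
interface is typed by provenance — *experimental* (the pair has a
structure element), *model-predicted* (recorded interaction, no element),
*model-suggested* (neither) — and each recorded interaction without a
detected interface is flagged *indirect*.

**Evaluation and variants.** Models assembled from ≥ 2 template entries
are compared against reference complexes: whole-complex Cα RMSD, plus the
docking-style ligand RMSD per predicted subunit (fit on the common
subunits, measure on the predicted one) with CAPRI classes ≤ 1 / ≤ 5 /
≤ 10 Å = high / medium / acceptable. Variants are mapped to disordered /
interior (relative accessibility < 0.1 on the isolated subunit) /
interface / surface environments; class enrichment against a baseline
class uses per-cell χ² and one-sided hypergeometric tests.

Because the full pipeline needs only structures, sequences and an
interaction table, everything is testable against the bundled synthetic
generator (`supramol.fixtures`), which plants complexes with known
geometry, contact areas, clashes, homologue ladders and variant
environments.

## Worked example

```
$ supramol fixtures --spec spec.json --out data/     # spec: 4-protein star,
wrote 6 files to data/                               # two leaves on one site
$ supramol assemble --inputs data/ --out models/
2 models; sizes [3, 3]
category tally: {'complex': 3, 'independent': 0, 'one_sided': 0, 'unknown': 0}
$ head -3 models/alternative_interfaces.tsv
model_id  owner  partner_a  partner_b
SN001_m01 P001   P002       P003
SN001_m02 P001   P003       P002
```

All three star edges have templates (`complex` category), so one
sub-network results. Because leaves P002 and P003 were planted on the same
hub site, each growth keeps whichever leaf it placed first and records the
other as an alternative partner of the hub interface — two 3-subunit
models survive deduplication, each with one alternative-interface record
naming (P001; P002, P003). Each model is written as a PDB file with a JSON
provenance sidecar (template entry, anchor, placement transform per
subunit), alongside interface, direct/indirect and sub-network tables.

The same stages are available as library calls (`build_element_dataset`,
`cluster_subnetworks`, `build_all_models`, `detect_interfaces`,
`map_variants`, ...); see `docs/methods.md` for the model's assumptions
and parameter choices.

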