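"""End-to-end driver: inputs on disk -> models, interfaces, annotations.

Ties the stages together in the canonical order (sequences + structures +
interactions -> elements -> sub-networks -> models -> interfaces) with
deterministic output naming, so that two runs on identical inputs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .assembly import ComplexModel, build_all_models
from .config import DEFAULT, Config
from .elements import PPIElement, build_element_dataset, element_dataset_to_json
from .interfaces import Interface, detect_interfaces, flag_indirect, type_interfaces
from .network import SubNetwork, cluster_subnetworks, subnetwork_to_json
from .sequences import read_fasta, read_interactions
from .structures_io import read_structure, write_complex

__all__ = ["run_pipeline", "load_inputs"]


def load_inputs(input_dir) -> Tuple[dict, list, list]:
    """Read FASTA, interaction TSV and every structure file in a directory."""
    input_dir = Path(input_dir)
    proteins = read_fasta(input_dir / "proteins.fasta")
    interactions = read_interactions(input_dir / "interactions.tsv")
    library = []
    for p in sorted(input_dir.glob("*.pdb")) + sorted(input_dir.glob("*.cif")):
        library.extend(read_structure(p))
    return proteins, interactions, library


def run_pipeline(
    input_dir,
    out_dir,
    mode: str = "degree",
    seed: int = 0,
    cfg: Config = DEFAULT,
) -> Dict[str, object]:
    """Full run; returns models, interfaces and annotations in memory too."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, interactions, library = load_inputs(input_dir)
    elements, tally = build_element_dataset(interactions, proteins, library, cfg=cfg)
    (out / "elements.json").write_text(element_dataset_to_json(elements))
    nets = cluster_subnetworks(elements)
    (out / "subnetworks.json").write_text(subnetwork_to_json(nets))
    all_models: List[ComplexModel] = []
    interfaces_by_model: Dict[str, List[Interface]] = {}
    alt_lines = ["model_id\towner\tpartner_a\tpartner_b"]
    iface_lines = ["model_id\tsubunit_a\tsubunit_b\tarea_a\tarea_b\ttype"
                   "\tresidues_a\tresidues_b\talternative_partners"]
    for net in nets:
        models = build_all_models(net, elements, mode=mode, seed=seed, cfg=cfg)
        for mi, model in enumerate(models):
            name = f"{net.net_id}_m{mi + 1:02d}"
            model.model_id = name
            write_complex(model, out / f"{name}.pdb")
            ifaces = type_interfaces(model, interactions, elements, cfg=cfg)
            interfaces_by_model[name] = ifaces
            for f in ifaces:
                iface_lines.append(
                    f"{name}\t{f.subunit_a}\t{f.subunit_b}"
                    f"\t{f.area_a:.1f}\t{f.area_b:.1f}\t{f.type}"
                    f"\t{','.join(map(str, sorted(f.residues_a)))}"
                    f"\t{','.join(map(str, sorted(f.residues_b)))}"
                    f"\t{','.join(sorted(f.alternative_partners))}"
                )
            for owner, pa, pb in model.alternative_records:
                alt_lines.append(f"{name}\t{owner}\t{pa}\t{pb}")
        all_models.extend(models)
    (out / "alternative_interfaces.tsv").write_text("\n".join(alt_lines) + "\n")
    (out / "interfaces.tsv").write_text("\n".join(iface_lines) + "\n")
    indirect_lines = ["model_id\tacc_a\tacc_b\tdirect\tdetection_method"]
    for model in all_models:
        for pair, direct, method in flag_indirect(
                model, interactions, interfaces_by_model[model.model_id], cfg):
            indirect_lines.append(
                f"{model.model_id}\t{pair[0]}\t{pair[1]}\t{int(direct)}\t{method}")
    (out / "direct_indirect.tsv").write_text("\n".join(indirect_lines) + "\n")
    summary = {
        "category_tally": tally,
        "n_elements": len(elements),
        "n_subnetworks": len(nets),
        "n_models": len(all_models),
        "model_sizes": [m.size for m in all_models],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return {
        "proteins": proteins,
        "interactions": interactions,
        "elements": elements,
        "tally": tally,
        "subnetworks": nets,
        "models": all_models,
        "interfaces": interfaces_by_model,
    }
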