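"""End-to-end orchestration: networks + omics in, scored pathways out.

Three stages mirror the analysis workflow: (1) prepare — read and
filter prior-knowledge networks against the measured genes; (2) infer —
fit Boolean rules per pathway (GA + local search); (3) score —
perturbation importance, per-contrast node modulation tables, and the
permutation-based pathway p-value table with BH adjustment.

A single global seed is fanned out deterministically to every
stochastic stage (GA, ERS sampling, permutations) by hashing the stage
name and pathway with CRC32, so each stage is independently
reproducible and a rerun with the same config is numerically identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import CombinedDataset, ContrastMatrix, load_design, load_layer
from .inference import GAConfig
from .model import MultiomicsBooleanNetwork
from .network import (
    SignedNetwork,
    filter_pathways,
    parse_kgml,
    read_graphml,
    write_annotated_graphml,
)
from .scoring import modulation_table, score_pathways

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int | None, stage: str) -> int | None:
    """Deterministic per-stage seed: CRC32 of the stage name mixed with
    the global seed, kept below 2^31."""
    if global_seed is None:
        return None
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with reproducibility baked in."""

    networks_dir: str | Path
    layer_paths: dict[str, str | Path]  # layer name -> expression matrix
    design_path: str | Path
    contrasts_path: str | Path
    out_dir: str | Path
    transforms: dict[str, str] = field(default_factory=dict)  # layer -> transform
    min_overlap: int = 5
    n_permutations: int = 1000
    n_rule_samples: int = 10
    ga: GAConfig = field(default_factory=GAConfig)
    seed: int | None = None

    def validate(self) -> None:
        for label, path in [
            ("networks_dir", self.networks_dir),
            ("design", self.design_path),
            ("contrasts", self.contrasts_path),
            *[(f"layer {n}", p) for n, p in self.layer_paths.items()],
        ]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")


def load_networks(networks_dir: str | Path) -> list[SignedNetwork]:
    """Read every graphml and KGML file in a directory."""
    networks = []
    directory = Path(networks_dir)
    for path in sorted(directory.glob("*.graphml")):
        networks.append(read_graphml(path))
    for path in sorted(list(directory.glob("*.kgml")) + list(directory.glob("*.xml"))):
        networks.append(parse_kgml(path))
    return networks


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run prepare -> infer -> score; write all artifacts; return the
    pathway p-value table.

    Per pathway: an ERS rule file, a graphml annotated with importance
    and per-contrast fold-changes, and one node modulation table per
    contrast.  Globally: ``pathway_pvalues.csv`` (with BH-adjusted
    p-values per contrast) and ``manifest.json`` recording inputs,
    settings, seed and package version.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    layers = [
        load_layer(path, name, transform=config.transforms.get(name, "none"))
        for name, path in config.layer_paths.items()
    ]
    design = load_design(config.design_path)
    contrasts = ContrastMatrix.from_file(config.contrasts_path)
    dataset = CombinedDataset(layers=layers, design=design)
    for _, cond_a, cond_b in contrasts:
        for cond in (cond_a, cond_b):
            if cond not in dataset.conditions:
                raise ValueError(f"contrast condition {cond!r} missing from design")

    networks = load_networks(config.networks_dir)
    kept = filter_pathways(networks, dataset.gene_universe, config.min_overlap)
    if not kept:
        raise ValueError(
            f"no pathway passed the >= {config.min_overlap}-gene overlap filter "
            f"({len(networks)} candidate networks)"
        )
    logger.info("%d/%d pathways pass the overlap filter", len(kept), len(networks))

    scored = []
    for pathway in kept:
        ga = GAConfig(
            population_size=config.ga.population_size,
            generations=config.ga.generations,
            crossover_prob=config.ga.crossover_prob,
            mutation_prob=config.ga.mutation_prob,
            tournament_size=config.ga.tournament_size,
            n_elite=config.ga.n_elite,
            seed=derive_seed(config.seed, f"ga:{pathway.name}"),
        )
        model = MultiomicsBooleanNetwork(pathway, dataset)
        results = model.fit(ga)
        (out / f"{pathway.name}_rules.txt").write_text(results.ers_text() + "\n")

        importance = results.importance_scores(
            n_rule_samples=config.n_rule_samples,
            seed=derive_seed(config.seed, f"importance:{pathway.name}"),
        )
        annotations = {
            node: {"importance": importance[node]} for node in results.network.nodes
        }
        for contrast_name, cond_a, cond_b in contrasts:
            table = modulation_table(
                results.network, (cond_a, cond_b), importance, dataset
            )
            table.to_csv(
                out / f"{pathway.name}_{contrast_name}_modulation.csv", index=False
            )
            for _, row in table.iterrows():
                for layer in dataset.layers:
                    annotations[row["gene"]][f"fc_{layer.name}_{contrast_name}"] = row[
                        f"fc_{layer.name}"
                    ]
        write_annotated_graphml(
            results.network, annotations, out / f"{pathway.name}_annotated.graphml"
        )
        scored.append((results.network, importance))

    pvalues = score_pathways(
        scored,
        dataset,
        contrasts,
        n_permutations=config.n_permutations,
        seed=derive_seed(config.seed, "permutation"),
    )
    pvalues.to_csv(out / "pathway_pvalues.csv", index=False, float_format="%.10g")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "min_overlap": config.min_overlap,
        "n_permutations": config.n_permutations,
        "n_rule_samples": config.n_rule_samples,
        "ga": {
            "population_size": config.ga.population_size,
            "generations": config.ga.generations,
            "crossover_prob": config.ga.crossover_prob,
            "mutation_prob": config.ga.mutation_prob,
        },
        "inputs": {
            "networks_dir": str(config.networks_dir),
            "layers": {n: str(p) for n, p in config.layer_paths.items()},
            "design": str(config.design_path),
            "contrasts": str(config.contrasts_path),
        },
        "pathways": [
            {"name": net.name, "nodes": len(net.nodes), "overlap": net.overlap}
            for net, _ in scored
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return pvalues
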