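"""Ground-truthed synthetic networks and multiomics datasets.

The generator emulates the setting the pipeline is built for: a signed
signaling network whose dynamics are governed by known OR-of-AND rules,
observed through several omics layers under matched experimental
conditions.  Conditions differ by the states clamped onto the network's
input nodes (in-degree 0), the way signaling stimuli enter a pathway;
each condition's attractor becomes that condition's mean log2-abundance
profile (bit 0 -> mean 4, bit 1 -> mean 8, placing the binarization
midpoint between the classes), observed with Gaussian noise and
per-layer gene dropout that emulates the partial overlap between real
omics layers.

What this does NOT emulate: mass-spectrometry intensity error models,
peptide-level structure, batch effects, or library-size variation.  A
green test on these fixtures establishes algorithmic correctness, not
robustness to real measurement artifacts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boolrules import Rule, enumerate_rule_space
from .data import CombinedDataset, ContrastMatrix, OmicsLayer
from .network import SignedNetwork, write_graphml
from .simulate import NetworkModel, attractor_average

#: log2-abundance anchors for Boolean states 0 and 1.
LOW_MEAN = 4.0
HIGH_MEAN = 8.0
#: Gaussian noise sd on the log2 scale; typical biological + technical
#: spread for replicate omics measurements.
DEFAULT_NOISE_SD = 0.5
#: replicates per condition, the usual design size for LC-MS studies.
DEFAULT_SAMPLES_PER_CONDITION = 3


@dataclass
class GroundTruth:
    """A synthetic world: network, true rules, condition attractors."""

    network: SignedNetwork
    rules: dict[str, Rule]
    condition_inputs: dict[str, dict[str, int]]  # condition -> input clamping
    attractors: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int | None = None

    @property
    def model(self) -> NetworkModel:
        return NetworkModel(network=self.network, rules=self.rules)

    @property
    def input_nodes(self) -> list[str]:
        return [n for n in sorted(self.network.nodes) if self.network.in_degree(n) == 0]


def generate_network(
    n_nodes: int,
    edge_density: float = 0.25,
    inhibition_fraction: float = 0.3,
    seed: int | None = None,
    max_retries: int = 200,
) -> SignedNetwork:
    """Random connected signed digraph with max in-degree 3 and >= 1 input.

    In-degrees are drawn per node (0..3, biased by ``edge_density``) and
    regulators sampled from the other nodes, so the in-degree bound
    holds by construction; draws are repeated until the graph is weakly
    connected with at least one in-degree-0 input node.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = random.Random(seed)
    names = [f"G{i:02d}" for i in range(n_nodes)]
    for _ in range(max_retries):
        edges: dict[tuple[str, str], int] = {}
        # expected in-degree = 3 * edge_density
        for target in names:
            k = sum(rng.random() < edge_density for _ in range(3))
            if k == 0:
                continue
            regulators = rng.sample([n for n in names if n != target], k)
            for reg in regulators:
                sign = -1 if rng.random() < inhibition_fraction else 1
                edges[(reg, target)] = sign
        net = SignedNetwork(name=f"synthetic{seed if seed is not None else ''}",
                            nodes=set(names), edges=edges)
        inputs = [n for n in names if net.in_degree(n) == 0]
        if not edges or not inputs:
            continue
        if _weakly_connected(net):
            return net
    raise RuntimeError(
        f"could not generate a connected max-in-degree-3 network with "
        f"density {edge_density} in {max_retries} tries"
    )


def _weakly_connected(net: SignedNetwork) -> bool:
    if not net.nodes:
        return False
    adjacency: dict[str, set[str]] = {n: set() for n in net.nodes}
    for u, v in net.edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    start = next(iter(net.nodes))
    seen = {start}
    stack = [start]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen == net.nodes


def generate_ground_truth(
    network: SignedNetwork,
    n_conditions: int = 2,
    seed: int | None = None,
) -> GroundTruth:
    """Draw a true rule per node and condition-specific input clampings.

    Condition ``cond0`` clamps all inputs to 0, ``cond1`` all to 1;
    further conditions get random input patterns.  Attractor-average
    states are computed per condition from an all-zero start for
    non-input nodes.
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    rng = random.Random(seed)
    rules: dict[str, Rule] = {}
    for node in sorted(network.nodes):
        regulators = network.regulators_of(node)
        if regulators:
            space = enumerate_rule_space(node, regulators)
            rules[node] = space[rng.randrange(len(space))]
    truth = GroundTruth(network=network, rules=rules, condition_inputs={}, seed=seed)
    inputs = truth.input_nodes
    patterns = [dict.fromkeys(inputs, 0), dict.fromkeys(inputs, 1)]
    while len(patterns) < n_conditions:
        patterns.append({n: rng.randint(0, 1) for n in inputs})
    for i, pattern in enumerate(patterns[:n_conditions]):
        condition = f"cond{i}"
        truth.condition_inputs[condition] = pattern
        init = {n: pattern.get(n, 0) for n in network.nodes}
        truth.attractors[condition] = attractor_average(truth.model, init)
    return truth


def generate_recovery_world(
    n_nodes: int,
    edge_density: float = 0.25,
    n_conditions: int = 2,
    seed: int | None = None,
    max_retries: int = 200,
) -> tuple[SignedNetwork, GroundTruth]:
    """A network plus ground truth whose noiseless observations are
    consistent with the truth.

    Rule recovery is only well-posed when the binarized training states
    actually encode the true attractors.  Two generator outcomes break
    that: limit-cycle attractors (fractional averages collapse to an
    arbitrary bit) and genes constant at the high state across every
    condition (min/max-midpoint thresholding sends constant genes to 0).
    Network and rules are resampled together until every condition
    attractor is a fixed point and no gene sits at 1 in all conditions,
    so a noiseless, dropout-free dataset binarizes back to the truth
    exactly.  (Some topologies — e.g. forced negative feedback loops
    between in-degree-1 nodes — admit no such rules, hence the joint
    resampling.)
    """
    rng = random.Random(seed)
    for _ in range(max_retries):
        network = generate_network(
            n_nodes, edge_density=edge_density, seed=rng.randrange(2**31)
        )
        truth = generate_ground_truth(
            network, n_conditions=n_conditions, seed=rng.randrange(2**31)
        )
        values = {
            gene: {truth.attractors[c][gene] for c in truth.attractors}
            for gene in network.nodes
        }
        if any(v not in (0.0, 1.0) for vals in values.values() for v in vals):
            continue  # limit cycle somewhere
        if any(vals == {1.0} for vals in values.values()):
            continue  # constant-high gene would binarize to 0
        return network, truth
    raise RuntimeError(f"no consistent ground truth found in {max_retries} tries")


def generate_null_truth(network: SignedNetwork, seed: int | None = None) -> GroundTruth:
    """A ground truth whose two conditions are identical in distribution.

    Both conditions clamp the input nodes to the same randomly drawn
    pattern, so every true fold-change is 0 and observed fold-changes
    are pure noise.  A random pattern (rather than all-off) keeps the
    null condition a *typical* condition: with all inputs forced off,
    the network's most influential nodes would all sit in the
    low-abundance state, tying importance to expression level in a way
    no real null comparison would.
    """
    rng = random.Random(seed)
    truth = generate_ground_truth(network, n_conditions=2, seed=rng.randrange(2**31))
    pattern = {n: rng.randint(0, 1) for n in truth.input_nodes}
    init = {n: pattern.get(n, 0) for n in network.nodes}
    attractor = attractor_average(truth.model, init)
    for condition in ("cond0", "cond1"):
        truth.condition_inputs[condition] = dict(pattern)
        truth.attractors[condition] = dict(attractor)
    return truth


def generate_multiomics(
    truth: GroundTruth,
    n_layers: int = 3,
    samples_per_condition: int = DEFAULT_SAMPLES_PER_CONDITION,
    noise_sd: float = DEFAULT_NOISE_SD,
    dropout_per_layer: float | list[float] = 0.0,
    seed: int | None = None,
) -> tuple[CombinedDataset, ContrastMatrix]:
    """Observe the truth's condition attractors through noisy omics layers.

    Per condition, each node's attractor-average value a in [0,1] maps
    to a mean log2 abundance 4 + 4a; samples add N(0, noise_sd) noise,
    floored at 0 to respect the nonnegativity of log-abundance tables.
    Each layer independently drops each gene with its dropout
    probability.  Returns the combined dataset plus one contrast per
    condition pair.
    """
    rng = np.random.default_rng(seed)
    conditions = list(truth.condition_inputs)
    genes = sorted(truth.network.nodes)
    if isinstance(dropout_per_layer, (int, float)):
        dropout = [float(dropout_per_layer)] * n_layers
    else:
        dropout = list(dropout_per_layer)
        if len(dropout) != n_layers:
            raise ValueError("dropout_per_layer length must equal n_layers")

    layers = []
    design: dict[str, str] = {}
    any_gene = False
    for li in range(n_layers):
        keep = [g for g in genes if rng.random() >= dropout[li]]
        columns = {}
        for condition in conditions:
            attractor = truth.attractors[condition]
            means = np.array(
                [LOW_MEAN + (HIGH_MEAN - LOW_MEAN) * attractor[g] for g in keep]
            )
            for r in range(samples_per_condition):
                sample = f"L{li}_{condition}_r{r}"
                noise = rng.normal(0.0, noise_sd, size=len(keep)) if noise_sd > 0 else 0.0
                columns[sample] = np.maximum(means + noise, 0.0)
                design[sample] = condition
        if keep:
            any_gene = True
            layers.append(
                OmicsLayer(
                    name=f"layer{li}",
                    abundance=pd.DataFrame(columns, index=keep),
                )
            )
    if not any_gene:
        raise ValueError("dropout removed every gene from every layer")

    contrast_list = [
        (f"{a}_vs_{b}", a, b)
        for i, a in enumerate(conditions)
        for b in conditions[i + 1:]
    ]
    dataset = CombinedDataset(layers=layers, design=design)
    return dataset, ContrastMatrix(contrast_list)


def generate_pathway_collection(
    n_pathways: int,
    n_nodes: int = 20,
    edge_density: float = 0.5,
    n_layers: int = 3,
    samples_per_condition: int = DEFAULT_SAMPLES_PER_CONDITION,
    noise_sd: float = DEFAULT_NOISE_SD,
    null: bool = False,
    seed: int | None = None,
) -> tuple[list[tuple[SignedNetwork, GroundTruth]], CombinedDataset, ContrastMatrix]:
    """Many pathways observed through one shared multiomics dataset.

    This mirrors how the tool is actually run: every pathway's genes are
    profiled in the same samples, and resampling pools for the
    permutation null span the whole dataset.  Pathway gene sets are
    disjoint (prefixed names).  With ``null=True`` each pathway's two
    conditions share one random input pattern, so no gene carries real
    signal — the fixture for p-value calibration checks.
    """
    rng = random.Random(seed)
    pathways: list[tuple[SignedNetwork, GroundTruth]] = []
    blocks: list[list[pd.DataFrame]] = [[] for _ in range(n_layers)]
    design: dict[str, str] = {}
    contrasts: ContrastMatrix | None = None
    for p in range(n_pathways):
        base = generate_network(n_nodes, edge_density=edge_density,
                                seed=rng.randrange(2**31))
        net = SignedNetwork(
            name=f"pw{p}",
            nodes={f"P{p}_{n}" for n in base.nodes},
            edges={(f"P{p}_{u}", f"P{p}_{v}"): s for (u, v), s in base.edges.items()},
        )
        if null:
            truth = generate_null_truth(net, seed=rng.randrange(2**31))
        else:
            truth = generate_ground_truth(net, seed=rng.randrange(2**31))
        ds, contrasts = generate_multiomics(
            truth, n_layers=n_layers, samples_per_condition=samples_per_condition,
            noise_sd=noise_sd, seed=rng.randrange(2**31),
        )
        for li, layer in enumerate(ds.layers):
            blocks[li].append(layer.abundance)
        design.update(ds.design)
        pathways.append((net, truth))
    layers = [
        OmicsLayer(name=f"layer{li}", abundance=pd.concat(block))
        for li, block in enumerate(blocks)
    ]
    assert contrasts is not None
    return pathways, CombinedDataset(layers=layers, design=design), contrasts


def write_fixture_bundle(
    out_dir: str | Path,
    n_pathways: int = 2,
    n_nodes: int = 10,
    n_layers: int = 3,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    dropout_per_layer: float | list[float] = 0.0,
) -> Path:
    """Write a complete on-disk input bundle for the pipeline.

    Produces ``networks/*.graphml``, per-layer expression TSVs, a design
    TSV, a contrast TSV and a ground-truth sidecar.  Pathways have
    disjoint gene sets (prefixed) but share one sample set per layer, as
    in a real experiment where all genes are profiled in the same
    samples.
    """
    out = Path(out_dir)
    (out / "networks").mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    layer_blocks: list[list[pd.DataFrame]] = [[] for _ in range(n_layers)]
    design: dict[str, str] = {}
    contrasts: ContrastMatrix | None = None
    sidecar_lines = []
    for p in range(n_pathways):
        net_seed = rng.randrange(2**31)
        base = generate_network(n_nodes, seed=net_seed)
        # prefix gene names so pathway gene sets are disjoint
        renamed = SignedNetwork(
            name=f"pathway{p}",
            nodes={f"P{p}{n}" for n in base.nodes},
            edges={(f"P{p}{u}", f"P{p}{v}"): s for (u, v), s in base.edges.items()},
        )
        truth = generate_ground_truth(renamed, seed=rng.randrange(2**31))
        dataset, contrasts = generate_multiomics(
            truth, n_layers=n_layers, noise_sd=noise_sd,
            dropout_per_layer=dropout_per_layer, seed=rng.randrange(2**31),
        )
        write_graphml(renamed, out / "networks" / f"pathway{p}.graphml")
        # sample names are pathway-independent, so gene rows stack onto
        # the same shared columns
        for li, layer in enumerate(dataset.layers):
            layer_blocks[li].append(layer.abundance)
        design.update(dataset.design)
        sidecar_lines.append(f"# {renamed.name} seed={net_seed}")
        for node, rule in truth.rules.items():
            sidecar_lines.append(rule.to_text())

    for li, blocks in enumerate(layer_blocks):
        frame = pd.concat(blocks, axis=0)
        frame.index.name = "gene"
        frame.to_csv(out / f"layer{li}.tsv", sep="\t")
    pd.DataFrame(
        {"sample": list(design), "condition": list(design.values())}
    ).to_csv(out / "design.tsv", sep="\t", index=False)
    assert contrasts is not None
    pd.DataFrame(
        contrasts.contrasts, columns=["name", "condition_A", "condition_B"]
    ).to_csv(out / "contrasts.tsv", sep="\t", index=False)
    (out / "ground_truth.txt").write_text("\n".join(sidecar_lines) + "\n")
    return out
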