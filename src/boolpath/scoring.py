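"""Perturbation-based node importance and pathway modulation scoring.

A node's importance I_g is measured by in-silico perturbation: every
training state is simulated twice, once with g clamped to 0 throughout
(knockout) and once clamped to 1 (knock-in), and the absolute
differences between the two attractors are summed over samples and over
all other nodes.  Importance depends only on topology and rules, never
on a contrast.

For a contrast C, a gene's node modulation score weights its importance
by the evidence for the gene across layers and by its per-layer
fold-change and variability:

    M_g = I_g * E_g * sum_d |FC_{C,d,g}| * CV_{d,g}

where E_g counts the layers in which g was measured.  The pathway
modulation score M_p sums M_g over pathway nodes, and its significance
comes from a permutation null: each of (by default) 1000 replicates
rebuilds M_p with per-gene-per-layer (FC, CV) pairs resampled from the
dataset-wide pool for the same contrast and layer; the observed M_p is
converted to a z-score against this null and p = 1 - Phi(z).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .data import BinarizedStates, CombinedDataset, fold_change, variability
from .inference import EquivalentRuleSet, TrainingStates
from .network import SignedNetwork
from .simulate import NetworkModel, attractor_average

DEFAULT_RULE_SAMPLES = 10
DEFAULT_PERMUTATIONS = 1000


@dataclass
class ImportanceScores:
    """Per-node knock-in vs knockout influence scores."""

    scores: pd.Series  # node -> I_g >= 0
    n_rule_samples: int
    seed: int | None

    def __getitem__(self, node: str) -> float:
        return float(self.scores.get(node, 0.0))


@dataclass
class PathwayResult:
    """Pathway-level modulation score with its permutation null."""

    pathway: str
    contrast: str
    modulation: float  # M_p
    null_mean: float
    null_sd: float
    z_score: float
    p_value: float
    adjusted_p: float | None = None


def importance_scores(
    network: SignedNetwork,
    ers: dict[str, EquivalentRuleSet],
    states: TrainingStates | BinarizedStates,
    n_rule_samples: int = DEFAULT_RULE_SAMPLES,
    seed: int | None = None,
) -> ImportanceScores:
    """Mean perturbation influence over sampled rule assignments.

    For each of ``n_rule_samples`` concrete models (one rule per node
    drawn uniformly from its ERS) and each node g:

        I_g = (1/n_rule_samples) * sum_models sum_{states i, nodes j != g}
              |O_{i,j} - Z_{i,j}|

    with O and Z the attractor-average states under knockout (g=0) and
    knock-in (g=1).  The perturbed node is excluded from the sum so the
    score quantifies influence over the rest of the network; a sink node
    therefore scores exactly 0.
    """
    if n_rule_samples < 1:
        raise ValueError("n_rule_samples must be >= 1")
    if isinstance(states, BinarizedStates):
        states = TrainingStates.from_binarized(network, states)
    rng = random.Random(seed)
    nodes = sorted(network.nodes)
    totals = {n: 0.0 for n in nodes}
    for _ in range(n_rule_samples):
        rules = {
            node: e.rules[rng.randrange(len(e.rules))] for node, e in ers.items()
        }
        model = NetworkModel(network=network, rules=rules)
        for g in nodes:
            for init, _ in states.states:
                knockout = attractor_average(model, init, clamp={g: 0})
                knockin = attractor_average(model, init, clamp={g: 1})
                totals[g] += sum(
                    abs(knockout[j] - knockin[j]) for j in nodes if j != g
                )
    scores = pd.Series(
        {n: totals[n] / n_rule_samples for n in nodes}, name="importance"
    )
    return ImportanceScores(scores=scores, n_rule_samples=n_rule_samples, seed=seed)


def evidence_score(gene: str, dataset: CombinedDataset) -> int:
    """Number of omics layers in which the gene was measured.

    A layer counts if the gene's row is present with nonzero abundance
    in at least one sample.  Ranges from 0 (pathway node never
    measured) to D, the number of layers.
    """
    gene = str(gene).strip().upper()
    count = 0
    for layer in dataset.layers:
        if gene in layer.abundance.index and (layer.abundance.loc[gene] != 0).any():
            count += 1
    return count


def node_modulation(
    gene: str,
    contrast: tuple[str, str],
    importance: ImportanceScores,
    dataset: CombinedDataset,
) -> float:
    """M_g = I_g * E_g * sum_d |FC_{C,d,g}| * CV_{d,g}.

    Absolute fold-change enters so up- and down-regulation both count as
    modulation; layers where the gene is unmeasured contribute 0.
    """
    gene = str(gene).strip().upper()
    i_g = importance[gene]
    e_g = evidence_score(gene, dataset)
    if i_g == 0.0 or e_g == 0:
        return 0.0
    layer_sum = 0.0
    for layer in dataset.layers:
        fc = fold_change(dataset, contrast, layer.name)
        cv = variability(dataset, contrast, layer.name)
        layer_sum += abs(float(fc.get(gene, 0.0))) * float(cv.get(gene, 0.0))
    return i_g * e_g * layer_sum


def modulation_table(
    pathway: SignedNetwork,
    contrast: tuple[str, str],
    importance: ImportanceScores,
    dataset: CombinedDataset,
) -> pd.DataFrame:
    """Per-gene modulation scores and their components for one contrast."""
    fcs = {l.name: fold_change(dataset, contrast, l.name) for l in dataset.layers}
    cvs = {l.name: variability(dataset, contrast, l.name) for l in dataset.layers}
    rows = []
    for gene in sorted(pathway.nodes):
        i_g = importance[gene]
        e_g = evidence_score(gene, dataset)
        layer_sum = sum(
            abs(float(fcs[l].get(gene, 0.0))) * float(cvs[l].get(gene, 0.0))
            for l in fcs
        )
        row = {
            "gene": gene,
            "importance": i_g,
            "evidence": e_g,
            "modulation": i_g * e_g * layer_sum,
        }
        for l in fcs:
            row[f"fc_{l}"] = float(fcs[l].get(gene, 0.0))
            row[f"cv_{l}"] = float(cvs[l].get(gene, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def pathway_modulation(
    pathway: SignedNetwork,
    contrast: tuple[str, str],
    importance: ImportanceScores,
    dataset: CombinedDataset,
) -> float:
    """M_p: sum of node modulation scores over the pathway's nodes."""
    return float(
        sum(node_modulation(g, contrast, importance, dataset) for g in pathway.nodes)
    )


def _fc_cv_pools(
    dataset: CombinedDataset, contrast: tuple[str, str]
) -> dict[str, np.ndarray]:
    """Per-layer pools of gene-wise (|FC|, CV) pairs over the whole dataset.

    Pairs are kept joint to preserve the empirical dependence between a
    gene's fold-change and its variability.
    """
    pools = {}
    for layer in dataset.layers:
        fc = fold_change(dataset, contrast, layer.name)
        cv = variability(dataset, contrast, layer.name)
        measured = sorted(layer.genes)
        if not measured:
            raise ValueError(f"layer {layer.name}: empty sampling pool")
        pools[layer.name] = np.column_stack(
            [np.abs(fc.loc[measured].to_numpy()), cv.loc[measured].to_numpy()]
        )
    return pools


def permutation_pvalue(
    pathway: SignedNetwork,
    contrast_name: str,
    contrast: tuple[str, str],
    importance: ImportanceScores,
    dataset: CombinedDataset,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> PathwayResult:
    """Permutation significance of a pathway's modulation score.

    Each replicate keeps the pathway's true importance and evidence
    scores but redraws, for every gene and layer, a (|FC|, CV) pair
    uniformly with replacement from the dataset-wide pool of measured
    genes for the same contrast and layer.  The replicate scores form
    the null; z = (M_p - mean) / sd and p = 1 - Phi(z).  A degenerate
    null (sd = 0) gives p = 0.5 when M_p equals the null value, else 0
    or 1 by the sign of the difference.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    observed = pathway_modulation(pathway, contrast, importance, dataset)
    pools = _fc_cv_pools(dataset, contrast)
    rng = np.random.default_rng(seed)

    genes = sorted(pathway.nodes)
    weights = np.array(
        [importance[g] * evidence_score(g, dataset) for g in genes]
    )  # I_g * E_g, held at their true values
    active = weights > 0
    null = np.zeros(n_permutations)
    if active.any():
        w = weights[active]
        for layer in dataset.layers:
            pool = pools[layer.name]
            idx = rng.integers(0, len(pool), size=(n_permutations, int(active.sum())))
            draws = pool[idx]  # (n_perm, genes, 2): |FC|, CV pairs
            null += (draws[:, :, 0] * draws[:, :, 1]) @ w

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    # a point-mass null leaves only float jitter in the sd; treat it as 0
    # so z is not dominated by rounding noise
    tiny = 1e-12 * max(1.0, abs(null_mean))
    if null_sd <= tiny:
        null_sd = 0.0
        if abs(observed - null_mean) <= tiny:
            z, p = 0.0, 0.5
        else:
            z = np.inf if observed > null_mean else -np.inf
            p = 0.0 if observed > null_mean else 1.0
    else:
        z = (observed - null_mean) / null_sd
        p = float(norm.sf(z))
    return PathwayResult(
        pathway=pathway.name,
        contrast=contrast_name,
        modulation=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=float(z),
        p_value=p,
    )


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def score_pathways(
    results: list[tuple[SignedNetwork, ImportanceScores]],
    dataset: CombinedDataset,
    contrasts,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pathway p-value table over all contrasts, BH-adjusted per contrast."""
    rows = []
    for contrast_name, cond_a, cond_b in contrasts:
        for k, (pathway, importance) in enumerate(results):
            pathway_seed = None if seed is None else (seed + 7919 * k) % (2**31)
            res = permutation_pvalue(
                pathway, contrast_name, (cond_a, cond_b), importance, dataset,
                n_permutations=n_permutations, seed=pathway_seed,
            )
            rows.append(res)
    table = pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "contrast": [r.contrast for r in rows],
            "modulation": [r.modulation for r in rows],
            "null_mean": [r.null_mean for r in rows],
            "null_sd": [r.null_sd for r in rows],
            "z_score": [r.z_score for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    table["adjusted_p"] = np.nan
    for contrast_name in table["contrast"].unique():
        mask = table["contrast"] == contrast_name
        table.loc[mask, "adjusted_p"] = bh_adjust(table.loc[mask, "p_value"].to_numpy())
    return table
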