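"""Model/Results interface for fitting a Boolean pathway model to data.

`MultiomicsBooleanNetwork` pairs a prior-knowledge network with a
multiomics dataset; `fit()` runs the genetic algorithm plus local
search and returns a `BooleanNetworkResults` carrying the fitted rule
assignment, per-node equivalent rule sets, training error, and
perturbation-based importance scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boolrules import MAX_REGULATORS
from .data import BinarizedStates, CombinedDataset, binarize
from .inference import (
    EquivalentRuleSet,
    FitnessReport,
    GAConfig,
    TrainingStates,
    ers_size_summary,
    ga_search,
    local_search,
)
from .network import SignedNetwork
from .simulate import NetworkModel
from .scoring import ImportanceScores, importance_scores


def prepare_network(
    network: SignedNetwork,
    binarized: BinarizedStates,
    max_indegree: int = MAX_REGULATORS,
) -> SignedNetwork:
    """Truncate in-degrees above ``max_indegree``.

    For an over-regulated node, the ``max_indegree`` regulators whose
    binarized states correlate most strongly (absolute Pearson, over all
    layer/sample states where both genes are measured) with the target's
    binarized state are kept; ties break alphabetically.  Regulators or
    targets without overlapping measurements score 0.
    """
    # per-gene bit vectors across the concatenated (layer, sample) states
    profiles: dict[str, list[float]] = {}
    layer_names = list(binarized.bits)
    for gene in network.nodes:
        vec: list[float] = []
        for layer in layer_names:
            frame = binarized.bits[layer]
            if gene in frame.index:
                vec.extend(float(b) for b in frame.loc[gene])
            else:
                vec.extend([np.nan] * frame.shape[1])
        profiles[gene] = vec

    def abs_corr(a: str, b: str) -> float:
        x = np.asarray(profiles[a])
        y = np.asarray(profiles[b])
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 2:
            return 0.0
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            return 0.0
        return float(abs(np.corrcoef(xs, ys)[0, 1]))

    edges = dict(network.edges)
    for node in sorted(network.nodes):
        regulators = [u for (u, v) in edges if v == node]
        if len(regulators) <= max_indegree:
            continue
        ranked = sorted(regulators, key=lambda u: (-abs_corr(u, node), u))
        for dropped in ranked[max_indegree:]:
            del edges[(dropped, node)]
    return SignedNetwork(name=network.name, nodes=set(network.nodes), edges=edges,
                         overlap=network.overlap)


class MultiomicsBooleanNetwork:
    """A Boolean network model of a signaling pathway, trained on
    binarized multiomics states.

    Parameters
    ----------
    network
        The prior-knowledge network giving the topology.  In-degrees
    are truncated to ``max_indegree`` during construction.
    dataset
        Combined multiomics layers with a shared design.  Each
        (layer, sample) binarized state is one training constraint;
        using several layers jointly constrains the rules more than any
        single layer alone.
    """

    def __init__(
        self,
        network: SignedNetwork,
        dataset: CombinedDataset,
        max_indegree: int = MAX_REGULATORS,
    ):
        self.dataset = dataset
        self.binarized = binarize(dataset)
        self.network = prepare_network(network, self.binarized, max_indegree)
        self.training = TrainingStates.from_binarized(self.network, self.binarized)

    @classmethod
    def from_layers(
        cls,
        network: SignedNetwork,
        layers,
        design: dict[str, str],
        **kwargs,
    ) -> "MultiomicsBooleanNetwork":
        return cls(network, CombinedDataset(layers=list(layers), design=design), **kwargs)

    def fit(self, config: GAConfig | None = None) -> "BooleanNetworkResults":
        """Run the GA then the node-local exhaustive search.

        Returns a results object with the refined rule assignment, the
        per-node equivalent rule sets and the fitness report.
        """
        config = config or GAConfig()
        incumbent, _, ga_log = ga_search(self.network, self.training, config)
        ers, refined = local_search(self.network, self.training, incumbent)
        from .inference import fitness as _fitness

        report = _fitness(refined, self.training)
        return BooleanNetworkResults(
            model=self,
            fitted=refined,
            ers=ers,
            fitness_report=report,
            ga_log=ga_log,
            config=config,
        )


@dataclass
class BooleanNetworkResults:
    """Results of fitting a Boolean pathway model.

    Attributes
    ----------
    fitted
        The refined executable model (one minimal-error rule per node).
    ers
        Per-node equivalent rule sets: all rules tying at the node's
        minimal training error.
    fitness_report
        Per-node mean training error and total.
    ga_log
        (generation, best_fitness) trace of the genetic algorithm.
    """

    model: MultiomicsBooleanNetwork
    fitted: NetworkModel
    ers: dict[str, EquivalentRuleSet]
    fitness_report: FitnessReport
    ga_log: pd.DataFrame
    config: GAConfig
    _importance: dict[tuple, ImportanceScores] = field(default_factory=dict, repr=False)

    @property
    def network(self) -> SignedNetwork:
        return self.model.network

    def importance_scores(
        self, n_rule_samples: int = 10, seed: int | None = None
    ) -> ImportanceScores:
        """Knock-in vs knockout influence of every node (cached per call
        signature)."""
        key = (n_rule_samples, seed)
        if key not in self._importance:
            self._importance[key] = importance_scores(
                self.network, self.ers, self.model.training,
                n_rule_samples=n_rule_samples, seed=seed,
            )
        return self._importance[key]

    def ers_summary(self, min_indegree: int = 3) -> pd.DataFrame:
        return ers_size_summary(self.ers, self.network, min_indegree=min_indegree)

    def rules_text(self) -> str:
        """All fitted rules, one line per node, with ERS annotations."""
        lines = []
        for node in sorted(self.fitted.rules):
            err = self.fitness_report.per_node.get(node, 0.0)
            lines.append(f"{self.fitted.rules[node].to_text()}"
                         f"  # |ERS|={len(self.ers[node])} error={err:.6f}")
        return "\n".join(lines)

    def ers_text(self) -> str:
        """Every candidate rule of every node's ERS with the shared error."""
        lines = []
        for node in sorted(self.ers):
            e = self.ers[node]
            lines.append(f"# {node}: {len(e)} equivalent rule(s), error={e.fitness:.6f}")
            lines.extend(rule.to_text() for rule in e.rules)
        return "\n".join(lines)

    def summary(self) -> str:
        """statsmodels-style text summary of the fit."""
        net = self.network
        n_edges = len(net.edges)
        header = [
            "Multiomics Boolean Network Results",
            "=" * 64,
            f"Pathway:            {net.name}",
            f"Nodes / edges:      {len(net.nodes)} / {n_edges}",
            f"Training states:    {len(self.model.training.states)} "
            f"({self.model.dataset.n_layers} layers)",
            f"GA:                 pop={self.config.population_size} "
            f"gen={self.config.generations} seed={self.config.seed}",
            f"Total error:        {self.fitness_report.total:.6f}",
            "-" * 64,
            f"{'node':<16}{'in_deg':>7}{'|ERS|':>7}{'error':>10}  rule",
        ]
        body = []
        for node in sorted(net.nodes):
            k = net.in_degree(node)
            if k == 0:
                body.append(f"{node:<16}{0:>7}{'-':>7}{'-':>10}  (input)")
            else:
                rule = self.fitted.rules[node].to_text().split(" = ", 1)[1]
                body.append(
                    f"{node:<16}{k:>7}{len(self.ers[node]):>7}"
                    f"{self.fitness_report.per_node[node]:>10.4f}  {rule}"
                )
        return "\n".join(header + body + ["=" * 64])
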