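"""Rule inference: genetic algorithm plus node-local exhaustive search.

The search space for a network is the cross-product of each node's
enumerable rule space (at most 127 rules per node).  A generational GA
with tournament selection, per-node crossover and per-node rule
resampling finds a good concrete rule assignment; an exhaustive local
search around that incumbent then recovers, for every node, the full
set of rules that fit the training data equally well — the equivalent
rule set (ERS), whose size proxies the uncertainty of rule
determination.

Fitness is mask-aware: each binarized (layer, sample) state initializes
the network (unmeasured nodes start at 0), the model is run to its
attractor, and a node's error is the mean absolute difference between
its attractor-average value and its observed bit, taken only over
states in which the node was measured.  Unmeasured observations are
never fabricated and never scored.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boolrules import Rule, enumerate_rule_space
from .data import BinarizedStates
from .network import SignedNetwork
from .simulate import NetworkModel, attractor_average

#: error equality for ERS membership is exact to this many decimals, so
#: ERS sizes are reproducible across platforms.
ERS_DECIMALS = 12


@dataclass
class GAConfig:
    """Genetic-algorithm settings (pathway-scale defaults)."""

    population_size: int = 24
    generations: int = 50
    crossover_prob: float = 0.6
    mutation_prob: float = 0.3
    tournament_size: int = 3
    n_elite: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class FitnessReport:
    """Per-node mean training error and its sum."""

    per_node: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_node.values()))


@dataclass
class EquivalentRuleSet:
    """All rules for one node achieving its minimal training error."""

    target: str
    rules: tuple[Rule, ...]
    fitness: float

    def __len__(self) -> int:
        return len(self.rules)

    def __contains__(self, rule: Rule) -> bool:
        return any(r.clauses == rule.clauses for r in self.rules)


@dataclass
class TrainingStates:
    """Binarized states projected onto a network's nodes.

    One entry per (layer, sample): an initial state over all network
    nodes (unmeasured nodes at 0) and the observed bits for measured
    nodes.
    """

    states: list[tuple[dict[str, int], dict[str, int]]]  # (init, observed)
    labels: list[tuple[str, str]] = field(default_factory=list)  # (layer, sample)

    @classmethod
    def from_binarized(
        cls, network: SignedNetwork, binarized: BinarizedStates
    ) -> "TrainingStates":
        states, labels = [], []
        nodes = sorted(network.nodes)
        for layer, sample, bits in binarized.states():
            observed = {n: int(bits[n]) for n in nodes if n in bits.index}
            init = {n: observed.get(n, 0) for n in nodes}
            states.append((init, observed))
            labels.append((layer, sample))
        if not states:
            raise ValueError("no (layer, sample) training states")
        return cls(states=states, labels=labels)


def fitness(model: NetworkModel, training: TrainingStates) -> FitnessReport:
    """Mean per-node |attractor value - observed bit| over training states."""
    errors: dict[str, float] = {n: 0.0 for n in model.node_order}
    counts: dict[str, int] = {n: 0 for n in model.node_order}
    for init, observed in training.states:
        steady = attractor_average(model, init)
        for node, bit in observed.items():
            errors[node] += abs(steady[node] - bit)
            counts[node] += 1
    per_node = {
        n: (errors[n] / counts[n] if counts[n] else 0.0) for n in model.node_order
    }
    return FitnessReport(per_node=per_node)


class _RuleSearch:
    """Shared machinery: per-node rule spaces and cached fitness."""

    def __init__(self, network: SignedNetwork, training: TrainingStates):
        self.network = network
        self.training = training
        self.rule_nodes = [n for n in sorted(network.nodes) if network.in_degree(n) >= 1]
        self.spaces = {
            n: enumerate_rule_space(n, network.regulators_of(n)) for n in self.rule_nodes
        }
        self._cache: dict[tuple[int, ...], FitnessReport] = {}

    def model_for(self, individual: tuple[int, ...]) -> NetworkModel:
        rules = {
            node: self.spaces[node][idx]
            for node, idx in zip(self.rule_nodes, individual)
        }
        return NetworkModel(network=self.network, rules=rules)

    def evaluate(self, individual: tuple[int, ...]) -> FitnessReport:
        if individual not in self._cache:
            self._cache[individual] = fitness(self.model_for(individual), self.training)
        return self._cache[individual]


def ga_search(
    network: SignedNetwork,
    training: TrainingStates,
    config: GAConfig | None = None,
) -> tuple[NetworkModel, FitnessReport, pd.DataFrame]:
    """Generational GA over rule assignments.

    Tournament selection, uniform per-node clause-set crossover, and
    per-node rule-resampling mutation, with elitism so the best fitness
    is non-increasing across generations.  Fully reproducible for a
    given ``config.seed``.

    Returns the best model found, its fitness report, and a log of
    (generation, best_fitness).
    """
    config = config or GAConfig()
    rng = random.Random(config.seed)
    search = _RuleSearch(network, training)
    nodes = search.rule_nodes
    if not nodes:
        model = NetworkModel(network=network, rules={})
        report = fitness(model, training)
        return model, report, pd.DataFrame({"generation": [], "best_fitness": []})

    def random_individual() -> tuple[int, ...]:
        return tuple(rng.randrange(len(search.spaces[n])) for n in nodes)

    def tournament(pop: list[tuple[int, ...]], totals: list[float]) -> tuple[int, ...]:
        picks = [rng.randrange(len(pop)) for _ in range(config.tournament_size)]
        best = min(picks, key=lambda i: totals[i])
        return pop[best]

    population = [random_individual() for _ in range(config.population_size)]
    log_rows = []
    for generation in range(config.generations + 1):
        totals = [search.evaluate(ind).total for ind in population]
        ranked = sorted(range(len(population)), key=lambda i: (totals[i], population[i]))
        best_total = totals[ranked[0]]
        log_rows.append((generation, best_total))
        if generation == config.generations or best_total == 0.0:
            break
        elite = [population[i] for i in ranked[: config.n_elite]]
        offspring = list(elite)
        while len(offspring) < config.population_size:
            p1 = tournament(population, totals)
            p2 = tournament(population, totals)
            child = list(p1)
            if rng.random() < config.crossover_prob:
                # uniform per-node exchange of whole clause sets
                child = [
                    (a if rng.random() < 0.5 else b) for a, b in zip(p1, p2)
                ]
            if rng.random() < config.mutation_prob:
                # resample one node's rule uniformly from its space
                pos = rng.randrange(len(nodes))
                child[pos] = rng.randrange(len(search.spaces[nodes[pos]]))
            offspring.append(tuple(child))
        population = offspring

    totals = [search.evaluate(ind).total for ind in population]
    ranked = sorted(range(len(population)), key=lambda i: (totals[i], population[i]))
    best = population[ranked[0]]
    log = pd.DataFrame(log_rows, columns=["generation", "best_fitness"])
    return search.model_for(best), search.evaluate(best), log


def local_search(
    network: SignedNetwork,
    training: TrainingStates,
    incumbent: NetworkModel,
) -> tuple[dict[str, EquivalentRuleSet], NetworkModel]:
    """Exhaustive per-node search around a GA incumbent.

    For each node independently, every rule in its enumerated space
    (at most 127) is evaluated with all other nodes held at their
    incumbent rules; the node's ERS is the set of rules achieving its
    minimal error (ties exact to 12 decimals).  The returned model
    carries, per node, the first minimal-error rule in enumeration
    order.
    """
    search = _RuleSearch(network, training)
    ers: dict[str, EquivalentRuleSet] = {}
    refined_rules = dict(incumbent.rules)
    for node in search.rule_nodes:
        node_errors = []
        for candidate in search.spaces[node]:
            rules = dict(refined_rules)
            rules[node] = candidate
            model = NetworkModel(network=network, rules=rules)
            err = 0.0
            count = 0
            for init, observed in training.states:
                if node not in observed:
                    continue
                steady = attractor_average(model, init)
                err += abs(steady[node] - observed[node])
                count += 1
            node_errors.append(err / count if count else 0.0)
        rounded = np.round(node_errors, ERS_DECIMALS)
        best = rounded.min()
        members = tuple(
            search.spaces[node][i] for i in range(len(rounded)) if rounded[i] == best
        )
        ers[node] = EquivalentRuleSet(target=node, rules=members, fitness=float(best))
        refined_rules[node] = members[0]
    refined = NetworkModel(network=network, rules=refined_rules)
    return ers, refined


def ers_size_summary(
    ers: dict[str, EquivalentRuleSet],
    network: SignedNetwork,
    min_indegree: int = 3,
) -> pd.DataFrame:
    """Table of (node, in_degree, ers_size) for nodes with in-degree >=
    ``min_indegree``; mean and median sizes in ``DataFrame.attrs``.

    ERS size proxies rule-determination uncertainty; high-in-degree
    nodes are where the rule space is large enough for it to matter.
    """
    rows = [
        (node, network.in_degree(node), len(ers[node]))
        for node in sorted(ers)
        if network.in_degree(node) >= min_indegree
    ]
    table = pd.DataFrame(rows, columns=["node", "in_degree", "ers_size"])
    table.attrs["mean"] = float(table["ers_size"].mean()) if len(table) else float("nan")
    table.attrs["median"] = float(table["ers_size"].median()) if len(table) else float("nan")
    return table
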