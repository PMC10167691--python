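"""Synchronous simulation of executable Boolean network models.

All nodes update simultaneously each step, so a trajectory from a given
initial state is deterministic and must enter a fixed point or a limit
cycle within 2^n steps.  Steady-state node values are attractor
averages: 0/1 at a fixed point, the cycle mean on a limit cycle.
In-degree-0 nodes hold their initial state and act as network inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .boolrules import Rule
from .network import SignedNetwork

#: default synchronous-update horizon; long enough for cycle entry on
#: pathway-scale networks.
DEFAULT_STEPS = 100
#: default averaging window over the trajectory tail.
DEFAULT_WINDOW = 20


@dataclass
class NetworkModel:
    """A concrete executable model: one rule per node with in-degree >= 1.

    Nodes without a rule (in-degree 0 after preparation) hold their
    state and act as inputs.
    """

    network: SignedNetwork
    rules: dict[str, Rule]
    _compiled: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        for node, rule in self.rules.items():
            if rule.target != node:
                raise ValueError(f"rule for {node} targets {rule.target}")
            for gene, _ in rule.regulators:
                if gene not in self.network.nodes:
                    raise ValueError(f"{node}: regulator {gene} not in network")

    @property
    def node_order(self) -> list[str]:
        return sorted(self.network.nodes)

    def _compile(self) -> list:
        """Per-node (regulator indices, truth table) against node_order."""
        if self._compiled is None:
            index = {n: i for i, n in enumerate(self.node_order)}
            compiled = []
            for node in self.node_order:
                rule = self.rules.get(node)
                if rule is None:
                    compiled.append(None)  # input node: holds state
                else:
                    reg_idx = tuple(index[g] for g, _ in rule.regulators)
                    compiled.append((reg_idx, rule.truth_table()))
            self._compiled = compiled
        return self._compiled

    def step(self, state: tuple[int, ...], clamp: Mapping[int, int] | None = None) -> tuple[int, ...]:
        """One synchronous update of a state vector (node_order layout)."""
        compiled = self._compile()
        nxt = []
        for i, entry in enumerate(compiled):
            if clamp is not None and i in clamp:
                nxt.append(clamp[i])
            elif entry is None:
                nxt.append(state[i])
            else:
                reg_idx, table = entry
                m = 0
                for bit_pos, j in enumerate(reg_idx):
                    m |= state[j] << bit_pos
                nxt.append(table[m])
        return tuple(nxt)

    def _state_vector(self, init: Mapping[str, int]) -> tuple[int, ...]:
        try:
            return tuple(int(init[n]) for n in self.node_order)
        except KeyError as exc:
            raise KeyError(f"initial state missing node {exc.args[0]!r}") from exc


def simulate_synchronous(
    model: NetworkModel,
    init: Mapping[str, int],
    steps: int = DEFAULT_STEPS,
) -> list[dict[str, int]]:
    """Deterministic synchronous trajectory of length ``steps + 1``."""
    if steps < 1:
        raise ValueError("steps must be >= 1")
    order = model.node_order
    state = model._state_vector(init)
    trajectory = [dict(zip(order, state))]
    for _ in range(steps):
        state = model.step(state)
        trajectory.append(dict(zip(order, state)))
    return trajectory


def steady_state(
    trajectory: list[dict[str, int]],
    window: int = DEFAULT_WINDOW,
) -> dict[str, float]:
    """Mean node value over the final ``window`` states of a trajectory.

    At a fixed point this is the point itself; on a limit cycle it is
    the cycle average provided the window spans whole periods.  For
    exact attractor averages regardless of window, use
    :func:`attractor_average`.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(trajectory):
        raise ValueError("window exceeds trajectory length")
    tail = trajectory[-window:]
    return {n: sum(s[n] for s in tail) / window for n in trajectory[0]}


def attractor_average(
    model: NetworkModel,
    init: Mapping[str, int],
    clamp: Mapping[str, int] | None = None,
    max_steps: int | None = None,
) -> dict[str, float]:
    """Exact attractor-average node values from a given initial state.

    Iterates the synchronous update until a state repeats (guaranteed
    within 2^n steps), then averages each node's value over the detected
    cycle.  ``clamp`` holds the given nodes at fixed values throughout,
    including at t=0 — the mechanism behind in-silico knockout (0) and
    knock-in (1) perturbations.
    """
    order = model.node_order
    index = {n: i for i, n in enumerate(order)}
    clamp_idx = (
        {index[g]: int(b) for g, b in clamp.items()} if clamp else None
    )
    state = list(model._state_vector(init))
    if clamp_idx:
        for i, b in clamp_idx.items():
            state[i] = b
    state = tuple(state)

    seen: dict[tuple[int, ...], int] = {}
    history: list[tuple[int, ...]] = []
    limit = max_steps if max_steps is not None else 2 ** len(order) + 1
    for _ in range(limit + 1):
        if state in seen:
            cycle = history[seen[state]:]
            means = [sum(s[i] for s in cycle) / len(cycle) for i in range(len(order))]
            return dict(zip(order, means))
        seen[state] = len(history)
        history.append(state)
        state = model.step(state, clamp=clamp_idx)
    # only reachable when max_steps is set below the cycle-entry time
    raise RuntimeError("no attractor found within max_steps")
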