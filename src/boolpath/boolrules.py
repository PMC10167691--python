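"""Boolean regulatory rules in OR-of-AND form.

A node's rule is a disjunction of conjunctive clauses over its (signed)
regulators: an inhibiting regulator enters a clause negated.  With k
regulators there are 2^k - 1 possible AND clauses and hence
2^(2^k - 1) - 1 nonempty clause sets; for k = 3, the most complex case
considered, that is 127 candidate rules.  Clause sets are stored as
given, without absorption-law reduction, so this count is exact and
rule equality is clause-set equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

MAX_REGULATORS = 3


def rule_space_size(k: int) -> int:
    """Number of OR-of-AND rules over k regulators: 2^(2^k - 1) - 1."""
    return 2 ** (2**k - 1) - 1


@dataclass(frozen=True)
class Rule:
    """One node's regulatory logic as an OR of AND clauses.

    ``regulators`` is an ordered tuple of (gene, sign) with sign +1 for
    activation and -1 for inhibition.  ``clauses`` is a frozenset of
    frozensets of regulator indices; each inner set is an AND clause over
    the (sign-adjusted) regulator states, and the rule value is the OR
    over clauses.
    """

    target: str
    regulators: tuple[tuple[str, int], ...]
    clauses: frozenset[frozenset[int]]

    def __post_init__(self) -> None:
        if not (1 <= len(self.regulators) <= MAX_REGULATORS):
            raise ValueError(
                f"{self.target}: rule needs 1..{MAX_REGULATORS} regulators"
            )
        if not self.clauses or any(not c for c in self.clauses):
            raise ValueError(f"{self.target}: clauses must be nonempty")
        valid = set(range(len(self.regulators)))
        for clause in self.clauses:
            if not clause <= valid:
                raise ValueError(f"{self.target}: clause references unknown regulator")

    def evaluate(self, state: Mapping[str, int]) -> int:
        """OR over clauses of AND over sign-adjusted regulator states."""
        inputs = []
        for gene, sign in self.regulators:
            bit = state[gene]
            inputs.append(bit if sign == 1 else 1 - bit)
        for clause in self.clauses:
            if all(inputs[i] for i in clause):
                return 1
        return 0

    def truth_table(self) -> tuple[int, ...]:
        """Rule output for every regulator-state combination.

        Entry ``m`` is the output when regulator ``i`` has raw state
        ``(m >> i) & 1``.
        """
        k = len(self.regulators)
        out = []
        for m in range(2**k):
            state = {g: (m >> i) & 1 for i, (g, _) in enumerate(self.regulators)}
            out.append(self.evaluate(state))
        return tuple(out)

    def to_text(self) -> str:
        """Human-readable form: ``TARGET* = (A and not B) or C``."""

        def literal(i: int) -> str:
            gene, sign = self.regulators[i]
            return gene if sign == 1 else f"not {gene}"

        parts = []
        for clause in sorted(self.clauses, key=lambda c: (len(c), sorted(c))):
            terms = " and ".join(literal(i) for i in sorted(clause))
            parts.append(f"({terms})" if len(clause) > 1 else terms)
        return f"{self.target}* = " + " or ".join(parts)


def enumerate_rule_space(
    target: str, regulators: Sequence[tuple[str, int]]
) -> list[Rule]:
    """All distinct OR-of-AND rules over the given regulators.

    Deterministic order: clause sets enumerated by size then clause
    content.  Raises for k = 0 or k > 3 (in-degree truncation happens
    upstream, during network preparation).
    """
    k = len(regulators)
    if not (1 <= k <= MAX_REGULATORS):
        raise ValueError(f"rule space defined for 1..{MAX_REGULATORS} regulators, got {k}")
    atoms = [
        frozenset(c)
        for size in range(1, k + 1)
        for c in combinations(range(k), size)
    ]
    rules = []
    for n_clauses in range(1, len(atoms) + 1):
        for clause_set in combinations(atoms, n_clauses):
            rules.append(
                Rule(
                    target=target,
                    regulators=tuple(regulators),
                    clauses=frozenset(clause_set),
                )
            )
    assert len(rules) == rule_space_size(k)
    return rules
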