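"""Weighted aggregation of the axiomatic and numerical battery scores.

Total = w_A * S_A + w_N * S_N, where S_A is the number of axioms satisfied
(0-6, P1 counted once as the conjunction of its three parts), S_N the
number of family criteria passed (0-6), and the nonnegative weights sum
to 1.  Scores stay on the 0-6 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .axiomatics import AxiomVerdictMatrix
from .benchmarks import BenchmarkVerdictMatrix

__all__ = ["ScoreCard", "score", "scorecards"]


@dataclass(frozen=True)
class ScoreCard:
    measure: str
    axiomatic: int  # S_A, 0-6
    numerical: int  # S_N, 0-6
    w_axiomatic: float
    w_numerical: float
    total: float


def score(s_a: int, s_n: int, w_a: float = 0.5, w_n: float = 0.5) -> float:
    """Weighted overall performance score."""
    if w_a < 0 or w_n < 0 or abs(w_a + w_n - 1.0) > 1e-12:
        raise ValueError("weights must be nonnegative and sum to 1")
    if not (0 <= s_a <= 6 and 0 <= s_n <= 6):
        raise ValueError("scores must lie in 0..6")
    return w_a * s_a + w_n * s_n


def scorecards(
    axiom_matrix: AxiomVerdictMatrix,
    benchmark_matrix: BenchmarkVerdictMatrix,
    w_axiomatic: float = 0.5,
    w_numerical: float = 0.5,
) -> list[ScoreCard]:
    """One card per measure, sorted by total descending, ties alphabetical."""
    if set(axiom_matrix.measures) != set(benchmark_matrix.measures):
        raise ValueError(
            "axiomatic and numerical matrices cover different measure sets"
        )
    s_a = axiom_matrix.satisfied_counts
    s_n = benchmark_matrix.passed_counts
    cards = [
        ScoreCard(
            m,
            s_a[m],
            s_n[m],
            w_axiomatic,
            w_numerical,
            score(s_a[m], s_n[m], w_axiomatic, w_numerical),
        )
        for m in axiom_matrix.measures
    ]
    cards.sort(key=lambda c: (-c.total, c.measure))
    return cards
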