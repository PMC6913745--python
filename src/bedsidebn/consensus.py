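"""Bootstrap arc-confidence estimation and thresholded consensus graphs.

Arc strength is the fraction of bootstrap-learned networks containing an
edge in either orientation; the direction coefficient is, among those, the
fraction carrying a given orientation.  The consensus keeps edges whose
strength strictly exceeds ``max(data-driven significance threshold,
strength floor)`` and directs an edge only when its direction coefficient
reaches the direction threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_model import Cohort
from .structure_learning import (ConstraintSet, Dag, EncodedData, ScoreParams,
                                 _find_cycle, _mmhc_encoded)

__all__ = [
    "ArcConfidence",
    "ConsensusGraph",
    "ConsensusCycleError",
    "bootstrap_confidence",
    "significance_threshold",
    "build_consensus",
    "orient_undirected",
    "confidence_frame",
    "write_confidence",
    "read_confidence",
]

log = logging.getLogger(__name__)

STRENGTH_FLOOR = 0.700
DIRECTION_THRESHOLD = 0.666


class ConsensusCycleError(ValueError):
    """The retained directed arcs form a cycle (reported, never repaired)."""


@dataclass(frozen=True)
class ArcConfidence:
    """Bootstrap confidence for one ordered arc.

    ``strength`` is orientation-free (equal for both orderings of a pair);
    ``direction`` is the share of this orientation among replicates that
    contain the edge at all, so the two orderings sum to 1.
    """

    from_: str
    to: str
    strength: float
    direction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0 and 0.0 <= self.direction <= 1.0):
            raise ValueError("strength and direction must lie in [0, 1]")


@dataclass(frozen=True)
class ConsensusGraph:
    nodes: tuple[str, ...]
    directed: tuple[tuple[str, str], ...]
    undirected: tuple[tuple[str, str], ...]
    strength_threshold: float
    direction_threshold: float

    def __post_init__(self) -> None:
        und = tuple(tuple(sorted(e)) for e in self.undirected)
        object.__setattr__(self, "undirected", und)
        if _find_cycle(self.nodes, self.directed):
            raise ConsensusCycleError("directed consensus arcs form a cycle")
        directed_pairs = {frozenset(a) for a in self.directed}
        if directed_pairs & {frozenset(e) for e in und}:
            raise ValueError("edge appears both directed and undirected")


def bootstrap_confidence(cohort: Cohort, replicates: int, seed: int,
                         params: ScoreParams = ScoreParams(),
                         constraints: ConstraintSet = ConstraintSet(),
                         ) -> list[ArcConfidence]:
    """Nonparametric bootstrap of the MMHC learner.

    Each replicate resamples ``n`` rows with replacement and relearns the
    network; every unordered node pair appears in the output (absent pairs
    with strength 0), each as two ordered records.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if cohort.n == 0:
        raise ValueError("empty cohort")
    enc = EncodedData.from_cohort(cohort)
    rng = np.random.default_rng(seed)
    nodes = sorted(enc.names)
    pair_counts: dict[tuple[str, str], int] = {}
    arc_counts: dict[tuple[str, str], int] = {}
    for rep in range(replicates):
        rows = rng.integers(0, enc.n, enc.n)
        try:
            dag = _mmhc_encoded(enc.resample(rows), params, constraints)
        except Exception:
            log.exception("structure learning failed on bootstrap replicate %d", rep)
            raise
        for u, v in dag.arcs:
            key = (u, v) if u < v else (v, u)
            pair_counts[key] = pair_counts.get(key, 0) + 1
            arc_counts[(u, v)] = arc_counts.get((u, v), 0) + 1
    out = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            present = pair_counts.get((a, b), 0)
            strength = present / replicates
            d_ab = arc_counts.get((a, b), 0) / present if present else 0.5
            out.append(ArcConfidence(a, b, strength, d_ab))
            out.append(ArcConfidence(b, a, strength, 1.0 - d_ab))
    return out


def significance_threshold(strengths) -> float:
    """Data-driven strength cutoff (L1 criterion).

    With ``F`` the empirical CDF of the strengths on [0, 1), pick the
    constant level ``t*`` minimizing the integral of ``|F(x) - t|`` and
    return the smallest strength value whose CDF reaches ``t*`` (0 when
    ``t* = 0``).  Arcs strictly above the returned value are significant.
    """
    s = np.sort(np.asarray(list(strengths), float))
    if s.size == 0:
        raise ValueError("no strengths given")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("strengths must lie in [0, 1]")
    n = s.size
    # F is a step function; the integral is piecewise linear in t with
    # kinks at the attained CDF levels, so checking those levels suffices.
    knots = np.concatenate([[0.0], np.unique(s), [1.0]])
    widths = np.diff(knots)
    cdf_levels = np.searchsorted(s, knots[:-1], side="right") / n
    candidates = np.unique(np.concatenate([[0.0, 1.0], cdf_levels]))
    objective = [
        float(np.sum(np.abs(cdf_levels - t) * widths)) for t in candidates
    ]
    t_star = float(candidates[int(np.argmin(objective))])
    if t_star <= 0.0:
        return 0.0
    # left-continuous empirical quantile: inf{x : F(x) >= t*}
    k = int(np.ceil(t_star * n)) - 1
    return float(s[min(max(k, 0), n - 1)])


def build_consensus(confidences: list[ArcConfidence],
                    strength_floor: float = STRENGTH_FLOOR,
                    direction_threshold: float = DIRECTION_THRESHOLD,
                    ) -> ConsensusGraph:
    """Threshold a confidence table into the consensus (averaged) graph.

    The effective strength threshold is the larger of the data-driven
    significance threshold and the configured floor; retained edges with a
    direction coefficient at or above the direction threshold are oriented
    accordingly, the rest stay undirected.
    """
    by_pair: dict[tuple[str, str], dict[tuple[str, str], ArcConfidence]] = {}
    nodes = set()
    for c in confidences:
        nodes.update((c.from_, c.to))
        key = tuple(sorted((c.from_, c.to)))
        by_pair.setdefault(key, {})[(c.from_, c.to)] = c
    for key, recs in by_pair.items():
        strengths = {c.strength for c in recs.values()}
        if len(strengths) > 1:
            raise ValueError(f"inconsistent strength for pair {key}")
        if len(recs) == 2 and list(recs.values())[0].strength > 0:
            d = sum(c.direction for c in recs.values())
            if abs(d - 1.0) > 1e-9:
                raise ValueError(f"direction coefficients of {key} do not sum to 1")
    pair_strength = {k: next(iter(v.values())).strength for k, v in by_pair.items()}
    effective = max(significance_threshold(list(pair_strength.values())),
                    strength_floor)
    directed, undirected = [], []
    for key in sorted(by_pair):
        if pair_strength[key] <= effective:
            continue
        recs = by_pair[key]
        oriented = None
        for (u, v), c in sorted(recs.items()):
            if c.direction >= direction_threshold:
                oriented = (u, v)
                break
        if oriented is not None:
            directed.append(oriented)
        else:
            undirected.append(key)
    return ConsensusGraph(tuple(sorted(nodes)), tuple(directed),
                          tuple(undirected), effective, direction_threshold)


def orient_undirected(graph: ConsensusGraph,
                      expert_orientations: dict[tuple[str, str], tuple[str, str]],
                      ) -> Dag:
    """Resolve the remaining undirected edges by expert knowledge.

    ``expert_orientations`` maps an (unordered) edge to its ordered arc.
    Every undirected edge must be covered; an orientation closing a cycle
    is an error.
    """
    normalized = {tuple(sorted(k)): tuple(v) for k, v in expert_orientations.items()}
    arcs = list(graph.directed)
    for edge in graph.undirected:
        if edge not in normalized:
            raise ValueError(f"undirected edge {edge} has no expert orientation")
        u, v = normalized[edge]
        if {u, v} != set(edge):
            raise ValueError(f"orientation {(u, v)} does not match edge {edge}")
        arcs.append((u, v))
    try:
        return Dag(graph.nodes, tuple(arcs))
    except ValueError as exc:
        raise ValueError(f"expert orientation induces an invalid graph: {exc}")


# --------------------------------------------------------------------------
# serialization (published confidence-table layout)
# --------------------------------------------------------------------------


def confidence_frame(confidences: list[ArcConfidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.from_, c.to, c.strength, c.direction) for c in confidences],
        columns=["from", "to", "strength", "direction"],
    )


def write_confidence(confidences: list[ArcConfidence], path: str | Path) -> None:
    confidence_frame(confidences).to_csv(path, index=False)


def read_confidence(path: str | Path) -> list[ArcConfidence]:
    df = pd.read_csv(path)
    return [ArcConfidence(r["from"], r["to"], float(r["strength"]),
                          float(r["direction"]))
            for _, r in df.iterrows()]
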