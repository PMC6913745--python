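"""Hybrid structure learning: Max-Min Parents-Children candidate restriction
with G2 conditional-independence tests, followed by greedy hill climbing
under the BDeu score with black/whitelists (the Max-Min Hill-Climbing
learner).

All search is deterministic for a fixed move-enumeration order: node names
are processed sorted, and additions are considered before deletions before
reversals.  The heavy lifting operates on an integer-encoded copy of the
cohort so the same code path serves single fits and bootstrap loops.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .cohort_model import Cohort

__all__ = [
    "Dag",
    "ConstraintSet",
    "ScoreParams",
    "EncodedData",
    "g2_test",
    "mmpc",
    "bdeu_local",
    "score_dag",
    "hill_climb",
    "mmhc",
    "CyclicWhitelistError",
]

_EPS_GAIN = 1e-10


class CyclicWhitelistError(ValueError):
    """The required (whitelisted) arcs already contain a directed cycle."""


# --------------------------------------------------------------------------
# graphs and constraints
# --------------------------------------------------------------------------


def _find_cycle(nodes, arcs) -> bool:
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in arcs:
        children[u].append(v)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {v: WHITE for v in nodes}

    def visit(v: str) -> bool:
        color[v] = GRAY
        for w in children[v]:
            if color[w] == GRAY or (color[w] == WHITE and visit(w)):
                return True
        color[v] = BLACK
        return False

    return any(color[v] == WHITE and visit(v) for v in nodes)


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over named variables."""

    nodes: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        arcs = tuple((str(u), str(v)) for u, v in self.arcs)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "arcs", arcs)
        node_set = set(nodes)
        if len(node_set) != len(nodes):
            raise ValueError("duplicate node names")
        seen = set()
        for u, v in arcs:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"arc ({u!r}, {v!r}) references unknown node")
            if (u, v) in seen:
                raise ValueError(f"duplicate arc ({u!r}, {v!r})")
            seen.add((u, v))
        if _find_cycle(nodes, arcs):
            raise ValueError("directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(u for u, v in self.arcs if v == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(v for u, v in self.arcs if u == node)

    def markov_blanket(self, node: str) -> frozenset[str]:
        """Parents, children and children's co-parents of ``node``."""
        kids = set(self.children(node))
        blanket = set(self.parents(node)) | kids
        for kid in kids:
            blanket |= set(self.parents(kid))
        blanket.discard(node)
        return frozenset(blanket)

    def topological_order(self) -> tuple[str, ...]:
        parents = {v: set(self.parents(v)) for v in self.nodes}
        order, placed = [], set()
        pending = list(self.nodes)
        while pending:
            for v in pending:
                if parents[v] <= placed:
                    order.append(v)
                    placed.add(v)
                    pending.remove(v)
                    break
            else:  # pragma: no cover - guarded by acyclicity check
                raise ValueError("cycle")
        return tuple(order)

    def skeleton(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((u, v)) for u, v in self.arcs)


@dataclass(frozen=True)
class ConstraintSet:
    blacklist: frozenset[tuple[str, str]] = frozenset()
    whitelist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        bl = frozenset(tuple(a) for a in self.blacklist)
        wl = frozenset(tuple(a) for a in self.whitelist)
        object.__setattr__(self, "blacklist", bl)
        object.__setattr__(self, "whitelist", wl)
        if bl & wl:
            raise ValueError("whitelist and blacklist overlap")
        nodes = sorted({x for a in wl for x in a})
        if _find_cycle(nodes, wl):
            raise CyclicWhitelistError("whitelisted arcs form a cycle")

    def both_ways_blacklisted(self, u: str, v: str) -> bool:
        return (u, v) in self.blacklist and (v, u) in self.blacklist


@dataclass(frozen=True)
class ScoreParams:
    """BDeu equivalent sample size and G2 test level (both configurable;
    conventional defaults)."""

    ess: float = 1.0
    alpha: float = 0.05
    max_sepset: int | None = None

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ValueError("ess must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# --------------------------------------------------------------------------
# encoded data
# --------------------------------------------------------------------------


@dataclass
class EncodedData:
    """Integer-coded view of a cohort restricted to complete columns."""

    names: tuple[str, ...]
    codes: np.ndarray  # (n, p) int64
    cards: np.ndarray  # (p,) int64
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {v: i for i, v in enumerate(self.names)}

    @classmethod
    def from_cohort(cls, cohort: Cohort, variables=None) -> "EncodedData":
        names = tuple(variables) if variables is not None else cohort.variables
        cols = [cohort.codes(v) for v in names]
        codes = np.column_stack(cols) if cols else np.zeros((cohort.n, 0), np.int64)
        cards = np.array([len(cohort.spec(v).states) for v in names], np.int64)
        return cls(names, codes, cards)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def resample(self, rows: np.ndarray) -> "EncodedData":
        return EncodedData(self.names, self.codes[rows], self.cards)

    def config_index(self, vars_: tuple[str, ...]) -> tuple[np.ndarray, int]:
        """Mixed-radix index of the joint configuration of ``vars_``."""
        idx = np.zeros(self.n, np.int64)
        q = 1
        for v in vars_:
            j = self.index[v]
            idx = idx * self.cards[j] + self.codes[:, j]
            q *= int(self.cards[j])
        return idx, q


# --------------------------------------------------------------------------
# G2 conditional-independence test
# --------------------------------------------------------------------------


def _g2(enc: EncodedData, x: str, y: str, z: tuple[str, ...]):
    rx = int(enc.cards[enc.index[x]])
    ry = int(enc.cards[enc.index[y]])
    zidx, qz = enc.config_index(z)
    flat = (zidx * rx + enc.codes[:, enc.index[x]]) * ry + enc.codes[:, enc.index[y]]
    counts = np.bincount(flat, minlength=qz * rx * ry).reshape(qz, rx, ry).astype(float)
    tot = counts.sum(axis=(1, 2))
    nonempty = tot > 0
    counts = counts[nonempty]
    tot = tot[nonempty]
    rows = counts.sum(axis=2, keepdims=True)
    cols = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = rows * cols / tot[:, None, None]
        terms = np.where(counts > 0, counts * np.log(counts / expected), 0.0)
    stat = float(2.0 * terms.sum())
    df = (rx - 1) * (ry - 1) * int(nonempty.sum())
    p = float(chi2_dist.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


def g2_test(cohort: Cohort, x: str, y: str, z=()) -> tuple[float, int, float]:
    """G2 = 2 * sum O*ln(O/E) within each configuration of z.

    Degrees of freedom count only conditioning strata with a nonzero total;
    zero observed cells contribute 0 to the statistic.
    """
    z = tuple(z)
    if x == y or x in z or y in z:
        raise ValueError("x, y and z must be distinct")
    if cohort.n == 0:
        raise ValueError("empty cohort")
    enc = EncodedData.from_cohort(cohort, (x, y, *z))
    return _g2(enc, x, y, z)


# --------------------------------------------------------------------------
# Max-Min Parents-Children
# --------------------------------------------------------------------------


def _subsets(items, max_size=None):
    items = tuple(items)
    top = len(items) if max_size is None else min(max_size, len(items))
    for k in range(top + 1):
        yield from itertools.combinations(items, k)


def _max_pvalue(enc, x, t, cpc, params) -> float:
    """min-association of x with t given CPC == the worst (largest) p-value
    over subsets of the current candidate set."""
    worst = 0.0
    for s in _subsets(cpc, params.max_sepset):
        _, _, p = _g2(enc, x, t, s)
        worst = max(worst, p)
        if worst > params.alpha:
            break
    return worst


def _mmpc_one(enc: EncodedData, t: str, params: ScoreParams,
              constraints: ConstraintSet) -> list[str]:
    candidates = sorted(
        v for v in enc.names
        if v != t and not constraints.both_ways_blacklisted(v, t)
    )
    cpc: list[str] = []
    remaining = list(candidates)
    while remaining:
        scored = []
        for x in list(remaining):
            p = _max_pvalue(enc, x, t, cpc, params)
            if p > params.alpha:
                remaining.remove(x)  # independent given some subset: drop for good
            else:
                scored.append((p, x))
        if not scored:
            break
        scored.sort()  # smallest worst-p first; name breaks ties
        _, best = scored[0]
        cpc.append(best)
        remaining.remove(best)
    # backward: shrink members now separable given the rest of the CPC
    for x in list(cpc):
        rest = tuple(v for v in cpc if v != x)
        if _max_pvalue(enc, x, t, rest, params) > params.alpha:
            cpc.remove(x)
    return sorted(cpc)


def _mmpc_encoded(enc, params, constraints) -> dict[str, tuple[str, ...]]:
    raw = {t: set(_mmpc_one(enc, t, params, constraints)) for t in enc.names}
    # symmetry correction: keep X in CPC(T) only if T in CPC(X)
    return {
        t: tuple(sorted(x for x in raw[t] if t in raw[x]))
        for t in enc.names
    }


def mmpc(cohort: Cohort, params: ScoreParams = ScoreParams(),
         constraints: ConstraintSet = ConstraintSet()) -> dict[str, tuple[str, ...]]:
    if cohort.n == 0:
        raise ValueError("empty cohort")
    enc = EncodedData.from_cohort(cohort)
    return _mmpc_encoded(enc, params, constraints)


# --------------------------------------------------------------------------
# BDeu scoring
# --------------------------------------------------------------------------


def _bdeu_local(enc: EncodedData, child: str, parents: tuple[str, ...],
                ess: float) -> float:
    r = int(enc.cards[enc.index[child]])
    pidx, q = enc.config_index(parents)
    njk = np.bincount(pidx * r + enc.codes[:, enc.index[child]],
                      minlength=q * r).reshape(q, r).astype(float)
    nj = njk.sum(axis=1)
    a_j = ess / q
    a_jk = ess / (q * r)
    # empty parent configurations contribute exactly 0
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + nj))
        + np.sum(gammaln(a_jk + njk) - gammaln(a_jk))
    )
    return score


def bdeu_local(cohort: Cohort, child: str, parents=(), ess: float = 1.0) -> float:
    """Local BDeu log marginal-likelihood term for one node."""
    if ess <= 0:
        raise ValueError("ess must be > 0")
    parents = tuple(parents)
    enc = EncodedData.from_cohort(cohort, (child, *parents))
    return _bdeu_local(enc, child, parents, ess)


def score_dag(dag: Dag, cohort: Cohort, ess: float = 1.0) -> float:
    """Total (decomposable) BDeu score: sum of local terms."""
    enc = EncodedData.from_cohort(cohort, dag.nodes)
    return sum(_bdeu_local(enc, v, tuple(sorted(dag.parents(v))), ess)
               for v in dag.nodes)


# --------------------------------------------------------------------------
# hill climbing
# --------------------------------------------------------------------------


class _Search:
    def __init__(self, enc: EncodedData, ess: float):
        self.enc = enc
        self.ess = ess
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def local(self, child: str, parents: frozenset[str]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = _bdeu_local(self.enc, child, key[1], self.ess)
        return self._cache[key]


def _creates_cycle(parents: dict[str, set[str]], u: str, v: str) -> bool:
    """Would adding u -> v create a cycle? True iff v reaches u already."""
    children = {x: [] for x in parents}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
    # search from v through descendants for u
    stack, seen = [v], {v}
    while stack:
        x = stack.pop()
        if x == u:
            return True
        for w in children[x]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _hill_climb_encoded(enc: EncodedData, constraints: ConstraintSet,
                        candidates, params: ScoreParams) -> Dag:
    nodes = tuple(sorted(enc.names))
    search = _Search(enc, params.ess)
    parents: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in sorted(constraints.whitelist):
        if u in parents and v in parents:
            parents[v].add(u)

    def allowed_add(u: str, v: str) -> bool:
        if (u, v) in constraints.blacklist:
            return False
        if candidates is not None and (u, v) not in constraints.whitelist:
            if u not in candidates.get(v, ()):
                return False
        return True

    while True:
        best_gain, best_move = _EPS_GAIN, None
        cur = {v: search.local(v, frozenset(parents[v])) for v in nodes}
        # additions
        for u in nodes:
            for v in nodes:
                if u == v or u in parents[v] or v in parents[u]:
                    continue
                if not allowed_add(u, v) or _creates_cycle(parents, u, v):
                    continue
                gain = search.local(v, frozenset(parents[v] | {u})) - cur[v]
                if gain > best_gain:
                    best_gain, best_move = gain, ("add", u, v)
        # deletions
        for v in nodes:
            for u in sorted(parents[v]):
                if (u, v) in constraints.whitelist:
                    continue
                gain = search.local(v, frozenset(parents[v] - {u})) - cur[v]
                if gain > best_gain:
                    best_gain, best_move = gain, ("delete", u, v)
        # reversals
        for v in nodes:
            for u in sorted(parents[v]):
                if (u, v) in constraints.whitelist or (v, u) in constraints.blacklist:
                    continue
                if candidates is not None and (v, u) not in constraints.whitelist \
                        and v not in candidates.get(u, ()):
                    continue
                parents[v].discard(u)
                cycle = _creates_cycle(parents, v, u)
                parents[v].add(u)
                if cycle:
                    continue
                gain = (search.local(v, frozenset(parents[v] - {u})) - cur[v]
                        + search.local(u, frozenset(parents[u] | {v})) - cur[u])
                if gain > best_gain:
                    best_gain, best_move = gain, ("reverse", u, v)
        if best_move is None:
            break
        kind, u, v = best_move
        if kind == "add":
            parents[v].add(u)
        elif kind == "delete":
            parents[v].discard(u)
        else:
            parents[v].discard(u)
            parents[u].add(v)
        arcs = [(p, c) for c in nodes for p in parents[c]]
        if _find_cycle(nodes, arcs):  # checked, not assumed
            raise RuntimeError(f"move {best_move} produced a cycle")

    arcs = tuple(sorted((p, c) for c in nodes for p in sorted(parents[c])))
    return Dag(nodes, arcs)


def hill_climb(cohort: Cohort, constraints: ConstraintSet = ConstraintSet(),
               candidates=None, params: ScoreParams = ScoreParams()) -> Dag:
    """Greedy BDeu search from the whitelist-only graph.

    At each step the single arc addition/deletion/reversal with the largest
    strictly positive gain is applied, among moves keeping acyclicity and
    honoring the constraint set (and restriction map, if given).
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    enc = EncodedData.from_cohort(cohort)
    return _hill_climb_encoded(enc, constraints, candidates, params)


def _mmhc_encoded(enc, params, constraints) -> Dag:
    cand = _mmpc_encoded(enc, params, constraints)
    return _hill_climb_encoded(enc, constraints, cand, params)


def mmhc(cohort: Cohort, params: ScoreParams = ScoreParams(),
         constraints: ConstraintSet = ConstraintSet()) -> Dag:
    """Max-Min Hill-Climbing: hill climbing restricted to the MMPC
    candidate sets (plus whitelisted arcs)."""
    if cohort.n == 0:
        raise ValueError("empty cohort")
    enc = EncodedData.from_cohort(cohort)
    return _mmhc_encoded(enc, params, constraints)
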