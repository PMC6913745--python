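"""Discrete Bayesian networks: CPT estimation, exact queries by variable
elimination, sequential query trees, ancestral sampling and per-patient
prediction of the estimate."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_model import MISSING, Cohort, VariableSpec
from .structure_learning import Dag

__all__ = [
    "Cpt",
    "BayesNet",
    "QueryTreeNode",
    "InconsistentEvidenceError",
    "UndefinedRowError",
    "fit_cpts",
    "posterior",
    "joint_enumeration_posterior",
    "query_tree",
    "tree_to_frame",
    "ancestral_sample",
    "predict_estimate",
    "save_net",
    "load_net",
]

_ATOL = 1e-9


class InconsistentEvidenceError(ValueError):
    """The supplied evidence has probability zero under the network."""


class UndefinedRowError(ValueError):
    """A CPT row cannot be estimated (unobserved parent configuration and
    no pseudocount)."""


@dataclass(frozen=True)
class Cpt:
    """P(child | parents): ``table`` has one axis per parent (in order)
    plus a trailing axis over child states; every row sums to 1."""

    child: str
    parents: tuple[str, ...]
    table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "table", t)
        if (t < 0).any():
            raise ValueError(f"negative probability in CPT of {self.child!r}")
        if not np.allclose(t.sum(axis=-1), 1.0, atol=_ATOL):
            raise ValueError(f"CPT rows of {self.child!r} do not sum to 1")
        if t.ndim != len(self.parents) + 1:
            raise ValueError(f"CPT of {self.child!r} has wrong rank")


@dataclass(frozen=True)
class BayesNet:
    dag: Dag
    states: dict[str, tuple[str, ...]]
    cpts: dict[str, Cpt]

    def __post_init__(self) -> None:
        for v in self.dag.nodes:
            if v not in self.states or v not in self.cpts:
                raise ValueError(f"node {v!r} lacks states or CPT")
            cpt = self.cpts[v]
            if tuple(cpt.parents) != tuple(sorted(self.dag.parents(v))):
                raise ValueError(f"CPT parents of {v!r} disagree with the DAG")
            shape = tuple(len(self.states[p]) for p in cpt.parents)
            shape += (len(self.states[v]),)
            if cpt.table.shape != shape:
                raise ValueError(f"CPT of {v!r} has shape {cpt.table.shape}, "
                                 f"expected {shape}")

    def state_index(self, var: str, state: str) -> int:
        try:
            return self.states[var].index(state)
        except ValueError:
            raise ValueError(f"{state!r} is not a state of {var!r}") from None


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def fit_cpts(dag: Dag, cohort: Cohort, pseudocount: float = 1.0) -> BayesNet:
    """Maximum a-posteriori CPT rows ``(N_jk + pc) / (N_j + r * pc)``."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    states = {v: cohort.spec(v).states for v in dag.nodes}
    codes = {v: cohort.codes(v) for v in dag.nodes}
    cpts = {}
    for v in dag.nodes:
        parents = tuple(sorted(dag.parents(v)))
        r = len(states[v])
        pcards = [len(states[p]) for p in parents]
        q = int(np.prod(pcards)) if parents else 1
        idx = np.zeros(cohort.n, np.int64)
        for p in parents:
            idx = idx * len(states[p]) + codes[p]
        njk = np.bincount(idx * r + codes[v], minlength=q * r).reshape(q, r)
        nj = njk.sum(axis=1, keepdims=True)
        if pseudocount == 0 and (nj == 0).any():
            j = int(np.flatnonzero(nj[:, 0] == 0)[0])
            raise UndefinedRowError(
                f"unobserved parent configuration {j} for {v!r} with pseudocount 0"
            )
        table = (njk + pseudocount) / (nj + r * pseudocount)
        cpts[v] = Cpt(v, parents, table.reshape(*pcards, r))
    return BayesNet(dag, states, cpts)


# --------------------------------------------------------------------------
# factors and variable elimination
# --------------------------------------------------------------------------


def _cpt_factor(bn: BayesNet, v: str):
    cpt = bn.cpts[v]
    return (cpt.parents + (v,), cpt.table)


def _reduce(factor, var: str, idx: int):
    vars_, table = factor
    if var not in vars_:
        return factor
    axis = vars_.index(var)
    return (vars_[:axis] + vars_[axis + 1:], np.take(table, idx, axis=axis))


def _multiply(f1, f2):
    v1, t1 = f1
    v2, t2 = f2
    out_vars = v1 + tuple(v for v in v2 if v not in v1)
    sl1 = tuple(slice(None) if v in v1 else None for v in out_vars)
    a1 = t1.transpose([v1.index(v) for v in out_vars if v in v1])[sl1]
    sl2 = tuple(slice(None) if v in v2 else None for v in out_vars)
    a2 = t2.transpose([v2.index(v) for v in out_vars if v in v2])[sl2]
    return (out_vars, a1 * a2)


def _sum_out(factor, var: str):
    vars_, table = factor
    axis = vars_.index(var)
    return (vars_[:axis] + vars_[axis + 1:], table.sum(axis=axis))


def _eliminate(factors, hidden):
    """Sum-product elimination with a min-degree ordering."""
    factors = list(factors)
    hidden = set(hidden)
    while hidden:
        # min-degree: eliminate the variable touching fewest other variables
        degree = {}
        for h in hidden:
            nbrs = set()
            for vars_, _ in factors:
                if h in vars_:
                    nbrs |= set(vars_)
            nbrs.discard(h)
            degree[h] = len(nbrs)
        h = min(sorted(hidden), key=lambda v: degree[v])
        touching = [f for f in factors if h in f[0]]
        rest = [f for f in factors if h not in f[0]]
        prod = touching[0]
        for f in touching[1:]:
            prod = _multiply(prod, f)
        rest.append(_sum_out(prod, h))
        factors = rest
        hidden.discard(h)
    prod = ((), np.array(1.0))
    for f in factors:
        prod = _multiply(prod, f)
    return prod


def posterior(bn: BayesNet, target: str, evidence: dict[str, str] | None = None
              ) -> dict[str, float]:
    """Exact conditional distribution of ``target`` by variable elimination."""
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError("target cannot be part of the evidence")
    factors = []
    for v in bn.dag.nodes:
        f = _cpt_factor(bn, v)
        for e_var, e_state in evidence.items():
            f = _reduce(f, e_var, bn.state_index(e_var, e_state))
        factors.append(f)
    hidden = [v for v in bn.dag.nodes if v != target and v not in evidence]
    vars_, table = _eliminate(factors, hidden)
    table = np.asarray(table, float).reshape(len(bn.states[target]))
    z = table.sum()
    if z <= 0:
        raise InconsistentEvidenceError(f"evidence {evidence!r} has probability 0")
    probs = table / z
    return {s: float(p) for s, p in zip(bn.states[target], probs)}


def evidence_probability(bn: BayesNet, evidence: dict[str, str]) -> float:
    """P(evidence) by eliminating every other variable."""
    factors = []
    for v in bn.dag.nodes:
        f = _cpt_factor(bn, v)
        for e_var, e_state in evidence.items():
            f = _reduce(f, e_var, bn.state_index(e_var, e_state))
        factors.append(f)
    hidden = [v for v in bn.dag.nodes if v not in evidence]
    _, table = _eliminate(factors, hidden)
    return float(np.asarray(table).reshape(()))


def joint_enumeration_posterior(bn: BayesNet, target: str,
                                evidence: dict[str, str] | None = None
                                ) -> dict[str, float]:
    """Brute-force oracle: build the full joint table and condition on the
    evidence by summation.  Exponential; for small nets and tests only."""
    evidence = dict(evidence or {})
    order = bn.dag.nodes
    joint = ((), np.array(1.0))
    for v in order:
        joint = _multiply(joint, _cpt_factor(bn, v))
    vars_, table = joint
    for e_var, e_state in evidence.items():
        axis = vars_.index(e_var)
        table = np.take(table, bn.state_index(e_var, e_state), axis=axis)
        vars_ = vars_[:axis] + vars_[axis + 1:]
    axis = vars_.index(target)
    table = table.sum(axis=tuple(i for i in range(table.ndim) if i != axis))
    z = table.sum()
    if z <= 0:
        raise InconsistentEvidenceError("zero-probability evidence")
    return {s: float(p) for s, p in zip(bn.states[target], table / z)}


# --------------------------------------------------------------------------
# query trees
# --------------------------------------------------------------------------


@dataclass
class QueryTreeNode:
    evidence: dict[str, str]
    probability: float           # P(accumulated evidence)
    branch_probability: float    # P(this split | parent evidence); 1 at root
    target_dist: dict[str, float]
    children: list["QueryTreeNode"] = field(default_factory=list)


def query_tree(bn: BayesNet, target: str, ordered_vars) -> QueryTreeNode:
    """Sequential conditional-probability tree over ``ordered_vars``.

    Each node holds the accumulated evidence, its probability, and the
    conditional distribution of the target; zero-probability branches are
    pruned so children's branch probabilities still sum to 1.
    """
    ordered_vars = tuple(ordered_vars)
    if target in ordered_vars:
        raise ValueError("target cannot appear among the split variables")

    def build(evidence: dict[str, str], prob: float, branch_p: float,
              depth: int) -> QueryTreeNode:
        node = QueryTreeNode(dict(evidence), prob, branch_p,
                             posterior(bn, target, evidence))
        if depth < len(ordered_vars):
            split = ordered_vars[depth]
            split_dist = posterior(bn, split, evidence)
            for state in bn.states[split]:
                p = split_dist[state]
                if p <= 0:
                    continue
                child_ev = dict(evidence)
                child_ev[split] = state
                node.children.append(build(child_ev, prob * p, p, depth + 1))
        return node

    return build({}, 1.0, 1.0, 0)


def tree_to_frame(root: QueryTreeNode, ordered_vars, target_states) -> pd.DataFrame:
    """Flatten a query tree into rows of (evidence, branch and path
    probabilities, target distribution)."""
    rows = []

    def walk(node: QueryTreeNode, depth: int) -> None:
        row = {"depth": depth}
        for v in ordered_vars:
            row[v] = node.evidence.get(v, "")
        row["branch_probability"] = node.branch_probability
        row["path_probability"] = node.probability
        for s in target_states:
            row[f"p_{s}"] = node.target_dist[s]
        rows.append(row)
        for child in node.children:
            walk(child, depth + 1)

    walk(root, 0)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# sampling and prediction
# --------------------------------------------------------------------------


def ancestral_sample(bn: BayesNet, n: int, seed: int | np.random.Generator,
                     specs: tuple[VariableSpec, ...] | None = None) -> Cohort:
    """I.i.d. draws in topological order; reproducible for a fixed seed."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = bn.dag.topological_order()
    drawn: dict[str, np.ndarray] = {}
    for v in order:
        cpt = bn.cpts[v]
        r = len(bn.states[v])
        idx = np.zeros(n, np.int64)
        for p in cpt.parents:
            idx = idx * len(bn.states[p]) + drawn[p]
        rows = cpt.table.reshape(-1, r)[idx]
        cum = np.cumsum(rows, axis=1)
        u = rng.random(n)
        drawn[v] = (u[:, None] > cum).sum(axis=1).clip(0, r - 1)
    if specs is None:
        specs = tuple(VariableSpec(v, bn.states[v]) for v in bn.dag.nodes)
    data = pd.DataFrame({
        s.name: np.asarray(bn.states[s.name], object)[drawn[s.name]]
        for s in specs
    })
    return Cohort(specs, data)


def predict_estimate(bn: BayesNet, record: dict[str, str],
                     target: str = "estimate") -> dict[str, float]:
    """Posterior of the estimate given a patient record.

    By Markov-blanket sufficiency the answer only depends on the blanket
    variables; any covered record yields the same distribution.
    """
    evidence = {k: v for k, v in record.items() if k != target and v != MISSING}
    blanket = bn.dag.markov_blanket(target)
    uncovered = blanket - set(evidence)
    if uncovered:
        raise ValueError(f"record does not cover the Markov blanket of "
                         f"{target!r}: missing {sorted(uncovered)}")
    return posterior(bn, target, evidence)


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def save_net(bn: BayesNet, path: str | Path) -> None:
    doc = {
        "nodes": list(bn.dag.nodes),
        "arcs": [list(a) for a in bn.dag.arcs],
        "states": {v: list(s) for v, s in bn.states.items()},
        "cpts": {
            v: {"parents": list(c.parents), "table": c.table.tolist()}
            for v, c in bn.cpts.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_net(path: str | Path) -> BayesNet:
    doc = json.loads(Path(path).read_text())
    dag = Dag(tuple(doc["nodes"]), tuple(tuple(a) for a in doc["arcs"]))
    states = {v: tuple(s) for v, s in doc["states"].items()}
    cpts = {
        v: Cpt(v, tuple(c["parents"]), np.array(c["table"], float))
        for v, c in doc["cpts"].items()
    }
    return BayesNet(dag, states, cpts)
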