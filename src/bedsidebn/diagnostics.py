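"""Diagnostic-accuracy statistics for the dichotomized estimate against the
dichotomized cardiac index: 2x2 tables, sensitivity/specificity/predictive
values with Wilson CIs, likelihood ratios with log-method CIs, exhaustive
reconstruction of the published pooled table, and 10-fold cross-validated
network prediction."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort_model import MISSING, Cohort
from .inference import fit_cpts, posterior
from .structure_learning import Dag

__all__ = [
    "TwoByTwo",
    "ConfInt",
    "DxMetrics",
    "CvResult",
    "ReconstructionError",
    "dichotomize_estimate",
    "dichotomize_ci",
    "crosstab",
    "wilson_interval",
    "dx_metrics",
    "metrics_frame",
    "reconstruct_overall_table",
    "auroc",
    "cross_validate",
    "round_half_away",
]

ESTIMATE_LOW = ("poor", "moderate")
ESTIMATE_HIGH = ("reasonable", "good")
CI_CUTOFF = 2.2

Z95 = 1.959963984540054  # norm.ppf(0.975)


class ReconstructionError(ValueError):
    """No (or more than one) integer table matches the printed summaries."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero, the convention of the printed tables."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def dichotomize_estimate(state: str) -> str:
    if state in ESTIMATE_LOW:
        return "low"
    if state in ESTIMATE_HIGH:
        return "high"
    raise ValueError(f"unknown estimate state {state!r}")


def dichotomize_ci(value: float, cutoff: float = CI_CUTOFF) -> str:
    if value <= 0:
        raise ValueError(f"cardiac index must be positive, got {value}")
    return "low" if value <= cutoff else "high"


@dataclass(frozen=True)
class TwoByTwo:
    """Rows: estimate low/high; columns: cardiac index low/high."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def crosstab(pred, truth) -> TwoByTwo:
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError("pred and truth differ in length")
    for seq, name in ((pred, "pred"), (truth, "truth")):
        bad = set(seq) - {"low", "high"}
        if bad:
            raise ValueError(f"{name} contains non-dichotomized values {bad}")
    tp = sum(p == "low" and t == "low" for p, t in zip(pred, truth))
    fp = sum(p == "low" and t == "high" for p, t in zip(pred, truth))
    fn = sum(p == "high" and t == "low" for p, t in zip(pred, truth))
    tn = sum(p == "high" and t == "high" for p, t in zip(pred, truth))
    return TwoByTwo(tp, fp, fn, tn)


@dataclass(frozen=True)
class ConfInt:
    point: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.point <= self.high or
                any(map(math.isnan, (self.low, self.point, self.high)))):
            raise ValueError("point estimate outside its interval")


def wilson_interval(k: int, n: int, z: float = Z95) -> ConfInt:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return ConfInt(math.nan, math.nan, math.nan)
    p = k / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # guard the containment identity against the last ulp of rounding
    return ConfInt(p, min(max(center - half, 0.0), p),
                   max(min(center + half, 1.0), p))


def _lr_interval(lr: float, se_terms: list[tuple[int, int]], z: float = Z95
                 ) -> ConfInt:
    """Log-method CI: exp(ln LR +/- z * sqrt(sum(1/k - 1/n)))."""
    if math.isinf(lr) or lr == 0 or any(k == 0 for k, _ in se_terms):
        return ConfInt(lr, math.nan, math.nan)
    se = math.sqrt(sum(1.0 / k - 1.0 / n for k, n in se_terms))
    return ConfInt(lr, math.exp(math.log(lr) - z * se),
                   math.exp(math.log(lr) + z * se))


@dataclass(frozen=True)
class DxMetrics:
    sensitivity: ConfInt
    specificity: ConfInt
    ppv: ConfInt
    npv: ConfInt
    accuracy: ConfInt
    lr_pos: ConfInt
    lr_neg: ConfInt


def dx_metrics(t: TwoByTwo) -> DxMetrics:
    """Point estimates with 95% CIs (Wilson for proportions, log method for
    likelihood ratios).  Zero denominators yield NaN points; an infinite
    LR+ is allowed (undefined CI)."""
    diseased = t.tp + t.fn
    healthy = t.fp + t.tn
    sens = wilson_interval(t.tp, diseased)
    spec = wilson_interval(t.tn, healthy)
    ppv = wilson_interval(t.tp, t.tp + t.fp)
    npv = wilson_interval(t.tn, t.tn + t.fn)
    acc = wilson_interval(t.tp + t.tn, t.total)
    if diseased == 0 or healthy == 0:
        lr_pos = ConfInt(math.nan, math.nan, math.nan)
        lr_neg = ConfInt(math.nan, math.nan, math.nan)
    else:
        s, c = t.tp / diseased, t.tn / healthy
        lrp = math.inf if c == 1.0 else s / (1.0 - c)
        lrn = math.nan if c == 0.0 else (1.0 - s) / c
        lr_pos = _lr_interval(lrp, [(t.tp, diseased), (t.fp, healthy)])
        lr_neg = _lr_interval(lrn, [(t.fn, diseased), (t.tn, healthy)])
    return DxMetrics(sens, spec, ppv, npv, acc, lr_pos, lr_neg)


def metrics_frame(m: DxMetrics) -> pd.DataFrame:
    """Published-table layout: one row per metric with point and CI bounds."""
    rows = []
    for name in ("sensitivity", "specificity", "ppv", "npv",
                 "lr_pos", "lr_neg", "accuracy"):
        ci: ConfInt = getattr(m, name)
        rows.append((name, ci.point, ci.low, ci.high))
    return pd.DataFrame(rows, columns=["metric", "point", "ci_low", "ci_high"])


# --------------------------------------------------------------------------
# reconstruction of the published pooled table
# --------------------------------------------------------------------------

#: printed overall column used as rounding constraints: point values in
#: percent (0 decimals) or ratio (2 decimals), plus the four LR CI bounds
PRINTED_OVERALL = {
    "sensitivity": 30, "specificity": 80, "ppv": 46, "npv": 67,
    "accuracy": 62, "lr_pos": 1.53, "lr_neg": 0.87,
    "lr_pos_ci": (1.19, 1.97), "lr_neg_ci": (0.80, 0.95),
}


def reconstruct_overall_table(low_margin: int = 183, high_margin: int = 600,
                              printed: dict | None = None) -> TwoByTwo:
    """Recover the integer 2x2 table behind the printed pooled summaries.

    Exhaustive search over (tp, tn) with ``fp = low_margin - tp`` and
    ``fn = high_margin - tn``; a candidate qualifies when every printed
    point value and all four likelihood-ratio CI bounds round (half away
    from zero) to the printed figures.  Exactly one table must qualify.
    """
    if low_margin <= 0 or high_margin <= 0:
        raise ValueError("margins must be positive")
    printed = dict(PRINTED_OVERALL if printed is None else printed)
    total = low_margin + high_margin
    tp = np.arange(low_margin + 1)[:, None].astype(float)
    tn = np.arange(high_margin + 1)[None, :].astype(float)
    fp = low_margin - tp
    fn = high_margin - tn
    with np.errstate(all="ignore"):
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        ppv = tp / (tp + fp)
        npv = tn / (tn + fn)
        acc = (tp + tn) / total
        lrp = sens / (1.0 - spec)
        lrn = (1.0 - sens) / spec
        se_p = np.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
        se_n = np.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        lrp_lo, lrp_hi = lrp * np.exp(-Z95 * se_p), lrp * np.exp(Z95 * se_p)
        lrn_lo, lrn_hi = lrn * np.exp(-Z95 * se_n), lrn * np.exp(Z95 * se_n)

    def rounds_to(arr: np.ndarray, target: float, nd: int) -> np.ndarray:
        scaled = np.floor(np.abs(arr) * 10.0 ** nd + 0.5) * np.sign(arr)
        return np.isfinite(arr) & (scaled / 10.0 ** nd == target)

    ok = np.ones_like(sens, dtype=bool)
    for key, arr in (("sensitivity", sens), ("specificity", spec),
                     ("ppv", ppv), ("npv", npv), ("accuracy", acc)):
        if key in printed:
            ok &= rounds_to(arr * 100.0, printed[key], 0)
    for key, arr in (("lr_pos", lrp), ("lr_neg", lrn)):
        if key in printed:
            ok &= rounds_to(arr, printed[key], 2)
    for key, (lo_arr, hi_arr) in (("lr_pos_ci", (lrp_lo, lrp_hi)),
                                  ("lr_neg_ci", (lrn_lo, lrn_hi))):
        if key in printed:
            lo, hi = printed[key]
            ok &= rounds_to(lo_arr, lo, 2) & rounds_to(hi_arr, hi, 2)
    matches = np.argwhere(ok)
    if len(matches) == 0:
        raise ReconstructionError("no table reproduces the printed summaries")
    if len(matches) > 1:
        raise ReconstructionError(
            f"{len(matches)} tables reproduce the printed summaries; "
            "the constraints are under-determined"
        )
    tp_i, tn_i = map(int, matches[0])
    return TwoByTwo(tp_i, low_margin - tp_i, high_margin - tn_i, tn_i)


# --------------------------------------------------------------------------
# cross-validated network prediction
# --------------------------------------------------------------------------


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula with tie
    correction; ``labels`` are "low"/"high" with low the positive class."""
    scores = np.asarray(list(scores), float)
    labels = np.asarray(list(labels), object)
    pos = labels == "low"
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: a single class present")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class CvResult:
    fold: np.ndarray              # fold id per cohort record
    p_low: np.ndarray             # predicted P(estimate low) per record
    predicted_class: np.ndarray   # dichotomized MAP estimate per record
    auroc: float
    sensitivity: float
    specificity: float
    n_validated: int


def cross_validate(cohort: Cohort, dag: Dag, folds: int = 10, seed: int = 0,
                   pseudocount: float = 1.0, target: str = "estimate",
                   outcome: str = "cardiac_index") -> CvResult:
    """10-fold cross-validated prediction of the estimate.

    The structure is fixed; CPTs are refitted on the training folds and
    each held-out record's estimate distribution is computed from its
    clinical variables.  Scores (predicted probability of a low estimate)
    are evaluated against the dichotomized cardiac index on the subset
    with a validated measurement.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if outcome not in cohort.variables:
        raise ValueError(f"cohort lacks the outcome column {outcome!r}")
    n = cohort.n
    rng = np.random.default_rng(seed)
    fold = np.empty(n, np.int64)
    fold[rng.permutation(n)] = np.arange(n) % folds
    clinical = [v for v in dag.nodes if v != target]
    states = cohort.spec(target).states
    low_idx = [i for i, s in enumerate(states) if dichotomize_estimate(s) == "low"]
    train_view = cohort.drop_variable(outcome)
    p_low = np.empty(n)
    pred_class = np.empty(n, object)
    for f in range(folds):
        train = train_view.subset(np.flatnonzero(fold != f))
        bn = fit_cpts(dag, train, pseudocount)
        memo: dict[tuple, dict[str, float]] = {}
        for i in np.flatnonzero(fold == f):
            key = tuple(cohort.data.at[i, v] for v in clinical)
            if key not in memo:
                memo[key] = posterior(bn, target, dict(zip(clinical, key)))
            dist = memo[key]
            p_low[i] = sum(dist[states[j]] for j in low_idx)
            map_state = max(states, key=lambda s: dist[s])
            pred_class[i] = dichotomize_estimate(map_state)
    validated = cohort.column(outcome).to_numpy() != MISSING
    truth = cohort.column(outcome).to_numpy()[validated]
    t = crosstab(pred_class[validated], truth)
    sens = t.tp / (t.tp + t.fn) if t.tp + t.fn else math.nan
    spec = t.tn / (t.tn + t.fp) if t.tn + t.fp else math.nan
    return CvResult(fold, p_low, pred_class,
                    auroc(p_low[validated], truth), sens, spec,
                    int(validated.sum()))
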