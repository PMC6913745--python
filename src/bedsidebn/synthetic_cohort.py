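"""Calibrated ground-truth network and synthetic cohort generator.

The study cohort is not publicly deposited, so analyses run against a
generative stand-in: a network with the published consensus structure whose
parameters are solved so that exact forward inference reproduces the
published marginal prevalences and the four ventilation/noradrenaline
conditionals of the estimate.  The dichotomized cardiac index attaches to
the estimate alone and is masked completely at random at the published
missingness fraction.

Calibration is purely algebraic: for a binary node the conditional rows
are ``base + sum(effect of each active parent)``, so its exact marginal is
``base + sum(effect * parent marginal)`` and ``base`` solves a linear
equation.  The estimate's CPT comes from a 2x2 linear system linking the
published ventilation-conditioned probabilities to the (unpublished)
dependence of peripheral-perfusion signs on ventilation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort_model import MISSING, Cohort, VariableSpec
from .inference import BayesNet, Cpt, ancestral_sample, posterior
from .structure_learning import Dag

__all__ = [
    "GroundTruthSpec",
    "CalibrationReport",
    "CalibrationError",
    "default_spec",
    "variable_specs",
    "consensus_dag",
    "expert_orientation",
    "build_ground_truth",
    "calibration_report",
    "generate",
    "implied_accuracy",
]

ESTIMATE = "estimate"
OUTCOME = "cardiac_index"
LOW_STATES = ("poor", "moderate")
HIGH_STATES = ("reasonable", "good")


class CalibrationError(ValueError):
    """A calibration target cannot be met with probabilities in [0, 1]."""


@dataclass(frozen=True)
class GroundTruthSpec:
    """Complete parameterization of the generative stand-in cohort."""

    arcs: tuple[tuple[str, str], ...]
    marginals: dict[str, float]
    effects: dict[str, dict[str, float]]
    p_dcrtm_given_mv: tuple[float, float]          # (MV = no, MV = yes)
    p_erg_targets: dict[str, float]                # keys mv_{yes,no}_na_{yes,no}
    estimate_splits: tuple[float, float]           # poor|low, reasonable|high
    outcome: tuple[float, float]                   # P(CI low | est low/high)
    missingness: float
    variables: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in [("missingness", self.missingness),
                            *self.marginals.items(),
                            ("p_dcrtm_given_mv", self.p_dcrtm_given_mv[0]),
                            ("p_dcrtm_given_mv", self.p_dcrtm_given_mv[1]),
                            *self.p_erg_targets.items(),
                            ("outcome", self.outcome[0]),
                            ("outcome", self.outcome[1])]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} = {value} outside [0, 1]")


@dataclass(frozen=True)
class CalibrationReport:
    """Achieved-vs-target check computed by exact inference (no sampling)."""

    marginals: dict[str, tuple[float, float]]      # var -> (target, achieved)
    conditionals: dict[str, tuple[float, float]]   # query -> (target, achieved)
    max_abs_deviation: float


def _load_defaults() -> dict:
    ref = importlib.resources.files("bedsidebn").joinpath("data/defaults.yaml")
    return yaml.safe_load(ref.read_text())


def default_spec(config: dict | str | Path | None = None) -> GroundTruthSpec:
    """Spec from the packaged defaults, or an override config file/dict."""
    if config is None:
        doc = _load_defaults()
    elif isinstance(config, dict):
        doc = config
    else:
        doc = yaml.safe_load(Path(config).read_text())
    gt = doc["ground_truth"]
    return GroundTruthSpec(
        arcs=tuple(tuple(a) for a in gt["arcs"]),
        marginals=dict(gt["marginals"]),
        effects={k: dict(v) for k, v in gt["effects"].items()},
        p_dcrtm_given_mv=(float(gt["p_dcrtm_given_mv"]["no"]),
                          float(gt["p_dcrtm_given_mv"]["yes"])),
        p_erg_targets=dict(gt["p_erg_targets"]),
        estimate_splits=(float(gt["estimate_splits"]["poor_within_low"]),
                         float(gt["estimate_splits"]["reasonable_within_high"])),
        outcome=(float(gt["outcome"]["p_low_given_estimate_low"]),
                 float(gt["outcome"]["p_low_given_estimate_high"])),
        missingness=float(gt["missingness"]),
        variables={k: dict(v) for k, v in doc["variables"].items()},
    )


def variable_specs(spec: GroundTruthSpec) -> tuple[VariableSpec, ...]:
    return tuple(
        VariableSpec(name, tuple(v["states"]), v.get("role", "clinical"))
        for name, v in spec.variables.items()
    )


def consensus_dag(spec: GroundTruthSpec) -> Dag:
    """The 15-node structure (clinical variables + estimate, no outcome)."""
    nodes = tuple(v for v in spec.variables if v != OUTCOME)
    return Dag(nodes, spec.arcs)


def expert_orientation() -> dict[tuple[str, str], tuple[str, str]]:
    """Orientation of the one edge left undirected by the bootstrap."""
    return {("high_respiratory_rate", "mechanical_ventilation"):
            ("high_respiratory_rate", "mechanical_ventilation")}


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


def _solve_estimate_rows(spec: GroundTruthSpec) -> dict[tuple[int, int], float]:
    """P(estimate reasonable-or-good | noradrenaline, dcrtm).

    For each noradrenaline level the two published ventilation-conditioned
    targets give two linear equations in the two unknown rows, because
    conditioning on ventilation only changes the mixing weight over dcrtm:
    ``P(ERG | MV, NA) = sum_d P(dcrtm = d | MV) * P(ERG | NA, d)``.
    """
    p0, p1 = spec.p_dcrtm_given_mv
    t = spec.p_erg_targets
    rows: dict[tuple[int, int], float] = {}
    for na, (mv_yes_key, mv_no_key) in (
            (1, ("mv_yes_na_yes", "mv_no_na_yes")),
            (0, ("mv_yes_na_no", "mv_no_na_no"))):
        a = np.array([[p1, 1.0 - p1], [p0, 1.0 - p0]])
        b = np.array([t[mv_yes_key], t[mv_no_key]])
        if abs(np.linalg.det(a)) < 1e-12:
            raise CalibrationError("p_dcrtm_given_mv levels coincide; the "
                                   "estimate rows are not identifiable")
        erg_d1, erg_d0 = np.linalg.solve(a, b)
        for d, value in ((1, erg_d1), (0, erg_d0)):
            if not 0.0 <= value <= 1.0:
                raise CalibrationError(
                    f"P(estimate reasonable-or-good | noradrenaline={na}, "
                    f"dcrtm={d}) = {value:.4f} outside [0, 1]"
                )
            rows[(na, d)] = float(value)
    return rows


def build_ground_truth(spec: GroundTruthSpec) -> BayesNet:
    """Calibrated 16-node network (15 consensus nodes + cardiac index)."""
    dag15 = consensus_dag(spec)
    est_parents = set(dag15.parents(ESTIMATE))
    if est_parents != {"noradrenaline", "dcrtm"}:
        raise CalibrationError(
            f"estimate parents must be noradrenaline and dcrtm, got {sorted(est_parents)}"
        )
    nodes = dag15.nodes + (OUTCOME,)
    arcs = dag15.arcs + ((ESTIMATE, OUTCOME),)
    dag = Dag(nodes, arcs)
    states = {name: tuple(v["states"]) for name, v in spec.variables.items()}

    # exact marginals accumulate in topological order; every binary child's
    # marginal is linear in its base rate
    marg: dict[str, float] = {}
    cpts: dict[str, Cpt] = {}
    for v in dag.topological_order():
        parents = tuple(sorted(dag.parents(v)))
        if v == ESTIMATE:
            cpts[v] = _estimate_cpt(spec, parents, states)
            continue
        if v == OUTCOME:
            p_lo, p_hi = spec.outcome
            table = np.array([[p_lo, 1 - p_lo], [p_lo, 1 - p_lo],
                              [p_hi, 1 - p_hi], [p_hi, 1 - p_hi]])
            cpts[v] = Cpt(v, parents, table)
            continue
        if v == "dcrtm":
            p0, p1 = spec.p_dcrtm_given_mv
            cpts[v] = Cpt(v, parents, np.array([[1 - p0, p0], [1 - p1, p1]]))
            marg[v] = (1 - marg["mechanical_ventilation"]) * p0 \
                + marg["mechanical_ventilation"] * p1
            continue
        target = spec.marginals.get(v)
        if target is None:
            raise CalibrationError(f"no marginal target or rule for {v!r}")
        effects = spec.effects.get(v, {})
        unknown = set(effects) - set(parents)
        if unknown:
            raise CalibrationError(f"effects of {v!r} name non-parents {unknown}")
        base = target - sum(effects.get(p, 0.0) * marg[p] for p in parents)
        shape = [2] * len(parents)
        table = np.empty((*shape, 2))
        for config in np.ndindex(*shape) if parents else [()]:
            p_yes = base + sum(effects.get(p, 0.0) * config[i]
                               for i, p in enumerate(parents))
            if not 0.0 <= p_yes <= 1.0:
                raise CalibrationError(
                    f"P({v} = yes | {dict(zip(parents, config))}) = "
                    f"{p_yes:.4f} outside [0, 1]"
                )
            table[config] = (1.0 - p_yes, p_yes)
        cpts[v] = Cpt(v, parents, table if parents else table.reshape(2))
        marg[v] = target
    return BayesNet(dag, states, cpts)


def _estimate_cpt(spec: GroundTruthSpec, parents: tuple[str, ...],
                  states: dict[str, tuple[str, ...]]) -> Cpt:
    erg = _solve_estimate_rows(spec)
    poor_in_low, reasonable_in_high = spec.estimate_splits
    # parents are sorted: (dcrtm, noradrenaline)
    assert parents == ("dcrtm", "noradrenaline")
    table = np.empty((2, 2, 4))
    for d in (0, 1):
        for na in (0, 1):
            p_high = erg[(na, d)]
            p_low = 1.0 - p_high
            table[d, na] = (
                p_low * poor_in_low,
                p_low * (1.0 - poor_in_low),
                p_high * reasonable_in_high,
                p_high * (1.0 - reasonable_in_high),
            )
    assert states[ESTIMATE] == ("poor", "moderate", "reasonable", "good")
    return Cpt(ESTIMATE, parents, table)


def calibration_report(spec: GroundTruthSpec,
                       bn: BayesNet | None = None) -> CalibrationReport:
    """Exact-inference audit of every calibration target."""
    bn = bn if bn is not None else build_ground_truth(spec)
    marginals = {}
    for v, target in spec.marginals.items():
        achieved = posterior(bn, v)["yes"]
        marginals[v] = (target, achieved)
    conditionals = {}
    for key, target in spec.p_erg_targets.items():
        _, mv, _, na = key.split("_")
        ev = {"mechanical_ventilation": mv, "noradrenaline": na}
        dist = posterior(bn, ESTIMATE, ev)
        achieved = sum(dist[s] for s in HIGH_STATES)
        conditionals[key] = (target, achieved)
    devs = [abs(t - a) for t, a in marginals.values()]
    devs += [abs(t - a) for t, a in conditionals.values()]
    return CalibrationReport(marginals, conditionals, max(devs))


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def generate(spec: GroundTruthSpec, n: int, seed: int,
             bn: BayesNet | None = None) -> Cohort:
    """Seeded synthetic cohort with the outcome masked at random."""
    bn = bn if bn is not None else build_ground_truth(spec)
    rng = np.random.default_rng(seed)
    cohort = ancestral_sample(bn, n, rng, specs=variable_specs(spec))
    mask = rng.random(n) < spec.missingness
    data = cohort.data.copy()
    data.loc[mask, OUTCOME] = MISSING
    return Cohort(cohort.specs, data)


def implied_accuracy(spec: GroundTruthSpec,
                     p_estimate_low: float | None = None) -> tuple[float, float]:
    """Exact sensitivity/specificity implied by the outcome attachment.

    Bayes inversion of P(cardiac index low | dichotomized estimate) against
    the dichotomized estimate marginal (the network's own unless supplied).
    """
    if p_estimate_low is None:
        dist = posterior(build_ground_truth(spec), ESTIMATE)
        p_estimate_low = sum(dist[s] for s in LOW_STATES)
    p_lo, p_hi = spec.outcome
    joint_ll = p_lo * p_estimate_low            # estimate low, CI low
    joint_hl = p_hi * (1.0 - p_estimate_low)    # estimate high, CI low
    joint_lh = (1.0 - p_lo) * p_estimate_low    # estimate low, CI high
    joint_hh = (1.0 - p_hi) * (1.0 - p_estimate_low)
    sensitivity = joint_ll / (joint_ll + joint_hl)
    specificity = joint_hh / (joint_hh + joint_lh)
    return float(sensitivity), float(specificity)
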