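"""Simulate costs, admissions and ED visits under a stratification policy.

A patient who would incur cost h and experience n_e undesirable events
with no enrollment is estimated, once enrolled in a program with
parameters (c_i, p), to incur h + c_i - n_e * p * c_e, with events thinned
by the avoided fraction p. Two modes: *expectation* applies the formulas
exactly (deterministic); *stochastic* realizes uptake as Bernoulli draws
and event avoidance as binomial thinning. Aggregating over the holdout
year's patients yields policy outcomes, sensitivity grids over (c_i, p,
uptake), attribute-combination tables for model generalization, the
minimum model accuracy at which a policy still beats no enrollment, and
the paired statistical comparison of two policies (one-sided paired t on
log costs; McNemar on admission / ED indicators).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.contingency_tables import mcnemar

from .strata_optimizer import (
    NULL_LEVEL_NAME,
    ManagementLevel,
    PercentileStats,
    StratificationPolicy,
    compute_percentile_stats,
    optimize_thresholds,
)


@dataclass
class PatientTrajectory:
    """Baseline (no-enrollment) future cost and events for one patient."""

    patient_id: str
    h: float  # future cost with no enrollment
    n_e: float  # future undesirable-event count
    admissions: float = 0.0
    ed_visits: float = 0.0

    def __post_init__(self):
        if self.h < 0 or self.n_e < 0:
            raise ValueError("baseline cost and event count must be nonnegative")


@dataclass
class PolicyOutcome:
    total_cost: float
    total_admissions: float
    total_ed_visits: float
    enrollment: dict[str, int]
    params: dict
    per_patient: pd.DataFrame | None = None
    floored_count: int = 0

    def to_dict(self) -> dict:
        return {
            "total_cost": self.total_cost,
            "total_admissions": self.total_admissions,
            "total_ed_visits": self.total_ed_visits,
            "enrollment": self.enrollment,
            "params": self.params,
            "floored_count": self.floored_count,
        }


def trajectories_from_bundle(bundle, year: int) -> list[PatientTrajectory]:
    """Observed year-``year`` trajectories: cost, acute asthma events, breakdown."""
    from .cohort_features import _acute_asthma

    enc = bundle.encounters[bundle.encounters["year"] == year]
    acute = enc[_acute_asthma(enc)]
    cost = enc.groupby("patient_id")["cost"].sum()
    ev = acute.groupby("patient_id").size()
    adm = acute[acute["visit_type"] == "inpatient"].groupby("patient_id").size()
    ed = acute[acute["visit_type"] == "emergency"].groupby("patient_id").size()
    out = []
    for pid in bundle.patients["patient_id"]:
        out.append(
            PatientTrajectory(
                pid,
                float(cost.get(pid, 0.0)),
                float(ev.get(pid, 0)),
                float(adm.get(pid, 0)),
                float(ed.get(pid, 0)),
            )
        )
    return out


def simulate_patient(
    traj: PatientTrajectory,
    level: ManagementLevel,
    c_e: float,
    uptake: float = 1.0,
    mode: str = "expectation",
    rng: np.random.Generator | None = None,
) -> dict:
    """Adjusted cost and events for one patient under one level.

    Expectation mode scales the enrollment effect by the uptake fraction;
    stochastic mode draws enrollment ~ Bernoulli(uptake) and thins each
    event category binomially with probability p. Negative estimated
    costs are floored at zero and flagged.
    """
    if mode not in ("expectation", "stochastic"):
        raise ValueError("mode must be 'expectation' or 'stochastic'")
    if mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        enrolled = level.name != NULL_LEVEL_NAME and rng.random() < uptake
        eff = 1.0 if enrolled else 0.0
    else:
        eff = uptake if level.name != NULL_LEVEL_NAME else 0.0

    cost = traj.h + eff * (level.c_i - traj.n_e * level.p * c_e)
    floored = cost < 0
    cost = max(cost, 0.0)
    if mode == "stochastic" and eff:
        events = float(rng.binomial(int(traj.n_e), 1 - level.p))
        adm = float(rng.binomial(int(traj.admissions), 1 - level.p))
        ed = float(rng.binomial(int(traj.ed_visits), 1 - level.p))
    else:
        keep = 1 - eff * level.p
        events, adm, ed = traj.n_e * keep, traj.admissions * keep, traj.ed_visits * keep
    return {
        "cost": cost,
        "events": events,
        "admissions": adm,
        "ed_visits": ed,
        "enrolled": eff > 0,
        "floored": bool(floored),
    }


def simulate_policy(
    trajectories: list[PatientTrajectory],
    predictions: np.ndarray,
    policy: StratificationPolicy,
    c_e: float,
    uptake: float = 1.0,
    mode: str = "expectation",
    seed: int = 0,
    keep_per_patient: bool = True,
) -> PolicyOutcome:
    """Apply a stratification policy to a ranked population and aggregate.

    Patients are ranked by predicted risk (descending) and mapped onto the
    policy's percentile bins; each patient is simulated under the bin's
    assigned level. Deterministic given the seed.
    """
    n = len(trajectories)
    predictions = np.asarray(predictions, dtype=float)
    if len(predictions) != n:
        raise ValueError("predictions must align with trajectories")
    unknown = set(policy.assignments) - set(policy.levels)
    if unknown:
        raise KeyError(f"policy references unknown levels {sorted(unknown)}")
    order = np.argsort(-predictions, kind="stable")
    chunks = np.array_split(order, len(policy.assignments))
    rng = np.random.default_rng(seed)
    rows = []
    floored = 0
    enrollment: dict[str, int] = {}
    for b, chunk in enumerate(chunks):
        level = policy.levels[policy.assignments[b]]
        for i in chunk:
            r = simulate_patient(trajectories[i], level, c_e, uptake, mode, rng)
            r["patient_id"] = trajectories[i].patient_id
            r["level"] = level.name
            r["bin"] = b + 1
            r["_pos"] = int(i)
            floored += r.pop("floored")
            rows.append(r)
            if r["enrolled"] and level.name != NULL_LEVEL_NAME:
                enrollment[level.name] = enrollment.get(level.name, 0) + 1
    # aggregate in input order so an all-null policy reproduces the
    # baseline totals bit-exactly (float addition is order-sensitive)
    df = pd.DataFrame(rows).sort_values("_pos").drop(columns="_pos").reset_index(drop=True)
    return PolicyOutcome(
        total_cost=float(df["cost"].sum()),
        total_admissions=float(df["admissions"].sum()),
        total_ed_visits=float(df["ed_visits"].sum()),
        enrollment=enrollment,
        params={"c_e": c_e, "uptake": uptake, "mode": mode, "seed": seed},
        per_patient=df if keep_per_patient else None,
        floored_count=int(floored),
    )


def baseline_outcome(trajectories: list[PatientTrajectory]) -> PolicyOutcome:
    """Totals with no enrollment at all."""
    df = pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in trajectories],
            "cost": [t.h for t in trajectories],
            "events": [t.n_e for t in trajectories],
            "admissions": [t.admissions for t in trajectories],
            "ed_visits": [t.ed_visits for t in trajectories],
            "enrolled": False,
            "level": NULL_LEVEL_NAME,
        }
    )
    return PolicyOutcome(
        float(df["cost"].sum()),
        float(df["admissions"].sum()),
        float(df["ed_visits"].sum()),
        {},
        {"uptake": 0.0, "mode": "expectation"},
        per_patient=df,
    )


def sensitivity_grid(
    trajectories: list[PatientTrajectory],
    predictions: np.ndarray,
    levels: list[ManagementLevel],
    stats: PercentileStats,
    target_level: str,
    c_i_range: tuple[float, float],
    p_range: tuple[float, float],
    uptake_range: tuple[float, float],
    n_levels: int = 5,
    mode: str = "expectation",
    seed: int = 0,
) -> pd.DataFrame:
    """Full-factorial sensitivity table over (c_i, p, uptake).

    Each axis takes ``n_levels`` values from its minimum to maximum
    (5 x 5 x 5 = 125 rows by default); thresholds are re-optimized per
    cell.
    """
    for lo, hi in (c_i_range, p_range, uptake_range):
        if lo > hi:
            raise ValueError("range minimum exceeds maximum")
    rows = []
    for c_i in np.linspace(*c_i_range, n_levels):
        for p in np.linspace(*p_range, n_levels):
            varied = [
                ManagementLevel(lv.name, float(c_i), float(p), lv.capacity)
                if lv.name == target_level
                else lv
                for lv in levels
            ]
            policy = optimize_thresholds(varied, stats)
            for uptake in np.linspace(*uptake_range, n_levels):
                out = simulate_policy(
                    trajectories,
                    predictions,
                    policy,
                    stats.c_e,
                    float(uptake),
                    mode,
                    seed,
                    keep_per_patient=False,
                )
                rows.append(
                    {
                        "c_i": float(c_i),
                        "p": float(p),
                        "uptake": float(uptake),
                        "total_cost": out.total_cost,
                        "total_admissions": out.total_admissions,
                        "total_ed_visits": out.total_ed_visits,
                        "enrolled": sum(out.enrollment.values()),
                    }
                )
    return pd.DataFrame(rows)


def attribute_combination_table(
    matrix,
    groups: list[str],
    spec,
    levels: list[ManagementLevel],
    trajectories: list[PatientTrajectory],
    holdout_year: int,
    c_e: float,
    n_bins: int = 20,
    n_folds: int = 5,
    subsets: list[tuple[str, ...]] | None = None,
    uptake: float = 1.0,
) -> pd.DataFrame:
    """Holdout accuracy and simulated outcomes per attribute-group subset.

    For each subset of attribute groups the model is retrained restricted
    to those features, scored on the holdout year, and the implied policy
    is simulated. Rows are sorted by simulated total cost, so a site
    missing some attribute groups can read off the expected consequences.
    """
    import warnings as _warnings

    from .risk_models import evaluate_holdout, train_and_cv

    if subsets is None:
        subsets = [
            c for r in range(1, len(groups) + 1) for c in combinations(groups, r)
        ]
    years = sorted(set(matrix.data.index.get_level_values("index_year")))
    train_years = [y for y in years if y != holdout_year]
    traj_by_id = {t.patient_id: t for t in trajectories}
    rows = []
    for subset in subsets:
        if not subset:
            _warnings.warn("empty attribute-group subset skipped")
            continue
        sub = matrix.select(groups=set(subset))
        if not sub.feature_names:
            _warnings.warn(f"subset {subset} selects no features; skipped")
            continue
        fitted, _ = train_and_cv(sub, spec, "label", n_folds, train_years)
        hold = evaluate_holdout(fitted, sub, holdout_year)
        mask = matrix.data.index.get_level_values("index_year") == holdout_year
        Xh = sub.encoded()[mask]
        preds = fitted.predict_risk(Xh)
        pids = matrix.data.index.get_level_values("patient_id")[mask]
        trajs = [traj_by_id[p] for p in pids]
        ev = np.array([t.n_e for t in trajs])
        stats_ = compute_percentile_stats(preds, ev, ev * c_e, n_bins=n_bins)
        policy = optimize_thresholds(levels, stats_)
        out = simulate_policy(
            trajs, preds, policy, stats_.c_e, uptake, keep_per_patient=False
        )
        rows.append(
            {
                "groups": "+".join(subset),
                "n_features": len(sub.feature_names),
                "holdout_metric": hold.value,
                "total_cost": out.total_cost,
                "total_admissions": out.total_admissions,
                "total_ed_visits": out.total_ed_visits,
            }
        )
    return pd.DataFrame(rows).sort_values("total_cost").reset_index(drop=True)


def min_accuracy_requirement(
    trajectories: list[PatientTrajectory],
    true_probs: np.ndarray,
    levels: list[ManagementLevel],
    c_e: float,
    n_bins: int = 100,
    seed: int = 0,
    tol: float = 1e-3,
    max_iter: int = 40,
) -> dict:
    """Minimum predictor AUC at which the optimized policy beats baseline.

    Degrades a calibrated predictor by blending with patient-wise noise,
    predictor(w) = (1 - w) * true_prob + w * noise, and bisects on w for
    the point where the simulated policy's total cost equals the
    no-enrollment baseline. Noise is drawn once, so cost is a
    deterministic function of w.
    """
    rng = np.random.default_rng(seed)
    true_probs = np.asarray(true_probs, dtype=float)
    noise = rng.uniform(size=len(true_probs))
    labels = np.array([1 if t.n_e > 0 else 0 for t in trajectories])
    events = np.array([t.n_e for t in trajectories])
    event_cost = events * c_e  # keeps the bin statistics consistent with c_e
    base = baseline_outcome(trajectories).total_cost

    def policy_cost(w: float) -> tuple[float, float]:
        preds = (1 - w) * true_probs + w * noise
        stats_ = compute_percentile_stats(preds, events, event_cost, n_bins)
        policy = optimize_thresholds(levels, stats_)
        out = simulate_policy(
            trajectories, preds, policy, stats_.c_e, keep_per_patient=False
        )
        auc = (
            float(roc_auc_score(labels, preds))
            if len(np.unique(labels)) == 2
            else float("nan")
        )
        return out.total_cost, auc

    cost0, auc0 = policy_cost(0.0)
    if cost0 >= base:
        return {"achievable": False, "auc_at_crossing": None, "baseline_cost": base}
    cost1, auc1 = policy_cost(1.0)
    if cost1 < base:
        return {
            "achievable": True,
            "auc_at_crossing": auc1,
            "blend_weight": 1.0,
            "baseline_cost": base,
            "note": "policy beats baseline even under a pure-noise predictor",
        }
    lo, hi = 0.0, 1.0  # lo beats baseline, hi does not
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        cost_m, _ = policy_cost(mid)
        if cost_m < base:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    _, auc_cross = policy_cost(lo)
    return {
        "achievable": True,
        "auc_at_crossing": auc_cross,
        "blend_weight": lo,
        "baseline_cost": base,
    }


@dataclass
class ComparisonReport:
    t_statistic: float
    t_pvalue: float
    mean_log_diff: float
    mcnemar_admissions: dict = field(default_factory=dict)
    mcnemar_ed: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def cost_reduced(self) -> bool:
        return self.t_pvalue < self.alpha


def _mcnemar_pairs(a: np.ndarray, b: np.ndarray) -> dict:
    """McNemar test on paired any-vs-none indicators."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    if n01 + n10 == 0:
        return {"informative": False, "discordant": 0, "pvalue": None}
    table = [[int((a & b).sum()), n10], [n01, int((~a & ~b).sum())]]
    res = mcnemar(table, exact=(n01 + n10) < 25)
    return {
        "informative": True,
        "discordant": n01 + n10,
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
    }


def compare_policies(
    outcome_a: PolicyOutcome,
    outcome_b: PolicyOutcome,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Paired one-sided comparison: does policy B lower costs vs policy A?

    Costs are log-transformed (log(cost + 1), admitting zero-cost
    patients); the one-sided alternative is mean log cost under B below
    that under A. Admissions and ED visits are dichotomized any-vs-none
    per patient and compared by McNemar's test.
    """
    pa, pb = outcome_a.per_patient, outcome_b.per_patient
    if pa is None or pb is None:
        raise ValueError("compare_policies needs per-patient outcome frames")
    a = pa.set_index("patient_id").sort_index()
    b = pb.set_index("patient_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("policies must cover the same patients")
    log_a = np.log(a["cost"].to_numpy() + 1.0)
    log_b = np.log(b["cost"].to_numpy() + 1.0)
    res = sps.ttest_rel(log_a, log_b, alternative="greater")
    return ComparisonReport(
        t_statistic=float(res.statistic) if np.isfinite(res.statistic) else 0.0,
        t_pvalue=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        mean_log_diff=float(np.mean(log_a - log_b)),
        mcnemar_admissions=_mcnemar_pairs(
            a["admissions"].to_numpy(), b["admissions"].to_numpy()
        ),
        mcnemar_ed=_mcnemar_pairs(a["ed_visits"].to_numpy(), b["ed_visits"].to_numpy()),
        alpha=alpha,
    )


def heuristic_policy(
    levels: dict[str, ManagementLevel],
    n_bins: int = 100,
    stats: PercentileStats | None = None,
) -> StratificationPolicy:
    """The literature's fixed pyramid: top 1% case management, next 4%
    disease management, next 15% supported self-care, rest wellness
    promotion — as a policy over ``n_bins`` equal bins. Level names must
    include the four tiers; missing tiers fall back to the null level.
    """
    tiers = [
        ("case management", 0.01),
        ("disease management", 0.05),
        ("supported self-care", 0.20),
        ("wellness promotion", 1.00),
    ]
    assignments = []
    for b in range(n_bins):
        frac = (b + 1) / n_bins
        name = next((t for t, cum in tiers if frac <= cum + 1e-12), NULL_LEVEL_NAME)
        assignments.append(name if name in levels else NULL_LEVEL_NAME)
    n_patients = (
        stats.n_patients if stats is not None else np.ones(n_bins, dtype=int)
    )
    avg = stats.avg_n_e if stats is not None else np.zeros(n_bins)
    c_e = stats.c_e if stats is not None else 0.0
    from .strata_optimizer import NULL_LEVEL, level_delta

    lv = dict(levels)
    lv.setdefault(NULL_LEVEL_NAME, NULL_LEVEL)
    deltas = np.array(
        [level_delta(lv[a], avg[b], c_e) for b, a in enumerate(assignments)]
    )
    return StratificationPolicy(assignments, deltas, np.asarray(n_patients), lv)
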