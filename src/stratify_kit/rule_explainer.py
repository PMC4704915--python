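"""Class association rules that explain high-risk predictions.

A rule is a conjunction of feature-value items associated with the
high-risk class:  p1 AND p2 AND ... AND pk  =>  high risk.  Its *support*
is the fraction of all patients who satisfy the left side AND are
high-risk (note the all-patients denominator); its *confidence* is the
fraction of left-side satisfiers who are high-risk. The miner performs a
level-wise (Apriori-style) enumeration, but counts candidate itemsets
over high-risk rows only — sound because the support numerator requires
the high-risk label, so itemset frequency among high-risk rows alone
decides the support threshold; confidence is then computed against the
full matrix. Rules carry attached interventions; a rule with at least one
intervention is *actionable*. Ranking puts actionable rules first, then
confidence desc, support desc, fewer items first.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class RuleItem:
    """One feature-value condition: equality or a half-open numeric range."""

    feature: str
    op: str  # "eq" | "range"
    value: object  # category/number for eq; (low, high) for range, low <= x < high

    def __post_init__(self):
        if self.op not in ("eq", "range"):
            raise ValueError(f"unknown item op {self.op!r}")
        if self.op == "range":
            lo, hi = self.value
            if not lo < hi:
                raise ValueError(f"range item needs lower < upper, got {self.value}")
            object.__setattr__(self, "value", (float(lo), float(hi)))

    def satisfied_by(self, column: pd.Series | np.ndarray) -> np.ndarray:
        col = np.asarray(column)
        if self.op == "eq":
            return col == self.value
        lo, hi = self.value
        colf = col.astype(float)
        return (colf >= lo) & (colf < hi)

    def describe(self) -> str:
        if self.op == "eq":
            return f"{self.feature} = {self.value}"
        lo, hi = self.value
        if math.isinf(hi):
            return f"{self.feature} >= {lo:g}"
        if math.isinf(lo):
            return f"{self.feature} < {hi:g}"
        return f"{self.feature} in [{lo:g}, {hi:g})"

    def key(self) -> str:
        if self.op == "eq":
            return f"{self.feature}=={self.value}"
        return f"{self.feature}@[{self.value[0]:g},{self.value[1]:g})"


@dataclass
class Rule:
    items: tuple[RuleItem, ...]
    support: float
    confidence: float
    interventions: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.items = tuple(sorted(self.items, key=lambda it: it.key()))

    @property
    def k(self) -> int:
        return len(self.items)

    @property
    def actionable(self) -> bool:
        return len(self.interventions) > 0

    @property
    def rule_id(self) -> str:
        """Canonical identity: sorted item list serialized to a stable string."""
        return " AND ".join(it.key() for it in self.items)

    def describe(self) -> str:
        return " AND ".join(it.describe() for it in self.items) + " => high risk"

    def to_dict(self) -> dict:
        return {
            "items": [
                {"feature": it.feature, "op": it.op, "value": it.value}
                for it in self.items
            ],
            "support": self.support,
            "confidence": self.confidence,
            "actionable": self.actionable,
            "interventions": self.interventions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        items = tuple(
            RuleItem(i["feature"], i["op"], tuple(i["value"]) if i["op"] == "range" else i["value"])
            for i in d["items"]
        )
        return cls(items, d["support"], d["confidence"], list(d.get("interventions", [])))


class UndefinedConfidenceError(ValueError):
    """No row satisfies the rule's left side, so confidence has no value."""


# ---------------------------------------------------------------------------
# discretization

def discretize(
    df: pd.DataFrame,
    n_bins: int = 4,
    max_categories: int = 8,
    overrides: dict[str, list[tuple[float, float]]] | None = None,
) -> dict[str, list[RuleItem]]:
    """Build the item catalog for a feature frame.

    Categorical or low-cardinality columns yield equality items, one per
    observed value. Other numeric columns yield half-open quantile bins
    [low, high), with the outer bins open-ended so unseen values still
    fall in a bin. ``overrides`` supplies explicit cut intervals per
    feature (clinical cut-points) in place of quantiles.
    """
    overrides = overrides or {}
    catalog: dict[str, list[RuleItem]] = {}
    for col in df.columns:
        s = df[col].dropna()
        if col in overrides:
            catalog[col] = [RuleItem(col, "range", (lo, hi)) for lo, hi in overrides[col]]
            continue
        if s.dtype == object or s.nunique() <= max_categories:
            catalog[col] = [RuleItem(col, "eq", v) for v in sorted(s.unique(), key=str)]
            continue
        qs = np.quantile(s.astype(float), np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs[1:-1])
        bounds = np.concatenate([[-np.inf], edges, [np.inf]])
        catalog[col] = [
            RuleItem(col, "range", (bounds[i], bounds[i + 1]))
            for i in range(len(bounds) - 1)
        ]
    return catalog


# ---------------------------------------------------------------------------
# support / confidence

def _lhs_mask(items: Iterable[RuleItem], df: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(df), dtype=bool)
    for it in items:
        if it.feature not in df.columns:
            raise KeyError(f"rule item references unknown feature {it.feature!r}")
        mask &= it.satisfied_by(df[it.feature])
    return mask


def compute_support_confidence(
    items: Iterable[RuleItem], df: pd.DataFrame, label_col: str = "label"
) -> tuple[float, float]:
    """(support, confidence) of a conjunction against a labelled matrix.

    support = |LHS and high-risk| / |all rows|;
    confidence = |LHS and high-risk| / |LHS|.
    """
    lhs = _lhs_mask(items, df)
    n_lhs = int(lhs.sum())
    if n_lhs == 0:
        raise UndefinedConfidenceError("no row satisfies the rule's left side")
    hr = np.asarray(df[label_col]) == 1
    both = int((lhs & hr).sum())
    return both / len(df), both / n_lhs


# ---------------------------------------------------------------------------
# mining

def mine_rules(
    df: pd.DataFrame,
    min_support: float = 0.01,
    min_confidence: float = 0.70,
    max_len: int = 4,
    label_col: str = "label",
    catalog: dict[str, list[RuleItem]] | None = None,
    constraints: dict[str, Callable[[RuleItem], bool]] | None = None,
    prune: bool = True,
    mine_from_high_risk: bool = True,
) -> list[Rule]:
    """Mine all class association rules for the high-risk class.

    Returns every rule with at most ``max_len`` items, support >=
    ``min_support`` and confidence >= ``min_confidence``, at most one item
    per feature, items restricted by per-feature ``constraints``
    (callables deciding which values may indicate high risk). When
    ``mine_from_high_risk`` is set (default) candidate itemsets are
    enumerated over high-risk rows only — an efficiency device that never
    changes the output. Redundant rules are removed via
    :func:`prune_redundant` unless ``prune=False``.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    if not 0 < min_confidence <= 1:
        raise ValueError("min_confidence must lie in (0, 1]")
    feats = [c for c in df.columns if c != label_col]
    if catalog is None:
        catalog = discretize(df[feats])
    constraints = constraints or {}

    n = len(df)
    hr = np.asarray(df[label_col]) == 1
    if not hr.any():
        return []
    min_count = min_support * n - 1e-9

    items: list[RuleItem] = []
    cols: list[np.ndarray] = []  # satisfaction mask per item, full matrix
    for feat, feat_items in catalog.items():
        allowed = constraints.get(feat)
        for it in feat_items:
            if allowed is not None and not allowed(it):
                continue
            items.append(it)
            cols.append(it.satisfied_by(df[feat]))
    if not items:
        return []
    sat = np.column_stack(cols)  # n x n_items
    sat_hr = sat[hr]  # candidate counting restricted to high-risk rows
    count_rows = sat_hr if mine_from_high_risk else sat
    feat_of = np.array([it.feature for it in items])

    # level 1
    frequent: dict[int, list[tuple[int, ...]]] = {}
    if mine_from_high_risk:
        counts1 = sat_hr.sum(axis=0)
    else:
        counts1 = (sat & hr[:, None]).sum(axis=0)
    frequent[1] = [(j,) for j in range(len(items)) if counts1[j] >= min_count]

    from collections import defaultdict

    for k in range(2, max_len + 1):
        prev = frequent.get(k - 1, [])
        if not prev:
            break
        prev_set = set(prev)
        by_prefix: dict[tuple, list[int]] = defaultdict(list)
        for t in prev:
            by_prefix[t[:-1]].append(t[-1])
        level: list[tuple[int, ...]] = []
        for prefix, lasts in by_prefix.items():
            prefix_mask = None
            for a_i, a_last in enumerate(lasts):
                for b_last in lasts[a_i + 1 :]:
                    cand = prefix + (a_last, b_last)
                    if len(set(feat_of[list(cand)])) < k:
                        continue  # one item per feature
                    if any(
                        tuple(c for ci, c in enumerate(cand) if ci != drop)
                        not in prev_set
                        for drop in range(k - 2)
                    ):
                        continue  # all (k-1)-subsets must be frequent
                    if prefix_mask is None:
                        prefix_mask = np.ones(count_rows.shape[0], dtype=bool)
                        for j in prefix:
                            prefix_mask &= count_rows[:, j]
                    m = prefix_mask & count_rows[:, a_last] & count_rows[:, b_last]
                    cnt = int(m.sum()) if mine_from_high_risk else int((m & hr).sum())
                    if cnt >= min_count:
                        level.append(cand)
        level.sort()
        frequent[k] = level

    rules: list[Rule] = []
    for k, sets in frequent.items():
        for idxs in sets:
            lhs = sat[:, idxs[0]].copy()
            for j in idxs[1:]:
                lhs &= sat[:, j]
            n_lhs = int(lhs.sum())
            both = int((lhs & hr).sum())
            conf = both / n_lhs
            if conf >= min_confidence - 1e-12:
                rules.append(Rule(tuple(items[j] for j in idxs), both / n, conf))
    if prune:
        rules = prune_redundant(rules)
    return rules


def prune_redundant(rules: list[Rule]) -> list[Rule]:
    """Drop a rule iff a strict sub-rule with confidence >= its own exists."""
    by_items = {frozenset(r.items): r for r in rules}
    kept = []
    for r in rules:
        fs = frozenset(r.items)
        dominated = False
        for size in range(1, len(fs)):
            for sub in combinations(fs, size):
                s = by_items.get(frozenset(sub))
                if s is not None and s.confidence >= r.confidence:
                    dominated = True
                    break
            if dominated:
                break
        if not dominated:
            kept.append(r)
    return kept


def rank_rules(rules: list[Rule]) -> list[Rule]:
    """Deterministic total order for display.

    Actionable rules first; within each block descending confidence, then
    descending support, then fewer items, then lexicographic item order.
    """
    return sorted(
        rules,
        key=lambda r: (not r.actionable, -r.confidence, -r.support, r.k, r.rule_id),
    )


# ---------------------------------------------------------------------------
# intervention registry

@dataclass
class InterventionRegistry:
    """Maps rule identity to intervention records, for reuse across runs.

    Each record: id, description, level ("patient" | "system"),
    cost_per_patient and avoided-event fraction for outcome simulation.
    Also holds an optional deny-list of rule ids judged clinically
    meaningless during review.
    """

    interventions: dict[str, list[dict]] = field(default_factory=dict)
    denied: set[str] = field(default_factory=set)

    def register(self, rule_id: str, intervention: dict) -> None:
        iv = dict(intervention)
        for key in ("id", "description", "level"):
            if key not in iv:
                raise ValueError(f"intervention missing field {key!r}")
        if iv["level"] not in ("patient", "system"):
            raise ValueError("intervention level must be 'patient' or 'system'")
        bucket = self.interventions.setdefault(rule_id, [])
        if any(existing["id"] == iv["id"] for existing in bucket):
            raise ValueError(f"duplicate intervention id {iv['id']!r} for rule")
        bucket.append(iv)

    def deny(self, rule_id: str) -> None:
        self.denied.add(rule_id)

    def attach(self, rules: list[Rule]) -> list[Rule]:
        """Drop denied rules and attach interventions to the rest."""
        out = []
        for r in rules:
            if r.rule_id in self.denied:
                continue
            r.interventions = list(self.interventions.get(r.rule_id, []))
            out.append(r)
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"interventions": self.interventions, "denied": sorted(self.denied)},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "InterventionRegistry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d.get("interventions", {}), set(d.get("denied", [])))


# ---------------------------------------------------------------------------
# matching and explanation

class RuleIndex:
    """Inverted item -> rule-ids map; matching intersects posting lists."""

    def __init__(self, rules: list[Rule]):
        self.rules = list(rules)
        self.postings: dict[str, list[int]] = {}
        for rid, rule in enumerate(self.rules):
            for it in rule.items:
                self.postings.setdefault(it.key(), []).append(rid)
        self._items = {it.key(): it for r in self.rules for it in r.items}

    def match(self, row: pd.Series) -> list[Rule]:
        """Rules whose every item the patient row satisfies, in input order."""
        hits = np.zeros(len(self.rules), dtype=int)
        for key, it in self._items.items():
            if it.feature not in row.index:
                continue
            if bool(it.satisfied_by(np.asarray([row[it.feature]]))[0]):
                hits[self.postings[key]] += 1
        return [r for rid, r in enumerate(self.rules) if hits[rid] == r.k]


def explain_patient(
    row: pd.Series,
    rules: list[Rule],
    k: int = 3,
    show_all: bool = False,
    index: RuleIndex | None = None,
) -> list[Rule]:
    """Top-k ranked rules matching a (predicted high-risk) patient row.

    May be empty: rare reasons for high risk need not be covered by any
    mined rule. ``rules`` should already be ranked; ranking is applied
    defensively regardless.
    """
    idx = index if index is not None else RuleIndex(rules)
    matched = rank_rules(idx.match(row))
    return matched if show_all else matched[:k]


def coverage_report(
    rules: list[Rule], df: pd.DataFrame, label_col: str = "label"
) -> dict:
    """Fraction of high-risk rows matched by >=1 actionable rule."""
    hr = np.asarray(df[label_col]) == 1
    n_hr = int(hr.sum())
    covered = np.zeros(len(df), dtype=bool)
    per_rule = {}
    for r in rules:
        m = _lhs_mask(r.items, df)
        per_rule[r.rule_id] = int((m & hr).sum())
        if r.actionable:
            covered |= m
    frac = float((covered & hr).sum() / n_hr) if n_hr else 0.0
    return {"coverage": frac, "n_high_risk": n_hr, "per_rule_matches": per_rule}


def save_rules(rules: list[Rule], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in rules], fh, indent=2)


def load_rules(path) -> list[Rule]:
    with open(path) as fh:
        return [Rule.from_dict(d) for d in json.load(fh)]
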