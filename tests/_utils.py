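"""Shared test helpers: independent oracles and tiny-matrix builders."""

from __future__ import annotations

import numpy as np
import pandas as pd

from stratify_kit.cohort_features import FeatureMatrix
from stratify_kit.rule_explainer import Rule, RuleItem


def brute_force_rules(
    df: pd.DataFrame,
    min_support: float,
    min_confidence: float,
    max_len: int,
    label_col: str = "label",
) -> list[Rule]:
    """Exhaustive enumeration of all qualifying conjunctions.

    Independent of the miner: walks every combination of equality items
    (at most one per feature, length <= max_len) and keeps those passing
    both thresholds. Only shortcut: a prefix satisfied by zero rows cannot
    produce a rule, nor can any extension of it.
    """
    feats = [c for c in df.columns if c != label_col]
    items: list[RuleItem] = []
    masks: list[np.ndarray] = []
    for c in feats:
        for v in sorted(pd.unique(df[c]), key=str):
            items.append(RuleItem(c, "eq", v))
            masks.append((df[c] == v).to_numpy())
    hr = (df[label_col] == 1).to_numpy()
    n = len(df)
    min_count = min_support * n - 1e-9
    out: list[Rule] = []

    def recurse(start: int, chosen: list[int], mask: np.ndarray):
        for j in range(start, len(items)):
            if any(items[j].feature == items[c].feature for c in chosen):
                continue
            m = mask & masks[j]
            n_lhs = int(m.sum())
            if n_lhs == 0:
                continue
            both = int((m & hr).sum())
            if both >= min_count:
                conf = both / n_lhs
                if conf >= min_confidence - 1e-12:
                    out.append(
                        Rule(tuple(items[c] for c in chosen) + (items[j],), both / n, conf)
                    )
            if len(chosen) + 1 < max_len:
                recurse(j + 1, chosen + [j], m)

    recurse(0, [], np.ones(n, dtype=bool))
    return out


def rule_signature(rules: list[Rule]) -> set[tuple]:
    return {
        (
            frozenset(it.key() for it in r.items),
            round(r.support, 9),
            round(r.confidence, 9),
        )
        for r in rules
    }


def make_feature_matrix(
    features: dict[str, np.ndarray],
    label: np.ndarray | None = None,
    cost: np.ndarray | None = None,
    n_years: int = 2,
    meta: dict | None = None,
) -> FeatureMatrix:
    """Build a small FeatureMatrix with the expected (patient, year) index."""
    n = len(next(iter(features.values())))
    years = np.tile(np.arange(2000, 2000 + n_years), -(-n // n_years))[:n]
    idx = pd.MultiIndex.from_arrays(
        [[f"P{i:04d}" for i in range(n)], years], names=["patient_id", "index_year"]
    )
    data = pd.DataFrame(features, index=idx)
    if label is not None:
        data["label"] = label
    if cost is not None:
        data["cost_outcome"] = cost
    if meta is None:
        meta = {k: {"family": "patient", "group": "g0"} for k in features}
    return FeatureMatrix(data, meta)
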