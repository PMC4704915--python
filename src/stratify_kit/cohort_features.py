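"""Cohort identification, outcome labelling and feature construction.

One row per patient per index year. Features come from the index year
(and static attributes); outcomes come from the following year, so there
is no temporal leakage by construction:

* patient features — demographics, prior-year utilisation by visit type,
  prior-year acute-event count and cost, controller-to-total asthma
  medication ratio;
* physician-profile features — log-scale panel composition counts of the
  patient's primary physician, leave-one-out mean outcome / cost /
  controller ratio of the physician's asthma panel (with a population
  fallback for thin panels), the physician's own attributes, and
  patient-physician match indicators;
* environmental features — yearly mean and max of each monitored
  variable at the station nearest the patient's home.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_cohort import (
    ACUTE_TYPES,
    CONTROLLER_CLASSES,
    RELIEVER_CLASS,
    VISIT_TYPES,
    CohortBundle,
)

OUTCOME_COLUMNS = ("label", "secondary", "cost_outcome")

QUALIFYING_CLASSES = CONTROLLER_CLASSES + (RELIEVER_CLASS,)


@dataclass
class FeatureMatrix:
    """Feature table keyed by (patient_id, index_year) plus outcome columns.

    ``feature_meta`` maps each feature name to its family
    (patient | physician_profile | environmental) and source attribute
    group, which downstream attribute-combination simulations use.
    """

    data: pd.DataFrame
    feature_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in OUTCOME_COLUMNS]

    def families(self) -> set[str]:
        return {m["family"] for m in self.feature_meta.values()}

    def select(
        self, families: set[str] | None = None, groups: set[str] | None = None
    ) -> "FeatureMatrix":
        """Restrict features to the given families and/or attribute groups."""
        keep = []
        for name in self.feature_names:
            meta = self.feature_meta.get(name, {})
            if families is not None and meta.get("family") not in families:
                continue
            if groups is not None and meta.get("group") not in groups:
                continue
            keep.append(name)
        cols = keep + [c for c in OUTCOME_COLUMNS if c in self.data.columns]
        return FeatureMatrix(
            self.data[cols].copy(),
            {k: v for k, v in self.feature_meta.items() if k in keep},
        )

    def encoded(self) -> pd.DataFrame:
        """One-hot-encoded numeric feature frame (outcomes excluded)."""
        X = self.data[self.feature_names]
        cat = [c for c in X.columns if X[c].dtype == object]
        X = pd.get_dummies(X, columns=cat, dtype=float)
        return X.astype(float).fillna(X.astype(float).median(numeric_only=True))

    def to_files(self, csv_path, meta_path) -> None:
        import json

        self.data.to_csv(csv_path)
        with open(meta_path, "w") as fh:
            json.dump(self.feature_meta, fh, indent=2)


def _month_index(df: pd.DataFrame) -> pd.Series:
    return df["year"] * 12 + (df["month"] - 1)


def identify_asthma(
    encounters: pd.DataFrame, dispensings: pd.DataFrame, window_months: int = 12
) -> set[str]:
    """Patients with asthma per the standard two-route definition.

    Included iff (a) any encounter carries a 493.xx diagnosis code, or
    (b) at least two qualifying asthma-medication dispensings (inhaled
    steroids, beta-agonists, leukotriene modifiers, other inhaled
    anti-inflammatories; oral steroids excluded) fall within any one-year
    span. Empty inputs give an empty set.
    """
    by_dx: set[str] = set()
    if len(encounters):
        dx = encounters["primary_dx"].astype(str).str.startswith("493")
        by_dx = set(encounters.loc[dx, "patient_id"])

    by_meds: set[str] = set()
    if len(dispensings):
        q = dispensings[dispensings["med_class"].isin(QUALIFYING_CLASSES)].copy()
        if len(q):
            q["midx"] = _month_index(q)
            for pid, grp in q.groupby("patient_id")["midx"]:
                m = np.sort(grp.to_numpy())
                if len(m) >= 2 and np.any(np.diff(m) <= window_months - 1):
                    by_meds.add(pid)
    return by_dx | by_meds


def _acute_asthma(enc: pd.DataFrame) -> pd.Series:
    return enc["visit_type"].isin(ACUTE_TYPES) & enc["primary_dx"].astype(
        str
    ).str.startswith("493")


def label_outcomes(
    bundle: CohortBundle, cohort: list[str], index_year: int
) -> pd.DataFrame:
    """Outcome columns for each cohort patient at ``index_year``.

    ``label`` — any inpatient / urgent-care / emergency encounter with a
    primary 493.xx diagnosis in ``index_year + 1``; ``secondary`` — summed
    reliever and oral-steroid refill amounts in that year; ``cost_outcome``
    — total encounter cost in that year. Cohort members with no records
    next year get 0 / 0 / 0: absence of care is observable absence of
    events.
    """
    next_year = index_year + 1
    if next_year not in bundle.years:
        raise ValueError(f"index_year {index_year}: year {next_year} not in bundle")
    idx = pd.Index(cohort, name="patient_id")
    enc = bundle.encounters[bundle.encounters["year"] == next_year]
    acute = enc[_acute_asthma(enc)]
    label = acute.groupby("patient_id").size().reindex(idx, fill_value=0).gt(0).astype(int)
    cost = enc.groupby("patient_id")["cost"].sum().reindex(idx, fill_value=0.0)
    disp = bundle.dispensings[
        (bundle.dispensings["year"] == next_year)
        & bundle.dispensings["med_class"].isin([RELIEVER_CLASS, "oral steroid"])
    ]
    secondary = disp.groupby("patient_id")["amount"].sum().reindex(idx, fill_value=0)
    return pd.DataFrame(
        {"label": label, "secondary": secondary.astype(float), "cost_outcome": cost}
    )


def _controller_ratio(disp_year: pd.DataFrame, idx: pd.Index) -> pd.Series:
    asthma_meds = disp_year[disp_year["med_class"].isin(QUALIFYING_CLASSES)]
    total = asthma_meds.groupby("patient_id").size().reindex(idx, fill_value=0)
    ctrl = (
        asthma_meds[asthma_meds["med_class"].isin(CONTROLLER_CLASSES)]
        .groupby("patient_id")
        .size()
        .reindex(idx, fill_value=0)
    )
    # neutral value for patients with no asthma medication this year
    ratio = ctrl / total.replace(0, np.nan)
    return ratio.fillna(0.5)


def build_patient_features(
    bundle: CohortBundle, cohort: list[str], index_year: int
) -> tuple[pd.DataFrame, dict]:
    idx = pd.Index(cohort, name="patient_id")
    pats = bundle.patients.set_index("patient_id")
    missing = idx.difference(pats.index)
    if len(missing):
        raise KeyError(f"unknown patient ids: {sorted(missing)[:5]}")
    pats = pats.loc[idx]

    enc = bundle.encounters[bundle.encounters["year"] == index_year]
    feats = pd.DataFrame(index=idx)
    feats["age"] = (index_year - pats["birth_year"]).astype(float)
    for col in ("gender", "race", "language", "insurance"):
        feats[col] = pats[col].replace("", np.nan).fillna("unknown")

    for vt in VISIT_TYPES:
        key = f"prior_{vt.replace(' ', '_')}_visits"
        feats[key] = (
            enc[enc["visit_type"] == vt]
            .groupby("patient_id")
            .size()
            .reindex(idx, fill_value=0)
            .astype(float)
        )
    feats["prior_event_count"] = (
        enc[_acute_asthma(enc)].groupby("patient_id").size().reindex(idx, fill_value=0).astype(float)
    )
    feats["prior_cost"] = enc.groupby("patient_id")["cost"].sum().reindex(idx, fill_value=0.0)
    disp = bundle.dispensings[bundle.dispensings["year"] == index_year]
    feats["controller_ratio"] = _controller_ratio(disp, idx)

    meta = {
        name: {"family": "patient", "group": grp}
        for name, grp in {
            "age": "demographics",
            "gender": "demographics",
            "race": "demographics",
            "language": "demographics",
            "insurance": "demographics",
            "prior_inpatient_visits": "utilization",
            "prior_outpatient_visits": "utilization",
            "prior_urgent_care_visits": "utilization",
            "prior_emergency_visits": "utilization",
            "prior_event_count": "utilization",
            "prior_cost": "utilization",
            "controller_ratio": "medication",
        }.items()
    }
    return feats, meta


def build_physician_profile_features(
    bundle: CohortBundle,
    cohort: list[str],
    index_year: int,
    min_panel: int = 5,
    log_normalizer: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Practice-profile features of each patient's primary physician.

    Panel-composition features are ``log(1 + count / log_normalizer)``.
    Leave-one-out panel means (outcome, cost, controller ratio) use the
    physician's asthma patients in the index year excluding the index
    patient; a physician with fewer than ``min_panel`` such patients falls
    back to the population mean.
    """
    idx = pd.Index(cohort, name="patient_id")
    pats = bundle.patients.set_index("patient_id").loc[idx]
    phys = bundle.physicians.set_index("physician_id")
    unknown = set(pats["physician_id"]) - set(phys.index)
    if unknown:
        raise KeyError(f"unresolvable physician ids: {sorted(unknown)}")

    enc = bundle.encounters[bundle.encounters["year"] == index_year]
    disp = bundle.dispensings[bundle.dispensings["year"] == index_year]

    # current-year "outcome" (acute asthma event) and cost per cohort patient
    cur_event = (
        enc[_acute_asthma(enc)].groupby("patient_id").size().reindex(idx, fill_value=0).gt(0).astype(float)
    )
    cur_cost = enc.groupby("patient_id")["cost"].sum().reindex(idx, fill_value=0.0)
    ctrl_ratio = _controller_ratio(disp, idx)

    panel = pd.DataFrame(
        {
            "physician_id": pats["physician_id"],
            "event": cur_event,
            "cost": cur_cost,
            "ctrl": ctrl_ratio,
            "female": (pats["gender"] == "F").astype(float),
            "pediatric": ((index_year - pats["birth_year"]) < 18).astype(float),
        },
        index=idx,
    )
    g = panel.groupby("physician_id")
    sums = g[["event", "cost", "ctrl", "female", "pediatric"]].sum()
    counts = g.size()
    pop_mean = panel[["event", "cost", "ctrl"]].mean()

    inpt = enc[enc["visit_type"] == "inpatient"].merge(
        bundle.patients[["patient_id", "physician_id"]], on="patient_id"
    )
    inpt_by_phys = inpt.groupby("physician_id").size()

    feats = pd.DataFrame(index=idx)
    pid = panel["physician_id"]
    n_panel = counts.reindex(pid).to_numpy()

    def _log(x):
        return np.log1p(np.asarray(x, dtype=float) / log_normalizer)

    feats["phys_panel_asthma_log"] = _log(n_panel)
    feats["phys_panel_female_log"] = _log(sums["female"].reindex(pid).to_numpy())
    feats["phys_panel_pediatric_log"] = _log(sums["pediatric"].reindex(pid).to_numpy())
    feats["phys_inpatient_log"] = _log(
        inpt_by_phys.reindex(pid).fillna(0).to_numpy()
    )

    # leave-one-out panel means with thin-panel fallback to population mean
    for col, name in (
        ("event", "phys_mean_outcome"),
        ("cost", "phys_mean_cost"),
        ("ctrl", "phys_mean_controller_ratio"),
    ):
        loo_sum = sums[col].reindex(pid).to_numpy() - panel[col].to_numpy()
        loo_n = n_panel - 1
        with np.errstate(invalid="ignore", divide="ignore"):
            loo = loo_sum / loo_n
        feats[name] = np.where(loo_n >= min_panel, loo, pop_mean[col])

    for col, name in (
        ("age", "phys_age"),
        ("office_hours_week", "phys_office_hours"),
        ("years_in_practice", "phys_years_in_practice"),
    ):
        feats[name] = phys[col].reindex(pid).to_numpy().astype(float)
    feats["phys_specialty"] = phys["specialty"].reindex(pid).to_numpy()

    # patient-physician match features
    ph = phys.reindex(pid)
    feats["distance_to_physician"] = np.hypot(
        pats["home_x"].to_numpy() - ph["office_x"].to_numpy(),
        pats["home_y"].to_numpy() - ph["office_y"].to_numpy(),
    )
    feats["same_gender"] = (pats["gender"].to_numpy() == ph["gender"].to_numpy()).astype(float)
    feats["same_language"] = np.array(
        [
            pl in str(dl).split(";")
            for pl, dl in zip(pats["language"], ph["languages"])
        ],
        dtype=float,
    )
    feats["insurance_accepted"] = np.array(
        [
            ins in str(acc).split(";")
            for ins, acc in zip(pats["insurance"], ph["insurances_accepted"])
        ],
        dtype=float,
    )

    groups = {
        "phys_panel_asthma_log": "physician_panel",
        "phys_panel_female_log": "physician_panel",
        "phys_panel_pediatric_log": "physician_panel",
        "phys_inpatient_log": "physician_panel",
        "phys_mean_outcome": "physician_panel",
        "phys_mean_cost": "physician_panel",
        "phys_mean_controller_ratio": "physician_panel",
        "phys_age": "physician_own",
        "phys_office_hours": "physician_own",
        "phys_years_in_practice": "physician_own",
        "phys_specialty": "physician_own",
        "distance_to_physician": "physician_match",
        "same_gender": "physician_match",
        "same_language": "physician_match",
        "insurance_accepted": "physician_match",
    }
    meta = {k: {"family": "physician_profile", "group": v} for k, v in groups.items()}
    return feats, meta


def build_env_features(
    bundle: CohortBundle, cohort: list[str], index_year: int
) -> tuple[pd.DataFrame, dict]:
    """Yearly mean and max of each environmental variable at the nearest station."""
    if bundle.stations.empty:
        raise ValueError("bundle has no monitoring stations")
    idx = pd.Index(cohort, name="patient_id")
    pats = bundle.patients.set_index("patient_id").loc[idx]
    st = bundle.stations
    d = np.hypot(
        pats["home_x"].to_numpy()[:, None] - st["x"].to_numpy()[None, :],
        pats["home_y"].to_numpy()[:, None] - st["y"].to_numpy()[None, :],
    )
    nearest = st["station_id"].to_numpy()[d.argmin(axis=1)]

    env = bundle.environment[bundle.environment["year"] == index_year]
    agg = env.groupby(["station_id", "variable"])["value"].agg(["mean", "max"]).unstack(
        "variable"
    )
    feats = pd.DataFrame(index=idx)
    meta = {}
    for var in sorted(env["variable"].unique()):
        for stat in ("mean", "max"):
            name = f"env_{var}_{stat}"
            feats[name] = agg[(stat, var)].reindex(nearest).to_numpy()
            meta[name] = {"family": "environmental", "group": "environment"}
    return feats, meta


def build_feature_matrix(
    bundle: CohortBundle,
    index_years: list[int] | None = None,
    cohort: set[str] | None = None,
    min_panel: int = 5,
) -> FeatureMatrix:
    """Assemble the full feature matrix over the given index years.

    The cohort defaults to patients identified as asthmatic from the
    observable tables. The last bundle year is used only as an outcome
    horizon, never as an index year.
    """
    if cohort is None:
        cohort = identify_asthma(bundle.encounters, bundle.dispensings)
    cohort_ids = sorted(cohort)
    if index_years is None:
        index_years = list(bundle.years)[:-1]

    blocks = []
    meta: dict[str, dict[str, str]] = {}
    for year in index_years:
        pf, m1 = build_patient_features(bundle, cohort_ids, year)
        df_, m2 = build_physician_profile_features(bundle, cohort_ids, year, min_panel)
        ef, m3 = build_env_features(bundle, cohort_ids, year)
        out = label_outcomes(bundle, cohort_ids, year)
        block = pd.concat([pf, df_, ef, out], axis=1)
        block["index_year"] = year
        blocks.append(block)
        meta = {**m1, **m2, **m3}
    data = pd.concat(blocks).set_index("index_year", append=True)
    return FeatureMatrix(data, meta)
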