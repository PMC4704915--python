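"""Seeded synthetic EHR-like cohort generator with known ground truth.

Emulates the statistical structure a risk-stratification pipeline relies
on: a chronic-disease (asthma-like) population with rare acute-care
events, a heavy-tailed "cost pyramid" (a small fraction of patients
accounts for most cost), planted feature patterns that drive event risk,
per-physician effects on outcomes, and regional environmental monitoring
series. Every random draw flows from a single integer seed, so a bundle
is bit-for-bit reproducible.

Tables are plain pandas DataFrames and serialize to CSV. The truth table
(per patient-year event probability, realized event count and cost) is
kept separate so pipelines can be run blind and evaluated afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ACUTE_TYPES = ("inpatient", "urgent care", "emergency")
VISIT_TYPES = ("inpatient", "outpatient", "urgent care", "emergency")

# minimal ICD-9-like vocabulary; 493.xx is the asthma family
ASTHMA_CODES = ("493.00", "493.02", "493.12", "493.20", "493.90", "493.92")
OTHER_CODES = ("250.00", "272.4", "401.9", "460", "486", "780.60", "786.2")

CONTROLLER_CLASSES = (
    "inhaled steroid",
    "leukotriene modifier",
    "other inhaled anti-inflammatory",
)
RELIEVER_CLASS = "beta-agonist"
MED_CLASSES = CONTROLLER_CLASSES + (RELIEVER_CLASS, "oral steroid", "other")

GENDERS = ("F", "M")
RACES = ("white", "black", "asian", "hispanic", "other")
LANGUAGES = ("english", "spanish", "other")
INSURANCES = ("commercial", "medicaid", "medicare", "selfpay")
SPECIALTIES = ("family medicine", "pediatrics", "internal medicine", "pulmonology")

#: 21 environmental variables: 11 pollutant/meteorology series plus 10
#: respiratory-virus activity series. Values are (annual mean, seasonal
#: amplitude, monthly noise SD, between-station SD of the mean).
DEFAULT_ENV_PROFILE: dict[str, tuple[float, float, float, float]] = {
    "pm2.5": (10.0, 4.0, 2.0, 3.0),
    "pm10": (22.0, 8.0, 4.0, 5.0),
    "co": (0.5, 0.2, 0.1, 0.1),
    "no2": (18.0, 6.0, 3.0, 4.0),
    "so2": (3.0, 1.0, 0.5, 0.8),
    "ozone": (45.0, 15.0, 5.0, 6.0),
    "temperature": (11.0, 12.0, 2.0, 2.5),
    "humidity": (55.0, 15.0, 5.0, 5.0),
    "wind_speed": (10.0, 3.0, 2.0, 2.0),
    "precipitation": (40.0, 20.0, 10.0, 8.0),
    "dew_point": (3.0, 9.0, 2.0, 2.0),
    "adenovirus": (5.0, 3.0, 1.5, 1.0),
    "enterovirus": (4.0, 3.0, 1.5, 1.0),
    "metapneumovirus": (3.0, 2.5, 1.0, 0.8),
    "influenza_a": (8.0, 7.5, 2.0, 1.5),
    "influenza_b": (4.0, 3.5, 1.5, 1.0),
    "parainfluenza_1": (2.0, 1.5, 0.8, 0.5),
    "parainfluenza_2": (2.0, 1.5, 0.8, 0.5),
    "parainfluenza_3": (3.0, 2.0, 1.0, 0.6),
    "rhinovirus": (12.0, 5.0, 3.0, 2.0),
    "rsv": (6.0, 5.5, 1.5, 1.2),
}


@dataclass(frozen=True)
class PlantedPattern:
    """A feature-condition conjunction that overrides or scales event risk.

    ``conditions`` is a tuple of ``(column, op, value)`` triples evaluated
    against the generator's per-patient-year risk frame (columns such as
    ``prior_inpatient``, ``prior_acute``, ``age``, ``gender``,
    ``physician_panel_asthma``, ``distance``). ``mode="absolute"`` sets the
    event probability to ``probability`` on matching rows; ``"multiplier"``
    scales it (clipped to [0, 1]). Patterns apply in list order, so later
    (more specific) patterns win on overlapping rows.
    """

    conditions: tuple[tuple[str, str, object], ...]
    probability: float
    mode: str = "absolute"


_OPS = {
    "==": lambda col, v: col == v,
    "!=": lambda col, v: col != v,
    "<": lambda col, v: col < v,
    "<=": lambda col, v: col <= v,
    ">": lambda col, v: col > v,
    ">=": lambda col, v: col >= v,
}


@dataclass
class GenerativeParams:
    n_patients: int = 2000
    n_physicians: int = 40
    n_years: int = 11
    start_year: int = 2000
    #: probability per patient-year of any acute-care event (asthma patients)
    base_event_rate: float = 0.06
    #: extra events beyond the first, Poisson mean, given an event year
    extra_event_rate: float = 0.3
    planted_patterns: tuple[PlantedPattern, ...] = (
        PlantedPattern((("prior_inpatient", ">=", 1),), 0.45),
        PlantedPattern(
            (("prior_inpatient", ">=", 1), ("physician_panel_asthma", "<", 10)), 0.80
        ),
    )
    #: SD of the per-physician additive effect on event log-odds
    physician_effect_sd: float = 0.5
    #: lognormal (location, within-year scale) of annual non-event "body"
    #: cost; combined with the persistent patient frailty below this
    #: reproduces the cost pyramid (a small fraction of patients carries
    #: most of the total cost, top 20% >= ~60-80%)
    cost_body: tuple[float, float] = (7.0, 0.9)
    #: SD of a per-patient lognormal location shift that persists across
    #: years (chronic high utilizers stay expensive)
    cost_frailty_sd: float = 1.3
    event_unit_cost_mean: float = 10_000.0
    event_cost_sigma: float = 0.4
    #: fraction of generated patients who truly have the chronic disease
    asthma_prevalence: float = 0.85
    #: event visit-type mix over (inpatient, emergency, urgent care)
    acute_type_probs: tuple[float, float, float] = (0.35, 0.45, 0.20)
    outpatient_rate: float = 1.5
    n_stations: int = 4
    env_profile: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENV_PROFILE)
    )
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "n_physicians", "n_years", "n_stations"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in ("base_event_rate", "asthma_prevalence", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for pat in self.planted_patterns:
            if pat.mode == "absolute" and not 0.0 <= pat.probability <= 1.0:
                raise ValueError(
                    "planted_patterns: absolute probability must be in [0, 1]"
                )
            if pat.probability < 0:
                raise ValueError("planted_patterns: probability must be nonnegative")
        if self.event_unit_cost_mean < 0:
            raise ValueError("event_unit_cost_mean must be nonnegative")
        if self.physician_effect_sd < 0:
            raise ValueError("physician_effect_sd must be nonnegative")
        if self.cost_frailty_sd < 0:
            raise ValueError("cost_frailty_sd must be nonnegative")
        if abs(sum(self.acute_type_probs) - 1.0) > 1e-9:
            raise ValueError("acute_type_probs must sum to 1")


@dataclass
class CohortBundle:
    """Linked synthetic tables plus the generative ground truth."""

    patients: pd.DataFrame
    physicians: pd.DataFrame
    encounters: pd.DataFrame
    dispensings: pd.DataFrame
    environment: pd.DataFrame
    stations: pd.DataFrame
    truth: pd.DataFrame
    params: GenerativeParams

    TABLE_NAMES = (
        "patients",
        "physicians",
        "encounters",
        "dispensings",
        "environment",
        "stations",
        "truth",
    )

    @property
    def years(self) -> range:
        p = self.params
        return range(p.start_year, p.start_year + p.n_years)

    def to_dir(self, path: str | Path) -> None:
        """Write each table as a UTF-8 CSV with a header row.

        The truth table goes to its own file so a pipeline can be run
        blind on the observable tables alone.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self.TABLE_NAMES:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path: str | Path, params: GenerativeParams | None = None) -> "CohortBundle":
        path = Path(path)
        tables = {
            name: pd.read_csv(path / f"{name}.csv", keep_default_na=False, na_values=[""])
            for name in cls.TABLE_NAMES
        }
        if params is None:
            years = tables["truth"]["year"]
            params = GenerativeParams(
                n_patients=tables["patients"].shape[0],
                n_physicians=tables["physicians"].shape[0],
                n_years=int(years.max() - years.min() + 1),
                start_year=int(years.min()),
                n_stations=tables["stations"].shape[0],
            )
        return cls(params=params, **tables)


def _pattern_mask(frame: pd.DataFrame, pattern: PlantedPattern) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for col, op, value in pattern.conditions:
        if col not in frame.columns:
            raise ValueError(f"planted pattern references unknown column {col!r}")
        if op not in _OPS:
            raise ValueError(f"planted pattern uses unknown operator {op!r}")
        mask &= np.asarray(_OPS[op](frame[col], value))
    return mask


def generate_env_series(
    params: GenerativeParams, rng: np.random.Generator | None = None,
    station_xy: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly environmental series per station: seasonal mean plus noise.

    Returns ``(environment, stations)``. Each variable v at station s in
    month m of year y takes ``mean_v + offset_{v,s} +
    amplitude_v * sin(2*pi*(m - phase_v)/12) + noise``; station offsets make
    readings of the same variable differ across monitoring stations.
    """
    params.validate()
    if not params.env_profile:
        raise ValueError("env_profile is empty")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if station_xy is None:
        station_xy = rng.uniform(size=(params.n_stations, 2))
    n_s = station_xy.shape[0]
    years = np.arange(params.start_year, params.start_year + params.n_years)
    months = np.arange(1, 13)
    rows = []
    for var, (mean, amp, noise_sd, station_sd) in params.env_profile.items():
        offsets = rng.normal(0.0, station_sd, size=n_s)
        phase = rng.uniform(0, 12)
        for s in range(n_s):
            seasonal = mean + offsets[s] + amp * np.sin(
                2 * np.pi * (np.tile(months, len(years)) - phase) / 12.0
            )
            vals = seasonal + rng.normal(0.0, noise_sd, size=seasonal.size)
            rows.append(
                pd.DataFrame(
                    {
                        "station_id": f"S{s:02d}",
                        "year": np.repeat(years, 12),
                        "month": np.tile(months, len(years)),
                        "variable": var,
                        "value": vals,
                    }
                )
            )
    env = pd.concat(rows, ignore_index=True)
    stations = pd.DataFrame(
        {
            "station_id": [f"S{s:02d}" for s in range(n_s)],
            "x": station_xy[:, 0],
            "y": station_xy[:, 1],
        }
    )
    return env, stations


def _make_physicians(params: GenerativeParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_physicians
    langs = []
    for _ in range(n):
        primary = LANGUAGES[rng.choice(len(LANGUAGES), p=[0.8, 0.15, 0.05])]
        extra = [l for l in LANGUAGES if l != primary and rng.random() < 0.2]
        langs.append(";".join([primary] + extra))
    accepted = []
    for _ in range(n):
        acc = [ins for ins in INSURANCES if rng.random() < 0.75]
        if not acc:
            acc = ["commercial"]
        accepted.append(";".join(acc))
    return pd.DataFrame(
        {
            "physician_id": [f"D{j:03d}" for j in range(n)],
            "age": rng.integers(30, 70, size=n),
            "gender": rng.choice(GENDERS, size=n),
            "languages": langs,
            "insurances_accepted": accepted,
            "office_x": rng.uniform(size=n),
            "office_y": rng.uniform(size=n),
            "office_hours_week": rng.integers(20, 61, size=n),
            "years_in_practice": rng.integers(1, 41, size=n),
            "specialty": rng.choice(SPECIALTIES, size=n, p=[0.4, 0.3, 0.2, 0.1]),
        }
    )


def _make_patients(
    params: GenerativeParams, physicians: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    n = params.n_patients
    # skewed panel sizes so some physicians have very small asthma panels
    panel_w = rng.dirichlet(np.full(params.n_physicians, 0.5))
    phys_idx = rng.choice(params.n_physicians, size=n, p=panel_w)
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "birth_year": rng.integers(params.start_year - 80, params.start_year, size=n),
            "gender": rng.choice(GENDERS, size=n),
            "race": rng.choice(RACES, size=n, p=[0.72, 0.06, 0.05, 0.13, 0.04]),
            "language": rng.choice(LANGUAGES, size=n, p=[0.82, 0.13, 0.05]),
            "insurance": rng.choice(INSURANCES, size=n, p=[0.55, 0.2, 0.15, 0.1]),
            "home_x": rng.uniform(size=n),
            "home_y": rng.uniform(size=n),
            "physician_id": physicians["physician_id"].to_numpy()[phys_idx],
        }
    )
    is_asthma = rng.random(n) < params.asthma_prevalence
    return patients, is_asthma


def generate_cohort(params: GenerativeParams) -> CohortBundle:
    """Generate a full linked cohort bundle from ``params``.

    Per patient-year, the event probability starts at ``base_event_rate``
    shifted on the log-odds scale by the patient's physician effect, then
    planted patterns override (or scale) it where their conditions hold.
    Realized events become acute encounters with a primary 493.xx
    diagnosis; true cost is a heavy-tailed body draw plus the event
    costs. Same params + seed => identical bundle.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    physicians = _make_physicians(params, rng)
    patients, is_asthma = _make_patients(params, physicians, rng)
    phys_effect = rng.normal(0.0, params.physician_effect_sd, size=params.n_physicians)
    phys_lookup = dict(zip(physicians["physician_id"], range(params.n_physicians)))

    station_xy = rng.uniform(size=(params.n_stations, 2))
    environment, stations = generate_env_series(params, rng, station_xy)

    n = params.n_patients
    pidx = patients["physician_id"].map(phys_lookup).to_numpy()
    panel_asthma = np.bincount(pidx[is_asthma], minlength=params.n_physicians)
    office = physicians[["office_x", "office_y"]].to_numpy()[pidx]
    home = patients[["home_x", "home_y"]].to_numpy()
    distance = np.hypot(*(home - office).T)

    base_logit = math.log(params.base_event_rate / (1 - params.base_event_rate)) if (
        0 < params.base_event_rate < 1
    ) else None

    # per-patient medication propensity (controller adherence heterogeneity)
    controller_lam = rng.gamma(2.0, 0.8, size=n)
    # persistent cost frailty: chronic high utilizers stay expensive
    frailty = rng.normal(0.0, params.cost_frailty_sd, size=n)

    mu_e = math.log(params.event_unit_cost_mean) - params.event_cost_sigma**2 / 2 if (
        params.event_unit_cost_mean > 0
    ) else None

    enc_rows: list[pd.DataFrame] = []
    disp_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []

    prior_inpatient = np.zeros(n, dtype=int)
    prior_acute = np.zeros(n, dtype=int)

    years = np.arange(params.start_year, params.start_year + params.n_years)
    for year in years:
        age = year - patients["birth_year"].to_numpy()
        frame = pd.DataFrame(
            {
                "age": age,
                "gender": patients["gender"].to_numpy(),
                "race": patients["race"].to_numpy(),
                "language": patients["language"].to_numpy(),
                "insurance": patients["insurance"].to_numpy(),
                "prior_inpatient": prior_inpatient,
                "prior_acute": prior_acute,
                "physician_panel_asthma": panel_asthma[pidx],
                "distance": distance,
            }
        )
        if base_logit is None:
            prob = np.full(n, params.base_event_rate)
        else:
            prob = 1.0 / (1.0 + np.exp(-(base_logit + phys_effect[pidx])))
        for pat in params.planted_patterns:
            mask = _pattern_mask(frame, pat)
            if pat.mode == "absolute":
                prob = np.where(mask, pat.probability, prob)
            elif pat.mode == "multiplier":
                prob = np.where(mask, np.clip(prob * pat.probability, 0.0, 1.0), prob)
            else:
                raise ValueError(f"planted pattern mode {pat.mode!r} unknown")
        prob = np.where(is_asthma, prob, 0.0)

        event_any = rng.random(n) < prob
        n_events = np.where(
            event_any, 1 + rng.poisson(params.extra_event_rate, size=n), 0
        )

        # acute encounters (one per event)
        total_events = int(n_events.sum())
        if total_events:
            owner = np.repeat(np.arange(n), n_events)
            etype = rng.choice(
                ["inpatient", "emergency", "urgent care"],
                size=total_events,
                p=params.acute_type_probs,
            )
            ecost = (
                rng.lognormal(mu_e, params.event_cost_sigma, size=total_events)
                if mu_e is not None
                else np.zeros(total_events)
            )
            enc_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[owner],
                        "year": year,
                        "month": rng.integers(1, 13, size=total_events),
                        "visit_type": etype,
                        "primary_dx": rng.choice(ASTHMA_CODES, size=total_events),
                        "cost": np.round(ecost, 2),
                    }
                )
            )
            event_cost_by_patient = np.bincount(owner, weights=ecost, minlength=n)
        else:
            event_cost_by_patient = np.zeros(n)

        # background outpatient encounters; body cost split across them
        n_outpt = 1 + rng.poisson(params.outpatient_rate, size=n)
        body_cost = rng.lognormal(params.cost_body[0] + frailty, params.cost_body[1])
        owner = np.repeat(np.arange(n), n_outpt)
        per_visit_cost = np.repeat(body_cost / n_outpt, n_outpt)
        dx_is_asthma = (rng.random(owner.size) < 0.6) & is_asthma[owner]
        dx = np.where(
            dx_is_asthma,
            rng.choice(ASTHMA_CODES, size=owner.size),
            rng.choice(OTHER_CODES, size=owner.size),
        )
        enc_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"].to_numpy()[owner],
                    "year": year,
                    "month": rng.integers(1, 13, size=owner.size),
                    "visit_type": "outpatient",
                    "primary_dx": dx,
                    "cost": np.round(per_visit_cost, 2),
                }
            )
        )

        # medication dispensings
        n_controller = np.where(is_asthma, rng.poisson(controller_lam), 0)
        n_reliever = np.where(is_asthma, rng.poisson(0.5 + 3.0 * prob), 0)
        n_oral = rng.binomial(n_events, 0.7)
        n_other = rng.poisson(0.2, size=n)
        for counts, classes in (
            (n_controller, CONTROLLER_CLASSES),
            (n_reliever, (RELIEVER_CLASS,)),
            (n_oral, ("oral steroid",)),
            (n_other, ("other",)),
        ):
            tot = int(counts.sum())
            if not tot:
                continue
            owner = np.repeat(np.arange(n), counts)
            disp_rows.append(
                pd.DataFrame(
                    {
                        "patient_id": patients["patient_id"].to_numpy()[owner],
                        "year": year,
                        "month": rng.integers(1, 13, size=tot),
                        "med_class": rng.choice(classes, size=tot),
                        "amount": rng.choice([30, 60, 90], size=tot),
                    }
                )
            )

        truth_rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"],
                    "year": year,
                    "true_event_prob": prob,
                    "true_event_count": n_events,
                    "true_cost": np.round(body_cost + event_cost_by_patient, 2),
                }
            )
        )

        inpat = np.zeros(n, dtype=int)
        if total_events:
            ev_owner = np.repeat(np.arange(n), n_events)
            inpat = np.bincount(ev_owner, weights=(etype == "inpatient"), minlength=n).astype(int)
        prior_inpatient = inpat
        prior_acute = n_events

    encounters = pd.concat(enc_rows, ignore_index=True)
    dispensings = (
        pd.concat(disp_rows, ignore_index=True)
        if disp_rows
        else pd.DataFrame(columns=["patient_id", "year", "month", "med_class", "amount"])
    )
    truth = pd.concat(truth_rows, ignore_index=True)

    # inject completely-at-random missingness into optional patient cells
    for col in ("race", "language"):
        blank = rng.random(n) < params.missing_rate
        patients.loc[blank, col] = ""

    return CohortBundle(
        patients=patients,
        physicians=physicians,
        encounters=encounters.sort_values(
            ["patient_id", "year", "month"], kind="stable"
        ).reset_index(drop=True),
        dispensings=dispensings.sort_values(
            ["patient_id", "year", "month"], kind="stable"
        ).reset_index(drop=True),
        environment=environment,
        stations=stations,
        truth=truth.reset_index(drop=True),
        params=params,
    )


def with_seed(params: GenerativeParams, seed: int) -> GenerativeParams:
    """Copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
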