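"""Synthetic FAERS-like data with known ground truth.

Every downstream stage (parsing, deduplication, event flagging,
disproportionality scoring, onset analysis) is tested against data from
this generator, because real spontaneous-report extracts are large,
partly licensed (the event terminology) and carry no ground truth.

The generative model, per report (case):

* demographics: age ~ Normal(``age_mean``, ``age_sd``) truncated to
  [1, 115] years; sex female with probability ``female_frac``; weight
  ~ Normal(``weight_mean``, ``weight_sd``); reporter category from
  ``reporter_mix``; receipt date uniform over the calendar window.
* drug exposures: each vocabulary drug independently with its
  ``background_exposure`` probability; the verbatim name on the drug
  line is drawn among the generic name and its brand synonyms (half the
  time upper-cased) to exercise name consolidation.
* events: each preferred term independently with its
  ``background_event`` probability, multiplied by the relative risk of
  every signal pair whose drug the case is exposed to, capped at 1.
  Because of the cap, the realized relative reporting ratio compresses
  toward 1 as ``rr * background_event`` approaches 1.
* onset: a "driver" drug is chosen (the first exposed signal-pair drug
  whose paired event occurred, else the first exposed drug); the single
  case-level event date is the driver's therapy start plus a log-normal
  number of days with the driver's class-specific (mu, sigma).  The
  driver is the report's primary-suspect drug line; other lines are
  concomitant.
* duplicates: with probability ``duplicate_rate`` the case also emits a
  superseded earlier version — same case id, strictly earlier receipt
  date, strictly smaller record id, weight perturbed — so the
  deduplication rule has real work to do.
* partial dates: a configurable fraction of therapy-start and event
  dates are truncated to 6-digit ``YYYYMM`` form.

Deterministic for a fixed seed (byte-identical tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .io import FaersTables, write_tables

__all__ = [
    "DrugSpec",
    "EventSpec",
    "SignalPair",
    "OnsetDist",
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticData",
    "generate",
    "default_config",
    "DRUG_CLASSES",
]

DRUG_CLASSES = ("hormonal", "oncological", "ophthalmic", "nervous system", "other")

REPORTER_OCCP = {
    "physician": "MD",
    "pharmacist": "PH",
    "other-health-professional": "OT",
    "consumer": "CN",
    "unknown": "",
}

# country mix of reported cases (share of reports by reporter country)
_COUNTRIES = ("US", "XX", "CA", "JP", "DE", "FR", "BR", "GB", "AU", "ES", "IT")
_COUNTRY_P = (0.5352, 0.1499, 0.0886, 0.0705, 0.0425, 0.0405, 0.0326, 0.0273, 0.0063, 0.0036, 0.0030)

_CLASS_ROUTES = {
    "hormonal": ("ORAL", "RESPIRATORY (INHALATION)"),
    "oncological": ("ORAL", "INTRAVENOUS"),
    "ophthalmic": ("OPHTHALMIC", "INTRAOCULAR"),
    "nervous system": ("ORAL", "ORAL"),
    "other": ("ORAL", "SUBCUTANEOUS"),
}

_CLASS_INDICATIONS = {
    "hormonal": "Rheumatoid arthritis",
    "oncological": "Plasma cell myeloma",
    "ophthalmic": "Macular degeneration",
    "nervous system": "Epilepsy",
    "other": "Other indication",
}


class DrugSpec(BaseModel):
    generic: str
    brands: list[str] = Field(default_factory=list)
    drug_class: str

    @field_validator("drug_class")
    @classmethod
    def _class_known(cls, v: str) -> str:
        if v not in DRUG_CLASSES:
            raise ValueError(f"drug_class must be one of {DRUG_CLASSES}, got {v!r}")
        return v


class EventSpec(BaseModel):
    pt: str
    smq_narrow: bool = False


class SignalPair(BaseModel):
    drug: str
    event: str
    rr: float = Field(ge=1.0)


class OnsetDist(BaseModel):
    """Log-normal onset-day parameters: ``days = exp(mu + sigma*Z)``."""

    mu: float
    sigma: float = Field(gt=0.0)

    @property
    def median_days(self) -> float:
        return float(np.exp(self.mu))

    @property
    def mean_days(self) -> float:
        return float(np.exp(self.mu + self.sigma**2 / 2))


def _default_onset_dists() -> dict[str, OnsetDist]:
    # class mean onset days: ophthalmic 120.29, oncological 128.9,
    # nervous system 196.26, hormonal 325.35, other 495.40;
    # sigma fixed at 0.8, mu = ln(mean) - sigma^2/2
    sigma = 0.8
    means = {
        "hormonal": 325.35,
        "oncological": 128.9,
        "ophthalmic": 120.29,
        "nervous system": 196.26,
        "other": 495.40,
    }
    return {
        cls: OnsetDist(mu=float(np.log(m) - sigma**2 / 2), sigma=sigma)
        for cls, m in means.items()
    }


def _default_vocab() -> list[DrugSpec]:
    v = [
        ("dexamethasone", ["Decadron", "Ozurdex"], "hormonal"),
        ("budesonide", ["Pulmicort", "Entocort"], "hormonal"),
        ("lenalidomide", ["Revlimid"], "oncological"),
        ("tamoxifen", ["Nolvadex"], "oncological"),
        ("aflibercept", ["Eylea"], "ophthalmic"),
        ("travoprost", ["Travatan"], "ophthalmic"),
        ("quetiapine", ["Seroquel"], "nervous system"),
        ("clobazam", ["Onfi", "Frisium"], "nervous system"),
        ("tamsulosin", ["Flomax"], "other"),
        ("nitisinone", ["Orfadin"], "other"),
        ("hydrochlorothiazide", ["Microzide"], "other"),
        ("sildenafil", ["Viagra"], "other"),
    ]
    return [DrugSpec(generic=g, brands=b, drug_class=c) for g, b, c in v]


def _default_events() -> list[EventSpec]:
    # toy terminology: a small synthetic stand-in for a licensed narrow
    # SMQ term list, NOT a real MedDRA extract
    narrow = ["Cataract", "Lens opacity", "Cataract subcapsular"]
    other = [
        "Headache", "Nausea", "Dizziness", "Rash", "Fatigue",
        "Arthralgia", "Pyrexia", "Insomnia", "Diarrhoea",
    ]
    return [EventSpec(pt=p, smq_narrow=True) for p in narrow] + [
        EventSpec(pt=p) for p in other
    ]


class SyntheticConfig(BaseModel):
    """Full parameterization of the generator; see module docstring."""

    n_cases: int = Field(ge=1, default=20_000)
    drug_vocab: list[DrugSpec] = Field(default_factory=_default_vocab)
    event_vocab: list[EventSpec] = Field(default_factory=_default_events)
    background_exposure: float | dict[str, float] = 0.05
    background_event: float | dict[str, float] = 0.01
    signal_pairs: list[SignalPair] = Field(
        default_factory=lambda: [
            SignalPair(drug="dexamethasone", event="Cataract", rr=10.0),
            SignalPair(drug="aflibercept", event="Cataract", rr=10.0),
            SignalPair(drug="tamsulosin", event="Lens opacity", rr=10.0),
        ]
    )
    duplicate_rate: float = Field(ge=0.0, lt=1.0, default=0.10)
    age_mean: float = 63.85
    age_sd: float = Field(gt=0.0, default=14.54)
    female_frac: float = Field(ge=0.0, le=1.0, default=0.6759)
    weight_mean: float = 74.72
    weight_sd: float = Field(gt=0.0, default=20.89)
    onset_dist: dict[str, OnsetDist] = Field(default_factory=_default_onset_dists)
    reporter_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "physician": 0.50,
            "pharmacist": 0.047,
            "other-health-professional": 0.183,
            "consumer": 0.27,
        }
    )
    window_start: str = "20040101"
    window_end: str = "20241231"
    partial_date_frac: float = Field(ge=0.0, lt=1.0, default=0.05)
    seed: int = 0

    @field_validator("background_exposure", "background_event")
    @classmethod
    def _probs_open_unit(cls, v, info):
        vals = v.values() if isinstance(v, dict) else [v]
        for p in vals:
            if not (0.0 < p < 1.0):
                raise ValueError(f"{info.field_name} probabilities must lie in (0, 1)")
        return v

    @field_validator("reporter_mix")
    @classmethod
    def _mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("reporter_mix must be non-empty")
        for k, p in v.items():
            if k not in REPORTER_OCCP:
                raise ValueError(f"reporter_mix: unknown category {k!r}")
            if p < 0:
                raise ValueError("reporter_mix proportions must be >= 0")
        total = sum(v.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"reporter_mix must sum to 1, got {total}")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "SyntheticConfig":
        generics = {d.generic for d in self.drug_vocab}
        if len(generics) != len(self.drug_vocab):
            raise ValueError("drug_vocab: duplicate generic names")
        pts = {e.pt for e in self.event_vocab}
        if len(pts) != len(self.event_vocab):
            raise ValueError("event_vocab: duplicate preferred terms")
        for pair in self.signal_pairs:
            if pair.drug not in generics:
                raise ValueError(f"signal_pairs: drug {pair.drug!r} not in drug_vocab")
            if pair.event not in pts:
                raise ValueError(f"signal_pairs: event {pair.event!r} not in event_vocab")
        if isinstance(self.background_exposure, dict):
            missing = set(self.background_exposure) - generics
            if missing:
                raise ValueError(f"background_exposure: unknown drugs {sorted(missing)}")
        if isinstance(self.background_event, dict):
            missing = set(self.background_event) - pts
            if missing:
                raise ValueError(f"background_event: unknown events {sorted(missing)}")
        for cls in {d.drug_class for d in self.drug_vocab}:
            if cls not in self.onset_dist:
                raise ValueError(f"onset_dist: missing class {cls!r}")
        if int(self.window_start) >= int(self.window_end):
            raise ValueError("window_start must precede window_end")
        return self

    def exposure_probs(self) -> np.ndarray:
        if isinstance(self.background_exposure, dict):
            return np.array(
                [self.background_exposure[d.generic] for d in self.drug_vocab]
            )
        return np.full(len(self.drug_vocab), self.background_exposure)

    def event_probs(self) -> np.ndarray:
        if isinstance(self.background_event, dict):
            return np.array([self.background_event[e.pt] for e in self.event_vocab])
        return np.full(len(self.event_vocab), self.background_event)


def default_config(**overrides) -> SyntheticConfig:
    """The stock generator configuration, optionally overridden per field."""
    return SyntheticConfig(**overrides)


@dataclass
class GroundTruth:
    """What the generator actually did, for exact downstream checks.

    ``records`` has one row per emitted DEMO row (record_id, case_id,
    version, is_duplicate — True marks the superseded version).
    ``exposures`` / ``events`` are boolean case-by-name matrices of the
    latent (current-version) state.  ``driver`` and ``onset_days`` give
    the per-case suspect drug and its true onset interval (NaN when the
    case has no event).  ``true_rr(drug, event)`` is the configured
    relative risk, exactly 1 for non-signal pairs.
    """

    records: pd.DataFrame
    exposures: pd.DataFrame
    events: pd.DataFrame
    reporters: pd.Series
    driver: pd.Series
    onset_days: pd.Series
    signal_pairs: pd.DataFrame

    def true_rr(self, drug: str, event: str) -> float:
        hit = self.signal_pairs.loc[
            (self.signal_pairs["drug"] == drug) & (self.signal_pairs["event"] == event),
            "rr",
        ]
        return float(hit.iloc[0]) if len(hit) else 1.0

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, obj in (
            ("records", self.records),
            ("exposures", self.exposures.reset_index()),
            ("events", self.events.reset_index()),
            ("reporters", self.reporters.rename("reporter").reset_index()),
            ("driver", self.driver.rename("driver").reset_index()),
            ("onset_days", self.onset_days.rename("onset_days").reset_index()),
            ("signal_pairs", self.signal_pairs),
        ):
            p = directory / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths


@dataclass
class SyntheticData:
    tables: FaersTables
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, directory: str | Path, *, delimiter: str = "$") -> dict[str, Path]:
        directory = Path(directory)
        paths = write_tables(self.tables, directory, delimiter=delimiter)
        paths.update(self.truth.write(directory / "ground_truth"))
        return paths


def _dates_to_str(days: np.ndarray, origin: pd.Timestamp) -> np.ndarray:
    """Integer day offsets -> YYYYMMDD strings."""
    stamps = origin + pd.to_timedelta(days.astype("int64"), unit="D")
    return pd.DatetimeIndex(stamps).strftime("%Y%m%d").to_numpy()


def _truncate_partial(dates: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = dates.astype(object).copy()
    for i in np.flatnonzero(mask):
        out[i] = out[i][:6]
    return out


def generate(config: SyntheticConfig) -> SyntheticData:
    """Draw one synthetic extract; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    drugs = config.drug_vocab
    events_v = config.event_vocab
    n_drugs, n_events = len(drugs), len(events_v)
    generics = [d.generic for d in drugs]
    pts = [e.pt for e in events_v]
    classes = np.array([d.drug_class for d in drugs])

    origin = pd.Timestamp(config.window_start[:4] + "0101")
    w_start = (pd.to_datetime(config.window_start, format="%Y%m%d") - origin).days
    w_end = (pd.to_datetime(config.window_end, format="%Y%m%d") - origin).days

    case_ids = np.array([f"{i + 1:07d}" for i in range(n)])

    # demographics -- drawn first, in fixed order, for reproducibility
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 1.0, 115.0).round(1)
    female = rng.random(n) < config.female_frac
    weight = np.clip(rng.normal(config.weight_mean, config.weight_sd, n), 30.0, 200.0).round(1)
    country = rng.choice(_COUNTRIES, p=_COUNTRY_P, size=n)
    reporter_cats = list(config.reporter_mix)
    reporter = rng.choice(reporter_cats, p=list(config.reporter_mix.values()), size=n)
    fda_days = rng.integers(w_start, w_end + 1, size=n)

    # exposures and events
    exposed = rng.random((n, n_drugs)) < config.exposure_probs()[None, :]
    p_event = np.broadcast_to(config.event_probs()[None, :], (n, n_events)).copy()
    drug_idx = {g: j for j, g in enumerate(generics)}
    event_idx = {p: k for k, p in enumerate(pts)}
    for pair in config.signal_pairs:
        j, k = drug_idx[pair.drug], event_idx[pair.event]
        p_event[exposed[:, j], k] *= pair.rr
    np.minimum(p_event, 1.0, out=p_event)
    occurred = rng.random((n, n_events)) < p_event

    # therapy starts: uniform over the window, leaving room for onsets
    start_hi = max(w_start + 1, w_end - 4 * 365)
    start_days = rng.integers(w_start, start_hi + 1, size=(n, n_drugs))

    # driver drug: first exposed signal drug whose paired event occurred,
    # else the first exposed drug
    signal_hit = np.zeros((n, n_drugs), dtype=bool)
    for pair in config.signal_pairs:
        j, k = drug_idx[pair.drug], event_idx[pair.event]
        signal_hit[:, j] |= exposed[:, j] & occurred[:, k]
    priority = signal_hit.astype(np.int8) * 2 + exposed.astype(np.int8)
    driver_j = np.argmax(priority, axis=1)
    has_drug = exposed.any(axis=1)
    has_event = occurred.any(axis=1)

    mu = np.array([config.onset_dist[c].mu for c in classes])
    sigma = np.array([config.onset_dist[c].sigma for c in classes])
    z = rng.standard_normal(n)
    onset = np.maximum(1, np.round(np.exp(mu[driver_j] + sigma[driver_j] * z))).astype(int)
    event_day = start_days[np.arange(n), driver_j] + onset
    have_onset = has_drug & has_event

    dup = rng.random(n) < config.duplicate_rate
    dup_delta = rng.integers(30, 365, size=n)  # receipt-date gap to superseded version

    partial_event = rng.random(n) < config.partial_date_frac
    partial_start = rng.random((n, n_drugs)) < config.partial_date_frac

    # ---------------- DEMO ----------------
    fda_str = _dates_to_str(fda_days, origin)
    event_str = np.where(
        have_onset, _truncate_partial(_dates_to_str(event_day, origin), partial_event & have_onset), ""
    ).astype(object)
    version = np.where(dup, 2, 1)
    demo_current = pd.DataFrame(
        {
            "primaryid": np.char.add(case_ids, version.astype(str)),
            "caseid": case_ids,
            "fda_dt": fda_str,
            "event_dt": event_str,
            "age": age.astype(str),
            "age_cod": "YR",
            "sex": np.where(female, "F", "M"),
            "wt": weight.astype(str),
            "reporter_country": country,
            "occp_cod": pd.Series(reporter).map(REPORTER_OCCP).to_numpy(),
        }
    )
    sup = np.flatnonzero(dup)
    demo_sup = demo_current.iloc[sup].copy()
    demo_sup["primaryid"] = np.char.add(case_ids[sup], "1")
    demo_sup["fda_dt"] = _dates_to_str(fda_days[sup] - dup_delta[sup], origin)
    demo_sup["wt"] = (weight[sup] + 1.0).round(1).astype(str)
    demo = pd.concat([demo_current, demo_sup], ignore_index=True)
    demo = demo.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    # ---------------- DRUG / THER ----------------
    ci, dj = np.nonzero(exposed)
    counts = exposed.sum(axis=1)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    seq = (np.arange(len(ci)) - offsets + 1).astype(int)

    brand_pool = [[d.generic] + list(d.brands) for d in drugs]
    pick = rng.integers(0, 1 << 30, size=len(ci))
    upper = rng.random(len(ci)) < 0.5
    verbatim = np.array(
        [brand_pool[j][p % len(brand_pool[j])] for j, p in zip(dj, pick)], dtype=object
    )
    verbatim = np.where(upper, np.char.upper(verbatim.astype(str)), verbatim.astype(str))

    route_pick = rng.random(len(ci)) < 0.5
    routes = np.array(
        [_CLASS_ROUTES[classes[j]][int(r)] for j, r in zip(dj, route_pick)], dtype=object
    )
    is_driver_line = driver_j[ci] == dj
    role = np.where(is_driver_line & has_drug[ci], "PS", "C")

    drug_tbl_current = pd.DataFrame(
        {
            "primaryid": np.char.add(case_ids[ci], version[ci].astype(str)),
            "drug_seq": seq.astype(str),
            "drugname": verbatim,
            "role_cod": role,
            "route": routes,
            "indi_pt": np.array([_CLASS_INDICATIONS[classes[j]] for j in dj], dtype=object),
        }
    )
    start_str = _dates_to_str(start_days[ci, dj], origin).astype(object)
    pmask = partial_start[ci, dj]
    start_str = _truncate_partial(start_str, pmask)
    ther_current = pd.DataFrame(
        {
            "primaryid": drug_tbl_current["primaryid"],
            "drug_seq": seq.astype(str),
            "start_dt": start_str,
        }
    )

    # ---------------- REAC ----------------
    ei, ek = np.nonzero(occurred)
    reac_current = pd.DataFrame(
        {
            "primaryid": np.char.add(case_ids[ei], version[ei].astype(str)),
            "pt": np.array(pts, dtype=object)[ek],
        }
    )

    # superseded versions repeat the case's drug and event lines
    def _sup_rows(frame: pd.DataFrame, case_rows: np.ndarray) -> pd.DataFrame:
        mask = dup[case_rows]
        sub = frame.loc[mask].copy()
        sub["primaryid"] = np.char.add(case_ids[case_rows[mask]], "1")
        return sub

    drug_tbl = pd.concat(
        [drug_tbl_current, _sup_rows(drug_tbl_current, ci)], ignore_index=True
    ).sort_values(["primaryid", "drug_seq"], kind="mergesort").reset_index(drop=True)
    ther_tbl = pd.concat(
        [ther_current, _sup_rows(ther_current, ci)], ignore_index=True
    ).sort_values(["primaryid", "drug_seq"], kind="mergesort").reset_index(drop=True)
    reac_tbl = pd.concat(
        [reac_current, _sup_rows(reac_current, ei)], ignore_index=True
    ).sort_values(["primaryid", "pt"], kind="mergesort").reset_index(drop=True)

    tables = FaersTables(demo=demo, drug=drug_tbl, reac=reac_tbl, ther=ther_tbl)

    # ---------------- ground truth ----------------
    rec_current = pd.DataFrame(
        {
            "record_id": np.char.add(case_ids, version.astype(str)),
            "case_id": case_ids,
            "version": version,
            "is_duplicate": False,
        }
    )
    rec_sup = pd.DataFrame(
        {
            "record_id": np.char.add(case_ids[sup], "1"),
            "case_id": case_ids[sup],
            "version": 1,
            "is_duplicate": True,
        }
    )
    records = pd.concat([rec_current, rec_sup], ignore_index=True).sort_values(
        "record_id", kind="mergesort"
    ).reset_index(drop=True)

    truth = GroundTruth(
        records=records,
        exposures=pd.DataFrame(exposed, index=pd.Index(case_ids, name="case_id"), columns=generics),
        events=pd.DataFrame(occurred, index=pd.Index(case_ids, name="case_id"), columns=pts),
        reporters=pd.Series(reporter, index=pd.Index(case_ids, name="case_id")),
        driver=pd.Series(
            np.where(has_drug, np.array(generics, dtype=object)[driver_j], None),
            index=pd.Index(case_ids, name="case_id"),
        ),
        onset_days=pd.Series(
            np.where(have_onset, onset.astype(float), np.nan),
            index=pd.Index(case_ids, name="case_id"),
        ),
        signal_pairs=pd.DataFrame(
            [(p.drug, p.event, p.rr) for p in config.signal_pairs],
            columns=["drug", "event", "rr"],
        ),
    )
    return SyntheticData(tables=tables, truth=truth, config=config)
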