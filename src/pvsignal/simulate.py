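"""Synthetic spontaneous-report generator with known ground truth.

The generator emulates the structure of a FAERS-style database closely
enough to exercise every downstream stage: multi-drug multi-event reports,
role codes, per-drug therapeutic indications, demographics with realistic
missingness, reporter mix, calendar skew, outcome flags — and, crucially,
*planted* drug-event reporting-rate ratios, sex/age subgroup effects, and
drug-pair interaction effects that downstream statistics should recover.

Sampling model (per report, independently):

* each catalog drug is included by an independent Bernoulli draw of its
  marginal probability; a report that draws no drug receives the designated
  background drug instead, so catalog marginals stay exact;
* each catalog event's inclusion probability is its baseline multiplied by
  every applicable association multiplier (drug present), subgroup
  multiplier (drug present and report in stratum), and interaction
  multiplier (both drugs present), capped at 1 (capping is counted and
  warned about);
* demographics, roles, indications, dates, and outcome flags are sampled
  from the configured mixes, independent of the event draws.

Events are conditionally independent given the drug set — there is no
report-level correlation beyond shared drugs.  This is the simplest
structure consistent with the case/non-case counting model; see the
methods note for what that simplification does and does not test.

Reproducibility: one root seed drives a counter-based bit generator
(Philox); report ``i`` consumes row ``i`` of a fixed-width uniform matrix,
so enlarging ``n_reports`` extends a collection without reshuffling the
reports already generated (catalogs held fixed).
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .reports import (
    DrugMention,
    EventMention,
    Outcome,
    ReportRecord,
    ReporterType,
    Role,
    Sex,
)

__all__ = ["SimulationConfig", "generate", "make_aslike_fixture"]

#: Stratum tokens accepted in subgroup_effects keys.
STRATA = ("male", "female", "age_0-24", "age_25-65", "age_>65")

_YEAR_BUCKETS = {"2004-2008": (2004, 2008), "2009-2013": (2009, 2013),
                 "2014-2018": (2014, 2018), "2019-2022": (2019, 2022)}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic collection.

    Multiplier maps are keyed by normalized (drug, pt[, stratum]) tuples;
    a missing key means multiplier 1.  ``background_drug`` is the drug
    assigned to reports whose Bernoulli draws select no catalog drug, so
    that configured catalog marginals are met exactly in expectation.
    """

    n_reports: int
    drug_catalog: tuple[tuple[str, float], ...]
    event_catalog: tuple[tuple[str, float], ...]
    seed: int = 0
    background_drug: str = "other medication"
    association_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)
    subgroup_effects: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    interaction_multipliers: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    p_female: float = 0.70          # among reports with known sex
    sex_missing: float = 0.12
    age_mean: float = 47.0
    age_sd: float = 12.0
    age_missing: float = 0.40
    reporter_mix: Mapping[str, float] = field(default_factory=lambda: {
        "healthcare_professional": 0.34, "consumer": 0.08, "unspecified": 0.58})
    year_bucket_weights: Mapping[str, float] = field(default_factory=lambda: {
        "2004-2008": 0.03, "2009-2013": 0.03, "2014-2018": 0.06, "2019-2022": 0.88})
    role_mix: Mapping[str, float] = field(default_factory=lambda: {
        "PS": 0.10, "SS": 0.75, "C": 0.15})
    indication_rules: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: {
        "death": 0.113, "hospitalization": 0.182, "life_threatening": 0.05,
        "disability": 0.05, "congenital_anomaly": 0.005, "other_serious": 0.50})
    start_date_recorded: float = 0.5
    onset_date_recorded: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        object.__setattr__(self, "drug_catalog",
                           tuple((n.casefold().strip(), float(p)) for n, p in self.drug_catalog))
        object.__setattr__(self, "event_catalog",
                           tuple((n.casefold().strip(), float(p)) for n, p in self.event_catalog))
        names = [n for n, _ in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug in catalog")
        for label, catalog in (("drug", self.drug_catalog), ("event", self.event_catalog)):
            for name, p in catalog:
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{label} {name!r}: probability {p} outside [0, 1]")
        for m in (self.association_multipliers, self.subgroup_effects,
                  self.interaction_multipliers):
            for key, v in m.items():
                if not (math.isfinite(v) and v >= 0):
                    raise ValueError(f"multiplier {key}: {v} must be finite and >= 0")
        for key in self.subgroup_effects:
            if key[2] not in STRATA:
                raise ValueError(f"unknown stratum {key[2]!r}; expected one of {STRATA}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_reports": self.n_reports,
            "seed": self.seed,
            "background_drug": self.background_drug,
            "drug_catalog": [[n, p] for n, p in self.drug_catalog],
            "event_catalog": [[n, p] for n, p in self.event_catalog],
            "association_multipliers": [[a, e, v] for (a, e), v in
                                        self.association_multipliers.items()],
            "subgroup_effects": [[a, e, s, v] for (a, e, s), v in
                                 self.subgroup_effects.items()],
            "interaction_multipliers": [[a, b, e, v] for (a, b, e), v in
                                        self.interaction_multipliers.items()],
            "p_female": self.p_female, "sex_missing": self.sex_missing,
            "age_mean": self.age_mean, "age_sd": self.age_sd,
            "age_missing": self.age_missing,
            "reporter_mix": dict(self.reporter_mix),
            "year_bucket_weights": dict(self.year_bucket_weights),
            "role_mix": dict(self.role_mix),
            "indication_rules": {k: list(v) for k, v in self.indication_rules.items()},
            "outcome_probs": dict(self.outcome_probs),
            "start_date_recorded": self.start_date_recorded,
            "onset_date_recorded": self.onset_date_recorded,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["drug_catalog"] = tuple((n, p) for n, p in d["drug_catalog"])
        d["event_catalog"] = tuple((n, p) for n, p in d["event_catalog"])
        d["association_multipliers"] = {(a, e): v for a, e, v in
                                        d.get("association_multipliers", [])}
        d["subgroup_effects"] = {(a, e, s): v for a, e, s, v in
                                 d.get("subgroup_effects", [])}
        d["interaction_multipliers"] = {(a, b, e): v for a, b, e, v in
                                        d.get("interaction_multipliers", [])}
        d["indication_rules"] = {k: tuple(v) for k, v in
                                 d.get("indication_rules", {}).items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _quarter_start(year: int, quarter: int) -> dt.date:
    return dt.date(year, 3 * (quarter - 1) + 1, 1)


def generate(config: SimulationConfig, seed: int | None = None) -> list[ReportRecord]:
    """Draw a fully reproducible synthetic report collection.

    ``seed`` overrides ``config.seed`` (convenient for replicate runs of
    one configuration).
    """
    n = config.n_reports
    n_drugs = len(config.drug_catalog)
    n_events = len(config.event_catalog)
    n_outcomes = len(Outcome)
    rng = np.random.Generator(np.random.Philox(config.seed if seed is None else seed))

    # Fixed-width uniform matrix: row i belongs to report i alone, so a
    # longer run extends a shorter one without reshuffling earlier reports.
    k_demo = 9
    cols_drug = 4    # presence, role, indication, start-lag
    cols_event = 2   # presence, onset-lag
    width = k_demo + cols_drug * n_drugs + cols_event * n_events + n_outcomes
    u = rng.random((n, width))

    u_sex, u_sexmiss = u[:, 0], u[:, 1]
    u_age1, u_age2, u_agemiss = u[:, 2], u[:, 3], u[:, 4]
    u_rep, u_year, u_quarter, u_vdate = u[:, 5], u[:, 6], u[:, 7], u[:, 8]
    off = k_demo
    u_drug = u[:, off:off + n_drugs]
    u_role = u[:, off + n_drugs:off + 2 * n_drugs]
    u_ind = u[:, off + 2 * n_drugs:off + 3 * n_drugs]
    u_start = u[:, off + 3 * n_drugs:off + 4 * n_drugs]
    off += 4 * n_drugs
    u_event = u[:, off:off + n_events]
    u_onset = u[:, off + n_events:off + 2 * n_events]
    off += 2 * n_events
    u_outcome = u[:, off:off + n_outcomes]

    # demographics ---------------------------------------------------------
    sex_missing = u_sexmiss < config.sex_missing
    female = u_sex < config.p_female
    # Box-Muller from the two dedicated uniform columns
    z = np.sqrt(-2.0 * np.log(np.clip(u_age1, 1e-12, None))) * np.cos(2 * np.pi * u_age2)
    ages = np.clip(config.age_mean + config.age_sd * z, 18.0, 95.0)
    age_missing = u_agemiss < config.age_missing

    rep_names = sorted(config.reporter_mix)  # sorted: output independent of dict order
    rep_cum = np.cumsum([config.reporter_mix[r] for r in rep_names])
    rep_cum = rep_cum / rep_cum[-1]
    rep_idx = np.searchsorted(rep_cum, u_rep, side="right")

    bucket_names = sorted(config.year_bucket_weights)
    b_cum = np.cumsum([config.year_bucket_weights[b] for b in bucket_names])
    b_cum = b_cum / b_cum[-1]
    bucket_idx = np.searchsorted(b_cum, u_year, side="right")

    # drugs ----------------------------------------------------------------
    drug_p = np.array([p for _, p in config.drug_catalog])
    has_drug = u_drug < drug_p[None, :]
    no_drug = ~has_drug.any(axis=1)

    role_names = sorted(config.role_mix)
    role_cum = np.cumsum([config.role_mix[r] for r in role_names])
    role_cum = role_cum / role_cum[-1]
    role_idx = np.searchsorted(role_cum, u_role, side="right")

    # events ---------------------------------------------------------------
    drug_index = {name: j for j, (name, _) in enumerate(config.drug_catalog)}
    event_index = {name: j for j, (name, _) in enumerate(config.event_catalog)}
    probs = np.tile(np.array([p for _, p in config.event_catalog]), (n, 1))

    for (drug, pt), rho in config.association_multipliers.items():
        d = drug_index.get(drug.casefold().strip())
        e = event_index.get(pt.casefold().strip())
        if d is None or e is None:
            raise KeyError(f"association multiplier refers to unknown {(drug, pt)}")
        probs[:, e] *= np.where(has_drug[:, d], rho, 1.0)

    stratum_masks = {
        "male": ~female & ~sex_missing,
        "female": female & ~sex_missing,
        "age_0-24": (ages < 25) & ~age_missing,
        "age_25-65": (ages >= 25) & (ages <= 65) & ~age_missing,
        "age_>65": (ages > 65) & ~age_missing,
    }
    for (drug, pt, stratum), mult in config.subgroup_effects.items():
        d = drug_index.get(drug.casefold().strip())
        e = event_index.get(pt.casefold().strip())
        if d is None or e is None:
            raise KeyError(f"subgroup effect refers to unknown {(drug, pt)}")
        mask = has_drug[:, d] & stratum_masks[stratum]
        probs[:, e] *= np.where(mask, mult, 1.0)

    for (drug_a, drug_b, pt), mult in config.interaction_multipliers.items():
        a = drug_index.get(drug_a.casefold().strip())
        b = drug_index.get(drug_b.casefold().strip())
        e = event_index.get(pt.casefold().strip())
        if a is None or b is None or e is None:
            raise KeyError(f"interaction multiplier refers to unknown {(drug_a, drug_b, pt)}")
        probs[:, e] *= np.where(has_drug[:, a] & has_drug[:, b], mult, 1.0)

    n_capped = int((probs > 1.0).sum())
    if n_capped:
        warnings.warn(f"{n_capped} event inclusion probabilities exceeded 1 and were capped")
    np.clip(probs, None, 1.0, out=probs)
    has_event = u_event < probs

    outcome_list = list(Outcome)
    out_p = np.array([config.outcome_probs.get(o.value, 0.0) for o in outcome_list])
    has_outcome = u_outcome < out_p[None, :]

    # assemble records -----------------------------------------------------
    role_map = {"PS": Role.primary_suspect, "SS": Role.secondary_suspect,
                "C": Role.concomitant, "I": Role.interacting}
    id_width = max(7, len(str(n)))
    records: list[ReportRecord] = []
    for i in range(n):
        lo_year, hi_year = _YEAR_BUCKETS[bucket_names[bucket_idx[i]]]
        span = hi_year - lo_year + 1
        year = lo_year + int(u_quarter[i] * span * 4) // 4
        quarter = int(u_quarter[i] * span * 4) % 4 + 1
        q_start = _quarter_start(year, quarter)
        vdate = q_start + dt.timedelta(days=int(u_vdate[i] * 89))

        mentions: list[DrugMention] = []
        drug_idxs = np.flatnonzero(has_drug[i])
        for j in drug_idxs:
            name = config.drug_catalog[j][0]
            rule = config.indication_rules.get(name)
            indication = None
            if rule is not None and u_ind[i, j] < rule[1]:
                indication = rule[0]
            start = None
            if u_start[i, j] < config.start_date_recorded:
                frac = u_start[i, j] / config.start_date_recorded
                start = vdate - dt.timedelta(days=40 + int(frac * 320))
            mentions.append(DrugMention(
                name=name, role=role_map[role_names[role_idx[i, j]]],
                indication=indication, start_date=start))
        if no_drug[i]:
            mentions.append(DrugMention(name=config.background_drug,
                                        role=Role.secondary_suspect))

        events: list[EventMention] = []
        for j in np.flatnonzero(has_event[i]):
            onset = None
            if u_onset[i, j] < config.onset_date_recorded:
                frac = u_onset[i, j] / config.onset_date_recorded
                onset = vdate - dt.timedelta(days=int(frac * 30))
            events.append(EventMention(pt=config.event_catalog[j][0], onset_date=onset))

        if sex_missing[i]:
            sex = Sex.missing
        else:
            sex = Sex.female if female[i] else Sex.male
        records.append(ReportRecord(
            report_id=f"SIM{i:0{id_width}d}",
            version_date=vdate,
            receipt_quarter=f"{year}Q{quarter}",
            reporter_type=ReporterType(rep_names[rep_idx[i]]),
            sex=sex,
            age_years=None if age_missing[i] else float(round(ages[i], 1)),
            drugs=tuple(mentions),
            events=tuple(events),
            outcomes=frozenset(o for o, flag in zip(outcome_list, has_outcome[i]) if flag),
        ))
    return records


# ---------------------------------------------------------------------------
# ready-made fixture
# ---------------------------------------------------------------------------

#: The ten PTs of the noninfectious myocarditis/pericarditis SMQ with
#: synthetic baseline reporting probabilities.
_SMQ_BASELINES: tuple[tuple[str, float], ...] = (
    ("pericarditis", 0.0008),
    ("red blood cell sedimentation rate increased", 0.0007),
    ("pericardial effusion", 0.0013),
    ("extrasystoles", 0.0004),
    ("cardiac failure acute", 0.0004),
    ("myocarditis", 0.0005),
    ("electrocardiogram abnormal", 0.0005),
    ("atrioventricular block", 0.0004),
    ("bundle branch block left", 0.0003),
    ("dilatation ventricular", 0.0002),
)

_BDMARDS: tuple[tuple[str, float], ...] = (
    ("adalimumab", 0.012), ("infliximab", 0.014), ("golimumab", 0.008),
    ("certolizumab", 0.008), ("etanercept", 0.014), ("secukinumab", 0.008),
    ("ustekinumab", 0.008),
)

_COMPARATORS: tuple[tuple[str, float], ...] = (
    ("tofacitinib", 0.006), ("upadacitinib", 0.003), ("sulfasalazine", 0.008),
    ("mesalazine", 0.006), ("methotrexate", 0.025), ("tocilizumab", 0.010),
)

#: Planted pericarditis reporting-rate ratios for the fixture drugs.
_FIXTURE_RRR: Mapping[str, float] = {
    "adalimumab": 10.0, "infliximab": 20.0, "golimumab": 15.0,
    "certolizumab": 15.0, "etanercept": 8.0, "secukinumab": 10.0,
    "ustekinumab": 25.0, "tofacitinib": 25.0, "sulfasalazine": 12.0,
    "methotrexate": 8.0,
}


def make_aslike_fixture(scale: int, seed: int) -> tuple[list[ReportRecord], SimulationConfig]:
    """A ready-made collection shaped like an ankylosing-spondylitis
    bDMARD pharmacovigilance extract.

    Seven bDMARD-like drugs and a comparator panel, the ten SMQ PTs plus
    common co-reported events, a female-skewed case profile (a x4 female
    subgroup effect on every bDMARD-pericarditis pair), year skew toward
    2019-2022, demographic missingness, and one planted drug-pair
    interaction (adalimumab x tocilizumab on pericarditis, x5).

    ``scale`` multiplies the base size of 30,000 reports.  Returns the
    collection together with its generating configuration — the ground
    truth for every planted effect.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    co_events = (
        ("oedema peripheral", 0.020), ("dizziness", 0.020),
        ("rheumatic fever", 0.004), ("dyspnoea", 0.025),
        ("peripheral swelling", 0.012), ("tachycardia", 0.008),
        ("systemic lupus erythematosus", 0.002), ("rheumatoid arthritis", 0.004),
    )
    assoc = {(d, "pericarditis"): r for d, r in _FIXTURE_RRR.items()}
    subgroup = {(d, "pericarditis", "female"): 4.0 for d, _ in _BDMARDS}
    config = SimulationConfig(
        n_reports=30_000 * scale,
        seed=seed,
        drug_catalog=_BDMARDS + _COMPARATORS,
        event_catalog=_SMQ_BASELINES + co_events,
        association_multipliers=assoc,
        subgroup_effects=subgroup,
        interaction_multipliers={("adalimumab", "tocilizumab", "pericarditis"): 5.0},
        indication_rules={d: ("ankylosing spondylitis", 0.9) for d, _ in _BDMARDS},
    )
    return generate(config), config
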