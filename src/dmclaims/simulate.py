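"""Synthetic statutory-health-insurance claims generator.

Produces an insured population with enrollment spells, latent diabetes
onsets, and the quarter-resolved claims those onsets generate: outpatient
diagnoses with certainty flags, inpatient main/secondary diagnoses, and
ATC-coded prescriptions.  The generator separates disease onset from its
*observation*: an onset produces an index diagnosis in its quarter only
with a probability given by the seasonal multiplier times any pandemic
disruption multiplier, and a suppressed index diagnosis is re-attempted in
later quarters (diagnostic catch-up).  Care disruption therefore shifts
when a case is documented, never whether the disease occurred.

Randomness is split into three independent streams (population, onsets,
claims) spawned from the scenario seed, so two scenarios differing only in
observation parameters (e.g. disruption) share identical populations and
onsets and can be compared pairwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig, rate_lookup
from .deprivation import categorize_districts
from .quarters import qindex, qnum, quarter_start, qyear

logger = logging.getLogger(__name__)

DIABETES_CODES = ("E10", "E11", "E12", "E13", "E14")
MISC_CODES = ("E12", "E13", "E14")
FILLER_CODES = ("I10", "J06", "K21", "M54", "E66")
INSULIN_ATC = "A10AB01"
ORAL_ATC = "A10BA02"
FILLER_ATC = "C07AB02"

DIAG_COLUMNS = ["person_id", "icd3", "setting", "certainty", "year", "quarter"]
RX_COLUMNS = ["person_id", "atc", "year", "quarter"]


def _streams(config: ScenarioConfig) -> dict[str, np.random.Generator]:
    pop, onset, claims, district = np.random.SeedSequence(config.rng_seed).spawn(4)
    return {
        "population": np.random.default_rng(pop),
        "onsets": np.random.default_rng(onset),
        "claims": np.random.default_rng(claims),
        "districts": np.random.default_rng(district),
    }


@dataclass
class SimulatedData:
    """All tables produced by one scenario run, plus the latent truth."""

    persons: pd.DataFrame
    spells: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    districts: pd.DataFrame
    onsets: pd.DataFrame


def _dates_in_year(years: np.ndarray, day_of_year: np.ndarray) -> pd.Series:
    base = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    )
    return base + pd.to_timedelta(day_of_year, unit="D")


def generate_districts(config: ScenarioConfig) -> pd.DataFrame:
    """District codes with a GISD-like deprivation score (higher = more
    deprived), drawn uniformly on [0, 1]."""
    rng = _streams(config)["districts"]
    codes = [f"D{i:03d}" for i in range(config.n_districts)]
    return pd.DataFrame(
        {"district_code": codes, "score": rng.random(config.n_districts)}
    )


def generate_population(
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw persons and their enrollment spells.

    Ages (completed years on 31 Dec of the first reporting year) and sexes
    follow the configured age/sex structure; birth dates are uniform within
    the birth year.  Every person enters observation at the later of birth
    and 1 Jan of the pre-observation year, and holds a single spell that is
    truncated by disenrollment or death, each acting as an annual hazard.
    """
    rng = _streams(config)["population"]
    first_year, last_year = config.years
    n = config.n_persons
    cells = config.age_sex_cells()
    if n == 0:
        persons = pd.DataFrame(
            columns=["person_id", "sex", "birth_date", "district_code", "prevalent"]
        )
        spells = pd.DataFrame(columns=["person_id", "start_date", "end_date"])
        return persons, spells

    counts = rng.multinomial(n, cells["proportion"].to_numpy())
    age = np.repeat(cells["age"].to_numpy(), counts)
    sex = np.repeat(cells["sex"].to_numpy(), counts)

    birth_year = first_year - age
    birth_date = _dates_in_year(birth_year, rng.integers(0, 365, n))
    district = np.array(
        [f"D{i:03d}" for i in rng.integers(0, config.n_districts, n)]
    )
    # pre-existing diabetes requires onset before the observation range, so
    # persons born during the first reporting year are never prevalent
    prevalent = (rng.random(n) < config.prevalent_fraction) & (birth_year < first_year)

    persons = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "birth_date": birth_date,
            "district_code": district,
            "prevalent": prevalent,
        }
    )

    entry = birth_date.clip(lower=pd.Timestamp(first_year - 1, 1, 1))
    p_leave = 1.0 - (1.0 - config.annual_disenrollment_prob) * (
        1.0 - config.annual_death_prob
    )
    if p_leave > 0:
        u = rng.random(n)
        survived = np.floor(np.log(u) / np.log1p(-p_leave)).astype(int)
    else:
        rng.random(n)  # keep the stream aligned across configurations
        survived = np.full(n, np.iinfo(np.int32).max)
    leave_year = entry.dt.year.to_numpy() + survived
    leave_day = rng.integers(0, 365, n)
    end = pd.Series(pd.Timestamp(last_year, 12, 31), index=persons.index)
    leaves = leave_year <= last_year
    if leaves.any():
        leave_dates = _dates_in_year(leave_year[leaves], leave_day[leaves])
        end[leaves] = leave_dates.to_numpy()
    end = end.clip(lower=entry)  # at least one insured day

    spells = pd.DataFrame(
        {"person_id": persons["person_id"], "start_date": entry, "end_date": end}
    )
    return persons, spells


def _spell_spans(spells: pd.DataFrame) -> pd.DataFrame:
    g = spells.groupby("person_id")
    return pd.DataFrame(
        {"span_start": g["start_date"].min(), "span_end": g["end_date"].max()}
    )


def deprivation_multipliers(config: ScenarioConfig, districts: pd.DataFrame) -> pd.Series:
    """True incidence multiplier per district: 1 for low deprivation,
    sqrt(ratio) for medium, ratio for high."""
    cat = categorize_districts(districts)
    ratio = config.deprivation_rate_ratio
    mult = cat["category"].map(
        {"low": 1.0, "medium": float(np.sqrt(ratio)), "high": ratio}
    )
    return pd.Series(mult.to_numpy(), index=cat["district_code"].to_numpy())


def simulate_onsets(
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    config: ScenarioConfig,
    districts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw latent diabetes onsets per person-quarter at risk.

    The quarterly onset hazard is the annual type/age/sex rate divided by
    four, times the deprivation multiplier of the person's district.
    Prevalent persons and persons with an earlier onset are never at risk;
    a person is at risk in a quarter if enrolled (and born) on its first
    day.  At most one onset per person.
    """
    rng = _streams(config)["onsets"]
    if districts is None:
        districts = generate_districts(config)
    first_year, last_year = config.years
    n = len(persons)
    empty = pd.DataFrame(
        columns=["person_id", "true_type", "year", "quarter", "medicated"]
    )
    if n == 0:
        return empty

    mult = deprivation_multipliers(config, districts)
    person_mult = persons["district_code"].map(mult).fillna(1.0).to_numpy()
    spans = _spell_spans(spells)
    span_start = persons["person_id"].map(spans["span_start"]).to_numpy()
    span_end = persons["person_id"].map(spans["span_end"]).to_numpy()
    birth_year = persons["birth_date"].dt.year.to_numpy()
    sex = persons["sex"].to_numpy()
    prevalent = persons["prevalent"].to_numpy()

    had_onset = np.zeros(n, dtype=bool)
    out: list[pd.DataFrame] = []
    for year in range(first_year, last_year + 1):
        ages = year - birth_year
        r1 = rate_lookup(config.true_incidence_t1, ages, sex)
        r2 = rate_lookup(config.true_incidence_t2, ages, sex)
        total = r1 + r2
        p_quarter = total / 100_000.0 / 4.0 * person_mult
        with np.errstate(invalid="ignore", divide="ignore"):
            p_t1 = np.where(total > 0, r1 / np.where(total > 0, total, 1.0), 0.0)
        for quarter in (1, 2, 3, 4):
            qs = quarter_start(year, quarter)
            u = rng.random(n)
            u_type = rng.random(n)
            at_risk = (
                ~prevalent
                & ~had_onset
                & (span_start <= qs)
                & (span_end >= qs)
                & (persons["birth_date"].to_numpy() <= qs.to_datetime64())
            )
            new = at_risk & (u < p_quarter)
            if not new.any():
                continue
            had_onset |= new
            idx = np.flatnonzero(new)
            out.append(
                pd.DataFrame(
                    {
                        "person_id": persons["person_id"].to_numpy()[idx],
                        "true_type": np.where(
                            u_type[idx] < p_t1[idx], "type1", "type2"
                        ),
                        "year": year,
                        "quarter": quarter,
                    }
                )
            )
    if not out:
        return empty
    onsets = pd.concat(out, ignore_index=True)
    u_med = rng.random(len(onsets))
    onsets["medicated"] = (onsets["true_type"] == "type1") | (
        u_med < config.t2_medicated_fraction
    )
    logger.info("simulated %d onsets among %d persons", len(onsets), n)
    return onsets.sort_values(["person_id"], kind="stable").reset_index(drop=True)


def _observation_probs(config: ScenarioConfig, t_lo: int, t_hi: int) -> np.ndarray:
    """Observation probability per absolute quarter index in [t_lo, t_hi]."""
    t = np.arange(t_lo, t_hi + 1)
    seasonal = np.asarray(config.seasonal_multipliers)[qnum(t) - 1]
    disruption = np.array(
        [config.disruption_multiplier(int(y), int(q)) for y, q in zip(qyear(t), qnum(t))]
    )
    return np.clip(seasonal * disruption, 0.0, 1.0)


def emit_claims(
    onsets: pd.DataFrame,
    persons: pd.DataFrame,
    spells: pd.DataFrame,
    config: ScenarioConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn latent onsets into diagnosis and prescription records.

    Each onset attempts an index diagnosis in its quarter (success
    probability = seasonal x disruption multiplier, clipped to [0, 1]); on
    failure the attempt repeats each later quarter with the catch-up
    probability applied on top, through Q4 of the last reporting year.  An
    observed index diagnosis receives a confirming outpatient diagnosis one
    to three quarters later with probability ``confirmation_prob``.  Coding
    is type-consistent (type 1 -> E10, type 2 -> E11) unless perturbed to
    E12/E13/E14 with ``misc_coding_prob``.  Type 1 cases receive insulin
    (A10A) prescriptions, medicated type 2 cases non-insulin anti-diabetics
    (A10B).  Prevalent persons emit qualifying outpatient diagnoses and
    prescriptions every enrolled year including the pre-observation year,
    so the record-based exclusion filter removes them exactly as it would
    on real data.  Filler diagnoses (non-diabetes codes, plus occasional
    *suspected* diabetes codes that no rule may count) and filler
    prescriptions are added as noise.  Confirmations and prescriptions may
    be dated up to Q3 of the year after the last reporting year so that
    late-Q4 cases remain confirmable.
    """
    rng = _streams(config)["claims"]
    first_year, last_year = config.years
    t_idx_max = int(qindex(last_year, 4))
    t_rec_max = int(qindex(last_year + 1, 3))
    t_lo = int(qindex(first_year - 1, 1))
    probs = _observation_probs(config, t_lo, t_rec_max)

    diag_parts: list[pd.DataFrame] = []
    rx_parts: list[pd.DataFrame] = []
    spans = _spell_spans(spells) if len(spells) else None

    # --- onset-driven records ---------------------------------------------
    if len(onsets):
        o = onsets.merge(
            persons[["person_id", "birth_date"]], on="person_id", how="left"
        )
        o["t0"] = qindex(o["year"].to_numpy(), o["quarter"].to_numpy())
        ss = o["person_id"].map(spans["span_start"])
        se = o["person_id"].map(spans["span_end"])
        q_start = pd.to_datetime(
            dict(year=o["year"], month=3 * (o["quarter"] - 1) + 1, day=1)
        )
        inside = (ss <= q_start) & (se >= q_start)
        if (~inside).any():
            logger.warning(
                "skipping %d onsets outside enrollment", int((~inside).sum())
            )
        o = o[inside].reset_index(drop=True)
        n_o = len(o)
        if n_o:
            t0 = o["t0"].to_numpy()
            max_off = t_idx_max - int(t0.min())
            offsets = np.arange(max_off + 1)
            t_mat = t0[:, None] + offsets[None, :]
            p_mat = probs[np.clip(t_mat - t_lo, 0, len(probs) - 1)]
            p_mat = np.where(
                offsets[None, :] > 0, p_mat * config.catch_up_prob, p_mat
            )
            p_mat = np.where(t_mat <= t_idx_max, p_mat, 0.0)
            u_obs = rng.random((n_o, max_off + 1))
            hit = u_obs < p_mat
            observed = hit.any(axis=1)
            first_hit = hit.argmax(axis=1)
            t_index = t0 + first_hit

            u_setting = rng.random(n_o)
            setting = np.where(
                u_setting < config.outpatient_index_prob,
                "outpatient",
                np.where(
                    u_setting
                    < config.outpatient_index_prob + config.inpatient_main_index_prob,
                    "inpatient_main",
                    "inpatient_secondary",
                ),
            )
            base_code = np.where(o["true_type"] == "type1", "E10", "E11")
            misc = rng.random(n_o) < config.misc_coding_prob
            misc_pick = rng.integers(0, len(MISC_CODES), n_o)
            code = np.where(misc, np.asarray(MISC_CODES)[misc_pick], base_code)
            confirmed = rng.random(n_o) < config.confirmation_prob
            delay = rng.integers(1, 4, n_o)
            t_conf = t_index + delay

            keep = observed
            diag_parts.append(
                pd.DataFrame(
                    {
                        "person_id": o["person_id"].to_numpy()[keep],
                        "icd3": code[keep],
                        "setting": setting[keep],
                        "certainty": "confirmed",
                        "t": t_index[keep],
                    }
                )
            )
            ck = keep & confirmed & (t_conf <= t_rec_max)
            diag_parts.append(
                pd.DataFrame(
                    {
                        "person_id": o["person_id"].to_numpy()[ck],
                        "icd3": code[ck],
                        "setting": "outpatient",
                        "certainty": "confirmed",
                        "t": t_conf[ck],
                    }
                )
            )
            treated = keep & o["medicated"].to_numpy()
            atc = np.where(o["true_type"] == "type1", INSULIN_ATC, ORAL_ATC)
            for off in (0, 1):
                tk = treated & (t_index + off <= t_rec_max)
                rx_parts.append(
                    pd.DataFrame(
                        {
                            "person_id": o["person_id"].to_numpy()[tk],
                            "atc": atc[tk],
                            "t": t_index[tk] + off,
                        }
                    )
                )

    # --- prevalent persons: qualifying records every enrolled year --------
    prev = (
        persons[persons["prevalent"]]
        if "prevalent" in persons.columns
        else persons.iloc[0:0]
    )
    if len(prev):
        ss = prev["person_id"].map(spans["span_start"])
        se = prev["person_id"].map(spans["span_end"])
        # chronic condition: one confirmed diagnosis in every quarter with
        # any enrolled day, so the record-based exclusion always sees them
        for year in range(first_year - 1, last_year + 1):
            for quarter in (1, 2, 3, 4):
                q_start = quarter_start(year, quarter)
                q_end = (
                    quarter_start(year + (quarter == 4), quarter % 4 + 1)
                    - pd.Timedelta(days=1)
                )
                enrolled = (ss <= q_end) & (se >= q_start)
                pid = prev["person_id"].to_numpy()[enrolled.to_numpy()]
                diag_parts.append(
                    pd.DataFrame(
                        {
                            "person_id": pid,
                            "icd3": "E11",
                            "setting": "outpatient",
                            "certainty": "confirmed",
                            "t": int(qindex(year, quarter)),
                        }
                    )
                )
                if quarter == 1:
                    rx_parts.append(
                        pd.DataFrame(
                            {"person_id": pid, "atc": ORAL_ATC, "t": int(qindex(year, 1))}
                        )
                    )

    # --- filler noise ------------------------------------------------------
    if len(persons) and config.filler_diagnosis_rate > 0:
        years = np.arange(first_year - 1, last_year + 1)
        counts = rng.poisson(
            config.filler_diagnosis_rate, size=(len(persons), len(years))
        )
        ss = persons["person_id"].map(spans["span_start"]).to_numpy()
        se = persons["person_id"].map(spans["span_end"]).to_numpy()
        year_starts = np.array([np.datetime64(f"{y}-01-01") for y in years])
        enrolled = (ss[:, None] <= year_starts[None, :]) & (
            se[:, None] >= year_starts[None, :]
        )
        counts = np.where(enrolled, counts, 0)
        pid = np.repeat(
            np.tile(persons["person_id"].to_numpy(), len(years)),
            counts.ravel(order="F"),
        )
        yr = np.repeat(np.repeat(years, len(persons)), counts.ravel(order="F"))
        m = len(pid)
        if m:
            quarter = rng.integers(1, 5, m)
            suspected = rng.random(m) < 0.15
            code = np.where(
                suspected,
                np.asarray(DIABETES_CODES)[rng.integers(0, 5, m)],
                np.asarray(FILLER_CODES)[rng.integers(0, len(FILLER_CODES), m)],
            )
            diag_parts.append(
                pd.DataFrame(
                    {
                        "person_id": pid,
                        "icd3": code,
                        "setting": "outpatient",
                        "certainty": np.where(suspected, "suspected", "confirmed"),
                        "t": qindex(yr, quarter),
                    }
                )
            )
            n_rx = m // 4
            if n_rx:
                rx_parts.append(
                    pd.DataFrame(
                        {
                            "person_id": pid[:n_rx],
                            "atc": FILLER_ATC,
                            "t": qindex(yr[:n_rx], rng.integers(1, 5, n_rx)),
                        }
                    )
                )

    def _finish(parts: list[pd.DataFrame], columns: list[str]) -> pd.DataFrame:
        parts = [p for p in parts if len(p)]
        if not parts:
            return pd.DataFrame(columns=columns)
        df = pd.concat(parts, ignore_index=True)
        df["year"] = qyear(df["t"].to_numpy())
        df["quarter"] = qnum(df["t"].to_numpy())
        df = df.drop(columns=["t"])
        sort_cols = [c for c in columns if c in df.columns]
        return (
            df[columns]
            .sort_values(sort_cols, kind="stable")
            .reset_index(drop=True)
        )

    diagnoses = _finish(diag_parts, DIAG_COLUMNS)
    prescriptions = _finish(rx_parts, RX_COLUMNS)
    logger.info(
        "emitted %d diagnosis and %d prescription records",
        len(diagnoses),
        len(prescriptions),
    )
    return diagnoses, prescriptions


def simulate_scenario(config: ScenarioConfig) -> SimulatedData:
    """Run the full generator: population, districts, onsets, claims."""
    persons, spells = generate_population(config)
    districts = generate_districts(config)
    onsets = simulate_onsets(persons, spells, config, districts=districts)
    diagnoses, prescriptions = emit_claims(onsets, persons, spells, config)
    return SimulatedData(persons, spells, diagnoses, prescriptions, districts, onsets)
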