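"""Indicator engine: claims -> hospital x quarter x indicator cells.

The engine determines, for each overuse indicator, which beneficiaries were
eligible to receive the indicator procedure, attributes them to hospitals via
the CMS Certification Number (CCN), detects indicator events among the
eligible, keeps only the first occurrence of an indicator per beneficiary,
quarter and hospital, and aggregates everything into cells carrying the
eligible count (the model offset), the event count and cell-level patient
covariates.

Eligibility comes in two flavours:

* *claim-based* — a qualifying diagnosis (or, rarely, procedure) code opens an
  eligibility window of ``eligibility_window_days`` starting at the claim date;
  the beneficiary is attributed to the CCN of that claim.
* *demographic-only* — eligibility is a pure demographic predicate (e.g. women
  above an age cutoff); attribution is deferred to the claim carrying the
  indicator procedure, and the beneficiary counts as eligible at every hospital
  where they have any claim in a quarter.

A beneficiary is eligible in a (hospital, quarter, indicator) cell when one of
their eligibility windows intersects that quarter; events are assigned to the
quarter of the event date.  Under this rule ``event_count <= eligible_count``
holds in every cell even when windows span quarter boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calendars import StudyCalendar, DEFAULT_CALENDAR

__all__ = [
    "IndicatorDefinition",
    "EngineLog",
    "ClaimsView",
    "exclude_specialty_hospitals",
    "find_eligible",
    "detect_events",
    "deduplicate_first_occurrence",
    "aggregate_cells",
    "apply_min_eligible_filter",
    "count_cells",
    "DEFAULT_SPECIALTY_KEYWORDS",
    "CELL_COLUMNS",
]

#: hospitals whose lowercased name contains any of these are out of scope
DEFAULT_SPECIALTY_KEYWORDS = (
    "children",
    "pediatric",
    "behavioral",
    "psychiatric",
    "rehabilitation",
)

CELL_COLUMNS = [
    "ccn",
    "system_id",
    "quarter_index",
    "indicator_id",
    "eligible_count",
    "event_count",
    "mean_age",
    "proportion_women",
    "median_chronic_conditions",
]


def normalize_code(code: str) -> str:
    """Uppercase and strip dots — the canonical code spelling for matching."""
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class IndicatorDefinition:
    """Declarative eligibility and event rules for one overuse indicator.

    Attributes
    ----------
    indicator_id : int
        1-based identifier, unique within a configuration.
    name : str
        Human-readable indicator name.
    min_age, max_age : float or None
        Inclusive age bounds (years) for eligibility; ``None`` means unbounded.
    sex : str or None
        Required sex ("F"/"M") or ``None``.
    eligibility_dx_codes, eligibility_px_codes : tuple of str
        Diagnosis / procedure code sets that establish eligibility.  Both
        empty means the indicator is demographic-only.
    event_codes : tuple of str
        Procedure codes identifying the indicator event (nonempty).
    attribution : str
        "eligibility_claim" (hospital of the qualifying claim) or
        "event_claim" (hospital of the procedure claim; demographic-only
        indicators only).
    eligibility_window_days : int
        Length of the eligibility window opened by a qualifying claim.
    prefix_match : bool
        If true, codes in the sets are treated as prefixes (the common way
        ICD-10 lists are maintained); otherwise exact match.
    """

    indicator_id: int
    name: str
    min_age: float | None = None
    max_age: float | None = None
    sex: str | None = None
    eligibility_dx_codes: tuple[str, ...] = ()
    eligibility_px_codes: tuple[str, ...] = ()
    event_codes: tuple[str, ...] = ()
    attribution: str = "eligibility_claim"
    eligibility_window_days: int = 90
    prefix_match: bool = True

    def __post_init__(self) -> None:
        if not self.event_codes:
            raise ValueError(f"indicator {self.indicator_id}: event_codes must be nonempty")
        if self.attribution not in ("eligibility_claim", "event_claim"):
            raise ValueError(f"indicator {self.indicator_id}: unknown attribution {self.attribution!r}")
        if self.attribution == "event_claim" and not self.demographic_only:
            raise ValueError(
                f"indicator {self.indicator_id}: event_claim attribution requires "
                "demographic-only eligibility"
            )
        if self.eligibility_window_days < 1:
            raise ValueError(f"indicator {self.indicator_id}: eligibility_window_days must be >= 1")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError(f"indicator {self.indicator_id}: sex must be 'F', 'M' or null")
        object.__setattr__(self, "eligibility_dx_codes", tuple(normalize_code(c) for c in self.eligibility_dx_codes))
        object.__setattr__(self, "eligibility_px_codes", tuple(normalize_code(c) for c in self.eligibility_px_codes))
        object.__setattr__(self, "event_codes", tuple(normalize_code(c) for c in self.event_codes))

    @property
    def demographic_only(self) -> bool:
        return not self.eligibility_dx_codes and not self.eligibility_px_codes

    def matches_demographics(self, age: np.ndarray, sex: pd.Series) -> np.ndarray:
        ok = np.ones(len(age), dtype=bool)
        if self.min_age is not None:
            ok &= age >= self.min_age
        if self.max_age is not None:
            ok &= age <= self.max_age
        if self.sex is not None:
            ok &= (sex == self.sex).to_numpy()
        return ok


@dataclass
class EngineLog:
    """Collects exclusion and adjustment counts emitted by the engine."""

    entries: list[dict] = field(default_factory=list)

    def record(self, stage: str, event: str, count: int, detail: str = "") -> None:
        self.entries.append({"stage": stage, "event": event, "count": int(count), "detail": detail})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["stage", "event", "count", "detail"])

    def total(self, event: str) -> int:
        return sum(e["count"] for e in self.entries if e["event"] == event)


class ClaimsView:
    """Claims table with parsed dates and long-format code tables.

    Preparing the exploded diagnosis/procedure code tables once makes
    repeated per-indicator matching cheap.
    """

    def __init__(self, claims: pd.DataFrame):
        claims = claims.copy()
        claims["service_date"] = pd.to_datetime(claims["service_date"])
        claims["ccn"] = claims["ccn"].astype(str)
        self.claims = claims
        self.dx = self._explode("diagnosis_codes")
        self.px = self._explode("procedure_codes")

    def _explode(self, col: str) -> pd.DataFrame:
        base = self.claims[["beneficiary_id", "service_date", "ccn"]].copy()
        codes = self.claims[col].fillna("").astype(str)
        base["code"] = codes.str.upper().str.replace(".", "", regex=False).str.split(";")
        long = base.explode("code")
        long["code"] = long["code"].str.strip()
        long = long[long["code"] != ""]
        long = long.reset_index().rename(columns={"index": "claim_row"})
        return long

    @staticmethod
    def match_codes(long: pd.DataFrame, codes: Sequence[str], prefix: bool) -> pd.DataFrame:
        if len(long) == 0 or not codes:
            return long.iloc[0:0]
        if prefix:
            mask = np.zeros(len(long), dtype=bool)
            for c in codes:
                mask |= long["code"].str.startswith(c).to_numpy()
        else:
            mask = long["code"].isin(codes).to_numpy()
        return long[mask]


def _as_view(claims) -> ClaimsView:
    return claims if isinstance(claims, ClaimsView) else ClaimsView(claims)


def exclude_specialty_hospitals(
    linkage: pd.DataFrame,
    keywords: Iterable[str] = DEFAULT_SPECIALTY_KEYWORDS,
    log: EngineLog | None = None,
) -> pd.DataFrame:
    """Drop hospitals whose name marks them as specialty facilities.

    Children's, behavioral-health, psychiatric and rehabilitation hospitals
    are identified by keyword search on the lowercased hospital name.
    """
    names = linkage["hospital_name"].fillna("").str.lower()
    mask = np.zeros(len(linkage), dtype=bool)
    for kw in keywords:
        mask |= names.str.contains(kw.lower(), regex=False).to_numpy()
    removed = linkage[mask]
    if log is not None:
        log.record(
            "linkage",
            "specialty_hospital_excluded",
            len(removed),
            ";".join(sorted(removed["ccn"].astype(str).unique())[:20]),
        )
    return linkage[~mask].reset_index(drop=True)


def _age_years(birth: pd.Series, at: pd.Series | pd.Timestamp) -> np.ndarray:
    if isinstance(at, pd.Timestamp):
        delta = at - birth
    else:
        delta = at.to_numpy() - birth.to_numpy()
    return np.asarray(delta, dtype="timedelta64[D]").astype(float) / 365.25


def find_eligible(
    claims,
    beneficiaries: pd.DataFrame,
    defn: IndicatorDefinition,
    calendar: StudyCalendar = DEFAULT_CALENDAR,
) -> pd.DataFrame:
    """Eligibility episodes (beneficiary, indicator, ccn, date window).

    Claim-based indicators yield one episode per qualifying claim, attributed
    to the CCN of that claim, with window ``[date, date + window_days]``.
    Demographic-only indicators yield one whole-quarter episode per
    (beneficiary, hospital, quarter) where the beneficiary has any claim,
    flagged for event-claim attribution.
    """
    view = _as_view(claims)
    bene = beneficiaries.copy()
    bene["birth_date"] = pd.to_datetime(bene["birth_date"])

    if defn.demographic_only:
        contact = view.claims[["beneficiary_id", "service_date", "ccn"]].copy()
        contact["quarter_index"] = calendar.quarter_of(contact["service_date"])
        contact = contact[contact["quarter_index"] > 0]
        contact = contact.drop_duplicates(["beneficiary_id", "ccn", "quarter_index"])
        contact = contact.merge(bene, on="beneficiary_id", how="inner")
        qstarts = pd.Series(
            [pd.Timestamp(calendar.quarter_start(q)) for q in contact["quarter_index"]],
            index=contact.index,
            dtype="datetime64[ns]",
        )
        age = _age_years(contact["birth_date"], qstarts)
        keep = defn.matches_demographics(age, contact["sex"])
        contact = contact[keep]
        episodes = pd.DataFrame(
            {
                "beneficiary_id": contact["beneficiary_id"],
                "indicator_id": defn.indicator_id,
                "ccn": contact["ccn"],
                "start_date": pd.to_datetime(
                    [calendar.quarter_start(q) for q in contact["quarter_index"]]
                ),
                "end_date": pd.to_datetime(
                    [calendar.quarter_end(q) for q in contact["quarter_index"]]
                ),
                "demographic_only": True,
            }
        )
        return episodes.reset_index(drop=True)

    hits = []
    if defn.eligibility_dx_codes:
        hits.append(ClaimsView.match_codes(view.dx, defn.eligibility_dx_codes, defn.prefix_match))
    if defn.eligibility_px_codes:
        hits.append(ClaimsView.match_codes(view.px, defn.eligibility_px_codes, defn.prefix_match))
    qual = pd.concat(hits, ignore_index=True) if hits else view.dx.iloc[0:0]
    qual = qual.drop_duplicates(["beneficiary_id", "service_date", "ccn"])
    # claims before the lookback start or after the study end cannot qualify
    in_window = (qual["service_date"] >= pd.Timestamp(calendar.lookback_start)) & (
        qual["service_date"] <= pd.Timestamp(calendar.study_end)
    )
    qual = qual[in_window]
    qual = qual.merge(bene, on="beneficiary_id", how="inner")
    age = _age_years(qual["birth_date"], qual["service_date"])
    qual = qual[defn.matches_demographics(age, qual["sex"])]
    episodes = pd.DataFrame(
        {
            "beneficiary_id": qual["beneficiary_id"],
            "indicator_id": defn.indicator_id,
            "ccn": qual["ccn"],
            "start_date": qual["service_date"],
            "end_date": qual["service_date"] + pd.to_timedelta(defn.eligibility_window_days, unit="D"),
            "demographic_only": False,
        }
    )
    return episodes.reset_index(drop=True)


def detect_events(
    claims,
    episodes: pd.DataFrame,
    defn: IndicatorDefinition,
    calendar: StudyCalendar = DEFAULT_CALENDAR,
    log: EngineLog | None = None,
) -> pd.DataFrame:
    """Indicator events: an event-code claim on a day the beneficiary was eligible.

    An event claim covered by several overlapping windows is attributed once,
    to the earliest-starting window.  Events outside every window are counted
    in the log and dropped.  Events dated outside the study quarters (e.g. in
    the lookback period) never count.
    """
    view = _as_view(claims)
    ev_claims = ClaimsView.match_codes(view.px, defn.event_codes, defn.prefix_match).copy()
    ev_claims["quarter_index"] = calendar.quarter_of(ev_claims["service_date"])
    ev_claims = ev_claims[ev_claims["quarter_index"] > 0]
    if len(ev_claims) == 0 or len(episodes) == 0:
        if log is not None:
            log.record(f"indicator_{defn.indicator_id}", "event_outside_window", len(ev_claims))
        return pd.DataFrame(
            columns=["beneficiary_id", "indicator_id", "ccn", "event_date", "quarter_index"]
        )

    cand = ev_claims.merge(
        episodes,
        on="beneficiary_id",
        how="inner",
        suffixes=("_claim", "_episode"),
    )
    covered = (cand["service_date"] >= cand["start_date"]) & (cand["service_date"] <= cand["end_date"])
    if defn.attribution == "event_claim":
        # demographic-only: the episode must be at the hospital of the procedure
        covered &= cand["ccn_claim"] == cand["ccn_episode"]
    cand = cand[covered]
    # one event per event claim; earliest-starting covering window wins
    cand = cand.sort_values(["claim_row", "start_date"], kind="mergesort")
    cand = cand.drop_duplicates("claim_row", keep="first")

    if log is not None:
        n_outside = ev_claims["claim_row"].nunique() - cand["claim_row"].nunique()
        log.record(f"indicator_{defn.indicator_id}", "event_outside_window", n_outside)

    ccn = cand["ccn_claim"] if defn.attribution == "event_claim" else cand["ccn_episode"]
    events = pd.DataFrame(
        {
            "beneficiary_id": cand["beneficiary_id"],
            "indicator_id": defn.indicator_id,
            "ccn": ccn,
            "event_date": cand["service_date"],
            "quarter_index": cand["quarter_index"],
        }
    )
    return events.reset_index(drop=True)


def deduplicate_first_occurrence(
    events: pd.DataFrame, calendar: StudyCalendar = DEFAULT_CALENDAR
) -> pd.DataFrame:
    """Keep only the first occurrence of an indicator per beneficiary, quarter, hospital.

    Distinct indicators in the same quarter-hospital are all retained; the
    same indicator in different quarters or hospitals is retained per cell.
    Idempotent.
    """
    if len(events) == 0:
        return events.copy()
    ev = events.copy()
    if "quarter_index" not in ev.columns:
        ev["quarter_index"] = calendar.quarter_of(ev["event_date"])
    ev = ev.sort_values("event_date", kind="mergesort")
    ev = ev.drop_duplicates(["beneficiary_id", "indicator_id", "quarter_index", "ccn"], keep="first")
    return ev.reset_index(drop=True)


def _episodes_by_quarter(episodes: pd.DataFrame, calendar: StudyCalendar) -> pd.DataFrame:
    """Expand episodes to the quarters their window intersects."""
    ep = episodes.reset_index(drop=True)
    start = ep["start_date"].clip(lower=pd.Timestamp(calendar.study_start))
    end = ep["end_date"].clip(upper=pd.Timestamp(calendar.study_end))
    ep = ep[start <= end]
    start, end = start.loc[ep.index], end.loc[ep.index]
    q1 = calendar.quarter_of(start)
    q2 = calendar.quarter_of(end)
    frames = []
    max_span = int((q2 - q1).max()) if len(ep) else 0
    for off in range(max_span + 1):
        sel = q1 + off <= q2
        sub = ep[sel].copy()
        sub["quarter_index"] = (q1 + off)[sel]
        frames.append(sub)
    if not frames:
        return ep.assign(quarter_index=np.int64(0)).iloc[0:0]
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(["beneficiary_id", "indicator_id", "ccn", "quarter_index"])


def _vintage_for_year(year: int, available: np.ndarray) -> int:
    target = 2016 if year <= 2017 else 2018
    if target in available:
        return target
    # single-vintage linkage: use what there is
    return int(available[0])


def aggregate_cells(
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    beneficiaries: pd.DataFrame,
    linkage: pd.DataFrame,
    calendar: StudyCalendar = DEFAULT_CALENDAR,
    log: EngineLog | None = None,
) -> pd.DataFrame:
    """Aggregate episodes and deduplicated events into cell records.

    ``eligible_count`` is the number of distinct eligible beneficiaries in the
    cell, ``event_count`` the deduplicated events, and the patient covariates
    (mean age at quarter start, proportion of women, median chronic-condition
    count) are computed over the cell's eligible beneficiaries.  Hospitals are
    mapped to health systems using the linkage vintage matching the claim
    year: 2016 linkage for 2016-2017 quarters, 2018 linkage for 2018 quarters.
    Cells whose CCN is absent from the applicable vintage are dropped and
    logged; zero-eligible cells do not exist by construction.
    """
    bene = beneficiaries.copy()
    bene["birth_date"] = pd.to_datetime(bene["birth_date"])
    elig = _episodes_by_quarter(episodes, calendar)
    elig = elig.merge(bene, on="beneficiary_id", how="inner")
    qstart = pd.to_datetime([calendar.quarter_start(int(q)) for q in elig["quarter_index"]])
    elig["age"] = _age_years(elig["birth_date"], pd.Series(qstart, index=elig.index))
    elig["is_female"] = (elig["sex"] == "F").astype(float)

    key = ["ccn", "quarter_index", "indicator_id"]
    cells = elig.groupby(key, as_index=False).agg(
        eligible_count=("beneficiary_id", "nunique"),
        mean_age=("age", "mean"),
        proportion_women=("is_female", "mean"),
        median_chronic_conditions=("chronic_condition_count", "median"),
    )

    ev = deduplicate_first_occurrence(events, calendar)
    if len(ev):
        ev_counts = ev.groupby(key, as_index=False).agg(event_count=("beneficiary_id", "nunique"))
    else:
        ev_counts = pd.DataFrame(columns=key + ["event_count"])
    cells = cells.merge(ev_counts, on=key, how="left")
    cells["event_count"] = (
        pd.to_numeric(cells["event_count"], errors="coerce").fillna(0).astype(int)
    )

    bad = cells["event_count"] > cells["eligible_count"]
    if bad.any():
        raise AssertionError(
            f"{int(bad.sum())} cells violate event_count <= eligible_count; "
            "events must come from detect_events on the same episodes"
        )

    # system linkage with vintage switching by calendar year of the quarter
    link = linkage.copy()
    link["ccn"] = link["ccn"].astype(str)
    available = link["vintage"].astype(int).unique()
    years = {q: calendar.calendar_year(q) for q in range(1, calendar.n_quarters + 1)}
    cells["_vintage"] = cells["quarter_index"].map(lambda q: _vintage_for_year(years[int(q)], available))
    link_small = link[["ccn", "system_id", "vintage"]].rename(columns={"vintage": "_vintage"})
    link_small["_vintage"] = link_small["_vintage"].astype(int)
    merged = cells.merge(link_small, on=["ccn", "_vintage"], how="left")
    unknown = merged["system_id"].isna()
    if log is not None and unknown.any():
        log.record(
            "aggregate",
            "unknown_ccn_cell_dropped",
            int(unknown.sum()),
            ";".join(sorted(merged.loc[unknown, "ccn"].unique())[:20]),
        )
    merged = merged[~unknown].drop(columns=["_vintage"])
    merged = merged[CELL_COLUMNS].sort_values(["ccn", "quarter_index", "indicator_id"])
    return merged.reset_index(drop=True)


def apply_min_eligible_filter(
    cells: pd.DataFrame,
    threshold: int = 20,
    per_quarter: bool = False,
    log: EngineLog | None = None,
) -> pd.DataFrame:
    """Sensitivity filter: drop hospital-indicator pairs with too few eligible.

    By default a hospital stops contributing to an indicator when fewer than
    ``threshold`` individuals were eligible for that indicator at that
    hospital over the whole study (all quarters of the pair are judged
    together).  With ``per_quarter=True`` the rule is applied cell by cell
    instead.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if per_quarter:
        keep = cells["eligible_count"] >= threshold
    else:
        totals = cells.groupby(["ccn", "indicator_id"])["eligible_count"].transform("sum")
        keep = totals >= threshold
    if log is not None:
        log.record("filter", "min_eligible_cell_removed", int((~keep).sum()))
    return cells[keep].reset_index(drop=True)


def count_cells(
    claims,
    beneficiaries: pd.DataFrame,
    linkage: pd.DataFrame,
    indicator_defs: Sequence[IndicatorDefinition],
    calendar: StudyCalendar = DEFAULT_CALENDAR,
    specialty_keywords: Iterable[str] = DEFAULT_SPECIALTY_KEYWORDS,
    min_eligible: int | None = None,
    min_eligible_per_quarter: bool = False,
    log: EngineLog | None = None,
) -> pd.DataFrame:
    """Full claims-to-cells stage over a set of indicator definitions."""
    view = _as_view(claims)
    link = exclude_specialty_hospitals(linkage, specialty_keywords, log=log)
    all_eps, all_evs = [], []
    for defn in indicator_defs:
        eps = find_eligible(view, beneficiaries, defn, calendar)
        evs = detect_events(view, eps, defn, calendar, log=log)
        all_eps.append(eps)
        all_evs.append(evs)
    episodes = pd.concat(all_eps, ignore_index=True)
    events = pd.concat(all_evs, ignore_index=True)
    cells = aggregate_cells(episodes, events, beneficiaries, link, calendar, log=log)
    if min_eligible is not None:
        cells = apply_min_eligible_filter(cells, min_eligible, min_eligible_per_quarter, log=log)
    return cells
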