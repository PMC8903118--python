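"""Synthetic claims generator with known ground truth.

Real Medicare claims and the AHRQ Compendium linkage are access-restricted,
so the generator is the canonical test fixture: it builds a nested
system/hospital/beneficiary population, Compendium-style system
characteristics whose effects on the latent system tendencies are planted on
the log-rate scale, and per-cell event counts drawn from the same NB2
random-intercept model the estimation stage fits:

    C ~ NB2(mean = n * exp(base + w_q + psi_j + phi_k + beta.X + b_h), alpha)

where *n* is the cell's eligible count.  Claims can be materialized so that
the indicator engine reconstructs the generator's cells exactly: one
eligibility-qualifying claim per eligible person, one event-procedure claim
per counted event, globally distinct beneficiaries, eligibility windows
clamped inside their quarter.  Event counts are capped at the eligible count
(events are per-person first occurrences); cap adjustments are counted.

Everything is driven by a single ``numpy`` Generator seed; identical
(config, seed) yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .associations import make_tertiles
from .calendars import StudyCalendar
from .config import default_indicator_definitions
from .indicators import IndicatorDefinition

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "SimulationTruth",
    "Structure",
    "SyntheticBundle",
    "generate_structure",
    "generate_cells",
    "generate_cells_and_claims",
    "generate_bundle",
]

# fixed standardization used when applying covariate betas on the eta scale
_COV_CENTER = np.array([73.4, 0.68, 7.6])
_COV_SCALE = np.array([3.0, 0.1, 1.5])

_STATES = ["CA", "TX", "FL", "NY", "PA", "OH", "IL", "MI", "NC", "GA", "WA", "MO"]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic population.

    The defaults are the conditions the estimation stages are exercised
    under: NB2 dispersion ``alpha = 0.5``, hospital-intercept variance
    ``sigma2_h = 0.25``, residual system-tendency SD 0.4 on top of planted
    characteristic effects (primary-care tertiles -0.3/-0.6, investor
    ownership +0.3, major teaching -0.2), and a base event rate of about 10%
    per eligible person (``base_log_rate = -2.3``).
    """

    n_systems: int = 30
    hospitals_per_system: tuple = ("poisson", 5.0)
    n_quarters: int = 12
    indicator_defs: tuple[IndicatorDefinition, ...] | None = None
    base_log_rate: float = -2.3
    quarter_effect_sd: float = 0.1
    indicator_effect_sd: float = 0.5
    phi_sd: float = 0.4
    characteristic_effects: dict = field(
        default_factory=lambda: {
            "pcp_tertile_2": -0.3,
            "pcp_tertile_3": -0.6,
            "investor_owned": 0.3,
            "major_teaching": -0.2,
        }
    )
    state_effect_sd: float = 0.0
    hospital_variance: float = 0.25
    dispersion: float = 0.5
    covariate_betas: tuple = (0.05, -0.05, 0.05)
    eligible_mean: float = 25.0
    duplicate_injection: float = 0.0

    def resolved_defs(self) -> list[IndicatorDefinition]:
        return list(self.indicator_defs) if self.indicator_defs else default_indicator_definitions()

    def validate(self) -> None:
        if self.n_systems < 1:
            raise ConfigurationError("n_systems must be >= 1")
        spec = self.hospitals_per_system
        if not (isinstance(spec, (tuple, list)) and len(spec) >= 2 and spec[0] in ("fixed", "poisson", "uniform")):
            raise ConfigurationError(
                "hospitals_per_system must be ('fixed', k), ('poisson', mean) or ('uniform', lo, hi)"
            )
        if spec[0] == "uniform" and (len(spec) != 3 or spec[1] > spec[2] or spec[1] < 1):
            raise ConfigurationError("hospitals_per_system: uniform spec needs 1 <= lo <= hi")
        if spec[0] in ("fixed", "poisson") and spec[1] < 1:
            raise ConfigurationError("hospitals_per_system: per-system mean/count must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0 (0 selects the Poisson limit)")
        if self.hospital_variance < 0:
            raise ConfigurationError("hospital_variance must be >= 0")
        if self.eligible_mean <= 0:
            raise ConfigurationError("eligible_mean must be > 0")
        if not 0 <= self.duplicate_injection <= 1:
            raise ConfigurationError("duplicate_injection must be in [0, 1]")


@dataclass
class SimulationTruth:
    """True generating values behind a synthetic bundle."""

    system_tendencies: dict  # system_id -> phi_k (log-rate scale)
    hospital_intercepts: dict  # ccn -> b_h
    quarter_effects: np.ndarray
    indicator_effects: np.ndarray
    covariate_betas: np.ndarray
    dispersion: float
    hospital_variance: float
    characteristic_effects: dict
    base_log_rate: float
    state_effects: dict = field(default_factory=dict)

    def validate(self, n_systems: int) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.hospital_variance < 0:
            raise ValueError("hospital_variance must be >= 0")
        if len(self.system_tendencies) != n_systems:
            raise ValueError("system_tendencies must have one entry per system")


@dataclass
class Structure:
    linkage: pd.DataFrame
    characteristics: pd.DataFrame
    truth: SimulationTruth
    config: GeneratorConfig
    seed: int


@dataclass
class SyntheticBundle:
    claims: pd.DataFrame
    beneficiaries: pd.DataFrame
    linkage: pd.DataFrame
    characteristics: pd.DataFrame
    truth: SimulationTruth
    seed: int
    cells: pd.DataFrame  # generator's per-cell truth (the round-trip oracle)
    n_capped: int = 0


def _draw_hospital_counts(spec, n_systems, rng) -> np.ndarray:
    kind = spec[0]
    if kind == "fixed":
        return np.full(n_systems, int(spec[1]))
    if kind == "poisson":
        return 1 + rng.poisson(max(spec[1] - 1.0, 0.0), size=n_systems)
    return rng.integers(int(spec[1]), int(spec[2]) + 1, size=n_systems)


def generate_structure(
    n_systems: int | None = None,
    hospitals_per_system=None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    **overrides,
) -> Structure:
    """Systems, hospitals, linkage, characteristics and latent tendencies.

    Characteristics are drawn with Compendium-like prevalences; the latent
    system tendency is ``phi_k = sum(planted characteristic effects) + state
    effect + Normal(0, phi_sd^2)``, and hospital intercepts are
    ``Normal(0, sigma2_h)``.
    """
    config = config or GeneratorConfig()
    if n_systems is not None:
        overrides["n_systems"] = n_systems
    if hospitals_per_system is not None:
        overrides["hospitals_per_system"] = hospitals_per_system
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(seed)
    K = config.n_systems

    sys_ids = [f"S{i + 1:04d}" for i in range(K)]
    n_hosp = _draw_hospital_counts(config.hospitals_per_system, K, rng)
    states = rng.choice(_STATES, size=K)

    # Compendium-style characteristics (counts right-skewed, flags at
    # prevalences in the ballpark of the published system descriptives)
    beds = np.round(np.exp(rng.normal(6.0, 1.1, K)) * np.sqrt(n_hosp)).astype(int) + 20
    pcp = np.round(np.exp(rng.normal(4.5, 1.2, K)) * np.sqrt(n_hosp)).astype(int) + 5
    physicians = pcp * 3 + np.round(np.exp(rng.normal(4.0, 1.0, K))).astype(int)
    medical_groups = np.round(np.exp(rng.normal(3.5, 1.1, K))).astype(int)
    discharges = beds * 45 + rng.poisson(500, K)
    interns = np.round(np.exp(rng.normal(2.0, 2.0, K))).astype(int) - 1
    interns = np.clip(interns, 0, None)
    teaching = rng.choice(["none", "minor", "major"], size=K, p=[0.31, 0.47, 0.22])
    chars = pd.DataFrame(
        {
            "system_id": sys_ids,
            "hospitals": n_hosp,
            "acute_care_hospitals": np.maximum(1, n_hosp - rng.binomial(1, 0.2, K)),
            "beds": beds,
            "discharges": discharges,
            "medical_groups": medical_groups,
            "physicians": physicians,
            "primary_care_physicians": pcp,
            "interns_residents": interns,
            "teaching_intensity": teaching,
            "investor_owned": rng.random(K) < 0.10,
            "very_major_teaching_hospital": (teaching == "major") & (rng.random(K) < 0.6),
            "major_teaching_hospital": (teaching == "major") | (rng.random(K) < 0.15),
            "high_disadvantaged_share": rng.random(K) < 0.33,
            "high_uncompensated_burden": rng.random(K) < 0.33,
            "upper_quartile_uncompensated": rng.random(K) < 0.20,
            "any_insurance_product": rng.random(K) < 0.33,
            "medicare_advantage": rng.random(K) < 0.20,
            "medicaid_managed_care": rng.random(K) < 0.17,
            "aco_contract": rng.random(K) < 0.44,
            "bundled_payment": rng.random(K) < 0.48,
            "alternative_payment_model": rng.random(K) < 0.71,
            "state": states,
        }
    )

    phi = rng.normal(0.0, config.phi_sd, K)
    for name, effect in config.characteristic_effects.items():
        phi += effect * _characteristic_dummy(chars, name)
    state_effects = {}
    if config.state_effect_sd > 0:
        uniq = sorted(set(states))
        draws = rng.normal(0.0, config.state_effect_sd, len(uniq))
        state_effects = dict(zip(uniq, draws))
        phi += np.array([state_effects[s] for s in states])

    ccns, names_, sys_of_hosp = [], [], []
    h_counter = 1
    for sid, nh in zip(sys_ids, n_hosp):
        for _ in range(nh):
            ccns.append(f"{h_counter:06d}")
            names_.append(f"General Medical Center {h_counter}")
            sys_of_hosp.append(sid)
            h_counter += 1
    b_h = rng.normal(0.0, np.sqrt(config.hospital_variance), len(ccns))

    one_vintage = pd.DataFrame({"ccn": ccns, "hospital_name": names_, "system_id": sys_of_hosp})
    linkage = pd.concat(
        [one_vintage.assign(vintage=2016), one_vintage.assign(vintage=2018)], ignore_index=True
    )

    J = len(config.resolved_defs())
    truth = SimulationTruth(
        system_tendencies=dict(zip(sys_ids, phi)),
        hospital_intercepts=dict(zip(ccns, b_h)),
        quarter_effects=rng.normal(0.0, config.quarter_effect_sd, config.n_quarters),
        indicator_effects=rng.normal(0.0, config.indicator_effect_sd, J),
        covariate_betas=np.asarray(config.covariate_betas, dtype=float),
        dispersion=float(config.dispersion),
        hospital_variance=float(config.hospital_variance),
        characteristic_effects=dict(config.characteristic_effects),
        base_log_rate=float(config.base_log_rate),
        state_effects=state_effects,
    )
    truth.validate(K)
    return Structure(linkage=linkage, characteristics=chars, truth=truth, config=config, seed=seed)


def _characteristic_dummy(chars: pd.DataFrame, name: str) -> np.ndarray:
    """Resolve a planted-effect name to a 0/1 vector over systems."""
    if name in ("pcp_tertile_2", "pcp_tertile_3"):
        labels, _ = make_tertiles(chars["primary_care_physicians"])
        return (labels == int(name[-1])).astype(float)
    if name == "investor_owned":
        return chars["investor_owned"].astype(float).to_numpy()
    if name == "major_teaching":
        return (chars["teaching_intensity"] == "major").astype(float).to_numpy()
    raise ConfigurationError(f"characteristic_effects: unknown characteristic {name!r}")


def _cell_grid(structure: Structure) -> pd.DataFrame:
    link = structure.linkage[structure.linkage["vintage"] == 2016]
    defs = structure.config.resolved_defs()
    grid = (
        pd.MultiIndex.from_product(
            [link["ccn"], range(1, structure.config.n_quarters + 1), [d.indicator_id for d in defs]],
            names=["ccn", "quarter_index", "indicator_id"],
        )
        .to_frame(index=False)
        .merge(link[["ccn", "system_id"]], on="ccn")
    )
    return grid


def _eta_fixed(grid: pd.DataFrame, truth: SimulationTruth, indicator_ids) -> np.ndarray:
    cfg_q = truth.quarter_effects
    ind_pos = {j: i for i, j in enumerate(indicator_ids)}
    return (
        truth.base_log_rate
        + cfg_q[grid["quarter_index"].to_numpy() - 1]
        + truth.indicator_effects[[ind_pos[j] for j in grid["indicator_id"]]]
        + np.array([truth.system_tendencies[s] for s in grid["system_id"]])
        + np.array([truth.hospital_intercepts[c] for c in grid["ccn"]])
    )


def _draw_counts(mean: np.ndarray, alpha: float, rng) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def generate_cells(structure: Structure, seed: int = 0) -> tuple[pd.DataFrame, int]:
    """Cell table straight from the generating model (no claims materialized).

    Covariates are drawn at the cell level; the returned frame matches the
    indicator engine's cell schema.  Returns ``(cells, n_capped)``.
    """
    cfg = structure.config
    rng = np.random.default_rng(seed)
    defs = cfg.resolved_defs()
    grid = _cell_grid(structure)
    n = rng.poisson(cfg.eligible_mean, len(grid))
    keep = n > 0
    grid, n = grid[keep].reset_index(drop=True), n[keep]

    sex_f = {d.indicator_id: d.sex == "F" for d in defs}
    sex_m = {d.indicator_id: d.sex == "M" for d in defs}
    mean_age = rng.normal(75.0, 2.0, len(grid))
    prop_women = np.clip(rng.normal(0.68, 0.08, len(grid)), 0.0, 1.0)
    prop_women = np.where([sex_f[j] for j in grid["indicator_id"]], 1.0, prop_women)
    prop_women = np.where([sex_m[j] for j in grid["indicator_id"]], 0.0, prop_women)
    med_chronic = np.clip(np.round(rng.normal(7.6, 1.5, len(grid))), 0, None)

    X = np.column_stack([mean_age, prop_women, med_chronic])
    eta = _eta_fixed(grid, structure.truth, [d.indicator_id for d in defs])
    eta = eta + ((X - _COV_CENTER) / _COV_SCALE) @ structure.truth.covariate_betas
    mean = n * np.exp(eta)
    y = _draw_counts(mean, structure.truth.dispersion, rng)
    n_capped = int((y > n).sum())
    y = np.minimum(y, n)

    cells = grid.assign(
        eligible_count=n.astype(int),
        event_count=y.astype(int),
        mean_age=mean_age,
        proportion_women=prop_women,
        median_chronic_conditions=med_chronic,
    )
    cols = [
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
    return cells[cols], n_capped


def generate_cells_and_claims(
    structure: Structure,
    seed: int = 0,
    calendar: StudyCalendar | None = None,
) -> SyntheticBundle:
    """Materialize claims so the indicator engine reconstructs the cells exactly.

    Per cell: ``n`` globally-distinct beneficiaries each contribute one
    eligibility-qualifying claim (or, for demographic-only indicators, one
    contact claim) at the cell's hospital, dated so the eligibility window
    stays inside the quarter; the first ``y`` of them additionally receive one
    event-procedure claim inside their window.  With ``duplicate_injection``
    a fraction of events get a same-quarter repeat event claim that the
    first-occurrence rule must remove.
    """
    cfg = structure.config
    calendar = calendar or StudyCalendar(n_quarters=cfg.n_quarters)
    rng = np.random.default_rng(seed)
    defs = {d.indicator_id: d for d in cfg.resolved_defs()}
    grid = _cell_grid(structure)
    n = rng.poisson(cfg.eligible_mean, len(grid))
    keep = n > 0
    grid, n = grid[keep].reset_index(drop=True), n[keep]

    q_start = np.array([np.datetime64(calendar.quarter_start(q)) for q in range(1, cfg.n_quarters + 1)])
    q_len = np.array(
        [
            (np.datetime64(calendar.quarter_end(q)) - np.datetime64(calendar.quarter_start(q))).astype(int) + 1
            for q in range(1, cfg.n_quarters + 1)
        ]
    )

    # per-cell eligibility-date offset, clamped so [date, date+window] fits
    ind = grid["indicator_id"].to_numpy()
    window = np.array([defs[j].eligibility_window_days for j in ind])
    demo = np.array([defs[j].demographic_only for j in ind])
    qlen = q_len[grid["quarter_index"].to_numpy() - 1]
    dmax = np.maximum(qlen - 1 - window, 0)
    cell_day = rng.integers(0, dmax + 1)

    # beneficiaries
    cell_idx = np.repeat(np.arange(len(grid)), n)
    N = len(cell_idx)
    bene_ids = np.array([f"B{i + 1:08d}" for i in range(N)])
    sex_req = np.array([defs[j].sex or "" for j in ind])[cell_idx]
    sex = np.where(
        sex_req != "", sex_req, np.where(rng.random(N) < 0.68, "F", "M")
    )
    lo = np.array([85.5 if defs[j].demographic_only else 66.5 for j in ind])[cell_idx]
    hi = np.array([94.0 if defs[j].demographic_only else 84.0 for j in ind])[cell_idx]
    age = rng.uniform(lo, hi)
    chronic = rng.poisson(7.6, N)

    qs = q_start[grid["quarter_index"].to_numpy() - 1][cell_idx]
    birth = qs - np.round(age * 365.25).astype(int).astype("timedelta64[D]")
    # exact age as the engine recomputes it (days / 365.25 at quarter start)
    age_exact = (qs - birth).astype("timedelta64[D]").astype(float) / 365.25

    beneficiaries = pd.DataFrame(
        {
            "beneficiary_id": bene_ids,
            "birth_date": birth.astype("datetime64[ns]"),
            "sex": sex,
            "chronic_condition_count": chronic,
        }
    )

    # cell covariates from the materialized beneficiaries
    cov = pd.DataFrame(
        {"cell": cell_idx, "age": age_exact, "female": (sex == "F").astype(float), "chronic": chronic}
    ).groupby("cell").agg(
        mean_age=("age", "mean"),
        proportion_women=("female", "mean"),
        median_chronic_conditions=("chronic", "median"),
    )
    cov = cov.reindex(range(len(grid)))

    X = cov[["mean_age", "proportion_women", "median_chronic_conditions"]].to_numpy()
    eta = _eta_fixed(grid, structure.truth, list(defs))
    eta = eta + ((X - _COV_CENTER) / _COV_SCALE) @ structure.truth.covariate_betas
    mean = n * np.exp(eta)
    y = _draw_counts(mean, structure.truth.dispersion, rng)
    n_capped = int((y > n).sum())
    y = np.minimum(y, n)

    # eligibility / contact claims (one per beneficiary)
    elig_day = np.where(demo[cell_idx], rng.integers(0, qlen[cell_idx]), cell_day[cell_idx])
    elig_date = qs + elig_day.astype("timedelta64[D]")
    dx_code = np.array(
        [d.eligibility_dx_codes[0] if d.eligibility_dx_codes else "" for d in (defs[j] for j in ind)]
    )[cell_idx]
    px_elig = np.array(
        [
            d.eligibility_px_codes[0] if (not d.eligibility_dx_codes and d.eligibility_px_codes) else ""
            for d in (defs[j] for j in ind)
        ]
    )[cell_idx]
    claims_elig = pd.DataFrame(
        {
            "beneficiary_id": bene_ids,
            "service_date": elig_date.astype("datetime64[ns]"),
            "ccn": grid["ccn"].to_numpy()[cell_idx],
            "diagnosis_codes": dx_code,
            "procedure_codes": px_elig,
            "setting": "outpatient",
        }
    )

    # event claims: the first y beneficiaries of each cell
    within = np.arange(N) - np.repeat(np.concatenate([[0], np.cumsum(n)[:-1]]), n)
    is_event = within < y[cell_idx]
    ev_sel = np.where(is_event)[0]
    room = np.where(
        demo[cell_idx[ev_sel]],
        qlen[cell_idx[ev_sel]] - 1 - elig_day[ev_sel],
        np.minimum(window[cell_idx[ev_sel]], qlen[cell_idx[ev_sel]] - 1 - elig_day[ev_sel]),
    )
    ev_off = rng.integers(0, np.maximum(room, 0) + 1)
    ev_date = elig_date[ev_sel] + ev_off.astype("timedelta64[D]")
    ev_code = np.array([defs[j].event_codes[0] for j in ind])[cell_idx[ev_sel]]
    claims_event = pd.DataFrame(
        {
            "beneficiary_id": bene_ids[ev_sel],
            "service_date": ev_date.astype("datetime64[ns]"),
            "ccn": grid["ccn"].to_numpy()[cell_idx[ev_sel]],
            "diagnosis_codes": "",
            "procedure_codes": ev_code,
            "setting": "outpatient",
        }
    )

    frames = [claims_elig, claims_event]
    if cfg.duplicate_injection > 0 and len(ev_sel):
        dup = rng.random(len(ev_sel)) < cfg.duplicate_injection
        if dup.any():
            extra = ev_off[dup] + 1
            extra = np.minimum(extra, np.maximum(room[dup], 0))
            dup_date = elig_date[ev_sel][dup] + extra.astype("timedelta64[D]")
            frames.append(
                pd.DataFrame(
                    {
                        "beneficiary_id": bene_ids[ev_sel][dup],
                        "service_date": dup_date.astype("datetime64[ns]"),
                        "ccn": grid["ccn"].to_numpy()[cell_idx[ev_sel]][dup],
                        "diagnosis_codes": "",
                        "procedure_codes": ev_code[dup],
                        "setting": "outpatient",
                    }
                )
            )
    claims = pd.concat(frames, ignore_index=True)
    claims = claims.sort_values(["beneficiary_id", "service_date", "procedure_codes"]).reset_index(drop=True)

    cells = grid.assign(
        eligible_count=n.astype(int),
        event_count=y.astype(int),
        mean_age=cov["mean_age"].to_numpy(),
        proportion_women=cov["proportion_women"].to_numpy(),
        median_chronic_conditions=cov["median_chronic_conditions"].to_numpy(),
    )[
        [
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
    ].sort_values(["ccn", "quarter_index", "indicator_id"]).reset_index(drop=True)

    return SyntheticBundle(
        claims=claims,
        beneficiaries=beneficiaries,
        linkage=structure.linkage,
        characteristics=structure.characteristics,
        truth=structure.truth,
        seed=seed,
        cells=cells,
        n_capped=n_capped,
    )


def generate_bundle(config: GeneratorConfig | None = None, seed: int = 0, **overrides) -> SyntheticBundle:
    """Structure plus materialized claims in one call (single top-level seed)."""
    structure = generate_structure(seed=seed, config=config, **overrides)
    return generate_cells_and_claims(structure, seed=seed + 1)
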