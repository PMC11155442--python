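"""Synthetic study cohorts with known per-subject ground truth.

Generates subject tables whose group structure and summary statistics follow
the reported validation cohort: 8 spontaneous-preterm (sPTB), 119 term and
5 indicated-preterm subjects, alongside a development phase and the attrition
categories (non-attenders, lost to follow-up, operator error). Per-subject
anterior/posterior elasticity and length are drawn from bivariate normal
sector models whose marginal means/SDs and induced average-SD match the
printed group rows; indicated-preterm subjects share the sPTB elasticity
distribution (their cervices soften similarly).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ConfigError

SPTB = "sptb"
TERM = "term"
INDICATED = "indicated_preterm"
DEVELOPMENT = "development"
EXCLUDED_NO_SHOW = "excluded_no_show"
EXCLUDED_LOST = "excluded_lost_followup"
EXCLUDED_OPERATOR = "excluded_operator_error"

VALIDATION_GROUPS = (SPTB, TERM, INDICATED)
TERM_THRESHOLD_DAYS = 259  # 37 completed weeks


@dataclass(frozen=True)
class SectorPairDistribution:
    """Average-first model for (anterior, posterior) sector values.

    The subject's two-sector average is drawn from a truncated normal — the
    printed group row for the averaged quantity, which is what the classifier
    uses. Sectors split multiplicatively and symmetrically around it:
    ``anterior = A (1 + x)``, ``posterior = A (1 - x)`` with
    ``x ~ N(offset_fraction, heterogeneity_fraction)``, so the average is
    preserved exactly and the printed anterior/posterior mean offset is
    honoured. The printed per-sector SDs are deliberately *not* matched: they
    exceed what any average-consistent tissue model allows (the posterior SD
    is below the average SD) because single-sector readings carry probe
    placement and repeat-measurement variance that this simulator does not
    model.
    """

    avg_mean: float
    avg_sd: float
    floor: float
    offset_fraction: float = 0.0        # (m_ant - m_post) / (m_ant + m_post)
    heterogeneity_fraction: float = 0.0  # SD of the relative sector split

    def __post_init__(self) -> None:
        if self.avg_sd <= 0:
            raise ConfigError("avg_sd must be positive")
        if self.heterogeneity_fraction < 0:
            raise ConfigError("heterogeneity_fraction must be non-negative")

    def sample_average(self, n: int, rng: np.random.Generator) -> np.ndarray:
        from scipy.stats import truncnorm
        a = (self.floor - self.avg_mean) / self.avg_sd
        return truncnorm.ppf(rng.uniform(size=n), a, np.inf,
                             loc=self.avg_mean, scale=self.avg_sd)

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        avg = self.sample_average(n, rng)
        x = rng.normal(self.offset_fraction, self.heterogeneity_fraction, size=n)
        ant = avg * (1.0 + x)
        post = avg * (1.0 - x)
        return np.maximum(ant, self.floor), np.maximum(post, self.floor)


@dataclass(frozen=True)
class DemographicsSpec:
    """Normal/Bernoulli models for the reported demographic summary rows."""

    age_mean: float
    age_sd: float
    height_mean: float
    height_sd: float
    weight_mean: float
    weight_sd: float
    parous_rate: float
    prior_ptb_rate: float
    ga_exam_mean_days: float
    ga_exam_sd_days: float
    ga_birth_mean_days: float
    ga_birth_sd_days: float

    def __post_init__(self) -> None:
        for name in ("age_sd", "height_sd", "weight_sd", "ga_exam_sd_days", "ga_birth_sd_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


# Defaults reproduce the printed validation-cohort average rows exactly;
# sector mean offsets come from the printed anterior/posterior rows, and the
# ~20% (elasticity) / ~8% (length) relative heterogeneity is a modelling
# choice for true between-sector tissue variation.
PRETERM_ELASTICITY = SectorPairDistribution(
    avg_mean=0.70, avg_sd=0.26, floor=0.05,
    offset_fraction=(0.73 - 0.68) / (0.73 + 0.68), heterogeneity_fraction=0.20)
TERM_ELASTICITY = SectorPairDistribution(
    avg_mean=1.63, avg_sd=0.65, floor=0.05,
    offset_fraction=(1.67 - 1.58) / (1.67 + 1.58), heterogeneity_fraction=0.20)
PRETERM_LENGTH = SectorPairDistribution(
    avg_mean=34.9, avg_sd=7.7, floor=10.0,
    offset_fraction=(34.9 - 34.8) / (34.9 + 34.8), heterogeneity_fraction=0.08)
TERM_LENGTH = SectorPairDistribution(
    avg_mean=30.4, avg_sd=6.8, floor=10.0,
    offset_fraction=(30.8 - 30.1) / (30.8 + 30.1), heterogeneity_fraction=0.08)
PRETERM_DEMOGRAPHICS = DemographicsSpec(
    age_mean=32.0, age_sd=5.3, height_mean=161.5, height_sd=8.4,
    weight_mean=82.7, weight_sd=13.8, parous_rate=0.50, prior_ptb_rate=0.25,
    ga_exam_mean_days=190.0, ga_exam_sd_days=8.0,   # 27w1d mean within the 24-28w window
    ga_birth_mean_days=243.0, ga_birth_sd_days=9.0,  # 34w5d mean, truncated below 37w
)
TERM_DEMOGRAPHICS = DemographicsSpec(
    age_mean=30.8, age_sd=6.2, height_mean=162.7, height_sd=6.7,
    weight_mean=81.1, weight_sd=17.9, parous_rate=0.38, prior_ptb_rate=0.09,
    ga_exam_mean_days=186.0, ga_exam_sd_days=8.0,   # 26w4d mean
    ga_birth_mean_days=274.0, ga_birth_sd_days=8.0,  # 39w1d mean, truncated at >= 37w
)
GA_EXAM_WINDOW_DAYS = (168.0, 202.0)  # 24w0d .. 28w6d
COMFORT_PROBS = (54 / 127, 65 / 127, 8 / 127)  # reported 3-point comfort shares


@dataclass(frozen=True)
class CohortConfig:
    """Counts and distributions for a full synthetic study cohort."""

    n_sptb: int = 8
    n_term: int = 119
    n_indicated: int = 5
    n_development: int = 34
    n_no_show: int = 5
    n_lost_followup: int = 7
    n_operator_error: int = 2
    elasticity_preterm: SectorPairDistribution = PRETERM_ELASTICITY
    elasticity_term: SectorPairDistribution = TERM_ELASTICITY
    length_preterm: SectorPairDistribution = PRETERM_LENGTH
    length_term: SectorPairDistribution = TERM_LENGTH
    demographics_preterm: DemographicsSpec = PRETERM_DEMOGRAPHICS
    demographics_term: DemographicsSpec = TERM_DEMOGRAPHICS

    def __post_init__(self) -> None:
        for name in ("n_sptb", "n_term", "n_indicated", "n_development",
                     "n_no_show", "n_lost_followup", "n_operator_error"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def n_validation(self) -> int:
        return self.n_sptb + self.n_term + self.n_indicated

    @property
    def n_enrolled(self) -> int:
        return (self.n_validation + self.n_development + self.n_no_show
                + self.n_lost_followup + self.n_operator_error)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Rejection-free truncated normal via the inverse CDF (deterministic in rng)."""
    from scipy.stats import truncnorm
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(rng.uniform(size=n), a, b, loc=mean, scale=sd)


def _group_rows(group: str, n: int, demo: DemographicsSpec,
                elasticity: SectorPairDistribution | None,
                length: SectorPairDistribution | None,
                spontaneous: bool, preterm_birth: bool,
                has_exam: bool, has_outcome: bool,
                rng: np.random.Generator) -> pd.DataFrame:
    ga_exam = _truncated_normal(rng, demo.ga_exam_mean_days, demo.ga_exam_sd_days,
                                *GA_EXAM_WINDOW_DAYS, n)
    if preterm_birth:
        ga_birth = _truncated_normal(rng, demo.ga_birth_mean_days, demo.ga_birth_sd_days,
                                     GA_EXAM_WINDOW_DAYS[1] + 1, TERM_THRESHOLD_DAYS - 1, n)
    else:
        ga_birth = _truncated_normal(rng, demo.ga_birth_mean_days, demo.ga_birth_sd_days,
                                     TERM_THRESHOLD_DAYS, 300.0, n)
    rows = {
        "group": group,
        "maternal_age_years": rng.normal(demo.age_mean, demo.age_sd, n).round(1),
        "height_cm": rng.normal(demo.height_mean, demo.height_sd, n).round(1),
        "weight_kg": rng.normal(demo.weight_mean, demo.weight_sd, n).round(1),
        "parity": (rng.uniform(size=n) < demo.parous_rate).astype(int),
        "prior_ptb": rng.uniform(size=n) < demo.prior_ptb_rate,
        "ga_exam_days": np.round(ga_exam),
        "ga_birth_days": np.round(ga_birth) if has_outcome else np.nan,
        "spontaneous_delivery": spontaneous if has_outcome else np.nan,
    }
    if has_exam and elasticity is not None and length is not None:
        e_ant, e_post = elasticity.sample(n, rng)
        l_ant, l_post = length.sample(n, rng)
        rows.update({
            "true_elasticity_anterior_kpa_mm": e_ant,
            "true_elasticity_posterior_kpa_mm": e_post,
            "true_elasticity_avg_kpa_mm": (e_ant + e_post) / 2.0,
            "true_length_anterior_mm": l_ant,
            "true_length_posterior_mm": l_post,
            "true_length_avg_mm": (l_ant + l_post) / 2.0,
        })
        rows["comfort"] = rng.choice([1, 2, 3], size=n, p=COMFORT_PROBS)
    df = pd.DataFrame(rows)
    if not has_exam:
        df["comfort"] = np.nan
    return df


def generate_cohort(config: CohortConfig = CohortConfig(),
                    seed: np.random.Generator | int | None = 0) -> pd.DataFrame:
    """Generate the full enrolled cohort as one subject-per-row table.

    Only validation-phase subjects (sPTB / term / indicated-preterm) carry
    ground-truth tissue parameters; development-phase and attrition subjects
    contribute demographics and accounting only. The draw order is fixed, so
    identical ``(config, seed)`` give identical tables.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    parts = [
        _group_rows(SPTB, config.n_sptb, config.demographics_preterm,
                    config.elasticity_preterm, config.length_preterm,
                    spontaneous=True, preterm_birth=True,
                    has_exam=True, has_outcome=True, rng=rng),
        _group_rows(TERM, config.n_term, config.demographics_term,
                    config.elasticity_term, config.length_term,
                    spontaneous=True, preterm_birth=False,
                    has_exam=True, has_outcome=True, rng=rng),
        _group_rows(INDICATED, config.n_indicated, config.demographics_preterm,
                    config.elasticity_preterm, config.length_preterm,
                    spontaneous=False, preterm_birth=True,
                    has_exam=True, has_outcome=True, rng=rng),
        _group_rows(DEVELOPMENT, config.n_development, config.demographics_term,
                    None, None, spontaneous=True, preterm_birth=False,
                    has_exam=False, has_outcome=True, rng=rng),
        _group_rows(EXCLUDED_NO_SHOW, config.n_no_show, config.demographics_term,
                    None, None, spontaneous=True, preterm_birth=False,
                    has_exam=False, has_outcome=True, rng=rng),
        _group_rows(EXCLUDED_LOST, config.n_lost_followup, config.demographics_term,
                    None, None, spontaneous=True, preterm_birth=False,
                    has_exam=False, has_outcome=False, rng=rng),
        _group_rows(EXCLUDED_OPERATOR, config.n_operator_error, config.demographics_term,
                    None, None, spontaneous=True, preterm_birth=False,
                    has_exam=False, has_outcome=True, rng=rng),
    ]
    df = pd.concat(parts, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(df))])
    return df
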