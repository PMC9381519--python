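"""Synthetic cytometry specimens and patient cohorts.

Every downstream stage (gating, classification, association screen,
survival) is exercised on cohorts generated here, so the generator mirrors
the statistical structure the analysis assumes:

* six SLA archetypes, each strictly inside its decision region, with
  published cohort proportions as the default mixing weights;
* per-marker event intensities from a two-component (negative/positive)
  log-normal model — only the realized percent-positive matters, the
  component parameterization is configurable;
* per-(SLA, lesion) mutation prevalences defaulting to published
  mutated/tested counts;
* exponential competing-risks outcomes (relapse vs death without relapse)
  after complete remission, with independent uniform censoring.

All randomness flows from one ``numpy`` generator seeded by a single
integer: identical config => byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from slaml.gating import CORE_MARKERS, EventMatrix

SLA_LABELS = ("HSC-L", "MPP-L", "CMP-L", "GMP-L", "GP-L", "MP-L")

EVENT_MARKERS = ("CD45", "SSC", "CD34", "CD117", "CD13", "CD33",
                 "MPO", "HLA-DR", "CD38", "CD123")

#: Default event-level positivity cutoffs (geometric midpoint of the two
#: intensity components; CD45 carries the blast-gate, not a cutoff).
DEFAULT_CUTOFFS: dict[str, float] = {m: 100.0 for m in EVENT_MARKERS
                                     if m not in ("CD45", "SSC")}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class IntensityModel:
    """Two-component log-normal intensity model shared across markers.

    ``neg_median``/``pos_median`` are the medians (linear scale) of the
    negative and positive components; ``log_sigma`` the common log-scale
    spread.  CD45/SSC locations describe the blast and lymphocyte
    populations used by the gate.
    """

    neg_median: float = 10.0
    pos_median: float = 1_000.0
    log_sigma: float = 0.4
    cd45_blast_median: float = 200.0
    cd45_lymph_median: float = 5_000.0
    cd45_log_sigma: float = 0.25
    ssc_median: float = 3_000.0
    ssc_log_sigma: float = 0.5


@dataclass(frozen=True)
class SLAArchetype:
    """One stage-of-arrest archetype: marker positive fractions + LSC load."""

    label: str
    positive_fraction: dict[str, float]
    lsc_fraction: float = 0.0
    intensity: IntensityModel = field(default_factory=IntensityModel)

    def __post_init__(self) -> None:
        if self.label not in SLA_LABELS:
            raise ValueError(f"unknown SLA label {self.label!r}")
        for marker, f in self.positive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"positive_fraction[{marker}]={f} outside [0, 1]")
        if not 0.0 <= self.lsc_fraction <= 1.0:
            raise ValueError("lsc_fraction outside [0, 1]")
        for m in CORE_MARKERS:
            if m not in self.positive_fraction:
                raise ValueError(f"archetype missing core marker {m!r}")

    def expected_profile(self) -> dict[str, float]:
        """Percent-of-blasts-positive the archetype targets (percent units)."""
        return {m: 100.0 * f for m, f in self.positive_fraction.items()}


def default_archetypes() -> dict[str, SLAArchetype]:
    """Archetypes sitting strictly inside their decision regions.

    LSC fractions default to the published per-stage medians (18.03% for
    HSC/MPP-L, 11.54% CMP-L, 7.83% GMP-L, <1% for GP/MP-L).
    """
    spec = {
        "HSC-L": (dict(CD34=0.85, CD117=0.10, CD13=0.05, CD33=0.08, MPO=0.02,
                       **{"HLA-DR": 0.60}, CD38=0.50, CD123=0.40), 0.1803),
        "MPP-L": (dict(CD34=0.80, CD117=0.50, CD13=0.60, CD33=0.70, MPO=0.05,
                       **{"HLA-DR": 0.40}, CD38=0.60, CD123=0.40), 0.1803),
        "CMP-L": (dict(CD34=0.75, CD117=0.60, CD13=0.70, CD33=0.65, MPO=0.40,
                       **{"HLA-DR": 0.50}, CD38=0.70, CD123=0.30), 0.1154),
        "GMP-L": (dict(CD34=0.85, CD117=0.60, CD13=0.70, CD33=0.65, MPO=0.85,
                       **{"HLA-DR": 0.30}, CD38=0.80, CD123=0.25), 0.0783),
        "GP-L": (dict(CD34=0.05, CD117=0.10, CD13=0.60, CD33=0.80, MPO=0.40,
                      **{"HLA-DR": 0.05}, CD38=0.85, CD123=0.20), 0.005),
        "MP-L": (dict(CD34=0.05, CD117=0.10, CD13=0.60, CD33=0.80, MPO=0.40,
                      **{"HLA-DR": 0.70}, CD38=0.85, CD123=0.20), 0.005),
    }
    return {lab: SLAArchetype(label=lab, positive_fraction=fr, lsc_fraction=lsc)
            for lab, (fr, lsc) in spec.items()}


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def simulate_events(
    archetype: SLAArchetype,
    n_events: int,
    seed: int,
    lymphocyte_fraction: float = 0.1,
) -> EventMatrix:
    """Simulate one specimen's event matrix.

    A ``lymphocyte_fraction`` of events is CD45-bright/marker-negative so the
    blast gate is non-trivial; the remainder are CD45-dim blasts whose marker
    intensities come from the positive component with probability
    ``positive_fraction[marker]``.

    When ``archetype.lsc_fraction > 0`` a matching share of blasts is forced
    CD34+CD38-CD123+; the remaining blasts are always CD38+ and their
    CD34/CD123 positive probabilities are adjusted so the CD34/CD123
    marginals still match the configured fractions.  (CD38's configured
    fraction is therefore overridden to ``1 - lsc_fraction`` in this mode.)
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if not 0.0 <= lymphocyte_fraction <= 1.0:
        raise ValueError("lymphocyte_fraction outside [0, 1]")

    rng = np.random.default_rng(seed)
    im = archetype.intensity
    cols = {m: np.empty(n_events) for m in EVENT_MARKERS}
    if n_events == 0:
        mat = np.empty((0, len(EVENT_MARKERS)))
        return EventMatrix(mat, list(EVENT_MARKERS), specimen_id=archetype.label)

    is_lymph = rng.random(n_events) < lymphocyte_fraction
    n_blast = int(np.count_nonzero(~is_lymph))
    n_lymph = n_events - n_blast

    cd45 = np.empty(n_events)
    cd45[~is_lymph] = _lognormal(rng, im.cd45_blast_median, im.cd45_log_sigma, n_blast)
    cd45[is_lymph] = _lognormal(rng, im.cd45_lymph_median, im.cd45_log_sigma, n_lymph)
    cols["CD45"] = cd45
    cols["SSC"] = _lognormal(rng, im.ssc_median, im.ssc_log_sigma, n_events)

    lsc = np.zeros(n_events, dtype=bool)
    if archetype.lsc_fraction > 0:
        lsc[~is_lymph] = rng.random(n_blast) < archetype.lsc_fraction

    for marker in EVENT_MARKERS:
        if marker in ("CD45", "SSC"):
            continue
        f = archetype.positive_fraction.get(marker, 0.0)
        positive = np.zeros(n_events, dtype=bool)
        blast_idx = np.flatnonzero(~is_lymph)
        if archetype.lsc_fraction > 0 and marker in ("CD34", "CD38", "CD123"):
            g = archetype.lsc_fraction
            if marker == "CD38":
                # non-LSC blasts are CD38+, LSC are CD38-: marginal = 1 - g
                positive[blast_idx] = ~lsc[blast_idx]
            else:
                p_adj = max(0.0, (f - g) / (1.0 - g)) if g < 1.0 else 0.0
                draw = rng.random(blast_idx.size) < p_adj
                positive[blast_idx] = np.where(lsc[blast_idx], True, draw)
        else:
            positive[blast_idx] = rng.random(blast_idx.size) < f
        out = np.empty(n_events)
        n_pos = int(np.count_nonzero(positive))
        out[positive] = _lognormal(rng, im.pos_median, im.log_sigma, n_pos)
        out[~positive] = _lognormal(rng, im.neg_median, im.log_sigma, n_events - n_pos)
        cols[marker] = out

    mat = np.column_stack([cols[m] for m in EVENT_MARKERS])
    return EventMatrix(mat, list(EVENT_MARKERS), specimen_id=archetype.label)


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

#: Published per-(SLA, lesion) mutated/tested counts used as prevalence
#: defaults (order: HSC-L, MPP-L, CMP-L, GMP-L, GP-L, MP-L).
DEFAULT_MUTATION_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "CEBPA":    {"HSC-L": (0, 6),  "MPP-L": (1, 163),  "CMP-L": (9, 248),
                 "GMP-L": (41, 125), "GP-L": (4, 59),  "MP-L": (14, 264)},
    "DNMT3A":   {"HSC-L": (0, 8),  "MPP-L": (13, 163), "CMP-L": (32, 250),
                 "GMP-L": (8, 155),  "GP-L": (6, 58),  "MP-L": (71, 250)},
    "FLT3-ITD": {"HSC-L": (5, 13), "MPP-L": (40, 264), "CMP-L": (61, 399),
                 "GMP-L": (28, 258), "GP-L": (35, 94), "MP-L": (126, 428)},
    "FLT3-TKD": {"HSC-L": (1, 6),  "MPP-L": (8, 159),  "CMP-L": (15, 234),
                 "GMP-L": (8, 152),  "GP-L": (4, 55),  "MP-L": (21, 212)},
    "IDH1":     {"HSC-L": (0, 8),  "MPP-L": (10, 231), "CMP-L": (29, 325),
                 "GMP-L": (12, 193), "GP-L": (13, 72), "MP-L": (37, 291)},
    "IDH2":     {"HSC-L": (1, 8),  "MPP-L": (25, 231), "CMP-L": (45, 325),
                 "GMP-L": (23, 193), "GP-L": (17, 72), "MP-L": (23, 291)},
    "NPM1":     {"HSC-L": (0, 9),  "MPP-L": (16, 271), "CMP-L": (49, 394),
                 "GMP-L": (18, 232), "GP-L": (75, 94), "MP-L": (269, 421)},
}

#: Published cohort SLA mixing proportions (n = 2087).
DEFAULT_SLA_PROPORTIONS: dict[str, float] = {
    "HSC-L": 0.009, "MPP-L": 0.219, "CMP-L": 0.302,
    "GMP-L": 0.172, "GP-L": 0.057, "MP-L": 0.241,
}

#: Published complete-remission rates per SLA (HSC/MPP pooled at 72%).
DEFAULT_CR_PROB: dict[str, float] = {
    "HSC-L": 0.72, "MPP-L": 0.72, "CMP-L": 0.76,
    "GMP-L": 0.87, "GP-L": 0.79, "MP-L": 0.85,
}

# Exponential hazards per month; ordered immature > mature so the simulated
# outcome gradient matches the published survival ordering qualitatively.
DEFAULT_RELAPSE_HAZARD: dict[str, float] = {
    "HSC-L": 0.10, "MPP-L": 0.08, "CMP-L": 0.06,
    "GMP-L": 0.02, "GP-L": 0.03, "MP-L": 0.035,
}
DEFAULT_DEATH_HAZARD: dict[str, float] = {
    "HSC-L": 0.05, "MPP-L": 0.04, "CMP-L": 0.03,
    "GMP-L": 0.010, "GP-L": 0.015, "MP-L": 0.015,
}
DEFAULT_OS_HAZARD: dict[str, float] = {
    "HSC-L": 0.080, "MPP-L": 0.060, "CMP-L": 0.045,
    "GMP-L": 0.020, "GP-L": 0.030, "MP-L": 0.030,
}


def default_mutation_prevalence() -> dict[str, dict[str, float]]:
    return {lesion: {s: k / n for s, (k, n) in cells.items()}
            for lesion, cells in DEFAULT_MUTATION_COUNTS.items()}


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int = 2087
    sla_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLA_PROPORTIONS))
    mutation_prevalence: dict[str, dict[str, float]] = field(
        default_factory=default_mutation_prevalence)
    tested_fraction: dict[str, float] = field(default_factory=dict)
    cr_prob: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CR_PROB))
    relapse_hazard: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELAPSE_HAZARD))
    death_hazard: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEATH_HAZARD))
    os_hazard: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OS_HAZARD))
    censor_max_months: float = 120.0
    jitter: float = 0.0          # logit-normal marker-profile dispersion
    events_per_specimen: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if set(self.sla_proportions) != set(SLA_LABELS):
            raise ConfigurationError("sla_proportions must cover the six SLA labels")
        total = sum(self.sla_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"sla_proportions sum to {total}, expected 1")
        for lesion, cells in self.mutation_prevalence.items():
            missing = set(SLA_LABELS) - set(cells)
            if missing:
                raise ConfigurationError(
                    f"prevalence table for {lesion!r} missing SLA column(s): "
                    f"{sorted(missing)}")
            for s, p in cells.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"P({lesion}|{s})={p} outside [0, 1]")
        for name in ("cr_prob",):
            for s, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name}[{s}]={p} outside [0, 1]")
        for name in ("relapse_hazard", "death_hazard", "os_hazard"):
            for s, h in getattr(self, name).items():
                if h < 0:
                    raise ConfigurationError(f"{name}[{s}]={h} must be >= 0")
        if self.events_per_specimen <= 0:
            raise ConfigurationError("events_per_specimen must be positive")
        if self.jitter < 0:
            raise ConfigurationError("jitter must be >= 0")

    def expected_lesion_frequency(self, lesion: str) -> float:
        """Closed-form mixture frequency sum_s P(s) * P(lesion | s)."""
        cells = self.mutation_prevalence[lesion]
        return sum(self.sla_proportions[s] * cells[s] for s in SLA_LABELS)


@dataclass
class SyntheticCohort:
    """Simulated cohort: marker profiles, genotypes, outcomes, ground truth."""

    config: CohortConfig
    profiles: pd.DataFrame
    genotypes: pd.DataFrame
    outcomes: pd.DataFrame
    true_sla: pd.Series

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.profiles.to_csv(outdir / "profiles.csv", index=False)
        self.genotypes.to_csv(outdir / "genotypes.csv", index=False)
        self.outcomes.to_csv(outdir / "outcomes.csv", index=False)
        self.true_sla.rename("true_sla").to_frame().assign(
            patient_id=self.profiles["patient_id"].to_numpy()
        )[["patient_id", "true_sla"]].to_csv(outdir / "true_sla.csv", index=False)


def _logit_jitter(rng: np.random.Generator, fractions: np.ndarray,
                  scale: float) -> np.ndarray:
    """Logit-normal jitter; scale 0 returns the fractions unchanged."""
    if scale == 0.0:
        return fractions.copy()
    eps = 1e-6
    f = np.clip(fractions, eps, 1.0 - eps)
    z = np.log(f / (1.0 - f)) + rng.normal(0.0, scale, size=f.shape)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_cohort(
    config: CohortConfig,
    archetypes: Mapping[str, SLAArchetype] | None = None,
) -> SyntheticCohort:
    """Draw one full cohort from ``config``.

    Per patient: a true SLA from ``sla_proportions``; a marker profile
    jittered around its archetype (exact at ``jitter == 0``); independent
    per-lesion mutation flags from ``P(lesion | SLA)``; a CR indicator; and
    competing-risks outcome times from per-SLA exponential hazards with
    independent uniform censoring.
    """
    rng = np.random.default_rng(config.seed)
    archetypes = dict(archetypes or default_archetypes())
    for lab in SLA_LABELS:
        if lab not in archetypes:
            raise ConfigurationError(f"archetype for {lab!r} not provided")

    n = config.n_patients
    labels = np.array(SLA_LABELS)
    probs = np.array([config.sla_proportions[s] for s in SLA_LABELS])
    sla_idx = rng.choice(len(labels), size=n, p=probs / probs.sum())
    true_sla = pd.Series(labels[sla_idx], name="true_sla")

    # --- marker profiles -------------------------------------------------
    markers = [m for m in EVENT_MARKERS if m not in ("CD45", "SSC")]
    base = np.array([[archetypes[s].positive_fraction.get(m, 0.0) for m in markers]
                     for s in true_sla])
    jittered = _logit_jitter(rng, base, config.jitter)
    profiles = pd.DataFrame(100.0 * jittered, columns=markers)
    profiles.insert(0, "patient_id", [f"P{i:05d}" for i in range(n)])
    profiles["n_blasts"] = config.events_per_specimen
    profiles["lsc_percent"] = 100.0 * np.array(
        [archetypes[s].lsc_fraction for s in true_sla])

    # --- genotypes -------------------------------------------------------
    geno = {"patient_id": profiles["patient_id"].to_numpy()}
    for lesion, cells in config.mutation_prevalence.items():
        p = np.array([cells[s] for s in true_sla])
        tested_p = config.tested_fraction.get(lesion, 1.0)
        tested = rng.random(n) < tested_p
        mutated = (rng.random(n) < p) & tested
        geno[lesion] = mutated.astype(int)
        geno[f"{lesion}_tested"] = tested.astype(int)
    genotypes = pd.DataFrame(geno)

    # --- outcomes --------------------------------------------------------
    cr_p = np.array([config.cr_prob[s] for s in true_sla])
    cr = rng.random(n) < cr_p
    h_os = np.array([config.os_hazard[s] for s in true_sla])
    t_death_os = rng.exponential(1.0 / np.where(h_os > 0, h_os, np.inf))
    c_os = rng.uniform(0.0, config.censor_max_months, size=n)
    os_months = np.minimum(t_death_os, c_os)
    os_event = (t_death_os <= c_os).astype(int)

    h_r = np.array([config.relapse_hazard[s] for s in true_sla])
    h_d = np.array([config.death_hazard[s] for s in true_sla])
    t_rel = rng.exponential(1.0 / np.where(h_r > 0, h_r, np.inf))
    t_dth = rng.exponential(1.0 / np.where(h_d > 0, h_d, np.inf))
    c_cr = rng.uniform(0.0, config.censor_max_months, size=n)

    t_first = np.minimum(t_rel, t_dth)
    dfs_months = np.where(cr, np.minimum(t_first, c_cr), np.nan)
    dfs_event = np.where(cr, (t_first <= c_cr).astype(float), np.nan)
    relapse_event = np.where(cr, ((t_rel <= t_dth) & (t_rel <= c_cr)).astype(float),
                             np.nan)
    death_prior_relapse = np.where(
        cr, ((t_dth < t_rel) & (t_dth <= c_cr)).astype(float), np.nan)

    outcomes = pd.DataFrame({
        "patient_id": profiles["patient_id"],
        "os_months": os_months,
        "os_event": os_event,
        "cr": cr.astype(int),
        "dfs_months": dfs_months,
        "dfs_event": dfs_event,
        "relapse_months": dfs_months,
        "relapse_event": relapse_event,
        "death_prior_relapse": death_prior_relapse,
    })

    return SyntheticCohort(config=config, profiles=profiles, genotypes=genotypes,
                           outcomes=outcomes, true_sla=true_sla)


def archetype_with_jitterless_profile(label: str) -> dict[str, float]:
    """Convenience: the exact percent profile of a default archetype."""
    return default_archetypes()[label].expected_profile()
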