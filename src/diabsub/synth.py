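"""Synthetic cohorts, genotypes, lipidomes and outcomes with planted truth.

The generators in this module emulate the statistical structure of a
three-subgroup recent-onset type 2 diabetes cohort: a mixture over the five
clinical classifiers (Gaussian for symmetric variables, log-normal for
skewed ones, each calibrated from published per-subgroup summaries),
allele-frequency-drawn genotype dosages with optional planted polygenic-score
shifts, a 315-species log-normal lipidome with planted subgroup effects and
batch offsets, exponential event times with planted subgroup hazard ratios,
and piecewise-geometric eGFR trajectories that do (or do not) trigger the
confirmed 40%-decline kidney endpoint.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Gaussian",
    "LogNormal",
    "SubgroupSpec",
    "HazardSpec",
    "LabSeries",
    "lognormal_from_median_iqr",
    "table1_subgroup_specs",
    "table1_counts",
    "table3_hazard_specs",
    "simulate_clinical_cohort",
    "simulate_table1_cohort",
    "simulate_genotypes",
    "simulate_lipidome",
    "simulate_outcomes",
    "simulate_egfr_series",
    "LIPID_CLASS_COUNTS",
]

#: z-score of the 0.75 quantile of the standard normal, used to convert an
#: inter-quartile range into a log-normal sigma.
Z75 = float(stats.norm.ppf(0.75))  # 0.6744897501960817


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gaussian:
    """Normal distribution parameterised by mean and SD (``mean +- sd``)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class LogNormal:
    """Log-normal distribution: ``ln X ~ N(mu, sigma)``."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(rng.normal(self.mu, self.sigma, size=n))


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> LogNormal:
    """Fit a log-normal from a reported ``median (Q1-Q3)`` summary.

    On the log scale the quartiles of a log-normal sit at
    ``mu +- z_{0.75} * sigma``, so

        mu    = ln(median)
        sigma = (ln q3 - ln q1) / (2 * z_{0.75})

    and the fitted distribution reproduces all three reported quantiles.

    Raises
    ------
    ValueError
        If the quantiles are non-positive or not strictly increasing
        around the median.
    """
    if not (0 < q1 < median < q3):
        raise ValueError(
            f"require 0 < q1 < median < q3, got q1={q1}, median={median}, q3={q3}"
        )
    mu = float(np.log(median))
    sigma = float((np.log(q3) - np.log(q1)) / (2.0 * Z75))
    return LogNormal(mu, sigma)


Distribution = Gaussian | LogNormal


@dataclass(frozen=True)
class SubgroupSpec:
    """Generating distributions for one diabetes subgroup.

    ``variables`` maps a column name to its distribution; ``sex_fraction``
    is the fraction of male participants; ``ethnicity_fractions`` must sum
    to one over its categories.
    """

    name: str
    weight: float
    variables: dict[str, Distribution]
    sex_fraction: float = 0.5
    ethnicity_fractions: dict[str, float] = field(
        default_factory=lambda: {"Chinese": 0.5, "Malay": 0.27, "Asian Indian": 0.23}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError(f"weight must be in [0,1], got {self.weight}")
        if not 0 <= self.sex_fraction <= 1:
            raise ValueError(f"sex_fraction must be in [0,1], got {self.sex_fraction}")
        total = sum(self.ethnicity_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"ethnicity fractions must sum to 1, got {total}")


def _validate_specs(specs: list[SubgroupSpec]) -> None:
    if not specs:
        raise ValueError("at least one SubgroupSpec is required")
    total = sum(s.weight for s in specs)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"subgroup weights must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# published-summary calibration
# ---------------------------------------------------------------------------

#: per-subgroup counts in the 687-participant discovery cohort
table1_counts: tuple[int, int, int] = (307, 130, 250)


def table1_subgroup_specs() -> list[SubgroupSpec]:
    """Default generating specs for the three subgroups.

    Calibrated to the published per-subgroup baseline summaries of the
    discovery cohort: Gaussian for variables reported as mean +- SD,
    log-normal (via :func:`lognormal_from_median_iqr`) for variables
    reported as median (IQR).  Subgroups: MOD (mild obesity-related,
    45%), SIRD-RII (severe insulin-resistant with relative insulin
    insufficiency, 19%), MARD-II (mild age-related with insulin
    insufficiency, 36%).
    """
    ln = lognormal_from_median_iqr
    return [
        SubgroupSpec(
            name="MOD",
            weight=307 / 687,
            variables={
                "onset_age": Gaussian(52.0, 9.4),
                "index_age": Gaussian(55.0, 9.6),
                "bmi": Gaussian(30.1, 5.0),
                "hba1c": Gaussian(6.9, 0.7),
                "homa2b": ln(96.9, 77.5, 131.7),
                "homa2ir": ln(2.2, 1.8, 2.9),
                "tg_hdl_ratio": ln(1.1, 0.8, 1.8),
                "triacylglycerol": ln(1.4, 1.1, 1.9),
                "hdl_cholesterol": Gaussian(1.3, 0.4),
                "egfr": Gaussian(92.0, 19.2),
            },
            sex_fraction=0.469,
            ethnicity_fractions={"Chinese": 0.401, "Malay": 0.339, "Asian Indian": 0.260},
        ),
        SubgroupSpec(
            name="SIRD-RII",
            weight=130 / 687,
            variables={
                "onset_age": Gaussian(40.0, 10.9),
                "index_age": Gaussian(43.0, 11.5),
                "bmi": Gaussian(31.6, 5.9),
                "hba1c": Gaussian(9.2, 1.2),
                "homa2b": ln(43.7, 32.4, 61.9),
                "homa2ir": ln(2.7, 1.9, 3.8),
                "tg_hdl_ratio": ln(1.6, 1.1, 2.3),
                "triacylglycerol": ln(1.8, 1.3, 2.4),
                "hdl_cholesterol": Gaussian(1.2, 0.3),
                "egfr": Gaussian(109.0, 19.7),
            },
            sex_fraction=0.569,
            ethnicity_fractions={"Chinese": 0.477, "Malay": 0.285, "Asian Indian": 0.238},
        ),
        SubgroupSpec(
            name="MARD-II",
            weight=250 / 687,
            variables={
                "onset_age": Gaussian(56.0, 9.9),
                "index_age": Gaussian(59.0, 9.9),
                "bmi": Gaussian(24.9, 3.4),
                "hba1c": Gaussian(7.1, 0.9),
                "homa2b": ln(53.3, 40.0, 66.0),
                "homa2ir": ln(1.3, 0.9, 1.6),
                "tg_hdl_ratio": ln(0.9, 0.6, 1.4),
                "triacylglycerol": ln(1.2, 0.9, 1.6),
                "hdl_cholesterol": Gaussian(1.4, 0.4),
                "egfr": Gaussian(92.0, 21.0),
            },
            sex_fraction=0.524,
            ethnicity_fractions={"Chinese": 0.628, "Malay": 0.196, "Asian Indian": 0.176},
        ),
    ]


# bounds applied after sampling; HbA1c is bounded by assay range, the
# positive floors guard the log transforms downstream
_CLIP_BOUNDS: dict[str, tuple[float, float]] = {
    "hba1c": (3.01, 19.99),
    "homa2b": (1e-3, np.inf),
    "homa2ir": (1e-3, np.inf),
    "tg_hdl_ratio": (1e-3, np.inf),
    "triacylglycerol": (1e-3, np.inf),
    "hdl_cholesterol": (0.3, np.inf),
    "egfr": (15.0, np.inf),
    "bmi": (12.0, np.inf),
    "onset_age": (18.0, np.inf),
    "index_age": (18.0, np.inf),
}


def simulate_clinical_cohort(
    specs: list[SubgroupSpec],
    n: int | None = None,
    counts: tuple[int, ...] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a clinical cohort table from a subgroup mixture.

    Either ``counts`` fixes the per-subgroup sizes, or ``n`` participants
    are allocated multinomially by the spec weights.  Variables are drawn
    independently within subgroup.  Returns a DataFrame with
    ``participant_id``, ``subgroup_true``, ``sex``, ``ethnicity`` and one
    column per spec variable; rows are shuffled so subgroup order carries
    no information.
    """
    _validate_specs(specs)
    rng = np.random.default_rng(seed)
    if counts is not None:
        if len(counts) != len(specs):
            raise ValueError("counts must have one entry per subgroup spec")
        sizes = np.asarray(counts, dtype=int)
    else:
        if n is None or n < 1:
            raise ValueError("n >= 1 required when counts not given")
        sizes = rng.multinomial(n, [s.weight for s in specs])

    frames = []
    for spec, size in zip(specs, sizes):
        cols: dict[str, np.ndarray] = {}
        for name, dist in spec.variables.items():
            x = dist.sample(size, rng)
            lo, hi = _CLIP_BOUNDS.get(name, (-np.inf, np.inf))
            cols[name] = np.clip(x, lo, hi)
        frame = pd.DataFrame(cols)
        frame.insert(0, "subgroup_true", spec.name)
        frame["sex"] = np.where(rng.random(size) < spec.sex_fraction, "male", "female")
        eth_names = list(spec.ethnicity_fractions)
        eth_p = np.array([spec.ethnicity_fractions[e] for e in eth_names])
        frame["ethnicity"] = rng.choice(eth_names, size=size, p=eth_p / eth_p.sum())
        frames.append(frame)
    cohort = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(cohort))
    cohort = cohort.iloc[order].reset_index(drop=True)
    cohort.insert(0, "participant_id", [f"P{i:05d}" for i in range(len(cohort))])
    return cohort


def simulate_table1_cohort(
    seed: int | np.random.Generator = 0, fixed_counts: bool = True
) -> pd.DataFrame:
    """Convenience wrapper: the 687-participant calibrated cohort."""
    specs = table1_subgroup_specs()
    if fixed_counts:
        return simulate_clinical_cohort(specs, counts=table1_counts, seed=seed)
    return simulate_clinical_cohort(specs, n=sum(table1_counts), seed=seed)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    panel: pd.DataFrame,
    subgroup_labels: np.ndarray | pd.Series,
    prs_shifts: dict[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw risk-allele dosages ``Binomial(2, f_v)`` per panel variant.

    ``prs_shifts`` maps a subgroup label to a planted mean difference of
    the weighted score for that subgroup.  The shift is realised by moving
    each variant's risk-allele frequency additively, with the per-variant
    move proportional to its weight (``delta_v = D * w_v / (2 * sum w^2)``),
    which yields the requested score-mean shift in expectation.

    Returns an ``n x variants`` DataFrame of dosages in [0, 2] oriented to
    the risk allele, indexed like ``subgroup_labels``.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(subgroup_labels).reset_index(drop=True)
    freqs = panel["freq"].to_numpy(float)
    weights = panel["weight"].to_numpy(float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")

    n = len(labels)
    shifted = np.tile(freqs, (n, 1))
    if prs_shifts:
        denom = 2.0 * float(np.sum(weights**2))
        if denom == 0:
            raise ValueError("cannot plant a score shift with all-zero weights")
        for group, delta in prs_shifts.items():
            mask = (labels == group).to_numpy()
            if not mask.any():
                continue
            f_new = freqs + delta * weights / denom
            if np.any((f_new <= 0) | (f_new >= 1)):
                raise ValueError(
                    f"planted shift {delta} for {group!r} pushes an allele "
                    "frequency outside (0, 1)"
                )
            shifted[mask] = f_new
    dosages = rng.binomial(2, shifted).astype(float)
    return pd.DataFrame(dosages, columns=panel["variant_id"].tolist())


# ---------------------------------------------------------------------------
# lipidome
# ---------------------------------------------------------------------------

#: species counts per lipid class, summing to 315
LIPID_CLASS_COUNTS: dict[str, int] = {
    "PC": 90,
    "PE": 55,
    "SM": 55,
    "Cer": 40,
    "PI": 30,
    "LPC": 30,
    "LPI": 10,
    "Hex1Cer": 5,
}


def _species_catalogue(n_species: int) -> pd.DataFrame:
    # fixed catalogue: species identities are a property of the assay panel,
    # not of the simulation seed, so discovery and validation share ids
    rng = np.random.default_rng(315)
    classes: list[str] = []
    for cls, cnt in LIPID_CLASS_COUNTS.items():
        classes.extend([cls] * cnt)
    if n_species <= len(classes):
        classes = classes[:n_species]
    else:  # pad by cycling the vocabulary
        vocab = list(LIPID_CLASS_COUNTS)
        while len(classes) < n_species:
            classes.append(vocab[len(classes) % len(vocab)])
    carbons = rng.integers(14, 41, size=n_species)
    dbs = rng.integers(0, 7, size=n_species)
    ids = [f"{c} {a}:{d}" for c, a, d in zip(classes, carbons, dbs)]
    # ensure uniqueness
    seen: dict[str, int] = {}
    for i, s in enumerate(ids):
        if s in seen:
            seen[s] += 1
            ids[i] = f"{s}_{seen[s]}"
        else:
            seen[s] = 0
    return pd.DataFrame({"species_id": ids, "lipid_class": classes})


def simulate_lipidome(
    n_per_group: dict[str, int],
    n_species: int = 315,
    effect_plan: dict[int, dict[str, float]] | None = None,
    batch_plan: dict[str, float] | None = None,
    snr_range: tuple[float, float] = (5.0, 50.0),
    low_snr_species: int = 0,
    seed: int | np.random.Generator = 0,
):
    """Simulate a species x sample lipid concentration matrix.

    Log-concentrations are Gaussian per species (baseline log-mean
    ``U(ln 0.1, ln 100)``, within-group log-SD ``U(0.2, 0.6)``).
    ``effect_plan`` maps a species index to ``{subgroup: shift}`` where the
    shift is expressed in within-group SD units on the log scale; a species
    may appear at most once.  ``batch_plan`` maps batch labels to additive
    log-scale offsets; samples are assigned to batches round-robin.
    ``low_snr_species`` species are given a signal-to-noise ratio below 3
    so that the SNR filter has something to remove.

    Returns a :class:`diabsub.lipidomics.LipidMatrix`.
    """
    from diabsub.lipidomics import LipidMatrix  # deferred: avoid cycle

    rng = np.random.default_rng(seed)
    effect_plan = effect_plan or {}
    if effect_plan and max(effect_plan) >= n_species:
        raise ValueError("effect_plan indexes a species beyond n_species")
    if len(effect_plan) != len(set(effect_plan)):
        raise ValueError("overlapping effect assignments to one species")

    species = _species_catalogue(n_species)
    groups = list(n_per_group)
    sample_group = np.concatenate([[g] * n_per_group[g] for g in groups])
    n_samples = len(sample_group)

    base_mu = rng.uniform(np.log(0.1), np.log(100.0), size=n_species)
    sd = rng.uniform(0.2, 0.6, size=n_species)

    log_conc = base_mu[:, None] + sd[:, None] * rng.standard_normal(
        (n_species, n_samples)
    )
    for sp_idx, shifts in effect_plan.items():
        for group, shift_sd in shifts.items():
            mask = sample_group == group
            log_conc[sp_idx, mask] += shift_sd * sd[sp_idx]

    batches = ["batch1"] if not batch_plan else list(batch_plan)
    sample_batch = np.array([batches[i % len(batches)] for i in range(n_samples)])
    if batch_plan:
        for b, offset in batch_plan.items():
            log_conc[:, sample_batch == b] += offset

    snr = rng.uniform(*snr_range, size=n_species)
    if low_snr_species:
        low_idx = rng.choice(n_species, size=low_snr_species, replace=False)
        snr[low_idx] = rng.uniform(0.5, 2.9, size=low_snr_species)

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    concentrations = pd.DataFrame(
        np.exp(log_conc), index=species["species_id"], columns=sample_ids
    )
    species_info = species.set_index("species_id")
    species_info["snr"] = snr
    sample_info = pd.DataFrame(
        {"subgroup": sample_group, "batch": sample_batch}, index=sample_ids
    )
    return LipidMatrix(concentrations, species_info, sample_info)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HazardSpec:
    """Constant-baseline-hazard generating spec for one outcome.

    ``baseline_rate`` is in events per person-year for the reference
    subgroup at the covariate reference (age at ``age_center``, female).
    ``subgroup_loghr`` maps non-reference subgroups to planted log hazard
    ratios.  Follow-up is administratively censored at a per-participant
    time drawn ``U(admin_low, admin_high)`` (default centred on a 7.3-year
    median), optionally preceded by random exponential censoring.
    ``weibull_shape`` = 1 gives exponential event times.
    """

    outcome: str
    baseline_rate: float
    subgroup_loghr: dict[str, float] = field(default_factory=dict)
    age_loghr: float = 0.0
    sex_loghr: float = 0.0
    age_center: float = 55.0
    admin_low: float = 6.3
    admin_high: float = 8.3
    random_censor_rate: float = 0.0
    weibull_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be > 0")
        if self.admin_high < 0 or self.admin_low < 0 or self.admin_high < self.admin_low:
            raise ValueError("administrative censoring window invalid")
        if self.weibull_shape <= 0:
            raise ValueError("weibull shape must be > 0")


def table3_hazard_specs() -> dict[str, HazardSpec]:
    """Planted-truth hazard specs for the four cardio-renal outcomes.

    Subgroup log-HRs are the published covariate-adjusted hazard ratios
    versus the MOD subgroup; baseline rates are set so the reference
    subgroup reproduces the published crude incidence scale.  Age and sex
    effects are modest, realistic values (they are adjusted away in the
    Cox fits, so the subgroup HRs remain the recovery targets).
    """
    ln = np.log
    common = dict(age_loghr=0.05, sex_loghr=0.3, age_center=55.0)
    return {
        "progressive_CKD": HazardSpec(
            "progressive_CKD", 0.0068,
            {"SIRD-RII": float(ln(3.67)), "MARD-II": float(ln(2.64))}, **common,
        ),
        "heart_failure": HazardSpec(
            "heart_failure", 0.0064,
            {"SIRD-RII": float(ln(5.23)), "MARD-II": float(ln(0.87))}, **common,
        ),
        "MACE": HazardSpec(
            "MACE", 0.009,
            {"SIRD-RII": float(ln(1.92)), "MARD-II": float(ln(0.61))}, **common,
        ),
        "all_cause_mortality": HazardSpec(
            "all_cause_mortality", 0.010,
            {"SIRD-RII": float(ln(2.99)), "MARD-II": float(ln(0.78))}, **common,
        ),
    }


def simulate_outcomes(
    cohort: pd.DataFrame,
    spec: HazardSpec,
    seed: int | np.random.Generator = 0,
    subgroup_column: str = "subgroup_true",
) -> pd.DataFrame:
    """Draw time-to-event records under a proportional-hazards model.

    The individual hazard is ``baseline_rate * exp(lp)`` with
    ``lp = subgroup log-HR + age_loghr * (index_age - age_center)
    + sex_loghr * [male]``.  Event times are Weibull with the spec's shape
    (exponential by default) and the requested rate scale; observation
    stops at the earlier of random censoring and the administrative
    censoring time.

    Returns an event table with ``participant_id``, ``outcome``,
    ``time_years``, ``event`` and the covariates needed for Cox fits.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    groups = cohort[subgroup_column].to_numpy()
    lp = np.zeros(n)
    for g, loghr in spec.subgroup_loghr.items():
        lp[groups == g] += loghr
    if spec.age_loghr and "index_age" in cohort:
        lp += spec.age_loghr * (cohort["index_age"].to_numpy(float) - spec.age_center)
    if spec.sex_loghr and "sex" in cohort:
        lp += spec.sex_loghr * (cohort["sex"].to_numpy() == "male")

    rate = spec.baseline_rate * np.exp(lp)
    # Weibull with hazard h(t) = rate * shape * t^(shape-1): inverse-CDF draw
    u = rng.random(n)
    t_event = (-np.log(u) / rate) ** (1.0 / spec.weibull_shape)

    admin = rng.uniform(spec.admin_low, spec.admin_high, size=n)
    if spec.random_censor_rate > 0:
        t_cens = np.minimum(admin, rng.exponential(1.0 / spec.random_censor_rate, n))
    else:
        t_cens = admin
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    out = pd.DataFrame(
        {
            "participant_id": cohort["participant_id"].to_numpy(),
            "outcome": spec.outcome,
            "time_years": time,
            "event": event,
            "subgroup": groups,
        }
    )
    for col in ("index_age", "sex", "ethnicity", "egfr"):
        if col in cohort:
            out[col] = cohort[col].to_numpy()
    return out


# ---------------------------------------------------------------------------
# longitudinal eGFR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabSeries:
    """Ordered longitudinal eGFR measurements for one participant."""

    participant_id: str
    times: np.ndarray
    egfr: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        e = np.asarray(self.egfr, float)
        if t.ndim != 1 or t.shape != e.shape:
            raise ValueError("times and egfr must be equal-length 1-D arrays")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        if np.any(e <= 0):
            raise ValueError("eGFR values must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "egfr", e)


@dataclass(frozen=True)
class TrajectoryPlan:
    """eGFR trajectory generator settings.

    Progressors decline geometrically fast enough to cross the 40%
    threshold within follow-up (with a confirming later visit);
    non-progressors drift slowly.  ``noise_sigma`` is multiplicative
    log-normal measurement noise.
    """

    progressor_fraction: float = 0.1
    visit_interval: float = 0.5
    follow_up: float = 7.3
    progressor_decline: tuple[float, float] = (0.11, 0.16)
    background_decline: tuple[float, float] = (0.0, 0.02)
    noise_sigma: float = 0.02
    egfr_floor: float = 5.0

    def __post_init__(self) -> None:
        if self.follow_up < self.visit_interval:
            raise ValueError("visit schedule needs at least 2 times")


def simulate_egfr_series(
    cohort: pd.DataFrame,
    plan: TrajectoryPlan | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[LabSeries], np.ndarray]:
    """Simulate per-participant eGFR trajectories.

    eGFR at visit time ``t`` is ``baseline * (1 - annual_decline)^t``
    times multiplicative noise, floored at a small positive value.
    Returns the series and the boolean planted-progressor flags
    (aligned with the cohort rows).
    """
    plan = plan or TrajectoryPlan()
    rng = np.random.default_rng(seed)
    n = len(cohort)
    baseline = cohort["egfr"].to_numpy(float)
    progressor = rng.random(n) < plan.progressor_fraction
    decline = np.where(
        progressor,
        rng.uniform(*plan.progressor_decline, size=n),
        rng.uniform(*plan.background_decline, size=n),
    )
    times = np.arange(plan.visit_interval, plan.follow_up + 1e-9, plan.visit_interval)
    series: list[LabSeries] = []
    for i, pid in enumerate(cohort["participant_id"]):
        noise = np.exp(plan.noise_sigma * rng.standard_normal(len(times)))
        values = baseline[i] * (1.0 - decline[i]) ** times * noise
        values = np.maximum(values, plan.egfr_floor)
        series.append(LabSeries(pid, times.copy(), values))
    return series, progressor
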