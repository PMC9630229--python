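"""End-to-end orchestration: simulate -> cluster -> PRS -> lipids -> outcomes.

A single :class:`RunConfig` (optionally read from YAML) drives the whole
pipeline on a synthetic scenario.  One master seed fans out to per-stage
seeds through a documented splitting rule (`SeedSequence` keyed on the
master seed and a stage-name hash), so any stage can be re-run in
isolation and reproduce its part of the report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from diabsub import cluster as cl
from diabsub import lipidomics as lip
from diabsub import outcomes as oc
from diabsub import prs as prsmod
from diabsub import synth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "stage_seed", "run_pipeline", "make_table1"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the master seed.

    Rule: ``SeedSequence([master_seed, crc32(stage)])`` -> first state
    word, masked to 31 bits.  Deterministic and stage-order independent.
    """
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class RunConfig:
    """Configuration for a full synthetic pipeline run."""

    seed: int = 17
    out_dir: str | None = None
    # stage toggles
    run_cluster: bool = True
    run_prs: bool = True
    run_lipids: bool = True
    run_outcomes: bool = True
    # cluster stage
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 8)
    restarts: int = 25
    bootstrap: int = 500
    # cohort / lipid scenario
    fixed_counts: bool = True
    validation_n: int = 226
    n_lipid_species: int = 315
    n_effect_species: int = 75
    n_validation_effect_species: int = 45
    lipid_effect_sd: float = 1.5
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.family_alpha < 1:
            raise ValueError("family_alpha must be in (0, 1)")
        if self.k != "auto" and int(self.k) < 1:
            raise ValueError("k must be 'auto' or a positive count")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Consolidated per-stage summaries of one pipeline run."""

    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(
            {"config_hash": self.config_hash, "version": self.version,
             "stages": self.stages},
            indent=2, sort_keys=True, default=default,
        )

    def to_markdown(self) -> str:
        lines = [f"# Pipeline report (config {self.config_hash})", ""]
        for name, summary in self.stages.items():
            lines.append(f"## {name}")
            lines.append("```")
            lines.append(json.dumps(summary, indent=2, sort_keys=True, default=str))
            lines.append("```")
            lines.append("")
        return "\n".join(lines)


def _default_effect_plan(n_species: int, n_effect: int, effect_sd: float,
                         species_info: pd.DataFrame) -> dict[int, dict[str, float]]:
    """Plant subgroup shifts mirroring the observed class directions.

    Glycerophospholipid and sphingolipid species rise in SIRD-RII and fall
    in MARD-II; LPC species show the opposite pattern.
    """
    classes = species_info["lipid_class"].to_numpy()
    plan: dict[int, dict[str, float]] = {}
    for idx in range(min(n_effect, n_species)):
        if classes[idx].startswith("LP"):
            plan[idx] = {"MARD-II": effect_sd, "SIRD-RII": -0.5 * effect_sd}
        else:
            plan[idx] = {"SIRD-RII": effect_sd, "MARD-II": -0.5 * effect_sd}
    return plan


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every enabled stage on the calibrated synthetic scenario."""
    report = RunReport(config_hash=config.config_hash(), version=_version())
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    cohort = synth.simulate_table1_cohort(
        seed=stage_seed(config.seed, "cohort"), fixed_counts=config.fixed_counts
    )
    report.stages["simulate"] = {
        "n": len(cohort),
        "subgroup_true_counts": cohort["subgroup_true"].value_counts().to_dict(),
    }
    if out_dir:
        cohort.to_csv(out_dir / "cohort.csv", index=False)
    logger.info("simulate stage done in %.1fs", time.time() - t0)

    labels = cohort["subgroup_true"]
    results = None
    if config.run_cluster:
        t0 = time.time()
        model = cl.SubtypeModel(cohort)
        results = model.fit(
            k=config.k, k_range=range(config.k_range[0], config.k_range[1] + 1),
            restarts=config.restarts, stability_bootstraps=config.bootstrap,
            seed=stage_seed(config.seed, "cluster"),
        )
        labels = results.labels
        sizes = results.model.cluster_sizes()
        report.stages["cluster"] = {
            "k": results.model.k,
            "votes": results.votes.votes if results.votes else None,
            "subgroup_sizes": {
                results.subgroup_names[c]: int(sizes[c]) for c in range(results.model.k)
            },
            "jaccard_means": (
                results.stability.per_cluster_mean.round(4).tolist()
                if results.stability else None
            ),
            "wss": round(results.model.wss, 3),
        }
        if out_dir:
            results.assigned_cohort().to_csv(out_dir / "cohort_assigned.csv", index=False)
            (out_dir / "cluster_summary.txt").write_text(results.summary())
        logger.info("cluster stage done in %.1fs", time.time() - t0)

    if config.run_prs:
        t0 = time.time()
        panel = prsmod.packaged_panel("beta_cell")
        geno = synth.simulate_genotypes(
            panel, labels, prs_shifts={"MARD-II": 1.39},
            seed=stage_seed(config.seed, "genotypes"),
        )
        scores = prsmod.compute_prs(geno, panel)
        rng = np.random.default_rng(stage_seed(config.seed, "pcs"))
        covs = pd.DataFrame(
            {"sex": cohort["sex"],
             "PC1": rng.standard_normal(len(cohort)),
             "PC2": rng.standard_normal(len(cohort)),
             "PC3": rng.standard_normal(len(cohort))}
        )
        assoc = prsmod.associate_prs(scores, labels, covs, reference="MOD",
                                     panel_label="beta_cell")
        report.stages["prs"] = {
            "panel": "beta_cell",
            "coefficients": assoc.table["coef"].round(4).to_dict(),
            "p_values": assoc.table["p"].round(4).to_dict(),
        }
        if out_dir:
            (out_dir / "prs_association.txt").write_text(assoc.summary())
        logger.info("prs stage done in %.1fs", time.time() - t0)

    if config.run_lipids:
        t0 = time.time()
        groups = ["MOD", "SIRD-RII", "MARD-II"]
        disc_sizes = dict(zip(groups, synth.table1_counts))
        catalogue = synth._species_catalogue(config.n_lipid_species)
        plan = _default_effect_plan(config.n_lipid_species, config.n_effect_species,
                                    config.lipid_effect_sd, catalogue)
        discovery = synth.simulate_lipidome(
            disc_sizes, config.n_lipid_species, effect_plan=plan,
            seed=stage_seed(config.seed, "lipid_discovery"),
        )
        discovery = lip.batch_correct(lip.filter_snr(discovery))
        screen = lip.kw_screen(discovery, groups, config.family_alpha)
        val_sizes = _split_counts(config.validation_n, synth.table1_counts)
        val_plan = {i: plan[i] for i in sorted(plan)[: config.n_validation_effect_species]}
        validation = synth.simulate_lipidome(
            dict(zip(groups, val_sizes)), config.n_lipid_species, effect_plan=val_plan,
            seed=stage_seed(config.seed, "lipid_validation"),
        )
        validation = lip.batch_correct(lip.filter_snr(validation))
        screen = lip.replicate(screen, validation, groups)
        report.stages["lipidomics"] = {
            "m": screen.m,
            "bonferroni_threshold": screen.bonferroni_threshold,
            "discovery_hits": int(len(screen.discovery_hits)),
            "replicated": int(len(screen.replicated)),
        }
        if out_dir:
            screen.table.to_csv(out_dir / "lipid_screen.csv")
            lip.heatmap_matrix(screen, validation, groups).to_csv(
                out_dir / "lipid_heatmap.csv")
        logger.info("lipidomics stage done in %.1fs", time.time() - t0)

    if config.run_outcomes:
        t0 = time.time()
        work = cohort.copy()
        work["subgroup"] = np.asarray(labels)
        outcome_rows = {}
        for name, spec in synth.table3_hazard_specs().items():
            events = synth.simulate_outcomes(
                work, spec, seed=stage_seed(config.seed, f"outcome_{name}"),
                subgroup_column="subgroup",
            )
            covs = ["subgroup", "index_age", "sex", "ethnicity"]
            if name == "progressive_CKD":
                covs.append("egfr")
            fit = oc.cox_fit(events, covariates=covs,
                             categorical_reference={"subgroup": "MOD"})
            inc = {}
            for g in events["subgroup"].unique():
                sub = events[events["subgroup"] == g]
                est = oc.incidence_rate(int(sub["event"].sum()),
                                        float(sub["time_years"].sum()))
                inc[str(g)] = {"rate": round(est.rate, 2),
                               "ci": [round(est.ci_low, 2), round(est.ci_high, 2)]}
            hr_rows = {
                idx: {"hr": round(row["hr"], 3),
                      "ci": [round(row["ci_low"], 3), round(row["ci_high"], 3)],
                      "p": round(row["p"], 4)}
                for idx, row in fit.table.iterrows() if idx.startswith("subgroup_")
            }
            outcome_rows[name] = {"incidence": inc, "cox": hr_rows}
            if out_dir:
                events.to_csv(out_dir / f"events_{name}.csv", index=False)
        report.stages["outcomes"] = outcome_rows
        logger.info("outcomes stage done in %.1fs", time.time() - t0)

    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.md").write_text(report.to_markdown())
    return report


def _split_counts(total: int, reference_counts: tuple[int, ...]) -> list[int]:
    """Allocate a total across groups proportional to reference counts."""
    ref = np.asarray(reference_counts, float)
    raw = total * ref / ref.sum()
    counts = np.floor(raw).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _version() -> str:
    from diabsub import __version__

    return __version__


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------

#: default reporting family per cohort variable
TABLE1_FAMILIES: dict[str, str] = {
    "onset_age": "gaussian",
    "index_age": "gaussian",
    "bmi": "gaussian",
    "hba1c": "gaussian",
    "egfr": "gaussian",
    "hdl_cholesterol": "gaussian",
    "homa2b": "lognormal",
    "homa2ir": "lognormal",
    "tg_hdl_ratio": "lognormal",
    "triacylglycerol": "lognormal",
    "sex": "categorical",
    "ethnicity": "categorical",
}


def make_table1(
    cohort: pd.DataFrame,
    labels,
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subgroup descriptive table with per-row significance tests.

    Gaussian variables are reported mean +- SD with a one-way ANOVA p;
    log-normal variables median (IQR) with a Kruskal-Wallis p; categorical
    variables n (%) with a chi-square p.  Unknown variables default to
    median (IQR) with a warning.
    """
    variables = variables or {
        v: f for v, f in TABLE1_FAMILIES.items() if v in cohort.columns
    }
    groups = pd.Series(labels).reset_index(drop=True)
    names = sorted(groups.unique())
    data = cohort.reset_index(drop=True)
    rows = []
    counts = groups.value_counts()
    rows.append(
        {"variable": "n", **{g: str(int(counts.get(g, 0))) for g in names}, "p": ""}
    )
    for var, family in variables.items():
        if family not in ("gaussian", "lognormal", "categorical"):
            logger.warning("unknown family %r for %s; using median (IQR)", family, var)
            family = "lognormal"
        row = {"variable": var}
        if family == "categorical":
            tab = pd.crosstab(data[var], groups)
            chi2, p = stats.chi2_contingency(tab.to_numpy())[:2]
            for g in names:
                top = tab[g].idxmax()
                row[g] = f"{tab[g].sum()} ({top})"
            row["p"] = _fmt_p(p)
        else:
            samples = [data.loc[groups == g, var].to_numpy(float) for g in names]
            if family == "gaussian":
                for g, s in zip(names, samples):
                    row[g] = f"{s.mean():.1f} ± {s.std(ddof=1):.1f}"
                p = _safe_p(stats.f_oneway, samples)
            else:
                for g, s in zip(names, samples):
                    q1, med, q3 = np.percentile(s, [25, 50, 75])
                    row[g] = f"{med:.1f} ({q1:.1f}–{q3:.1f})"
                p = _safe_p(stats.kruskal, samples)
            row["p"] = _fmt_p(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def _safe_p(test, samples) -> float:
    flat = np.concatenate(samples)
    if np.ptp(flat) == 0:
        return 1.0
    return float(test(*samples)[1])


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.2f}"
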