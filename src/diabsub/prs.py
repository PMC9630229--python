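"""Weighted polygenic risk scores and subgroup association.

A polygenic risk score (PRS) is the weighted sum of risk-allele dosages,
``score_i = sum_v w_v * d_iv`` with dosages in [0, 2] oriented to the risk
allele.  Three panels ship with the package (beta-cell dysfunction, 35
SNPs; insulin resistance, 20 SNPs; type 1 diabetes, 9 SNPs) as synthetic
stand-ins for unavailable published SNP tables — the pipeline treats a
panel purely as data, so any TSV with the same columns can be swapped in.

Association with subgroup membership is tested by ordinary least squares
with the score as the dependent variable and subgroup indicators (MOD as
reference), sex and the top genotype principal components as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "load_panel",
    "packaged_panel",
    "PACKAGED_PANELS",
    "compute_prs",
    "associate_prs",
    "top_percentile_flag",
    "vcf_to_dosages",
    "PRSResult",
]

PANEL_COLUMNS = ("variant_id", "risk_allele", "other_allele", "weight", "freq")

#: packaged synthetic panels: label -> resource filename
PACKAGED_PANELS = {
    "beta_cell": "panel_beta_cell_synthetic.tsv",
    "insulin_resistance": "panel_insulin_resistance_synthetic.tsv",
    "t1d": "panel_t1d_synthetic.tsv",
}


def load_panel(path) -> pd.DataFrame:
    """Read and validate a PRS weight panel TSV."""
    panel = pd.read_csv(path, sep="\t")
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns: {missing}")
    if panel["variant_id"].duplicated().any():
        dups = panel.loc[panel["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in panel: {dups}")
    if not np.all(np.isfinite(panel["weight"])):
        raise ValueError("panel weights must be finite")
    return panel


def packaged_panel(label: str) -> pd.DataFrame:
    """Load one of the packaged synthetic panels by label."""
    if label not in PACKAGED_PANELS:
        raise KeyError(f"unknown panel {label!r}; choose from {sorted(PACKAGED_PANELS)}")
    ref = resources.files("diabsub") / "data" / PACKAGED_PANELS[label]
    with resources.as_file(ref) as path:
        return load_panel(path)


def compute_prs(
    dosages: pd.DataFrame,
    panel: pd.DataFrame,
    counted_alleles: dict[str, str] | None = None,
    missing: str = "mean",
) -> np.ndarray:
    """Weighted risk-allele dosage sum per participant.

    ``counted_alleles`` gives, per variant, the allele the dosage file
    counted; when it equals the panel's other allele the dosage is flipped
    to ``2 - d`` before weighting.  Missing dosages are mean-imputed per
    variant by default (``missing='strict'`` raises instead); a panel
    variant absent from the matrix is an error under strict policy and is
    skipped (logged via the returned score being weight-free) otherwise.
    """
    if missing not in ("mean", "strict"):
        raise ValueError("missing policy must be 'mean' or 'strict'")
    scores = np.zeros(len(dosages))
    for _, row in panel.iterrows():
        vid = row["variant_id"]
        if vid not in dosages.columns:
            if missing == "strict":
                raise ValueError(f"panel variant {vid!r} absent from dosage matrix")
            continue
        d = dosages[vid].to_numpy(float)
        if counted_alleles and vid in counted_alleles:
            counted = counted_alleles[vid]
            if counted == row["other_allele"]:
                d = 2.0 - d
            elif counted != row["risk_allele"]:
                raise ValueError(
                    f"counted allele {counted!r} for {vid!r} matches neither panel allele"
                )
        nan = np.isnan(d)
        if nan.any():
            if missing == "strict":
                raise ValueError(f"missing dosages for {vid!r} under strict policy")
            fill = np.nanmean(d) if (~nan).any() else 2 * row["freq"]
            d = np.where(nan, fill, d)
        if np.any((d < 0) | (d > 2)):
            raise ValueError(f"dosages for {vid!r} outside [0, 2]")
        scores += row["weight"] * d
    return scores


@dataclass
class PRSResult:
    """Scores plus the OLS association with subgroup membership."""

    panel_label: str
    scores: np.ndarray
    table: pd.DataFrame          # coef, ci_low, ci_high, p per term
    ols_results: object          # statsmodels RegressionResults

    def summary(self) -> str:
        head = f"PRS association ({self.panel_label}); reference subgroup in intercept"
        return head + "\n" + self.table.round(4).to_string()


def associate_prs(
    scores,
    membership,
    covariates: pd.DataFrame | None = None,
    reference: str = "MOD",
    panel_label: str = "PRS",
) -> PRSResult:
    """OLS of the score on subgroup indicators plus covariates.

    The reference subgroup (default MOD, the largest) is absorbed in the
    intercept; Wald 95% CIs and two-sided p-values are reported per term.
    Categorical covariate columns (e.g. sex) are indicator-coded against
    their first level.
    """
    y = np.asarray(scores, float)
    groups = pd.Series(membership).reset_index(drop=True)
    if reference not in set(groups):
        raise ValueError(f"reference subgroup {reference!r} absent from membership")
    parts = [pd.get_dummies(groups, prefix="subgroup", dtype=float).drop(
        columns=f"subgroup_{reference}")]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        num = cov.select_dtypes(include=[np.number])
        cat = cov.select_dtypes(exclude=[np.number])
        parts.append(num.astype(float))
        if not cat.empty:
            parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1)
    X.insert(0, "intercept", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for col in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                collinear.append(col)
        raise ValueError(f"design is rank deficient; collinear columns: {collinear}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {"coef": fit.params, "ci_low": ci[0], "ci_high": ci[1], "p": fit.pvalues}
    )
    return PRSResult(panel_label=panel_label, scores=y, table=table, ols_results=fit)


def top_percentile_flag(scores, top_fraction: float = 0.05) -> np.ndarray:
    """Flag scores at or above the empirical (1 - top_fraction) quantile.

    The threshold uses the nearest-rank-above convention, so with n
    distinct scores exactly ``floor(top_fraction * n)`` are flagged; ties
    at the threshold are all kept (a fully tied vector flags everyone,
    with a warning).
    """
    s = np.asarray(scores, float)
    if s.size == 0:
        raise ValueError("scores must be non-empty")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    threshold = np.quantile(s, 1.0 - top_fraction, method="higher")
    flags = s >= threshold
    if flags.all():
        import warnings

        warnings.warn("all scores tie at the top-percentile threshold; all flagged")
    return flags


def vcf_to_dosages(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Convert diploid GT fields of a VCF to ALT-allele dosages.

    Returns a samples x variants dosage DataFrame plus the counted-allele
    map (the ALT allele per variant) for orientation in
    :func:`compute_prs`.  Unphased and phased genotypes are accepted;
    missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    counted: dict[str, str] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        gt = np.asarray(variant.gt_types, float)  # 0,1,2 = ALT count; 3 = missing
        gt[gt == 3] = np.nan
        cols[vid] = gt
        counted[vid] = variant.ALT[0] if variant.ALT else variant.REF
    return pd.DataFrame(cols, index=samples), counted
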