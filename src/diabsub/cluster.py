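"""De novo k-means subtyping of recent-onset type 2 diabetes.

The subtyping procedure standardises five clinical classifiers (age at
diabetes onset, BMI, HbA1c, log HOMA2-B, log HOMA2-IR) to zero mean and
unit SD, partitions participants by k-means (Lloyd iterations, k-means++
seeding, best of many restarts), chooses the number of clusters by
majority voting over twelve internal validity indices, and assesses
cluster stability by a nonparametric bootstrap Jaccard index.  Clusters
are mapped to the three phenotype labels MOD (mild obesity-related),
SIRD-RII (severe insulin-resistant with relative insulin insufficiency)
and MARD-II (mild age-related with insulin insufficiency) from their
centroid profile.

``SubtypeModel`` / ``SubtypeResults`` is the high-level fitting API; the
individual steps are exposed as functions for composition and testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from diabsub._indices import DEFAULT_INDEX_SET, compute_index_scores, preferred_k

logger = logging.getLogger(__name__)

DEFAULT_CLASSIFIERS: tuple[str, ...] = ("onset_age", "bmi", "hba1c", "homa2b", "homa2ir")
DEFAULT_LOG_COLUMNS: tuple[str, ...] = ("homa2b", "homa2ir")
PHENOTYPE_NAMES: tuple[str, ...] = ("MOD", "SIRD-RII", "MARD-II")


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScalingParams:
    """Per-classifier location/scale on the analysis scale.

    The analysis scale applies the natural log to the columns in
    ``log_columns`` first; ``ddof=1`` gives the sample-SD convention
    (``ddof=0`` the population-SD alternative).
    """

    columns: tuple[str, ...]
    log_columns: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    ddof: int = 1

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("all scales must be > 0")

    def _to_analysis_scale(self, data: pd.DataFrame) -> np.ndarray:
        X = data.loc[:, list(self.columns)].to_numpy(float).copy()
        for j, col in enumerate(self.columns):
            if col in self.log_columns:
                if np.any(X[:, j] <= 0):
                    raise ValueError(f"non-positive value in log-transformed column {col!r}")
                X[:, j] = np.log(X[:, j])
        return X

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        return (self._to_analysis_scale(data) - self.means) / self.sds

    def inverse_transform(self, Z: np.ndarray) -> pd.DataFrame:
        X = np.asarray(Z, float) * self.sds + self.means
        out = pd.DataFrame(X, columns=list(self.columns))
        for col in self.log_columns:
            out[col] = np.exp(out[col])
        return out


def _as_frame(matrix, columns=None) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix if columns is None else matrix.loc[:, list(columns)]
    X = np.asarray(matrix, float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    names = columns or [f"x{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def standardize(
    matrix,
    columns: tuple[str, ...] | None = None,
    log_columns: tuple[str, ...] = (),
    params: ScalingParams | None = None,
    ddof: int = 1,
) -> tuple[np.ndarray, ScalingParams]:
    """Standardise classifier columns to mean 0 and SD 1.

    When ``params`` is given it is applied unchanged (reference-cohort
    scaling); otherwise location and scale are fitted from the data after
    log-transforming the ``log_columns``.

    Raises
    ------
    ValueError
        For a zero-variance column (named in the message), a non-positive
        value under a log flag, or n < 2 when fitting.
    """
    data = _as_frame(matrix, columns)
    if params is not None:
        return params.transform(data), params
    if len(data) < 2:
        raise ValueError("need at least 2 rows to fit scaling parameters")
    log_cols = tuple(c for c in log_columns if c in data.columns)
    probe = ScalingParams(
        tuple(data.columns), log_cols,
        means=np.zeros(data.shape[1]), sds=np.ones(data.shape[1]), ddof=ddof,
    )
    X = probe._to_analysis_scale(data)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    for j, col in enumerate(data.columns):
        if sds[j] <= 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardise")
    fitted = ScalingParams(tuple(data.columns), log_cols, means, sds, ddof)
    return (X - means) / sds, fitted


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    """A fitted k-means partition on the standardised scale.

    ``labels`` are canonically renumbered 0..k-1 by descending cluster
    size (ties by first occurrence in row order) so outputs are
    deterministic across label permutations.
    """

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    wss: float
    scaling: ScalingParams | None = None
    classifier_names: tuple[str, ...] = ()

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """Nearest-centroid (Euclidean) assignment; ties to lowest index."""
        return np.argmin(cdist(np.asarray(Z, float), self.centroids), axis=1)

    def centroids_raw(self) -> pd.DataFrame:
        """Centroids back-transformed to the original measurement scale."""
        if self.scaling is None:
            raise ValueError("model has no scaling parameters")
        return self.scaling.inverse_transform(self.centroids)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _canonicalize(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = len(centroids)
    sizes = np.bincount(labels, minlength=k)
    first_seen = np.full(k, np.iinfo(np.int64).max)
    for pos, lab in enumerate(labels):
        if first_seen[lab] > pos:
            first_seen[lab] = pos
    order = sorted(range(k), key=lambda c: (-sizes[c], first_seen[c]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels], centroids[order]


def kmeans_fit(
    Z,
    k: int,
    restarts: int = 25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    scaling: ScalingParams | None = None,
    classifier_names: tuple[str, ...] = (),
) -> ClusterModel:
    """Fit k-means (Lloyd, k-means++ init, best of ``restarts`` by WSS)."""
    Z = np.asarray(Z, float)
    n = len(Z)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n={n}], got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=restarts, max_iter=max_iter,
        tol=tol, algorithm="lloyd", random_state=seed,
    ).fit(Z)
    labels, centroids = _canonicalize(km.labels_.astype(int), km.cluster_centers_)
    return ClusterModel(
        k=k, centroids=centroids, labels=labels, wss=float(km.inertia_),
        scaling=scaling, classifier_names=tuple(classifier_names),
    )


# ---------------------------------------------------------------------------
# optimal k by majority voting
# ---------------------------------------------------------------------------


@dataclass
class VoteTable:
    """Per-index scores, preferences and the modal winning k."""

    scores: pd.DataFrame          # index name x k
    preferred: dict[str, int | None]
    votes: dict[int, int]
    winner: int

    def __str__(self) -> str:
        lines = ["index preferences:"]
        for name, k in self.preferred.items():
            lines.append(f"  {name:>18}: {'abstain' if k is None else k}")
        lines.append(f"votes: {self.votes} -> k = {self.winner}")
        return "\n".join(lines)


def select_k_majority_vote(
    Z,
    k_range=range(2, 9),
    index_set: dict[str, str] | None = None,
    restarts: int = 25,
    seed: int | None = None,
) -> VoteTable:
    """Choose k by majority voting over internal validity indices.

    k-means is fitted for every k in the candidate range (plus the k-1 /
    k+1 neighbours needed by the difference-based indices); each index
    votes for the k its own criterion prefers; the winner is the modal k,
    ties broken to the smallest.  An index undefined over the whole range
    abstains (logged).
    """
    Z = np.asarray(Z, float)
    ks = sorted(k_range)
    if ks[0] < 2 or ks[-1] > len(Z) - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    index_set = index_set or DEFAULT_INDEX_SET
    fit_ks = sorted(set(ks) | {ks[0] - 1, ks[-1] + 1})
    fits = {
        k: kmeans_fit(Z, k, restarts=restarts, seed=None if seed is None else seed + k)
        for k in fit_ks
        if 1 <= k <= len(Z)
    }
    scores = compute_index_scores(Z, fits, ks, index_set)
    preferred: dict[str, int | None] = {}
    for name, direction in index_set.items():
        pick = preferred_k(scores[name], direction, ks)
        preferred[name] = pick
        if pick is None:
            logger.info("index %s abstained over k range %s", name, ks)
    votes: dict[int, int] = {k: 0 for k in ks}
    for pick in preferred.values():
        if pick is not None:
            votes[pick] += 1
    winner = min(k for k in ks if votes[k] == max(votes.values()))
    table = pd.DataFrame(scores).T.reindex(columns=ks)
    return VoteTable(scores=table, preferred=preferred, votes=votes, winner=winner)


# ---------------------------------------------------------------------------
# bootstrap Jaccard stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Bootstrap cluster-stability summary (mean Jaccard per cluster)."""

    per_cluster_mean: np.ndarray
    B: int
    per_bootstrap: np.ndarray     # B x k

    def min_mean(self) -> float:
        return float(self.per_cluster_mean.min())


def jaccard_stability(
    Z,
    model: ClusterModel,
    B: int = 500,
    seed: int | None = None,
    restarts: int = 10,
) -> StabilityReport:
    """Bootstrap Jaccard stability of a fitted partition.

    For each of ``B`` nonparametric bootstraps the rows are resampled with
    replacement and k-means refitted with the same k; every original
    cluster (restricted to the resampled rows, membership counted over
    distinct original rows) is matched greedily to the bootstrap cluster
    maximising the Jaccard index |A∩C|/|A∪C|.  Reported per-cluster means
    equal the mean of the per-bootstrap values exactly.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    Z = np.asarray(Z, float)
    rng = np.random.default_rng(seed)
    n, k = len(Z), model.k
    per_boot = np.zeros((B, k))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sampled = np.unique(idx)
        refit = kmeans_fit(Z[idx], k, restarts=restarts,
                           seed=int(rng.integers(0, 2**31 - 1)))
        # membership of each bootstrap cluster as distinct original rows
        boot_members = []
        for c in range(k):
            rows = np.unique(idx[refit.labels == c])
            mask = np.zeros(n, dtype=bool)
            mask[rows] = True
            boot_members.append(mask)
        in_sample = np.zeros(n, dtype=bool)
        in_sample[sampled] = True
        for c in range(k):
            orig = (model.labels == c) & in_sample
            if not orig.any():
                per_boot[b, c] = 0.0
                continue
            best = 0.0
            for mask in boot_members:
                inter = np.count_nonzero(orig & mask)
                union = np.count_nonzero(orig | mask)
                if union and inter / union > best:
                    best = inter / union
            per_boot[b, c] = best
    return StabilityReport(per_cluster_mean=per_boot.mean(axis=0), B=B, per_bootstrap=per_boot)


# ---------------------------------------------------------------------------
# reference ('centroid-coordinate') assignment
# ---------------------------------------------------------------------------


def reference_centroids(
    data: pd.DataFrame, labels: np.ndarray, variables: tuple[str, ...]
) -> pd.DataFrame:
    """Per-cluster raw-scale means of the chosen variables."""
    frame = data.loc[:, list(variables)].copy()
    frame["_label"] = np.asarray(labels)
    return frame.groupby("_label").mean().sort_index()


def assign_by_reference(
    centroids_raw: pd.DataFrame,
    new_data: pd.DataFrame,
    scaling: ScalingParams | None = None,
) -> np.ndarray:
    """Assign rows to published/raw cluster centroids by Euclidean distance.

    With ``scaling`` (the reference cohort's parameters over the centroid
    variables) both centroids and rows are standardised before measuring
    distance — otherwise variables with large units dominate.  Ties go to
    the lowest cluster index.
    """
    variables = list(centroids_raw.columns)
    missing = [v for v in variables if v not in new_data.columns]
    if missing:
        raise ValueError(f"new data is missing centroid variables: {missing}")
    if scaling is not None:
        C = scaling.transform(centroids_raw)
        X = scaling.transform(new_data)
    else:
        C = centroids_raw.to_numpy(float)
        X = new_data.loc[:, variables].to_numpy(float)
    return np.argmin(cdist(X, C), axis=1)


# ---------------------------------------------------------------------------
# covariate residualisation and concordance
# ---------------------------------------------------------------------------


def residualize_on_covariate(matrix, covariate) -> pd.DataFrame:
    """Replace each column by its OLS residual on intercept + covariate.

    Used to check that the subtyping is not driven by sex: clustering the
    residualised classifiers should reproduce the primary partition.
    """
    data = _as_frame(matrix)
    z = np.asarray(covariate, float)
    if np.ptp(z) == 0:
        raise ValueError("covariate is constant; residualisation undefined")
    design = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(design, data.to_numpy(float), rcond=None)
    resid = data.to_numpy(float) - design @ coef
    return pd.DataFrame(resid, columns=data.columns, index=data.index)


def concordance(labels_a, labels_b) -> tuple[float, float]:
    """Agreement fraction and Cohen's kappa after optimal label alignment.

    Labelings are aligned by Hungarian matching on the confusion matrix
    (maximising agreement), so the measure is invariant to label
    permutations.
    """
    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    conf = pd.crosstab(a, b)
    square = conf.reindex(
        index=conf.index.union(conf.columns), columns=conf.index.union(conf.columns),
        fill_value=0,
    )
    M = square.to_numpy(float)
    rows, cols = linear_sum_assignment(-M)
    aligned = M[np.ix_(rows, cols)]
    n = M.sum()
    po = np.trace(aligned) / n
    pe = float((aligned.sum(axis=1) * aligned.sum(axis=0)).sum()) / n**2
    kappa = 1.0 if pe == 1.0 else (po - pe) / (1.0 - pe)
    return float(po), float(kappa)


# ---------------------------------------------------------------------------
# phenotype naming
# ---------------------------------------------------------------------------


def name_subgroups(model: ClusterModel) -> list[str]:
    """Map the k=3 clusters to MOD / SIRD-RII / MARD-II phenotype labels.

    Rule (on standardised centroids): SIRD-RII is the cluster with the
    highest HbA1c centroid; of the remaining two, MARD-II has the higher
    onset-age centroid; the last is MOD.  For k != 3, or degenerate
    (indistinguishable) centroids, generic names are returned with a
    warning.
    """
    generic = [f"cluster_{c + 1}" for c in range(model.k)]
    if model.k != 3:
        warnings.warn("phenotype naming requires k=3; using generic cluster names")
        return generic
    names = model.classifier_names or DEFAULT_CLASSIFIERS
    try:
        j_hba1c = names.index("hba1c") if isinstance(names, tuple) else tuple(names).index("hba1c")
        j_onset = tuple(names).index("onset_age")
    except ValueError:
        warnings.warn("classifiers lack hba1c/onset_age; using generic cluster names")
        return generic
    C = model.centroids
    if np.allclose(C.max(axis=0), C.min(axis=0)):
        warnings.warn("centroids are indistinguishable; using generic cluster names")
        return generic
    out = [""] * 3
    sird = int(np.argmax(C[:, j_hba1c]))
    rest = [c for c in range(3) if c != sird]
    mard = rest[0] if C[rest[0], j_onset] >= C[rest[1], j_onset] else rest[1]
    mod = next(c for c in rest if c != mard)
    out[sird], out[mard], out[mod] = "SIRD-RII", "MARD-II", "MOD"
    return out


# ---------------------------------------------------------------------------
# high-level model / results API
# ---------------------------------------------------------------------------


class SubtypeModel:
    """Clinical-variable subtyping model for a cohort table.

    Parameters
    ----------
    data : DataFrame
        Cohort table; rows with a missing classifier are dropped (count
        logged).
    classifiers : tuple of str
        Columns to cluster on (default: the five-classifier set).
    log_columns : tuple of str
        Classifiers log-transformed before standardisation.
    ddof : int
        SD convention for standardisation (1 = sample SD).

    Examples
    --------
    >>> from diabsub.synth import simulate_table1_cohort
    >>> from diabsub import SubtypeModel
    >>> cohort = simulate_table1_cohort(seed=1)
    >>> res = SubtypeModel(cohort).fit(k=3, seed=1)
    >>> sorted(res.fractions)            # doctest: +SKIP
    ['MARD-II', 'MOD', 'SIRD-RII']
    """

    def __init__(
        self,
        data: pd.DataFrame,
        classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS,
        log_columns: tuple[str, ...] = DEFAULT_LOG_COLUMNS,
        ddof: int = 1,
    ):
        missing = [c for c in classifiers if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks classifier columns: {missing}")
        complete = data.dropna(subset=list(classifiers))
        n_dropped = len(data) - len(complete)
        if n_dropped:
            logger.warning("dropped %d rows with missing classifiers", n_dropped)
        self.data = complete.reset_index(drop=True)
        self.classifiers = tuple(classifiers)
        self.log_columns = tuple(log_columns)
        self.ddof = ddof

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "SubtypeModel":
        return cls(data, **kwargs)

    def fit(
        self,
        k: int | str = 3,
        k_range=range(2, 9),
        restarts: int = 25,
        stability_bootstraps: int = 0,
        seed: int | None = None,
    ) -> "SubtypeResults":
        """Standardise, (optionally) vote on k, fit k-means, name clusters.

        ``k='auto'`` selects k by index majority voting over ``k_range``.
        ``stability_bootstraps > 0`` adds a bootstrap Jaccard stability
        report.
        """
        Z, scaling = standardize(
            self.data, columns=self.classifiers, log_columns=self.log_columns,
            ddof=self.ddof,
        )
        votes = None
        if k == "auto":
            votes = select_k_majority_vote(Z, k_range=k_range, seed=seed)
            k = votes.winner
        model = kmeans_fit(
            Z, int(k), restarts=restarts, seed=seed, scaling=scaling,
            classifier_names=self.classifiers,
        )
        stability = None
        if stability_bootstraps:
            stability = jaccard_stability(
                Z, model, B=stability_bootstraps,
                seed=None if seed is None else seed + 1,
            )
        names = name_subgroups(model)
        return SubtypeResults(self, Z, model, names, votes, stability)


@dataclass
class SubtypeResults:
    """Fitted subtyping results: partition, names, votes, stability."""

    spec: SubtypeModel
    Z: np.ndarray
    model: ClusterModel
    subgroup_names: list[str] = field(default_factory=list)
    votes: VoteTable | None = None
    stability: StabilityReport | None = None

    @property
    def labels(self) -> pd.Series:
        """Phenotype label per participant row."""
        return pd.Series(
            [self.subgroup_names[c] for c in self.model.labels], name="subgroup"
        )

    @property
    def fractions(self) -> dict[str, float]:
        """Fraction of participants per named subgroup."""
        sizes = self.model.cluster_sizes()
        n = sizes.sum()
        return {self.subgroup_names[c]: sizes[c] / n for c in range(self.model.k)}

    def assigned_cohort(self) -> pd.DataFrame:
        out = self.spec.data.copy()
        out["subgroup"] = self.labels.to_numpy()
        return out

    def summary(self) -> str:
        """Human-readable fit summary (sizes, centroids, votes, stability)."""
        m = self.model
        lines = [
            "Subtype model fit",
            "=" * 60,
            f"n = {len(m.labels)}, k = {m.k}, classifiers = {list(self.spec.classifiers)}",
            f"total within-cluster SS = {m.wss:.2f}",
            "",
            "cluster sizes:",
        ]
        sizes = m.cluster_sizes()
        for c in range(m.k):
            name = self.subgroup_names[c] if self.subgroup_names else f"cluster_{c+1}"
            lines.append(f"  {name:>10}: {sizes[c]:5d}  ({100*sizes[c]/sizes.sum():.1f}%)")
        if m.scaling is not None:
            lines += ["", "centroids (original scale):"]
            raw = m.centroids_raw().round(2)
            raw.index = [self.subgroup_names[c] if self.subgroup_names else c
                         for c in range(m.k)]
            lines.append(raw.to_string())
        if self.votes is not None:
            lines += ["", str(self.votes)]
        if self.stability is not None:
            vals = ", ".join(f"{v:.3f}" for v in self.stability.per_cluster_mean)
            lines += ["", f"bootstrap Jaccard means (B={self.stability.B}): {vals}"]
        return "\n".join(lines)
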