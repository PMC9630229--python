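"""Internal cluster-validity indices for optimal-k majority voting.

Twelve indices form the default electorate: Calinski-Harabasz, average
silhouette width and Davies-Bouldin (via scikit-learn), plus native
implementations of Dunn, C-index, Ball-Hall (successive-difference rule),
Hartigan, Krzanowski-Lai, McClain-Rao, point-biserial, Ratkowsky-Lance and
Xie-Beni.  Each index exposes its own optimality direction; an index that
is undefined at some k abstains for that k.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist
from sklearn import metrics

__all__ = ["DEFAULT_INDEX_SET", "compute_index_scores", "preferred_k"]


def _pair_masks(labels: np.ndarray) -> np.ndarray:
    """Boolean 'same cluster' indicator over condensed pair order."""
    iu, ju = np.triu_indices(len(labels), k=1)
    return labels[iu] == labels[ju]


def _wgss_per_variable(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-group and total sum of squares per variable."""
    grand = X.mean(axis=0)
    tss = ((X - grand) ** 2).sum(axis=0)
    bgss = np.zeros(X.shape[1])
    for c in np.unique(labels):
        sub = X[labels == c]
        bgss += len(sub) * (sub.mean(axis=0) - grand) ** 2
    return bgss, tss


def _dunn(D: np.ndarray, same: np.ndarray) -> float:
    within = D[same]
    between = D[~same]
    if len(within) == 0 or len(between) == 0:
        return np.nan
    diam = within.max()
    if diam == 0:
        return np.nan
    return float(between.min() / diam)


def _c_index(D: np.ndarray, same: np.ndarray) -> float:
    n_w = int(same.sum())
    if n_w == 0 or n_w == len(D):
        return np.nan
    s_w = D[same].sum()
    part = np.partition(D, [n_w - 1, len(D) - n_w])
    s_min = part[:n_w].sum()
    s_max = np.sort(D)[-n_w:].sum()
    if s_max == s_min:
        return np.nan
    return float((s_w - s_min) / (s_max - s_min))


def _mcclain_rao(D: np.ndarray, same: np.ndarray) -> float:
    n_w = int(same.sum())
    n_b = len(D) - n_w
    if n_w == 0 or n_b == 0:
        return np.nan
    mean_b = D[~same].mean()
    if mean_b == 0:
        return np.nan
    return float(D[same].mean() / mean_b)


def _point_biserial(D: np.ndarray, same: np.ndarray) -> float:
    if same.all() or not same.any() or D.std() == 0:
        return np.nan
    # correlation between pair distance and the 'between clusters' indicator
    return float(np.corrcoef(D, (~same).astype(float))[0, 1])


def _xie_beni(X: np.ndarray, centroids: np.ndarray, wss: float) -> float:
    k = len(centroids)
    if k < 2:
        return np.nan
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    min_sep = d2.min()
    if min_sep == 0 or not np.isfinite(min_sep):
        return np.nan
    return float(wss / (len(X) * min_sep))


def _ratkowsky_lance(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    bgss, tss = _wgss_per_variable(X, labels)
    valid = tss > 0
    if not valid.any():
        return np.nan
    c_bar = np.sqrt(bgss[valid] / tss[valid]).mean()
    return float(c_bar / np.sqrt(k))


# direction: "max" / "min" pick the arg-extremum of the score curve;
# "diff_max" picks the k with the largest drop score(k-1) - score(k);
# "hartigan" picks the smallest k whose statistic falls to <= 10.
DEFAULT_INDEX_SET: dict[str, str] = {
    "calinski_harabasz": "max",
    "silhouette": "max",
    "davies_bouldin": "min",
    "dunn": "max",
    "c_index": "min",
    "mcclain_rao": "min",
    "point_biserial": "max",
    "ratkowsky_lance": "max",
    "xie_beni": "min",
    "ball_hall": "diff_max",
    "hartigan": "hartigan",
    "krzanowski_lai": "max",
}


def compute_index_scores(
    X: np.ndarray,
    fits: dict[int, "object"],
    ks: list[int],
    index_set: dict[str, str] | None = None,
) -> dict[str, dict[int, float]]:
    """Score every configured index at every candidate k.

    ``fits`` maps k to a fitted cluster model (``labels``, ``centroids``,
    ``wss`` attributes) and should also contain k-1 / k+1 neighbours of the
    candidate range where available, for the difference-based indices.
    Undefined scores are NaN (the index abstains there).
    """
    index_set = index_set or DEFAULT_INDEX_SET
    n, p = X.shape
    D = pdist(X)
    wss = {k: fits[k].wss for k in fits}
    same_by_k = {k: _pair_masks(fits[k].labels) for k in ks if k in fits}

    scores: dict[str, dict[int, float]] = {name: {} for name in index_set}
    for k in ks:
        if k not in fits:
            continue
        labels, cents = fits[k].labels, fits[k].centroids
        same = same_by_k[k]
        for name in index_set:
            val = np.nan
            try:
                if name == "calinski_harabasz":
                    val = metrics.calinski_harabasz_score(X, labels)
                elif name == "silhouette":
                    val = metrics.silhouette_score(X, labels)
                elif name == "davies_bouldin":
                    val = metrics.davies_bouldin_score(X, labels)
                elif name == "dunn":
                    val = _dunn(D, same)
                elif name == "c_index":
                    val = _c_index(D, same)
                elif name == "mcclain_rao":
                    val = _mcclain_rao(D, same)
                elif name == "point_biserial":
                    val = _point_biserial(D, same)
                elif name == "ratkowsky_lance":
                    val = _ratkowsky_lance(X, labels, k)
                elif name == "xie_beni":
                    val = _xie_beni(X, cents, wss[k])
                elif name == "ball_hall":
                    val = wss[k] / k
                elif name == "hartigan":
                    if k + 1 in wss and wss[k + 1] > 0:
                        val = (wss[k] / wss[k + 1] - 1.0) * (n - k - 1)
                elif name == "krzanowski_lai":
                    if k - 1 in wss and k + 1 in wss:
                        diff_k = (k - 1) ** (2 / p) * wss[k - 1] - k ** (2 / p) * wss[k]
                        diff_k1 = k ** (2 / p) * wss[k] - (k + 1) ** (2 / p) * wss[k + 1]
                        if diff_k1 != 0:
                            val = abs(diff_k) / abs(diff_k1)
            except ValueError:
                val = np.nan
            scores[name][k] = float(val)
    # ball_hall needs the k-1 value for its successive-difference rule
    if "ball_hall" in scores:
        for k in ks:
            if k - 1 in wss and k - 1 not in scores["ball_hall"]:
                scores["ball_hall"][k - 1] = wss[k - 1] / (k - 1)
    return scores


def preferred_k(
    score_curve: dict[int, float], direction: str, ks: list[int]
) -> int | None:
    """Apply an index's optimality rule to its score curve.

    Returns None (abstention) when the curve is undefined everywhere the
    rule needs it.  Ties break to the smallest k.
    """
    valid = {k: v for k, v in score_curve.items() if k in ks and np.isfinite(v)}
    if direction in ("max", "min"):
        if not valid:
            return None
        sign = 1.0 if direction == "max" else -1.0
        best = max(sorted(valid), key=lambda k: sign * valid[k])
        return best
    if direction == "diff_max":
        # largest improvement over the previous candidate k; both k and k-1
        # must lie inside the candidate range (NbClust convention), so the
        # smallest candidate cannot win by differencing against k-1 outside it
        diffs = {
            k: score_curve[k - 1] - score_curve[k]
            for k in ks
            if k - 1 in ks
            and np.isfinite(score_curve.get(k, np.nan))
            and np.isfinite(score_curve.get(k - 1, np.nan))
        }
        if not diffs:
            return None
        return max(sorted(diffs), key=lambda k: diffs[k])
    if direction == "hartigan":
        if not valid:
            return None
        small = [k for k in sorted(valid) if valid[k] <= 10.0]
        if small:
            return small[0]
        # no k satisfies the rule-of-thumb: take the largest successive drop
        diffs = {
            k: valid[k - 1] - valid[k] for k in sorted(valid) if k - 1 in valid
        }
        if not diffs:
            return None
        return max(sorted(diffs), key=lambda k: diffs[k])
    raise ValueError(f"unknown index direction {direction!r}")
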