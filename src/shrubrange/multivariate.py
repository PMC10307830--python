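"""Ordination and permutation tests on species trait space.

PCA operates on the centred (and, by default, unit-scaled) species x
trait matrix of log-scale summaries; component signs are pinned so the
largest-magnitude loading of each component is positive (loading signs
are otherwise arbitrary).

PERMANOVA computes the pseudo-F

    F = (SS_between / (g - 1)) / (SS_within / (n - g))

from squared Euclidean distances, where SS_total = sum_{i<j} d_ij^2 / n
and SS_within sums the within-group analogues; the null distribution
comes from uniformly permuting group labels.  p-values use the add-one
estimator (1 + #{F_perm >= F_obs}) / (1 + permutations), so they are
never zero.  Dispersion homogeneity follows the distance-to-centroid
construction (betadisper): a one-way ANOVA on each point's Euclidean
distance to its own group centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from statsmodels.stats.multitest import multipletests

from .inference import FitResult, ModelSpec, fit_model


@dataclass
class OrdinationResult:
    scores: pd.DataFrame           # species x component
    loadings: pd.DataFrame         # trait x component
    variance_fraction: np.ndarray  # per component, sums to 1


@dataclass
class PermanovaResult:
    statistic: float
    p_value: float
    permutations: int
    n: int
    n_groups: int


@dataclass
class DispersionResult:
    group_mean_distance: pd.Series
    distances: pd.Series
    statistic: float
    p_value: float


def pca(matrix: pd.DataFrame, centre_scale: bool = True) -> OrdinationResult:
    """Principal components of a complete species x trait matrix."""
    X = matrix.astype(float)
    if X.isna().any().any():
        bad = X.index[X.isna().any(axis=1)].tolist()
        raise ValueError(f"PCA requires a complete matrix; missing cells for: {bad}")
    if len(X) < 3:
        raise ValueError("PCA requires at least 3 species")
    Z = X - X.mean(axis=0)
    if centre_scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = sd.index[sd == 0].tolist()
            raise ValueError(f"constant trait column(s) cannot be scaled: {const}")
        Z = Z / sd
    Zv = Z.to_numpy()
    _, s, vt = np.linalg.svd(Zv, full_matrices=False)
    loadings = vt.T  # trait x component
    # sign convention: largest-magnitude loading per component is positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
    scores = Zv @ loadings
    var = s**2
    comp = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp),
        variance_fraction=var / var.sum(),
    )


def _squared_distances(data, distance: bool) -> np.ndarray:
    if distance:
        d = np.asarray(data, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        return d**2
    return squareform(pdist(np.asarray(data, dtype=float))) ** 2


def permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F from a squared-distance matrix and group labels."""
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    g = groups.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp, ng in zip(groups, counts):
        idx = np.where(labels == grp)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(data, groups, permutations: int = 999, seed: int | None = None,
              distance: bool = False) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances with a permutation null.

    ``data`` is a species x variable matrix, or a square distance matrix
    when ``distance=True``.  Labels are permuted uniformly, without
    strata.
    """
    labels = np.asarray(pd.Series(groups).to_numpy())
    _, counts = np.unique(labels, return_counts=True)
    if counts.size < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    d2 = _squared_distances(data, distance)
    if d2.shape[0] != labels.size:
        raise ValueError("groups length must match the number of rows")
    observed = permanova_f(d2, labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        if permanova_f(d2, rng.permutation(labels)) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + permutations)
    return PermanovaResult(float(observed), float(p), permutations,
                           int(labels.size), int(counts.size))


def dispersion_homogeneity(data, groups, distance: bool = False) -> DispersionResult:
    """Distance-to-centroid dispersion and a one-way ANOVA homogeneity test."""
    labels = pd.Series(groups).reset_index(drop=True)
    uniq = labels.unique()
    if uniq.size < 2 or labels.value_counts().min() < 2:
        raise ValueError("dispersion test requires >= 2 groups of >= 2 members")
    if distance:
        raise NotImplementedError("dispersion_homogeneity requires coordinates")
    X = np.asarray(data, dtype=float)
    dist = np.empty(len(labels))
    for grp in uniq:
        idx = np.where(labels.to_numpy() == grp)[0]
        centroid = X[idx].mean(axis=0)
        dist[idx] = np.linalg.norm(X[idx] - centroid, axis=1)
    samples = [dist[labels.to_numpy() == grp] for grp in uniq]
    if all(np.allclose(s, s[0] if s.size else 0.0) for s in samples) and np.allclose(dist, dist[0]):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*samples)
        # between-group variance can round to a tiny negative number when
        # group dispersions are exactly equal; that is F = 0, p = 1
        if not np.isfinite(f_stat) or f_stat < 0:
            f_stat = 0.0
        if not np.isfinite(p):
            p = 1.0
    means = pd.Series({grp: float(dist[labels.to_numpy() == grp].mean()) for grp in uniq})
    return DispersionResult(means, pd.Series(dist, index=labels.index),
                            float(f_stat), float(p))


def adjust_pvalues(p_values, method: str = "holm") -> np.ndarray:
    """Holm / Bonferroni / no adjustment of a vector of raw p-values."""
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def pairwise_permanova(data, groups, permutations: int = 999,
                       adjust: str = "holm", seed: int | None = None) -> pd.DataFrame:
    """PERMANOVA on every pair of groups, with p-value adjustment."""
    labels = pd.Series(groups).reset_index(drop=True)
    X = np.asarray(data, dtype=float)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("pairwise comparisons require at least 2 groups")
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(uniq, 2):
        mask = labels.isin([a, b]).to_numpy()
        res = permanova(X[mask], labels[mask].to_numpy(), permutations=permutations,
                        seed=int(rng.integers(2**31)))
        rows.append({"group1": a, "group2": b, "statistic": res.statistic,
                     "p_raw": res.p_value})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = adjust_pvalues(out["p_raw"].to_numpy(), adjust)
    out["method"] = adjust
    return out


def scores_models(ordination: OrdinationResult, responses: pd.DataFrame,
                  categories: pd.Series | None = None,
                  weights: pd.Series | None = None, random_state: int = 0):
    """Linear models of each PC score against each response variable.

    Each of the first two component scores is modelled as a response
    against every column of ``responses`` (one model per pairing) and,
    when ``categories`` is given, against the category labels.  Species
    missing from ``responses`` are dropped and reported.  Returns
    ``(fits, skipped_species)``.
    """
    scores = ordination.scores
    common = scores.index.intersection(responses.index)
    skipped = sorted(scores.index.difference(responses.index).tolist())
    data = scores.loc[common].join(responses.loc[common])
    if categories is not None:
        data["category"] = categories.reindex(common)
    if weights is not None:
        data["weight"] = weights.reindex(common)
    w = "weight" if weights is not None else None
    fits: list[FitResult] = []
    for pc in scores.columns[:2]:
        predictor_sets = [[resp] for resp in responses.columns]
        if categories is not None:
            predictor_sets.append(["category"])
        for preds in predictor_sets:
            spec = ModelSpec(label=f"{pc}~{preds[0]}", response=pc,
                             predictors=preds, weights=w)
            try:
                fits.append(fit_model(spec, data, random_state=random_state))
            except Exception:
                continue
    return fits, skipped
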