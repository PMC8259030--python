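"""Beta-diversity trajectory analysis.

The pipeline mirrors a 16S time-series workflow: rarefy the count table
to a fixed depth, convert to pseudocounted relative abundances, compute
the square-root Jensen-Shannon divergence between all sample pairs (a
metric on probability distributions, bounded by sqrt(ln 2)), embed with
classical principal coordinate analysis, smooth the first coordinate per
group with loess, and test group contrasts day by day with Mann-Whitney
plus Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable
from .loess import LoessSmoother

__all__ = [
    "Rarefier", "rarefy", "to_relative", "jsd_distance", "pairwise_jsd",
    "PCoA", "pcoa", "loess_trajectory", "per_day_group_tests",
    "MAX_SQRT_JSD", "DEFAULT_PSEUDOCOUNT", "DEFAULT_DEPTH",
]

logger = logging.getLogger(__name__)

MAX_SQRT_JSD = float(np.sqrt(np.log(2.0)))
DEFAULT_PSEUDOCOUNT = 1e-6
DEFAULT_DEPTH = 4000


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------
class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample every sample to `depth` reads without replacement.

    Samples with fewer than `depth` total reads are dropped (logged).
    Subsampling is multivariate hypergeometric, seeded by `random_state`.
    """

    def __init__(self, depth: int = DEFAULT_DEPTH, random_state: int | None = 0):
        self.depth = depth
        self.random_state = random_state

    def fit(self, X: FeatureTable, y=None):
        if self.depth <= 0:
            raise ValueError("depth must be >= 1")
        return self

    def transform(self, X: FeatureTable) -> FeatureTable:
        self.fit(X)
        rng = np.random.default_rng(self.random_state)
        totals = X.sample_sums()
        keep = totals.index[totals >= self.depth]
        dropped = totals.index.difference(keep)
        if len(dropped):
            logger.info("rarefy: dropping %d samples below depth %d: %s",
                        len(dropped), self.depth, list(dropped)[:10])
        self.dropped_samples_ = list(dropped)
        rows = {}
        for s in keep:
            c = X.counts.loc[s].to_numpy()
            if totals[s] == self.depth:
                rows[s] = c
            else:
                rows[s] = rng.multivariate_hypergeometric(c, self.depth)
        sub = pd.DataFrame.from_dict(rows, orient="index", columns=X.counts.columns)
        return FeatureTable(sub, X.metadata, X.taxonomy)


def rarefy(table: FeatureTable, depth: int = DEFAULT_DEPTH, seed: int = 0) -> FeatureTable:
    return Rarefier(depth=depth, random_state=seed).transform(table)


# ---------------------------------------------------------------------------
# profiles and distance
# ---------------------------------------------------------------------------
def to_relative(table, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Pseudocounted relative-abundance profiles, one row per sample.

    Proportions get `pseudocount` added and are renormalized, so every
    entry is strictly positive and each row sums to one.  Accepts a
    FeatureTable or a counts DataFrame/array.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(counts.index[zero])}")
    p = counts.to_numpy(dtype=float) / totals[:, None] + pseudocount
    p /= p.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, index=counts.index, columns=counts.columns)


def jsd_distance(p, q) -> float:
    """sqrt(JSD(p, q)) with natural-log Kullback-Leibler divergences.

    D = sqrt(KLD(p, m)/2 + KLD(q, m)/2), m = (p + q)/2.  Zero entries
    contribute zero to their own KLD term (x log x -> 0).
    """
    p = np.asarray(p, dtype=float).reshape(-1)
    q = np.asarray(q, dtype=float).reshape(-1)
    if p.shape != q.shape:
        raise ValueError("profiles differ in length")
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.where(p > 0, p * np.log(p / m), 0.0).sum()
        kl_qm = np.where(q > 0, q * np.log(q / m), 0.0).sum()
    jsd = max(0.5 * kl_pm + 0.5 * kl_qm, 0.0)
    return float(np.sqrt(jsd))


def pairwise_jsd(profiles) -> pd.DataFrame:
    """Symmetric matrix of sqrt-JSD distances between sample profiles.

    `profiles` is a samples x features DataFrame (rows sum to 1) or a
    list of profiles.  Vectorized over pairs.
    """
    if isinstance(profiles, pd.DataFrame):
        P = profiles.to_numpy(dtype=float)
        ids = list(profiles.index)
    else:
        P = np.asarray([np.asarray(p, dtype=float).reshape(-1) for p in profiles])
        ids = list(range(len(P)))
    if len(P) < 2:
        raise ValueError("need at least 2 profiles")
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(P), 0.0)
    ent = -(P * logP).sum(axis=1)  # Shannon entropy, natural log
    n = len(P)
    D = np.zeros((n, n))
    for i in range(n):
        M = 0.5 * (P[i][None, :] + P[i + 1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            ent_m = -np.where(M > 0, M * np.log(M), 0.0).sum(axis=1)
        jsd = ent_m - 0.5 * (ent[i] + ent[i + 1:])
        D[i, i + 1:] = D[i + 1:, i] = np.sqrt(np.clip(jsd, 0.0, None))
    return pd.DataFrame(D, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------
class PCoA(BaseEstimator, TransformerMixin):
    """Classical scaling (Torgerson) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by
    sqrt(eigenvalue) for the positive eigenvalues.  Negative eigenvalues
    are reported unaltered in `eigenvalues_`.  Axis signs are fixed
    deterministically: each coordinate column has its largest-magnitude
    entry positive.

    Attributes (after fit)
    ----------------------
    coordinates_ : (n, k) array of sample coordinates.
    eigenvalues_ : all n eigenvalues, sorted descending.
    proportion_explained_ : share of the positive eigenvalue mass per axis.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        D, ids = _as_distance_matrix(X)
        n = len(D)
        k = self.n_components if self.n_components is not None else n - 1
        if not (1 <= k < n):
            raise ValueError("n_components must satisfy 1 <= k < n_samples")
        B = -0.5 * D ** 2
        B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
        evals, evecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        pos = np.clip(evals[:k], 0.0, None)
        coords = evecs[:, :k] * np.sqrt(pos)
        for j in range(coords.shape[1]):
            i = int(np.argmax(np.abs(coords[:, j])))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
        self.trace_B_ = float(np.trace(B))
        self.eigenvalues_ = evals
        pos_total = float(np.sum(np.clip(evals, 0.0, None)))
        self.proportion_explained_ = (
            np.clip(evals[:k], 0.0, None) / pos_total if pos_total > 0
            else np.zeros(k))
        self.coordinates_ = coords
        self.sample_ids_ = ids
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).coordinates_

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates_.shape[1])]
        return pd.DataFrame(self.coordinates_, index=self.sample_ids_, columns=cols)


def _as_distance_matrix(X):
    if isinstance(X, pd.DataFrame):
        D, ids = X.to_numpy(dtype=float), list(X.index)
    else:
        D, ids = np.asarray(X, dtype=float), list(range(len(X)))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("distance matrix must have zero diagonal and no negatives")
    return D, ids


def pcoa(D, k: int | None = None) -> PCoA:
    return PCoA(n_components=k).fit(D)


# ---------------------------------------------------------------------------
# trajectories and tests
# ---------------------------------------------------------------------------
def loess_trajectory(values, day, group, span: float = 0.75,
                     eval_days=None, min_points: int = 5) -> pd.DataFrame:
    """Per-group loess fit of an ordination axis against day.

    Returns a tidy frame (group, day, fit, lo, hi) with 95% pointwise
    bands (fit +/- 1.96 SE).  Groups with fewer than `min_points` samples
    are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    day = np.asarray(day, dtype=float)
    group = np.asarray(group)
    out = []
    for g in pd.unique(group):
        m = group == g
        if m.sum() < min_points:
            warnings.warn(f"group {g!r} has fewer than {min_points} samples; skipped")
            continue
        xs = eval_days if eval_days is not None else np.unique(day[m])
        sm = LoessSmoother(span=span, degree=2).fit(day[m], values[m])
        fit, se = sm.predict(xs, return_se=True)
        out.append(pd.DataFrame({
            "group": g, "day": xs, "fit": fit,
            "lo": fit - 1.96 * se, "hi": fit + 1.96 * se,
        }))
    if not out:
        return pd.DataFrame(columns=["group", "day", "fit", "lo", "hi"])
    return pd.concat(out, ignore_index=True)


def per_day_group_tests(values, metadata: pd.DataFrame, pairs) -> pd.DataFrame:
    """Two-sided Mann-Whitney per (day, group pair) with joint BH correction.

    Exact null when both sides have <= 8 samples and no ties straddle the
    groups; mid-rank normal approximation with tie correction otherwise.
    Cells with fewer than 2 samples on either side are recorded with NaN
    statistics and excluded from the BH family.
    """
    values = np.asarray(values, dtype=float)
    md = metadata.reset_index(drop=True)
    rows = []
    for d in sorted(md["day"].unique()):
        for ga, gb in pairs:
            a = values[(md["day"] == d) & (md["group"] == ga)]
            b = values[(md["day"] == d) & (md["group"] == gb)]
            if len(a) < 2 or len(b) < 2:
                rows.append({"day": d, "group_a": ga, "group_b": gb,
                             "n_a": len(a), "n_b": len(b),
                             "U": np.nan, "p": np.nan})
                continue
            ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
            method = "exact" if (max(len(a), len(b)) <= 8 and not ties) else "asymptotic"
            res = mannwhitneyu(a, b, alternative="two-sided", method=method)
            rows.append({"day": d, "group_a": ga, "group_b": gb,
                         "n_a": len(a), "n_b": len(b),
                         "U": float(res.statistic), "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
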