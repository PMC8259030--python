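"""Condition-specific microbial association networks.

Workflow, mirroring a SPIEC-EASI-style analysis: filter ASVs to >= 20%
prevalence, centered-log-ratio transform the compositions, fit a sparse
inverse covariance (graphical lasso) along a log-spaced penalty path, and
pick the penalty by StARS stability selection (subsample the samples,
refit the path, and keep the densest graph whose edge instability stays
below a threshold).  Condition subsets ("normal condition", "lactose
feeding", "treatment") are defined by (group, day) selectors; node sizes
are per-condition mean relative abundances of the top-k most abundant
ASVs, and per-taxon contrasts use two-sided Mann-Whitney tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .feature_table import FeatureTable
from .glasso import EDGE_EPS, glasso_path, lambda_max
from .ordination import to_relative, DEFAULT_PSEUDOCOUNT

__all__ = [
    "prevalence_filter", "clr_transform", "StarsGraphicalLasso", "stars_select",
    "ConditionSubset", "DEFAULT_SUBSETS", "condition_networks",
    "taxon_abundance_compare", "NetworkModel",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------
def prevalence_filter(table: FeatureTable, min_prevalence: float = 0.2) -> FeatureTable:
    """Keep features present (count > 0) in at least `min_prevalence` of samples.

    The threshold is inclusive: a feature in exactly 20% of samples is kept
    at min_prevalence=0.2.  Feature order is preserved.
    """
    if not (0 < min_prevalence <= 1):
        raise ValueError("min_prevalence must lie in (0, 1]")
    prev = (table.counts > 0).mean(axis=0)
    keep = [f for f in table.feature_ids if prev[f] >= min_prevalence]
    if not keep:
        raise ValueError("prevalence filter removed every feature")
    return table.select_features(keep)


def clr_transform(table, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Centered log-ratio transform of pseudocounted proportions.

    Per sample: log p_i - mean_j log p_j; each row sums to zero.
    """
    p = to_relative(table, pseudocount=pseudocount)
    logp = np.log(p.to_numpy())
    clr = logp - logp.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=p.index, columns=p.columns)


# ---------------------------------------------------------------------------
# StARS selection
# ---------------------------------------------------------------------------
def _stars_subsample_size(n: int) -> int:
    return min(int(np.floor(10 * np.sqrt(n))), int(np.floor(0.8 * n)))


def _correlation(X: np.ndarray, shrink: float = 0.05) -> np.ndarray:
    """Sample correlation; scale-invariant input to the glasso.

    The precision-matrix support is invariant to this diagonal rescaling,
    and the unit diagonal keeps the solver well scaled when n << p.  For
    rank-deficient panels (n <= p) the correlation is shrunk toward the
    identity by `shrink`, bounding the precision at weak penalties.
    """
    S = np.cov(X, rowvar=False)
    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    R = S / np.outer(d, d)
    n, p = X.shape
    if n <= p:
        R = (1.0 - shrink) * R
        np.fill_diagonal(R, 1.0)
    return R


class StarsGraphicalLasso(BaseEstimator):
    """Graphical lasso with StARS penalty selection.

    Fits a log-spaced penalty path from lambda_max (empty graph) down to
    lambda_max * `lambda_min_ratio` on the sample covariance, estimates
    per-edge selection frequencies over `rep_num` subsamples without
    replacement of size min(floor(10 sqrt(n)), floor(0.8 n)), and selects
    the densest penalty whose monotonized mean edge instability
    2 xi (1 - xi) stays at or below `beta`.  The final model is refit on
    the full data at the selected penalty.

    Attributes (after fit)
    ----------------------
    precision_ : (p, p) selected precision matrix.
    adjacency_ : boolean (p, p) off-diagonal support.
    selected_lambda_ : chosen penalty.
    lambdas_ : the penalty path (descending).
    instability_path_ : raw mean instability per penalty.
    monotone_instability_ : running supremum along decreasing penalty.
    """

    def __init__(self, nlambda: int = 20, lambda_min_ratio: float = 0.01,
                 rep_num: int = 50, beta: float = 0.05,
                 random_state: int | None = 0, tol: float = 1e-6,
                 max_iter: int = 5000):
        self.nlambda = nlambda
        self.lambda_min_ratio = lambda_min_ratio
        self.rep_num = rep_num
        self.beta = beta
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 10:
            raise ValueError("StARS needs at least 10 samples")
        rng = np.random.default_rng(self.random_state)
        S = _correlation(X)
        lam_hi = lambda_max(S)
        if lam_hi <= 0:
            raise ValueError("degenerate covariance: no off-diagonal signal")
        lambdas = np.exp(np.linspace(np.log(lam_hi), np.log(lam_hi * self.lambda_min_ratio),
                                     self.nlambda))
        b = _stars_subsample_size(n)
        n_edges = p * (p - 1) // 2
        iu = np.triu_indices(p, k=1)
        freq = np.zeros((self.nlambda, n_edges))
        for _ in range(self.rep_num):
            idx = rng.choice(n, size=b, replace=False)
            Ssub = _correlation(X[idx])
            for k, (_, adj) in enumerate(glasso_path(Ssub, lambdas, tol=self.tol,
                                                     max_iter=self.max_iter)):
                freq[k] += adj[iu]
        xi = freq / self.rep_num
        instability = (2 * xi * (1 - xi)).mean(axis=1)
        sup = np.maximum.accumulate(instability)
        ok = np.nonzero(sup <= self.beta)[0]
        self.stars_converged_ = len(ok) > 0
        sel = int(ok[-1]) if len(ok) else self.nlambda - 1

        path = glasso_path(S, lambdas, tol=self.tol, max_iter=self.max_iter)
        Theta, adj = path[sel]
        self.precision_ = Theta
        self.adjacency_ = adj
        self.selected_lambda_ = float(lambdas[sel])
        self.selected_index_ = sel
        self.lambdas_ = lambdas
        self.instability_path_ = instability
        self.monotone_instability_ = sup
        self.subsample_size_ = b
        self.edge_frequencies_ = xi
        self.full_path_edge_counts_ = np.array([int(a.sum() // 2) for _, a in path])
        return self


def stars_select(data, nlambda: int = 20, lambda_min_ratio: float = 0.01,
                 rep_num: int = 50, beta: float = 0.05, seed: int | None = 0,
                 **kw) -> StarsGraphicalLasso:
    """Functional wrapper around :class:`StarsGraphicalLasso`."""
    kw.setdefault("random_state", seed)
    return StarsGraphicalLasso(nlambda=nlambda, lambda_min_ratio=lambda_min_ratio,
                               rep_num=rep_num, beta=beta,
                               **kw).fit(np.asarray(data, dtype=float))


# ---------------------------------------------------------------------------
# condition subsets
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ConditionSubset:
    """A named set of (group, day) selectors."""

    name: str
    selector: tuple  # ((group, day), ...)

    def sample_ids(self, table: FeatureTable) -> list[str]:
        pairs = {(g, int(d)) for g, d in self.selector}
        md = table.metadata
        return [s for s in table.sample_ids
                if (md.at[s, "group"], int(md.at[s, "day"])) in pairs]


DEFAULT_SUBSETS = (
    ConditionSubset("normal_condition", (("untreated", 7), ("untreated", 11))),
    ConditionSubset("lactose_feeding", (("model", 5), ("model", 7), ("model", 11),
                                        ("control", 5), ("control", 7), ("control", 11),
                                        ("test", 5), ("test", 7))),
    ConditionSubset("treatment", (("test", 11), ("test", 13))),
)


@dataclass
class NetworkModel:
    """Selected network for one condition subset (or the pooled data)."""

    name: str
    nodes: pd.DataFrame            # node, class, mean abundance, top-k flag
    adjacency: pd.DataFrame        # 0/1 symmetric, zero diagonal
    selected_lambda: float
    lambdas: np.ndarray
    instability_path: np.ndarray
    stars_converged: bool = True
    estimator: StarsGraphicalLasso | None = field(default=None, repr=False)

    def edge_list(self) -> pd.DataFrame:
        A = self.adjacency.to_numpy()
        ids = list(self.adjacency.index)
        rows = [(ids[i], ids[j]) for i, j in zip(*np.nonzero(np.triu(A, 1)))]
        return pd.DataFrame(rows, columns=["node_a", "node_b"])


def _validate_subsets(subsets):
    seen = {}
    for sub in subsets:
        for pair in sub.selector:
            key = (pair[0], int(pair[1]))
            if key in seen and seen[key] != sub.name:
                raise ValueError(f"selector {key} appears in both "
                                 f"{seen[key]!r} and {sub.name!r}")
            seen[key] = sub.name


def condition_networks(table: FeatureTable, subsets=DEFAULT_SUBSETS, top_k: int = 50,
                       min_prevalence: float = 0.2, mode: str = "per_subset",
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       **stars_kw) -> dict[str, NetworkModel]:
    """Build per-condition networks with node mean abundances.

    Features are prevalence-filtered on the full table so every network
    shares one node set.  With ``mode="per_subset"`` (default) one network
    is inferred from each subset's own samples; with ``mode="pooled"`` a
    single network is inferred from all subset samples combined and reused
    per subset, with only the node abundances recomputed.  Nodes are
    flagged as top-k by overall mean relative abundance.
    """
    _validate_subsets(subsets)
    filtered = prevalence_filter(table, min_prevalence=min_prevalence)
    classes = (filtered.lineage_rank("class") if filtered.taxonomy is not None
               else pd.Series("", index=filtered.feature_ids))
    rel_all = filtered.relative_abundance()
    overall_mean = rel_all.mean(axis=0)
    top = set(overall_mean.sort_values(ascending=False).index[:top_k])

    ids_by_subset = {}
    for sub in subsets:
        ids = sub.sample_ids(filtered)
        if not ids:
            raise ValueError(f"subset {sub.name!r} matches no samples")
        ids_by_subset[sub.name] = ids

    def fit_on(sample_ids):
        clr = clr_transform(filtered.select_samples(sample_ids),
                            pseudocount=pseudocount)
        return stars_select(clr.to_numpy(), **stars_kw)

    pooled_est = None
    if mode == "pooled":
        pooled_ids = [s for sub in subsets for s in ids_by_subset[sub.name]]
        pooled_est = fit_on(pooled_ids)
    elif mode != "per_subset":
        raise ValueError("mode must be 'per_subset' or 'pooled'")

    out = {}
    for sub in subsets:
        est = pooled_est if pooled_est is not None else fit_on(ids_by_subset[sub.name])
        mean_ab = rel_all.loc[ids_by_subset[sub.name]].mean(axis=0)
        nodes = pd.DataFrame({
            "node": filtered.feature_ids,
            "class": [classes[f] for f in filtered.feature_ids],
            "subset": sub.name,
            "mean_abundance": [float(mean_ab[f]) for f in filtered.feature_ids],
            "top50_flag": [f in top for f in filtered.feature_ids],
        })
        adj = pd.DataFrame(est.adjacency_.astype(int), index=filtered.feature_ids,
                           columns=filtered.feature_ids)
        out[sub.name] = NetworkModel(
            name=sub.name, nodes=nodes, adjacency=adj,
            selected_lambda=est.selected_lambda_, lambdas=est.lambdas_,
            instability_path=est.instability_path_,
            stars_converged=est.stars_converged_, estimator=est)
    return out


def taxon_abundance_compare(table: FeatureTable, subsets=DEFAULT_SUBSETS,
                            taxon: str = "Bacteroides") -> dict[str, pd.DataFrame]:
    """Per-subset abundance of one genus, with pairwise Mann-Whitney tests.

    The taxon's abundance in a sample is the summed relative abundance of
    all features whose genus label matches `taxon` (any confidence; the
    mean confidence is reported alongside).
    """
    if table.taxonomy is None:
        raise ValueError("taxonomy required to resolve taxa")
    genus = table.lineage_rank("genus")
    feats = [f for f in table.feature_ids if genus[f] == taxon]
    if not feats:
        raise ValueError(f"taxon {taxon!r} not found in taxonomy")
    conf = float(table.taxonomy.loc[feats, "confidence"].mean()) \
        if "confidence" in table.taxonomy else np.nan
    rel = table.relative_abundance()[feats].sum(axis=1)

    values = {}
    summary_rows = []
    for sub in subsets:
        ids = sub.sample_ids(table)
        if not ids:
            raise ValueError(f"subset {sub.name!r} matches no samples")
        v = rel.loc[ids].to_numpy()
        values[sub.name] = v
        summary_rows.append({
            "subset": sub.name, "n": len(v), "mean": float(v.mean()),
            "se": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "mean_confidence": conf,
        })
    test_rows = []
    names = [s.name for s in subsets]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = values[names[i]], values[names[j]]
            res = mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if max(len(a), len(b)) <= 8 else "asymptotic")
            test_rows.append({"subset_a": names[i], "subset_b": names[j],
                              "U": float(res.statistic), "p": float(res.pvalue)})
    return {"summary": pd.DataFrame(summary_rows), "tests": pd.DataFrame(test_rows)}
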