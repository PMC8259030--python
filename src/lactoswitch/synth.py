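"""Synthetic data generators emulating the 21-day murine study design.

``simulate_study`` produces an ASV count table for a 4-group x 21-day
experiment (10 mice per group; phase I normal care days 1-3, phase II
lactose challenge days 4-9, phase III bacterial treatment days 10-15,
phase IV restoration days 16-21) with a known ground truth:

* a log-normal baseline over features, with 35 of the 50 most abundant
  ASVs labelled class Bacteroidia (genus Bacteroides);
* a shared temporal drift of the Bacteroidia block in all groups, ramping
  over days 3-11 (a stand-in for the unexplained drift of healthy gut
  communities, not a mechanistic claim);
* a lactose effect (suppression of the Bacteroides-like block, boost of a
  Lactobacillus-like taxon) in the lactose-fed groups: model/control/test
  during phase II, model/control during phase III; the test group reverts
  to the baseline trend once treated;
* Dirichlet-multinomial counts at log-normally distributed depths.

``null_study`` zeroes every effect for type-I calibration, and
``simulate_precision_graph_data`` draws Gaussian data from known sparse
precision graphs for network-recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_table import FeatureTable

__all__ = ["StudyConfig", "simulate_study", "null_study",
           "simulate_precision_graph_data", "PHASES"]

PHASES = {"I": range(1, 4), "II": range(4, 10), "III": range(10, 16),
          "IV": range(16, 22)}

_CLASS_POOL = ("Clostridia", "Bacilli", "Verrucomicrobiae",
               "Gammaproteobacteria", "Coriobacteriia")
_GENUS_BY_CLASS = {
    "Clostridia": ("Lachnospiraceae_NK4A136", "Roseburia", "Oscillibacter"),
    "Bacilli": ("Ligilactobacillus", "Enterococcus"),
    "Verrucomicrobiae": ("Akkermansia",),
    "Gammaproteobacteria": ("Escherichia-Shigella",),
    "Coriobacteriia": ("Enterorhabdus",),
}


@dataclass(frozen=True)
class StudyConfig:
    """Design and effect sizes of a simulated study."""

    n_mice_per_group: int = 10
    groups: tuple = ("untreated", "model", "control", "test")
    sampling_days: tuple = tuple(range(1, 22, 2))
    mice_per_day: int = 5          # rotating subset sampled each day
    n_features: int = 300
    depth_mean: float = 8000.0
    depth_sigma: float = 0.35      # lognormal shape of sequencing depth
    baseline_sd: float = 1.5       # log-abundance spread across features
    mouse_sd: float = 0.3          # per-mouse log-abundance heterogeneity
    cage_sd: float = 0.0           # cage random intercept (off by default)
    drift_magnitude: float = 0.8   # shared Bacteroidia drift, log units
    bacteroides_suppression: float = -0.5   # lactose effect, log-fold
    lactobacillus_boost: float = 0.7        # lactose effect, log-fold
    concentration: float = 200.0   # Dirichlet concentration (overdispersion)
    drift_days: tuple = (3, 11)    # drift ramps linearly over this window
    seed: int = 0

    def __post_init__(self):
        if self.n_mice_per_group < 1 or self.n_features < 10:
            raise ValueError("need >= 1 mouse per group and >= 10 features")
        if not (0 < self.mice_per_day <= self.n_mice_per_group):
            raise ValueError("mice_per_day must lie in [1, n_mice_per_group]")
        if self.drift_days[0] >= self.drift_days[1]:
            raise ValueError("invalid drift window")


def _lactose_groups(day: int) -> tuple:
    """Groups under the lactose effect on a given day."""
    if day in PHASES["II"]:
        return ("model", "control", "test")
    if day in PHASES["III"]:
        return ("model", "control")   # test reverts to baseline trend
    return ()


def _taxonomy(cfg: StudyConfig, base_log: np.ndarray, rng) -> pd.DataFrame:
    n = cfg.n_features
    order = np.argsort(base_log)[::-1]
    top50 = order[:min(50, n)]
    n_bact = min(35, len(top50))
    bacteroidia = rng.choice(top50, size=n_bact, replace=False)
    # one dominant Lactobacillus-like taxon among the remaining top features
    rest_top = [i for i in top50 if i not in set(bacteroidia)]
    lacto = rest_top[0] if rest_top else int(order[min(50, n - 1)])

    lineages = [""] * n
    classes = [""] * n
    for i in range(n):
        if i in set(bacteroidia):
            sp = "Bacteroides acidifaciens" if rng.random() < 0.4 else f"Bacteroides sp{i:03d}"
            lineages[i] = ("Bacteria;Bacteroidota;Bacteroidia;Bacteroidales;"
                           f"Bacteroidaceae;Bacteroides;{sp}")
            classes[i] = "Bacteroidia"
        elif i == lacto:
            lineages[i] = ("Bacteria;Firmicutes;Bacilli;Lactobacillales;"
                           "Lactobacillaceae;Lactobacillus;Lactobacillus murinus")
            classes[i] = "Bacilli"
        else:
            c = _CLASS_POOL[rng.integers(len(_CLASS_POOL))]
            g = _GENUS_BY_CLASS[c][rng.integers(len(_GENUS_BY_CLASS[c]))]
            lineages[i] = f"Bacteria;phylum_{c};{c};order_{c};family_{g};{g};{g} sp{i:03d}"
            classes[i] = c
    tax = pd.DataFrame({
        "lineage": lineages,
        "confidence": rng.uniform(0.70, 0.995, size=n).round(3),
    }, index=[f"ASV{i:04d}" for i in range(n)])
    tax["is_bacteroides_block"] = [c == "Bacteroidia" for c in classes]
    tax["is_lactobacillus"] = [i == lacto for i in range(n)]
    return tax


def simulate_study(config: StudyConfig | None = None, **overrides) -> FeatureTable:
    """Generate one study; deterministic given ``config.seed``."""
    cfg = replace(config or StudyConfig(), **overrides) if (config or overrides) \
        else StudyConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_features

    base_log = rng.normal(0.0, cfg.baseline_sd, size=n)
    tax = _taxonomy(cfg, base_log, rng)
    block = tax["is_bacteroides_block"].to_numpy()
    lacto = tax["is_lactobacillus"].to_numpy()

    mouse_eff = {}
    cage_eff = {}
    for g in cfg.groups:
        for m in range(cfg.n_mice_per_group):
            mouse_eff[(g, m)] = rng.normal(0.0, cfg.mouse_sd, size=n)
            cage = m // 2
            if (g, cage) not in cage_eff:
                cage_eff[(g, cage)] = (rng.normal(0.0, cfg.cage_sd, size=n)
                                       if cfg.cage_sd > 0 else np.zeros(n))

    d0, d1 = cfg.drift_days
    rows, meta = {}, []
    for k, day in enumerate(cfg.sampling_days):
        ramp = float(np.clip((day - d0) / (d1 - d0), 0.0, 1.0))
        start = (k * cfg.mice_per_day) % cfg.n_mice_per_group
        mice = [(start + i) % cfg.n_mice_per_group for i in range(cfg.mice_per_day)]
        for g in cfg.groups:
            lactose = g in _lactose_groups(day)
            for m in mice:
                logab = base_log + mouse_eff[(g, m)] + cage_eff[(g, m // 2)]
                logab = logab + cfg.drift_magnitude * ramp * block
                if lactose:
                    logab = logab + cfg.bacteroides_suppression * block \
                        + cfg.lactobacillus_boost * lacto
                p = np.exp(logab - logab.max())
                p /= p.sum()
                theta = rng.dirichlet(cfg.concentration * p)
                depth = int(np.round(rng.lognormal(
                    np.log(cfg.depth_mean) - cfg.depth_sigma ** 2 / 2,
                    cfg.depth_sigma)))
                sid = f"{g[:2]}{m:02d}d{day:02d}"
                rows[sid] = rng.multinomial(max(depth, 1), theta)
                meta.append({"sample_id": sid, "group": g, "day": day,
                             "mouse_id": f"{g[:2]}{m:02d}", "cage": f"{g[:2]}c{m // 2}"})

    counts = pd.DataFrame.from_dict(rows, orient="index", columns=tax.index)
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return FeatureTable(counts, metadata, tax)


def null_study(config: StudyConfig | None = None, **overrides) -> FeatureTable:
    """A study with every effect and the drift set to zero (groups exchangeable)."""
    cfg = replace(config or StudyConfig(), **overrides)
    cfg = replace(cfg, drift_magnitude=0.0, bacteroides_suppression=0.0,
                  lactobacillus_boost=0.0)
    return simulate_study(cfg)


def simulate_precision_graph_data(p: int, n: int, graph: str = "band",
                                  density: float = 0.1, seed: int = 0,
                                  strength: float = 0.3):
    """Gaussian samples from a known sparse precision matrix.

    graph: "chain" (first off-diagonal), "band" (two off-diagonals at
    `strength` and `strength`/2) or "random" (Erdos-Renyi at `density`,
    signs random).  The matrix is rescaled to diagonal dominance so it is
    positive definite.  Returns (X, adjacency, precision).
    """
    if p < 2 or n < 2:
        raise ValueError("need p >= 2 and n >= 2")
    rng = np.random.default_rng(seed)
    P = np.eye(p)
    if graph == "chain":
        for i in range(p - 1):
            P[i, i + 1] = P[i + 1, i] = -strength
    elif graph == "band":
        for i in range(p - 1):
            P[i, i + 1] = P[i + 1, i] = -strength
        for i in range(p - 2):
            P[i, i + 2] = P[i + 2, i] = -strength / 2
    elif graph == "random":
        iu = np.triu_indices(p, k=1)
        m = len(iu[0])
        n_edges = int(round(density * m))
        if n_edges < 1:
            raise ValueError("density too low: no edges")
        pick = rng.choice(m, size=n_edges, replace=False)
        vals = strength * rng.choice([-1.0, 1.0], size=n_edges)
        P[iu[0][pick], iu[1][pick]] = vals
        P[iu[1][pick], iu[0][pick]] = vals
    else:
        raise ValueError(f"unknown graph type {graph!r}")

    # enforce strict diagonal dominance
    row = np.abs(P).sum(axis=1) - np.abs(np.diag(P))
    scale = max(row.max() / 0.9, 1.0)
    off = ~np.eye(p, dtype=bool)
    P[off] /= scale

    adjacency = (np.abs(P) > 0) & off
    Sigma = np.linalg.inv(P)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((n, p)) @ L.T
    return X, adjacency, P
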