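"""Group inference: rank-based normalization, t-tests, multiple-testing
corrections, and the bootstrap density-sweep AUC comparison.

Three procedures are provided, mirroring the three levels of a
connectome group analysis:

1. network level — within-network mean connectivity per subject,
   inverse-normal transformed, two-sample t-test, Bonferroni over the
   (seven) networks;
2. edge level — every unique parcel pair, inverse-normal transformed,
   two-sample t-test, Benjamini-Hochberg FDR;
3. whole-graph level — per group, bootstrap resamples of subjects are
   averaged into group matrices, swept over the density grid, and each
   metric's AUC distribution is compared by a two-sample t-test with
   Bonferroni correction over the metric family.

A statistical caveat of the bootstrap comparison is deliberately
preserved rather than "fixed": replicate AUCs within a group are
resamples of the same subjects, so the t statistic grows without bound
in the number of bootstrap replicates under a fixed true effect. This is
the mechanism behind the very large t values such pipelines report; it
is surfaced in the result metadata (``n_boot`` and the df used) so the
numbers can be read for what they are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix, ParcelAtlas, network_mean_fc, upper_triangle
from .graph import DEFAULT_GRID, METRIC_NAMES, DensityGrid, sweep

logger = logging.getLogger(__name__)

#: metrics in the default Bonferroni family of 3 (family size configurable to 4)
DEFAULT_FAMILY_SIZE = 3


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample Student t-test."""

    t: float
    p: float
    df: int
    n1: int
    n2: int


@dataclass(frozen=True)
class BootstrapConfig:
    """Configuration of the bootstrap AUC group comparison."""

    n_boot: int = 1000
    seed: int = 0
    grid: DensityGrid = DEFAULT_GRID
    alpha: float = 0.05
    family_size: int = DEFAULT_FAMILY_SIZE

    def __post_init__(self):
        if self.n_boot < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.family_size < 1:
            raise ValueError("family_size must be at least 1")


@dataclass(frozen=True)
class GroupComparisonResult:
    """One contrast: statistic, raw and corrected p, and direction."""

    contrast_name: str
    t: float
    df: int
    p_raw: float
    p_corrected: float
    correction: str  # bonferroni | fdr_bh | none
    direction: int  # sign of (group1 - group2)


def inverse_normal_transform(x, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    y_i = Phi^-1((r_i - c) / (n - 2c + 1)) with average ranks for ties
    and c = 3/8 by default. Monotone in the input; sample mean ~ 0.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample of length >= 2")
    if np.all(x == x[0]):
        raise ValueError("all values identical; inverse normal transform undefined")
    return _int_ranks(sps.rankdata(x), x.size, offset)


def _int_ranks(ranks: np.ndarray, n: int, offset: float) -> np.ndarray:
    return sps.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def _int_columns(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Column-wise inverse normal transform of a subjects x features matrix."""
    ranks = sps.rankdata(x, axis=0)
    return _int_ranks(ranks, x.shape[0], offset)


def two_sample_t(x, y) -> TTestResult:
    """Pooled-variance Student t-test (df = n1 + n2 - 2), two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return two_sample_t_from_summary(
        x.size, x.mean(), x.std(ddof=1), y.size, y.mean(), y.std(ddof=1)
    )


def two_sample_t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float
) -> TTestResult:
    """Identical test from per-group summary statistics (n, mean, sd)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0.0:
        raise ValueError("zero pooled variance; t statistic undefined")
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), p=float(p), df=df, n1=n1, n2=n2)


def _pooled_t_columns(x1: np.ndarray, x2: np.ndarray):
    """Vectorized pooled t over feature columns; returns (t, p, df)."""
    n1, n2 = x1.shape[0], x2.shape[0]
    df = n1 + n2 - 2
    v = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n2 - 1) * x2.var(axis=0, ddof=1)) / df
    se = np.sqrt(v * (1.0 / n1 + 1.0 / n2))
    t = (x1.mean(axis=0) - x2.mean(axis=0)) / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, p, df


def bonferroni(p, m: int | None = None, alpha: float = 0.05):
    """Bonferroni correction: p_corr = min(1, p * m); threshold alpha / m."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be at least 1")
    return np.minimum(1.0, p * m), alpha / m


def fdr_bh(p, q: float = 0.05):
    """Benjamini-Hochberg step-up FDR; returns (reject mask, adjusted p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# Bootstrap AUC comparison


def _stack(group: list[ConnectivityMatrix]) -> np.ndarray:
    zs = np.stack([cm.z for cm in group])
    return zs


def bootstrap_mean_matrices(
    group: list[ConnectivityMatrix] | np.ndarray, n_boot: int, seed: int
) -> np.ndarray:
    """Averaged z-matrices of ``n_boot`` with-replacement subject resamples.

    Replicate ``b`` depends only on ``(seed, b)``, so the stream is
    reproducible and insensitive to how many replicates are requested.
    Returns an ``(n_boot, N, N)`` array.
    """
    zs = group if isinstance(group, np.ndarray) else _stack(group)
    n_sub = zs.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    out = np.empty((n_boot, zs.shape[1], zs.shape[2]))
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), b]))
        idx = rng.integers(0, n_sub, size=n_sub)
        out[b] = zs[idx].mean(axis=0)
    return out


def _auc_samples(zs_boot: np.ndarray, grid: DensityGrid) -> dict[str, np.ndarray]:
    aucs = {m: np.empty(zs_boot.shape[0]) for m in METRIC_NAMES}
    for b in range(zs_boot.shape[0]):
        sweeps = sweep(zs_boot[b], grid)
        for m in METRIC_NAMES:
            aucs[m][b] = sweeps[m].auc
    return aucs


def compare_graph_metrics(
    group1: list[ConnectivityMatrix],
    group2: list[ConnectivityMatrix],
    cfg: BootstrapConfig,
):
    """Bootstrap density-sweep AUC comparison of the four graph metrics.

    Per group and replicate: resample subjects with replacement, average
    their z-matrices, threshold+binarize across the density grid, and
    integrate each metric's curve into an AUC. The two per-group AUC
    samples are compared with a pooled two-sample t-test per metric,
    Bonferroni-corrected over ``cfg.family_size`` (default 3). NaN AUCs
    (degenerate metric values, e.g. zero-variance assortativity) are
    excluded with a logged count.

    Returns ``(results, metadata)`` where results maps metric name to
    :class:`GroupComparisonResult`.
    """
    zs1, zs2 = _stack(group1), _stack(group2)
    # distinct, order-derived streams per group so the two groups never
    # share bootstrap draws even when passed identical matrices
    seed1 = int(np.random.SeedSequence([int(cfg.seed), 1]).generate_state(1)[0])
    seed2 = int(np.random.SeedSequence([int(cfg.seed), 2]).generate_state(1)[0])
    boot1 = bootstrap_mean_matrices(zs1, cfg.n_boot, seed1)
    boot2 = bootstrap_mean_matrices(zs2, cfg.n_boot, seed2)
    auc1 = _auc_samples(boot1, cfg.grid)
    auc2 = _auc_samples(boot2, cfg.grid)
    results: dict[str, GroupComparisonResult] = {}
    nan_counts: dict[str, int] = {}
    for m in METRIC_NAMES:
        a1, a2 = auc1[m], auc2[m]
        nan_counts[m] = int(np.isnan(a1).sum() + np.isnan(a2).sum())
        if nan_counts[m]:
            logger.warning(
                "metric %s: %d NaN AUC replicate(s) excluded", m, nan_counts[m]
            )
        a1, a2 = a1[~np.isnan(a1)], a2[~np.isnan(a2)]
        if a1.size < 2 or a2.size < 2:
            raise ValueError(
                f"metric {m!r}: too few finite AUC replicates on grid "
                f"{cfg.grid.densities[0]:.2f}-{cfg.grid.densities[-1]:.2f}"
            )
        tt = two_sample_t(a1, a2)
        p_corr, _ = bonferroni([tt.p], m=cfg.family_size, alpha=cfg.alpha)
        results[m] = GroupComparisonResult(
            contrast_name=f"{m}_auc",
            t=tt.t,
            df=tt.df,
            p_raw=tt.p,
            p_corrected=float(p_corr[0]),
            correction="bonferroni",
            direction=int(np.sign(tt.t)),
        )
    metadata = {
        "n_boot": cfg.n_boot,
        "seed": cfg.seed,
        "grid": list(cfg.grid.densities),
        "family_size": cfg.family_size,
        "alpha": cfg.alpha,
        "nan_auc_counts": nan_counts,
        "df": 2 * cfg.n_boot - 2,
        "note": (
            "replicate AUCs within a group resample the same subjects; the t "
            "statistic therefore grows with n_boot under a fixed true effect"
        ),
    }
    return results, metadata


# ---------------------------------------------------------------------------
# Network- and edge-level comparisons


def compare_networks(
    group1: list[ConnectivityMatrix],
    group2: list[ConnectivityMatrix],
    atlas: ParcelAtlas,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Within-network mean FC contrast per network, Bonferroni-corrected.

    Each subject contributes one mean z per network; values are
    inverse-normal transformed across the pooled subjects per network
    before the pooled two-sample t-test. Family size = number of
    networks (seven for the canonical atlas).
    """
    networks = atlas.networks
    feats = []
    for cm in list(group1) + list(group2):
        means = network_mean_fc(cm, atlas)
        feats.append([means[nw] for nw in networks])
    x = _int_columns(np.asarray(feats))
    n1 = len(group1)
    t, p, df = _pooled_t_columns(x[:n1], x[n1:])
    p_corr, threshold = bonferroni(p, m=len(networks), alpha=alpha)
    return pd.DataFrame(
        {
            "contrast": list(networks),
            "t": t,
            "df": df,
            "p_raw": p,
            "p_corrected": p_corr,
            "correction": "bonferroni",
            "direction": np.sign(t).astype(int),
            "significant": p_corr < alpha,
            "threshold": threshold,
        }
    )


def compare_edges(
    group1: list[ConnectivityMatrix],
    group2: list[ConnectivityMatrix],
    q: float = 0.05,
) -> pd.DataFrame:
    """Edge-wise FC contrast over all unique parcel pairs, BH-FDR corrected.

    Edge values are inverse-normal transformed across the pooled
    subjects per edge before testing (same normalization order as the
    network level).
    """
    labels, _ = upper_triangle(group1[0])
    rows = []
    for cm in list(group1) + list(group2):
        lab, vals = upper_triangle(cm)
        if lab != labels:
            raise ValueError("subjects have inconsistent parcel orderings")
        rows.append(vals)
    x = _int_columns(np.asarray(rows))
    n1 = len(group1)
    t, p, df = _pooled_t_columns(x[:n1], x[n1:])
    reject, p_adj = fdr_bh(p, q=q)
    return pd.DataFrame(
        {
            "parcel_i": [a for a, _ in labels],
            "parcel_j": [b for _, b in labels],
            "t": t,
            "df": df,
            "p_raw": p,
            "p_corrected": p_adj,
            "correction": "fdr_bh",
            "direction": np.sign(t).astype(int),
            "significant": reject,
        }
    )
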