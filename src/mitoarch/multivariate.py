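"""Correlation-matrix PCA and Spearman correlation tests.

PCA is the eigendecomposition of the Pearson correlation matrix of a
feature table (taxa x features): variance fractions are eigenvalues/p and
scores are the standardised data projected on the eigenvectors, with a
deterministic sign convention. The Spearman test reports the rank Pearson
coefficient with both the t-approximation p-value and a seeded permutation
p-value (two-sided, add-one corrected). The combined report correlates a
scalar MGO divergence (events from a reference arrangement) with
substitution-rate columns and habitat indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_orders import GeneOrder
from .rearrangement import event_count_to_reference

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA on the Pearson correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    feature_names: tuple[str, ...]
    loadings: np.ndarray       # p x p, columns = components
    scores: np.ndarray         # n x p
    variance_fractions: np.ndarray
    dropped: tuple[str, ...] = ()


def pca_correlation(table: pd.DataFrame) -> PCAResult:
    """Principal components of the Pearson correlation matrix.

    Constant columns are dropped (and reported); the sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    num = table.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise ValueError("feature table has missing cells; drop or impute first")
    sd = num.std(axis=0, ddof=1)
    dropped = tuple(sd.index[sd == 0])
    for col in dropped:
        logger.warning("pca_correlation: dropping constant column %r", col)
    num = num.drop(columns=list(dropped))
    p = num.shape[1]
    if p < 2:
        raise ValueError("need at least 2 non-constant feature columns")
    X = num.to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(p):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PCAResult(
        feature_names=tuple(num.columns),
        loadings=vecs,
        scores=Z @ vecs,
        variance_fractions=np.clip(vals, 0.0, None) / p,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Spearman correlation with permutation p-value
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float | None
    p_t: float | None
    p_perm: float | None
    n: int
    undefined: bool = False


def spearman(x: Sequence[float], y: Sequence[float],
             n_perm: int = 999, seed: int = 0) -> SpearmanResult:
    """Spearman rho with t-based and seeded permutation p-values.

    rho is the Pearson correlation of average ranks (ties allowed); the
    permutation p is two-sided with add-one correction over ``n_perm``
    shuffles of ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        logger.warning("spearman: zero variance in ranks; rho undefined")
        return SpearmanResult(None, None, None, n, undefined=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        p_t = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p_t = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    rng = np.random.default_rng(seed)
    zx = (rx - rx.mean()) / rx.std()
    zy = (ry - ry.mean()) / ry.std()
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = zx @ rng.permutation(zy) / n
    hits = int(np.sum(np.abs(perm) >= abs(rho) - 1e-12))
    p_perm = (hits + 1) / (n_perm + 1)
    return SpearmanResult(rho, p_t, float(p_perm), n)


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def plot_pca_scores(result: PCAResult, labels: Sequence[str] | None = None,
                    groups: Mapping[str, str] | None = None,
                    path: str | None = None):
    """Optional static PC1/PC2 scatter (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xs, ys = result.scores[:, 0], result.scores[:, 1]
    if labels is not None and groups:
        cats = sorted({groups.get(l, "") for l in labels})
        for cat in cats:
            idx = [i for i, l in enumerate(labels) if groups.get(l, "") == cat]
            ax.scatter(xs[idx], ys[idx], s=12, label=cat or "(none)")
        ax.legend(fontsize=7)
    else:
        ax.scatter(xs, ys, s=12)
    ax.set_xlabel(f"PC1 ({100 * result.variance_fractions[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * result.variance_fractions[1]:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# MGO divergence vs rates / habitat
# ---------------------------------------------------------------------------

def mgo_divergence(orders: Sequence[GeneOrder], reference: GeneOrder) -> pd.Series:
    """Per-taxon rearrangement-event count from the reference arrangement."""
    return pd.Series(
        {o.taxon_id: event_count_to_reference(o, reference) for o in orders},
        name="mgo_divergence",
    )


def mgo_rate_correlation(orders: Sequence[GeneOrder], reference: GeneOrder,
                         rates: pd.DataFrame,
                         habitat: Mapping[str, str] | None = None,
                         n_perm: int = 999, seed: int = 0,
                         adjust: bool = False) -> pd.DataFrame:
    """Tidy Spearman report: divergence vs each rate column and habitat.

    ``rates`` must carry a taxon_id column; each habitat category becomes a
    binary membership indicator. Rows: pairing, rho, p_t, p_perm, n.
    """
    div = mgo_divergence(orders, reference)
    df = rates.set_index("taxon_id")
    common = div.index.intersection(df.index)
    if len(common) < 4:
        raise ValueError("fewer than 4 taxa overlap between orders and rates")
    rows = []
    seed_step = 0
    for col in df.columns:
        res = spearman(div.loc[common], df.loc[common, col],
                       n_perm=n_perm, seed=seed + seed_step)
        seed_step += 1
        rows.append({"pairing": f"mgo_divergence~{col}", "rho": res.rho,
                     "p_t": res.p_t, "p_perm": res.p_perm, "n": res.n,
                     "undefined": res.undefined})
    if habitat:
        hab = pd.Series(habitat)
        hab = hab.loc[hab.index.intersection(common)]
        for cat in sorted(hab.unique()):
            indicator = (hab == cat).astype(float)
            idx = hab.index
            res = spearman(div.loc[idx], indicator,
                           n_perm=n_perm, seed=seed + seed_step)
            seed_step += 1
            rows.append({"pairing": f"mgo_divergence~habitat:{cat}", "rho": res.rho,
                         "p_t": res.p_t, "p_perm": res.p_perm, "n": res.n,
                         "undefined": res.undefined})
    out = pd.DataFrame(rows)
    if adjust and len(out):
        ok = out["p_perm"].notna()
        out.loc[ok, "p_perm_bh"] = benjamini_hochberg(out.loc[ok, "p_perm"].to_numpy())
    return out
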