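"""HERMES-style single-factor index of relative mitochondrial evolutionary speed.

Five per-taxon variables — root-to-tip distance (RtoTdist), path distance
from the designated outgroup (MLdist), percentage of unassigned regions
(UR%), the fraction of taxa sharing the same protein-coding arrangement
(AMIGA) and the strand usage skew (SUskew) — are standardised and summarised
by a one-factor maximum-likelihood factor model fitted to their 5x5 Pearson
correlation matrix. The factor score is the index: a single number per taxon
expressing how much mitochondrial change it has accumulated relative to the
rest of the dataset.

Fit statistics follow the SEM conventions: a Bartlett-corrected
likelihood-ratio chi-square for the model (df = 5 for p=5, k=1), Bartlett's
sphericity chi-square for the independence model (df = 10), and TLI, RMSEA
and SRMR derived from the two. Communality_i = loading_i^2; the mean
communality is the share of total standardised variance the index captures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

HERMES_VARIABLES = ("rtot_dist", "ml_dist", "ur_percent", "amiga", "su_skew")


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def tree_distances(tree: dendropy.Tree | str, outgroup: str) -> pd.DataFrame:
    """Per-leaf root-to-tip and outgroup path distances.

    Accepts a dendropy tree or a newick string/path; all branch lengths must
    be present and non-negative. The outgroup leaf is excluded from the
    output rows.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = dendropy.Tree.get(data=str(tree), schema="newick") if str(tree).strip().startswith("(") \
            else dendropy.Tree.get(path=str(tree), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise ValueError(f"missing branch length on the edge above {head}")
        if edge.length < 0:
            raise ValueError("negative branch length in tree")

    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}

    rtot: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        rtot[leaf.taxon.label] = d

    rows = []
    for label in labels:
        if label == outgroup:
            continue
        rows.append({
            "taxon_id": label,
            "rtot_dist": rtot[label],
            "ml_dist": pdm.patristic_distance(taxa[outgroup], taxa[label]),
        })
    return pd.DataFrame(rows).sort_values("taxon_id").reset_index(drop=True)


def build_variables(distances: pd.DataFrame,
                    profiles: pd.DataFrame,
                    amiga: Mapping[str, float]) -> pd.DataFrame:
    """Join the five HERMES variables; taxa with any missing value dropped."""
    df = distances.merge(
        profiles[["taxon_id", "ur_percent", "su_skew"]], on="taxon_id", how="inner"
    )
    df["amiga"] = df["taxon_id"].map(amiga)
    df = df[["taxon_id", *HERMES_VARIABLES]]
    n0 = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n0:
        logger.warning("dropped %d taxa with missing HERMES variables", n0 - len(df))
    return df


# ---------------------------------------------------------------------------
# single-factor maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class HermesResult:
    variables: tuple[str, ...]
    loadings: np.ndarray
    uniquenesses: np.ndarray
    communalities: np.ndarray
    mean_communality: float
    fit: dict[str, float]
    scores: dict[str, float]
    heywood: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "loadings": [float(x) for x in self.loadings],
            "uniquenesses": [float(x) for x in self.uniquenesses],
            "communalities": [float(x) for x in self.communalities],
            "mean_communality": float(self.mean_communality),
            "fit": {k: float(v) for k, v in sorted(self.fit.items())},
            "scores": {k: float(v) for k, v in sorted(self.scores.items())},
            "heywood": self.heywood,
            "degenerate": self.degenerate,
        }


_PSI_FLOOR = 5e-3


def _profile_objective(psi: np.ndarray, S: np.ndarray) -> float:
    """Joreskog's concentrated ML discrepancy for a k=1 factor model."""
    d = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(d, d)
    theta = np.linalg.eigvalsh(Sstar)[::-1]
    tail = theta[1:]
    return float(np.sum(tail - np.log(tail) - 1.0))


def _fit_single_factor(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    p = S.shape[0]
    # standard start: psi_j = (1 - k/(2p)) / diag(S^-1)
    start = (1.0 - 1.0 / (2.0 * p)) / np.diag(np.linalg.inv(S))
    start = np.clip(start, _PSI_FLOOR, 1.0)
    res = optimize.minimize(
        _profile_objective, start, args=(S,), method="L-BFGS-B",
        bounds=[(_PSI_FLOOR, 1.0)] * p,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    psi = np.clip(res.x, _PSI_FLOOR, 1.0)
    d = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(d, d)
    vals, vecs = np.linalg.eigh(Sstar)
    theta1, v1 = vals[-1], vecs[:, -1]
    load = np.sqrt(psi) * v1 * math.sqrt(max(theta1 - 1.0, 0.0))
    heywood = bool(np.any(psi <= _PSI_FLOOR * 1.001))
    return load, psi, float(res.fun), heywood


def fit_hermes(variables: pd.DataFrame, n: int | None = None) -> HermesResult:
    """Fit the one-factor model and score every taxon.

    ``variables`` holds a taxon_id column plus the five HERMES variables
    (extra numeric columns are used as-is, so the fit generalises to any
    variable set). The factor is oriented so the loading on the first
    variable (rtot_dist) is non-negative; scores use the regression
    (Thomson) method on standardised data.
    """
    cols = [c for c in variables.columns if c != "taxon_id"]
    X = variables[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        keep = ~np.isnan(X).any(axis=1)
        logger.warning("fit_hermes: dropping %d rows with missing cells", (~keep).sum())
        X = X[keep]
        variables = variables.loc[keep]
    n = n or X.shape[0]
    p = X.shape[1]
    if n < 10:
        raise ValueError("need at least 10 complete taxa to fit the index")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant variables cannot be factored: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    S = np.corrcoef(Z, rowvar=False)
    # guard: the ML discrepancy needs a positive-definite correlation matrix
    if np.linalg.eigvalsh(S)[0] <= 1e-10:
        raise ValueError("correlation matrix is not positive definite")

    k = 1
    df_model = ((p - k) ** 2 - (p + k)) // 2
    sign, logdet = np.linalg.slogdet(S)
    chi2_null = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df_null = p * (p - 1) // 2
    # degenerate when the independence model is not rejected (chi2_null ~
    # df_null): the ML solution is then unidentified along a flat direction,
    # so report the one-step principal-factor solution instead
    from scipy import stats as _stats

    degenerate = bool(chi2_null < _stats.chi2.ppf(0.95, df_null))
    if degenerate:
        vals, vecs = np.linalg.eigh(S)
        load = vecs[:, -1] * math.sqrt(max(vals[-1] - 1.0, 0.0))
        psi = np.clip(1.0 - load**2, _PSI_FLOOR, 1.0)
        fmin = _profile_objective(psi, S)
        heywood = False
        logger.warning("independence model fits the data: the factor is vacuous "
                       "(chi2_null ~ df_null)")
    else:
        load, psi, fmin, heywood = _fit_single_factor(S)
    if load[0] < 0:
        load = -load

    bartlett = n - 1 - (2 * p + 5) / 6.0 - 2.0 * k / 3.0
    chi2_model = max(bartlett, 0.0) * fmin

    ratio_m = chi2_model / df_model if df_model else np.nan
    ratio_0 = chi2_null / df_null if df_null else np.nan
    tli = (ratio_0 - ratio_m) / (ratio_0 - 1.0) if ratio_0 != 1.0 else np.nan
    rmsea = math.sqrt(max(chi2_model - df_model, 0.0) / (df_model * (n - 1)))
    implied = np.outer(load, load) + np.diag(psi)
    resid = S - implied
    tri = np.tril_indices(p)
    srmr = math.sqrt(float(np.mean(resid[tri] ** 2)))


    # regression (Thomson) scores on the model-implied covariance
    weights = np.linalg.solve(implied, load)
    f = Z @ weights
    scores = dict(zip(variables["taxon_id"].tolist(), f.tolist()))

    comm = load ** 2
    return HermesResult(
        variables=tuple(cols),
        loadings=load,
        uniquenesses=psi,
        communalities=comm,
        mean_communality=float(comm.mean()),
        fit={
            "chi2_model": float(chi2_model),
            "df_model": float(df_model),
            "chi2_null": float(chi2_null),
            "df_null": float(df_null),
            "TLI": float(tli),
            "SRMR": float(srmr),
            "RMSEA": float(rmsea),
        },
        scores=scores,
        heywood=heywood,
        degenerate=degenerate,
    )
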