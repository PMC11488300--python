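"""Co-expression network construction and in-silico gene knockout.

The network is a directed, weighted gene-gene matrix built by principal
component regression: each gene's expression across cells is regressed
(ridge-regularized) on the top principal components of all the other
genes, and the PC coefficients are mapped back to per-gene weights.  Row g
of the adjacency holds the inferred influence of every other gene on g.
The matrix is sparsified at a quantile of |weight| and scaled so
max |weight| = 1.

A virtual knockout deletes a gene's row and column; its downstream impact
is measured by a truncated diffusion: S(A) = sum_{t=0..horizon} (alpha A)^t
accumulates walk contributions up to ``horizon`` steps, and each gene is
scored by the Euclidean distance between its rows of S(intact) and
S(knockout).  Genes with no path of length <= horizon touching the target
score exactly zero.  This is a deliberately simplified propagation scheme
(tagged ``method="pcnet-diffusion"``), not a reimplementation of the
tensor-decomposition/manifold-alignment knockout tools it stands in for.
"""

from __future__ import annotations

import difflib
import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import eigsh

from .cells import normalize_log
from .errors import ConfigurationError

__all__ = [
    "AdjacencyNetwork",
    "PerturbationProfile",
    "build_network",
    "knockout",
    "perturbation_profile",
    "knockout_report",
]

log = logging.getLogger(__name__)

METHOD_TAG = "pcnet-diffusion"


@dataclass
class AdjacencyNetwork:
    """Directed weighted gene-gene matrix; ``weights[g, r]`` is the
    influence of regulator r on gene g.  Diagonal is zero and, after
    normalization, max |weight| is 1 unless the matrix is all zero."""

    genes: list[str]
    weights: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.genes)
        if self.weights.shape != (p, p):
            raise ConfigurationError("weights shape does not match genes")

    def to_sparse_table(self) -> pd.DataFrame:
        """Nonzero entries as a (source, target, weight) triplet table."""
        rows, cols = np.nonzero(self.weights)
        return pd.DataFrame({
            "source": [self.genes[c] for c in cols],
            "target": [self.genes[r] for r in rows],
            "weight": self.weights[rows, cols],
        })


def _top_components(
    cov: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenpairs of a covariance block, deterministic sign.

    Uses Lanczos with a fixed start vector for speed; eigenvector signs
    are fixed so each component's largest-|loading| entry is positive.
    """
    p = cov.shape[0]
    k = min(k, p - 1) if p > 1 else 1
    if p <= max(2 * k + 1, 20):
        vals, vecs = np.linalg.eigh(cov)
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        v0 = np.full(p, 1.0 / np.sqrt(p))
        vals, vecs = eigsh(cov, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return np.maximum(vals, 0.0), vecs


def build_network(
    cells: ad.AnnData,
    gene_subset: list[str] | None = None,
    n_pcs: int = 5,
    ridge: float = 1.0,
    sparsity_quantile: float = 0.95,
) -> AdjacencyNetwork:
    """Principal-component-regression co-expression network.

    ``gene_subset`` defaults to the 500 most variable genes (log-normalized
    variance).  Requires >=50 cells and >=10 genes after subsetting.
    Constant genes keep zero rows/columns (warned).
    """
    if cells.n_obs < 50:
        raise ConfigurationError(f"need >=50 cells, have {cells.n_obs}")
    if "lognorm" not in cells.layers:
        cells = normalize_log(cells)
    lognorm = cells.layers["lognorm"]
    if sparse.issparse(lognorm):
        lognorm = lognorm.toarray()
    lognorm = np.asarray(lognorm, float)

    if gene_subset is None:
        variances = lognorm.var(axis=0)
        top = np.argsort(variances, kind="stable")[::-1][:500]
        top = np.sort(top)
        genes = [cells.var_names[i] for i in top]
        X = lognorm[:, top]
    else:
        missing = [g for g in gene_subset if g not in cells.var_names]
        if missing:
            raise ConfigurationError(
                f"gene_subset members absent from dataset: {missing[:5]}")
        idx = pd.Index(cells.var_names).get_indexer(gene_subset)
        genes = list(gene_subset)
        X = lognorm[:, idx]
    p = len(genes)
    if p < 10:
        raise ConfigurationError(f"need >=10 genes after subsetting, have {p}")

    X = X - X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant genes get zero network "
            "rows/columns", stacklevel=2)

    cov = X.T @ X  # gene x gene Gram matrix of centered data
    weights = np.zeros((p, p))
    keep = np.flatnonzero(~constant)
    for g in keep:
        others = keep[keep != g]
        if others.size < 2:
            continue
        block = cov[np.ix_(others, others)]
        vals, vecs = _top_components(block, n_pcs)
        # ridge solution in PC space: T'T is diagonal with the eigenvalues
        xty = cov[others, g]
        beta = (vecs.T @ xty) / (vals + ridge)
        weights[g, others] = vecs @ beta
    np.fill_diagonal(weights, 0.0)

    off = np.abs(weights[~np.eye(p, dtype=bool)])
    if off.size and off.max() > 0:
        cut = np.quantile(off, sparsity_quantile)
        weights[np.abs(weights) < cut] = 0.0
        m = np.abs(weights).max()
        if m > 0:
            weights = weights / m
    return AdjacencyNetwork(
        genes=genes,
        weights=weights,
        params={"n_pcs": n_pcs, "ridge": ridge,
                "sparsity_quantile": sparsity_quantile,
                "method": METHOD_TAG},
    )


def knockout(net: AdjacencyNetwork, target: str) -> AdjacencyNetwork:
    """Copy of the network with the target's row and column zeroed."""
    if target not in net.genes:
        near = difflib.get_close_matches(target, net.genes, n=3)
        raise ConfigurationError(
            f"unknown target {target!r}; nearest identifiers: {near}")
    i = net.genes.index(target)
    weights = net.weights.copy()
    weights[i, :] = 0.0
    weights[:, i] = 0.0
    return AdjacencyNetwork(genes=list(net.genes), weights=weights,
                            params={**net.params, "knockout": target})


@dataclass
class PerturbationProfile:
    """Per-gene perturbation scores after a virtual knockout.

    ``table`` ranks all non-target genes by descending score; the target's
    own score is reported separately and excluded from ranking.
    """

    target: str
    table: pd.DataFrame
    target_score: float
    params: dict = field(default_factory=dict)


def _diffusion(weights: np.ndarray, alpha: float, horizon: int) -> np.ndarray:
    s = np.eye(weights.shape[0])
    term = np.eye(weights.shape[0])
    a = alpha * weights
    for _ in range(horizon):
        term = term @ a
        s = s + term
    return s


def perturbation_profile(
    net: AdjacencyNetwork,
    net_ko: AdjacencyNetwork,
    alpha: float = 0.5,
    horizon: int = 3,
) -> PerturbationProfile:
    """Score genes by how much the knockout changes their accumulated
    influence profile.

    ``score(g)`` is the Euclidean distance between row g of the truncated
    diffusion operators of the intact and knocked-out networks; the robust
    z-score is (score - median) / MAD over non-target genes.
    """
    if net.genes != net_ko.genes:
        raise ConfigurationError("networks are over different gene universes")
    if "knockout" not in net_ko.params:
        raise ConfigurationError("second network is not a knockout copy")
    target = net_ko.params["knockout"]
    radius = np.max(np.abs(np.linalg.eigvals(net.weights)))
    if alpha * radius >= 1:
        warnings.warn(
            f"alpha * spectral radius = {alpha * radius:.3f} >= 1; "
            "diffusion terms are not contracting", stacklevel=2)
    s0 = _diffusion(net.weights, alpha, horizon)
    s1 = _diffusion(net_ko.weights, alpha, horizon)
    score = np.linalg.norm(s0 - s1, axis=1)
    ti = net.genes.index(target)
    others = [g for g in net.genes if g != target]
    other_scores = np.delete(score, ti)
    med = np.median(other_scores)
    mad = np.median(np.abs(other_scores - med))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(mad > 0, (other_scores - med) / mad,
                     np.where(other_scores == med, 0.0, np.inf))
    table = pd.DataFrame({"gene": others, "score": other_scores,
                          "zscore": z})
    table = table.sort_values(["score", "gene"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return PerturbationProfile(
        target=target,
        table=table,
        target_score=float(score[ti]),
        params={"alpha": alpha, "horizon": horizon, "method": METHOD_TAG},
    )


def knockout_report(
    profile: PerturbationProfile, top_n: int = 50
) -> tuple[pd.DataFrame, list[str]]:
    """Top-N perturbed genes and the companion plain gene list for
    external enrichment tools (same order as the table)."""
    if top_n < 0:
        raise ConfigurationError("top_n must be >= 0")
    if top_n > len(profile.table):
        log.info("top_n=%d exceeds %d-gene universe; truncating",
                 top_n, len(profile.table))
        top_n = len(profile.table)
    top = profile.table.head(top_n).copy()
    return top, list(top["gene"])
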