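"""Single-cell QC, signature scoring, senescence annotation and group
comparison.

Cells are held in an :class:`anndata.AnnData` (cells x genes, raw counts
in ``.X``).  QC removes barcodes outside a detected-genes window or a
mitochondrial-fraction window using strict inequalities ("less than /
more than"), so a cell sitting exactly on a boundary is retained.  Two
window presets from retinal and ECFC lifespan experiments are shipped.

Per-cell signature scores use a rank-based Mann-Whitney U statistic (the
UCell idea): genes are ranked within each cell by normalized expression,
ranks are clipped at ``r_max + 1``, and the score is one minus the
normalized U of the signature genes, so 1 means the signature occupies the
very top of the cell's transcriptome and 0 means it lies entirely beyond
the rank cap.  Being rank-based, the score is invariant to any monotone
transformation of a cell's expression profile.

Binary senescence annotation fits a two-component 1-D Gaussian mixture to
the scores; the component with the larger mean is "senescent" and cells
are labelled by posterior > 0.5.  This is a deliberately simple stand-in
for published senescence-index annotators and is tagged as such in its
output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .errors import (ConfigurationError, SignatureNotPresentError,
                     UndefinedCorrelationError)
from .signatures import GeneSignature

__all__ = [
    "QCThresholds",
    "QC_PRESETS",
    "CellScores",
    "SenescenceCall",
    "qc_filter",
    "normalize_log",
    "score_cells",
    "correlate_scores",
    "annotate_senescence",
    "compare_groups",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Barcode QC window: detected-gene counts and mitochondrial fraction."""

    min_genes: int
    max_genes: int
    min_mito: float
    max_mito: float

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ConfigurationError("min_genes must be < max_genes")
        if not self.min_mito < self.max_mito:
            raise ConfigurationError("min_mito must be < max_mito")


#: Windows quoted from the two scRNA-seq experiments this pipeline mirrors:
#: mouse retina (500-6000 genes, 1-20% mito) and the human ECFC lifespan
#: dataset (2000-9000 genes, 1-10% mito).
QC_PRESETS: dict[str, QCThresholds] = {
    "mouse-retina": QCThresholds(500, 6000, 0.01, 0.20),
    "human-ecfc": QCThresholds(2000, 9000, 0.01, 0.10),
}

_QC_CRITERIA = ("genes_low", "genes_high", "mito_high", "mito_low")


def _detected_genes(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        return np.asarray((X > 0).sum(axis=1)).ravel()
    return (np.asarray(X) > 0).sum(axis=1)


def qc_filter(
    adata: ad.AnnData, thr: QCThresholds
) -> tuple[ad.AnnData, dict]:
    """Remove cells outside the QC window.

    A cell fails if ``detected_genes < min_genes`` or ``> max_genes``, or
    ``mito_fraction > max_mito`` or ``< min_mito`` (all strict).  Each
    removed cell is attributed to the first failing criterion in the order
    genes-low, genes-high, mito-high, mito-low.  Returns the filtered
    dataset and a report with per-criterion removal counts.
    """
    detected = _detected_genes(adata)
    if "mito_fraction" not in adata.obs:
        raise ConfigurationError("cells lack a mito_fraction column")
    mito = adata.obs["mito_fraction"].to_numpy(float)

    fails = {
        "genes_low": detected < thr.min_genes,
        "genes_high": detected > thr.max_genes,
        "mito_high": mito > thr.max_mito,
        "mito_low": mito < thr.min_mito,
    }
    attributed = np.full(adata.n_obs, "", dtype=object)
    for crit in _QC_CRITERIA:
        newly = fails[crit] & (attributed == "")
        attributed[newly] = crit
    keep = attributed == ""
    report = {
        "total": int(adata.n_obs),
        "retained": int(keep.sum()),
        "removed": {crit: int((attributed == crit).sum())
                    for crit in _QC_CRITERIA},
        "thresholds": {
            "min_genes": thr.min_genes, "max_genes": thr.max_genes,
            "min_mito": thr.min_mito, "max_mito": thr.max_mito,
        },
    }
    if report["retained"] == 0:
        warnings.warn("QC filter removed every cell", stacklevel=2)
    filtered = adata[keep].copy()
    filtered.obs["detected_genes"] = detected[keep]
    return filtered, report


def normalize_log(
    adata: ad.AnnData, target_sum: float = 1e4
) -> ad.AnnData:
    """Depth-normalize each cell to ``target_sum`` total counts, then
    log1p.  The result is stored in ``layers['lognorm']``; cells with zero
    total counts are dropped with a warning."""
    X = adata.X
    if sparse.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
    else:
        totals = np.asarray(X).sum(axis=1)
    if (totals < 0).any() or (sparse.issparse(X) and (X < 0).nnz > 0):
        raise ConfigurationError("counts must be non-negative")
    empty = totals == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} zero-count cells",
                      stacklevel=2)
        adata = adata[~empty].copy()
        totals = totals[~empty]
    out = adata.copy()
    scale = target_sum / totals
    if sparse.issparse(out.X):
        norm = sparse.diags(scale) @ sparse.csr_matrix(out.X, dtype=float)
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(np.asarray(out.X, dtype=float) * scale[:, None])
    out.layers["lognorm"] = norm
    out.uns["normalize_log"] = {"target_sum": target_sum}
    return out


@dataclass
class CellScores:
    """Per-cell scores for one signature, with the method parameters that
    produced them."""

    values: pd.Series
    signature: str
    method: str = "rank-ucell"
    r_max: int = 1500

    def __len__(self) -> int:
        return self.values.size


def _cell_ranks(lognorm: np.ndarray) -> np.ndarray:
    """Descending ranks per cell (rows), average ranks on ties.

    All-zero genes tie and share the average of the bottom ranks.
    """
    return stats.rankdata(-lognorm, axis=1)


def score_cells(
    adata: ad.AnnData, sig: GeneSignature, r_max: int = 1500
) -> CellScores:
    """Rank-based signature score per cell.

    For the up-set, ranks of signature genes are clipped at ``r_max + 1``
    and summed into a Mann-Whitney U'; the score is ``1 - U'/U'_max``
    where ``U'_max`` is the largest attainable U' under the clipping, so
    the score is exactly 1 when the signature occupies the top ranks and
    exactly 0 when every signature gene lies beyond ``r_max``.  For a
    signature with a down-set the final score is score_up - score_down.
    """
    if "lognorm" not in adata.layers:
        adata = normalize_log(adata)
    lognorm = adata.layers["lognorm"]
    if sparse.issparse(lognorm):
        lognorm = lognorm.toarray()
    ranks = np.minimum(_cell_ranks(lognorm), r_max + 1)

    var_index = pd.Index(adata.var_names)

    def one_direction(genes: list[str]) -> np.ndarray | None:
        idx = var_index.get_indexer([g for g in genes if g in var_index])
        idx = idx[idx >= 0]
        if idx.size == 0:
            return None
        n = idx.size
        u = ranks[:, idx].sum(axis=1) - n * (n + 1) / 2
        u_max = n * (r_max + 1) - n * (n + 1) / 2
        return 1.0 - u / u_max

    up = one_direction(sig.up) if sig.up else None
    down = one_direction(sig.down) if sig.down else None
    if up is None and down is None:
        raise SignatureNotPresentError(
            f"no gene of signature {sig.name!r} present in the dataset")
    if up is not None and down is not None:
        score = up - down
    else:
        score = up if up is not None else -down
    return CellScores(
        values=pd.Series(score, index=adata.obs_names, name=sig.name),
        signature=sig.name,
        r_max=r_max,
    )


def correlate_scores(a: CellScores, b: CellScores) -> tuple[float, float]:
    """Pearson correlation between two per-cell score vectors with a
    two-sided t-based p-value."""
    if not a.values.index.equals(b.values.index):
        raise ConfigurationError("scores are not over the same cells")
    if len(a) < 3:
        raise ConfigurationError("need >=3 cells for correlation")
    x = a.values.to_numpy(float)
    y = b.values.to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "a score vector has zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SenescenceCall:
    """Binary senescent / non-senescent annotation of cells.

    ``method`` records that this is a Gaussian-mixture annotation, not a
    reimplementation of any published senescence-index tool.
    """

    labels: pd.Series
    posterior: pd.Series
    component_means: tuple[float, float]
    fraction_senescent: float
    group_fractions: pd.Series | None = None
    method: str = "gmm-2comp"
    fallback: bool = False


def annotate_senescence(
    scores: CellScores,
    seed: int = 0,
    groups: pd.Series | None = None,
) -> SenescenceCall:
    """Two-component Gaussian-mixture annotation of per-cell scores.

    EM with k-means initialization (``random_state=seed``), tolerance
    1e-8, at most 500 iterations.  The component with the larger mean is
    senescent; cells are labelled by posterior > 0.5.  Degenerate fits
    (component weight < 1e-3, or constant scores) fall back to a median
    split with a warning.
    """
    x = scores.values.to_numpy(float)
    if x.size < 20:
        raise ConfigurationError("need >=20 cells to fit the mixture")

    def median_split(reason: str) -> SenescenceCall:
        warnings.warn(
            f"mixture fit degenerate ({reason}); falling back to a median "
            "split", stacklevel=3)
        order = np.argsort(x, kind="stable")
        labels = np.zeros(x.size, bool)
        labels[order[x.size // 2:]] = True  # top half by score
        posterior = labels.astype(float)
        return _assemble(labels, posterior, (float(np.min(x)),
                                             float(np.max(x))), True)

    def _assemble(labels, posterior, means, fallback) -> SenescenceCall:
        lab = pd.Series(labels, index=scores.values.index, name="senescent")
        post = pd.Series(posterior, index=scores.values.index,
                         name="posterior")
        gf = None
        if groups is not None:
            gf = lab.groupby(groups.loc[lab.index], observed=True).mean()
            gf.name = "fraction_senescent"
        return SenescenceCall(
            labels=lab, posterior=post,
            component_means=(float(means[0]), float(means[1])),
            fraction_senescent=float(lab.mean()),
            group_fractions=gf, fallback=fallback)

    if np.std(x) == 0:
        return median_split("constant scores")

    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=2, covariance_type="full", tol=1e-8, max_iter=500,
        init_params="kmeans", n_init=1, random_state=seed,
    ).fit(x.reshape(-1, 1))
    if gm.weights_.min() < 1e-3:
        return median_split(f"component weight {gm.weights_.min():.2e}")
    means = gm.means_.ravel()
    hi = int(np.argmax(means))
    posterior = gm.predict_proba(x.reshape(-1, 1))[:, hi]
    labels = posterior > 0.5
    return _assemble(labels, posterior,
                     (means[1 - hi], means[hi]), False)


def compare_groups(
    scores: CellScores, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group score summaries and pairwise Mann-Whitney tests.

    Groups with fewer than 3 cells are excluded with a warning.  Pairwise
    two-sided Mann-Whitney p-values are Benjamini-Hochberg adjusted across
    the pairs.
    """
    from itertools import combinations

    from statsmodels.stats.multitest import multipletests

    aligned = groups.loc[scores.values.index]
    sizes = aligned.value_counts()
    usable = [g for g in sizes.index if sizes[g] >= 3]
    dropped = [g for g in sizes.index if sizes[g] < 3]
    if dropped:
        warnings.warn(f"groups excluded with <3 cells: {dropped}",
                      stacklevel=2)
    if len(usable) < 2:
        raise ConfigurationError("need >=2 groups with >=3 cells")
    order = [g for g in (aligned.cat.categories
                         if isinstance(aligned.dtype, pd.CategoricalDtype)
                         else sorted(sizes.index)) if g in usable]
    by_group = {g: scores.values[aligned == g].to_numpy(float)
                for g in order}
    summary = pd.DataFrame(
        {
            "group": order,
            "n": [by_group[g].size for g in order],
            "mean": [by_group[g].mean() for g in order],
            "median": [np.median(by_group[g]) for g in order],
        }
    )
    rows = []
    for a, b in combinations(order, 2):
        u, p = stats.mannwhitneyu(by_group[a], by_group[b],
                                  alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "u_stat": float(u),
                     "p_value": float(p),
                     "median_diff": float(np.median(by_group[a])
                                          - np.median(by_group[b]))})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p_value"],
                                      method="fdr_bh")[1]
    return summary, pairwise
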