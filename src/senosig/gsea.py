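"""Preranked gene-set enrichment: running-sum ES, permutation NES, and a
multi-signature/multi-dataset benchmarking harness.

The enrichment score is the classical weighted Kolmogorov-Smirnov running
sum: walking down the ranked list, hitting a set member increments the sum
by that gene's weighted metric share, missing decrements by 1/(N - N_hit);
the ES is the running-sum value of maximal absolute deviation from zero.
Significance and normalization come from a gene-label permutation null
(random same-size sets), appropriate when datasets have too few samples
for phenotype permutation.  NES divides the ES by the mean |ES| of
same-sign null scores, and the permutation p-value uses the standard +1
smoothing so it is never exactly zero.

Also provides the interferon signature metric (ISM): a per-sample summary
of an ISG panel, computed as the median of per-gene z-scores relative to a
reference condition.  The exact normalization used by the original
clinical metric is not public; median-of-z is a documented stand-in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexp import BulkExpression, _welch
from .errors import (ConfigurationError, InsufficientReplicationError,
                     UndefinedScoreError)
from .signatures import GeneSignature

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "normalized_enrichment",
    "benchmark",
    "ism_score",
    "write_rnk",
]

log = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes sorted by a ranking metric, descending.

    Ties in the metric are broken lexicographically by gene id so the
    order (and hence the ES) is deterministic.
    """

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.size != self.metric.size:
            raise ConfigurationError("genes and metric lengths differ")
        if pd.Index(self.genes).duplicated().any():
            raise ConfigurationError("ranked list contains duplicate genes")
        if np.any(np.diff(self.metric) > 0):
            raise ConfigurationError("metric must be sorted descending")

    def __len__(self) -> int:
        return self.genes.size


@dataclass
class EnrichmentResult:
    signature_name: str
    es: float
    nes: float
    p_perm: float
    n_perm: int
    leading_edge: list[str] = field(default_factory=list)
    seed: int | None = None


def rank_genes(
    expr: BulkExpression, contrast: tuple[str, str] = ("senescent", "EP")
) -> RankedList:
    """Rank all genes by the Welch t-statistic of ``contrast[0]`` vs
    ``contrast[1]`` (all models pooled)."""
    cond_hi, cond_lo = contrast
    hi = expr.samples.index[expr.samples["condition"] == cond_hi]
    lo = expr.samples.index[expr.samples["condition"] == cond_lo]
    if len(hi) < 2 or len(lo) < 2:
        raise InsufficientReplicationError(
            f"need >=2 samples per condition, have {len(hi)} {cond_hi!r} "
            f"and {len(lo)} {cond_lo!r}")
    t, _ = _welch(expr.values[hi].to_numpy(float),
                  expr.values[lo].to_numpy(float))
    order = pd.DataFrame({"gene": expr.genes, "t": t}).sort_values(
        ["t", "gene"], ascending=[False, True], kind="stable")
    return RankedList(genes=order["gene"].to_numpy(),
                      metric=order["t"].to_numpy())


def _es_core(
    metric: np.ndarray, mask: np.ndarray, weight_exponent: float
) -> tuple[float, np.ndarray, int]:
    """ES, running sum and extremum index for a boolean hit mask."""
    n = metric.size
    n_hit = int(mask.sum())
    w = np.abs(metric) ** weight_exponent
    denom = w[mask].sum()
    steps = np.empty(n)
    if denom > 0:
        steps[mask] = w[mask] / denom
    else:  # all hit metrics are zero: fall back to equal increments
        steps[mask] = 1.0 / n_hit
    steps[~mask] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    i_star = int(np.argmax(np.abs(running)))
    return float(running[i_star]), running, i_star


def enrichment_score(
    ranked: RankedList,
    gene_set: set[str] | list[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted KS enrichment score of ``gene_set`` on ``ranked``.

    Returns ``(es, running_sum, hit_indices)``.  Raises
    :class:`UndefinedScoreError` if the set has no gene in the list or
    covers the whole list.
    """
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranked.genes), bool,
                       len(ranked))
    n_hit = int(mask.sum())
    if n_hit == 0 or n_hit == len(ranked):
        raise UndefinedScoreError(
            f"gene set of size {len(members)} hits {n_hit} of "
            f"{len(ranked)} ranked genes; ES undefined")
    es, running, _ = _es_core(ranked.metric, mask, weight_exponent)
    return es, running, np.flatnonzero(mask)


def leading_edge(
    ranked: RankedList,
    gene_set: set[str] | list[str],
    weight_exponent: float = 1.0,
) -> list[str]:
    """Set members at or before (positive ES) / at or after (negative ES)
    the running-sum extremum."""
    members = set(gene_set)
    mask = np.fromiter((g in members for g in ranked.genes), bool,
                       len(ranked))
    es, _, i_star = _es_core(ranked.metric, mask, weight_exponent)
    if es > 0:
        sel = mask & (np.arange(len(ranked)) <= i_star)
    elif es < 0:
        sel = mask & (np.arange(len(ranked)) >= i_star)
    else:
        return []
    return list(ranked.genes[sel])


def normalized_enrichment(
    ranked: RankedList,
    gene_set: set[str] | list[str],
    n_perm: int = 1000,
    seed: int | None = 0,
    weight_exponent: float = 1.0,
    signature_name: str = "",
) -> EnrichmentResult:
    """ES with gene-label permutation NES and p-value.

    The null draws ``n_perm`` random gene sets of the same effective size
    (without replacement from the ranked universe).  NES = ES divided by
    the mean |null ES| over nulls of the same sign; the p-value is the
    +1-smoothed fraction of same-sign nulls at least as extreme.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    es, _, hit_idx = enrichment_score(ranked, gene_set, weight_exponent)
    n = len(ranked)
    n_hit = hit_idx.size
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n, bool)
        mask[rng.choice(n, n_hit, replace=False)] = True
        null[i], _, _ = _es_core(ranked.metric, mask, weight_exponent)
    if es == 0:
        return EnrichmentResult(signature_name, 0.0, 0.0, 1.0, n_perm,
                                [], seed)
    same = null[np.sign(null) == np.sign(es)]
    if same.size == 0:
        warnings.warn("no same-sign permutation scores; NES undefined",
                      stacklevel=2)
        nes = float("nan")
        p = 1.0 / (1.0 + 0)
    else:
        nes = es / np.abs(same).mean()
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + same.size)
    return EnrichmentResult(
        signature_name=signature_name,
        es=es,
        nes=float(nes),
        p_perm=float(p),
        n_perm=n_perm,
        leading_edge=leading_edge(ranked, gene_set, weight_exponent),
        seed=seed,
    )


def benchmark(
    signatures: list[GeneSignature],
    datasets: list[tuple[BulkExpression, tuple[str, str]]],
    dataset_names: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Score every signature direction on every dataset.

    Returns a long table with one row per (signature, direction, dataset):
    ``signature, direction, dataset, es, nes, p_perm, n_leading_edge``.
    Each cell gets its own deterministic seed offset.  Signature directions
    with no genes in a dataset are skipped (logged).
    """
    if not signatures or not datasets:
        raise ConfigurationError("need >=1 signature and >=1 dataset")
    if dataset_names is None:
        dataset_names = [f"dataset{i + 1}" for i in range(len(datasets))]
    rows = []
    cell = 0
    for ds_name, (expr, contrast) in zip(dataset_names, datasets):
        ranked = rank_genes(expr, contrast)
        universe = set(ranked.genes)
        for sig in signatures:
            for direction, genes in (("up", sig.up), ("down", sig.down)):
                cell += 1
                present = [g for g in genes if g in universe]
                if not present:
                    log.info("signature %s_%s has no genes in %s; skipped",
                             sig.name, direction, ds_name)
                    continue
                res = normalized_enrichment(
                    ranked, present, n_perm=n_perm, seed=seed + cell,
                    weight_exponent=weight_exponent,
                    signature_name=f"{sig.name}_{direction}")
                rows.append({
                    "signature": sig.name,
                    "direction": direction,
                    "dataset": ds_name,
                    "es": res.es,
                    "nes": res.nes,
                    "p_perm": res.p_perm,
                    "n_leading_edge": len(res.leading_edge),
                })
    return pd.DataFrame(rows)


def ism_score(
    expr: BulkExpression,
    isg_panel: set[str] | list[str],
    reference_condition: str = "EP",
) -> pd.Series:
    """Interferon signature metric: per-sample median z-score of an ISG
    panel, standardized against the reference condition.

    Panel genes absent from the dataset or with zero reference SD are
    dropped with a warning.
    """
    ref = expr.samples.index[expr.samples["condition"] == reference_condition]
    if len(ref) < 2:
        raise InsufficientReplicationError(
            f"reference condition {reference_condition!r} has "
            f"{len(ref)} samples; need >=2")
    panel = [g for g in isg_panel if g in expr.genes]
    if not panel:
        raise ConfigurationError("no panel gene present in the dataset")
    sub = expr.values.loc[panel]
    mu = sub[ref].mean(axis=1)
    sd = sub[ref].std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} panel genes with zero reference SD "
            "dropped", stacklevel=2)
        sub, mu, sd = sub[~degenerate], mu[~degenerate], sd[~degenerate]
        if sub.empty:
            raise ConfigurationError(
                "all panel genes degenerate in the reference condition")
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    return z.median(axis=0).rename("ism")


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    """Export a ranked list in RNK format (gene TAB metric)."""
    lines = [f"{g}\t{m:.6g}" for g, m in zip(ranked.genes, ranked.metric)]
    Path(path).write_text("\n".join(lines) + "\n")
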