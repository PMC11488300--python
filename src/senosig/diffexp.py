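"""Per-model differential expression and consensus-signature derivation.

Each senescence-induction model is tested separately: per gene, a Welch
two-sample t-test (or a donor-paired t-test) of senescent vs early-passage
log2 values, with the conventional microarray gates |log2FC| > 1.0 and
p < 0.05 (strict inequalities, no multiple-testing correction by default —
the gate is a fold-change/p-value compound, not an FDR).  The consensus
signature is the intersection of per-model significant sets: genes up in
every model form the up signature, genes down in every model the down
signature, ordered by mean log2 fold change across models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientReplicationError
from .signatures import GeneSignature

__all__ = [
    "BulkExpression",
    "differential_expression",
    "derive_consensus",
    "top_signature_genes",
    "intersect_with_treatment",
]

log = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "t_stat", "p_value",
              "significant_up", "significant_down"]


@dataclass
class BulkExpression:
    """Log2 expression values (genes x samples) with sample annotations.

    ``samples`` is indexed by sample id with columns ``donor``, ``model``
    and ``condition`` (``EP``, ``senescent`` or a treatment label such as
    ``IFN``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            if set(self.values.columns) != set(self.samples.index):
                raise ConfigurationError(
                    "expression columns and sample annotations do not match")
            self.samples = self.samples.loc[self.values.columns]
        if self.values.isna().any().any():
            raise ConfigurationError("expression table contains missing values")
        if self.values.index.duplicated().any():
            raise ConfigurationError("gene identifiers are not unique")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset(self, model: str) -> "BulkExpression":
        keep = self.samples.index[self.samples["model"] == model]
        return BulkExpression(values=self.values[keep],
                              samples=self.samples.loc[keep])


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test of per-gene rows ``a`` vs ``b``.

    Degenerate genes (zero variance in both arms) get t = 0, p = 1 when the
    means agree, else an infinite statistic with p = 0.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    bad = ~np.isfinite(t)
    if bad.any():
        log.info("%d genes with zero variance in both arms; p set by "
                 "convention", int(bad.sum()))
        t = np.where(bad, np.where(diff == 0, 0.0,
                                   np.sign(diff) * np.inf), t)
        p = np.where(bad, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def _paired(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_rel(a, b, axis=1)
    diff = (a - b).mean(axis=1)
    bad = ~np.isfinite(t)
    if bad.any():
        t = np.where(bad, np.where(diff == 0, 0.0,
                                   np.sign(diff) * np.inf), t)
        p = np.where(bad, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def differential_expression(
    expr: BulkExpression,
    model: str,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    paired: bool = False,
    conditions: tuple[str, str] = ("senescent", "EP"),
    fdr: bool = False,
) -> pd.DataFrame:
    """Differential expression of ``conditions[0]`` vs ``conditions[1]``
    within one model.

    Returns one row per gene in the input gene order with columns
    ``gene, log2fc, t_stat, p_value, significant_up, significant_down``.
    ``log2fc`` is mean(first condition) - mean(second condition).
    Significance requires ``p < p_threshold`` and ``log2fc`` beyond
    ``+/- fc_threshold`` (strict).  With ``fdr=True`` the p gate is applied
    to Benjamini-Hochberg adjusted p-values instead of raw ones.
    """
    sub = expr.samples[expr.samples["model"] == model]
    cond_hi, cond_lo = conditions
    hi = sub.index[sub["condition"] == cond_hi]
    lo = sub.index[sub["condition"] == cond_lo]
    if len(hi) < 2 or len(lo) < 2:
        raise InsufficientReplicationError(
            f"model {model!r}: need >=2 samples per arm, have "
            f"{len(hi)} {cond_hi!r} and {len(lo)} {cond_lo!r}"
        )
    a = expr.values[hi].to_numpy(float)
    b = expr.values[lo].to_numpy(float)
    if paired:
        donors_hi = sub.loc[hi, "donor"]
        donors_lo = sub.loc[lo, "donor"]
        if sorted(donors_hi) != sorted(donors_lo) or donors_hi.duplicated().any():
            raise ConfigurationError(
                f"model {model!r}: samples do not pair one-to-one by donor")
        a = expr.values[hi[np.argsort(donors_hi.to_numpy())]].to_numpy(float)
        b = expr.values[lo[np.argsort(donors_lo.to_numpy())]].to_numpy(float)
        t, p = _paired(a, b)
    else:
        t, p = _welch(a, b)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    p_gate = p
    if fdr:
        from statsmodels.stats.multitest import multipletests
        p_gate = multipletests(p, method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "gene": expr.genes,
            "log2fc": log2fc,
            "t_stat": t,
            "p_value": p,
            "significant_up": (log2fc > fc_threshold) & (p_gate < p_threshold),
            "significant_down": (log2fc < -fc_threshold) & (p_gate < p_threshold),
        }
    ).reset_index(drop=True)
    return result


def _flagged(res: pd.DataFrame, column: str) -> set[str]:
    return set(res.loc[res[column], "gene"])


def _mean_log2fc(per_model_results: dict[str, pd.DataFrame]) -> pd.Series:
    stacked = pd.concat(
        [r.set_index("gene")["log2fc"] for r in per_model_results.values()],
        axis=1,
    )
    return stacked.mean(axis=1)


def _ordered(genes: set[str], mean_fc: pd.Series, descending: bool) -> list[str]:
    # primary key mean log2FC, ties broken lexicographically by gene id
    key = mean_fc.reindex(sorted(genes))
    return list(key.sort_values(ascending=not descending,
                                kind="stable").index)


def derive_consensus(
    per_model_results: dict[str, pd.DataFrame], name: str = "consensus"
) -> tuple[GeneSignature, dict]:
    """Intersect per-model significant sets into a consensus signature.

    ``overlap_counts`` reports the Euler decomposition of the significant
    sets for both directions: per-model totals, every pairwise
    intersection, and the full intersection.
    """
    if len(per_model_results) < 2:
        raise ConfigurationError("derive_consensus requires >=2 models")
    up_sets = {m: _flagged(r, "significant_up")
               for m, r in per_model_results.items()}
    down_sets = {m: _flagged(r, "significant_down")
                 for m, r in per_model_results.items()}

    def euler(sets: dict[str, set[str]]) -> dict:
        models = list(sets)
        counts = {
            "per_model": {m: len(sets[m]) for m in models},
            "pairwise": {
                f"{a}&{b}": len(sets[a] & sets[b])
                for a, b in combinations(models, 2)
            },
            "full": len(set.intersection(*sets.values())),
        }
        return counts

    up = set.intersection(*up_sets.values())
    down = set.intersection(*down_sets.values())
    if not up and not down:
        warnings.warn(f"consensus signature {name!r} is empty", stacklevel=2)
    mean_fc = _mean_log2fc(per_model_results)
    signature = GeneSignature(
        name=name,
        up=_ordered(up, mean_fc, descending=True),
        down=_ordered(down, mean_fc, descending=False),
    )
    overlap_counts = {"up": euler(up_sets), "down": euler(down_sets)}
    return signature, overlap_counts


def top_signature_genes(
    sig: GeneSignature,
    per_model_results: dict[str, pd.DataFrame],
    n: int = 20,
) -> pd.DataFrame:
    """First ``n`` up-signature genes by descending mean log2FC.

    Ties are broken lexicographically by gene id.  If ``n`` exceeds the
    signature size the whole up-set is returned (logged).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    mean_fc = _mean_log2fc(per_model_results)
    ordered = _ordered(set(sig.up), mean_fc, descending=True)
    if n > len(ordered):
        log.info("requested top %d of a %d-gene up-set; returning all",
                 n, len(ordered))
        n = len(ordered)
    top = ordered[:n]
    return pd.DataFrame({"gene": top,
                         "mean_log2fc": mean_fc.reindex(top).to_numpy()})


def intersect_with_treatment(
    consensus: GeneSignature, treatment_results: pd.DataFrame
) -> tuple[list[str], list[str]]:
    """Overlap of the consensus signature with a treatment's DE genes.

    Returns the consensus-ordered lists of consensus-up genes that are
    also significantly up under the treatment, and consensus-down genes
    also significantly down.
    """
    treat_up = _flagged(treatment_results, "significant_up")
    treat_down = _flagged(treatment_results, "significant_down")
    up_overlap = [g for g in consensus.up if g in treat_up]
    down_overlap = [g for g in consensus.down if g in treat_down]
    return up_overlap, down_overlap
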