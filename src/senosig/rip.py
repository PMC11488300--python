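"""RIP-qPCR quantification: percent-input normalization, delta-delta-Ct,
and fold enrichment.

Each immunoprecipitated fraction (specific antibody, RIP; non-specific
IgG, NS) is normalized to the input fraction.  Because only a percentage
of the input is assayed (1% by default, i.e. a 100x dilution), the input
Ct is first shifted down by log2(dilution factor) to represent 100% of
the material:

    dCt[fraction]  = Ct[fraction] - (Ct[input] - log2(dilution))
    ddCt[RIP/NS]   = dCt[RIP] - dCt[NS]
    fold           = 2 ** (-ddCt[RIP/NS])

Fold enrichment is therefore > 1 when the specific antibody pulls down
more target RNA than the isotype control.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = ["normalized_dct", "fold_enrichment", "analyze_rip_table",
           "read_ct_table", "write_fold_table"]

FRACTIONS = ("RIP", "NS", "input")


def normalized_dct(
    ct_fraction: float, ct_input: float, dilution_factor: float = 100.0
) -> float:
    """Ct of a fraction relative to the dilution-adjusted input."""
    if not (math.isfinite(ct_fraction) and math.isfinite(ct_input)):
        raise ConfigurationError("Ct values must be finite")
    if not (math.isfinite(dilution_factor) and dilution_factor > 0):
        raise ConfigurationError("dilution_factor must be > 0")
    return ct_fraction - (ct_input - math.log2(dilution_factor))


def fold_enrichment(dct_rip: float, dct_ns: float) -> float:
    """Fold enrichment of the specific pulldown over the control,
    2^-(dCt_RIP - dCt_NS)."""
    if not (math.isfinite(dct_rip) and math.isfinite(dct_ns)):
        raise ConfigurationError("delta-Ct values must be finite")
    return 2.0 ** (-(dct_rip - dct_ns))


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table CSV with columns target, fraction, antibody, ct."""
    table = pd.read_csv(path)
    required = {"target", "fraction", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"Ct table lacks columns: {sorted(missing)}")
    if "antibody" not in table.columns:
        table["antibody"] = "RIP"
    return table


def analyze_rip_table(
    table: pd.DataFrame,
    dilution_factor: float = 100.0,
    replicate_policy: str = "mean_ct",
) -> pd.DataFrame:
    """Fold enrichment per target (and antibody) from a long Ct table.

    ``table`` has columns ``target``, ``fraction`` (RIP / NS / input),
    optional ``antibody``, and ``ct``.  Technical replicates of the same
    target x fraction are averaged on the Ct scale before the delta-delta
    computation (``replicate_policy='mean_ct'``, the default) or carried
    through as per-replicate folds that are then averaged
    (``'mean_fold'``; requires equal replicate counts per fraction, paired
    in row order).
    """
    if replicate_policy not in ("mean_ct", "mean_fold"):
        raise ConfigurationError(
            f"unknown replicate_policy {replicate_policy!r}")
    bad = set(table["fraction"]) - set(FRACTIONS)
    if bad:
        raise ConfigurationError(
            f"unknown fractions {sorted(bad)}; expected {FRACTIONS}")
    if table["ct"].isna().any() or ~np.isfinite(table["ct"]).all():
        raise ConfigurationError("Ct table contains non-finite values")
    if "antibody" not in table.columns:
        table = table.assign(antibody="RIP")

    rows = []
    for (target, antibody), grp in table.groupby(
            ["target", "antibody"], sort=True):
        cts = {f: grp.loc[grp["fraction"] == f, "ct"].to_numpy(float)
               for f in FRACTIONS}
        if cts["input"].size == 0:
            raise ConfigurationError(
                f"target {target!r}: no input-fraction Ct")
        if cts["RIP"].size == 0 and cts["NS"].size == 0:
            raise ConfigurationError(
                f"target {target!r}: need a RIP or NS Ct")
        if replicate_policy == "mean_ct" or cts["RIP"].size != cts["NS"].size:
            ct_in = cts["input"].mean()
            dct_rip = (normalized_dct(cts["RIP"].mean(), ct_in,
                                      dilution_factor)
                       if cts["RIP"].size else np.nan)
            dct_ns = (normalized_dct(cts["NS"].mean(), ct_in,
                                     dilution_factor)
                      if cts["NS"].size else np.nan)
            fold = (fold_enrichment(dct_rip, dct_ns)
                    if np.isfinite(dct_rip) and np.isfinite(dct_ns)
                    else np.nan)
        else:  # per-replicate folds, averaged
            ct_in = cts["input"].mean()
            dcts_rip = np.array([
                normalized_dct(c, ct_in, dilution_factor)
                for c in cts["RIP"]])
            dcts_ns = np.array([
                normalized_dct(c, ct_in, dilution_factor)
                for c in cts["NS"]])
            folds = 2.0 ** (-(dcts_rip - dcts_ns))
            dct_rip, dct_ns = dcts_rip.mean(), dcts_ns.mean()
            fold = folds.mean()
        rows.append({
            "target": target,
            "antibody": antibody,
            "dct_rip": dct_rip,
            "dct_ns": dct_ns,
            "ddct": (dct_rip - dct_ns
                     if np.isfinite(dct_rip) and np.isfinite(dct_ns)
                     else np.nan),
            "fold_enrichment": fold,
        })
    return pd.DataFrame(rows)


def write_fold_table(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, index=False, float_format="%.6g")
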