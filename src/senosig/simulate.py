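"""Synthetic bulk and single-cell datasets with planted senescence structure.

The bulk generator emulates a paired multi-model senescence study: three
donors, each contributing an early-passage (EP) and a senescent sample for
every induction model (replicative exhaustion, X-ray irradiation,
etoposide), on a continuous log2-intensity scale as produced by expression
microarrays.  A shared senescence program (75 up- and 209 down-regulated
genes by default) is planted across all models, each model additionally
perturbs its own private gene set, and an optional interferon-treated arm
re-uses part of the shared program — the structure needed to exercise
consensus-signature derivation and treatment-overlap analysis downstream.

The single-cell generator emulates a replicative-lifespan experiment with
four groups (proliferating EP, quiescent, mid-passage, late-passage) whose
planted senescent fractions rise from 1% to 77%.  Each cell carries a
latent signature activity and a latent SASP activity; the two are coupled
so that their empirical Pearson correlation over the QC-passing cells
equals ``target_sasp_corr`` exactly.  Counts are negative binomial
(gamma–Poisson) with a per-cell library size, and a configurable number of
QC-violating cells (too few / too many detected genes, too high / too low
mitochondrial fraction) is planted outside the configured filter window.

Every draw goes through one :class:`numpy.random.Generator`, so a fixed
seed fixes every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.io import mmread, mmwrite

from .diffexp import BulkExpression
from .errors import ConfigurationError

__all__ = [
    "BulkSimConfig",
    "ScSimConfig",
    "GroundTruth",
    "simulate_bulk",
    "simulate_cells",
    "write_bulk",
    "read_bulk",
    "write_cells",
    "read_cells",
]

#: gene-name fixture mapping a few synthetic identifiers to the interferon
#: pathway genes discussed in the docs (documentation aid only; the
#: generator itself never consults it).
EXAMPLE_GENE_ALIASES = {"G000001": "DDX58", "G000002": "IRF7", "G000003": "ISG15"}


@dataclass(frozen=True)
class BulkSimConfig:
    """Configuration of the bulk (microarray-like) simulation.

    Effects are on the log2 scale.  ``n_model_specific`` genes are planted
    per model, half up- and half down-regulated, only in that model's
    senescent arm.  When ``ifn_arm`` is set, an interferon-treated arm is
    added (its own EP controls plus IFN-treated samples per donor); the
    treatment induces ``n_ifn_overlap_up`` genes drawn from the shared up
    program, represses ``n_ifn_overlap_down`` genes from the shared down
    program, and additionally perturbs IFN-specific genes outside the
    senescence program.
    """

    n_genes: int = 5000
    n_donors: int = 3
    models: tuple[str, ...] = ("replicative", "xray", "etoposide")
    n_shared_up: int = 75
    n_shared_down: int = 209
    n_model_specific: int = 300
    effect_log2fc: float = 2.0
    residual_sd: float = 0.5
    donor_sd: float = 0.3
    ifn_arm: bool = True
    n_ifn_overlap_up: int = 19
    n_ifn_overlap_down: int = 8
    n_ifn_specific_up: int = 150
    n_ifn_specific_down: int = 50
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for fld in ("n_genes", "n_donors", "n_shared_up", "n_shared_down",
                    "n_model_specific"):
            if getattr(self, fld) <= 0:
                raise ConfigurationError(f"{fld} must be > 0")
        if len(self.models) < 1:
            raise ConfigurationError("models must name at least one model")
        if len(set(self.models)) != len(self.models):
            raise ConfigurationError("models contains duplicate labels")
        planted = (self.n_shared_up + self.n_shared_down
                   + self.n_model_specific * len(self.models))
        if self.ifn_arm:
            planted += self.n_ifn_specific_up + self.n_ifn_specific_down
        if planted > self.n_genes:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {planted} planted genes"
            )
        if self.n_ifn_overlap_up > self.n_shared_up:
            raise ConfigurationError("n_ifn_overlap_up exceeds n_shared_up")
        if self.n_ifn_overlap_down > self.n_shared_down:
            raise ConfigurationError("n_ifn_overlap_down exceeds n_shared_down")
        for fld in ("residual_sd", "donor_sd", "baseline_sd"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0")


@dataclass(frozen=True)
class ScSimConfig:
    """Configuration of the single-cell (UMI count) simulation.

    ``groups`` lists ``(label, n_cells, senescent_fraction)``; the number
    of senescent cells per group is ``round(fraction * n_cells)`` so the
    planted fractions are exact.  ``signature_shift`` is the natural-log
    fold effect of the senescent state on the planted program genes.
    ``nb_dispersion`` is the gamma–Poisson shape (larger = closer to
    Poisson).  The QC window fields define the filter applied downstream;
    normal cells are guaranteed strictly inside it and the
    ``qc_violators`` counts ``(genes_low, genes_high, mito_high,
    mito_low)`` are planted strictly outside it.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int, float], ...] = (
        ("EP_prolif", 700, 0.01),
        ("quiescent", 700, 0.0),
        ("mid", 700, 0.29),
        ("late", 700, 0.77),
    )
    n_signature_genes: int = 75
    n_sasp_genes: int = 75
    signature_shift: float = 1.5
    activity_sd: float = 0.3
    target_sasp_corr: float = 0.8
    nb_dispersion: float = 25.0
    library_size_mean: float = 10_000.0
    library_size_log_sd: float = 0.3
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    program_log_mean: float = -0.25
    program_log_sd: float = 0.5
    min_genes: int = 300
    max_genes: int = 1950
    min_mito: float = 0.01
    max_mito: float = 0.10
    qc_violators: tuple[int, int, int, int] = (10, 10, 10, 10)
    plant_driver_module: bool = False
    n_driver_targets: int = 10
    driver_coupling: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be > 0")
        if not self.groups:
            raise ConfigurationError("groups must not be empty")
        for label, n, frac in self.groups:
            if n <= 0:
                raise ConfigurationError(f"group {label!r}: n_cells must be > 0")
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"group {label!r}: senescent_fraction must be in [0, 1]"
                )
        if not -1.0 <= self.target_sasp_corr <= 1.0:
            raise ConfigurationError("target_sasp_corr must be in [-1, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.library_size_mean <= 0:
            raise ConfigurationError("library_size_mean must be > 0")
        planted = self.n_signature_genes + self.n_sasp_genes
        if self.plant_driver_module:
            if self.n_driver_targets <= 0:
                raise ConfigurationError("n_driver_targets must be > 0")
            planted += 1 + self.n_driver_targets
        if planted > self.n_genes:
            raise ConfigurationError("program gene counts exceed n_genes")
        if not self.min_genes < self.max_genes:
            raise ConfigurationError("min_genes must be < max_genes")
        if not self.min_mito < self.max_mito:
            raise ConfigurationError("min_mito must be < max_mito")
        if self.max_genes > self.n_genes - 20:
            raise ConfigurationError(
                "max_genes must leave headroom (<= n_genes - 20) for planted "
                "high-gene violators"
            )
        if any(v < 0 for v in self.qc_violators) or len(self.qc_violators) != 4:
            raise ConfigurationError(
                "qc_violators must be four non-negative counts"
            )


@dataclass
class GroundTruth:
    """Planted truth recorded exactly as generated.

    Bulk simulations fill the gene-set fields; single-cell simulations fill
    ``signature_genes``, ``sasp_genes`` and the per-cell ``cells`` table
    (group, senescent state, latent activities, planted QC failure label).
    """

    shared_up: list[str] = field(default_factory=list)
    shared_down: list[str] = field(default_factory=list)
    model_specific: dict[str, list[str]] = field(default_factory=dict)
    model_specific_up: dict[str, list[str]] = field(default_factory=dict)
    model_specific_down: dict[str, list[str]] = field(default_factory=dict)
    ifn_up: list[str] = field(default_factory=list)
    ifn_down: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)
    sasp_genes: list[str] = field(default_factory=list)
    driver_gene: str = ""
    driver_targets: list[str] = field(default_factory=list)
    cells: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in asdict(self).items() if k != "cells"}
        if self.cells is not None:
            payload["cells"] = self.cells.reset_index().to_dict(orient="list")
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        cells = payload.pop("cells", None)
        truth = cls(**payload)
        if cells is not None:
            truth.cells = pd.DataFrame(cells).set_index("barcode")
        return truth


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:06d}" for i in range(n)]


# ---------------------------------------------------------------------------
# bulk


def simulate_bulk(config: BulkSimConfig) -> tuple[BulkExpression, GroundTruth]:
    """Simulate a paired multi-model bulk senescence study.

    Returns the log2 expression table with sample annotations and the
    planted :class:`GroundTruth`.  Senescent samples of every model are
    shifted by ``+effect_log2fc`` on the shared up program and
    ``-effect_log2fc`` on the shared down program; model-specific genes are
    shifted only in that model.  A donor intercept is shared by all samples
    of a donor, and i.i.d. residual noise is added per measurement.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    perm = rng.permutation(config.n_genes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        sel = perm[cursor:cursor + n]
        cursor += n
        return [genes[i] for i in sel]

    shared_up = take(config.n_shared_up)
    shared_down = take(config.n_shared_down)
    model_up: dict[str, list[str]] = {}
    model_down: dict[str, list[str]] = {}
    for model in config.models:
        spec = take(config.n_model_specific)
        half = config.n_model_specific // 2
        model_up[model] = spec[:half]
        model_down[model] = spec[half:]
    if config.ifn_arm:
        ifn_specific_up = take(config.n_ifn_specific_up)
        ifn_specific_down = take(config.n_ifn_specific_down)
        ifn_up = [shared_up[i] for i in rng.choice(
            config.n_shared_up, config.n_ifn_overlap_up, replace=False)]
        ifn_down = [shared_down[i] for i in rng.choice(
            config.n_shared_down, config.n_ifn_overlap_down, replace=False)]
    else:
        ifn_specific_up = ifn_specific_down = []
        ifn_up = ifn_down = []

    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          config.n_genes)
    donors = [f"d{i + 1}" for i in range(config.n_donors)]
    donor_effect = dict(zip(donors, rng.normal(0.0, config.donor_sd,
                                               config.n_donors)))

    sample_ids: list[str] = []
    annotations: list[dict] = []
    shifts: list[np.ndarray] = []
    eff = config.effect_log2fc

    def senescence_shift(model: str) -> np.ndarray:
        shift = np.zeros(config.n_genes)
        for g in shared_up:
            shift[gene_index[g]] += eff
        for g in shared_down:
            shift[gene_index[g]] -= eff
        for g in model_up[model]:
            shift[gene_index[g]] += eff
        for g in model_down[model]:
            shift[gene_index[g]] -= eff
        return shift

    for model in config.models:
        sen_shift = senescence_shift(model)
        for condition in ("EP", "senescent"):
            for donor in donors:
                sample_ids.append(f"{model}_{condition}_{donor}")
                annotations.append(
                    {"donor": donor, "model": model, "condition": condition}
                )
                shifts.append(sen_shift if condition == "senescent"
                              else np.zeros(config.n_genes))
    if config.ifn_arm:
        ifn_shift = np.zeros(config.n_genes)
        for g in list(ifn_up) + list(ifn_specific_up):
            ifn_shift[gene_index[g]] += eff
        for g in list(ifn_down) + list(ifn_specific_down):
            ifn_shift[gene_index[g]] -= eff
        for condition in ("EP", "IFN"):
            for donor in donors:
                sample_ids.append(f"ifn_{condition}_{donor}")
                annotations.append(
                    {"donor": donor, "model": "ifn", "condition": condition}
                )
                shifts.append(ifn_shift if condition == "IFN"
                              else np.zeros(config.n_genes))

    n_samples = len(sample_ids)
    noise = rng.normal(0.0, config.residual_sd, (config.n_genes, n_samples))
    values = baseline[:, None] + noise
    for j, (ann, shift) in enumerate(zip(annotations, shifts)):
        values[:, j] += donor_effect[ann["donor"]] + shift

    expr = BulkExpression(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        samples=pd.DataFrame(annotations, index=sample_ids),
    )
    truth = GroundTruth(
        shared_up=shared_up,
        shared_down=shared_down,
        model_specific={m: model_up[m] + model_down[m] for m in config.models},
        model_specific_up=model_up,
        model_specific_down=model_down,
        ifn_up=list(ifn_up),
        ifn_down=list(ifn_down),
    )
    return expr, truth


# ---------------------------------------------------------------------------
# single cell


def _exact_corr_pair(
    primary: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Return a vector whose empirical Pearson correlation with ``primary``
    is exactly ``rho`` (up to floating point), on the same mean/scale.

    The companion is built from standardized ``primary`` plus an
    empirically orthogonalized noise vector, so the realized (not just
    expected) correlation equals the target.
    """
    s = primary - primary.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ConfigurationError("primary latent activity has zero variance")
    s = s / s.std()
    if abs(rho) == 1.0:
        companion_std = np.sign(rho) * s
    else:
        e = rng.normal(size=primary.size)
        e = e - e.mean()
        e = e - (e @ s) / (s @ s) * s  # exact empirical orthogonality
        e = e / e.std()
        companion_std = rho * s + np.sqrt(1.0 - rho**2) * e
    return primary.mean() + primary.std() * companion_std


def simulate_cells(config: ScSimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a four-group replicative-lifespan scRNA-seq dataset.

    Returns an :class:`anndata.AnnData` (cells x genes, sparse integer
    counts; per-cell ``group``, ``detected_genes`` and ``mito_fraction``
    in ``.obs``) and the planted :class:`GroundTruth` with per-cell latent
    states.  QC-violating cells are appended after the group cells and
    guaranteed to fall strictly outside the configured QC window, while
    every normal cell is guaranteed strictly inside it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)

    # planted program membership
    perm = rng.permutation(config.n_genes)
    sig_idx = perm[:config.n_signature_genes]
    sasp_idx = perm[config.n_signature_genes:
                    config.n_signature_genes + config.n_sasp_genes]
    cursor = config.n_signature_genes + config.n_sasp_genes
    if config.plant_driver_module:
        driver_idx = int(perm[cursor])
        target_idx = perm[cursor + 1:cursor + 1 + config.n_driver_targets]
    else:
        driver_idx, target_idx = None, np.array([], dtype=int)

    # group cells with exact planted senescent counts
    labels: list[str] = []
    states: list[int] = []
    for label, n_cells, frac in config.groups:
        n_sen = int(round(frac * n_cells))
        labels += [label] * n_cells
        states += [1] * n_sen + [0] * (n_cells - n_sen)
    state = np.asarray(states)
    n_normal = state.size

    sig_act = state * config.signature_shift + rng.normal(
        0.0, config.activity_sd, n_normal)
    sasp_act = _exact_corr_pair(sig_act, config.target_sasp_corr, rng)

    # violators are non-senescent cells appended after the group cells
    n_low, n_high, n_mhigh, n_mlow = config.qc_violators
    n_viol = n_low + n_high + n_mhigh + n_mlow
    viol_groups = [config.groups[i % len(config.groups)][0]
                   for i in range(n_viol)]
    viol_sig = rng.normal(0.0, config.activity_sd, n_viol)
    viol_sasp = rng.normal(0.0, config.activity_sd, n_viol)

    all_sig = np.concatenate([sig_act, viol_sig])
    all_sasp = np.concatenate([sasp_act, viol_sasp])
    all_labels = labels + viol_groups
    n_cells_total = n_normal + n_viol

    # baseline gene weights; program genes kept moderately expressed so
    # their ranks stay responsive to activity rather than saturating
    log_w = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                       config.n_genes)
    log_w[sig_idx] = rng.normal(config.program_log_mean,
                                config.program_log_sd,
                                config.n_signature_genes)
    log_w[sasp_idx] = rng.normal(config.program_log_mean,
                                 config.program_log_sd, config.n_sasp_genes)
    weights = np.exp(log_w)

    lib = np.exp(rng.normal(np.log(config.library_size_mean),
                            config.library_size_log_sd, n_cells_total))

    log_rate = np.tile(np.log(weights)[:, None], (1, n_cells_total))
    log_rate[sig_idx, :] += all_sig[None, :]
    log_rate[sasp_idx, :] += all_sasp[None, :]
    if driver_idx is not None:
        # regulator module: a driver gene whose per-cell activity is
        # propagated into its target genes' rates
        driver_act = rng.normal(0.0, 1.0, n_cells_total)
        log_rate[driver_idx, :] += driver_act
        log_rate[target_idx, :] += config.driver_coupling * driver_act[None, :]
    rate = np.exp(log_rate)
    rate /= rate.sum(axis=0, keepdims=True)
    mean = rate * lib[None, :]
    theta = config.nb_dispersion
    counts = rng.poisson(rng.gamma(theta, mean / theta)).astype(np.int64)

    # mitochondrial fraction: simulated directly as metadata
    logit = np.log(0.04 / 0.96)
    mito = 1.0 / (1.0 + np.exp(-(rng.normal(logit, 0.3, n_cells_total))))
    mito = np.clip(mito, config.min_mito + 0.005, config.max_mito - 0.005)

    # plant violators and enforce the QC window exactly
    qc_fail = np.array(["none"] * n_cells_total, dtype=object)
    v0 = n_normal
    slices = {
        "genes_low": slice(v0, v0 + n_low),
        "genes_high": slice(v0 + n_low, v0 + n_low + n_high),
        "mito_high": slice(v0 + n_low + n_high, v0 + n_low + n_high + n_mhigh),
        "mito_low": slice(v0 + n_low + n_high + n_mhigh, n_cells_total),
    }
    for reason, sl in slices.items():
        qc_fail[sl] = reason

    low_target = max(config.min_genes - 100, 1)
    high_target = min(config.max_genes + 50, config.n_genes)
    for c in range(*slices["genes_low"].indices(n_cells_total)):
        _force_detected(counts, c, low_target, rng)
    for c in range(*slices["genes_high"].indices(n_cells_total)):
        _force_detected(counts, c, high_target, rng)
    mito[slices["mito_high"]] = rng.uniform(
        config.max_mito + 0.02, min(config.max_mito + 0.25, 0.9),
        n_mhigh)
    mito[slices["mito_low"]] = rng.uniform(0.0, config.min_mito / 2, n_mlow)

    # clamp any cell that is not a planted gene-count violator (normal or
    # mito violator) into the detected-genes window, so each violator
    # fails exactly its intended criterion
    detected = (counts > 0).sum(axis=0)
    gene_violator = np.zeros(n_cells_total, bool)
    gene_violator[slices["genes_low"]] = True
    gene_violator[slices["genes_high"]] = True
    for c in np.flatnonzero(~gene_violator):
        if detected[c] < config.min_genes:
            _force_detected(counts, c, config.min_genes + 20, rng)
        elif detected[c] > config.max_genes:
            _force_detected(counts, c, config.max_genes - 20, rng)
    detected = (counts > 0).sum(axis=0)

    barcodes = [f"BC{i + 1:05d}" for i in range(n_cells_total)]
    obs = pd.DataFrame(
        {
            "group": pd.Categorical(
                all_labels, categories=[g[0] for g in config.groups]),
            "detected_genes": detected,
            "mito_fraction": mito,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.T),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["simulation"] = {"kind": "lifespan", "seed": config.seed}

    truth_cells = pd.DataFrame(
        {
            "group": all_labels,
            "senescent": np.concatenate(
                [state, np.zeros(n_viol, dtype=int)]).astype(bool),
            "sig_activity": all_sig,
            "sasp_activity": all_sasp,
            "qc_fail": qc_fail,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    truth = GroundTruth(
        signature_genes=[genes[i] for i in sig_idx],
        sasp_genes=[genes[i] for i in sasp_idx],
        driver_gene=genes[driver_idx] if driver_idx is not None else "",
        driver_targets=[genes[i] for i in target_idx],
        cells=truth_cells,
    )
    return adata, truth


def _force_detected(
    counts: np.ndarray, cell: int, target: int, rng: np.random.Generator
) -> None:
    """Force a cell's number of detected genes to exactly ``target``.

    Keeps the highest-count genes when shrinking and lights up zero-count
    genes (one unit each, in a seeded random order) when growing.
    """
    col = counts[:, cell]
    nz = np.flatnonzero(col)
    if nz.size > target:
        order = nz[np.argsort(col[nz], kind="stable")]
        col[order[: nz.size - target]] = 0
    elif nz.size < target:
        zeros = np.flatnonzero(col == 0)
        add = rng.permutation(zeros)[: target - nz.size]
        col[add] = 1
    counts[:, cell] = col


# ---------------------------------------------------------------------------
# on-disk formats


def write_bulk(expr: BulkExpression, out_dir: str | Path) -> None:
    """Write a bulk dataset as ``expression.tsv`` + ``samples.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(out / "expression.tsv", sep="\t",
                       index_label="gene", float_format="%.6f")
    expr.samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample")


def read_bulk(in_dir: str | Path) -> BulkExpression:
    src = Path(in_dir)
    values = pd.read_csv(src / "expression.tsv", sep="\t", index_col="gene")
    samples = pd.read_csv(src / "samples.tsv", sep="\t", index_col="sample")
    return BulkExpression(values=values, samples=samples)


def write_cells(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write a cell dataset as an MTX triplet plus a cell-metadata TSV.

    ``matrix.mtx`` is genes x cells (CellRanger orientation) with
    ``genes.tsv`` and ``barcodes.tsv``; per-cell metadata goes to
    ``cells.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sparse.csc_matrix(adata.X.T)
    mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    (out / "genes.tsv").write_text(
        "\n".join(adata.var_names) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    adata.obs.to_csv(out / "cells.tsv", sep="\t", index_label="barcode")


def read_cells(in_dir: str | Path) -> ad.AnnData:
    src = Path(in_dir)
    mat = mmread(str(src / "matrix.mtx"))
    genes = (src / "genes.tsv").read_text().splitlines()
    barcodes = (src / "barcodes.tsv").read_text().splitlines()
    obs = pd.read_csv(src / "cells.tsv", sep="\t", index_col="barcode")
    obs = obs.loc[barcodes]
    adata = ad.AnnData(
        X=sparse.csr_matrix(mat.T),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata
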