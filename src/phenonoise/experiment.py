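"""The full noise-robustness experiment.

For each noise proportion and replicate: stratified 70/30 train/test
split, training-only monomorphic/collinearity edits, label flips injected
into the *training* labels, per-method hyperparameter tuning by stratified
10-fold CV on balanced accuracy, prediction of the untouched test set, and
scoring against the original test labels. One metrics record per
(noise, replicate, method) cell; failed cells are logged and skipped
rather than aborting the grid.

Leakage guards are structural: locus edits are computed from training rows
only and applied verbatim to the test split; noise never touches test
labels; scoring reads only the original labels. ``run_experiment``
additionally checksums the label vector before and after the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import METHODS, ModelSpec, tune
from .noise import inject_label_noise, noise_grid
from .qc import qc_training_loci
from .simdata import CarrierLabels, GenotypeMatrix

__all__ = [
    "SplitPlan",
    "MetricsRecord",
    "ExperimentResult",
    "split_train_test",
    "compute_metrics",
    "run_experiment",
    "aggregate",
    "table1_layout",
    "labels_checksum",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("acc", "tpr", "tnr", "ter", "fpr", "fnr")


def labels_checksum(y: CarrierLabels | np.ndarray) -> str:
    """Stable digest of a label vector (leakage audit)."""
    values = y.values if isinstance(y, CarrierLabels) else np.asarray(y)
    return hashlib.sha256(np.ascontiguousarray(values, dtype=np.int8)
                          .tobytes()).hexdigest()


@dataclass(frozen=True)
class SplitPlan:
    """Replicated stratified train/test splitting policy.

    The training set takes ``floor(train_fraction * n)`` individuals with a
    proportional (rounded) share of carriers; each replicate draws a fresh
    split from a seed spawned off the master seed.
    """

    train_fraction: float = 0.70
    n_replicates: int = 10
    stratified: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def replicate_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.master_seed)
        return [int(s % 2**31)
                for s in ss.generate_state(self.n_replicates, dtype=np.uint64)]


def split_train_test(y: CarrierLabels, plan: SplitPlan, replicate: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test partition; deterministic per replicate."""
    if not 0 <= replicate < plan.n_replicates:
        raise ValueError("replicate index out of range")
    n = len(y)
    n_train = int(np.floor(plan.train_fraction * n))
    rng = np.random.default_rng(plan.replicate_seeds[replicate])
    if not plan.stratified:
        perm = rng.permutation(n)
        train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    else:
        pos = np.flatnonzero(y.values == 1)
        neg = np.flatnonzero(y.values == 0)
        k_pos = int(round(plan.train_fraction * pos.size))
        k_pos = min(max(k_pos, 1), pos.size - 1)  # both partitions need carriers
        k_neg = n_train - k_pos
        if not 1 <= k_neg <= neg.size - 1:
            raise ValueError("split leaves a partition without non-carriers")
        pos, neg = rng.permutation(pos), rng.permutation(neg)
        train = np.sort(np.concatenate([pos[:k_pos], neg[:k_neg]]))
        test = np.sort(np.concatenate([pos[k_pos:], neg[k_neg:]]))
    if y.values[test].sum() == 0 or y.values[train].sum() == 0:
        raise ValueError("split produced a partition without carriers")
    return train, test


@dataclass
class MetricsRecord:
    """Classification metrics for one (noise, replicate, method) cell."""

    acc: float
    tpr: float
    tnr: float
    ter: float
    fpr: float
    fnr: float
    noise_proportion: float | None = None
    replicate: int | None = None
    method: str | None = None
    params: str | None = None  # selected hyperparameters, JSON
    wall_time: float | None = None  # logged, never asserted
    error: str | None = None


def compute_metrics(y_true: CarrierLabels | np.ndarray,
                    y_pred: CarrierLabels | np.ndarray) -> MetricsRecord:
    """ACC/TPR/TNR and their reciprocals (TER/FPR/FNR) on a test set.

    ACC is the proportion of correct predictions; TPR the proportion of
    true carriers identified; TNR the proportion of true non-carriers
    identified. ``y_true`` must contain both classes, otherwise TPR or TNR
    is undefined.
    """
    yt = (y_true.values if isinstance(y_true, CarrierLabels)
          else np.asarray(y_true)).ravel()
    yp = (y_pred.values if isinstance(y_pred, CarrierLabels)
          else np.asarray(y_pred)).ravel()
    if yt.size != yp.size:
        raise ValueError("length mismatch between truth and prediction")
    pos = yt == 1
    if not pos.any() or pos.all():
        raise ValueError("y_true must contain both classes")
    acc = float((yt == yp).mean())
    tpr = float((yp[pos] == 1).mean())
    tnr = float((yp[~pos] == 0).mean())
    return MetricsRecord(acc=acc, tpr=tpr, tnr=tnr,
                         ter=1.0 - acc, fpr=1.0 - tnr, fnr=1.0 - tpr)


@dataclass
class ExperimentResult:
    """Per-cell records plus the run manifest (config, seeds, QC audit)."""

    records: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        return aggregate(self.records)

    def table1(self) -> pd.DataFrame:
        return table1_layout(self.records)


def run_experiment(
    g: GenotypeMatrix,
    labels: CarrierLabels,
    *,
    noise_levels: list[float] | None = None,
    methods: tuple[str, ...] = METHODS,
    replicates: int = 10,
    master_seed: int = 0,
    train_fraction: float = 0.70,
    cv_folds: int = 10,
    grids: dict[str, dict] | None = None,
    exclude_loci: tuple[str, ...] = (),
    collinear_threshold: float = 0.99,
    noise_target: str = "train",
) -> ExperimentResult:
    """Run the noise x replicate x method grid on a QC-complete panel.

    ``exclude_loci`` removes named loci (typically the causal mutation
    locus, whose genotype *defines* carrier status) from the predictor set
    before anything else, so classifiers must learn from flanking markers.
    ``noise_target`` is ``"train"`` (flip only training labels, the study
    design) or ``"all"`` (flip before splitting, for comparison); scoring
    always uses the original test labels.
    """
    if not g.is_complete():
        raise ValueError("panel has missing calls; run call-rate filter and "
                         "imputation first")
    if len(labels) != g.n_individuals:
        raise ValueError("labels length does not match panel")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if noise_target not in ("train", "all"):
        raise ValueError("noise_target must be 'train' or 'all'")
    noise_levels = noise_grid() if noise_levels is None else list(noise_levels)

    if exclude_loci:
        keep = [i for i in g.locus_ids if i not in set(exclude_loci)]
        g = g.subset_by_locus_ids(keep)

    label_digest = labels_checksum(labels)
    plan = SplitPlan(train_fraction=train_fraction, n_replicates=replicates,
                     master_seed=master_seed)
    ss = np.random.SeedSequence(master_seed)
    # independent streams per (noise, replicate) cell for flips and tuning
    cell_seeds = ss.spawn(len(noise_levels) * replicates)

    rows: list[MetricsRecord] = []
    qc_audit: dict[str, dict] = {}
    flip_audit: dict[str, str] = {}
    for r in range(replicates):
        train_idx, test_idx = split_train_test(labels, plan, r)
        g_train = g.subset(rows=train_idx)
        g_test = g.subset(rows=test_idx)
        kept_ids, qc_report = qc_training_loci(g_train, collinear_threshold)
        Xtr_full = g_train.subset_by_locus_ids(kept_ids).values
        Xte = g_test.subset_by_locus_ids(kept_ids).values
        y_test = labels.subset(test_idx)
        qc_audit[f"replicate_{r}"] = {
            "n_train": int(train_idx.size),
            "n_test": int(test_idx.size),
            "loci_kept": len(kept_ids),
            "monomorphic_removed": len(qc_report.snps_removed_monomorphic),
            "collinear_removed": len(qc_report.snps_removed_collinear),
            # digest of the kept-locus list: training-only edit decisions
            # must be reproducible from training rows alone
            "loci_checksum": hashlib.sha256(
                ",".join(map(str, kept_ids)).encode()).hexdigest(),
        }
        for ni, p in enumerate(noise_levels):
            cell = cell_seeds[ni * replicates + r]
            flip_seed, tune_seed = [int(s % 2**31)
                                    for s in cell.generate_state(2, np.uint64)]
            if noise_target == "train":
                y_train_noisy, flip_mask = inject_label_noise(
                    labels.subset(train_idx), p, seed=flip_seed)
            else:
                noisy_all, flip_mask = inject_label_noise(labels, p,
                                                          seed=flip_seed)
                y_train_noisy = noisy_all.subset(train_idx)
            flip_audit[f"p{p}_r{r}"] = hashlib.sha256(
                np.packbits(flip_mask).tobytes()).hexdigest()
            for method in methods:
                t0 = time.perf_counter()
                try:
                    spec = ModelSpec(method, (grids or {}).get(method, {}))
                    tuned = tune(spec, Xtr_full, y_train_noisy.values,
                                 folds=cv_folds, seed=tune_seed)
                    y_pred = tuned.predict(Xte)
                    rec = compute_metrics(y_test, y_pred)
                    rec.params = json.dumps(tuned.params, default=float)
                    rec.wall_time = time.perf_counter() - t0
                except Exception as exc:  # degrade gracefully, keep the grid
                    logger.warning("cell failed (p=%s, rep=%s, %s): %s",
                                   p, r, method, exc)
                    rec = MetricsRecord(*([float("nan")] * 6),
                                        wall_time=time.perf_counter() - t0,
                                        error=str(exc))
                rec.noise_proportion = p
                rec.replicate = r
                rec.method = method
                rows.append(rec)

    if labels_checksum(labels) != label_digest:
        raise AssertionError("label vector mutated during the run")

    records = pd.DataFrame([vars(r) for r in rows])
    manifest = {
        "master_seed": master_seed,
        "replicate_seeds": plan.replicate_seeds,
        "train_fraction": train_fraction,
        "cv_folds": cv_folds,
        "noise_levels": noise_levels,
        "methods": list(methods),
        "noise_target": noise_target,
        "excluded_loci": list(exclude_loci),
        "label_checksum": label_digest,
        "qc": qc_audit,
        "flips": flip_audit,
    }
    return ExperimentResult(records=records, manifest=manifest)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric by (noise proportion, method).

    Failed cells (NaN metrics) are excluded from the means; a cell with no
    successful replicate is reported as missing, not zero.
    """
    cols = list(METRIC_COLUMNS)
    return (records.groupby(["noise_proportion", "method"], sort=True)[cols]
            .mean().reset_index())


def table1_layout(records: pd.DataFrame) -> pd.DataFrame:
    """Error-rate summary: rows (noise, TER/FPR/FNR), columns methods."""
    agg = aggregate(records)
    long = agg.melt(id_vars=["noise_proportion", "method"],
                    value_vars=["ter", "fpr", "fnr"],
                    var_name="variable", value_name="value")
    long["variable"] = long["variable"].str.upper()
    table = long.pivot_table(index=["noise_proportion", "variable"],
                             columns="method", values="value", sort=False,
                             dropna=False)
    order = ["TER", "FPR", "FNR"]
    table = table.reindex(
        pd.MultiIndex.from_product(
            [sorted(agg["noise_proportion"].unique()), order],
            names=["noise_proportion", "variable"]))
    return table
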