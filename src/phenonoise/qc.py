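"""Genotype quality control.

Editing order is fixed and mirrors how such panels are prepared in
practice: call-rate filters on the full panel, then imputation of residual
missing calls, and — per train/test replicate, on the *training rows only*
— removal of monomorphic and collinear loci. Keeping the training-only
edits out of the test split is what prevents information leakage.

Imputation here is modal (most frequent observed dose per locus, ties to
the smaller dose), with an optional LD-based alternative that borrows the
genotype distribution of the most-correlated observed locus. Both are
simple single-marker schemes, adequate for the low missingness rates
(<= 5%) this pipeline deals with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import GenotypeMatrix

__all__ = [
    "QCReport",
    "filter_call_rate",
    "impute_modal",
    "impute_ld",
    "remove_monomorphic",
    "remove_collinear",
    "qc_training_loci",
]


@dataclass
class QCReport:
    """Audit trail of one QC pass."""

    snps_removed_callrate: list = field(default_factory=list)
    individuals_removed_callrate: list = field(default_factory=list)
    snps_removed_monomorphic: list = field(default_factory=list)
    snps_removed_collinear: list = field(default_factory=list)  # (id, partner_id)
    entries_imputed: int = 0
    imputation_method: str | None = None

    @property
    def n_snps_removed_callrate(self) -> int:
        return len(self.snps_removed_callrate)

    @property
    def n_individuals_removed_callrate(self) -> int:
        return len(self.individuals_removed_callrate)

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            self.snps_removed_callrate + other.snps_removed_callrate,
            self.individuals_removed_callrate + other.individuals_removed_callrate,
            self.snps_removed_monomorphic + other.snps_removed_monomorphic,
            self.snps_removed_collinear + other.snps_removed_collinear,
            self.entries_imputed + other.entries_imputed,
            other.imputation_method or self.imputation_method,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [("callrate_snp", i, "") for i in self.snps_removed_callrate]
        rows += [("callrate_individual", i, "") for i in self.individuals_removed_callrate]
        rows += [("monomorphic", i, "") for i in self.snps_removed_monomorphic]
        rows += [("collinear", i, p) for i, p in self.snps_removed_collinear]
        df = pd.DataFrame(rows, columns=["rule", "removed_id", "partner_id"])
        df.attrs["entries_imputed"] = self.entries_imputed
        return df


def filter_call_rate(g: GenotypeMatrix, threshold: float = 0.95,
                     axis: str = "snp") -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs or individuals whose call rate is strictly below threshold.

    A call rate exactly equal to the threshold is kept.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if axis not in ("snp", "individual"):
        raise ValueError("axis must be 'snp' or 'individual'")
    observed = ~np.isnan(g.values)
    report = QCReport()
    if axis == "snp":
        rate = observed.mean(axis=0)
        keep = rate >= threshold
        if not keep.any():
            raise ValueError("call-rate filter removed every SNP; panel unusable")
        report.snps_removed_callrate = list(g.locus_ids[~keep])
        out = g.subset(cols=np.flatnonzero(keep))
    else:
        rate = observed.mean(axis=1)
        keep = rate >= threshold
        if not keep.any():
            raise ValueError("call-rate filter removed every individual")
        report.individuals_removed_callrate = list(g.individual_ids[~keep])
        out = g.subset(rows=np.flatnonzero(keep))
    return out, report


def impute_modal(g: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """Replace missing calls by the most frequent observed dose per locus.

    Ties break toward the smaller dose. Every locus must have at least one
    observed call (the call-rate filter guarantees this upstream).
    """
    values = g.values
    missing = np.isnan(values)
    report = QCReport(entries_imputed=int(missing.sum()),
                      imputation_method="modal")
    if not missing.any():
        return g.copy(), report
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        bad = g.locus_ids[fully_missing][:5]
        raise ValueError(f"fully missing loci (run call-rate filter first): {list(bad)}")
    counts = np.stack([(values == d).sum(axis=0) for d in (0.0, 1.0, 2.0)])
    modes = counts.argmax(axis=0).astype(np.float64)  # argmax ties -> smaller dose
    out = g.copy()
    out.values[missing] = np.broadcast_to(modes, values.shape)[missing]
    return out, report


def impute_ld(g: GenotypeMatrix) -> tuple[GenotypeMatrix, QCReport]:
    """LD-aware single-marker imputation.

    For each locus with missing calls, find the most-correlated other locus
    (complete cases) and fill each hole with the modal dose among
    individuals sharing the partner's genotype; falls back to the plain
    locus mode when the partner is also missing or uninformative.
    """
    values = g.values
    missing = np.isnan(values)
    report = QCReport(entries_imputed=int(missing.sum()), imputation_method="ld")
    if not missing.any():
        return g.copy(), report
    out, _ = impute_modal(g)  # fallback fill & correlation substrate
    X = out.values
    C = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(C, 0.0)
    C = np.nan_to_num(np.abs(C))
    for j in np.flatnonzero(missing.any(axis=0)):
        partner = int(C[j].argmax())
        if C[j, partner] <= 0:
            continue
        for i in np.flatnonzero(missing[:, j]):
            peers = (~missing[:, j]) & (values[:, partner] == values[i, partner])
            obs = values[peers, j]
            obs = obs[~np.isnan(obs)]
            if obs.size:
                doses, counts = np.unique(obs, return_counts=True)
                out.values[i, j] = doses[counts.argmax()]
    return out, report


def remove_monomorphic(g_train: GenotypeMatrix) -> list:
    """Locus ids that are polymorphic in the training rows."""
    values = g_train.values
    if np.isnan(values).any():
        raise ValueError("impute before the monomorphic filter")
    poly = values.std(axis=0) > 0
    return list(g_train.locus_ids[poly])


def remove_collinear(g_train: GenotypeMatrix, threshold: float = 0.99
                     ) -> tuple[list, list]:
    """Greedy collinearity pruning in map order.

    A locus is dropped when its absolute Pearson correlation with any
    already-kept, earlier-position locus strictly exceeds ``threshold``;
    the earlier locus wins. Returns (kept ids, removed (id, partner) pairs).
    Absolute correlation is used: a perfectly anti-correlated pair is just
    as linearly dependent as a perfectly correlated one.
    """
    values = g_train.values
    if np.isnan(values).any():
        raise ValueError("impute before the collinearity filter")
    if (values.std(axis=0) == 0).any():
        raise ValueError("remove monomorphic loci before the collinearity filter")
    m = values.shape[1]
    C = np.abs(np.corrcoef(values, rowvar=False))
    ids = g_train.locus_ids
    kept_idx: list[int] = []
    removed: list[tuple] = []
    for j in range(m):
        if kept_idx:
            r = C[j, kept_idx]
            worst = int(np.argmax(r))
            if r[worst] > threshold:
                removed.append((ids[j], ids[kept_idx[worst]]))
                continue
        kept_idx.append(j)
    return [ids[j] for j in kept_idx], removed


def qc_training_loci(g_train: GenotypeMatrix, collinear_threshold: float = 0.99
                     ) -> tuple[list, QCReport]:
    """Training-only locus edits: monomorphic, then collinear.

    Returns the kept-id list (to be applied unchanged to the test split)
    and the report of what was removed and why.
    """
    kept_poly = remove_monomorphic(g_train)
    mono = sorted(set(g_train.locus_ids) - set(kept_poly))
    g_poly = g_train.subset_by_locus_ids(kept_poly)
    kept, collinear_pairs = remove_collinear(g_poly, collinear_threshold)
    report = QCReport(snps_removed_monomorphic=mono,
                      snps_removed_collinear=collinear_pairs)
    return kept, report
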