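"""Synthetic SNP panels with a recessive carrier locus.

Generates diploid genotype matrices (allele doses 0/1/2) whose statistical
structure emulates a dairy-cattle carrier-screening cohort: strong class
imbalance (~4% carriers of a harmful recessive mutation), a single
chromosome of moderately linked common SNPs, the causal locus at the start
of the chromosome, and a small fraction of missing calls.

Linkage disequilibrium is produced by a first-order haplotype mosaic: each
new haplotype copies segments of previously generated haplotypes, switching
template at each locus with probability ``1 - rho``. The copy probability
``rho`` is calibrated by bisection so that the mean pairwise genotype
r-squared over the panel hits a configurable target.

Carriers are heterozygous at the mutation locus by construction and never
homozygous (the mutation is harmful recessive; homozygotes do not reach
genotyping). The mutant allele rides on a single founder haplotype, so SNPs
near the chromosome start tag carrier status through LD, which is what makes
the classification problem learnable from the flanking markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "CarrierLabels",
    "HaplotypePool",
    "CalibrationError",
    "simulate_population",
    "mean_pairwise_r2",
    "inject_missingness",
]


class CalibrationError(RuntimeError):
    """The LD target cannot be reached by the mosaic copy process."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic panel.

    Defaults reproduce the study population: 3116 individuals, 1512 SNPs on
    one chromosome, 4.04% carriers, mean pairwise LD r² = 0.126.

    Parameters
    ----------
    n_individuals, n_snps
        Panel dimensions.
    carrier_frequency
        Proportion of carriers, in (0, 0.5). The realised carrier count is
        exactly ``round(carrier_frequency * n_individuals)``.
    ld_target_r2
        Mean pairwise genotype r² the mosaic process is calibrated to, in
        [0, 1).
    maf_range
        Uniform range for neutral-locus founder minor-allele frequencies,
        both ends in (0, 0.5].
    missing_rate
        Per-entry missingness probability, in [0, 0.05].
    mutation_locus_index
        Column holding the causal locus (fixed at the chromosome start).
    seed
        Master seed; identical configs produce byte-identical panels.
    copy_prob
        Optional fixed mosaic copy probability; when ``None`` (default) it
        is calibrated against ``ld_target_r2`` by bisection.
    carrier_background_ld
        When True (default) the mutant allele is placed on a founder
        haplotype shared by every carrier, so flanking SNPs are in LD with
        carrier status. When False carriers get the mutant allele on an
        ordinary neutral background (negative control: no flanking signal).
    carrier_segment_continuation
        Per-locus probability that the founder segment carried by a carrier
        extends one locus further; mean shared-segment length is
        ``1 / (1 - value)`` loci, emulating an identical-by-descent
        haplotype block around the mutation.
    """

    n_individuals: int
    n_snps: int
    carrier_frequency: float = 0.0404
    ld_target_r2: float = 0.126
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    mutation_locus_index: int = 0
    seed: int = 0
    copy_prob: float | None = None
    carrier_background_ld: bool = True
    carrier_segment_continuation: float = 0.975

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        if not 0.0 < self.carrier_frequency < 0.5:
            raise ValueError("carrier_frequency must be in (0, 0.5)")
        if not 0.0 <= self.ld_target_r2 < 1.0:
            raise ValueError("ld_target_r2 must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate <= 0.05:
            raise ValueError("missing_rate must be in [0, 0.05]")
        if self.mutation_locus_index != 0:
            raise ValueError("the mutation locus sits at the chromosome start (index 0)")
        if round(self.carrier_frequency * self.n_individuals) < 1:
            raise ValueError(
                "carrier_frequency * n_individuals rounds to zero carriers"
            )
        if not 0.0 <= self.carrier_segment_continuation < 1.0:
            raise ValueError("carrier_segment_continuation must be in [0, 1)")

    @property
    def n_carriers(self) -> int:
        return int(round(self.carrier_frequency * self.n_individuals))

    def to_flat_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_snps": self.n_snps,
            "carrier_frequency": self.carrier_frequency,
            "ld_target_r2": self.ld_target_r2,
            "maf_low": self.maf_range[0],
            "maf_high": self.maf_range[1],
            "missing_rate": self.missing_rate,
            "mutation_locus_index": self.mutation_locus_index,
            "seed": self.seed,
            "carrier_background_ld": self.carrier_background_ld,
            "carrier_segment_continuation": self.carrier_segment_continuation,
        }

    @classmethod
    def from_flat_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        maf = (float(d.pop("maf_low", 0.05)), float(d.pop("maf_high", 0.5)))
        return cls(
            n_individuals=int(d["n_individuals"]),
            n_snps=int(d["n_snps"]),
            carrier_frequency=float(d.get("carrier_frequency", 0.0404)),
            ld_target_r2=float(d.get("ld_target_r2", 0.126)),
            maf_range=maf,
            missing_rate=float(d.get("missing_rate", 0.0)),
            mutation_locus_index=int(d.get("mutation_locus_index", 0)),
            seed=int(d.get("seed", 0)),
            carrier_background_ld=bool(d.get("carrier_background_ld", True)),
            carrier_segment_continuation=float(
                d.get("carrier_segment_continuation", 0.975)
            ),
        )


@dataclass
class HaplotypePool:
    """Phased binary haplotypes, two per individual (rows 2i and 2i+1)."""

    haplotypes: np.ndarray  # (2n, m) int8 in {0, 1}
    allele_frequencies: np.ndarray  # (m,) founder frequencies

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("need an even number of haplotype rows")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dose matrix with a locus map.

    ``values`` is float64 with entries in {0, 1, 2} and NaN for missing
    calls. ``locus_table`` has columns id / chromosome / position (1-based
    bp, strictly increasing within a chromosome).
    """

    values: np.ndarray
    locus_table: pd.DataFrame
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, m = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length must match row count")
        if len(self.locus_table) != m:
            raise ValueError("locus_table length must match column count")
        required = {"id", "chromosome", "position"}
        if not required.issubset(self.locus_table.columns):
            raise ValueError(f"locus_table needs columns {sorted(required)}")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("doses must be 0, 1, 2 or NaN")
        for _, sub in self.locus_table.groupby("chromosome", sort=False):
            pos = sub["position"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing per chromosome")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def locus_ids(self) -> np.ndarray:
        return self.locus_table["id"].to_numpy()

    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def subset(self, rows: Sequence[int] | None = None,
               cols: Sequence[int] | None = None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            values=self.values[np.ix_(rows, cols)].copy(),
            locus_table=self.locus_table.iloc[cols].reset_index(drop=True),
            individual_ids=self.individual_ids[rows].copy(),
        )

    def subset_by_locus_ids(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = pd.Index(self.locus_table["id"])
        cols = index.get_indexer(list(ids))
        if (cols < 0).any():
            missing = [i for i, c in zip(ids, cols) if c < 0]
            raise KeyError(f"unknown locus ids: {missing[:5]}")
        return self.subset(cols=cols)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy(), self.locus_table.copy(),
                              self.individual_ids.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.values, other.values, equal_nan=True)
            and self.locus_table.reset_index(drop=True).equals(
                other.locus_table.reset_index(drop=True))
            and np.array_equal(self.individual_ids, other.individual_ids)
        )


@dataclass
class CarrierLabels:
    """Binary carrier status per individual (1 = carrier)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_carriers(self) -> int:
        return int(self.values.sum())

    def subset(self, rows: Sequence[int]) -> "CarrierLabels":
        return CarrierLabels(self.values[np.asarray(rows)].copy())

    def copy(self) -> "CarrierLabels":
        return CarrierLabels(self.values.copy())


# ---------------------------------------------------------------------------
# Mosaic haplotype process


_MUTATION_RATE = 0.015  # per-locus fresh-draw probability in the mosaic


def _founder_count(target_r2: float) -> int:
    """Founder-panel size giving headroom above the LD target.

    With F independent founders, fully linked loci reach a sample r² of
    roughly 1/(F-1); sizing F so that this ceiling sits comfortably above
    the target leaves the copy probability room to calibrate.
    """
    if target_r2 <= 0.005:
        return 32
    return max(2, int(round(0.5 / target_r2)))


def _mosaic_pool(rng: np.random.Generator, freqs: np.ndarray, rho: float,
                 n_hap: int, n_founders: int) -> np.ndarray:
    """Build ``n_hap`` haplotypes as Markov mosaics of a founder panel.

    A small panel of ``n_founders`` haplotypes is drawn independently from
    the founder allele frequencies. Each sample haplotype then walks along
    the chromosome copying its current founder template, keeping the same
    template at the next locus with probability ``rho`` (else jumping to a
    uniformly chosen founder), and replacing the copied allele by a fresh
    frequency draw at a small mutation rate. Shared founder segments are
    what induces linkage disequilibrium; the finite panel bounds its level.
    """
    m = freqs.size
    founders = (rng.random((n_founders, m)) < freqs).astype(np.int8)
    # keep every locus segregating in the panel: a founder column fixed for
    # one allele would leave that locus with (almost) no LD to calibrate
    colsum = founders.sum(axis=0)
    fixed = (colsum == 0) | (colsum == n_founders)
    if fixed.any():
        rows = rng.integers(0, n_founders, size=int(fixed.sum()))
        founders[rows, np.flatnonzero(fixed)] ^= 1
    cols = np.arange(m)
    H = np.empty((n_hap, m), dtype=np.int8)
    for k in range(n_hap):
        stay = rng.random(m) < rho
        stay[0] = False
        seg = np.cumsum(~stay) - 1
        templates = rng.integers(0, n_founders, size=seg[-1] + 1)
        hap = founders[templates[seg], cols]
        mut = rng.random(m) < _MUTATION_RATE
        if mut.any():
            hap = np.where(mut, (rng.random(m) < freqs).astype(np.int8), hap)
        H[k] = hap
    return H


def _pool_mean_r2(H: np.ndarray) -> float:
    """Mean pairwise genotype r² of a haplotype pool (paired rows)."""
    G = (H[0::2].astype(np.float64) + H[1::2])
    sd = G.std(axis=0)
    poly = sd > 0
    if poly.sum() < 2:
        return float("nan")
    C = np.corrcoef(G[:, poly], rowvar=False)
    iu = np.triu_indices_from(C, k=1)
    return float(np.mean(C[iu] ** 2))


def _calibrate_copy_prob(freqs: np.ndarray, target: float, n_hap: int,
                         n_founders: int, seed: int, tol: float = 0.004,
                         max_iter: int = 16) -> float:
    """Bisect the mosaic copy probability against the mean-r² target.

    Common random numbers (the evaluation rng is re-seeded identically at
    every candidate) make mean r² monotone in rho almost surely, so plain
    bisection converges.
    """

    def evaluate(rho: float) -> float:
        rng = np.random.default_rng(seed)
        return _pool_mean_r2(_mosaic_pool(rng, freqs, rho, n_hap, n_founders))

    lo, hi = 0.0, 0.9999
    r2_lo, r2_hi = evaluate(lo), evaluate(hi)
    if target <= r2_lo:
        if target <= 0.01:  # independence floor; rho=0 is the answer
            return 0.0
        raise CalibrationError(
            f"target r²={target:.4g} below the no-copying floor {r2_lo:.4g}")
    if target >= r2_hi:
        raise CalibrationError(
            f"target r²={target:.4g} above the maximal mosaic LD {r2_hi:.4g} "
            f"reachable under maf_range={freqs.min():.3g}-{freqs.max():.3g}")
    rho = 0.5
    for _ in range(max_iter):
        rho = 0.5 * (lo + hi)
        r2 = evaluate(rho)
        if abs(r2 - target) < tol:
            return rho
        if r2 < target:
            lo = rho
        else:
            hi = rho
    return rho


# ---------------------------------------------------------------------------
# Public operations


def simulate_population(config: SimulationConfig) -> tuple[GenotypeMatrix, CarrierLabels]:
    """Simulate one panel and its ground-truth carrier labels.

    Exactly ``round(carrier_frequency * n_individuals)`` individuals are
    carriers, each heterozygous at the mutation locus; every non-carrier is
    homozygous reference there. Deterministic given ``config.seed``.
    """
    n, m = config.n_individuals, config.n_snps
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_pool, s_carrier, s_map, s_missing = ss.spawn(5)

    rng_freq = np.random.default_rng(s_freq)
    freqs = rng_freq.uniform(config.maf_range[0], config.maf_range[1], size=m)

    n_founders = _founder_count(config.ld_target_r2)
    pool_seed = int(s_pool.generate_state(1)[0] % 2**31)
    rho = config.copy_prob
    if rho is None:
        # calibrate against the very stream that generates the panel, so the
        # realised mean r² lands within the bisection tolerance of the target
        rho = _calibrate_copy_prob(
            freqs, config.ld_target_r2, n_hap=2 * n, n_founders=n_founders,
            seed=pool_seed)
    H = _mosaic_pool(np.random.default_rng(pool_seed), freqs, rho, 2 * n,
                     n_founders)
    H[:, 0] = 0  # the causal locus is not a neutral SNP

    k = config.n_carriers
    rng_car = np.random.default_rng(s_carrier)
    carrier_idx = np.sort(rng_car.choice(n, size=k, replace=False))
    labels = np.zeros(n, dtype=np.int8)
    labels[carrier_idx] = 1

    # Mutant founder haplotype: one ancestral background shared (in decaying
    # segments) by every carrier, so flanking SNPs tag carrier status. It is
    # an *ordinary* haplotype of the population (a mosaic of the founder
    # panel) distinguished by sparse private mutations flipped toward the
    # rarer allele: a few strongly tagging markers over a diffuse weak
    # signal, the tagging structure of a recent mutation on a common
    # haplotype background.
    founder = _mosaic_pool(np.random.default_rng(
        int(s_carrier.generate_state(1)[0] % 2**31)),
        freqs, rho, 1, n_founders)[0]
    private = rng_car.random(m) < 0.2
    founder[private] = np.where(freqs[private] < 0.5, 1, 0)
    founder[0] = 1
    eta = config.carrier_segment_continuation
    for i in carrier_idx:
        hap = H[2 * i]
        if config.carrier_background_ld:
            # geometric IBD segment from the mutation, then recombine back
            # onto the individual's own neutral background
            seg_len = int(rng_car.geometric(1.0 - eta)) if eta > 0 else 1
            seg_len = min(seg_len, m)
            hap[:seg_len] = founder[:seg_len]
        hap[0] = 1

    values = (H[0::2] + H[1::2]).astype(np.float64)

    rng_map = np.random.default_rng(s_map)
    gaps = rng_map.integers(2_000, 80_000, size=m)
    positions = np.cumsum(gaps)
    locus_table = pd.DataFrame({
        "id": [f"snp{j + 1:05d}" for j in range(m)],
        "chromosome": ["19"] * m,
        "position": positions.astype(np.int64),
    })
    individual_ids = np.array([f"ind{i + 1:05d}" for i in range(n)], dtype=object)

    g = GenotypeMatrix(values, locus_table, individual_ids)
    if config.missing_rate > 0:
        g = inject_missingness(g, config.missing_rate,
                               seed=int(s_missing.generate_state(1)[0] % 2**31))
    return g, CarrierLabels(labels)


def mean_pairwise_r2(g: GenotypeMatrix) -> float:
    """Mean squared Pearson correlation over all unordered locus pairs.

    Monomorphic columns are excluded (with a warning); missing entries must
    be imputed beforehand.
    """
    X = np.asarray(g.values if isinstance(g, GenotypeMatrix) else g, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing entries; impute before LD")
    sd = X.std(axis=0)
    poly = sd > 0
    n_mono = int((~poly).sum())
    if poly.sum() < 2:
        raise ValueError("fewer than two polymorphic loci; mean r² undefined")
    if n_mono:
        warnings.warn(f"excluding {n_mono} monomorphic loci from mean r²",
                      stacklevel=2)
    C = np.corrcoef(X[:, poly], rowvar=False)
    iu = np.triu_indices_from(C, k=1)
    return float(np.mean(C[iu] ** 2))


def inject_missingness(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each currently observed entry missing with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = g.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random(out.values.shape) < rate
    mask &= ~np.isnan(out.values)
    out.values[mask] = np.nan
    return out
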