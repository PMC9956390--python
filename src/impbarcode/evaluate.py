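"""Imputation accuracy assessment.

Aggregate R^2 (AR2) is the squared Pearson correlation between imputed
genotype dosages and true genotype counts, pooled over every (variant,
individual) pair in a minor-allele-count (MAC) bin.  MAC can be counted in
the whole reference panel or in the target group; the choice decides which
variants count as monomorphic and therefore enter no defined bin (AR2 is
undefined when the truth has zero variance).  AR2*/AR2 ratios compare a
reduced-panel run against the full-panel baseline; values above 1 mean the
reduction improved accuracy.

Hard calls round dosages to the nearest of 0/1/2 (half-way ties round up),
and 3x3 truth-by-call confusion tables are tallied for rare MAC levels
(0-3 in the target group), where a false positive is a truly
homozygous-reference genotype called heterozygous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MacBins",
    "AccuracyReport",
    "hard_call",
    "compute_mac",
    "aggregate_r2",
    "individual_ar2",
    "ar2_ratio",
    "confusion_table",
    "confusion_percent_change",
    "count_false_positive_hets",
]

GENO_LABELS = ["AA", "Aa", "aa"]


@dataclass(frozen=True)
class MacBins:
    """Disjoint ordered MAC bins: edges (lo, hi) inclusive on both sides."""

    edges: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (2, 2), (3, 3),
                                          (4, 5), (6, 10), (11, 20), (21, 10 ** 9))
    mac_universe: str = "target"

    def __post_init__(self) -> None:
        for (a_lo, a_hi), (b_lo, b_hi) in zip(self.edges, self.edges[1:]):
            if a_hi >= b_lo or a_lo > a_hi:
                raise ValueError("bins must be disjoint, ordered, non-empty")

    def labels(self) -> list[str]:
        return [f"{lo}" if lo == hi else f"{lo}-{hi}" for lo, hi in self.edges]

    def assign(self, mac: np.ndarray) -> np.ndarray:
        """Bin index per site; -1 when the MAC falls in no bin."""
        out = np.full(len(mac), -1, dtype=int)
        for b, (lo, hi) in enumerate(self.edges):
            out[(mac >= lo) & (mac <= hi)] = b
        return out


@dataclass
class AccuracyReport:
    """Per-bin AR2 with variant/genotype counts (NaN where undefined)."""

    bins: MacBins
    ar2: np.ndarray
    n_variants: np.ndarray
    n_genotypes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": self.bins.labels(),
            "ar2": self.ar2,
            "n_variants": self.n_variants,
            "n_genotypes": self.n_genotypes,
        })


def hard_call(dosage: np.ndarray) -> np.ndarray:
    """Round genotype dosages to the nearest of {0, 1, 2}; ties round up."""
    d = np.asarray(dosage, dtype=float)
    if d.size and (d.min() < -1e-9 or d.max() > 2.0 + 1e-9):
        raise ValueError("genotype dosages must lie in [0, 2]")
    d = np.clip(d, 0.0, 2.0)  # forgive summation round-off at the bounds
    return np.floor(d + 0.5).astype(np.int8)  # 0.5 -> 1, 1.5 -> 2


def compute_mac(alleles: np.ndarray) -> np.ndarray:
    """Minor allele count per site (row) over a 0/1 haplotype matrix."""
    a = np.asarray(alleles)
    ones = a.sum(axis=1)
    return np.minimum(ones, a.shape[1] - ones).astype(np.int64)


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    vx = x - x.mean()
    vy = y - y.mean()
    denom = (vx @ vx) * (vy @ vy)
    if denom == 0.0:
        return float("nan")
    return float((vx @ vy) ** 2 / denom)


def aggregate_r2(dosages: np.ndarray, truth: np.ndarray, mac: np.ndarray,
                 bins: MacBins) -> AccuracyReport:
    """Pooled AR2 per MAC bin.

    ``dosages`` and ``truth`` are (n_variants, n_individuals) genotype
    matrices aligned over untyped, non-synthetic sites; ``mac`` gives each
    variant's MAC in the chosen universe.  A bin whose pooled truth is
    constant (e.g. every variant monomorphic in the target group) gets NaN:
    AR2 cannot be computed there.
    """
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth)
    if dosages.shape != truth.shape:
        raise ValueError(f"dosage shape {dosages.shape} != truth shape {truth.shape}")
    if len(mac) != dosages.shape[0]:
        raise ValueError("mac length must equal the variant count")
    which = bins.assign(np.asarray(mac))
    n_bins = len(bins.edges)
    ar2 = np.full(n_bins, np.nan)
    n_var = np.zeros(n_bins, dtype=int)
    n_gen = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        rows = np.flatnonzero(which == b)
        n_var[b] = len(rows)
        n_gen[b] = len(rows) * dosages.shape[1]
        if len(rows) == 0:
            continue
        t = truth[rows].ravel()
        if np.ptp(t) == 0:
            continue  # truly monomorphic bin: AR2 undefined
        ar2[b] = _pearson_r2(dosages[rows].ravel(), t)
    return AccuracyReport(bins=bins, ar2=ar2, n_variants=n_var, n_genotypes=n_gen)


def individual_ar2(dosages: np.ndarray, truth: np.ndarray,
                   individual: int) -> float:
    """AR2 across variants for one individual (column); NaN if truth constant."""
    d = np.asarray(dosages, dtype=float)[:, individual]
    t = np.asarray(truth)[:, individual]
    if len(d) < 2 or np.ptp(t) == 0:
        return float("nan")
    return _pearson_r2(d, t)


def ar2_ratio(report_reduced: AccuracyReport,
              report_baseline: AccuracyReport) -> np.ndarray:
    """Element-wise AR2*/AR2 per bin; NaN propagates from either side."""
    if report_reduced.bins.edges != report_baseline.bins.edges:
        raise ValueError("reports use different MAC bins")
    with np.errstate(invalid="ignore", divide="ignore"):
        return report_reduced.ar2 / report_baseline.ar2


def confusion_table(dosages: np.ndarray, truth: np.ndarray, mac: np.ndarray,
                    levels: tuple[int, ...] = (0, 1, 2, 3)) -> dict[int, pd.DataFrame]:
    """3x3 truth-by-call counts per MAC level over all (variant, individual).

    MAC is conventionally measured across the whole target group, which is
    what makes the level-0 heterozygous and homozygous-alternative truth
    rows structurally empty (a target-monomorphic variant has no carriers).
    """
    calls = hard_call(dosages)
    truth = np.asarray(truth).astype(np.int8)
    mac = np.asarray(mac)
    out: dict[int, pd.DataFrame] = {}
    for level in levels:
        rows = np.flatnonzero(mac == level)
        counts = np.zeros((3, 3), dtype=np.int64)
        if len(rows):
            t = truth[rows].ravel()
            c = calls[rows].ravel()
            np.add.at(counts, (t, c), 1)
        out[level] = pd.DataFrame(counts, index=GENO_LABELS, columns=GENO_LABELS)
    return out


def confusion_percent_change(reduced: dict[int, pd.DataFrame],
                             baseline: dict[int, pd.DataFrame]) -> dict[int, pd.DataFrame]:
    """Per-cell 100 * (reduced - baseline) / baseline; NaN where baseline 0."""
    out = {}
    for level, base in baseline.items():
        b = base.to_numpy(dtype=float)
        r = reduced[level].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(b > 0, 100.0 * (r - b) / b, np.nan)
        out[level] = pd.DataFrame(pct, index=GENO_LABELS, columns=GENO_LABELS)
    return out


def count_false_positive_hets(dosages: np.ndarray, truth: np.ndarray,
                              mac: np.ndarray, level: int = 0) -> int:
    """Truth-AA genotypes hard-called Aa at variants with the given target MAC."""
    tables = confusion_table(dosages, truth, mac, levels=(level,))
    return int(tables[level].loc["AA", "Aa"])
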