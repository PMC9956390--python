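"""Haploid Li-Stephens imputation engine.

A target haplotype is modelled as an imperfect mosaic of the N reference
haplotypes.  The hidden state at typed site i is the donating haplotype
h_ij in {1..N}; the observation is the target allele o_ij.  Emission is
1 - eps on an allele match and eps on a mismatch.  Between adjacent typed
sites the chain jumps, with probability q_i = 1 - exp(-4*ne*g_i / N)
(g_i the genetic distance in Morgans), to a uniformly chosen haplotype,
and otherwise stays.  Scaled forward-backward gives the donor posteriors
P(h_ij = k | o_j) at every typed site; linear interpolation in physical
position carries them to untyped sites, and the imputed haplotype dosage
at an untyped site i' is the posterior-weighted mean of the reference
alleles there:

    d_{i'j} = sum_k P(h_{i'j} = k | o_j) * H_{i'k}

Genotype dosages are sums of the two haplotype dosages of an individual.
`n_total` in :class:`HmmParams` pins the recombination scale (the N in q_i
and in the uniform-jump mass q_i/N) to a fixed haplotype count, so that
runs against reduced panels stay on the same copying dynamics as the full
panel they are compared with; by default it is the panel at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel_io import HaplotypePanel

__all__ = [
    "HmmParams",
    "PosteriorMatrix",
    "DosageMatrix",
    "forward_backward",
    "interpolate_posteriors",
    "interpolation_weights",
    "impute_haplotype",
    "impute_genotype",
    "impute_pseudo_individual",
    "impute_all_haplotypes",
]


@dataclass(frozen=True)
class HmmParams:
    """Li-Stephens copying parameters.

    error_rate
        Per-site emission mismatch probability eps, in (0, 0.5).
    ne
        Effective-size-like scale of the switch probability; the jump
        probability between typed sites is 1 - exp(-4*ne*g/N).
    cm_per_mb
        Constant genetic map used when no map is supplied (1 cM/Mb).
    genetic_map
        Optional (positions_bp, cM) arrays; linear interpolation between
        map points, constant extrapolation outside.
    n_total
        Recombination-scale haplotype count; None means "use the panel's N".
    """

    error_rate: float = 1e-3
    ne: float = 1e4
    cm_per_mb: float = 1.0
    genetic_map: tuple[np.ndarray, np.ndarray] | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in (0, 0.5), got {self.error_rate}")
        if self.ne <= 0:
            raise ValueError("ne must be positive")

    def morgans(self, positions_bp: np.ndarray) -> np.ndarray:
        """Cumulative genetic position in Morgans at the given bp positions."""
        positions_bp = np.asarray(positions_bp, dtype=float)
        if self.genetic_map is None:
            return positions_bp * self.cm_per_mb * 1e-8  # cM/Mb -> Morgan/bp
        xp, fp = self.genetic_map
        return np.interp(positions_bp, xp, fp) * 1e-2


@dataclass
class PosteriorMatrix:
    """Donor posteriors for one target haplotype: (S typed sites, N donors)."""

    values: np.ndarray
    typed_positions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.typed_positions = np.asarray(self.typed_positions, dtype=np.int64)
        if self.values.shape[0] != self.typed_positions.shape[0]:
            raise ValueError("row count must match typed position count")

    def check_rows(self, tol: float = 1e-8) -> None:
        sums = self.values.sum(axis=1)
        if np.abs(sums - 1.0).max() > tol or (self.values < 0).any():
            raise ValueError("posterior rows must be non-negative and sum to 1")


@dataclass
class DosageMatrix:
    """Imputed dosages: rows = untyped sites, columns = target haplotypes
    (level="haplotype", entries in [0,1]) or individuals (level="genotype",
    entries in [0,2])."""

    values: np.ndarray
    site_index: np.ndarray  # indices into the panel's site list
    column_ids: list[str]
    level: str = "haplotype"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.level not in ("haplotype", "genotype"):
            raise ValueError(f"unknown dosage level {self.level!r}")
        hi = 1.0 if self.level == "haplotype" else 2.0
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > hi + 1e-9):
            raise ValueError(f"{self.level} dosages out of [0, {hi}]")


def _transition_q(positions: np.ndarray, n_total: int, params: HmmParams) -> np.ndarray:
    g = np.diff(params.morgans(positions))
    return -np.expm1(-4.0 * params.ne * g / n_total)


def forward_backward(target_hap: np.ndarray, panel: HaplotypePanel,
                     params: HmmParams) -> PosteriorMatrix:
    """Scaled forward-backward donor posteriors at the panel's (typed) sites.

    ``panel`` must already be restricted to the typed sites; ``target_hap``
    is the 0/1 allele sequence of one target haplotype over those sites.
    """
    obs = np.asarray(target_hap)
    if obs.size and not np.isin(obs, (0, 1)).all():
        raise ValueError("target alleles must be 0/1")
    S, N = panel.n_sites, panel.n_haplotypes
    if S < 1 or N < 1:
        raise ValueError("need at least one typed site and one reference haplotype")
    if obs.shape[0] != S:
        raise ValueError(f"target has {obs.shape[0]} alleles for {S} typed sites")

    eps = params.error_rate
    n_total = params.n_total or N
    q = _transition_q(panel.positions, n_total, params)
    # emission[i, k] = 1-eps if panel allele matches obs else eps
    emit = np.where(panel.alleles == obs[:, None], 1.0 - eps, eps)

    fwd = np.empty((S, N))
    scale = np.empty(S)
    fwd[0] = emit[0] / n_total
    scale[0] = fwd[0].sum()
    fwd[0] /= scale[0]
    for i in range(1, S):
        stay = (1.0 - q[i - 1]) * fwd[i - 1]
        jump = q[i - 1] / n_total * fwd[i - 1].sum()
        fwd[i] = emit[i] * (stay + jump)
        scale[i] = fwd[i].sum()
        fwd[i] /= scale[i]

    bwd = np.empty((S, N))
    bwd[-1] = 1.0
    for i in range(S - 2, -1, -1):
        nxt = emit[i + 1] * bwd[i + 1]
        bwd[i] = (1.0 - q[i]) * nxt + q[i] / n_total * nxt.sum()
        bwd[i] /= bwd[i].sum()

    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return PosteriorMatrix(values=post, typed_positions=panel.positions)


def interpolation_weights(typed_positions: np.ndarray,
                          query_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(left row index, right row index, lambda) for linear interpolation.

    Queries before the first typed position or after the last copy the
    nearest row (lambda 0 against identical left/right indices).
    """
    tp = np.asarray(typed_positions, dtype=np.int64)
    qp = np.asarray(query_positions, dtype=np.int64)
    right = np.searchsorted(tp, qp, side="left")
    left = right - 1
    left = np.clip(left, 0, len(tp) - 1)
    right = np.clip(right, 0, len(tp) - 1)
    span = (tp[right] - tp[left]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(span > 0, (qp - tp[left]) / np.where(span > 0, span, 1.0), 0.0)
    exact = np.isin(qp, tp) & (tp[np.clip(right, 0, len(tp) - 1)] == qp)
    lam = np.where(exact, 1.0, lam)  # exact hits resolve to the matching row
    lam = np.clip(lam, 0.0, 1.0)
    return left, right, lam


def interpolate_posteriors(posterior: PosteriorMatrix,
                           query_position: int | np.ndarray) -> np.ndarray:
    """Donor weight vector(s) at untyped position(s) by linear interpolation.

    Between flanking typed sites at p_i < p < p_{i+1} the weights are
    (1-lambda) * row_i + lambda * row_{i+1} with
    lambda = (p - p_i) / (p_{i+1} - p_i); outside the typed span the nearest
    row is copied.
    """
    qp = np.atleast_1d(np.asarray(query_position, dtype=np.int64))
    left, right, lam = interpolation_weights(posterior.typed_positions, qp)
    out = ((1.0 - lam)[:, None] * posterior.values[left]
           + lam[:, None] * posterior.values[right])
    if np.isscalar(query_position) or np.ndim(query_position) == 0:
        return out[0]
    return out


def impute_haplotype(target_hap: np.ndarray, panel: HaplotypePanel,
                     typed_index: np.ndarray, params: HmmParams,
                     query_index: np.ndarray | None = None) -> np.ndarray:
    """Haplotype dosages at untyped sites for one target haplotype.

    ``target_hap`` holds alleles over ``typed_index`` (panel site indices);
    ``query_index`` defaults to every non-typed panel site.  Dosages are
    convex combinations of panel alleles, so they lie in [0, 1] by
    construction.
    """
    typed_index = np.asarray(typed_index, dtype=np.intp)
    if query_index is None:
        query_index = np.setdiff1d(np.arange(panel.n_sites, dtype=np.intp), typed_index)
    query_index = np.asarray(query_index, dtype=np.intp)
    post = forward_backward(target_hap, panel.restrict_sites(typed_index), params)
    qpos = panel.positions[query_index]
    weights = interpolate_posteriors(post, qpos)  # (U, N)
    return (weights * panel.alleles[query_index]).sum(axis=1)


def impute_genotype(hap1: np.ndarray, hap2: np.ndarray, panel: HaplotypePanel,
                    typed_index: np.ndarray, params: HmmParams,
                    query_index: np.ndarray | None = None) -> np.ndarray:
    """Genotype dosage for one individual: sum of its two haplotype dosages."""
    d1 = impute_haplotype(hap1, panel, typed_index, params, query_index)
    d2 = impute_haplotype(hap2, panel, typed_index, params, query_index)
    return d1 + d2


def impute_pseudo_individual(target_hap: np.ndarray, panel: HaplotypePanel,
                             typed_index: np.ndarray, params: HmmParams,
                             query_index: np.ndarray | None = None) -> np.ndarray:
    """Haplotype dosage via the pseudo-individual workaround.

    The haplotype is paired with itself, imputed as a diploid, and the
    genotype dosage is halved.  With a haploid engine this is exactly
    equivalent to :func:`impute_haplotype`; the operation exists to mirror
    the workflow imposed by diploid-only imputation software, and its parity
    with the native haplotype route is part of the test contract.
    """
    geno = impute_genotype(target_hap, target_hap, panel, typed_index, params,
                           query_index)
    return geno / 2.0


def impute_all_haplotypes(target_alleles: np.ndarray, column_ids: list[str],
                          panel: HaplotypePanel, typed_index: np.ndarray,
                          params: HmmParams,
                          query_index: np.ndarray | None = None) -> DosageMatrix:
    """Haplotype-level DosageMatrix for a matrix of target haplotypes.

    ``target_alleles`` has one row per typed site (aligned with
    ``typed_index``) and one column per target haplotype.
    """
    typed_index = np.asarray(typed_index, dtype=np.intp)
    if query_index is None:
        query_index = np.setdiff1d(np.arange(panel.n_sites, dtype=np.intp), typed_index)
    query_index = np.asarray(query_index, dtype=np.intp)
    out = np.empty((len(query_index), target_alleles.shape[1]))
    for j in range(target_alleles.shape[1]):
        out[:, j] = impute_haplotype(target_alleles[:, j], panel, typed_index,
                                     params, query_index)
    return DosageMatrix(values=out, site_index=query_index,
                        column_ids=list(column_ids), level="haplotype")
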