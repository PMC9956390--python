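"""Imputation barcodes: synthetic group-indicator variants.

To see which reference groups donate haplotype segments during imputation,
a batch of synthetic variants is injected 1 bp downstream of selected
well-behaved typed ("tagged") sites — one synthetic record per reference
group, sharing a single physical position.  The group-Z record carries the
alternative allele on every group-Z haplotype and the reference allele on
everyone else, so its imputed haplotype dosage equals the posterior donor
mass on group Z at that point of the genome.  Each batch is an "imputation
barcode"; summing and scaling barcode dosages genome-wide estimates the
contribution of each group to an individual's imputation.

Because the synthetic records are untyped, they can never enter the HMM:
injection is exactly neutral for the imputation of every real site, which
is asserted by :func:`check_injection_neutrality`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ls_hmm import DosageMatrix, HmmParams, impute_all_haplotypes
from .panel_io import HaplotypePanel, Site, TargetHaplotypes

logger = logging.getLogger(__name__)

__all__ = [
    "BarcodeBatch",
    "BarcodeSet",
    "BarcodeDosageTensor",
    "select_tagged_sites",
    "inject_barcodes",
    "check_injection_neutrality",
    "extract_barcode_dosages",
    "estimate_global_proportions",
]

#: LD-pruning window: pairs further apart than this are treated as unlinked
PRUNE_WINDOW_BP = 1_000_000


@dataclass(frozen=True)
class BarcodeBatch:
    """One barcode: group-indicator records sharing tagged_pos + 1."""

    batch_id: int
    chrom: str
    tagged_pos: int

    @property
    def barcode_pos(self) -> int:
        return self.tagged_pos + 1


@dataclass
class BarcodeSet:
    """All injected barcodes plus the fixed group order of their records."""

    batches: list[BarcodeBatch]
    group_order: list[str]

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def record_id(self, batch: BarcodeBatch, group: str) -> str:
        return f"bc{batch.batch_id}_{group}"

    def to_frame(self) -> pd.DataFrame:
        rows = [(b.batch_id, b.chrom, b.tagged_pos, b.barcode_pos, g)
                for b in self.batches for g in self.group_order]
        return pd.DataFrame(rows, columns=["batch_id", "chrom", "tagged_pos",
                                           "barcode_pos", "group"])


@dataclass
class BarcodeDosageTensor:
    """Barcode dosages indexed (target haplotype, batch, group), each in [0,1].

    For every (haplotype, batch) the group dosages sum to 1 (up to
    interpolation round-off): the groups partition the panel and dosages
    are convex combinations of indicator alleles.
    """

    values: np.ndarray  # (n_haplotypes, n_batches, n_groups)
    haplotype_ids: list[str]
    barcode_set: BarcodeSet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expect = (len(self.haplotype_ids), self.barcode_set.n_batches,
                  len(self.barcode_set.group_order))
        if self.values.shape != expect:
            raise ValueError(f"tensor shape {self.values.shape}, expected {expect}")

    def check_closure(self, tol: float = 1e-6) -> float:
        """Max deviation of per-(haplotype, batch) group sums from 1."""
        if self.values.size == 0:
            return 0.0
        dev = float(np.abs(self.values.sum(axis=2) - 1.0).max())
        if dev > tol:
            raise ValueError(f"batch closure violated: max deviation {dev:.3g}")
        return dev


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared haplotype-allele correlation of two 0/1 site rows."""
    va = a - a.mean()
    vb = b - b.mean()
    denom = (va @ va) * (vb @ vb)
    if denom == 0:
        return 0.0
    return float((va @ vb) ** 2 / denom)


def select_tagged_sites(panel: HaplotypePanel, typed_index: np.ndarray,
                        maf_min: float = 0.2, r2_max: float = 0.02,
                        gap_bp: int = 1) -> np.ndarray:
    """Choose the typed sites whose downstream flank will carry a barcode.

    Filters, in order: panel-wide MAF above ``maf_min``; greedy
    left-to-right LD pruning so every retained pair within
    :data:`PRUNE_WINDOW_BP` has r^2 below ``r2_max``; and the
    shoulder-to-shoulder rule — any candidate with another panel site
    within ``gap_bp`` downstream is dropped, so the barcode position
    (tagged position + 1) is guaranteed free.
    """
    typed_index = np.asarray(typed_index, dtype=np.intp)
    maf = panel.minor_allele_frequency()
    candidates = [int(i) for i in typed_index if maf[i] > maf_min]

    kept: list[int] = []
    for i in candidates:
        ok = True
        for j in reversed(kept):
            if panel.sites[i].pos - panel.sites[j].pos > PRUNE_WINDOW_BP:
                break
            if _pairwise_r2(panel.alleles[i].astype(float),
                            panel.alleles[j].astype(float)) >= r2_max:
                ok = False
                break
        if ok:
            kept.append(i)

    positions = set(int(p) for p in panel.positions)
    final = [i for i in kept
             if not any(panel.sites[i].pos + d in positions
                        for d in range(1, gap_bp + 1))]
    n_shoulder = len(kept) - len(final)
    logger.info("tagged-site selection: %d pass MAF, %d survive pruning, "
                "%d dropped by the shoulder rule, %d tagged",
                len(candidates), len(kept), n_shoulder, len(final))
    return np.array(final, dtype=np.intp)


def inject_barcodes(panel: HaplotypePanel,
                    tagged_index: np.ndarray) -> tuple[HaplotypePanel, BarcodeSet]:
    """Insert one group-indicator record per group 1 bp after each tagged site.

    The group-Z record's allele is 1 for every group-Z haplotype and 0
    otherwise.  Records are flagged synthetic; they are untyped by
    construction and excluded from all accuracy metrics.  Their REF/ALT are
    written as A/T and carry no biological meaning.
    """
    tagged_index = np.asarray(tagged_index, dtype=np.intp)
    group_order = panel.group_labels
    col_groups = panel.group_of_columns()
    existing = set(int(p) for p in panel.positions)

    batches: list[BarcodeBatch] = []
    new_sites: list[Site] = []
    new_rows: list[np.ndarray] = []
    for b, i in enumerate(tagged_index):
        site = panel.sites[int(i)]
        batch = BarcodeBatch(batch_id=b, chrom=site.chrom, tagged_pos=site.pos)
        if batch.barcode_pos in existing:
            raise ValueError(
                f"barcode position {site.chrom}:{batch.barcode_pos} collides "
                "with an existing site")
        batches.append(batch)
        for g in group_order:
            new_sites.append(Site(site.chrom, batch.barcode_pos, "A", "T",
                                  is_synthetic=True,
                                  site_id=f"bc{b}_{g}"))
            new_rows.append((col_groups == g).astype(np.int8))

    barcode_set = BarcodeSet(batches=batches, group_order=group_order)
    if not batches:
        return panel, barcode_set

    all_sites = list(panel.sites) + new_sites
    all_rows = np.vstack([panel.alleles, np.array(new_rows, dtype=np.int8)])
    order = np.argsort([s.pos for s in all_sites], kind="stable")
    augmented = HaplotypePanel(
        sites=[all_sites[i] for i in order],
        alleles=all_rows[order],
        haplotype_ids=list(panel.haplotype_ids),
        groups=dict(panel.groups),
    )
    return augmented, barcode_set


def check_injection_neutrality(panel: HaplotypePanel, augmented: HaplotypePanel,
                               targets: TargetHaplotypes, typed_sites: set[tuple[str, int]],
                               params: HmmParams) -> float:
    """Max |dosage with barcodes - without| over original untyped sites.

    Synthetic records are untyped, so they cannot enter the forward-backward
    pass; the difference is structurally zero and this check makes that
    explicit on a concrete instance.
    """
    from .panel_io import split_typed_untyped

    typed_a, untyped_a = split_typed_untyped(panel, typed_sites)
    typed_b, untyped_b = split_typed_untyped(augmented, typed_sites)
    # original untyped sites only, matched by (chrom, pos, alleles)
    orig_keys = {panel.sites[i].key for i in untyped_a}
    untyped_b = np.array([i for i in untyped_b if augmented.sites[i].key in orig_keys],
                         dtype=np.intp)

    typed_keys = [panel.sites[i].key for i in typed_a]
    tgt_typed = _restrict_targets(targets, typed_keys)

    d_a = impute_all_haplotypes(tgt_typed, targets.haplotype_ids, panel,
                                typed_a, params, untyped_a)
    d_b = impute_all_haplotypes(tgt_typed, targets.haplotype_ids, augmented,
                                typed_b, params, untyped_b)
    return float(np.abs(d_a.values - d_b.values).max())


def _restrict_targets(targets: TargetHaplotypes,
                      typed_keys: list[tuple]) -> np.ndarray:
    lookup = {s.key: i for i, s in enumerate(targets.sites)}
    try:
        rows = [lookup[k] for k in typed_keys]
    except KeyError as exc:  # pragma: no cover - guarded by panel invariants
        raise ValueError(f"typed site {exc} absent from targets") from exc
    return targets.alleles[rows]


def extract_barcode_dosages(dosages: DosageMatrix, panel: HaplotypePanel,
                            barcode_set: BarcodeSet) -> BarcodeDosageTensor:
    """Collect the imputed dosages of every barcode record into a tensor.

    ``dosages`` must be a haplotype-level matrix computed on the augmented
    panel; entry (j, b, Z) is target haplotype j's dosage at batch b's
    group-Z record.
    """
    if dosages.level != "haplotype":
        raise ValueError("barcode extraction needs haplotype-level dosages")
    row_of_id = {panel.sites[int(si)].site_id: r
                 for r, si in enumerate(dosages.site_index)}
    n_h = len(dosages.column_ids)
    tensor = np.empty((n_h, barcode_set.n_batches, len(barcode_set.group_order)))
    for b, batch in enumerate(barcode_set.batches):
        for z, g in enumerate(barcode_set.group_order):
            rid = barcode_set.record_id(batch, g)
            if rid not in row_of_id:
                raise ValueError(f"barcode record {rid} missing from dosage output")
            tensor[:, b, z] = dosages.values[row_of_id[rid]]
    return BarcodeDosageTensor(values=tensor, haplotype_ids=list(dosages.column_ids),
                               barcode_set=barcode_set)


def estimate_global_proportions(tensor: BarcodeDosageTensor,
                                per_individual: bool = True,
                                pairing: dict[str, tuple[int, int]] | None = None
                                ) -> pd.DataFrame:
    """Summed-and-scaled barcode dosages as group-contribution proportions.

    proportion_Z = (sum over batches of dosage_Z) / (sum over batches and
    groups); every returned vector sums to 1.  With ``per_individual`` the
    two haplotypes of each individual are averaged (``pairing`` defaults to
    consecutive haplotype pairs).
    """
    if tensor.barcode_set.n_batches == 0:
        raise ValueError("cannot estimate proportions with zero barcode batches")
    sums = tensor.values.sum(axis=1)  # (n_haplotypes, n_groups)
    props = sums / sums.sum(axis=1, keepdims=True)
    groups = tensor.barcode_set.group_order
    if per_individual:
        if pairing is None:
            ids = tensor.haplotype_ids
            pairing = {ids[i][: -2]: (i, i + 1) for i in range(0, len(ids), 2)}
        rows = {ind: (props[a] + props[b]) / 2.0 for ind, (a, b) in pairing.items()}
        return pd.DataFrame.from_dict(rows, orient="index", columns=groups)
    return pd.DataFrame(props, index=tensor.haplotype_ids, columns=groups)


def plot_proportions(proportions: pd.DataFrame, ax=None, sort: bool = True):
    """Stacked-bar plot of per-individual group proportions (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    df = proportions
    if sort:
        df = df.sort_values(by=list(df.columns), ascending=False)
    bottom = np.zeros(len(df))
    for g in df.columns:
        ax.bar(range(len(df)), df[g].to_numpy(), bottom=bottom, width=1.0, label=g)
        bottom += df[g].to_numpy()
    ax.set_xlim(-0.5, len(df) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("proportion of imputation")
    ax.legend(fontsize="small", ncol=len(df.columns))
    return ax
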