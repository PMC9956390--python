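"""Synthetic population generator.

Builds everything the rest of the toolkit needs without external data:

* a reference panel of K differentiated groups.  Per-site group allele
  frequencies follow a Balding-Nichols-style model (ancestral frequency
  uniform on (0.05, 0.95), group frequencies Beta-distributed around it with
  variance scaled by Fst).  A handful of founder haplotypes per group are
  drawn site-wise from the group frequencies; the remaining haplotypes are
  founder mosaics with a per-bp switch rate, which creates within-group LD;
* admixed target haplotypes: ancestry tracts with exponential lengths tile
  the chromosome, each tract copies one uniformly chosen panel haplotype of
  its source group with a small per-site copy-error rate, and the true tract
  boundaries are returned;
* group-private rare variants (minor allele count 1-3, carriers confined to
  one group) injected as untyped sites, the raw material for the
  false-positive analysis of rare-variant imputation;
* an array-site subset standing in for a genotyping-array manifest.

All randomness flows from ``SimConfig.seed``; repeat runs are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .panel_io import HaplotypePanel, Site, TargetHaplotypes

__all__ = [
    "SimConfig",
    "AncestryTracts",
    "simulate_reference_panel",
    "simulate_admixed_targets",
    "inject_private_rare",
    "select_array_sites",
    "default_group_labels",
]

#: per-site probability that a copied target allele is flipped, so targets
#: are near- but never exact copies of panel haplotypes
COPY_ERROR_RATE = 1e-3

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def default_group_labels(k: int) -> list[str]:
    """Continental-style labels for up to five groups, POP6.. beyond."""
    base = ["AFR", "EUR", "EAS", "SAS", "AMR"]
    return base[:k] + [f"POP{i + 1}" for i in range(5, k)]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic scenario.

    Defaults describe the desk-scale analogue of imputing recently admixed
    individuals against a five-group cosmopolitan panel: a few-Mb
    chromosome, moderate differentiation (Fst 0.1), a dominant source group
    with minor contributions from the others, and mean admixture tracts of a
    few hundred kb.
    """

    n_groups: int = 5
    haps_per_group: int = 40
    n_sites: int = 4000
    chrom_length: int = 8_000_000
    fst: float = 0.1
    founder_count: int = 10
    mosaic_switch_rate: float = 5e-6
    admix_proportions: tuple[float, ...] = (0.75, 0.15, 0.05, 0.03, 0.02)
    tract_mean_bp: float = 2_000_000.0
    n_targets: int = 20
    private_rare_per_group: int = 25
    array_fraction: float = 0.3
    chrom: str = "1"
    seed: int = 2023

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst must be in (0, 1), got {self.fst}")
        for name in ("n_groups", "haps_per_group", "n_sites", "chrom_length",
                     "founder_count", "n_targets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(self.admix_proportions) != self.n_groups:
            raise ValueError("admix_proportions length must equal n_groups")
        if abs(sum(self.admix_proportions) - 1.0) > 1e-12:
            raise ValueError("admix_proportions must sum to 1")
        if self.founder_count > self.haps_per_group:
            raise ValueError("founder_count cannot exceed haps_per_group")

    @property
    def group_labels(self) -> list[str]:
        return default_group_labels(self.n_groups)


@dataclass
class AncestryTracts:
    """Ground-truth ancestry mosaic per target haplotype.

    ``tracts[hap_id]`` is an ordered list of (start_pos, end_pos,
    source_group) with 1-based inclusive coordinates tiling
    [1, chrom_length] without gaps or overlaps.
    """

    tracts: dict[str, list[tuple[int, int, str]]]
    chrom_length: int
    group_labels: list[str]

    def genome_proportions(self, hap_id: str) -> dict[str, float]:
        """Length-weighted truth proportion per group for one haplotype."""
        out = {g: 0.0 for g in self.group_labels}
        for start, end, g in self.tracts[hap_id]:
            out[g] += (end - start + 1) / self.chrom_length
        return out

    def mean_proportions(self) -> dict[str, float]:
        sums = {g: 0.0 for g in self.group_labels}
        for hap in self.tracts:
            for g, p in self.genome_proportions(hap).items():
                sums[g] += p
        n = len(self.tracts)
        return {g: s / n for g, s in sums.items()}

    def to_frame(self):
        import pandas as pd

        rows = [(h, s, e, g) for h, tr in self.tracts.items() for s, e, g in tr]
        return pd.DataFrame(rows, columns=["hap_id", "start", "end", "group"])


def _group_frequencies(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """(n_sites, n_groups) allele frequencies under Balding-Nichols."""
    p = rng.uniform(0.05, 0.95, size=config.n_sites)
    c = (1.0 - config.fst) / config.fst
    a = p * c
    b = (1.0 - p) * c
    freqs = rng.beta(a[:, None], b[:, None],
                     size=(config.n_sites, config.n_groups))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def simulate_reference_panel(config: SimConfig) -> HaplotypePanel:
    """Simulate K differentiated groups of phased haplotypes with LD.

    Founders are drawn site-wise from the group frequencies; every other
    haplotype in a group is a founder mosaic whose copying source switches
    between adjacent sites with probability ``1 - exp(-rate * gap_bp)``.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.sort(rng.choice(
        np.arange(2, config.chrom_length, dtype=np.int64),
        size=config.n_sites, replace=False))
    freqs = _group_frequencies(rng, config)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_sites)
    gaps = np.diff(positions).astype(float)
    switch_p = 1.0 - np.exp(-config.mosaic_switch_rate * gaps)

    labels = config.group_labels
    blocks = []
    hap_ids: list[str] = []
    groups: dict[str, str] = {}
    for g, label in enumerate(labels):
        founders = (rng.random((config.n_sites, config.founder_count))
                    < freqs[:, g][:, None]).astype(np.int8)
        cols = [founders]
        n_mosaic = config.haps_per_group - config.founder_count
        if n_mosaic > 0:
            # mosaic copying: per haplotype, a founder index path with
            # geometric-ish segment lengths driven by inter-site gaps
            src = np.empty((config.n_sites, n_mosaic), dtype=np.intp)
            src[0] = rng.integers(0, config.founder_count, size=n_mosaic)
            switch = rng.random((config.n_sites - 1, n_mosaic)) < switch_p[:, None]
            new = rng.integers(0, config.founder_count,
                               size=(config.n_sites - 1, n_mosaic))
            for i in range(1, config.n_sites):
                src[i] = np.where(switch[i - 1], new[i - 1], src[i - 1])
            cols.append(founders[np.arange(config.n_sites)[:, None], src])
        blocks.append(np.concatenate(cols, axis=1))
        for h in range(config.haps_per_group):
            sample = f"{label}{h // 2:03d}"
            hid = f"{sample}_{h % 2 + 1}"
            hap_ids.append(hid)
            groups[hid] = label

    alleles = np.concatenate(blocks, axis=1)
    sites = [Site(config.chrom, int(pos), *_ALLELE_PAIRS[pi])
             for pos, pi in zip(positions, pair_idx)]
    return HaplotypePanel(sites=sites, alleles=alleles,
                          haplotype_ids=hap_ids, groups=groups)


def _draw_tracts(rng: np.random.Generator, config: SimConfig) -> list[tuple[int, int, int]]:
    """Exponential-length ancestry tracts tiling [1, chrom_length]."""
    tracts = []
    pos = 1
    props = np.asarray(config.admix_proportions)
    while pos <= config.chrom_length:
        length = max(1, int(np.ceil(rng.exponential(config.tract_mean_bp))))
        end = min(pos + length - 1, config.chrom_length)
        group = int(rng.choice(config.n_groups, p=props))
        tracts.append((pos, end, group))
        pos = end + 1
    return tracts


def simulate_admixed_targets(panel: HaplotypePanel, config: SimConfig,
                             donor_columns: np.ndarray | None = None
                             ) -> tuple[TargetHaplotypes, AncestryTracts]:
    """Build admixed target haplotypes as mosaics of panel haplotypes.

    Each of ``2 * n_targets`` target haplotypes is tiled by ancestry tracts
    (exponential lengths, groups drawn from ``admix_proportions``); within a
    tract the target copies one uniformly chosen haplotype of that group,
    with per-site copy errors at rate :data:`COPY_ERROR_RATE`.  Returns the
    targets over *all* panel sites (truth included) plus the truth tracts.

    ``donor_columns`` restricts the copying pool (per group, its
    intersection with that group's columns); :func:`simulate_held_out_study`
    uses this to emulate targets whose source haplotypes are absent from
    the reference panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    labels = config.group_labels
    group_cols = {g: panel.columns_of_group(g) for g in labels}
    if donor_columns is not None:
        pool = np.asarray(donor_columns, dtype=np.intp)
        group_cols = {g: np.intersect1d(cols, pool)
                      for g, cols in group_cols.items()}
    for g in labels:
        if config.admix_proportions[labels.index(g)] > 0 and len(group_cols[g]) == 0:
            raise ValueError(f"group {g} has zero haplotypes in the panel")
    positions = panel.positions
    n_haps = 2 * config.n_targets

    alleles = np.empty((panel.n_sites, n_haps), dtype=np.int8)
    hap_ids: list[str] = []
    pairing: dict[str, tuple[int, int]] = {}
    truth: dict[str, list[tuple[int, int, str]]] = {}
    for j in range(n_haps):
        sample = f"TGT{j // 2:03d}"
        hid = f"{sample}_{j % 2 + 1}"
        hap_ids.append(hid)
        pairing[sample] = (2 * (j // 2), 2 * (j // 2) + 1)
        tracts = _draw_tracts(rng, config)
        truth[hid] = [(s, e, labels[g]) for s, e, g in tracts]
        hap = np.empty(panel.n_sites, dtype=np.int8)
        for start, end, g in tracts:
            mask = (positions >= start) & (positions <= end)
            if not mask.any():
                continue
            donor_cols = group_cols[labels[g]]
            donor = int(donor_cols[rng.integers(0, len(donor_cols))])
            hap[mask] = panel.alleles[mask, donor]
        flips = rng.random(panel.n_sites) < COPY_ERROR_RATE
        hap[flips] = 1 - hap[flips]
        alleles[:, j] = hap

    targets = TargetHaplotypes(sites=list(panel.sites), alleles=alleles,
                               haplotype_ids=hap_ids, pairing=pairing)
    return targets, AncestryTracts(tracts=truth, chrom_length=config.chrom_length,
                                   group_labels=labels)


def inject_private_rare(panel: HaplotypePanel, config: SimConfig,
                        groups: list[str] | None = None,
                        carrier_pool: np.ndarray | None = None) -> HaplotypePanel:
    """Add group-private rare variants (MAC 1-3) at fresh untyped positions.

    For each group (default: all; restrict with ``groups`` to, e.g., load
    private mutations onto a single population), ``private_rare_per_group``
    new sites are created where 1-3 haplotypes of that single group carry
    the alternative allele and every other panel haplotype carries the
    reference allele.  These mimic recent, population-private mutations;
    they are never placed adjacent to an existing site and never enter the
    typed set.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 13)))
    taken = set(int(p) for p in panel.positions)
    # keep +/-1 bp clear of existing sites so barcode placement stays valid
    blocked = set()
    for p in taken:
        blocked.update((p - 1, p, p + 1))

    new_sites: list[Site] = []
    new_rows: list[np.ndarray] = []
    for label in (groups if groups is not None else panel.group_labels):
        cols = panel.columns_of_group(label)
        if carrier_pool is not None:
            cols = np.intersect1d(cols, np.asarray(carrier_pool, dtype=np.intp))
        made = 0
        while made < config.private_rare_per_group:
            pos = int(rng.integers(2, config.chrom_length))
            if pos in blocked:
                continue
            blocked.update((pos - 1, pos, pos + 1))
            mac = int(rng.integers(1, 4))
            carriers = rng.choice(cols, size=min(mac, len(cols)), replace=False)
            row = np.zeros(panel.n_haplotypes, dtype=np.int8)
            row[carriers] = 1
            new_sites.append(Site(panel.sites[0].chrom if panel.sites else config.chrom,
                                  pos, "A", "T",
                                  site_id=f"rare_{label}_{made}"))
            new_rows.append(row)
            made += 1

    if not new_sites:
        return panel
    all_sites = list(panel.sites) + new_sites
    all_rows = np.vstack([panel.alleles] + [np.array(new_rows, dtype=np.int8)])
    order = np.argsort([s.pos for s in all_sites], kind="stable")
    return HaplotypePanel(
        sites=[all_sites[i] for i in order],
        alleles=all_rows[order],
        haplotype_ids=list(panel.haplotype_ids),
        groups=dict(panel.groups),
    )


def simulate_held_out_study(config: SimConfig,
                            donor_reserve_per_group: int = 10,
                            rare_groups: list[str] | None = None
                            ) -> tuple[HaplotypePanel, TargetHaplotypes, AncestryTracts]:
    """Simulate a study whose target source haplotypes are not in the panel.

    Each group gets ``donor_reserve_per_group`` extra haplotypes (same
    founders, same mosaic process); targets copy only from that reserve,
    and the returned reference panel excludes it.  This reproduces the
    realistic regime where targets come from the panel's populations but
    their exact haplotypes are absent, so the HMM must blend donors — the
    setting in which distant groups carrying private rare alleles can cause
    false-positive heterozygotes.  ``rare_groups`` limits private-rare
    injection to the named groups (default: all); carriers are always drawn
    from panel haplotypes, never the reserve.
    """
    big_cfg = replace(config,
                      haps_per_group=config.haps_per_group + donor_reserve_per_group)
    big = simulate_reference_panel(big_cfg)
    keep_cols, reserve_cols = [], []
    for g in big_cfg.group_labels:
        cols = big.columns_of_group(g)
        keep_cols.extend(cols[: config.haps_per_group])
        reserve_cols.extend(cols[config.haps_per_group:])
    keep_cols = np.array(sorted(keep_cols), dtype=np.intp)
    reserve_cols = np.array(sorted(reserve_cols), dtype=np.intp)
    big = inject_private_rare(big, config, groups=rare_groups,
                              carrier_pool=keep_cols)
    targets, truth = simulate_admixed_targets(big, config,
                                              donor_columns=reserve_cols)
    panel = big.restrict_haplotypes(keep_cols)
    return panel, targets, truth


def select_array_sites(panel: HaplotypePanel, config: SimConfig) -> set[tuple[str, int]]:
    """Deterministic genotyping-array manifest for the simulated panel.

    Arrays ascertain common variation: candidates are panel sites with
    MAF >= 0.05, thinned evenly to ``array_fraction`` of all sites.
    Synthetic and injected rare sites never qualify.
    """
    maf = panel.minor_allele_frequency()
    candidates = [i for i, s in enumerate(panel.sites)
                  if not s.is_synthetic and maf[i] >= 0.05]
    n_want = max(2, int(round(config.array_fraction * panel.n_sites)))
    n_want = min(n_want, len(candidates))
    picks = np.unique(np.linspace(0, len(candidates) - 1, n_want).round().astype(int))
    return {(panel.sites[candidates[i]].chrom, panel.sites[candidates[i]].pos)
            for i in picks}
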