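"""Phased-panel I/O and typed/untyped site bookkeeping.

A reference panel is a matrix of phased 0/1 alleles (one row per bi-allelic
SNV, one column per haplotype) with per-haplotype group labels, e.g. the
continental super-populations of a cosmopolitan sequencing panel.  Targets
carry the same representation restricted to the sites on a genotyping array
(the "typed" sites); every other panel site is "untyped" and is what
imputation fills in.

Coordinates are 1-based, matching VCF.  Within a chromosome, sites are kept
sorted by position; position ties are allowed only among synthetic barcode
records sharing a position (see :mod:`impbarcode.barcodes`).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "HaplotypePanel",
    "TargetHaplotypes",
    "read_group_table",
    "read_site_list",
    "read_panel",
    "write_panel",
    "split_typed_untyped",
]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class Site:
    """One bi-allelic SNV record.

    ``is_synthetic`` flags injected barcode records; those never enter the
    typed set and are excluded from all accuracy metrics.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    is_synthetic: bool = False
    site_id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with site metadata and group labels.

    ``alleles`` has shape (n_sites, n_haplotypes) with entries in {0, 1};
    column order is (sample1_hap1, sample1_hap2, sample2_hap1, ...).
    ``groups`` maps every haplotype id to exactly one group label.
    """

    sites: list[Site]
    alleles: np.ndarray
    haplotype_ids: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape != (len(self.sites), len(self.haplotype_ids)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{len(self.sites)} sites x {len(self.haplotype_ids)} haplotypes"
            )
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        missing = [h for h in self.haplotype_ids if h not in self.groups]
        if missing:
            raise ValueError(f"haplotypes without a group label: {missing[:5]}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for a, b in zip(self.sites, self.sites[1:]):
            if a.chrom == b.chrom:
                if b.pos < a.pos:
                    raise ValueError(f"sites out of order at {a.chrom}:{a.pos} > {b.pos}")
                if b.pos == a.pos and not (a.is_synthetic or b.is_synthetic):
                    raise ValueError(
                        f"duplicate position {a.chrom}:{a.pos} among non-synthetic sites"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for h in self.haplotype_ids:
            seen.setdefault(self.groups[h], None)
        return list(seen)

    def group_of_columns(self) -> np.ndarray:
        """Group label per haplotype column, as an object array."""
        return np.array([self.groups[h] for h in self.haplotype_ids], dtype=object)

    def columns_of_group(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.group_of_columns() == label)

    def restrict_sites(self, index: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the given site indices (order preserved)."""
        index = np.asarray(index, dtype=np.intp)
        return HaplotypePanel(
            sites=[self.sites[i] for i in index],
            alleles=self.alleles[index],
            haplotype_ids=list(self.haplotype_ids),
            groups=dict(self.groups),
        )

    def restrict_haplotypes(self, columns: np.ndarray) -> "HaplotypePanel":
        columns = np.asarray(columns, dtype=np.intp)
        ids = [self.haplotype_ids[c] for c in columns]
        return HaplotypePanel(
            sites=list(self.sites),
            alleles=self.alleles[:, columns],
            haplotype_ids=ids,
            groups={h: self.groups[h] for h in ids},
        )

    def minor_allele_frequency(self) -> np.ndarray:
        """Panel-wide MAF per site."""
        p = self.alleles.mean(axis=1)
        return np.minimum(p, 1.0 - p)


@dataclass
class TargetHaplotypes:
    """Phased target alleles over an ordered list of sites.

    ``pairing`` maps individual id -> (column of hap 1, column of hap 2).
    After simulation the site list covers the whole panel (truth included);
    :meth:`restrict_sites` cuts it down to the typed set for imputation.
    """

    sites: list[Site]
    alleles: np.ndarray
    haplotype_ids: list[str]
    pairing: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.sites), len(self.haplotype_ids)):
            raise ValueError("alleles shape does not match sites x haplotypes")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def restrict_sites(self, index: np.ndarray) -> "TargetHaplotypes":
        index = np.asarray(index, dtype=np.intp)
        return TargetHaplotypes(
            sites=[self.sites[i] for i in index],
            alleles=self.alleles[index],
            haplotype_ids=list(self.haplotype_ids),
            pairing=dict(self.pairing),
        )


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_group_table(path) -> dict[str, str]:
    """Read a two-column TSV of (sample_id, group_label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str,
                     comment="#")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample in group table: {dup}")
    return dict(zip(df["sample"], df["group"]))


def read_site_list(path) -> set[tuple[str, int]]:
    """Read a two-column TSV of (chrom, pos) array positions."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos"],
                     dtype={"chrom": str, "pos": np.int64}, comment="#")
    return set(zip(df["chrom"], df["pos"]))


def read_panel(vcf_path, group_table_path) -> HaplotypePanel:
    """Read a phased VCF plus a sample->group table into a HaplotypePanel.

    Only bi-allelic SNV records are kept; anything else is skipped with a
    logged count.  Unphased or missing genotypes raise, naming the record:
    the panels this toolkit models are complete and phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    group_map = read_group_table(group_table_path)
    absent = [s for s in samples if s not in group_map]
    if absent:
        raise ValueError(f"samples missing from group table: {absent[:5]}")

    sites: list[Site] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1 \
                or rec.REF not in _NUCLEOTIDES or alts[0] not in _NUCLEOTIDES:
            n_skipped += 1
            continue
        gt = rec.genotype.array()  # (n_samples, 3): a0, a1, phased flag
        if (gt[:, :2] < 0).any():
            raise ValueError(f"missing genotype at {rec.CHROM}:{rec.POS}")
        if not gt[:, 2].all():
            bad = samples[int(np.flatnonzero(~gt[:, 2].astype(bool))[0])]
            raise ValueError(f"unphased genotype for {bad} at {rec.CHROM}:{rec.POS}")
        synthetic = rec.INFO.get("SYNTH") is not None
        sites.append(Site(str(rec.CHROM), rec.POS, rec.REF, alts[0],
                          is_synthetic=synthetic,
                          site_id=rec.ID or "."))
        rows.append(gt[:, :2].reshape(-1).astype(np.int8))
    if n_skipped:
        logger.info("skipped %d non-bi-allelic-SNV records", n_skipped)

    hap_ids = [f"{s}_{i}" for s in samples for i in (1, 2)]
    groups = {f"{s}_{i}": group_map[s] for s in samples for i in (1, 2)}
    alleles = np.vstack(rows) if rows else np.zeros((0, len(hap_ids)), dtype=np.int8)
    panel = HaplotypePanel(sites=sites, alleles=alleles,
                           haplotype_ids=hap_ids, groups=groups)
    panel.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return panel


def write_panel(panel: HaplotypePanel, vcf_path, extra_header: list[str] | None = None) -> None:
    """Write a panel as VCF 4.2 with phased GT.

    Synthetic barcode records are written as ordinary SNV records at their
    stated positions, tagged INFO/SYNTH so a round trip preserves the flag.
    Sites must already be sorted (panel invariant); order within position
    ties is preserved as stored.
    """
    if panel.n_haplotypes % 2 != 0:
        raise ValueError("panel must contain whole diploid samples (even haplotype count)")
    samples = [panel.haplotype_ids[c][: -2] for c in range(0, panel.n_haplotypes, 2)]
    with _open_text(vcf_path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in panel.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=SYNTH,Number=0,Type=Flag,Description='
                 '"Synthetic group-indicator (barcode) record">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        for line in extra_header or []:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, site in enumerate(panel.sites):
            row = panel.alleles[i]
            gts = "\t".join(f"{row[c]}|{row[c + 1]}" for c in range(0, len(row), 2))
            info = "SYNTH" if site.is_synthetic else "."
            fh.write(f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref_allele}\t"
                     f"{site.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_dosage_vcf(panel: HaplotypePanel, site_index, dosages, column_ids,
                     vcf_path, hard_calls=None, extra_header: list[str] | None = None) -> None:
    """Write genotype dosages (FORMAT DS, optional GT hard call) as VCF 4.2."""
    site_index = np.asarray(site_index, dtype=np.intp)
    dosages = np.asarray(dosages, dtype=float)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with _open_text(vcf_path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">\n')
        if hard_calls is not None:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard call">\n')
        for line in extra_header or []:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(column_ids) + "\n")
        fmt = "DS" if hard_calls is None else "GT:DS"
        for r, si in enumerate(site_index):
            site = panel.sites[int(si)]
            if hard_calls is None:
                cells = "\t".join(f"{d:.4f}" for d in dosages[r])
            else:
                cells = "\t".join(f"{gt_of[int(g)]}:{d:.4f}"
                                  for g, d in zip(hard_calls[r], dosages[r]))
            info = "SYNTH" if site.is_synthetic else "."
            fh.write(f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref_allele}\t"
                     f"{site.alt_allele}\t.\tPASS\t{info}\t{fmt}\t{cells}\n")


def split_typed_untyped(panel: HaplotypePanel,
                        site_list: set[tuple[str, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Partition panel site indices into (typed, untyped) by an array-site list.

    A site is typed iff its (chrom, pos) appears in ``site_list``; synthetic
    records are always untyped.  List entries absent from the panel are
    warned about, not fatal.
    """
    panel_keys = {(s.chrom, s.pos) for s in panel.sites if not s.is_synthetic}
    missing = site_list - panel_keys
    if missing:
        logger.warning("%d site-list entries not present in panel", len(missing))
    typed = np.array(
        [i for i, s in enumerate(panel.sites)
         if not s.is_synthetic and (s.chrom, s.pos) in site_list],
        dtype=np.intp,
    )
    untyped = np.setdiff1d(np.arange(panel.n_sites, dtype=np.intp), typed)
    return typed, untyped
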