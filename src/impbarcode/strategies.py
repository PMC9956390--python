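"""Reference-panel reduction strategies.

Imputation is run in genomic chunks.  Two ways of shrinking the reference
panel per run are provided:

* informed choice — a first full-panel pass computes the barcode dosage
  tensor; a group Z is then retained for (target haplotype j, chunk c) only
  if some barcode batch in c gives Z a dosage above a threshold (default
  0.9).  Each haplotype gets its own panel per chunk.
* global threshold — per-individual group proportions (barcode-derived or
  supplied externally) are thresholded once (default 0.01) and the retained
  set applies to both haplotypes over every chunk.

:func:`run_with_assignment` executes either assignment (or an all-groups
baseline) chunk by chunk with a flanking buffer that feeds the HMM but is
never reported.  Reduced runs keep the recombination scale of the full
panel (``HmmParams.n_total``) so dosages remain directly comparable to the
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barcodes import BarcodeDosageTensor, BarcodeSet, extract_barcode_dosages
from .ls_hmm import DosageMatrix, HmmParams, impute_all_haplotypes
from .panel_io import HaplotypePanel, TargetHaplotypes

logger = logging.getLogger(__name__)

__all__ = [
    "ChunkDefinition",
    "PanelAssignment",
    "define_chunks",
    "all_groups_assignment",
    "informed_choice_assignment",
    "global_threshold_assignment",
    "run_with_assignment",
]

DEFAULT_BUFFER_BP = 250_000
DEFAULT_INFORMED_THRESHOLD = 0.9
DEFAULT_GLOBAL_THRESHOLD = 0.01


@dataclass
class ChunkDefinition:
    """Ordered chunks (chrom, start, end) tiling the chromosome.

    Boundaries are inclusive; ``buffer_bp`` is the flank added on each side
    for HMM computation only — buffered sites feed the forward-backward
    pass but are never reported by the buffered chunk.
    """

    chunks: list[tuple[str, int, int]]
    buffer_bp: int = DEFAULT_BUFFER_BP

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    def chunk_of_position(self, chrom: str, pos: int) -> int:
        for c, (ch, start, end) in enumerate(self.chunks):
            if ch == chrom and start <= pos <= end:
                return c
        raise ValueError(f"position {chrom}:{pos} outside all chunks")


@dataclass
class PanelAssignment:
    """Retained reference-group subset per (target haplotype, chunk)."""

    retained: dict[tuple[str, int], list[str]]

    def groups_for(self, hap_id: str, chunk: int) -> list[str]:
        return self.retained[(hap_id, chunk)]

    def to_frame(self) -> pd.DataFrame:
        rows = [(h, c, ",".join(gs)) for (h, c), gs in sorted(self.retained.items())]
        return pd.DataFrame(rows, columns=["hap_id", "chunk_id", "retained_groups"])


def define_chunks(panel: HaplotypePanel, typed_index: np.ndarray,
                  n_chunks: int, buffer_bp: int = DEFAULT_BUFFER_BP,
                  chrom_length: int | None = None) -> ChunkDefinition:
    """Split the chromosome so each chunk holds ~equal numbers of typed sites.

    Boundaries fall midway between the last typed site of one chunk and the
    first of the next; the first chunk starts at 1 and the last extends to
    ``chrom_length`` (default: past the final panel site), so every panel
    site maps to exactly one chunk.
    """
    typed_index = np.asarray(typed_index, dtype=np.intp)
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    if n_chunks > len(typed_index):
        raise ValueError(f"n_chunks={n_chunks} exceeds typed site count {len(typed_index)}")
    chroms = {panel.sites[int(i)].chrom for i in typed_index}
    if len(chroms) != 1:
        raise ValueError("chunking expects a single chromosome")
    chrom = chroms.pop()
    tpos = np.sort(panel.positions[typed_index])
    edges_idx = np.linspace(0, len(tpos), n_chunks + 1).round().astype(int)
    last_pos = int(chrom_length or max(int(panel.positions.max()) + 1, int(tpos[-1]) + 1))
    chunks = []
    start = 1
    for c in range(n_chunks):
        if c == n_chunks - 1:
            end = last_pos
        else:
            left = int(tpos[edges_idx[c + 1] - 1])
            right = int(tpos[edges_idx[c + 1]])
            end = (left + right) // 2
        chunks.append((chrom, start, end))
        start = end + 1
    return ChunkDefinition(chunks=chunks, buffer_bp=buffer_bp)


def all_groups_assignment(hap_ids: list[str], groups: list[str],
                          chunk_def: ChunkDefinition) -> PanelAssignment:
    """Baseline assignment: every group retained everywhere."""
    return PanelAssignment(retained={
        (h, c): list(groups) for h in hap_ids for c in range(chunk_def.n_chunks)})


def _batch_chunks(barcode_set: BarcodeSet, chunk_def: ChunkDefinition) -> np.ndarray:
    return np.array([chunk_def.chunk_of_position(b.chrom, b.barcode_pos)
                     for b in barcode_set.batches], dtype=np.intp)


def informed_choice_assignment(tensor: BarcodeDosageTensor,
                               chunk_def: ChunkDefinition,
                               threshold: float = DEFAULT_INFORMED_THRESHOLD
                               ) -> PanelAssignment:
    """Per-(haplotype, chunk) panels from first-pass barcode dosages.

    Group Z survives for (j, c) iff some batch in chunk c gives Z a dosage
    above ``threshold`` for haplotype j.  If no group passes, the single
    group with the largest in-chunk maximum is kept (minimal-panel intent;
    logged).  A chunk with no batches retains all groups (logged).
    """
    groups = tensor.barcode_set.group_order
    batch_chunk = _batch_chunks(tensor.barcode_set, chunk_def)
    retained: dict[tuple[str, int], list[str]] = {}
    n_fallback = n_empty = 0
    for c in range(chunk_def.n_chunks):
        in_chunk = np.flatnonzero(batch_chunk == c)
        for j, hap in enumerate(tensor.haplotype_ids):
            if len(in_chunk) == 0:
                retained[(hap, c)] = list(groups)
                n_empty += 1
                continue
            peak = tensor.values[j, in_chunk, :].max(axis=0)  # (n_groups,)
            keep = [g for z, g in enumerate(groups) if peak[z] > threshold]
            if not keep:
                keep = [groups[int(peak.argmax())]]
                n_fallback += 1
            retained[(hap, c)] = keep
    if n_empty:
        logger.info("%d (haplotype, chunk) pairs had no barcodes; all groups retained",
                    n_empty // max(len(tensor.haplotype_ids), 1))
    if n_fallback:
        logger.info("argmax fallback used for %d (haplotype, chunk) pairs", n_fallback)
    return PanelAssignment(retained=retained)


def global_threshold_assignment(proportions: pd.DataFrame,
                                pairing: dict[str, tuple[int, int]],
                                hap_ids: list[str],
                                chunk_def: ChunkDefinition,
                                threshold: float = DEFAULT_GLOBAL_THRESHOLD
                                ) -> PanelAssignment:
    """One retained set per individual: groups with proportion > threshold.

    ``proportions`` is per-individual (rows = individual ids, columns =
    groups), either barcode-derived or supplied externally, e.g. by an
    ancestry-deconvolution tool.  Both haplotypes of an individual share
    the set across every chunk; an empty set falls back to the argmax group.
    """
    retained: dict[tuple[str, int], list[str]] = {}
    groups = list(proportions.columns)
    for ind, (a, b) in pairing.items():
        vec = proportions.loc[ind]
        keep = [g for g in groups if vec[g] > threshold]
        if not keep:
            keep = [vec.idxmax()]
        for col in (a, b):
            for c in range(chunk_def.n_chunks):
                retained[(hap_ids[col], c)] = list(keep)
    return PanelAssignment(retained=retained)


def run_with_assignment(targets: TargetHaplotypes, panel: HaplotypePanel,
                        typed_index: np.ndarray, assignment: PanelAssignment,
                        chunk_def: ChunkDefinition, params: HmmParams,
                        barcode_set: BarcodeSet | None = None
                        ) -> tuple[DosageMatrix, DosageMatrix, BarcodeDosageTensor | None]:
    """Chunked imputation under a PanelAssignment.

    For each chunk and target haplotype, forward-backward runs on the
    chunk's typed sites plus ``buffer_bp`` flanks, using only the retained
    groups' haplotype columns, and dosages are reported for the chunk's own
    untyped sites.  The recombination scale is pinned to the full panel's
    haplotype count so reduced panels share the baseline's copying
    dynamics.  Returns (haplotype-level dosages, genotype-level dosages
    summed per individual, barcode tensor if a BarcodeSet is given).
    Per-chunk outputs concatenate so every untyped site appears exactly once.
    """
    typed_index = np.asarray(typed_index, dtype=np.intp)
    untyped_index = np.setdiff1d(np.arange(panel.n_sites, dtype=np.intp), typed_index)
    params = HmmParams(error_rate=params.error_rate, ne=params.ne,
                       cm_per_mb=params.cm_per_mb, genetic_map=params.genetic_map,
                       n_total=params.n_total or panel.n_haplotypes)
    # targets aligned to the panel's typed sites
    tgt_lookup = {s.key: i for i, s in enumerate(targets.sites)}
    tgt_rows = np.array([tgt_lookup[panel.sites[int(i)].key] for i in typed_index],
                        dtype=np.intp)
    typed_alleles = targets.alleles[tgt_rows]
    positions = panel.positions
    col_of_group = {g: panel.columns_of_group(g) for g in panel.group_labels}

    n_h = targets.n_haplotypes
    hap_values = np.full((len(untyped_index), n_h), np.nan)
    untyped_row = {int(si): r for r, si in enumerate(untyped_index)}

    for c, (chrom, start, end) in enumerate(chunk_def.chunks):
        tpos = positions[typed_index]
        in_buffer = (tpos >= start - chunk_def.buffer_bp) & (tpos <= end + chunk_def.buffer_bp)
        chunk_typed = typed_index[in_buffer]
        if len(chunk_typed) == 0:
            raise ValueError(f"chunk {c} has no typed sites even with buffer")
        upos = positions[untyped_index]
        report = untyped_index[(upos >= start) & (upos <= end)]
        if len(report) == 0:
            continue
        obs = typed_alleles[in_buffer]
        for j, hap in enumerate(targets.haplotype_ids):
            cols = np.sort(np.concatenate(
                [col_of_group[g] for g in assignment.groups_for(hap, c)]))
            sub = panel.restrict_haplotypes(cols)
            d = impute_all_haplotypes(obs[:, [j]], [hap], sub, chunk_typed,
                                      params, report)
            rows = [untyped_row[int(si)] for si in report]
            hap_values[rows, j] = d.values[:, 0]

    if np.isnan(hap_values).any():
        raise AssertionError("some untyped sites were reported by no chunk")
    hap_dos = DosageMatrix(values=hap_values, site_index=untyped_index,
                           column_ids=list(targets.haplotype_ids), level="haplotype")

    inds = list(targets.pairing)
    geno = np.empty((len(untyped_index), len(inds)))
    for k, ind in enumerate(inds):
        a, b = targets.pairing[ind]
        geno[:, k] = hap_values[:, a] + hap_values[:, b]
    geno_dos = DosageMatrix(values=geno, site_index=untyped_index,
                            column_ids=inds, level="genotype")

    tensor = None
    if barcode_set is not None and barcode_set.n_batches:
        tensor = extract_barcode_dosages(hap_dos, panel, barcode_set)
    return hap_dos, geno_dos, tensor
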