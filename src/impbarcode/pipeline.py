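"""End-to-end workflows chaining simulation, barcoding and strategies.

The canonical two-pass experiment:

1. simulate (or load) a reference panel, admixed targets and an array-site
   list; 2. select tagged sites, inject barcodes; 3. first pass — chunked
   baseline imputation with the full panel, extracting the barcode dosage
   tensor and global group proportions; 4. informed choice — per-(haplotype,
   chunk) panel reduction from the tensor, second imputation pass;
   5. evaluation — AR2 by MAC bin, AR2*/AR2 ratios and rare-MAC confusion
   tables against the simulated truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import barcodes, evaluate, popsim, strategies
from .ls_hmm import DosageMatrix, HmmParams
from .panel_io import HaplotypePanel, TargetHaplotypes, split_typed_untyped
from .popsim import SimConfig

__all__ = ["Scenario", "FirstPass", "simulate_scenario", "private_rare_scenario",
           "first_pass", "informed_choice_pass", "evaluation_inputs",
           "TYPED_PER_CHUNK"]

#: default typed-site count per imputation chunk.  Chosen so a default
#: scenario yields a handful of chunks whose span stays below the mean
#: admixture tract length and which each hold tens of barcodes, the regime
#: a genome-scale run of a few hundred chunks operates in.
TYPED_PER_CHUNK = 300


@dataclass
class Scenario:
    """A simulated study: panel, targets, truth and the array-site split."""

    config: SimConfig
    panel: HaplotypePanel            # includes injected private-rare sites
    targets: TargetHaplotypes        # over all panel sites (truth included)
    truth_tracts: popsim.AncestryTracts
    typed_sites: set[tuple[str, int]]
    typed_index: np.ndarray
    untyped_index: np.ndarray


@dataclass
class FirstPass:
    """Full-panel chunked run with barcodes: the tracking pass."""

    augmented: HaplotypePanel
    barcode_set: barcodes.BarcodeSet
    typed_index: np.ndarray          # into the augmented panel
    untyped_index: np.ndarray
    chunk_def: strategies.ChunkDefinition
    params: HmmParams
    hap_dosages: DosageMatrix
    geno_dosages: DosageMatrix
    tensor: barcodes.BarcodeDosageTensor
    proportions: pd.DataFrame        # per individual


def simulate_scenario(config: SimConfig) -> Scenario:
    """Panel + private rare variants + admixed targets + array split."""
    panel = popsim.simulate_reference_panel(config)
    panel = popsim.inject_private_rare(panel, config)
    targets, truth = popsim.simulate_admixed_targets(panel, config)
    typed_sites = popsim.select_array_sites(panel, config)
    typed_index, untyped_index = split_typed_untyped(panel, typed_sites)
    return Scenario(config=config, panel=panel, targets=targets,
                    truth_tracts=truth, typed_sites=typed_sites,
                    typed_index=typed_index, untyped_index=untyped_index)


def private_rare_scenario(seed: int) -> Scenario:
    """The rare-variant false-positive study.

    Three moderately differentiated groups (Fst 0.05, recently diverged in
    spirit); targets are 70/30 admixtures of the first two, so the third is
    irrelevant to them, yet it carries private MAC 1-3 alternative alleles
    at sites where the target group is truly monomorphic.  Target source
    haplotypes are held out of the reference panel, so the HMM must blend
    donors — the regime where borrowing the irrelevant group manufactures
    false-positive heterozygotes that informed choice can avoid.
    """
    cfg = SimConfig(n_groups=3, haps_per_group=50, n_sites=2500,
                    chrom_length=5_000_000, fst=0.05,
                    admix_proportions=(0.7, 0.3, 0.0),
                    tract_mean_bp=1_500_000, n_targets=15,
                    private_rare_per_group=120, seed=seed)
    panel, targets, truth = popsim.simulate_held_out_study(
        cfg, rare_groups=[cfg.group_labels[2]])
    typed_sites = popsim.select_array_sites(panel, cfg)
    typed_index, untyped_index = split_typed_untyped(panel, typed_sites)
    return Scenario(config=cfg, panel=panel, targets=targets, truth_tracts=truth,
                    typed_sites=typed_sites, typed_index=typed_index,
                    untyped_index=untyped_index)


def first_pass(scenario: Scenario, params: HmmParams | None = None,
               maf_min: float = 0.2, r2_max: float = 0.02, gap_bp: int = 1,
               n_chunks: int | None = None,
               buffer_bp: int = strategies.DEFAULT_BUFFER_BP) -> FirstPass:
    """Inject barcodes and run the chunked full-panel baseline."""
    params = params or HmmParams()
    tagged = barcodes.select_tagged_sites(scenario.panel, scenario.typed_index,
                                          maf_min=maf_min, r2_max=r2_max,
                                          gap_bp=gap_bp)
    augmented, barcode_set = barcodes.inject_barcodes(scenario.panel, tagged)
    typed_index, untyped_index = split_typed_untyped(augmented, scenario.typed_sites)
    if n_chunks is None:
        n_chunks = max(1, math.ceil(len(typed_index) / TYPED_PER_CHUNK))
    chrom_length = scenario.config.chrom_length if scenario.config else None
    chunk_def = strategies.define_chunks(augmented, typed_index, n_chunks,
                                         buffer_bp=buffer_bp,
                                         chrom_length=chrom_length)
    assignment = strategies.all_groups_assignment(
        scenario.targets.haplotype_ids, augmented.group_labels, chunk_def)
    hap_dos, geno_dos, tensor = strategies.run_with_assignment(
        scenario.targets, augmented, typed_index, assignment, chunk_def,
        params, barcode_set=barcode_set)
    if tensor is None:
        raise ValueError("no tagged sites survived selection; cannot barcode")
    proportions = barcodes.estimate_global_proportions(
        tensor, per_individual=True, pairing=scenario.targets.pairing)
    return FirstPass(augmented=augmented, barcode_set=barcode_set,
                     typed_index=typed_index, untyped_index=untyped_index,
                     chunk_def=chunk_def, params=params, hap_dosages=hap_dos,
                     geno_dosages=geno_dos, tensor=tensor,
                     proportions=proportions)


def informed_choice_pass(scenario: Scenario, fp: FirstPass,
                         threshold: float = strategies.DEFAULT_INFORMED_THRESHOLD
                         ) -> tuple[strategies.PanelAssignment, DosageMatrix,
                                    DosageMatrix, barcodes.BarcodeDosageTensor]:
    """Second pass with per-(haplotype, chunk) reduced panels."""
    assignment = strategies.informed_choice_assignment(fp.tensor, fp.chunk_def,
                                                       threshold=threshold)
    hap_dos, geno_dos, tensor = strategies.run_with_assignment(
        scenario.targets, fp.augmented, fp.typed_index, assignment,
        fp.chunk_def, fp.params, barcode_set=fp.barcode_set)
    return assignment, hap_dos, geno_dos, tensor


def evaluation_inputs(scenario: Scenario, fp: FirstPass,
                      geno_dosages: DosageMatrix
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(dosages, truth, target MAC, panel MAC) over real untyped sites.

    Synthetic barcode records are dropped; rows align across all four
    arrays.  Truth genotypes are the simulated target allele sums.
    """
    aug = fp.augmented
    keep = np.array([r for r, si in enumerate(geno_dosages.site_index)
                     if not aug.sites[int(si)].is_synthetic], dtype=np.intp)
    site_idx = geno_dosages.site_index[keep]
    dos = geno_dosages.values[keep]

    tgt_lookup = {s.key: i for i, s in enumerate(scenario.targets.sites)}
    tgt_rows = np.array([tgt_lookup[aug.sites[int(si)].key] for si in site_idx],
                        dtype=np.intp)
    inds = geno_dosages.column_ids
    truth = np.empty((len(site_idx), len(inds)), dtype=np.int8)
    for k, ind in enumerate(inds):
        a, b = scenario.targets.pairing[ind]
        truth[:, k] = (scenario.targets.alleles[tgt_rows, a]
                       + scenario.targets.alleles[tgt_rows, b])

    target_mac = evaluate.compute_mac(scenario.targets.alleles[tgt_rows])
    panel_rows = np.array([int(si) for si in site_idx], dtype=np.intp)
    panel_mac = evaluate.compute_mac(aug.alleles[panel_rows])
    return dos, truth, target_mac, panel_mac
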