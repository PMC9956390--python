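"""Chunking, informed choice, global threshold and reduced-panel runs."""

import numpy as np
import pandas as pd
import pytest

from impbarcode import strategies
from impbarcode.barcodes import BarcodeBatch, BarcodeDosageTensor, BarcodeSet
from impbarcode.ls_hmm import HmmParams
from impbarcode.strategies import (ChunkDefinition, all_groups_assignment,
                                   define_chunks, global_threshold_assignment,
                                   informed_choice_assignment,
                                   run_with_assignment)


class TestDefineChunks:
    def test_single_chunk_covers_everything(self, small_scenario):
        sc = small_scenario
        cd = define_chunks(sc.panel, sc.typed_index, 1,
                           chrom_length=sc.config.chrom_length)
        assert cd.n_chunks == 1
        assert cd.chunks[0][1] == 1
        assert cd.chunks[0][2] >= sc.panel.positions.max()

    def test_equal_typed_site_counts(self, small_scenario):
        sc = small_scenario
        cd = define_chunks(sc.panel, sc.typed_index, 4)
        tpos = sc.panel.positions[sc.typed_index]
        counts = [((tpos >= s) & (tpos <= e)).sum() for _, s, e in cd.chunks]
        assert max(counts) - min(counts) <= 1

    def test_chunks_partition_all_sites(self, small_scenario):
        sc = small_scenario
        cd = define_chunks(sc.panel, sc.typed_index, 3,
                           chrom_length=sc.config.chrom_length)
        assigned = [cd.chunk_of_position(s.chrom, s.pos) for s in sc.panel.sites]
        assert set(assigned) <= {0, 1, 2}
        starts = [s for _, s, _ in cd.chunks]
        ends = [e for _, _, e in cd.chunks]
        assert starts[0] == 1
        assert all(s == e + 1 for s, e in zip(starts[1:], ends[:-1]))

    def test_too_many_chunks_rejected(self, small_scenario):
        sc = small_scenario
        with pytest.raises(ValueError, match="exceeds typed site count"):
            define_chunks(sc.panel, sc.typed_index, len(sc.typed_index) + 1)


def _tensor(values, groups=("P1", "P2", "P3"), positions=(100, 900)):
    bset = BarcodeSet(batches=[BarcodeBatch(i, "1", p)
                               for i, p in enumerate(positions)],
                      group_order=list(groups))
    return BarcodeDosageTensor(values=np.asarray(values, dtype=float),
                               haplotype_ids=["T0_1"], barcode_set=bset)


class TestInformedChoice:
    chunk_def = ChunkDefinition(chunks=[("1", 1, 2000)], buffer_bp=0)

    def test_group_below_threshold_removed(self):
        t = _tensor([[[0.85, 0.10, 0.05], [0.95, 0.04, 0.01]]])
        asn = informed_choice_assignment(t, self.chunk_def, threshold=0.9)
        assert asn.groups_for("T0_1", 0) == ["P1"]

    def test_single_high_dosage_retains_group(self):
        t = _tensor([[[0.05, 0.95, 0.0], [0.92, 0.05, 0.03]]])
        asn = informed_choice_assignment(t, self.chunk_def, threshold=0.9)
        assert asn.groups_for("T0_1", 0) == ["P1", "P2"]

    def test_all_below_threshold_falls_back_to_argmax(self):
        t = _tensor([[[0.5, 0.3, 0.2], [0.4, 0.45, 0.15]]])
        asn = informed_choice_assignment(t, self.chunk_def, threshold=0.9)
        assert asn.groups_for("T0_1", 0) == ["P1"]  # max dosage 0.5

    def test_boundary_dosage_not_retained(self):
        """The rule is strictly 'above' the threshold."""
        t = _tensor([[[0.9, 0.91, 0.0], [0.1, 0.2, 0.0]]])
        asn = informed_choice_assignment(t, self.chunk_def, threshold=0.9)
        assert asn.groups_for("T0_1", 0) == ["P2"]

    def test_chunk_without_batches_retains_all(self, caplog):
        cd = ChunkDefinition(chunks=[("1", 1, 1000), ("1", 1001, 2000)],
                             buffer_bp=0)
        t = _tensor([[[0.95, 0.1, 0.0], [0.96, 0.0, 0.0]]],
                    positions=(100, 900))  # both batches in chunk 0
        asn = informed_choice_assignment(t, cd, threshold=0.9)
        assert asn.groups_for("T0_1", 1) == ["P1", "P2", "P3"]


class TestGlobalThreshold:
    chunk_def = ChunkDefinition(chunks=[("1", 1, 1000), ("1", 1001, 2000)],
                                buffer_bp=0)

    def _assign(self, vec, threshold=0.01):
        props = pd.DataFrame([vec], index=["T0"],
                             columns=["P1", "P2", "P3", "P4", "P5"][: len(vec)])
        return global_threshold_assignment(props, {"T0": (0, 1)},
                                           ["T0_1", "T0_2"], self.chunk_def,
                                           threshold=threshold)

    def test_small_contributions_dropped(self):
        asn = self._assign([0.7, 0.295, 0.005, 0.0, 0.0])
        for hap in ("T0_1", "T0_2"):
            for c in (0, 1):
                assert asn.groups_for(hap, c) == ["P1", "P2"]

    def test_zero_threshold_keeps_positive_groups(self):
        asn = self._assign([0.7, 0.295, 0.005, 0.0, 0.0], threshold=0.0)
        assert asn.groups_for("T0_1", 0) == ["P1", "P2", "P3"]

    def test_empty_retained_set_falls_back_to_argmax(self):
        asn = self._assign([0.4, 0.6], threshold=0.95)
        assert asn.groups_for("T0_2", 1) == ["P2"]

    def test_external_proportions_accepted(self):
        """A user-supplied table (e.g. from an ancestry tool) drives the
        assignment verbatim."""
        props = pd.DataFrame({"P1": [0.2], "P2": [0.8]}, index=["T0"])
        asn = global_threshold_assignment(props, {"T0": (0, 1)},
                                          ["T0_1", "T0_2"], self.chunk_def,
                                          threshold=0.5)
        assert asn.groups_for("T0_1", 0) == ["P2"]


class TestRunWithAssignment:
    def test_all_groups_reproduces_baseline_exactly(self, small_scenario,
                                                    small_first_pass):
        """Retaining every group everywhere is a bit-identical no-op."""
        sc, fp = small_scenario, small_first_pass
        asn = all_groups_assignment(sc.targets.haplotype_ids,
                                    fp.augmented.group_labels, fp.chunk_def)
        hap, geno, _ = run_with_assignment(sc.targets, fp.augmented,
                                           fp.typed_index, asn, fp.chunk_def,
                                           fp.params)
        assert np.array_equal(hap.values, fp.hap_dosages.values)
        assert np.abs(geno.values - fp.geno_dosages.values).max() == 0.0

    def test_zero_threshold_informed_choice_is_noop(self, small_scenario,
                                                    small_first_pass):
        sc, fp = small_scenario, small_first_pass
        asn = informed_choice_assignment(fp.tensor, fp.chunk_def, threshold=-1.0)
        # threshold below every dosage retains all groups everywhere
        hap, _, _ = run_with_assignment(sc.targets, fp.augmented,
                                        fp.typed_index, asn, fp.chunk_def,
                                        fp.params)
        assert np.array_equal(hap.values, fp.hap_dosages.values)

    def test_single_group_restriction_bounds_dosages(self, small_scenario,
                                                     small_first_pass):
        """With one retained group, dosages are convex combinations of that
        group's alleles only: monomorphic-in-group sites become exact."""
        sc, fp = small_scenario, small_first_pass
        label = fp.augmented.group_labels[0]
        asn = strategies.PanelAssignment(retained={
            (h, c): [label] for h in sc.targets.haplotype_ids
            for c in range(fp.chunk_def.n_chunks)})
        hap, _, _ = run_with_assignment(sc.targets, fp.augmented,
                                        fp.typed_index, asn, fp.chunk_def,
                                        fp.params)
        cols = fp.augmented.columns_of_group(label)
        sub = fp.augmented.alleles[:, cols]
        lo = sub[hap.site_index].min(axis=1)
        hi = sub[hap.site_index].max(axis=1)
        assert (hap.values >= lo[:, None] - 1e-12).all()
        assert (hap.values <= hi[:, None] + 1e-12).all()

    def test_removing_zero_mass_group_changes_dosages_below_1e9(self):
        """Dropping a group whose posterior mass is effectively zero (it
        mismatches the target at every typed site, tiny emission error)
        perturbs chunk dosages by < 1e-9: the recombination scale is pinned
        to the full panel count, so absent donors only withdraw their own
        negligible mass."""
        from conftest import make_panel
        from impbarcode.panel_io import TargetHaplotypes

        rng = np.random.default_rng(0)
        S, U, n1, n2 = 60, 40, 20, 10
        pos = np.sort(rng.choice(np.arange(100, 20_000), S + U, replace=False))
        typed = np.sort(rng.choice(S + U, S, replace=False))
        g1 = rng.integers(0, 2, size=(S + U, n1))
        target = g1[typed, 0].copy()
        g2 = rng.integers(0, 2, size=(S + U, n2))
        g2[typed] = (1 - target)[:, None]  # group B mismatches everywhere typed
        panel = make_panel(np.concatenate([g1, g2], axis=1), pos,
                           groups=["A"] * n1 + ["B"] * n2)
        targets = TargetHaplotypes(
            sites=[panel.sites[int(i)] for i in typed],
            alleles=np.column_stack([target, target]),
            haplotype_ids=["T0_1", "T0_2"], pairing={"T0": (0, 1)})
        params = HmmParams(error_rate=1e-6)
        cd = define_chunks(panel, typed, 2, buffer_bp=2_000)
        base = all_groups_assignment(targets.haplotype_ids, ["A", "B"], cd)
        only_a = strategies.PanelAssignment(
            retained={k: ["A"] for k in base.retained})
        hap_full, _, _ = run_with_assignment(targets, panel, typed, base,
                                             cd, params)
        hap_red, _, _ = run_with_assignment(targets, panel, typed, only_a,
                                            cd, params)
        assert np.abs(hap_full.values - hap_red.values).max() < 1e-9

    def test_every_untyped_site_reported_once(self, small_first_pass):
        fp = small_first_pass
        assert len(fp.hap_dosages.site_index) == len(np.unique(fp.hap_dosages.site_index))
        assert set(fp.hap_dosages.site_index.tolist()) == set(fp.untyped_index.tolist())
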