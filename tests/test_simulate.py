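"""Planted-truth generators: determinism, calibration and bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from tadpersist import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SimulationConfig,
    assign_persistent_sites,
    derive_knockdown_truth,
    internal_boundaries,
    simulate_celltype_panel,
    simulate_contact_matrix,
    simulate_gene_annotation,
    simulate_peak_collection,
    simulate_tad_segmentation,
)
from tadpersist.genome import distance_to_nearest, overlap_flags


def make_config(**kw) -> SimulationConfig:
    layout = kw.pop(
        "layout",
        GenomeLayout((("chrS", 20_000_000),), bin_size=40_000),
    )
    return SimulationConfig(layout=layout, **kw)


class TestSegmentation:
    def test_deterministic_under_seed(self):
        cfg = make_config(seed=11)
        t1, g1 = simulate_tad_segmentation(cfg)
        t2, g2 = simulate_tad_segmentation(cfg)
        assert t1 == t2 and g1 == g2

    def test_median_length_matches_target(self):
        cfg = make_config(
            layout=GenomeLayout((("chrL", 100_000_000),), bin_size=40_000), seed=2
        )
        tads, _ = simulate_tad_segmentation(cfg)
        med = np.median([iv.length for iv in tads])
        assert abs(med - 720_000) / 720_000 < 0.15

    def test_minimum_two_bins(self):
        cfg = make_config(tad_median_bp=80_000, tad_sigma_log=0.8, seed=3)
        tads, _ = simulate_tad_segmentation(cfg)
        assert len(tads) > 0
        assert all(iv.length >= 2 * 40_000 for iv in tads)

    def test_tiling_never_overlaps(self):
        cfg = make_config(seed=4)
        tads, gaps = simulate_tad_segmentation(cfg)
        both = IntervalSet(list(tads) + list(gaps))
        assert both.is_disjoint()


class TestContactMatrix:
    def test_symmetric_integer_nonnegative_zero_diagonal(self):
        cfg = make_config(seed=5)
        tads, _ = simulate_tad_segmentation(cfg)
        m = simulate_contact_matrix(tads, cfg, "chrS").counts
        assert np.array_equal(m, m.T)
        assert (m >= 0).all() and np.array_equal(m, np.round(m))
        assert np.diag(m).sum() == 0

    def test_boost_disabled_distance_only(self):
        cfg = make_config(within_tad_boost=0.0, depth=50.0, seed=6)
        tads, _ = simulate_tad_segmentation(cfg)
        m = simulate_contact_matrix(tads, cfg, "chrS").counts
        bs = 40_000
        ids = np.full(500, -1)
        for t, iv in enumerate(tads):
            ids[iv.start // bs : iv.end // bs] = t
        d = 3
        i = np.arange(500 - d)
        j = i + d
        same = (ids[i] == ids[j]) & (ids[i] >= 0)
        within, between = m[i[same], j[same]], m[i[~same], j[~same]]
        expect = 50.0 * (d + 1) ** -1.0
        assert within.mean() == pytest.approx(expect, rel=0.15)
        assert between.mean() == pytest.approx(expect, rel=0.15)

    def test_boost_ratio_matches_model(self):
        """With beta=2 the within-domain mean at fixed distance is ~3x the
        between-domain mean (Monte-Carlo over >= 1e4 bin pairs)."""
        cfg = make_config(
            layout=GenomeLayout((("chrL", 100_000_000),), bin_size=40_000),
            within_tad_boost=2.0, depth=50.0, seed=7,
        )
        tads, _ = simulate_tad_segmentation(cfg)
        m = simulate_contact_matrix(tads, cfg, "chrL").counts
        bs = 40_000
        n = m.shape[0]
        ids = np.full(n, -1)
        for t, iv in enumerate(tads):
            ids[iv.start // bs : iv.end // bs] = t
        within_vals, between_vals = [], []
        for d in range(1, 6):
            i = np.arange(n - d)
            j = i + d
            same = (ids[i] == ids[j]) & (ids[i] >= 0)
            within_vals.append(m[i[same], j[same]] / (d + 1) ** -1.0)
            between_vals.append(m[i[~same], j[~same]] / (d + 1) ** -1.0)
        within = np.concatenate(within_vals)
        between = np.concatenate(between_vals)
        assert within.size + between.size >= 10_000
        assert within.mean() / between.mean() == pytest.approx(3.0, rel=0.1)


class TestKnockdownTruth:
    def _setup(self, seed=8, **kw):
        cfg = make_config(seed=seed, **kw)
        tads, _ = simulate_tad_segmentation(cfg)
        bt = internal_boundaries(tads, cfg.layout)
        bt, assignment = assign_persistent_sites(bt, cfg, cfg.rng(11))
        return cfg, tads, bt, assignment

    def test_full_survival_is_identity(self):
        cfg, tads, bt, _ = self._setup(knockdown_boundary_survival=1.0)
        kd, events, _ = derive_knockdown_truth(tads, bt, cfg)
        assert [(iv.chrom, iv.start, iv.end) for iv in kd] == [
            (iv.chrom, iv.start, iv.end) for iv in tads
        ]
        assert events == []

    def test_total_merging_without_protection(self):
        """survival=0 and no persistent sites collapses every contiguous
        abutting block into a single domain."""
        cfg = make_config(seed=9, knockdown_boundary_survival=0.0,
                          persistent_fraction=0.0)
        tads, _ = simulate_tad_segmentation(cfg)
        bt = internal_boundaries(tads, cfg.layout)
        bt, _ = assign_persistent_sites(bt, cfg, cfg.rng(11))
        kd, events, bt2 = derive_knockdown_truth(tads, bt, cfg)
        # count contiguous abutting blocks directly from the planted tiling
        blocks = 1
        ivs = list(tads)
        for prev, nxt in zip(ivs, ivs[1:]):
            if prev.chrom != nxt.chrom or prev.end != nxt.start:
                blocks += 1
        assert len(kd) == blocks
        n_dissolved = int((bt2["abutting"] & ~bt2["survives"]).sum())
        assert sum(len(e.dissolved) for e in events) == n_dissolved

    def test_dissolution_count_matches_truth(self):
        cfg, tads, bt, _ = self._setup(seed=10)
        kd, events, bt2 = derive_knockdown_truth(tads, bt, cfg)
        n_dissolved = int((bt2["abutting"] & ~bt2["survives"]).sum())
        assert sum(len(e.dissolved) for e in events) == n_dissolved
        # persistent-carrying boundaries always survive
        assert bt2.loc[bt2["has_persistent"], "survives"].all()
        # merged spans cover their absorbed domains exactly
        for ev in events:
            assert ev.absorbing.start == ev.absorbed[0].start
            assert ev.absorbing.end == ev.absorbed[-1].end


class TestPeakCollection:
    def test_all_persistent_appears_everywhere(self):
        cfg, tads, bt, assignment = TestKnockdownTruth()._setup(
            seed=12, persistent_fraction=1.0, n_peaks=60, gained_fraction=0.0
        )
        coll, truth = simulate_peak_collection(bt, assignment, cfg)
        assert (truth["label"] == "persistent").all()
        sets = [s for _, _, s in coll.replicate_items()]
        assert len(sets) == 6
        for s in sets:
            assert len(s) == 60

    def test_bookkeeping_totals(self):
        cfg, tads, bt, assignment = TestKnockdownTruth()._setup(
            seed=13, n_peaks=150, persistent_fraction=1 / 3, gained_fraction=0.0
        )
        coll, truth = simulate_peak_collection(bt, assignment, cfg)
        counts = truth["label"].value_counts()
        assert counts["persistent"] == 50 and counts["lost"] == 100

    def test_no_same_replicate_overlap(self):
        cfg, tads, bt, assignment = TestKnockdownTruth()._setup(seed=14, n_peaks=400)
        coll, _ = simulate_peak_collection(bt, assignment, cfg)
        for _, _, s in coll.replicate_items():
            assert s.is_disjoint()

    def test_space_exhaustion_raises(self):
        layout = GenomeLayout((("tiny", 10_000),), bin_size=1_000)
        cfg = SimulationConfig(
            layout=layout, n_peaks=200, peak_width=400,
            persistent_fraction=0.0, gained_fraction=0.0,
            tad_median_bp=2_000, seed=15,
        )
        tads, _ = simulate_tad_segmentation(cfg)
        bt = internal_boundaries(tads, layout)
        bt, assignment = assign_persistent_sites(bt, cfg, cfg.rng(11))
        with pytest.raises(ValueError, match="space exhausted|could not place"):
            simulate_peak_collection(bt, assignment, cfg)


class TestCelltypePanel:
    def _truth(self, seed=16, **kw):
        cfg, tads, bt, assignment = TestKnockdownTruth()._setup(seed=seed, **kw)
        coll, truth = simulate_peak_collection(bt, assignment, cfg)
        return cfg, bt, truth

    def test_presence_counts_in_range(self):
        cfg, bt, truth = self._truth()
        bsets, psets, presence = simulate_celltype_panel(bt, truth, cfg)
        assert len(bsets) == 8 and len(psets) == 8
        assert presence["k"].between(1, 8).all()

    def test_pure_core_panel_is_fully_constitutive(self):
        cfg, bt, truth = self._truth(seed=17)
        cfg2 = SimulationConfig(**{**cfg.__dict__, "noncore_per_core": 0.0})
        _, _, presence = simulate_celltype_panel(bt, truth, cfg2)
        assert (presence["k"] == 8).all()

    def test_core_boundaries_present_in_every_member(self):
        cfg, bt, truth = self._truth(seed=18)
        bsets, _, presence = simulate_celltype_panel(bt, truth, cfg)
        core = presence[presence["is_core"]]
        flank = cfg.boundary_flank
        centers = IntervalSet(
            [
                GenomicInterval(r.chrom, max(0, r.pos - flank), r.pos + flank)
                for r in core.itertuples()
            ]
        )
        for name, s in bsets.items():
            assert overlap_flags(centers, s).all()


class TestGeneAnnotation:
    def _boundaries(self):
        return IntervalSet(
            [GenomicInterval("chrS", p, p + 200_000) for p in range(1_000_000, 18_000_000, 2_000_000)]
        )

    def test_null_multiplier_flat_rate(self):
        cfg = make_config(
            seed=19, housekeeping_boundary_enrichment=1.0, n_genes=4000
        )
        genes, flags = simulate_gene_annotation(self._boundaries(), cfg)
        d = distance_to_nearest(genes, self._boundaries())
        near = d <= cfg.housekeeping_window
        assert flags[near].mean() == pytest.approx(flags[~near].mean(), abs=0.03)
        assert flags.mean() == pytest.approx(0.10, abs=0.02)

    def test_enriched_near_boundaries(self):
        cfg = make_config(seed=20, housekeeping_boundary_enrichment=6.0, n_genes=4000)
        genes, flags = simulate_gene_annotation(self._boundaries(), cfg)
        d = distance_to_nearest(genes, self._boundaries())
        near = d <= cfg.housekeeping_window
        assert flags[near].mean() > 2.5 * flags[~near].mean()

    def test_zero_genes(self):
        cfg = make_config(seed=21, n_genes=0)
        genes, flags = simulate_gene_annotation(self._boundaries(), cfg)
        assert len(genes) == 0 and flags.size == 0
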