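"""Triad bias classification, divergence clustering and TE-in-promoter
enrichment."""

import numpy as np
import pandas as pd
import pytest

from embryodyn.intervals import GeneModel, Genome, GenomicInterval
from embryodyn.matrix import StageMatrix
from embryodyn.polyploidy import (TRIAD_CENTROIDS, classify_fractions,
                                  classify_triads, divergence_classify,
                                  te_promoter_enrichment,
                                  triad_balance_timecourse)


def triad_matrix(frac_rows, level=90.0, stages=("a", "b")):
    """One triad per row of fractions; members scaled by 3*frac."""
    genes, vals = [], []
    for t, frac in enumerate(frac_rows):
        for sg, f in zip("ABD", frac):
            genes.append(f"t{t}{sg}")
            vals.append([level * 3 * f] * len(stages))
    df = pd.DataFrame({f"{s}.r1": np.asarray(vals)[:, i]
                       for i, s in enumerate(stages)}, index=genes)
    tmap = pd.DataFrame([(f"T{t}", f"t{t}A", f"t{t}B", f"t{t}D")
                         for t in range(len(frac_rows))],
                        columns=["triad_id", "A", "B", "D"])
    return StageMatrix(df, list(stages), "TPM"), tmap


class TestCentroids:
    def test_balanced_exact(self):
        assert classify_fractions([1 / 3, 1 / 3, 1 / 3]) == "balanced"

    def test_dominant_example(self):
        assert classify_fractions([0.8, 0.1, 0.1]) == "A-dominant"

    def test_suppressed_example(self):
        assert classify_fractions([0.05, 0.475, 0.475]) == "A-suppressed"

    def test_all_centroids_self_classify(self):
        for cat, c in TRIAD_CENTROIDS.items():
            assert classify_fractions(c) == cat

    def test_noisy_centroids_mostly_recovered(self, rng):
        ok = tot = 0
        for _ in range(200):
            for cat, c in TRIAD_CENTROIDS.items():
                f = np.clip(c + rng.normal(0, 0.05, 3), 0, None)
                f = f / f.sum()
                tot += 1
                ok += classify_fractions(f) == cat
        assert ok / tot >= 0.95


class TestClassifyTriads:
    def test_fractions_and_categories(self):
        m, tmap = triad_matrix([[1 / 3, 1 / 3, 1 / 3], [0.8, 0.1, 0.1]])
        recs = classify_triads(m, tmap)
        assert recs[0].category == "balanced"
        assert recs[1].category == "A-dominant"
        assert recs[1].fractions == pytest.approx((0.8, 0.1, 0.1))

    def test_low_expression_not_categorized(self):
        m, tmap = triad_matrix([[1 / 3, 1 / 3, 1 / 3]], level=0.1)
        [rec] = classify_triads(m, tmap)
        assert not rec.expressed and rec.category is None

    def test_incomplete_triad_skipped(self):
        m, tmap = triad_matrix([[1 / 3, 1 / 3, 1 / 3]])
        tmap.loc[0, "D"] = "missing_gene"
        assert classify_triads(m, tmap) == []

    def test_invariant_to_library_scaling(self):
        m, tmap = triad_matrix([[0.5, 0.3, 0.2]])
        m2 = StageMatrix(m.df * 7.5, m.stages, m.units)
        [a] = classify_triads(m, tmap)
        [b] = classify_triads(m2, tmap)
        assert a.fractions == pytest.approx(b.fractions)

    def test_planted_categories_recovered(self, small_ds):
        from embryodyn.expression import tpm_normalize
        lengths = {g.gene_id: g.span[1] - g.span[0]
                   for g in small_ds.genome.genes}
        tpm = tpm_normalize(small_ds.expression.counts, lengths)
        tmap = small_ds.triad_map
        recs = classify_triads(tpm, tmap)
        truth = small_ds.truth.triad_category
        scored = [(r.category == truth[r.triad_id]) for r in recs
                  if r.expressed]
        assert np.mean(scored) >= 0.9


class TestDivergence:
    def anc_matrix(self, profiles, stages):
        df = pd.DataFrame({f"{s}.anc": np.asarray(profiles)[:, i]
                           for i, s in enumerate(stages)},
                          index=[f"g{i}" for i in range(len(profiles))])
        return StageMatrix(df, list(stages), "TPM")

    def test_identical_profile_conserved_negated_dysfunction(self, rng):
        stages = [f"s{i}" for i in range(8)]
        base = rng.gamma(2, 30, size=(30, 8))
        hex_m = StageMatrix(pd.DataFrame(
            {f"{s}.r1": base[:, i] for i, s in enumerate(stages)},
            index=[f"g{i}" for i in range(30)]), stages, "TPM")
        anc_vals = base.copy()
        anc_vals[0] = base[0]
        anc_vals[1] = base[1].max() - base[1]       # negated
        anc = self.anc_matrix(anc_vals, stages)
        recs = {r.gene_id: r for r in divergence_classify(hex_m, anc)}
        assert recs["g0"].r == pytest.approx(1.0)
        assert recs["g1"].r == pytest.approx(-1.0, abs=1e-9)
        assert recs["g0"].cluster == "conserved"
        assert recs["g1"].cluster == "dysfunction"

    def test_constant_profile_flagged_not_clustered(self, rng):
        stages = [f"s{i}" for i in range(4)]
        vals = rng.gamma(2, 30, size=(5, 4))
        vals[2] = 7.0
        m = StageMatrix(pd.DataFrame(
            {f"{s}.r1": vals[:, i] for i, s in enumerate(stages)},
            index=[f"g{i}" for i in range(5)]), stages, "TPM")
        anc = self.anc_matrix(vals, stages)
        recs = {r.gene_id: r for r in divergence_classify(m, anc)}
        assert recs["g2"].cluster is None
        assert np.isnan(recs["g2"].r)

    def test_threshold_mode(self, rng):
        stages = [f"s{i}" for i in range(6)]
        vals = rng.gamma(2, 30, size=(3, 6))
        m = StageMatrix(pd.DataFrame(
            {f"{s}.r1": vals[:, i] for i, s in enumerate(stages)},
            index=["g0", "g1", "g2"]), stages, "TPM")
        anc = self.anc_matrix(vals, stages)
        recs = divergence_classify(m, anc, method="threshold",
                                   thresholds=(0.3, 0.7))
        assert all(r.cluster == "conserved" for r in recs)

    def test_kmeans_rerun_stability(self, small_ds):
        hex_m = StageMatrix(
            small_ds.expression.mean_tpm.rename(columns=lambda s: f"{s}.m"),
            list(small_ds.config.stages), "TPM")
        runs = [tuple(r.cluster for r in
                      divergence_classify(hex_m, small_ds.expression.ancestor))
                for _ in range(3)]
        assert runs[0] == runs[1] == runs[2]

    def test_planted_groups_recovered_on_noiseless_profiles(self, small_ds):
        hex_m = StageMatrix(
            small_ds.expression.mean_tpm.rename(columns=lambda s: f"{s}.m"),
            list(small_ds.config.stages), "TPM")
        recs = divergence_classify(hex_m, small_ds.expression.ancestor)
        truth = small_ds.truth.divergence_label
        scored = [r.cluster == truth[r.gene_id] for r in recs if r.cluster]
        assert np.mean(scored) >= 0.9


class TestTePromoter:
    def make_genome(self, te_positions):
        genes = []
        for i in range(8):
            tss = 20_000 + i * 10_000
            genes.append(GeneModel(
                f"g{i}", "c", "+", tss=tss, tes=tss + 1_000,
                feature_intervals=[("exon", GenomicInterval(
                    "c", tss, tss + 1_000, strand="+"))]))
        tes = [GenomicInterval("c", s, e) for s, e in te_positions]
        return Genome({"c": 200_000}, genes, tes)

    def test_window_boundary_one_bp_counts(self):
        # TE ending exactly at TSS-3000+1 overlaps the half-open window
        genome = self.make_genome([(20_000 - 3_000 - 100, 20_000 - 3_000 + 1)])
        res, freq = te_promoter_enrichment(["g0"], ["g1"], genome)
        assert freq["A_with_te"] == 1

    def test_te_below_window_does_not_count(self):
        genome = self.make_genome([(20_000 - 1_400, 20_000 - 100)])
        _, freq = te_promoter_enrichment(["g0"], ["g1"], genome)
        assert freq["A_with_te"] == 0

    def test_identical_sets_p_one(self):
        tes = [(20_000 + i * 10_000 - 2_500, 20_000 + i * 10_000 - 2_000)
               for i in range(2)]
        genome = self.make_genome(tes)
        res, _ = te_promoter_enrichment(["g0", "g1"], ["g0", "g1"], genome)
        assert res.p_value == pytest.approx(1.0)

    def test_full_contrast_matches_enumeration(self):
        import math
        tes = [(20_000 + i * 10_000 - 2_500, 20_000 + i * 10_000 - 2_000)
               for i in range(4)]
        genome = self.make_genome(tes)
        set_a = [f"g{i}" for i in range(4)]       # all have the TE
        set_b = [f"g{i}" for i in range(4, 8)]    # none do
        res, freq = te_promoter_enrichment(set_a, set_b, genome)
        assert res.effect == np.inf
        assert res.p_value == pytest.approx(1 / math.comb(8, 4), rel=1e-9)

    def test_degenerate_window_rejected(self):
        genome = self.make_genome([])
        with pytest.raises(ValueError):
            te_promoter_enrichment(["g0"], ["g1"], genome, window=(3000, 1500))

    def test_planted_dysfunction_te_bias(self, small_ds):
        truth = small_ds.truth
        dys = [g for g, l in truth.divergence_label.items()
               if l == "dysfunction"]
        con = [g for g, l in truth.divergence_label.items()
               if l == "conserved"]
        res, freq = te_promoter_enrichment(dys, con, small_ds.genome)
        assert freq["A"] > freq["B"]
        assert res.p_value < 0.05


class TestTimecourse:
    def test_identical_members_always_balanced(self):
        m, tmap = triad_matrix([[1 / 3, 1 / 3, 1 / 3]] * 4,
                               stages=("a", "b", "c"))
        tc = triad_balance_timecourse(m, tmap)
        assert (tc["balanced"] == 4).all()
        assert np.allclose(tc["frac_balanced"], 1.0)

    def test_per_stage_fractions_sum_to_one(self, small_ds):
        from embryodyn.expression import tpm_normalize
        lengths = {g.gene_id: g.span[1] - g.span[0]
                   for g in small_ds.genome.genes}
        tpm = tpm_normalize(small_ds.expression.counts, lengths)
        tc = triad_balance_timecourse(tpm, small_ds.triad_map)
        frac_cols = [c for c in tc.columns if c.startswith("frac_")]
        sums = tc[frac_cols].sum(axis=1)
        assert np.allclose(sums[~sums.isna()], 1.0)
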