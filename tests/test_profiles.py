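"""Flanking-nucleosome anchors, oriented metagene averaging, gene subsets."""

import numpy as np
import pandas as pd
import pytest

import nucbarrier as nb


def genes_df(rows):
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "strand", "tss",
                                       "orf_end"])


def calls_df(dyads, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "dyad": dyads,
                         "fuzziness": np.full(len(dyads), 10.0)})


class TestFindFlanking:
    def test_watson_at_or_downstream(self):
        genes = genes_df([("g1", "chr1", "+", 1000, 3000)])
        fl = nb.find_flanking(genes, calls_df([900, 1000, 1200]))
        assert fl.loc[0, "plus1"] == 1000  # equality counts as +1
        assert fl.loc[0, "minus1"] == 900

    def test_crick_mirrored(self):
        genes = genes_df([("g1", "chr1", "-", 5000, 3000)])
        fl = nb.find_flanking(genes, calls_df([4800, 5100]))
        assert fl.loc[0, "plus1"] == 4800
        assert fl.loc[0, "minus1"] == 5100

    def test_missing_anchor_is_nan_not_error(self):
        genes = genes_df([("g1", "chr1", "+", 1000, 3000)])
        fl = nb.find_flanking(genes, calls_df([1200]))  # nothing upstream
        assert fl.loc[0, "plus1"] == 1200
        assert np.isnan(fl.loc[0, "minus1"])

    def test_three_prime_inclusive_side_is_upstream(self):
        genes = genes_df([("g1", "chr1", "+", 1000, 3000)])
        fl = nb.find_flanking(genes, calls_df([2800, 3000, 3200]), at="orf_end")
        assert fl.loc[0, "minus1"] == 3000  # at or upstream of the ORF end
        assert fl.loc[0, "plus1"] == 3200  # strictly downstream

    def test_cohort_anchors_equal_truth(self, cohort):
        fl = nb.find_flanking(cohort.genes, cohort.calls)
        m = fl.merge(cohort.truth, on="feature_id")
        assert (m["plus1"] == m["plus1_dyad"]).all()
        assert (m["minus1"] == m["minus1_dyad"]).all()


class TestAlignAverage:
    def test_single_spike_identity(self):
        d = nb.DensityMap({"chr1": np.zeros(10000)})
        d.tracks["chr1"][4000] = 1.0
        anchors = pd.DataFrame(
            {"chrom": ["chr1"], "strand": ["+"], "plus1": [4000.0]}
        )
        prof = nb.align_average(d, anchors, window=500)
        assert prof.value_at(0) == 1.0
        assert prof.mean_weight.sum() == 1.0

    def test_strand_orientation(self):
        # spikes 100 bp downstream of each anchor in transcription direction
        d = nb.DensityMap({"chr1": np.zeros(10000)})
        d.tracks["chr1"][4100] = 1.0  # Watson anchor 4000, downstream +100
        d.tracks["chr1"][6900] = 1.0  # Crick anchor 7000, downstream -100
        anchors = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "strand": ["+", "-"],
             "plus1": [4000.0, 7000.0]}
        )
        prof = nb.align_average(d, anchors, window=500)
        assert prof.value_at(100) == 1.0
        assert prof.value_at(-100) == 0.0

    def test_averaging_linearity(self, cohort, cohort_density):
        anchors = nb.find_flanking(cohort.genes, cohort.calls)
        doubled = nb.DensityMap(
            {c: 2 * t for c, t in cohort_density.tracks.items()}
        )
        p1 = nb.align_average(cohort_density, anchors, window=300)
        p2 = nb.align_average(doubled, anchors, window=300)
        np.testing.assert_allclose(p2.mean_weight, 2 * p1.mean_weight)

    def test_mirror_property(self, cohort, cohort_density):
        """-1 alignment mirrored equals aligning mirrored data with +1 semantics."""
        anchors = nb.find_flanking(cohort.genes, cohort.calls)
        pm = nb.align_average(cohort_density, anchors, window=400,
                              anchor_col="minus1")
        flipped = anchors.copy()
        flipped["strand"] = np.where(anchors["strand"] == "+", "-", "+")
        pm_flip = nb.align_average(cohort_density, flipped, window=400,
                                   anchor_col="minus1")
        np.testing.assert_allclose(pm.mirrored().mean_weight, pm_flip.mean_weight)

    def test_plus1_profile_peaks_at_origin(self, cohort, cohort_profiles):
        # pinned +1 nucleosomes put the profile maximum at offset 0
        pp, _ = cohort_profiles
        assert pp.offsets[np.argmax(pp.mean_weight)] == pytest.approx(0, abs=2)

    def test_no_anchors_is_error(self, cohort_density):
        anchors = pd.DataFrame({"chrom": [], "strand": [], "plus1": []})
        with pytest.raises(ValueError):
            nb.align_average(cohort_density, anchors, window=100)


class TestPositionDistributions:
    def test_gap_arithmetic(self):
        genes = genes_df([("g1", "chr1", "+", 400, 3000)])
        dists = nb.position_distributions(genes, calls_df([353, 553]), b=147)
        assert dists["gap"][0] == pytest.approx(53.0)
        assert dists["plus1_to_tss"][0] == pytest.approx(153.0)
        assert dists["minus1_to_tss"][0] == pytest.approx(-47.0)

    def test_touching_nucleosomes_have_zero_gap(self):
        genes = genes_df([("g1", "chr1", "+", 400, 3000)])
        dists = nb.position_distributions(genes, calls_df([353, 500]), b=147)
        assert dists["gap"][0] == pytest.approx(0.0)

    def test_cohort_gap_mean(self, cohort):
        dists = nb.position_distributions(cohort.genes, cohort.calls, b=147)
        gap = dists["gap"]
        gap = gap[np.isfinite(gap)]
        assert abs(gap.mean() - 140.0) < 3 * 25.0 / np.sqrt(len(gap)) + 1.0


class TestSubsetGenes:
    def test_long2000_strict(self):
        genes = genes_df(
            [("g1", "chr1", "+", 0, 2000), ("g2", "chr1", "+", 5000, 7001)]
        )
        sub = nb.subset_genes(genes, "long2000")
        assert list(sub["feature_id"]) == ["g2"]

    def test_clean_upstream_keeps_isolated_gene(self):
        genes = genes_df(
            [("g1", "chr1", "+", 5000, 7000), ("g2", "chr1", "+", 1000, 3500)]
        )
        # g2's ORF end is 1500 bp upstream of g1's TSS: g1 is clean
        sub = nb.subset_genes(genes, "clean_upstream1000")
        assert "g1" in list(sub["feature_id"])

    def test_clean_upstream_drops_crowded_gene(self):
        genes = genes_df(
            [("g1", "chr1", "+", 5000, 7000), ("g2", "chr1", "+", 1000, 4500)]
        )
        sub = nb.subset_genes(genes, "clean_upstream1000")
        assert "g1" not in list(sub["feature_id"])

    def test_counts_match_bruteforce_scan(self, cohort):
        genes = cohort.genes
        sub = nb.subset_genes(genes, "long2000")
        brute = sum(
            1 for _, g in genes.iterrows() if abs(g["orf_end"] - g["tss"]) > 2000
        )
        assert len(sub) == brute

        sub2 = nb.subset_genes(genes, "clean_upstream1000")
        pts = np.sort(
            np.concatenate([genes["tss"].to_numpy(float),
                            genes["orf_end"].to_numpy(float)])
        )
        brute2 = 0
        for _, g in genes.iterrows():
            lo, hi = (
                (g["tss"] - 1000, g["tss"])
                if g["strand"] == "+"
                else (g["tss"], g["tss"] + 1000)
            )
            inside = pts[(pts >= lo) & (pts <= hi)]
            others = len(inside) - int(np.sum(inside == g["tss"]))
            brute2 += others == 0
        assert len(sub2) == brute2

    def test_unknown_mode_rejected(self, cohort):
        with pytest.raises(ValueError):
            nb.subset_genes(cohort.genes, "nonsense")
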