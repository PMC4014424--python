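"""Nearest-TSS assignment and region classification."""

import numpy as np
import pytest

from nrpeak.io_formats import GeneModel, Peak
from nrpeak.peak_annotation import (
    annotate_peaks,
    assign_nearest_gene,
    classify_region,
    distal_histogram,
    map_subfeature,
    proximal_promoter_summary,
    summarize_by_distance,
    summarize_distribution,
    tss_histogram,
)


def peak_at(center: int, chrom: str = "chr1", width: int = 200) -> Peak:
    return Peak(chrom, center - width // 2, center + width - width // 2,
                peak_id=f"p{center}")


PLUS = GeneModel("plus", "chr1", "+", 50_000, 70_000)
MINUS = GeneModel("minus", "chr1", "-", 50_000, 70_000)


class TestAssignment:
    def test_upstream_of_plus_strand_is_negative(self):
        gene, d = assign_nearest_gene(peak_at(49_500), [PLUS])
        assert gene.gene_id == "plus" and d == -500

    def test_upstream_of_minus_strand_is_negative(self):
        # 500 bp 5' of a minus-strand TSS lies genomically to its right
        gene, d = assign_nearest_gene(peak_at(70_499), [MINUS])
        assert gene.gene_id == "minus" and d == -500

    def test_no_gene_on_chromosome(self):
        gene, d = assign_nearest_gene(peak_at(100, chrom="chr9"), [PLUS])
        assert gene is None and d is None
        cls = classify_region(peak_at(100, chrom="chr9"), None, None)
        assert cls.region_class == "gene_desert" and cls.gene_id is None

    def test_tie_break_is_order_independent(self):
        # two TSSs at |d| = 300 each; winner decided by |TES distance| then id
        a = GeneModel("a", "chr1", "+", 10_300, 30_000)
        b = GeneModel("b", "chr1", "-", 1_000, 9_700)  # TSS at 9699... adjust
        b = GeneModel("b", "chr1", "-", 1_000, 9_701)  # TSS = 9700
        peak = peak_at(10_000)
        winner_ab, _ = assign_nearest_gene(peak, [a, b])
        winner_ba, _ = assign_nearest_gene(peak, [b, a])
        assert winner_ab.gene_id == winner_ba.gene_id
        # b's TES (1000) is farther from the center than a's (30000-1=29999)?
        # |10000-29999| = 19999 < |10000-1000| = 9000 is false; b wins on TES
        assert winner_ab.gene_id == "b"

    def test_exhaustive_search_oracle(self):
        rng = np.random.default_rng(11)
        genes = []
        for i in range(20):
            start = int(rng.integers(0, 900_000))
            length = int(rng.integers(1_000, 40_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i:02d}", "chr1", strand, start, start + length))
        peaks = [peak_at(int(rng.integers(200, 999_000))) for _ in range(200)]
        for p in peaks:
            gene, d = assign_nearest_gene(p, genes)
            # oracle: full scan minimizing the same deterministic key
            best = min(
                genes,
                key=lambda g: (abs(p.center - g.tss), abs(p.center - g.tes), g.gene_id),
            )
            assert gene.gene_id == best.gene_id
            assert abs(d) == abs(p.center - best.tss)


class TestClassification:
    @pytest.mark.parametrize(
        "center,expected",
        [
            (49_500, "promoter"),           # d = -500
            (48_000, "promoter"),           # d = -2000, band edge inclusive
            (45_000, "five_prime_distal_I"),  # d = -5000
            (40_000, "five_prime_distal_II"),  # d = -10000 edge
            (25_000, "five_prime_distal_II"),
            (50_000, "within_gene"),        # d = 0: center on the TSS
            (60_000, "within_gene"),
            (71_000, "three_prime_proximal"),
            (75_000, "three_prime_distal_I"),
            (95_000, "three_prime_distal_II"),
            (220_000, "gene_desert"),       # 150 kb past the TES
        ],
    )
    def test_band_edges_plus_strand(self, center, expected):
        p = peak_at(center)
        gene, d = assign_nearest_gene(p, [PLUS])
        assert classify_region(p, gene, d).region_class == expected

    def test_strand_antisymmetry(self):
        """Mirroring the genome leaves every region class unchanged."""
        L = 1_000_000
        genes = [
            GeneModel("g1", "chr1", "+", 50_000, 70_000),
            GeneModel("g2", "chr1", "-", 200_000, 230_000),
        ]
        # position x mirrors to L-1-x; half-open [s,e) mirrors to [L-e, L-s)
        mirrored = [
            GeneModel(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                L - g.tx_end, L - g.tx_start,
            )
            for g in genes
        ]
        rng = np.random.default_rng(5)
        for _ in range(300):
            center = int(rng.integers(500, L - 500))
            p = peak_at(center)
            pm = peak_at(L - 1 - center)
            cls = classify_region(p, *assign_nearest_gene(p, genes))
            cls_m = classify_region(pm, *assign_nearest_gene(pm, mirrored))
            assert cls.region_class == cls_m.region_class, (center, cls, cls_m)
            assert cls.signed_tss_distance == cls_m.signed_tss_distance

    def test_proximal_flag_within_1kb(self):
        p = peak_at(49_100)  # d = -900
        cls = classify_region(p, *assign_nearest_gene(p, [PLUS]))
        assert cls.proximal_promoter and cls.region_class == "promoter"
        p2 = peak_at(47_900)  # d = -2100 -> distal I, not proximal
        cls2 = classify_region(p2, *assign_nearest_gene(p2, [PLUS]))
        assert not cls2.proximal_promoter


class TestSubfeature:
    GENE3 = GeneModel(
        "g3", "chr1", "+", 1000, 10_000,
        ((1000, 2000), (4000, 5000), (8000, 10_000)),
    )

    def test_exons_and_introns_brute_force(self):
        """Every in-gene position agrees with a direct boundary walk."""
        for center in range(1000, 10_000, 37):
            got = map_subfeature(peak_at(center), self.GENE3)
            expected = None
            for i, (s, e) in enumerate(self.GENE3.exons):
                if s <= center < e:
                    expected = f"exon {i + 1}"
                elif center < s:
                    expected = f"intron {i}"
                if expected:
                    break
            assert got == expected

    def test_minus_strand_flips_indices(self):
        gene = GeneModel(
            "gm", "chr1", "-", 1000, 10_000,
            ((1000, 2000), (4000, 5000), (8000, 10_000)),
        )
        assert map_subfeature(peak_at(9000), gene) == "exon 1"  # genomically last
        assert map_subfeature(peak_at(1500), gene) == "exon 3"
        assert map_subfeature(peak_at(6000), gene) == "intron 1"  # between exons 2,3

    def test_single_exon_gene(self):
        gene = GeneModel("gs", "chr1", "+", 1000, 3000)
        assert map_subfeature(peak_at(2000), gene) == "exon 1"

    def test_outside_body_is_an_error(self):
        with pytest.raises(ValueError):
            map_subfeature(peak_at(500), self.GENE3)


class TestSummaries:
    @staticmethod
    def _classes(counts: dict[str, int]):
        from nrpeak.peak_annotation import RegionClassification

        out = []
        for cls, n in counts.items():
            out.extend(
                RegionClassification(f"{cls}{i}", "g", -500, cls) for i in range(n)
            )
        return out

    def test_percentages_round_half_away(self):
        cls = self._classes({"promoter": 490, "gene_desert": 535})
        table = summarize_distribution(cls)
        assert table["count"].sum() == 1025
        assert int(table.loc[table.region_class == "promoter", "percent"].iloc[0]) == 48

    def test_single_class_is_100(self):
        table = summarize_distribution(self._classes({"within_gene": 7}))
        assert int(table.loc[table.region_class == "within_gene", "percent"].iloc[0]) == 100

    def test_percent_sum_within_rounding(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = {c: int(n) for c, n in zip(
                ["promoter", "within_gene", "gene_desert"], rng.integers(1, 400, 3))}
            table = summarize_distribution(self._classes(counts))
            assert abs(table["percent"].sum() - 100) <= 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_distribution([])

    def test_proximal_promoter_fraction(self):
        from nrpeak.peak_annotation import RegionClassification

        cls = [
            RegionClassification(f"p{i}", "g", -500, "promoter", None, i < 257)
            for i in range(1025)
        ]
        assert proximal_promoter_summary(cls)["percent"] == 25


class TestHistograms:
    def test_tss_histogram_counts_proximal_only(self):
        from nrpeak.peak_annotation import RegionClassification

        cls = [
            RegionClassification("a", "g", 0, "within_gene", "exon 1", True),
            RegionClassification("b", "g", -999, "promoter", None, True),
            RegionClassification("c", "g", -5000, "five_prime_distal_I"),
        ]
        h = tss_histogram(cls)
        assert h["count"].sum() == 2
        zero_bin = h[(h.bin_start <= 0) & (h.bin_end > 0)]
        assert int(zero_bin["count"].iloc[0]) == 1

    def test_empty_histogram(self):
        from nrpeak.peak_annotation import RegionClassification

        h = tss_histogram([RegionClassification("a", "g", 5000, "three_prime_distal_I")])
        assert h["count"].sum() == 0

    def test_distal_bins(self):
        from nrpeak.peak_annotation import RegionClassification

        cls = [RegionClassification("a", "g", -15_000, "five_prime_distal_II")]
        h = distal_histogram(cls)["five_prime_distal_II"]
        row = h[(h.bin_start == 10_000) & (h.bin_end == 20_000)]
        assert int(row["count"].iloc[0]) == 1


def test_enrichment_decays_with_distance_in_generator(bundle):
    """Planted enrichment decreases with |TSS distance|: band medians are
    monotone non-increasing."""
    peaks = bundle.peaks_by_stratum["D8"]
    genes = bundle.genes
    cls = annotate_peaks(peaks, genes)
    table = summarize_by_distance(cls, peaks, bundle.expression)
    medians = table["enrichment_median"].dropna().tolist()
    assert all(a >= b for a, b in zip(medians, medians[1:]))
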