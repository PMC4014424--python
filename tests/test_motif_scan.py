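"""Repeat-element grammar scanner vs an independent brute-force oracle."""

import numpy as np
import pytest

from nrpeak.io_formats import Peak, revcomp
from nrpeak.nr_motif_scan import (
    HALF_SITES,
    HalfSiteModel,
    best_element,
    compare_strata,
    extract_window,
    find_elements,
    frequency_table,
    no_call,
)


# --------------------------------------------------------------------------
# independent oracle: direct enumeration of (position, family, spacer, strand)
# --------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _half_mm(six: str) -> int:
    if "N" in six:
        return 99
    return min(_hamming(six, h) for h in HALF_SITES)


def _half_mm_rc(six: str) -> int:
    if "N" in six:
        return 99
    return min(_hamming(six, revcomp(h)) for h in HALF_SITES)


def oracle_scan(seq: str, per_half: int = 1, total: int = 2):
    """All (family, spacer, strand, start, mismatches) tuples by brute force.

    IR/ER are strand-symmetric and enumerated once on +; DR is enumerated on
    both strands (the - strand via reverse-complement of the element).
    """
    seq = seq.upper()
    hits = []
    for n in range(0, 9):
        span = 12 + n
        for p in range(0, len(seq) - span + 1):
            sub = seq[p : p + span]
            if "N" in sub:
                continue
            h1, h2 = sub[:6], sub[6 + n :]
            combos = {
                ("DR", "+"): _half_mm(h1) + _half_mm(h2),
                ("IR", "+"): _half_mm(h1) + _half_mm_rc(h2),
                ("ER", "+"): _half_mm_rc(h1) + _half_mm(h2),
            }
            # DR on the minus strand: revcomp(sub) must be a plus-strand DR
            rc = revcomp(sub)
            combos[("DR", "-")] = _half_mm(rc[:6]) + _half_mm(rc[6 + n :])
            for (family, strand), mm in combos.items():
                halves = {
                    ("DR", "+"): (_half_mm(h1), _half_mm(h2)),
                    ("IR", "+"): (_half_mm(h1), _half_mm_rc(h2)),
                    ("ER", "+"): (_half_mm_rc(h1), _half_mm(h2)),
                    ("DR", "-"): (_half_mm(rc[:6]), _half_mm(rc[6 + n :])),
                }[(family, strand)]
                if max(halves) <= per_half and mm <= total:
                    hits.append((family, n, strand, p, mm))
    return sorted(hits)


def random_seq(rng: np.random.Generator, length: int = 250) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# --------------------------------------------------------------------------
# constructed examples
# --------------------------------------------------------------------------

class TestGrammarExamples:
    def test_dr1_with_a_spacer(self):
        calls = find_elements("AGGTCAAAGGTCA")
        exact = [c for c in calls if c.mismatches == 0]
        assert len(exact) == 1
        c = exact[0]
        assert (c.family, c.spacer, c.spacer_sequence, c.start) == ("DR", 1, "A", 0)

    def test_ir1_by_construction(self):
        calls = find_elements("AGGTCA" + "T" + revcomp("AGGTCA"))
        exact = [c for c in calls if c.mismatches == 0 and c.family == "IR"]
        assert [(c.spacer, c.start) for c in exact] == [(1, 0)]

    def test_er6_by_construction(self):
        seq = revcomp("AGTTCA") + "GATCGA" + "AGAACA"
        exact = [c for c in find_elements(seq) if c.mismatches == 0 and c.family == "ER"]
        assert [(c.spacer, c.start) for c in exact] == [(6, 0)]

    def test_minus_strand_dr(self):
        seq = revcomp("AGGTCA" + "G" + "AGTTCA")
        exact = [c for c in find_elements(seq) if c.mismatches == 0]
        assert [(c.family, c.spacer, c.strand) for c in exact] == [("DR", 1, "-")]

    def test_n_never_matches(self):
        assert not [
            c for c in find_elements("AGGTCANAGGTCA") if c.mismatches == 0
        ]
        # N in a half-site disqualifies even under the mismatch budget
        calls = find_elements("AGGTCNAGGTCA")
        assert all(c.spacer != 0 or c.mismatches >= 1 for c in calls)
        assert not [c for c in calls if c.start == 0 and c.spacer == 0]

    def test_short_sequence_no_calls(self):
        assert find_elements("AGGTCA") == []


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            seq = random_seq(rng)
            got = sorted(
                (c.family, c.spacer, c.strand, c.start, c.mismatches)
                for c in find_elements(seq)
            )
            assert got == oracle_scan(seq)

    def test_matches_oracle_at_zero_budget(self):
        rng = np.random.default_rng(7)
        model = HalfSiteModel(max_mismatch_per_half=0, max_total_mismatch=0)
        for _ in range(10):
            seq = random_seq(rng)
            got = sorted(
                (c.family, c.spacer, c.strand, c.start, c.mismatches)
                for c in find_elements(seq, model)
            )
            assert got == oracle_scan(seq, per_half=0, total=0)


class TestProperties:
    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = random_seq(rng, 120)
            fwd = sorted(
                (c.family, c.spacer, c.mismatches) for c in find_elements(seq)
            )
            rev = sorted(
                (c.family, c.spacer, c.mismatches)
                for c in find_elements(revcomp(seq))
            )
            assert fwd == rev

    def test_minus_dr_mirrors_plus_dr(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            seq = random_seq(rng, 120)
            minus = {
                (c.spacer, len(seq) - (c.start + 12 + c.spacer), c.mismatches)
                for c in find_elements(seq)
                if c.family == "DR" and c.strand == "-"
            }
            plus_of_rc = {
                (c.spacer, c.start, c.mismatches)
                for c in find_elements(revcomp(seq))
                if c.family == "DR" and c.strand == "+"
            }
            assert minus == plus_of_rc

    def test_budget_monotonicity(self):
        rng = np.random.default_rng(13)
        loose = HalfSiteModel(max_mismatch_per_half=1, max_total_mismatch=2)
        tight = HalfSiteModel(max_mismatch_per_half=1, max_total_mismatch=1)
        for _ in range(10):
            seq = random_seq(rng, 150)
            keys = lambda calls: {
                (c.family, c.spacer, c.strand, c.start) for c in calls
            }
            assert keys(find_elements(seq, tight)) <= keys(find_elements(seq, loose))


class TestBestElement:
    def _call(self, family, spacer, mm, start=0, strand="+"):
        from nrpeak.nr_motif_scan import RepeatElementCall

        return RepeatElementCall("p", family, spacer, strand, start, mm, "")

    def test_fewest_mismatches_wins(self):
        best = best_element([self._call("IR", 1, 1), self._call("DR", 1, 0)])
        assert (best.family, best.mismatches) == ("DR", 0)

    def test_family_order_breaks_ties(self):
        best = best_element([self._call("IR", 1, 1), self._call("DR", 4, 1)])
        assert best.family == "DR" and best.spacer == 4

    def test_empty_gives_none(self):
        assert best_element([], "pk").family is None
        assert best_element([], "pk").label == "none"


class TestWindow:
    def test_centered_arithmetic(self):
        genome = {"chr1": "A" * 2000}
        p = Peak("chr1", 900, 1100, peak_id="x")  # center 1000
        assert len(extract_window(p, genome)) == 250

    def test_truncation_at_contig_edge(self):
        genome = {"chr1": "A" * 300}
        p = Peak("chr1", 0, 100, peak_id="x")  # center 50
        assert len(extract_window(p, genome)) == 175  # [0, 175)

    def test_absent_chromosome_raises(self):
        with pytest.raises(KeyError):
            extract_window(Peak("chrZ", 0, 100, peak_id="x"), {"chr1": "A" * 300})

    def test_planted_motif_recovered_through_window(self, bundle):
        peaks = {p.peak_id: p for p in bundle.peaks_by_stratum["D8"]}
        planted = [
            r for r in bundle.manifest["peaks"]["D8"] if r["motif"] is not None
        ][:20]
        for rec in planted:
            window = extract_window(peaks[rec["peak_id"]], bundle.genome)
            motif = rec["motif"]
            off = motif["window_offset"]
            assert window[off : off + len(motif["sequence"])] == motif["sequence"]


class TestFrequencyTables:
    def _best_calls(self, labels):
        calls = []
        for i, lbl in enumerate(labels):
            if lbl == "none":
                calls.append(no_call(f"p{i}"))
            else:
                from nrpeak.nr_motif_scan import RepeatElementCall

                calls.append(
                    RepeatElementCall(f"p{i}", lbl[:2], int(lbl[2:]), "+", 0, 0, "")
                )
        return calls

    def test_percentages_complete_to_100(self):
        table = frequency_table(
            {"all": self._best_calls(["DR1"] * 29 + ["none"] * 71)}
        )
        dr1 = table[(table.stratum == "all") & (table.motif == "DR1")]
        none = table[(table.stratum == "all") & (table.motif == "none")]
        assert float(dr1["percent"].iloc[0]) == 29.0
        assert float(none["percent"].iloc[0]) == 71.0
        assert np.isclose(table["percent"].sum(), 100.0)

    def test_all_none(self):
        table = frequency_table({"s": self._best_calls(["none"] * 5)})
        assert float(table["percent"].iloc[0]) == 100.0

    def test_empty_stratum_is_an_error(self):
        with pytest.raises(ValueError):
            frequency_table({"s": []})

    def test_identical_tables_give_null_comparison(self):
        t = frequency_table({"s": self._best_calls(["DR1"] * 3 + ["none"] * 7)})
        cmp = compare_strata(t, t)
        assert np.allclose(cmp["delta"], 0.0)
        assert np.allclose(cmp["pvalue"], 1.0)

    def test_large_cohort_difference_is_significant(self):
        prox = frequency_table(
            {"p": self._best_calls(["DR1"] * 72 + ["none"] * (257 - 72))}
        )  # 28% of 257
        dist = frequency_table(
            {"d": self._best_calls(["DR1"] * 39 + ["none"] * (490 - 39))}
        )  # 8% of 490
        cmp = compare_strata(prox, dist)
        row = cmp[cmp.motif == "DR1"].iloc[0]
        assert row["delta"] < 0 and row["pvalue"] < 0.01

    def test_single_peak_strata_do_not_crash(self):
        a = frequency_table({"a": self._best_calls(["DR1"])})
        b = frequency_table({"b": self._best_calls(["none"])})
        cmp = compare_strata(a, b)
        assert np.isfinite(cmp["pvalue"]).all()
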