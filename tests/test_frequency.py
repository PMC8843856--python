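import math

import numpy as np
import pandas as pd
import pytest

from oracles import fisher_greater_brute

from polyte.core import PolyteError, PopulationAssignment
from polyte.frequency import (
    benjamini_hochberg,
    classify_sharing,
    distance_sharing_correlation,
    fisher_exact_greater,
    insertion_frequencies,
    low_frequency_bias_test,
    sfs_and_composition,
    shared_te_count_matrix,
)


def _pops(n_per=4, labels=("NE", "NW", "S")):
    return PopulationAssignment.from_pairs(
        (f"{lab}_{i}", lab) for lab in labels for i in range(n_per)
    )


def _matrix(columns, pops):
    return pd.DataFrame(columns, index=pops.accessions)


class TestInsertionFrequencies:
    def test_three_of_ten(self):
        pops = PopulationAssignment.from_pairs((f"a{i}", "X" if i < 5 else "Y") for i in range(10))
        matrix = pd.DataFrame({"L1": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]}, index=pops.accessions)
        out = insertion_frequencies(matrix, pops)
        assert out["freq_overall"].iloc[0] == pytest.approx(0.3)

    def test_complete_case_with_na(self):
        pops = PopulationAssignment.from_pairs((f"a{i}", "X" if i < 5 else "Y") for i in range(10))
        col = [1, 1, 1, 0, 0, 0, 0, 0, np.nan, np.nan]
        matrix = pd.DataFrame({"L1": col}, index=pops.accessions)
        out = insertion_frequencies(matrix, pops)
        assert out["freq_overall"].iloc[0] == pytest.approx(3 / 8)

    def test_all_na_flagged(self):
        pops = PopulationAssignment.from_pairs([("a0", "X"), ("a1", "Y")])
        matrix = pd.DataFrame({"L1": [np.nan, np.nan]}, index=pops.accessions)
        out = insertion_frequencies(matrix, pops)
        assert math.isnan(out["freq_overall"].iloc[0])


class TestClassifySharing:
    def test_examples(self):
        pops = _pops()
        freqs = pd.DataFrame(
            {
                "locus_id": ["L1", "L2", "L3"],
                "freq_overall": [0.1, 0.4, 0.0],
                "freq_NE": [0.2, 0.2, 0.0],
                "freq_NW": [0.0, 0.1, 0.3],
                "freq_S": [0.0, 0.9, 0.2],
            }
        )
        out = classify_sharing(freqs, pops)
        assert out["sharing_class"].tolist() == [
            "pop-specific:NE",
            "all-shared",
            "partial",
        ]

    def test_planted_specific_fraction_recovered(self):
        from polyte.simulate import simulate_te_genotype_matrix

        loci, matrix, _ = simulate_te_genotype_matrix(
            400, {"NE": 20, "NW": 20, "S": 20}, pop_specific_fraction=0.1, seed=11
        )
        pops = PopulationAssignment.from_pairs(
            (a, a.rsplit("_", 1)[0]) for a in matrix.index
        )
        freqs = classify_sharing(insertion_frequencies(matrix, pops), pops)
        specific = freqs["sharing_class"].str.startswith("pop-specific").mean()
        # planted 10% are specific by construction; baseline loci can also
        # be incidentally specific, so check at least the planted mass
        planted = (loci["planted_specific_pop"] != "").mean()
        assert specific >= planted - 3 * np.sqrt(planted * (1 - planted) / 400)

    def test_specific_locus_zero_elsewhere(self):
        from polyte.simulate import simulate_te_genotype_matrix

        loci, matrix, _ = simulate_te_genotype_matrix(
            50, {"NE": 10, "NW": 10, "S": 10}, pop_specific_fraction=0.2, seed=5
        )
        pops = PopulationAssignment.from_pairs(
            (a, a.rsplit("_", 1)[0]) for a in matrix.index
        )
        freqs = insertion_frequencies(matrix, pops).set_index("locus_id")
        for row in loci.itertuples():
            if row.planted_specific_pop:
                for pop in ("NE", "NW", "S"):
                    if pop != row.planted_specific_pop:
                        assert freqs.loc[row.locus_id, f"freq_{pop}"] == 0.0


class TestLowFrequencyBias:
    def _tables(self, cds_low, cds_high, ig_low, ig_high):
        rows = []
        freqs = []
        i = 0
        for cat, low, high in [("CDS", cds_low, cds_high), ("intergenic", ig_low, ig_high)]:
            for _ in range(low):
                rows.append({"locus_id": f"L{i}", "genic_category": cat})
                freqs.append({"locus_id": f"L{i}", "freq_overall": 0.05})
                i += 1
            for _ in range(high):
                rows.append({"locus_id": f"L{i}", "genic_category": cat})
                freqs.append({"locus_id": f"L{i}", "freq_overall": 0.5})
                i += 1
        return pd.DataFrame(freqs), pd.DataFrame(rows)

    def test_odds_ratio_16(self):
        freqs, cats = self._tables(8, 2, 20, 80)
        out = low_frequency_bias_test(freqs, cats)
        assert out["odds_ratio"].iloc[0] == pytest.approx(16.0)
        assert out["p_value"].iloc[0] == pytest.approx(
            fisher_greater_brute(8, 2, 20, 80), abs=1e-12
        )

    def test_identical_proportions_null(self):
        freqs, cats = self._tables(10, 30, 20, 60)
        out = low_frequency_bias_test(freqs, cats)
        assert out["odds_ratio"].iloc[0] == pytest.approx(1.0)
        assert out["p_value"].iloc[0] >= 0.5

    def test_empty_reference_error(self):
        freqs, cats = self._tables(5, 5, 0, 0)
        with pytest.raises(PolyteError):
            low_frequency_bias_test(freqs, cats)

    def test_fisher_matches_oracle_small_margins(self, rng):
        from scipy import stats

        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            table = np.array([[a, b], [c, d]])
            _, p = fisher_exact_greater(table)
            assert p == pytest.approx(fisher_greater_brute(a, b, c, d), abs=1e-12)

    def test_bh_correction_matches_reference(self):
        p = [0.01, 0.04, 0.03, 0.5]
        from scipy.stats import false_discovery_control

        assert benjamini_hochberg(p) == pytest.approx(
            list(false_discovery_control(p, method="bh")), abs=1e-12
        )


class TestSfsComposition:
    def _freqs(self, values, classes=None):
        n = len(values)
        out = pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(n)],
                "freq_overall": values,
            }
        )
        if classes is not None:
            out["sharing_class"] = classes
        return out

    def _loci(self, superfamilies):
        return pd.DataFrame(
            {
                "locus_id": [f"L{i}" for i in range(len(superfamilies))],
                "superfamily": superfamilies,
            }
        )

    def test_all_low_first_bin(self):
        hist, _ = sfs_and_composition(
            self._freqs([0.05] * 7), self._loci(["Gypsy"] * 7)
        )
        assert hist["count"].iloc[0] == 7
        assert hist["count"].sum() == 7

    def test_composition_sums_to_one(self):
        values = [0.1, 0.9, 0.5, 0.3]
        classes = ["all-shared", "all-shared", "pop-specific:NE", "partial"]
        hist, comp = sfs_and_composition(
            self._freqs(values, classes), self._loci(["Gypsy", "Copia", "Helitron", "Gypsy"])
        )
        for group, sub in comp.groupby("group"):
            assert sub["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_u_shape_recovered(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            f = rng.beta(0.3, 0.3, size=300)
            hist, _ = sfs_and_composition(
                self._freqs(f), self._loci(["other"] * 300)
            )
            counts = hist["count"].to_numpy()
            extremes = counts[0] + counts[-1]
            if extremes == max(
                counts[i] + counts[j]
                for i in range(10)
                for j in range(i + 1, 10)
            ):
                hits += 1
        assert hits >= 19


class TestDistanceSharing:
    def test_perfect_negative(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dist = pd.DataFrame(d, index=list("abc"), columns=list("abc"))
        shared = pd.DataFrame(-d, index=list("abc"), columns=list("abc"))
        out = distance_sharing_correlation(dist, shared)
        assert out["r"] == pytest.approx(-1.0)

    def test_single_pair_error(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(PolyteError):
            distance_sharing_correlation(d, d)

    def test_constant_vector_flagged(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        s = pd.DataFrame(np.ones((4, 4)), index=list("abcd"), columns=list("abcd"))
        out = distance_sharing_correlation(d, s)
        assert math.isnan(out["r"])

    def test_null_r_small(self, rng):
        n = 50
        rs = []
        for _ in range(20):
            x = rng.normal(size=(n, n))
            x = x + x.T
            y = rng.normal(size=(n, n))
            y = y + y.T
            dist = pd.DataFrame(x, index=range(n), columns=range(n))
            shared = pd.DataFrame(y, index=range(n), columns=range(n))
            rs.append(distance_sharing_correlation(dist, shared)["r"])
        assert abs(np.mean(rs)) < 0.02

    def test_shared_count_matrix(self):
        pops = PopulationAssignment.from_pairs([("a", "X"), ("b", "X"), ("c", "Y")])
        matrix = pd.DataFrame(
            {"L1": [1, 1, 0], "L2": [1, np.nan, 1], "L3": [0, 1, 1]},
            index=["a", "b", "c"],
        )
        shared = shared_te_count_matrix(matrix)
        assert shared.loc["a", "b"] == 1  # L1 only (L2 NA for b)
        assert shared.loc["a", "c"] == 1  # L2
        assert shared.loc["b", "c"] == 1  # L3
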