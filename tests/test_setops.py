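"""Target-set algebra: quadrants, NAC classes, dimers, category tables."""

import numpy as np
import pandas as pd
import pytest

from rncmap.containers import InvalidConfigError, TargetSet
from rncmap.setops import (
    ConsistencyError,
    EmptyClassError,
    MissingAnnotationError,
    category_table,
    category_table_from_counts,
    dimer_assign,
    enrichment_distribution,
    nac_dependence,
    quadrant_classify,
    round_percent,
    sstm_fraction,
)


def ts(genes, condition="x", q=1.0):
    return TargetSet(condition=condition, q_threshold=q, genes=frozenset(genes))


@pytest.fixture()
def random_universe(rng):
    universe = {f"g{i:03d}" for i in range(200)}
    pick = lambda frac: {g for g in universe if rng.random() < frac}
    return universe, pick


class TestQuadrants:
    def test_definitional_cases(self):
        universe = {"a", "b", "c", "d"}
        labels = quadrant_classify(ts({"a", "b"}), ts({"b", "c"}), universe)
        assert labels["a"] == "SRP+/Mem-"
        assert labels["b"] == "SRP+/Mem+"
        assert labels["c"] == "SRP-/Mem+"
        assert labels["d"] == "SRP-/Mem-"

    def test_empty_sets_give_all_negative(self):
        universe = {"a", "b"}
        labels = quadrant_classify(ts(set()), ts(set()), universe)
        assert (labels == "SRP-/Mem-").all()

    def test_counts_partition_universe(self, random_universe):
        universe, pick = random_universe
        srp, mem = pick(0.3), pick(0.4)
        labels = quadrant_classify(ts(srp), ts(mem), universe)
        counts = labels.value_counts()
        assert counts.sum() == len(universe)
        # brute-force recount
        assert counts.get("SRP+/Mem+", 0) == len(srp & mem)
        assert counts.get("SRP+/Mem-", 0) == len(srp - mem)
        assert counts.get("SRP-/Mem+", 0) == len(mem - srp)
        assert counts.get("SRP-/Mem-", 0) == len(universe - srp - mem)

    def test_symmetry_transposes_counts(self, random_universe):
        universe, pick = random_universe
        a, b = pick(0.25), pick(0.5)
        ab = quadrant_classify(ts(a), ts(b), universe).value_counts()
        ba = quadrant_classify(ts(b), ts(a), universe).value_counts()
        assert ab.get("SRP+/Mem-", 0) == ba.get("SRP-/Mem+", 0)
        assert ab.get("SRP+/Mem+", 0) == ba.get("SRP+/Mem+", 0)

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ConsistencyError):
            quadrant_classify(ts({"zz"}), ts(set()), {"a"})


class TestNacDependence:
    def test_identical_sets_all_independent(self):
        universe = {"a", "b", "c"}
        labels = nac_dependence(ts({"a", "b"}), ts({"a", "b"}), universe)
        assert (labels[["a", "b"]] == "NAC-independent").all()
        assert labels["c"] == "none"

    def test_disjoint_sets(self):
        universe = {"a", "b", "c", "d"}
        labels = nac_dependence(ts({"a"}), ts({"b", "c"}), universe)
        assert (labels == "NAC-dependent").sum() == 1
        assert (labels == "Off-target").sum() == 2

    def test_counts_match_set_expressions(self, random_universe):
        universe, pick = random_universe
        wt, dn = pick(0.3), pick(0.3)
        labels = nac_dependence(ts(wt), ts(dn), universe)
        counts = labels.value_counts()
        assert counts.get("NAC-independent", 0) == len(wt & dn)
        assert counts.get("NAC-dependent", 0) == len(wt - dn)
        assert counts.get("Off-target", 0) == len(dn - wt)
        assert counts.sum() == len(universe)

    def test_idempotent_relabeling(self, random_universe):
        universe, pick = random_universe
        wt, dn = pick(0.2), pick(0.4)
        first = nac_dependence(ts(wt), ts(dn), universe)
        second = nac_dependence(ts(wt), ts(dn), set(first.index))
        pd.testing.assert_series_equal(first, second)


class TestDimerAssign:
    def test_unique_egd2_is_homodimer(self):
        labels = dimer_assign(ts(set()), ts({"a"}), ts(set()))
        assert labels["a"] == "Egd2-homodimer"

    def test_triple_overlap_goes_to_egd1_egd2(self):
        labels = dimer_assign(ts({"a"}), ts({"a"}), ts({"a"}))
        assert labels["a"] == "Egd1/Egd2"

    def test_class_counts_match_recount(self, rng):
        pool = [f"g{i}" for i in range(100)]
        e1 = {g for g in pool if rng.random() < 0.4}
        e2 = {g for g in pool if rng.random() < 0.5}
        b1 = {g for g in pool if rng.random() < 0.3}
        labels = dimer_assign(ts(e1), ts(e2), ts(b1))
        counts = labels.value_counts()
        assert counts.get("Egd1/Egd2", 0) == len(e1 & e2)
        assert counts.get("Btt1/Egd2", 0) == len((e2 & b1) - e1)
        assert counts.get("Egd2-homodimer", 0) == len(e2 - e1 - b1)
        assert counts.get("Btt1-homodimer", 0) == len(b1 - e2 - e1)
        assert counts.get("Egd1-only", 0) == len(e1 - e2 - b1)
        assert counts.get("unassigned", 0) == len((e1 & b1) - e2)
        assert counts.sum() == len(e1 | e2 | b1)


class TestSstmFraction:
    def make_annotations(self, flags):
        return pd.DataFrame(
            {
                "gene_id": list(flags),
                "has_ss": [f[0] for f in flags.values()],
                "has_tm": [f[1] for f in flags.values()],
            }
        ).set_index("gene_id")

    def test_pure_ss_set(self):
        ann = self.make_annotations({"a": (True, False), "b": (True, False)})
        frac = sstm_fraction(ts({"a", "b"}), ann)
        assert frac == {"ss_only": 1.0, "tm_only": 0.0, "both": 0.0, "neither": 0.0}

    def test_fractions_sum_to_one_and_match_recount(self, rng):
        flags = {
            f"g{i}": (bool(rng.random() < 0.3), bool(rng.random() < 0.4))
            for i in range(120)
        }
        ann = self.make_annotations(flags)
        targets = {g for g in flags if rng.random() < 0.5}
        frac = sstm_fraction(ts(targets), ann)
        assert sum(frac.values()) == pytest.approx(1.0)
        n = len(targets)
        assert frac["both"] == pytest.approx(
            sum(1 for g in targets if flags[g] == (True, True)) / n
        )
        assert frac["neither"] == pytest.approx(
            sum(1 for g in targets if flags[g] == (False, False)) / n
        )

    def test_unannotated_gene_rejected(self):
        ann = self.make_annotations({"a": (True, False)})
        with pytest.raises(MissingAnnotationError):
            sstm_fraction(ts({"a", "zz"}), ann)


class TestCategoryTable:
    def test_published_percentage_examples(self):
        # 63 of 213 -> 29.6%; 40 of 541 -> 7.4%
        assert round_percent(63, 213) == 29.6
        assert round_percent(40, 541) == 7.4

    def test_rounding_is_half_up(self):
        assert round_percent(1, 16) == 6.3  # 6.25 rounds up, not to even
        assert round_percent(3, 8) == 37.5

    def test_multi_membership_counts_once_per_category(self):
        cmap = {"a": {"X", "Y"}, "b": {"X"}, "c": set()}
        table = category_table(ts({"a", "b", "c"}), cmap)
        rows = table.rows.set_index("category")
        assert rows.loc["X", "count"] == 2
        assert rows.loc["Y", "count"] == 1
        assert rows["count"].sum() == 3  # may exceed total by design
        assert table.total == 3

    def test_rows_sorted_by_descending_count(self, rng):
        cmap = {
            f"g{i}": {c for c in "ABCD" if rng.random() < 0.5} for i in range(50)
        }
        table = category_table(ts(set(cmap)), cmap)
        counts = table.rows["count"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidConfigError):
            category_table(ts(set()), {})
        with pytest.raises(InvalidConfigError):
            category_table_from_counts({"X": 1}, total=0)


class TestEnrichmentDistribution:
    def test_constant_scores_collapse_box(self):
        scores = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        stats = enrichment_distribution({"only": {"a", "b", "c"}}, scores)
        box = stats["only"]
        assert box.median == box.q25 == box.q75 == 2.0

    def test_shifted_class_has_higher_median(self, rng):
        scores = pd.Series(
            {f"tm{i}": rng.normal(3, 0.5) for i in range(40)}
            | {f"no{i}": rng.normal(0, 0.5) for i in range(40)}
        )
        classes = {
            "TM": {f"tm{i}" for i in range(40)},
            "neither": {f"no{i}" for i in range(40)},
        }
        stats = enrichment_distribution(classes, scores)
        assert stats["TM"].median > stats["neither"].median

    def test_medians_match_recount(self, rng):
        scores = pd.Series({f"g{i}": float(rng.normal()) for i in range(30)})
        members = {f"g{i}" for i in range(0, 30, 2)}
        stats = enrichment_distribution({"even": members}, scores)
        assert stats["even"].median == pytest.approx(
            float(np.median([scores[g] for g in members]))
        )

    def test_empty_class_rejected(self):
        with pytest.raises(EmptyClassError):
            enrichment_distribution({"none": set()}, pd.Series(dtype=float))
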