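"""Haplogroup calling, enumeration, deduplication and frequency tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ytopo.haplogroups import (InconsistentProfileError, MarkerTree,
                               adjust_pvalues, assign_haplogroup,
                               canonical_profile, dedup_paternal_relatives,
                               enumerate_haplogroups, fisher_exact_2x2,
                               frequency_table_from_counts,
                               haplogroup_frequencies, modified_wald_ci,
                               round_half_away)
from ytopo.io import IndividualRecord

from .conftest import full_profile


# ---------------------------------------------------------------------------
# assignment

class TestAssign:
    def test_canonical_r_u152_profile(self, tree):
        """The fully derived R1b chain down to U152/S28 gets the terminal label."""
        call = assign_haplogroup(canonical_profile(tree, "U152/S28"), tree)
        assert call.label == "R-U152/S28"
        assert call.path[-1] == "U152/S28"
        assert not call.star

    def test_all_ancestral_is_root_paragroup(self, tree):
        call = assign_haplogroup(canonical_profile(tree, None), tree)
        assert call.label == "Y*"
        assert call.star and call.path == ()

    def test_star_requires_typed_ancestral_children(self, tree):
        """Derived S116 with both sub-markers ancestral is the paragroup R-S116*;
        with untyped sub-markers no star can be claimed."""
        prof = canonical_profile(tree, "S116")
        assert assign_haplogroup(prof, tree).label == "R-S116*"
        for kid in ("U152/S28", "M529/S145"):
            prof.pop(kid)
        assert assign_haplogroup(prof, tree).label == "R-S116"

    def test_missing_on_path_tolerated_with_deeper_derived(self, tree):
        """An untyped marker inside a derived chain does not break the call."""
        prof = canonical_profile(tree, "U152/S28")
        prof.pop("M412/S167")
        assert assign_haplogroup(prof, tree).label == "R-U152/S28"

    def test_truncates_at_last_confirmed_marker(self, tree):
        """With the deep markers missing the call stops at the deepest
        confirmed derived marker."""
        prof = canonical_profile(tree, "U152/S28")
        for m in ("U152/S28", "S116", "L11/S127"):
            prof[m] = "missing"
        assert assign_haplogroup(prof, tree).label.startswith("R-M412/S167")

    def test_derived_under_typed_ancestral_parent_is_inconsistent(self, tree):
        prof = canonical_profile(tree, "U152/S28")
        prof["S116"] = "ancestral"
        with pytest.raises(InconsistentProfileError) as exc:
            assign_haplogroup(prof, tree)
        assert ("S116", "U152/S28") in exc.value.pairs

    def test_two_incompatible_branches_inconsistent(self, tree):
        prof = canonical_profile(tree, "M253")
        prof["M304"] = "derived"
        with pytest.raises(InconsistentProfileError):
            assign_haplogroup(prof, tree)

    def test_empty_genotype_rejected(self, tree):
        with pytest.raises(ValueError):
            assign_haplogroup({}, tree)

    def test_round_trip_every_canonical_profile(self, tree):
        """Each distinguishable label maps back to itself through its own
        canonical profile (full enumeration round trip)."""
        children = tree.children
        for label in enumerate_haplogroups(tree):
            if label == "Y*":
                marker = None
            else:
                marker = label.split("-", 1)[1].rstrip("*")
            call = assign_haplogroup(canonical_profile(tree, marker), tree)
            assert call.label == label


# ---------------------------------------------------------------------------
# enumeration

def brute_force_labels(tree):
    """Independent enumeration: run every consistent fully typed profile
    through the caller and collect distinct labels."""
    markers = sorted(tree.markers)
    labels = set()
    # consistent fully typed profiles = derived exactly along a root path
    terminals = [None] + markers
    for term in terminals:
        labels.add(assign_haplogroup(canonical_profile(tree, term), tree).label)
    return labels


class TestEnumerate:
    def test_linear_chain(self):
        t = MarkerTree(parent={"A1": "ROOT", "A2": "A1"},
                       major={"A1": "H", "A2": "H"})
        labels = enumerate_haplogroups(t)
        assert sorted(labels) == ["H-A1*", "H-A2", "Y*"]

    def test_canonical_tree_matches_brute_force(self, tree):
        labels = enumerate_haplogroups(tree)
        assert set(labels) == brute_force_labels(tree)
        assert len(labels) == len(set(labels))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_trees_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        parent = {}
        names = [f"M{i}" for i in range(n)]
        for i, name in enumerate(names):
            parent[name] = "ROOT" if i == 0 else names[int(rng.integers(0, i))]
        t = MarkerTree(parent=parent, major={m: "X" for m in names})
        labels = enumerate_haplogroups(t)
        assert set(labels) == brute_force_labels(t)
        # one outcome per marker plus the root paragroup
        assert len(labels) == n + 1


# ---------------------------------------------------------------------------
# tree validation

class TestTreeValidation:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle|not in the tree"):
            MarkerTree(parent={"A": "B", "B": "A"}, major={"A": "X", "B": "X"})

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="not in the tree"):
            MarkerTree(parent={"A": "Z"}, major={"A": "X"})

    def test_major_letter_cannot_reappear(self):
        with pytest.raises(ValueError, match="reappears"):
            MarkerTree(parent={"A": "ROOT", "B": "A", "C": "B"},
                       major={"A": "R", "B": "Q", "C": "R"})


# ---------------------------------------------------------------------------
# dedup

def _rec(rid, hg="R-M17", profile=None, descent="g1"):
    return IndividualRecord(id=rid, snp_profile={}, haplogroup=hg,
                            str_profile=profile or full_profile(),
                            descent_group=descent)


class TestDedup:
    def test_identical_triplet_keeps_smallest_id(self):
        records = [_rec("c"), _rec("a"), _rec("b", hg="I-M253", descent="g2")]
        kept, removed = dedup_paternal_relatives(records)
        assert [r.id for r in kept] == ["a", "b"]
        assert [r.id for r in removed] == ["c"]

    def test_distinct_descent_groups_not_collapsed(self):
        records = [_rec("a", descent="g1"), _rec("b", descent="g2")]
        kept, removed = dedup_paternal_relatives(records)
        assert len(kept) == 2 and not removed

    def test_distinct_str_profiles_not_collapsed(self):
        records = [_rec("a"), _rec("b", profile=full_profile(DYS19=15.0))]
        kept, _ = dedup_paternal_relatives(records)
        assert len(kept) == 2

    def test_missing_descent_group_never_collapsed(self):
        records = [_rec("a", descent=None), _rec("b", descent=None)]
        kept, _ = dedup_paternal_relatives(records)
        assert len(kept) == 2

    def test_idempotent(self):
        records = [_rec(x) for x in "abcd"] + [_rec("e", descent="g2")]
        kept1, _ = dedup_paternal_relatives(records)
        kept2, removed2 = dedup_paternal_relatives(kept1)
        assert [r.id for r in kept2] == [r.id for r in kept1]
        assert not removed2


# ---------------------------------------------------------------------------
# frequencies

class TestFrequencies:
    def test_major_clade_share_rounds_to_printed_percentage(self):
        """152 of 270 chromosomes correspond to 56.3% after one-decimal
        rounding (report-table convention)."""
        table = frequency_table_from_counts({"all": {"R1": 152, "other": 118}})
        f = table.set_index("haplogroup").loc["R1", "frequency"]
        assert round_half_away(100 * f, 1) == 56.3

    def test_frequencies_sum_to_one_and_cis_cover_estimate(self):
        table = frequency_table_from_counts(
            {"g": {"a": 5, "b": 0, "c": 15}, "h": {"a": 1, "b": 2, "c": 0}})
        for _, grp in table.groupby("group"):
            assert abs(grp["frequency"].sum() - 1.0) < 1e-12
        assert (table["ci_low"] <= table["frequency"] + 1e-12).all()
        assert (table["ci_high"] >= table["frequency"] - 1e-12).all()

    def test_zero_count_ci_clamped(self):
        lo, hi = modified_wald_ci(0, 20)
        assert lo == 0.0 and 0 < hi < 1

    def test_modified_wald_formula(self):
        """Direct evaluation of the add-2/add-2 formula for 38 of 270."""
        x, n = 38, 270
        p = (x + 2) / (n + 4)
        half = 1.96 * np.sqrt(p * (1 - p) / (n + 4))
        lo, hi = modified_wald_ci(x, n)
        assert lo == pytest.approx(p - half, abs=1e-12)
        assert hi == pytest.approx(p + half, abs=1e-12)

    def test_informative_threshold_flag(self):
        # below 5% is non-informative; exactly 5% still counts
        table = frequency_table_from_counts({"g": {"a": 1, "b": 2, "c": 37}},
                                            informative_threshold=0.05)
        flags = table.set_index("haplogroup")["informative"]
        assert not flags["a"] and flags["b"] and flags["c"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            frequency_table_from_counts({"g": {}})

    def test_record_grouping_includes_zero_counts(self):
        recs = ([_rec(f"a{i}", hg="R-M17", descent=None) for i in range(3)]
                + [_rec(f"b{i}", hg="I-M253", descent=None) for i in range(2)])
        group_of = {r.id: ("A" if r.id.startswith("a") else "B") for r in recs}
        table = haplogroup_frequencies(recs, lambda r: group_of[r.id])
        sub = table.set_index(["group", "haplogroup"])
        assert sub.loc[("A", "I-M253"), "count"] == 0
        assert sub.loc[("B", "R-M17"), "count"] == 0
        assert sub.loc[("A", "R-M17"), "count"] == 3


# ---------------------------------------------------------------------------
# Fisher's exact test

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher P by explicit hypergeometric enumeration."""
    r1, N, c1 = a + b, a + b + c + d, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, N, r1, c1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # 2 / C(6,3) = 0.1
        _, p = fisher_exact_2x2([[3, 0], [0, 3]])
        assert p == pytest.approx(0.1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2([[0, 0], [3, 3]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1.5, 2], [3, 4]])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        _, p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


# ---------------------------------------------------------------------------
# multiple-testing adjustment

def bh_oracle(p, alpha=0.05):
    """Step-up FDR from its definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


class TestAdjustPvalues:
    def test_single_p_unchanged_under_bh(self):
        adj, _ = adjust_pvalues([0.03], method="BH")
        assert adj[0] == pytest.approx(0.03)

    def test_stepup_all_significant(self):
        _, sig = adjust_pvalues([0.01, 0.02, 0.03, 0.04], method="BH", alpha=0.05)
        assert sig.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_bh_matches_definition_and_by_dominates(self, p):
        adj_bh, _ = adjust_pvalues(p, method="BH")
        adj_by, _ = adjust_pvalues(p, method="BY")
        assert np.allclose(adj_bh, bh_oracle(p), atol=1e-12)
        assert np.all(adj_by >= adj_bh - 1e-12)

    def test_bonferroni(self):
        adj, _ = adjust_pvalues([0.01, 0.4], method="bonferroni")
        assert np.allclose(adj, [0.02, 0.8])
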