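import itertools

import numpy as np
import pandas as pd
import pytest

from hhsort import sorter
from hhsort.sorter import (
    FilterConfig,
    ResponseCall,
    apply_branch_filters,
    assign_group,
    classify_response,
    default_retained_groups,
    flags_consistent,
    group_flags,
    retain_candidate_groups,
)

Y, N = True, False


class TestAssignGroup:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((Y, Y, Y, Y, Y), 1),
            ((N, N, N, N, N), 32),
            ((N, N, Y, Y, Y), 25),  # Hh response appears only with Esrrb
        ],
    )
    def test_anchor_patterns(self, flags, expected):
        assert assign_group(flags) == expected

    def test_bijection_over_all_patterns(self):
        groups = [
            assign_group(f) for f in itertools.product([Y, N], repeat=5)
        ]
        assert sorted(groups) == list(range(1, 33))

    def test_hh_responsive_patterns_fill_groups_1_to_16(self):
        for flags in itertools.product([Y, N], repeat=4):
            assert assign_group((Y, *flags)) <= 16
            assert assign_group((N, *flags)) >= 17

    def test_group_flags_inverts_assign_group(self):
        for gid in range(1, 33):
            assert assign_group(group_flags(gid)) == gid

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            assign_group((Y, Y, Y))


class TestConsistencyPredicate:
    def test_exactly_eight_candidate_groups_survive(self):
        assert len(default_retained_groups()) == 8

    def test_all_yes_is_consistent(self):
        assert flags_consistent((Y, Y, Y, Y, Y))

    def test_equality_chain_contradiction(self):
        # ctrl==esrrb_hh and esrrb==esrrb_hh force ctrl==esrrb, so a
        # significant ctrl-vs-esrrb cannot coexist with them
        assert not flags_consistent((Y, Y, N, Y, N))

    def test_lost_response_archetype_is_consistent(self):
        # responds to Hh alone, nothing once Esrrb is present
        assert flags_consistent((Y, N, N, Y, N))


class TestRetainCandidateGroups:
    @pytest.fixture()
    def assignments(self):
        flags = list(itertools.product([Y, N], repeat=5))
        df = pd.DataFrame(flags, columns=list(sorter.FLAG_IDS))
        df.index = [f"g{i}" for i in range(len(flags))]
        df["group_id"] = [assign_group(f) for f in flags]
        return df

    def test_full_set_is_identity(self, assignments):
        kept = retain_candidate_groups(assignments, set(range(1, 33)))
        assert len(kept) == len(assignments)

    def test_empty_set_empties_output(self, assignments):
        assert len(retain_candidate_groups(assignments, set())) == 0

    def test_default_keeps_only_consistent_hh_responders(self, assignments):
        kept = retain_candidate_groups(assignments)
        assert len(kept) == 8
        assert kept["C1"].all()
        for _, row in kept.iterrows():
            assert flags_consistent(tuple(row[list(sorter.FLAG_IDS)]))

    def test_out_of_range_ids_rejected(self, assignments):
        with pytest.raises(ValueError):
            retain_candidate_groups(assignments, {0, 5})


def bruteforce_branch_filter(c, h, e, eh, c4, cfg):
    """Literal transcription of the six removal inequalities."""
    eps = cfg.denominator_pseudocount
    if c4:
        removed = (
            -cfg.rel_change_floor
            < (eh - h) / (h + eps)
            < cfg.rel_change_floor
            or -cfg.rel_change_floor < (h - c) / (c + eps) < cfg.rel_change_floor
            or -cfg.abs_change_floor_rpkm
            < (eh - h)
            < cfg.abs_change_floor_rpkm
        )
    else:
        drift = (eh - h) / (h + eps)
        removed = (
            -cfg.rel_change_floor < (h - c) / (c + eps) < cfg.rel_change_floor
            or drift > cfg.nonsig_drift_ceiling
            or drift < -cfg.nonsig_drift_ceiling
            or -cfg.rel_change_floor < (e - c) / (c + eps) < cfg.rel_change_floor
        )
    return not removed


class TestBranchFilters:
    @pytest.mark.parametrize(
        "means,c4,survives",
        [
            # strong response in both contexts, large absolute shift
            (dict(ctrl=10, hh=40, esrrb=12, esrrb_hh=160), True, True),
            # esrrb_hh barely moves off hh: relative floor kills it
            (dict(ctrl=10, hh=40, esrrb=12, esrrb_hh=42), True, False),
            # proportional-additive shape survives branch B
            (dict(ctrl=10, hh=40, esrrb=30, esrrb_hh=41), False, True),
        ],
    )
    def test_worked_examples(self, means, c4, survives):
        got, branch = apply_branch_filters(means, c4)
        assert got is survives
        assert branch == ("A" if c4 else "B")

    def test_matches_bruteforce_on_random_quadruples(self):
        cfg = FilterConfig()
        rng = np.random.default_rng(5)
        for c4 in (True, False):
            quads = rng.uniform(0, 200, size=(10_000, 4))
            for c, h, e, eh in quads:
                means = dict(ctrl=c, hh=h, esrrb=e, esrrb_hh=eh)
                got, _ = apply_branch_filters(means, c4, cfg)
                assert got == bruteforce_branch_filter(c, h, e, eh, c4, cfg)

    def test_all_combination_mode_is_laxer(self):
        cfg_any = FilterConfig()
        cfg_all = FilterConfig(combination="all")
        rng = np.random.default_rng(6)
        for c, h, e, eh in rng.uniform(0, 50, size=(500, 4)):
            means = dict(ctrl=c, hh=h, esrrb=e, esrrb_hh=eh)
            any_ok, _ = apply_branch_filters(means, True, cfg_any)
            all_ok, _ = apply_branch_filters(means, True, cfg_all)
            assert all_ok or not any_ok  # any-removal is the stricter gate

    def test_missing_mean_is_an_error(self):
        means = dict(ctrl=np.nan, hh=1.0, esrrb=1.0, esrrb_hh=1.0)
        with pytest.raises(ValueError, match="missing"):
            apply_branch_filters(means, True)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(rel_change_floor=0)
        with pytest.raises(ValueError):
            FilterConfig(combination="sometimes")


class TestClassifyResponse:
    def _call(self, flags, r1, r5, survived=True):
        log2fc = {"C1": r1, "C2": 0, "C3": 0, "C4": 0, "C5": r5}
        return classify_response("g", flags, log2fc, survived)

    def test_hsd11b1_like_is_enhanced(self):
        # 21-fold without Esrrb vs 59-fold with it
        call = self._call((Y, N, Y, Y, Y), np.log2(21), np.log2(59))
        assert call.category == "enhanced" and call.is_differential

    def test_ogn_like_repression_is_enhanced(self):
        # 57% inhibition deepening to 83%: stronger repression
        call = self._call((Y, N, Y, Y, Y), np.log2(0.43), np.log2(0.17))
        assert call.category == "enhanced"

    def test_weakened_response_is_depressed(self):
        call = self._call((Y, N, Y, Y, Y), 3.0, 1.2)
        assert call.category == "depressed"

    def test_c5_not_significant_means_lost(self):
        call = self._call((Y, N, Y, Y, N), 2.0, 0.1)
        assert call.category == "lost" and call.branch == "A"

    def test_gated_pattern_bypasses_filters(self):
        call = self._call((N, N, Y, Y, Y), 0.2, 2.0, survived=False)
        assert call.category == "gated" and call.is_differential

    def test_gated_needs_twofold_c5(self):
        call = self._call((N, N, Y, Y, Y), 0.2, 0.8, survived=False)
        assert not call.is_differential

    def test_proportional_additive_needs_esrrb_baseline_shift(self):
        log2fc = {"C1": 2.0, "C2": 2.0, "C3": 0, "C4": 0, "C5": 2.1}
        with_shift = classify_response("g", (Y, Y, Y, Y, Y), log2fc, True)
        assert with_shift.category == "proportional_additive"
        no_shift = self._call((Y, N, Y, Y, Y), 2.0, 2.1)
        assert no_shift.category == "none"

    def test_opposite_sign_responses_left_uncalled(self):
        call = self._call((Y, N, Y, Y, Y), 2.0, -2.0)
        assert call.category == "none" and not call.is_differential

    def test_filtered_out_candidate_gets_no_category(self):
        call = self._call((Y, N, Y, Y, N), 2.0, 0.1, survived=False)
        assert call.category == "none"

    def test_response_call_invariants(self):
        with pytest.raises(ValueError):
            ResponseCall("g", True, "none", "lost")
        with pytest.raises(ValueError):
            ResponseCall("g", False, "none", "mystery")


class TestClassifyAll:
    def test_every_gene_gets_exactly_one_category(self, small_experiment):
        from hhsort import detest, pipeline, quantify

        _, counts, _ = small_experiment
        comparisons = detest.run_comparisons(counts)
        means = quantify.condition_means(quantify.compute_rpkm(counts))
        out = sorter.classify_all(comparisons, means)
        assert len(out) == len(counts.gene_ids)
        assert out.index.is_unique
        assert out["category"].isin(sorter.CATEGORIES).all()
        # lost and gated exclude each other by their C1/C5 flag constraints
        lost = out[out["category"] == "lost"]
        gated = out[out["category"] == "gated"]
        assert lost["C1"].all() and not lost["C5"].any()
        assert gated["C5"].all() and not gated["C1"].any()
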