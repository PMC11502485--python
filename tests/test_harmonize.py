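"""Instrument selection, allele alignment, orientation, proxies, bookkeeping."""

import numpy as np
import pytest

from stratmr.errors import ValidationError
from stratmr.harmonize import (
    align_alleles,
    build_instrument_set,
    find_proxy,
    harmonize_aligned,
    orient_to_exposure_increasing,
    select_instruments,
)
from stratmr.simulate import SimulationConfig, simulate_two_sample_study, variant_ids
from stratmr.sumstats import LDReference, SummaryStatsTable
from .conftest import make_assoc, make_record


class TestSelectInstruments:
    def test_threshold_is_strict(self):
        table = SummaryStatsTable.from_records(
            [
                make_assoc(vid="at", pval=5.0e-8),
                make_assoc(vid="below", pval=4.9e-8, pos=2000),
            ]
        )
        sel = select_instruments(table, 5.0e-8)
        assert [r.variant_id for r in sel] == ["below"]

    def test_all_pvals_one_gives_empty_set(self):
        table = SummaryStatsTable.from_records(
            [make_assoc(vid=f"v{i}", pval=1.0, pos=i + 1) for i in range(5)]
        )
        assert select_instruments(table, 5e-8) == []

    def test_count_matches_direct_scan(self, rng):
        pvals = 10.0 ** rng.uniform(-12, 0, size=100)
        table = SummaryStatsTable.from_records(
            [make_assoc(vid=f"v{i}", pval=p, pos=i + 1) for i, p in enumerate(pvals)]
        )
        expected = int(np.sum(pvals < 5e-8))
        assert len(select_instruments(table, 5e-8)) == expected


class TestAlignAlleles:
    def test_matching_alleles_unchanged(self):
        ref = make_assoc(ea="A", oa="G", beta=0.5)
        oth = make_assoc(ea="A", oa="G", beta=0.2, eaf=0.3)
        res = align_alleles(ref, oth)
        assert res.status == "ok"
        assert res.record.beta == 0.2
        assert res.record.eaf == 0.3

    def test_swapped_alleles_negate_beta_complement_eaf(self):
        ref = make_assoc(ea="A", oa="G")
        oth = make_assoc(ea="G", oa="A", beta=0.2, eaf=0.3)
        res = align_alleles(ref, oth)
        assert res.record.beta == -0.2
        assert res.record.eaf == 0.7
        assert (res.record.effect_allele, res.record.other_allele) == ("A", "G")

    def test_strand_flip_relabels_without_sign_change(self):
        # complement of T/C is A/G: same variant read off the other strand
        ref = make_assoc(ea="A", oa="G")
        oth = make_assoc(ea="T", oa="C", beta=0.2, eaf=0.3)
        res = align_alleles(ref, oth)
        assert res.status == "ok"
        assert res.record.beta == 0.2
        assert (res.record.effect_allele, res.record.other_allele) == ("A", "G")

    def test_strand_flip_then_swap(self):
        ref = make_assoc(ea="A", oa="G")
        oth = make_assoc(ea="C", oa="T", beta=0.2, eaf=0.3)
        res = align_alleles(ref, oth)
        assert res.record.beta == -0.2
        assert res.record.eaf == 0.7

    @pytest.mark.parametrize("eaf_ref,eaf_oth", [(0.5, 0.5), (0.45, 0.2), (0.2, 0.55), (None, 0.2)])
    def test_palindromic_ambiguous_dropped(self, eaf_ref, eaf_oth):
        ref = make_assoc(ea="A", oa="T", eaf=eaf_ref)
        oth = make_assoc(ea="A", oa="T", eaf=eaf_oth)
        res = align_alleles(ref, oth, palindrome_window=0.08)
        assert res.status == "dropped"
        assert res.reason == "palindromic-ambiguous"

    def test_palindromic_resolved_by_eaf_concordance(self):
        ref = make_assoc(ea="G", oa="C", eaf=0.2)
        same_side = make_assoc(ea="G", oa="C", eaf=0.25, beta=0.4)
        other_side = make_assoc(ea="G", oa="C", eaf=0.75, beta=0.4)
        assert align_alleles(ref, same_side).record.beta == 0.4
        flipped = align_alleles(ref, other_side).record
        assert flipped.beta == -0.4
        assert flipped.eaf == 0.25

    def test_irreconcilable_alleles_drop(self):
        ref = make_assoc(ea="A", oa="G")
        oth = make_assoc(ea="A", oa="C")
        res = align_alleles(ref, oth)
        assert res.status == "dropped"
        assert res.reason == "allele-mismatch"


class TestOrient:
    def test_positive_beta_unchanged(self):
        rec = make_record(bx=0.1)
        assert orient_to_exposure_increasing(rec) is rec

    def test_negative_beta_flips_all_three(self):
        rec = make_record(bx=-0.1, bz=0.05, by=-0.02, ea="A", oa="G", eaf=0.3)
        out = orient_to_exposure_increasing(rec)
        assert (out.beta_x, out.beta_z, out.beta_y) == (0.1, -0.05, 0.02)
        assert (out.effect_allele, out.other_allele) == ("G", "A")
        assert out.eaf == 0.7

    def test_idempotent(self):
        rec = make_record(bx=-0.1)
        once = orient_to_exposure_increasing(rec)
        assert orient_to_exposure_increasing(once) == once

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValidationError):
            orient_to_exposure_increasing(make_record(bx=0.0))


def _target_table(ids, positions=None):
    recs = []
    for i, vid in enumerate(ids):
        recs.append(make_assoc(vid=vid, pos=(positions or {}).get(vid, 1000 * (i + 1))))
    return SummaryStatsTable.from_records(recs)


class TestFindProxy:
    def test_r2_threshold_is_strict(self):
        ld = LDReference()
        ld.add_position("idx", "1", 1000)
        ld.add_position("cand", "1", 2000)
        ld.add_pair("idx", "cand", 0.69)
        target = _target_table(["cand"])
        decision = find_proxy("idx", target, ld, r2_min=0.7)
        assert decision.proxy_id is None

    def test_variant_is_its_own_proxy(self):
        decision = find_proxy("idx", _target_table(["idx"]), LDReference())
        assert decision.proxy_id == "idx"
        assert decision.r2 == 1.0

    def test_tie_broken_by_distance_then_id(self):
        ld = LDReference()
        ld.add_position("idx", "1", 1_000_000)
        ld.add_position("far", "1", 1_500_000)
        ld.add_position("near", "1", 1_100_000)
        ld.add_pair("idx", "far", 0.9)
        ld.add_pair("idx", "near", 0.9)
        target = _target_table(["far", "near"], {"far": 1_500_000, "near": 1_100_000})
        assert find_proxy("idx", target, ld).proxy_id == "near"
        # equal r2 and distance: lexicographically smallest id wins
        ld2 = LDReference()
        ld2.add_position("idx", "1", 1_000_000)
        ld2.add_position("b", "1", 1_100_000)
        ld2.add_position("a", "1", 900_000)
        ld2.add_pair("idx", "a", 0.9)
        ld2.add_pair("idx", "b", 0.9)
        target2 = _target_table(["a", "b"], {"a": 900_000, "b": 1_100_000})
        assert find_proxy("idx", target2, ld2).proxy_id == "a"

    def test_distance_window_enforced(self):
        ld = LDReference()
        ld.add_position("idx", "1", 1_000_000)
        ld.add_position("far", "1", 2_500_000)
        ld.add_pair("idx", "far", 0.95)
        target = _target_table(["far"], {"far": 2_500_000})
        assert find_proxy("idx", target, ld, max_dist=1_000_000).proxy_id is None

    def test_unknown_position_reported(self):
        decision = find_proxy("idx", _target_table(["other"]), LDReference())
        assert decision.proxy_id is None
        assert decision.reason == "no-position"


class TestBuildInstrumentSet:
    def _study(self, seed=7):
        cfg = SimulationConfig(n_variants=50, seed=seed)
        return cfg, simulate_two_sample_study(cfg)

    def test_bookkeeping_with_deletions_and_proxies(self):
        cfg, res = self._study()
        ids = variant_ids(cfg.n_variants)
        deleted = ids[10:15]  # 5 variants removed from the outcome table
        outcome = SummaryStatsTable(
            df=res.outcome.df[~res.outcome.df["variant_id"].isin(deleted)].reset_index(drop=True)
        )
        ld = LDReference()
        for j, vid in enumerate(ids):
            ld.add_position(vid, "1", 1 + j * 50_000)
        for vid in deleted[:3]:  # proxies exist for 3 of the 5
            j = ids.index(vid)
            ld.add_pair(vid, ids[j + 20], 0.9)
        hset = build_instrument_set(res.exposure, res.indicator, outcome, ld, p_threshold=1.0)
        assert len(hset.provenance) == 50
        assert len(hset) == 48
        dropped = hset.provenance[hset.provenance["status"] == "dropped"]
        assert len(dropped) == 2
        assert set(dropped["reason"]) == {"no-proxy"}
        proxied = hset.provenance[hset.provenance["status"] == "proxied-kept"]
        assert len(proxied) == 3
        proxy_recs = [r for r in hset.records if r.proxy_of is not None]
        assert {r.variant_id for r in proxy_recs} == set(deleted[:3])

    def test_conservation_selected_equals_kept_plus_dropped(self):
        for seed in (1, 2, 3):
            _, res = self._study(seed)
            hset = build_instrument_set(res.exposure, res.indicator, res.outcome, None, p_threshold=1.0)
            n_kept = (hset.provenance["status"] != "dropped").sum()
            n_dropped = (hset.provenance["status"] == "dropped").sum()
            assert n_kept + n_dropped == len(hset.provenance)
            assert n_kept == len(hset)

    def test_all_records_oriented_with_common_allele(self):
        _, res = self._study()
        hset = build_instrument_set(res.exposure, res.indicator, res.outcome, None, p_threshold=1.0)
        assert all(r.beta_x >= 0 for r in hset.records)

    def test_fast_path_matches_general_path(self):
        _, res = self._study()
        full = build_instrument_set(res.exposure, res.indicator, res.outcome, None, p_threshold=1.0)
        fast = harmonize_aligned(res.exposure, res.indicator, res.outcome, p_threshold=1.0)
        f1, f2 = full.to_frame(), fast.to_frame()
        assert list(f1["variant_id"]) == list(f2["variant_id"])
        np.testing.assert_allclose(
            f1[["beta_x", "beta_z", "beta_y"]].values, f2[["beta_x", "beta_z", "beta_y"]].values
        )

    def test_missing_indicator_kept_and_marked(self):
        _, res = self._study()
        ids = variant_ids(50)
        indicator = SummaryStatsTable(
            df=res.indicator.df[~res.indicator.df["variant_id"].isin(ids[:5])].reset_index(drop=True)
        )
        hset = build_instrument_set(res.exposure, indicator, res.outcome, None, p_threshold=1.0)
        assert len(hset) == 50
        missing = [r for r in hset.records if r.beta_z is None]
        assert {r.variant_id for r in missing} == set(ids[:5])
        marked = hset.provenance[hset.provenance["reason"] == "indicator-missing"]
        assert set(marked["variant_id"]) == set(ids[:5])
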