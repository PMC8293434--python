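"""Ratio formation, floor imputation, category and score semantics."""

import pytest
from hypothesis import given, settings, strategies as st

from ryr2apms.errors import ConfigurationError, DataError
from ryr2apms.enrichment_scoring import (
    EnrichmentRecord,
    RatioPair,
    assign_tier,
    classify_enrichment,
    compute_ratio_pair,
    enrichment_score,
    impute_floor,
    score_experiments,
)
from conftest import make_pg, make_table


class TestImputeFloor:
    def test_zero_becomes_background_floor(self):
        assert impute_floor(0.0) == 50_000.0

    def test_positive_intensity_passes_through(self):
        assert impute_floor(1.0e6) == 1.0e6

    def test_parameterized_floor(self):
        assert impute_floor(0.0, floor=1.0) == 1.0

    def test_negative_intensity_rejected(self):
        with pytest.raises(DataError):
            impute_floor(-1.0)


class TestComputeRatioPair:
    def test_plain_arithmetic(self):
        rec = compute_ratio_pair(make_pg("A", 150_000, 100_000, 50_000))
        assert (rec.ratio_igg, rec.ratio_beads) == (1.5, 3.0)
        assert rec.imputed_channels == ()

    def test_zero_controls_hit_the_floor(self):
        rec = compute_ratio_pair(make_pg("A", 1.0e7, 0, 0))
        assert (rec.ratio_igg, rec.ratio_beads) == (200.0, 200.0)
        assert rec.imputed_channels == ("igg", "beads")

    def test_all_zero_row_is_unit_ratios(self):
        rec = compute_ratio_pair(make_pg("A", 0, 0, 0))
        assert (rec.ratio_igg, rec.ratio_beads) == (1.0, 1.0)
        assert rec.imputed_channels == ("anti_bait", "igg", "beads")

    def test_missing_channel_is_configuration_error(self):
        row = make_pg("A", 1, 1, 1)
        with pytest.raises(ConfigurationError, match="sepharose"):
            compute_ratio_pair(row, channels=("anti_bait", "igg", "sepharose"))


class TestClassifyEnrichment:
    @pytest.mark.parametrize("ratios,category", [
        ((2.0, 1.6), "both_enriched"),
        ((1.5, 1.5), "not_enriched"),   # strict inequality at the cutoff
        ((1.6, 0.5), "igg_only"),
        ((0.5, 1.6), "beads_only"),
        ((0.9, 0.9), "not_enriched"),
    ])
    def test_categories(self, ratios, category):
        rec = EnrichmentRecord("A", *ratios)
        assert classify_enrichment(rec).category == category

    def test_bait_labelled_regardless_of_ratios(self):
        rec = EnrichmentRecord("E9Q401", 0.1, 0.1)
        assert classify_enrichment(rec, bait_id="E9Q401").category == "bait"


class TestEnrichmentScore:
    def test_counting(self):
        pairs = [RatioPair("e1", 1.6, 1.2), RatioPair("e2", 0.4, 1.7),
                 RatioPair("e3", 1.0, 1.0)]
        rec = enrichment_score("A", pairs)
        assert rec.score == 2
        assert rec.contributing == (("e1", ("igg",)), ("e2", ("beads",)))

    def test_single_experiment_caps_at_two(self):
        rec = enrichment_score("A", [RatioPair("e1", 2.0, 2.0)])
        assert rec.score == 2

    def test_absent_ratio_contributes_nothing(self):
        rec = enrichment_score("A", [RatioPair("e1", 2.0, None)])
        assert rec.score == 1

    def test_duplicate_experiment_label_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            enrichment_score("A", [RatioPair("e1", 2.0, 2.0),
                                   RatioPair("e1", 2.0, 2.0)])


class TestAssignTier:
    @pytest.mark.parametrize("score,tier", [
        (0, "unscored"), (1, "low"), (2, "low"), (3, "high"),
        (4, "high"), (5, "top"), (6, "top"),
    ])
    def test_mapping(self, score, tier):
        assert assign_tier(score) == tier

    @pytest.mark.parametrize("score", [-1, 7])
    def test_out_of_range(self, score):
        with pytest.raises(ValueError):
            assign_tier(score)


# --- properties -------------------------------------------------------------

_maybe_ratio = st.one_of(st.none(), st.floats(min_value=1e-3, max_value=1e3,
                                              allow_nan=False))
_pairs = st.lists(_maybe_ratio.flatmap(
    lambda _: st.tuples(_maybe_ratio, _maybe_ratio)), min_size=0, max_size=3)


@settings(deadline=None, derandomize=True, max_examples=300)
@given(_pairs, st.floats(min_value=0.5, max_value=3.0))
def test_score_equals_brute_force_count(pairs, cutoff):
    """The score is exactly the count of flattened ratios strictly above cutoff."""
    ratio_pairs = [RatioPair(f"e{i}", a, b) for i, (a, b) in enumerate(pairs)]
    flat = [r for a, b in pairs for r in (a, b) if r is not None]
    expected = sum(1 for r in flat if r > cutoff)
    assert enrichment_score("A", ratio_pairs, cutoff=cutoff).score == expected


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.floats(min_value=1e3, max_value=1e9),
       st.floats(min_value=1e3, max_value=1e9),
       st.floats(min_value=1e3, max_value=1e9),
       st.sampled_from([1e-3, 0.5, 2.0, 1e3]))
def test_ratios_scale_invariant_without_imputation(anti, igg, beads, c):
    """Multiplying all channels by a positive constant leaves ratios unchanged."""
    base = compute_ratio_pair(make_pg("A", anti, igg, beads))
    scaled = compute_ratio_pair(make_pg("A", anti * c, igg * c, beads * c))
    assert scaled.ratio_igg == pytest.approx(base.ratio_igg, rel=1e-12)
    assert scaled.ratio_beads == pytest.approx(base.ratio_beads, rel=1e-12)


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.floats(min_value=1e5, max_value=1e8),
       st.floats(min_value=1e5, max_value=1e8),
       st.floats(min_value=1e5, max_value=1e8),
       st.floats(min_value=1.01, max_value=10.0))
def test_raising_anti_bait_never_lowers_ratios(anti, igg, beads, bump):
    low = compute_ratio_pair(make_pg("A", anti, igg, beads))
    high = compute_ratio_pair(make_pg("A", anti * bump, igg, beads))
    assert high.ratio_igg >= low.ratio_igg
    assert high.ratio_beads >= low.ratio_beads


def test_cutoff_boundary_never_scores():
    rec = enrichment_score("A", [RatioPair("e1", 1.5, 1.5),
                                 RatioPair("e2", 1.5, None)])
    assert rec.score == 0
    assert rec.tier == "unscored"


def test_score_experiments_excludes_bait_and_sorts():
    bait = "E9Q401"
    exps = []
    for label in ("e1", "e2"):
        exps.append((label, make_table([
            make_pg(bait, 1e9, 1e6, 1e6),
            make_pg("AAA", 5e6, 1e6, 1e6),   # enriched both ratios, both exps
            make_pg("BBB", 1e6, 1e6, 1e6),   # never enriched
        ])))
    # CCC appears only in e2
    exps[1] = ("e2", make_table(list(exps[1][1].rows) + [make_pg("CCC", 5e6, 1e6, 1e6)]))
    per_exp, scores = score_experiments(exps, bait_id=bait)
    assert set(per_exp) == {"e1", "e2"}
    assert [s.protein_id for s in scores] == ["AAA", "CCC", "BBB"]
    assert [s.score for s in scores] == [4, 2, 0]
    assert per_exp["e1"][0].category == "bait"
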