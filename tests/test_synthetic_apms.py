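"""Generator contracts: determinism, class means, noiseless limits, recovery."""

import math

import numpy as np
import pytest

from ryr2apms.errors import ConfigurationError, DataError
from ryr2apms.enrichment_scoring import ScoreRecord, score_experiments
from ryr2apms.phospho_differential import PhosphoRecord
from ryr2apms.synthetic_apms import (
    BAIT_ID,
    SimParams,
    evaluate_recovery,
    generate_experiment,
    generate_psm_study,
    generate_study,
)


def test_row_count_is_roster_size():
    params = SimParams(n_true=5, n_background=20, n_contaminant=3, seed=1)
    table, truth = generate_experiment(params, 0)
    assert len(table.rows) == 29  # 5 + 20 + 3 + bait
    assert truth.bait_id() == BAIT_ID
    assert len(truth.of_class("true_interactor")) == 5


def test_same_seed_reproduces_tables_exactly():
    params = SimParams(n_true=4, n_background=10, n_contaminant=2, seed=9)
    t1, _ = generate_experiment(params, 1)
    t2, _ = generate_experiment(params, 1)
    assert t1.rows == t2.rows
    other, _ = generate_experiment(params, 2)
    assert other.rows != t1.rows


def test_adding_proteins_does_not_perturb_existing_rows():
    small = SimParams(n_true=4, n_background=10, n_contaminant=2, seed=9)
    big = SimParams(n_true=4, n_background=30, n_contaminant=2, seed=9)
    t_small, _ = generate_experiment(small, 0)
    t_big, _ = generate_experiment(big, 0)
    # the first 1 + 4 + 10 rows are keyed by the same streams
    assert t_big.rows[:15] == t_small.rows[:15]


def test_zero_dropout_means_no_zero_intensities():
    params = SimParams(dropout_p=0.0, seed=3)
    table, _ = generate_experiment(params, 0)
    assert all(v > 0 for row in table.rows for v in row.lfq.values())


def test_contaminant_rows_carry_ig_keratin_genes():
    params = SimParams(n_true=2, n_background=2, n_contaminant=4, seed=0)
    table, truth = generate_experiment(params, 0)
    contaminants = [r.gene_symbol for r in table.rows
                    if truth.entries[r.protein_id].clazz == "contaminant"]
    assert all(g.startswith(("Krt", "Ig")) for g in contaminants)


def test_noiseless_limit_recovers_truth_perfectly():
    """With no noise and no dropout every true interactor maxes the score
    and every unit-enrichment background protein scores zero."""
    params = SimParams(lfq_cv=0.0, dropout_p=0.0, n_true=6, n_background=12,
                       n_contaminant=0, seed=5)
    experiments, truth = generate_study(params)
    _, scores = score_experiments(experiments, bait_id=BAIT_ID)
    by_id = {s.protein_id: s.score for s in scores}
    for entry in truth.of_class("true_interactor"):
        assert by_id[entry.protein_id] == 2 * params.n_experiments
    for entry in truth.of_class("background"):
        assert by_id[entry.protein_id] == 0


def test_invalid_params_rejected():
    with pytest.raises(ConfigurationError):
        SimParams(dropout_p=1.5).validate()
    with pytest.raises(ConfigurationError):
        SimParams(interactor_enrichment=0).validate()


def test_psm_means_follow_class_multipliers():
    """Monte-Carlo check: over many a_up_d_down interactors the empirical
    mean S2814A/WT PSM ratio lands within 10% of the simulated 1.5 effect."""
    params = SimParams(
        n_true=500, n_background=0, n_contaminant=0, seed=11,
        phospho_effects={"a_up_d_down": (1.5, 0.5)},
        psm_base_range=(50.0, 200.0),
    )
    table, truth = generate_psm_study(params)
    ratios = []
    for row in table.rows:
        if truth.entries[row.protein_id].clazz != "true_interactor":
            continue
        if row.psm["WT"] > 0:
            ratios.append(row.psm["S2814A"] / row.psm["WT"])
    assert len(ratios) == 500
    assert np.mean(ratios) == pytest.approx(1.5, rel=0.10)


def test_psm_null_effects_give_unit_mean_ratio():
    params = SimParams(
        n_true=300, n_background=0, n_contaminant=0, seed=12,
        phospho_effects={"unchanged": (1.0, 1.0)},
        psm_base_range=(50.0, 200.0),
    )
    table, truth = generate_psm_study(params)
    ratios = [row.psm["S2814A"] / row.psm["WT"] for row in table.rows
              if truth.entries[row.protein_id].clazz == "true_interactor"
              and row.psm["WT"] > 0]
    assert np.mean(ratios) == pytest.approx(1.0, rel=0.05)


def test_log_intensity_mean_converges_to_class_mean():
    """Law-of-large-numbers check on the control-channel log-intensities of a
    single protein across many experiments."""
    params = SimParams(n_true=0, n_background=1, n_contaminant=0,
                       lfq_cv=0.3, dropout_p=0.0, seed=21)
    logs = []
    for exp in range(400):
        table, _ = generate_experiment(params, exp)
        row = table.rows[1]  # the single background protein
        logs.append(math.log(row.lfq["igg"]))
    # log-intensity ~ Normal(log(per-protein mean), lfq_cv); the per-protein
    # mean is constant across experiments and observable via a noise-free draw
    se = params.lfq_cv / math.sqrt(len(logs))
    noise_free, _ = generate_experiment(
        SimParams(n_true=0, n_background=1, n_contaminant=0,
                  lfq_cv=0.0, dropout_p=0.0, seed=21), 0)
    mu = math.log(noise_free.rows[1].lfq["igg"])
    assert abs(np.mean(logs) - mu) < 3 * se


def test_evaluate_recovery_degenerate_limits():
    params = SimParams(n_true=3, n_background=2, n_contaminant=0, seed=1)
    _, truth = generate_experiment(params, 0)
    true_ids = [e.protein_id for e in truth.of_class("true_interactor")]
    perfect = [ScoreRecord(pid, 6, "top") for pid in true_ids]
    summary = evaluate_recovery(truth, perfect)
    assert summary.sensitivity == 1.0
    assert summary.specificity == 1.0  # absent negatives count as score 0
    nulls = [ScoreRecord(pid, 0, "unscored") for pid in true_ids]
    assert evaluate_recovery(truth, nulls).sensitivity == 0.0


def test_evaluate_recovery_rejects_unknown_ids():
    params = SimParams(n_true=1, n_background=0, n_contaminant=0, seed=1)
    _, truth = generate_experiment(params, 0)
    with pytest.raises(DataError, match="truth"):
        evaluate_recovery(truth, [ScoreRecord("GHOST", 6, "top")])


def test_quadrant_accuracy_uses_expected_quadrants():
    params = SimParams(n_true=2, n_background=0, n_contaminant=0, seed=1,
                       phospho_effects={"a_up_d_down": (1.5, 0.5)})
    _, truth = generate_experiment(params, 0)
    ids = [e.protein_id for e in truth.of_class("true_interactor")]
    quadrants = [
        PhosphoRecord(ids[0], {}, {}, ratio_a_wt=1.4, ratio_d_wt=0.5,
                      quadrant="a_up_d_down"),
        PhosphoRecord(ids[1], {}, {}, ratio_a_wt=0.5, ratio_d_wt=0.4,
                      quadrant="both_down"),
    ]
    summary = evaluate_recovery(truth, [], quadrants)
    assert summary.quadrant_accuracy == 0.5
    assert summary.quadrant_accuracy_by_class == {"a_up_d_down": 0.5}
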