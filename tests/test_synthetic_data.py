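import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ectomark.errors import ConfigurationError, DegenerateDataError, InputError
from ectomark.survival_core import fit_cox, logrank_test
from ectomark.synthetic_data import (
    SimConfig,
    _encode_covariates,
    simulate_ihc_table,
    simulate_normal_tissue_matrix,
    simulate_tumor_cohort,
)


@pytest.mark.parametrize(
    "field,value,fragment",
    [
        ("n_patients", 0, "n_patients"),
        ("activation_fraction", 1.5, "activation_fraction"),
        ("baseline_hazard", 0.0, "baseline_hazard"),
        ("n_true_prognostic", 99, "n_true_prognostic"),
        ("censor_time", -1.0, "censor_time"),
    ],
)
def test_invalid_config_names_offending_field(field, value, fragment):
    cfg = SimConfig(n_genes=10, n_tissue_specific=2, n_ectopic_candidates=5, **{field: value})
    with pytest.raises(ConfigurationError, match=fragment):
        cfg.validate()


def test_generators_are_deterministic(small_config):
    p1, t1 = simulate_normal_tissue_matrix(small_config)
    p2, t2 = simulate_normal_tissue_matrix(small_config)
    assert p1.expression.values.equals(p2.expression.values)
    assert t1.tissue_specific_genes == t2.tissue_specific_genes

    c1, u1 = simulate_tumor_cohort(small_config)
    c2, u2 = simulate_tumor_cohort(small_config)
    assert c1.expression.values.equals(c2.expression.values)
    assert c1.clinical.equals(c2.clinical)
    assert u1.activation_matrix_truth.equals(u2.activation_matrix_truth)

    i1 = simulate_ihc_table(small_config, u1.activation_matrix_truth.iloc[:3])
    i2 = simulate_ihc_table(small_config, u2.activation_matrix_truth.iloc[:3])
    assert i1.equals(i2)


def test_expression_non_negative_and_survival_valid(small_cohort):
    cohort, _ = small_cohort
    assert (cohort.expression.values.to_numpy() >= 0).all()
    assert (cohort.time > 0).all()
    assert set(np.unique(cohort.event)) <= {0, 1}


def test_planted_genes_dominant_in_home_tissue():
    cfg = SimConfig(n_genes=100, n_tissue_specific=50, n_ectopic_candidates=50, seed=11)
    panel, truth = simulate_normal_tissue_matrix(cfg)
    expr = panel.expression.values
    tissue = panel.tissue_of_sample
    # exhaustive per-gene per-tissue mean comparison
    means = expr.T.groupby(tissue).mean().T
    for gene, home in truth.tissue_specific_genes.items():
        row = means.loc[gene]
        assert row.idxmax() == home
        assert (row[home] > row.drop(home)).all()


def test_no_planting_leaves_no_contrast():
    cfg = SimConfig(n_genes=80, n_tissue_specific=0, n_ectopic_candidates=10, seed=3)
    panel, truth = simulate_normal_tissue_matrix(cfg)
    assert truth.tissue_specific_genes == {}
    means = panel.expression.values.T.groupby(panel.tissue_of_sample).mean().T
    # no gene shows the planted-level contrast (active/background ~ 500x)
    ratio = means.max(axis=1) / means.apply(lambda r: r.nlargest(2).iloc[-1], axis=1)
    assert ratio.max() < 50


def test_null_effect_gives_unit_hazard_ratio():
    cfg = SimConfig(
        n_genes=5, n_tissue_specific=2, n_ectopic_candidates=5, n_true_prognostic=3,
        log_hazard_per_activation=0.0, n_patients=2000, covariate_effects={}, seed=21,
    )
    cohort, truth = simulate_tumor_cohort(cfg)
    count = truth.activation_matrix_truth.loc[
        sorted(truth.true_prognostic_genes)
    ].sum(axis=0).to_numpy(float)
    fit = fit_cox(count[:, None], cohort.time, cohort.event)
    assert abs(fit.coefficients[0]) < 0.15


def test_cox_recovers_planted_log_hazard():
    cfg = SimConfig(n_genes=5, n_tissue_specific=2, n_ectopic_candidates=5, n_true_prognostic=3,
                    n_patients=2000, seed=13)
    cohort, truth = simulate_tumor_cohort(cfg)
    count = truth.activation_matrix_truth.loc[
        sorted(truth.true_prognostic_genes)
    ].sum(axis=0).to_numpy(float)
    enc = _encode_covariates(cohort.clinical)
    X = np.column_stack([count, enc["age"], enc["stage_late"]])
    fit = fit_cox(X, cohort.time, cohort.event, names=["count", "age", "stage_late"])
    assert abs(fit.coefficients[0] - np.log(2.5)) < 0.1


def test_degenerate_censoring_yields_no_events():
    cfg = SimConfig(n_genes=5, n_tissue_specific=2, n_ectopic_candidates=5, n_patients=100,
                    censor_time=1e-9, seed=4)
    cohort, truth = simulate_tumor_cohort(cfg)
    assert cohort.event.sum() == 0
    assert (cohort.time <= 1e-9).all() and (cohort.time > 0).all()
    with pytest.raises(DegenerateDataError):
        logrank_test(
            cohort.time, cohort.event,
            truth.activation_matrix_truth.iloc[0].to_numpy(),
        )


def test_logrank_null_calibration_uniform_p():
    """With no gene effect, the log-rank p over a true activation split is U(0,1)."""
    cfg0 = SimConfig(n_genes=3, n_tissue_specific=1, n_ectopic_candidates=3, n_true_prognostic=0,
                     n_patients=150, covariate_effects={})
    pvals = []
    for rep in range(500):
        cfg = SimConfig(**{**cfg0.to_dict(), "seed": 10_000 + rep,
                           "germline_tissues": cfg0.germline_tissues})
        cohort, truth = simulate_tumor_cohort(cfg)
        split = truth.activation_matrix_truth.iloc[0].to_numpy()
        pvals.append(logrank_test(cohort.time, cohort.event, split).p_value)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_effect_monotonicity_on_fully_activated_median():
    medians = []
    for i, beta in enumerate([0.0, np.log(2.0), np.log(4.0)]):
        cfg = SimConfig(n_genes=3, n_tissue_specific=1, n_ectopic_candidates=3, n_true_prognostic=3,
                        n_patients=2000, log_hazard_per_activation=beta,
                        covariate_effects={}, seed=31)
        cohort, truth = simulate_tumor_cohort(cfg)
        fully = truth.activation_matrix_truth.sum(axis=0).to_numpy() == 3
        medians.append(float(np.median(cohort.time[fully])))
    assert medians[0] > medians[1] > medians[2]


# --- IHC generator ---------------------------------------------------------

def _ihc_association_p(cfg, truth):
    from ectomark.ihc_scoring import MARKERS, score_ihc_table

    table = simulate_ihc_table(cfg, truth)
    scored = score_ihc_table(table)
    calls = []
    actives = []
    for marker, gene in zip(MARKERS, truth.index[:3]):
        high = (scored[marker] == "high").astype(int)
        active = truth.loc[gene, scored.index].astype(int)
        calls.append(high.to_numpy())
        actives.append(active.to_numpy())
    calls, actives = np.concatenate(calls), np.concatenate(actives)
    table22 = np.array(
        [
            [((calls == 1) & (actives == 1)).sum(), ((calls == 0) & (actives == 1)).sum()],
            [((calls == 1) & (actives == 0)).sum(), ((calls == 0) & (actives == 0)).sum()],
        ]
    )
    return table22, stats.chi2_contingency(table22).pvalue


def test_ihc_coupling_raises_high_rate_among_activated(small_cohort):
    _, truth = small_cohort
    markers = truth.activation_matrix_truth.iloc[:3]
    cfg = SimConfig(n_genes=60, n_ectopic_candidates=20, n_patients=200, seed=7)
    table22, _ = _ihc_association_p(cfg, markers)
    rate_active = table22[0, 0] / table22[0].sum()
    rate_inactive = table22[1, 0] / table22[1].sum()
    assert rate_active > rate_inactive + 0.3


def test_ihc_null_coupling_independent_of_truth():
    pvals = []
    for rep in range(30):
        cfg = SimConfig(n_genes=5, n_tissue_specific=2, n_ectopic_candidates=5, n_patients=150,
                        ihc_coupling=0.0, seed=500 + rep)
        _, truth = simulate_tumor_cohort(cfg)
        _, p = _ihc_association_p(cfg, truth.activation_matrix_truth.iloc[:3])
        pvals.append(p)
    # independence: p-values not concentrated near 0
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_ihc_missing_marker_rejected(small_cohort):
    _, truth = small_cohort
    cfg = SimConfig(n_genes=60, n_ectopic_candidates=20, seed=7)
    with pytest.raises(InputError, match="NOPE"):
        simulate_ihc_table(
            cfg,
            truth.activation_matrix_truth.iloc[:3],
            marker_genes=("NOPE", "G00001", "G00002"),
        )


def test_ihc_value_ranges(small_cohort):
    _, truth = small_cohort
    cfg = SimConfig(n_genes=60, n_ectopic_candidates=20, n_patients=200, seed=7)
    table = simulate_ihc_table(cfg, truth.activation_matrix_truth.iloc[:3])
    assert table["intensity"].isin([0, 1, 2, 3]).all()
    assert table["percent_positive"].between(0, 100).all()
    assert len(table) == 3 * 200
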