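import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ectomark.errors import InputError
from ectomark.io_formats import GeneSet
from ectomark.signature import (
    differential_expression,
    gsea_enrichment,
    select_signature_genes,
    signature_correlation,
)


def gsea_oracle(genes, metric, members, weight=1.0):
    """Independent step-by-step running-sum enrichment score."""
    order = sorted(range(len(genes)), key=lambda i: (-metric[i], genes[i]))
    hits = [genes[i] in members for i in order]
    w = [abs(metric[i]) ** weight for i in order]
    total_hit = sum(wi for wi, h in zip(w, hits) if h)
    n_miss = len(genes) - sum(hits)
    running, cur, best = [], 0.0, 0.0
    for wi, h in zip(w, hits):
        cur += (wi / total_hit) if h else (-1.0 / n_miss)
        running.append(cur)
    return max(running, key=abs), running


def _ranking(rng, n=20):
    genes = [f"g{i:02d}" for i in range(n)]
    return pd.Series(rng.normal(size=n), index=genes)


# --- differential expression ----------------------------------------------

def _matrix(rng, n_genes=50, n_pos=10, n_neg=10, shift_genes=(), shift=2.0):
    cols = [f"pos{i}" for i in range(n_pos)] + [f"neg{i}" for i in range(n_neg)]
    base = rng.lognormal(2, 1, (n_genes, len(cols)))
    df = pd.DataFrame(base, index=[f"g{i:03d}" for i in range(n_genes)], columns=cols)
    for g in shift_genes:
        df.loc[g, cols[:n_pos]] *= shift
    groups = pd.Series(
        ["positive"] * n_pos + ["negative"] * n_neg, index=cols
    )
    return df, groups


def test_identical_groups_no_signal(rng):
    df, groups = _matrix(rng, n_pos=5, n_neg=5)
    df.iloc[:, 5:] = df.iloc[:, :5].to_numpy()  # negative group duplicates positive
    table = differential_expression(df, groups)
    assert np.allclose(table["log_ratio"], 0.0)
    assert np.allclose(table["p_value"], 1.0)


def test_label_swap_negates_log_ratios_exactly(rng):
    df, groups = _matrix(rng)
    swapped = groups.map({"positive": "negative", "negative": "positive"})
    a = differential_expression(df, groups)
    b = differential_expression(df, swapped)
    assert np.array_equal(a["log_ratio"].to_numpy(), -b["log_ratio"].to_numpy())
    assert np.allclose(a["p_value"], b["p_value"], atol=1e-12)


def test_planted_fold_change_detected(rng):
    df, groups = _matrix(
        rng, n_genes=100, n_pos=50, n_neg=50, shift_genes=("g000", "g001"), shift=4.0
    )
    # low within-group noise for the planted genes
    df.loc["g000"] = np.r_[np.full(50, 40.0), np.full(50, 10.0)] * rng.lognormal(0, 0.1, 100)
    table = differential_expression(df, groups)
    assert table.loc["g000", "fold_change"] > 2
    assert table.loc["g000", "p_value"] < 0.01
    sets = select_signature_genes(table)
    assert "g000" in sets.up


def test_zero_variance_handling():
    df = pd.DataFrame(
        {
            "p1": [1.0, 1.0], "p2": [1.0, 1.0],
            "n1": [1.0, 3.0], "n2": [1.0, 3.0],
        },
        index=["same", "diff"],
    )
    groups = pd.Series(["positive", "positive", "negative", "negative"],
                       index=df.columns)
    table = differential_expression(df, groups)
    assert table.loc["same", "p_value"] == 1.0
    assert table.loc["diff", "p_value"] == 0.0
    assert np.isfinite(table["t_statistic"]).all()


def test_group_size_precondition(rng):
    df, groups = _matrix(rng, n_pos=1, n_neg=5)
    with pytest.raises(InputError):
        differential_expression(df, groups)


def test_signature_selection_monotone_in_thresholds(rng):
    df, groups = _matrix(rng, n_genes=200, n_pos=20, n_neg=20)
    table = differential_expression(df, groups)
    s2 = select_signature_genes(table, fc_min=2.0, p_max=0.05)
    s3 = select_signature_genes(table, fc_min=3.0, p_max=0.05)
    assert s3.up <= s2.up and s3.down <= s2.down
    empty = select_signature_genes(table, fc_min=1e9, p_max=1e-12)
    assert not empty.up and not empty.down


# --- GSEA ------------------------------------------------------------------

def test_es_matches_oracle_on_random_sets(rng):
    ranking = _ranking(rng)
    genes = list(ranking.index)
    for k in (3, 5, 10):
        members = set(rng.choice(genes, size=k, replace=False))
        gs = GeneSet("S", "", tuple(sorted(members)))
        res = gsea_enrichment(ranking, gs, n_permutations=0)
        expected, running = gsea_oracle(genes, ranking.to_numpy(), members)
        assert res.es == pytest.approx(expected, abs=1e-12)
        assert abs(running[-1]) < 1e-9  # running sum terminates at zero


def test_top_k_set_is_positively_enriched(rng):
    ranking = _ranking(rng)
    top = ranking.sort_values(ascending=False).index[:5]
    res = gsea_enrichment(ranking, GeneSet("top", "", tuple(top)), n_permutations=200, seed=1)
    assert res.es > 0.5
    assert res.p_value < 0.05


def test_weight_zero_reduces_to_ks_statistic(rng):
    ranking = _ranking(rng, n=40)
    genes = list(ranking.index)
    members = set(rng.choice(genes, size=12, replace=False))
    res = gsea_enrichment(ranking, GeneSet("S", "", tuple(sorted(members))),
                          weight=0.0, n_permutations=0)
    order = ranking.sort_values(ascending=False, kind="stable")
    ranks = np.arange(len(order))
    hit_ranks = ranks[[g in members for g in order.index]]
    miss_ranks = ranks[[g not in members for g in order.index]]
    ks = stats.ks_2samp(hit_ranks, miss_ranks).statistic
    assert abs(res.es) == pytest.approx(ks, abs=1e-12)


def test_es_invariant_to_positive_scaling(rng):
    ranking = _ranking(rng)
    members = tuple(sorted(rng.choice(list(ranking.index), size=6, replace=False)))
    gs = GeneSet("S", "", members)
    r1 = gsea_enrichment(ranking, gs, n_permutations=0)
    r2 = gsea_enrichment(ranking * 37.5, gs, n_permutations=0)
    assert r1.es == pytest.approx(r2.es, abs=1e-12)


def test_null_sets_symmetric_es(rng):
    ranking = _ranking(rng, n=50)
    es = []
    for rep in range(200):
        members = tuple(sorted(rng.choice(list(ranking.index), size=10, replace=False)))
        es.append(gsea_enrichment(ranking, GeneSet("S", "", members), n_permutations=0).es)
    assert abs(np.mean(es)) < 3 * np.std(es) / np.sqrt(len(es)) + 0.05


def test_gsea_determinism_and_errors(rng):
    ranking = _ranking(rng)
    gs = GeneSet("S", "", tuple(sorted(ranking.index[:4])))
    a = gsea_enrichment(ranking, gs, n_permutations=100, seed=7)
    b = gsea_enrichment(ranking, gs, n_permutations=100, seed=7)
    assert a.to_dict() == b.to_dict()
    with pytest.raises(InputError, match="no genes"):
        gsea_enrichment(ranking, GeneSet("X", "", ("absent",)))
    with pytest.raises(InputError, match="proper subset"):
        gsea_enrichment(ranking, GeneSet("all", "", tuple(ranking.index)))


# --- correlation -----------------------------------------------------------

def test_signature_correlation_identity_and_negation(rng):
    df, groups = _matrix(rng, n_genes=30)
    table = differential_expression(df, groups)
    assert signature_correlation(table, table)["correlation"] == pytest.approx(1.0)
    neg = table.copy()
    neg["log_ratio"] = -neg["log_ratio"]
    assert signature_correlation(table, neg)["correlation"] == pytest.approx(-1.0)


def test_signature_correlation_needs_shared_genes(rng):
    df, groups = _matrix(rng, n_genes=5)
    table = differential_expression(df, groups)
    other = table.rename(index=lambda g: g + "_x")
    with pytest.raises(InputError):
        signature_correlation(table, other)
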