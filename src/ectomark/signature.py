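"""Genome-wide signature of panel-positive vs negative tumours, and GSEA.

Differential expression uses a Welch two-sample t-test per gene on
log2(x + 1)-transformed values; the log ratio is the difference of group means
on that scale and the signed linear fold change is +/- 2^|log ratio|.
Signature sets keep genes with |fold change| above a threshold and p below a
threshold (2 and 0.01 in the original selection). The GSEA engine is the
weighted Kolmogorov-Smirnov-like running sum over the ranked gene list, with a
seeded gene-label permutation null for the nominal p and normalised ES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io_formats import GeneSet

POSITIVE, NEGATIVE = "positive", "negative"


def differential_expression(
    expression: pd.DataFrame,
    groups: pd.Series,
    test: str = "welch",
) -> pd.DataFrame:
    """Per-gene DE table between 'positive' and 'negative' patient groups.

    ``expression`` is genes x patients (linear scale); ``groups`` maps patient
    to 'positive'/'negative'. Returns a DataFrame indexed by gene with columns
    log_ratio (positive minus negative, log2 scale), t_statistic, p_value, and
    fold_change (signed linear). Genes constant in both groups get p = 1 when
    the means agree (no evidence) and p = 0 when two distinct constants differ.
    """
    groups = groups.astype(str)
    pos = [p for p in expression.columns if groups.get(p) == POSITIVE]
    neg = [p for p in expression.columns if groups.get(p) == NEGATIVE]
    if len(pos) < 2 or len(neg) < 2:
        raise InputError("both groups need >= 2 patients")
    log_expr = np.log2(expression.to_numpy(dtype=float) + 1.0)
    a = log_expr[:, [expression.columns.get_loc(p) for p in pos]]
    b = log_expr[:, [expression.columns.get_loc(p) for p in neg]]

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log_ratio = mean_a - mean_b
    # zero-variance genes are patched below; silence the precision warning
    # scipy emits for them
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if test == "welch":
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        elif test == "student":
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        else:
            raise InputError(f"unknown test {test!r}")
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(zero_var, 0.0, t)
    p = np.where(zero_var, np.where(log_ratio == 0.0, 1.0, 0.0), p)
    fold = np.sign(log_ratio) * np.exp2(np.abs(log_ratio))
    fold = np.where(log_ratio == 0.0, 1.0, fold)
    return pd.DataFrame(
        {
            "log_ratio": log_ratio,
            "t_statistic": t,
            "p_value": p,
            "fold_change": fold,
        },
        index=expression.index,
    )


@dataclass(frozen=True)
class SignatureSets:
    """Up- and downregulated signature gene sets under the DE thresholds."""

    up: frozenset
    down: frozenset
    fc_min: float
    p_max: float

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise InputError("up and down signatures overlap")

    def to_dict(self) -> dict:
        return {
            "up": sorted(self.up),
            "down": sorted(self.down),
            "fc_min": self.fc_min,
            "p_max": self.p_max,
        }


def select_signature_genes(
    table: pd.DataFrame, fc_min: float = 2.0, p_max: float = 0.01
) -> SignatureSets:
    """Keep genes with fold change beyond +/-``fc_min`` and p below ``p_max``."""
    sig = table["p_value"] < p_max
    up = frozenset(table.index[sig & (table["fold_change"] > fc_min)])
    down = frozenset(table.index[sig & (table["fold_change"] < -fc_min)])
    return SignatureSets(up=up, down=down, fc_min=fc_min, p_max=p_max)


@dataclass
class GSEAResult:
    geneset: str
    es: float
    nes: float
    p_value: float
    n_hits: int
    n_genes: int
    n_permutations: int
    permutation_scheme: str
    weight: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "geneset": self.geneset,
            "es": float(self.es),
            "nes": None if np.isnan(self.nes) else float(self.nes),
            "p_value": None if np.isnan(self.p_value) else float(self.p_value),
            "n_hits": int(self.n_hits),
            "n_genes": int(self.n_genes),
            "n_permutations": int(self.n_permutations),
            "permutation_scheme": self.permutation_scheme,
            "weight": float(self.weight),
            "seed": int(self.seed),
        }


def _running_sum_es(metric_sorted: np.ndarray, hits: np.ndarray, weight: float) -> float:
    """ES = signed extremum of the weighted running sum over the ranked list."""
    w = np.abs(metric_sorted) ** weight
    hit_w = w[hits]
    total_hit = hit_w.sum()
    n = metric_sorted.size
    n_miss = n - hits.sum()
    if total_hit == 0:
        # all hit metrics are exactly zero: fall back to equal increments
        inc = np.where(hits, 1.0 / hits.sum(), 0.0)
    else:
        inc = np.where(hits, w / total_hit, 0.0)
    dec = np.where(hits, 0.0, 1.0 / n_miss)
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_enrichment(
    ranking: pd.Series,
    geneset: GeneSet,
    weight: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Weighted running-sum enrichment of a gene set in a ranked gene list.

    Genes sort by metric descending (ties broken by gene ID ascending); member
    genes increment the running sum by |metric|^weight normalised over the
    members, non-members decrement by 1/(N - N_hits); the enrichment score is
    the signed extremum. The nominal p and NES come from seeded gene-label
    permutations (random member sets of the same size), sign-matched as in the
    standard formulation.
    """
    if ranking.index.has_duplicates:
        raise InputError("ranking contains duplicate gene IDs")
    metric = ranking.to_numpy(dtype=float)
    if not np.all(np.isfinite(metric)):
        raise InputError("ranking metric must be finite")
    members = geneset.members & set(ranking.index)
    if not members:
        raise InputError(f"gene set {geneset.name!r} shares no genes with the ranking")
    if len(members) == len(ranking):
        raise InputError(
            f"gene set {geneset.name!r} covers the whole ranking; a proper subset is required"
        )

    order = sorted(range(len(ranking)), key=lambda i: (-metric[i], str(ranking.index[i])))
    metric_sorted = metric[order]
    genes_sorted = ranking.index.to_numpy()[order]
    hits = np.isin(genes_sorted, list(members))
    es = _running_sum_es(metric_sorted, hits, weight)

    nes = float("nan")
    p = float("nan")
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        n, k = len(genes_sorted), int(hits.sum())
        perm_es = np.empty(n_permutations)
        for b in range(n_permutations):
            idx = rng.choice(n, size=k, replace=False)
            ph = np.zeros(n, dtype=bool)
            ph[idx] = True
            perm_es[b] = _running_sum_es(metric_sorted, ph, weight)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same:
            p = float((np.abs(perm_es[same_sign]) >= abs(es)).sum() / n_same)
            mean_same = float(np.abs(perm_es[same_sign]).mean())
            if mean_same > 0:
                nes = es / mean_same
    return GSEAResult(
        geneset=geneset.name,
        es=es,
        nes=nes,
        p_value=p,
        n_hits=int(hits.sum()),
        n_genes=len(genes_sorted),
        n_permutations=n_permutations,
        permutation_scheme="gene_label",
        weight=weight,
        seed=seed,
    )


def signature_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Pearson correlation of log ratios over the genes shared by two DE tables."""
    shared = table_a.index.intersection(table_b.index)
    x = table_a.loc[shared, "log_ratio"].to_numpy(float)
    y = table_b.loc[shared, "log_ratio"].to_numpy(float)
    finite = np.isfinite(x) & np.isfinite(y)
    if finite.sum() < 3:
        raise InputError("signature correlation needs >= 3 shared genes")
    r = stats.pearsonr(x[finite], y[finite])
    return {
        "correlation": float(r.statistic),
        "p_value": float(r.pvalue),
        "n_shared": int(finite.sum()),
    }
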