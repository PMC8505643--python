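"""Tissue-predominant silent-gene cataloguing on a normal-tissue panel.

A candidate ectopic-activation marker must be predominantly expressed in one
tissue and silent (or very low) in every non-germline adult somatic tissue.
This module summarises each gene's per-tissue expression, selects genes passing
the silence/predominance criteria, and derives per-gene somatic background
ceilings that later anchor activation thresholds in tumours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GeneLookupError, InputError
from .io_formats import NormalTissuePanel

_EPSILON = 1e-6
DEFAULT_FLOOR_CONSTANT = 0.1


@dataclass(frozen=True)
class TissueCriteria:
    """Quantitative cutoffs of the silent/predominant gene filter.

    ``silence_ceiling``: maximum tissue summary allowed in any non-germline
    somatic tissue. ``predominance_floor``: minimum summary required in the top
    tissue. ``predominance_ratio``: top tissue over best other somatic tissue.
    """

    silence_ceiling: float = 1.0
    predominance_floor: float = 10.0
    predominance_ratio: float = 5.0
    tissue_summary_statistic: str = "median"

    def __post_init__(self) -> None:
        if self.silence_ceiling < 0:
            raise ConfigurationError("silence_ceiling must be >= 0")
        if not self.predominance_floor > self.silence_ceiling:
            raise ConfigurationError("predominance_floor must exceed silence_ceiling")
        if self.predominance_ratio < 1:
            raise ConfigurationError("predominance_ratio must be >= 1")
        if self.tissue_summary_statistic not in ("mean", "median"):
            raise ConfigurationError("tissue_summary_statistic must be 'mean' or 'median'")

    def to_dict(self) -> dict:
        return {
            "silence_ceiling": self.silence_ceiling,
            "predominance_floor": self.predominance_floor,
            "predominance_ratio": self.predominance_ratio,
            "tissue_summary_statistic": self.tissue_summary_statistic,
        }


@dataclass
class TissueProfile:
    """Per-tissue expression summary of one gene."""

    gene_id: str
    tissue_summary: pd.Series        # tissue -> summary expression
    predominant_tissue: str
    max_somatic_nongermline: float   # max summary over non-germline tissues
    background_ceiling: float        # max per-sample value over non-germline samples

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "tissue_summary": {k: float(v) for k, v in self.tissue_summary.items()},
            "predominant_tissue": self.predominant_tissue,
            "max_somatic_nongermline": float(self.max_somatic_nongermline),
            "background_ceiling": float(self.background_ceiling),
        }


def _tissue_summaries(panel: NormalTissuePanel, statistic: str) -> pd.DataFrame:
    """Genes x tissues summary matrix (tissues sorted by name)."""
    counts = panel.tissue_of_sample.value_counts()
    if (counts == 0).any():
        raise InputError("every tissue needs at least one sample")
    grouped = panel.expression.values.T.groupby(panel.tissue_of_sample)
    summary = grouped.median() if statistic == "median" else grouped.mean()
    return summary.T.sort_index(axis=1)  # genes x tissues


def summarize_gene_tissue_profile(
    panel: NormalTissuePanel, gene_id: str, statistic: str = "median"
) -> TissueProfile:
    """Summarise one gene; predominant tissue is the summary argmax
    (lexicographically first tissue on ties)."""
    if gene_id not in panel.expression.values.index:
        raise GeneLookupError(f"gene {gene_id!r} not in panel")
    summaries = _tissue_summaries(panel, statistic)
    return _profile_from_row(panel, gene_id, summaries.loc[gene_id])


def _profile_from_row(panel, gene_id, row: pd.Series) -> TissueProfile:
    predominant = row.idxmax()  # ties -> first (lexicographic, index is sorted)
    somatic = [t for t in row.index if t not in panel.germline_tissues]
    max_somatic = float(row[somatic].max()) if somatic else 0.0
    somatic_samples = [
        s for s in panel.expression.sample_ids
        if panel.tissue_of_sample[s] not in panel.germline_tissues
    ]
    ceiling = (
        float(panel.expression.values.loc[gene_id, somatic_samples].max())
        if somatic_samples
        else 0.0
    )
    return TissueProfile(
        gene_id=gene_id,
        tissue_summary=row,
        predominant_tissue=str(predominant),
        max_somatic_nongermline=max_somatic,
        background_ceiling=ceiling,
    )


def select_tissue_predominant_silent_genes(
    panel: NormalTissuePanel, criteria: TissueCriteria = TissueCriteria()
) -> tuple[list, dict]:
    """Select genes silent in all somatic tissues and predominant in one tissue.

    A gene is selected iff (1) its max non-germline somatic summary is at most
    ``silence_ceiling``, (2) its predominant-tissue summary reaches
    ``predominance_floor``, and (3) the predominant summary exceeds the best
    *other* somatic summary by ``predominance_ratio``. Returns the sorted list
    of selected genes and a dict of per-gene :class:`TissueProfile`.
    """
    if not panel.expression.gene_ids:
        raise InputError("empty panel")
    summaries = _tissue_summaries(panel, criteria.tissue_summary_statistic)
    tissues = list(summaries.columns)
    somatic_mask = np.array([t not in panel.germline_tissues for t in tissues])

    arr = summaries.to_numpy()
    pred_idx = np.argmax(arr, axis=1)
    pred_val = arr[np.arange(arr.shape[0]), pred_idx]
    somatic_arr = np.where(somatic_mask[None, :], arr, -np.inf)
    max_somatic = somatic_arr.max(axis=1)
    max_somatic = np.where(np.isfinite(max_somatic), max_somatic, 0.0)
    # best somatic tissue other than the predominant one
    other = somatic_arr.copy()
    other[np.arange(arr.shape[0]), pred_idx] = -np.inf
    best_other = other.max(axis=1)
    best_other = np.where(np.isfinite(best_other), best_other, 0.0)

    passes = (
        (max_somatic <= criteria.silence_ceiling)
        & (pred_val >= criteria.predominance_floor)
        & (pred_val / np.maximum(best_other, _EPSILON) >= criteria.predominance_ratio)
    )

    # per-sample somatic upper envelope for background ceilings
    somatic_samples = [
        s for s in panel.expression.sample_ids
        if panel.tissue_of_sample[s] not in panel.germline_tissues
    ]
    env = (
        panel.expression.values[somatic_samples].max(axis=1)
        if somatic_samples
        else pd.Series(0.0, index=summaries.index)
    )

    profiles: dict[str, TissueProfile] = {}
    for i, gene in enumerate(summaries.index):
        profiles[gene] = TissueProfile(
            gene_id=str(gene),
            tissue_summary=summaries.iloc[i],
            predominant_tissue=str(tissues[pred_idx[i]]),
            max_somatic_nongermline=float(max_somatic[i]),
            background_ceiling=float(env.loc[gene]),
        )
    selected = sorted(str(g) for g, ok in zip(summaries.index, passes) if ok)
    return selected, profiles


def derive_background_ceiling(
    profile: TissueProfile,
    multiplier: float = 2.0,
    floor_constant: float = DEFAULT_FLOOR_CONSTANT,
) -> float:
    """Activation threshold = multiplier x max(background ceiling, floor).

    The floor constant keeps the threshold positive for genes fully silent in
    every somatic tissue, so zero background never yields a zero threshold.
    """
    if multiplier < 1:
        raise ConfigurationError("multiplier must be >= 1")
    return float(multiplier * max(profile.background_ceiling, floor_constant))
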