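"""Binary ectopic-activation calls from continuous expression.

A gene is "activated" in a tumour when its expression strictly exceeds a
per-gene threshold. Three strategies derive that threshold: from the normal
panel's somatic background ceiling (units comparable across cohorts,
RNA-seq-like data), from the midpoint of the longest significant percentile
run of a threshold scan, or from a fixed percentile of the cohort's own
distribution (cohort-internal, the only option for microarray-like units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .biomarker_screen import ThresholdScan, longest_significant_interval
from .errors import DerivationError, InputError
from .io_formats import TumorCohort
from .tissue_catalog import TissueProfile, derive_background_ceiling

STRATEGIES = ("background_based", "interval_midpoint", "fixed_percentile")


@dataclass(frozen=True)
class ActivationRule:
    """Per-gene activation threshold with provenance.

    Exactly one of ``threshold_value`` (expression units) or
    ``threshold_percentile`` (resolved against the target cohort) is set.
    """

    gene_id: str
    strategy: str
    threshold_value: Optional[float] = None
    threshold_percentile: Optional[float] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise InputError(f"unknown strategy {self.strategy!r}")
        has_value = self.threshold_value is not None
        has_pct = self.threshold_percentile is not None
        if has_value == has_pct:
            raise InputError("exactly one of threshold_value/threshold_percentile must be set")
        if self.strategy == "background_based" and not has_value:
            raise InputError("background_based rules carry a threshold value")
        if self.strategy in ("interval_midpoint", "fixed_percentile") and not has_pct:
            raise InputError(f"{self.strategy} rules carry a threshold percentile")
        if has_pct and not 0 < self.threshold_percentile < 100:
            raise InputError("threshold_percentile must lie in (0, 100)")

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "strategy": self.strategy,
            "threshold_value": self.threshold_value,
            "threshold_percentile": self.threshold_percentile,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationRule":
        return cls(
            gene_id=d["gene_id"],
            strategy=d["strategy"],
            threshold_value=d.get("threshold_value"),
            threshold_percentile=d.get("threshold_percentile"),
            provenance=d.get("provenance", ""),
        )


def derive_activation_threshold(
    gene_id: str,
    strategy: str = "background_based",
    profile: Optional[TissueProfile] = None,
    scan: Optional[ThresholdScan] = None,
    percentile: Optional[float] = None,
    multiplier: float = 2.0,
) -> ActivationRule:
    """Derive one gene's activation rule under the requested strategy."""
    if strategy == "background_based":
        if profile is None:
            raise DerivationError("background_based needs a TissueProfile")
        value = derive_background_ceiling(profile, multiplier=multiplier)
        return ActivationRule(
            gene_id=gene_id,
            strategy=strategy,
            threshold_value=value,
            provenance=(
                f"{multiplier} x somatic background ceiling "
                f"{profile.background_ceiling:.6g} of normal panel"
            ),
        )
    if strategy == "interval_midpoint":
        if scan is None:
            raise DerivationError("interval_midpoint needs a ThresholdScan")
        runs = scan.significant_runs()
        if not runs:
            raise DerivationError(
                "no significant percentile run; consider the background_based "
                "or fixed_percentile fallback"
            )
        widths = [hi - lo for lo, hi in runs]
        lo, hi = runs[int(np.argmax(widths))]
        mid = (lo + hi) / 2.0
        return ActivationRule(
            gene_id=gene_id,
            strategy=strategy,
            threshold_percentile=mid,
            provenance=f"midpoint of longest significant run [{lo:g}, {hi:g}]",
        )
    if strategy == "fixed_percentile":
        if percentile is None:
            raise DerivationError("fixed_percentile needs a percentile")
        return ActivationRule(
            gene_id=gene_id,
            strategy=strategy,
            threshold_percentile=float(percentile),
            provenance="configured fixed percentile",
        )
    raise InputError(f"unknown strategy {strategy!r}")


@dataclass
class ActivationMatrix:
    """Binary genes x patients activation calls with the rule used per gene."""

    calls: pd.DataFrame          # 0/1, genes x patients
    rules: dict                  # gene -> ActivationRule

    def count_per_patient(self, genes: Optional[Sequence[str]] = None) -> pd.Series:
        sub = self.calls if genes is None else self.calls.loc[list(genes)]
        return sub.sum(axis=0).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return self.calls


def call_activations(
    cohort: TumorCohort, rules: Mapping[str, ActivationRule]
) -> ActivationMatrix:
    """Apply activation rules to a cohort: call = 1 iff expression > threshold.

    Percentile rules resolve against the cohort's own per-gene distribution
    (linear-interpolation quantile); value rules apply as absolute units.
    """
    genes = list(rules)
    missing = [g for g in genes if g not in cohort.expression.values.index]
    if missing:
        raise InputError(f"rules reference genes absent from cohort: {missing[:5]}")
    calls = {}
    for gene in genes:
        rule = rules[gene]
        expr = cohort.expression.gene(gene)
        if rule.threshold_value is not None:
            thr = float(rule.threshold_value)
        else:
            thr = float(np.percentile(expr, rule.threshold_percentile))
        calls[gene] = (expr > thr).astype(int)
    frame = pd.DataFrame(calls, index=cohort.patient_ids).T
    return ActivationMatrix(calls=frame, rules=dict(rules))
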