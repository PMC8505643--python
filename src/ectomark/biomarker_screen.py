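"""Step-1 gene screen: Cox association + percentile threshold-stability scan.

For each candidate gene the screen (1) fits a univariate Cox model of survival
on standardised expression and requires a significant hazard increase with
overexpression, (2) scans a grid of expression percentiles, dichotomising the
cohort at each and testing the two groups by log-rank, and (3) requires the
longest contiguous run of significant percentiles to span more than a minimum
width (50 percentile points by default) — the threshold-stability property
that makes a marker robust to the measurement platform.

Raw (uncorrected) p-values are used by design, as in the original selection
procedure; every report records the number of candidates tested so users can
judge the multiplicity burden themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io_formats import TumorCohort
from .survival_core import fit_cox, logrank_scan
from .errors import DegenerateDataError


@dataclass(frozen=True)
class ScreenCriteria:
    """The three selection criteria and the scan configuration."""

    cox_alpha: float = 0.05
    logrank_alpha: float = 0.05
    min_interval_width: float = 50.0        # percentile points, strict >
    percentile_grid: tuple = tuple(range(10, 91))
    direction_required: bool = True         # high expression must be the worse group
    min_group_size: int = 5
    min_group_events: int = 1
    interval_rule: str = "contiguous"       # or "total" (sensitivity analysis)

    def __post_init__(self) -> None:
        grid = np.asarray(self.percentile_grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ConfigurationError("percentile_grid must be strictly increasing")
        if grid[0] <= 0 or grid[-1] >= 100:
            raise ConfigurationError("percentile_grid must lie strictly inside (0, 100)")
        for name in ("cox_alpha", "logrank_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if not 0 < self.min_interval_width < 100:
            raise ConfigurationError("min_interval_width must lie in (0, 100)")
        if self.interval_rule not in ("contiguous", "total"):
            raise ConfigurationError("interval_rule must be 'contiguous' or 'total'")

    def to_dict(self) -> dict:
        return {
            "cox_alpha": self.cox_alpha,
            "logrank_alpha": self.logrank_alpha,
            "min_interval_width": self.min_interval_width,
            "percentile_grid": list(self.percentile_grid),
            "direction_required": self.direction_required,
            "min_group_size": self.min_group_size,
            "min_group_events": self.min_group_events,
            "interval_rule": self.interval_rule,
        }


@dataclass
class ThresholdScan:
    """Per-percentile dichotomisation results for one gene."""

    table: pd.DataFrame  # percentile, threshold, evaluable, p_value, high_worse, significant, ...

    @property
    def percentiles(self) -> np.ndarray:
        return self.table["percentile"].to_numpy()

    @property
    def significant(self) -> np.ndarray:
        return self.table["significant"].to_numpy(dtype=bool)

    def significant_runs(self) -> list[tuple[float, float]]:
        """Maximal runs of consecutive significant grid percentiles, as (q_lo, q_hi)."""
        runs: list[tuple[float, float]] = []
        q = self.percentiles
        sig = self.significant
        start = None
        for i in range(len(q)):
            if sig[i] and start is None:
                start = i
            if start is not None and (not sig[i]):
                runs.append((float(q[start]), float(q[i - 1])))
                start = None
        if start is not None:
            runs.append((float(q[start]), float(q[-1])))
        return runs

    def to_dict(self) -> dict:
        return {c: self.table[c].tolist() for c in self.table.columns}


@dataclass
class GeneScreenResult:
    gene_id: str
    cox_p: float
    cox_coefficient: float
    cox_hazard_ratio: float     # per standardised expression unit
    scan: ThresholdScan
    interval_width: float
    passes_criterion_1: bool
    passes_criterion_2: bool
    passes_criterion_3: bool
    note: str = ""

    @property
    def selected(self) -> bool:
        return self.passes_criterion_1 and self.passes_criterion_2 and self.passes_criterion_3

    def to_dict(self, include_scan: bool = True) -> dict:
        d = {
            "gene_id": self.gene_id,
            "cox_p": None if np.isnan(self.cox_p) else float(self.cox_p),
            "cox_coefficient": None if np.isnan(self.cox_coefficient) else float(self.cox_coefficient),
            "cox_hazard_ratio": None if np.isnan(self.cox_hazard_ratio) else float(self.cox_hazard_ratio),
            "interval_width": float(self.interval_width),
            "passes_criterion_1": bool(self.passes_criterion_1),
            "passes_criterion_2": bool(self.passes_criterion_2),
            "passes_criterion_3": bool(self.passes_criterion_3),
            "selected": bool(self.selected),
            "note": self.note,
        }
        if include_scan:
            d["scan"] = self.scan.to_dict()
        return d


def scan_thresholds(
    expression: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> ThresholdScan:
    """Dichotomise at every grid percentile and log-rank the two groups.

    The threshold at percentile q is the linear-interpolation quantile of the
    cohort's own expression; patients with expression strictly above it form
    the "high" group (ties go low). Splits leaving a group below the minimum
    size or event count are non-evaluable, not errors. A grid point is
    significant iff the log-rank p is below ``logrank_alpha`` and, when
    direction is required, the high group has more observed than expected
    events (worse survival).
    """
    expression = np.asarray(expression, dtype=float)
    time = np.asarray(time, dtype=float)
    if expression.shape != time.shape:
        raise InputError("expression and survival must align on patients")
    grid = np.asarray(criteria.percentile_grid, dtype=float)
    thresholds = np.percentile(expression, grid)  # linear interpolation
    high = expression[None, :] > thresholds[:, None]
    res = logrank_scan(
        time,
        event,
        high,
        min_group_size=criteria.min_group_size,
        min_group_events=criteria.min_group_events,
    )
    evaluable = res["evaluable"]
    high_worse = res["o_high"] > res["e_high"]
    significant = evaluable & (res["p"] < criteria.logrank_alpha)
    if criteria.direction_required:
        significant &= high_worse
    table = pd.DataFrame(
        {
            "percentile": grid,
            "threshold": thresholds,
            "evaluable": evaluable,
            "chi_square": res["chi_square"],
            "p_value": res["p"],
            "high_worse": high_worse,
            "significant": significant,
            "n_high": res["n_high"],
            "events_high": res["events_high"],
        }
    )
    return ThresholdScan(table)


def longest_significant_interval(
    scan: ThresholdScan, rule: str = "contiguous"
) -> float:
    """Width (q_max - q_min) of the longest maximal run of significant
    consecutive grid percentiles; 0 for an empty set or a single point.

    ``rule='total'`` instead sums the spans of all runs (sensitivity variant).
    """
    runs = scan.significant_runs()
    if not runs:
        return 0.0
    widths = [hi - lo for lo, hi in runs]
    if rule == "total":
        return float(sum(widths))
    return float(max(widths))


def screen_gene(
    expression: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    criteria: ScreenCriteria = ScreenCriteria(),
    gene_id: str = "",
) -> GeneScreenResult:
    """Apply the three selection criteria to one gene.

    Criterion 1 is a univariate Cox fit on z-scored expression requiring
    p < ``cox_alpha`` with a positive coefficient (overexpression associated
    with shorter survival); criterion 2 requires at least one significant grid
    percentile; criterion 3 requires the longest significant run to exceed
    ``min_interval_width`` percentile points. Degenerate genes (constant
    expression, no events) are recorded as failing, never raised.

    Non-negative (linear-scale) expression is log2(x+1)-transformed before
    z-scoring: TPM/FPKM-like values are heavy-tailed and a linear Cox
    predictor would let a handful of extreme values dominate the Wald test.
    Data containing negatives are assumed already log-scale and z-scored
    directly. The scan criteria (2 and 3) are invariant to either choice.
    """
    expression = np.asarray(expression, dtype=float)
    note = ""
    cox_p = cox_beta = cox_hr = float("nan")
    c1 = False
    cox_input = np.log2(expression + 1.0) if expression.min() >= 0 else expression
    sd = cox_input.std()
    if sd == 0:
        note = "constant expression; Cox fit not possible"
    else:
        z = (cox_input - cox_input.mean()) / sd
        try:
            fit = fit_cox(z[:, None], time, event, names=[gene_id or "expression"])
            if fit.converged:
                cox_p = float(fit.p_values[0])
                cox_beta = float(fit.coefficients[0])
                cox_hr = float(fit.hazard_ratios[0])
                c1 = cox_p < criteria.cox_alpha and cox_beta > 0
            else:
                note = "Cox fit did not converge"
        except (InputError, DegenerateDataError) as exc:
            note = f"Cox fit refused: {exc}"
    scan = scan_thresholds(expression, time, event, criteria)
    width = longest_significant_interval(scan, rule=criteria.interval_rule)
    c2 = bool(scan.significant.any())
    c3 = width > criteria.min_interval_width
    return GeneScreenResult(
        gene_id=gene_id,
        cox_p=cox_p,
        cox_coefficient=cox_beta,
        cox_hazard_ratio=cox_hr,
        scan=scan,
        interval_width=width,
        passes_criterion_1=c1,
        passes_criterion_2=c2,
        passes_criterion_3=c3,
        note=note,
    )


@dataclass
class ScreenReport:
    """Per-gene screen results, ranked by Cox p (gene ID tiebreak)."""

    results: list           # of GeneScreenResult, ranked
    criteria: ScreenCriteria
    n_candidates: int
    n_patients: int
    n_events: int

    @property
    def selected_genes(self) -> list:
        return [r.gene_id for r in self.results if r.selected]

    def ranked_gene_ids(self) -> list:
        return [r.gene_id for r in self.results]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "cox_p": r.cox_p,
                    "cox_hazard_ratio": r.cox_hazard_ratio,
                    "interval_width": r.interval_width,
                    "criterion_1": r.passes_criterion_1,
                    "criterion_2": r.passes_criterion_2,
                    "criterion_3": r.passes_criterion_3,
                    "selected": r.selected,
                }
                for r in self.results
            ]
        )

    def to_dict(self, include_scans: bool = False) -> dict:
        return {
            "criteria": self.criteria.to_dict(),
            "n_candidates_tested": int(self.n_candidates),
            "n_patients": int(self.n_patients),
            "n_events": int(self.n_events),
            "selected_genes": self.selected_genes,
            "results": [r.to_dict(include_scan=include_scans) for r in self.results],
        }


def run_screen(
    cohort: TumorCohort,
    candidate_genes: Sequence[str],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> ScreenReport:
    """Screen every candidate gene of a cohort; deterministic ranking."""
    candidates = list(candidate_genes)
    if not candidates:
        raise InputError("empty candidate list")
    missing = [g for g in candidates if g not in cohort.expression.values.index]
    if missing:
        raise InputError(f"candidates absent from cohort: {missing[:5]}")
    time, event = cohort.time, cohort.event
    results = [
        screen_gene(cohort.expression.gene(g), time, event, criteria, gene_id=g)
        for g in candidates
    ]
    results.sort(key=lambda r: (np.isnan(r.cox_p), r.cox_p if not np.isnan(r.cox_p) else 0.0, r.gene_id))
    return ScreenReport(
        results=results,
        criteria=criteria,
        n_candidates=len(candidates),
        n_patients=len(time),
        n_events=int(event.sum()),
    )
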