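"""Activation-count panel classification and its survival analyses.

The classifier counts activated panel genes per patient (0..3 for the
AREG/CCNA1/DDX20 panel) and assigns the risk group: "good" for 0-1
activations, "poor" for 2-3. Stratified Kaplan-Meier / log-rank / Cox
analyses, TNM early/late and HPV/site subgroup analyses, and multivariate Cox
models with clinical covariates mirror the validation analyses of the study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .activation import ActivationMatrix
from .errors import DegenerateDataError, InputError
from .survival_core import CoxFit, KaplanMeierCurve, fit_cox, kaplan_meier, logrank_test

GOOD, POOR = "good", "poor"


def risk_group_from_count(count: int) -> str:
    """0 or 1 activated genes -> good prognosis; 2 or more -> poor."""
    return GOOD if count <= 1 else POOR


def score_panel(activations: ActivationMatrix, panel_genes: Sequence[str]) -> pd.DataFrame:
    """Per-patient activation count over the panel genes and the risk group."""
    panel = list(panel_genes)
    missing = [g for g in panel if g not in activations.calls.index]
    if missing:
        raise InputError(f"panel genes absent from activation matrix: {missing}")
    counts = activations.calls.loc[panel].sum(axis=0).astype(int)
    return pd.DataFrame(
        {
            "activation_count": counts,
            "risk_group": [risk_group_from_count(c) for c in counts],
        },
        index=counts.index.rename("patient_id"),
    )


@dataclass
class StratificationReport:
    """KM/log-rank/Cox summary of a cohort stratified by the panel."""

    km_by_count: dict                      # count -> KaplanMeierCurve
    km_by_risk: dict                       # 'good'/'poor' -> KaplanMeierCurve
    logrank_by_count: Optional[object]    # LogrankResult or None
    logrank_by_risk: Optional[object]
    cox_count: Optional[CoxFit]           # count as single numeric covariate
    group_sizes: dict
    n_patients: int
    n_events: int
    notices: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group_sizes": {str(k): int(v) for k, v in self.group_sizes.items()},
            "n_patients": int(self.n_patients),
            "n_events": int(self.n_events),
            "km_by_count": {str(k): v.to_dict() for k, v in self.km_by_count.items()},
            "km_by_risk": {k: v.to_dict() for k, v in self.km_by_risk.items()},
            "logrank_by_count": None if self.logrank_by_count is None else self.logrank_by_count.to_dict(),
            "logrank_by_risk": None if self.logrank_by_risk is None else self.logrank_by_risk.to_dict(),
            "cox_count": None if self.cox_count is None else self.cox_count.to_dict(),
            "notices": list(self.notices),
        }


def stratified_survival_analysis(
    scores: pd.DataFrame, clinical: pd.DataFrame
) -> StratificationReport:
    """KM per count group and risk group, k-group and 2-group log-rank, and a
    Cox model with the activation count as the single explanatory variable.

    Degenerate strata (a single group, no events) are reported as notices with
    the corresponding test skipped; KM curves are always emitted.
    """
    joined = scores.join(clinical[["os_months", "event"]], how="inner")
    if len(joined) == 0:
        raise InputError("no patients shared between scores and clinical table")
    if len(joined) < len(scores):
        raise InputError("patients in scores missing from clinical table")
    time = joined["os_months"].to_numpy(float)
    event = joined["event"].to_numpy(int)
    counts = joined["activation_count"].to_numpy(int)
    risk = joined["risk_group"].to_numpy()

    notices: list[str] = []
    km_by_count = {
        int(c): kaplan_meier(time[counts == c], event[counts == c])
        for c in sorted(set(counts))
    }
    km_by_risk = {
        str(r): kaplan_meier(time[risk == r], event[risk == r]) for r in sorted(set(risk))
    }
    group_sizes = {
        **{f"count={c}": int((counts == c).sum()) for c in sorted(set(counts))},
        **{f"risk={r}": int((risk == r).sum()) for r in sorted(set(risk))},
    }

    def _try_logrank(labels, what):
        try:
            return logrank_test(time, event, labels)
        except DegenerateDataError as exc:
            notices.append(f"log-rank by {what} skipped: {exc}")
            return None

    lr_count = _try_logrank(counts, "count") if len(set(counts)) >= 2 else None
    if len(set(counts)) < 2:
        notices.append("log-rank by count skipped: single count group")
    lr_risk = _try_logrank(risk, "risk group") if len(set(risk)) >= 2 else None
    if len(set(risk)) < 2:
        notices.append("log-rank by risk group skipped: single risk group")

    cox = None
    if len(set(counts)) >= 2 and event.sum() > 0:
        try:
            cox = fit_cox(counts.astype(float)[:, None], time, event, names=["activation_count"])
        except (InputError, DegenerateDataError) as exc:
            notices.append(f"Cox on activation count skipped: {exc}")
    else:
        notices.append("Cox on activation count skipped: degenerate grouping")

    return StratificationReport(
        km_by_count=km_by_count,
        km_by_risk=km_by_risk,
        logrank_by_count=lr_count,
        logrank_by_risk=lr_risk,
        cox_count=cox,
        group_sizes=group_sizes,
        n_patients=len(joined),
        n_events=int(event.sum()),
        notices=notices,
    )


# ---------------------------------------------------------------------------
# clinical covariates

def derive_clinical_covariates(clinical: pd.DataFrame, m1_is_late: bool = True) -> pd.DataFrame:
    """Derive analysis covariates from the raw clinical table.

    TNM stage class: early iff (T in {1,2}) and (N in {0,1}); late iff (T >= 3)
    or (N >= 2); M1 additionally forces late when ``m1_is_late`` (distant
    metastasis read conservatively as late stage). Unknown T or N propagates to
    an unknown stage class. Site class is TBOT for tonsil / base-of-tongue.
    """
    t = clinical["t_stage"]
    n = clinical["n_stage"]
    m = clinical["m_stage"] if "m_stage" in clinical.columns else pd.Series(pd.NA, index=clinical.index)

    late = (t >= 3) | (n >= 2)
    if m1_is_late:
        late = late | (m == 1)
    early = (t.isin([1, 2])) & (n.isin([0, 1])) & ~late.fillna(False)
    stage = np.where(late.fillna(False), "late", np.where(early.fillna(False), "early", "unknown"))

    site = clinical["site"].astype(str)
    site_class = np.where(
        site.str.lower().isin(["tbot", "tonsil", "base of tongue"]),
        "TBOT",
        np.where(site == "unknown", "unknown", "other"),
    )
    out = pd.DataFrame(
        {
            "stage_class": stage,
            "hpv": clinical["hpv"].astype(str),
            "site_class": site_class,
            "age": clinical["age"].astype(float),
            "gender": clinical["gender"].astype(str),
        },
        index=clinical.index,
    )
    if "grade" in clinical.columns:
        out["grade"] = clinical["grade"].astype(str)
    return out


def subgroup_analysis(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    clinical: pd.DataFrame,
    by: str,
) -> dict:
    """Re-run the stratified analysis within each known level of a covariate.

    Returns level -> {"report": StratificationReport | None, "flags": [...]}.
    Levels whose patients fall into fewer than two risk groups, or where one
    risk group is nearly empty, are flagged as degenerate (the tests inside the
    report are then skipped or unreliable).
    """
    if by not in covariates.columns:
        raise InputError(f"unknown covariate {by!r}")
    out: dict[str, dict] = {}
    levels = [l for l in sorted(covariates[by].astype(str).unique()) if l != "unknown"]
    if not levels:
        raise InputError(f"covariate {by!r} has no known levels")
    for level in levels:
        ids = covariates.index[covariates[by].astype(str) == level]
        ids = [i for i in ids if i in scores.index]
        flags: list[str] = []
        if not ids:
            out[level] = {"report": None, "flags": ["empty subgroup"]}
            continue
        sub_scores = scores.loc[ids]
        risk_counts = sub_scores["risk_group"].value_counts()
        if len(risk_counts) < 2:
            flags.append("degenerate subgroup: a single risk group")
        elif risk_counts.min() <= 1:
            flags.append(
                "degenerate subgroup: a near-empty risk group "
                f"(n={int(risk_counts.min())})"
            )
        report = stratified_survival_analysis(sub_scores, clinical.loc[ids])
        out[level] = {"report": report, "flags": flags}
    return out


@dataclass
class MultivariateReport:
    fit: Optional[CoxFit]
    n_total: int
    n_complete: int
    covariates_used: list
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fit": None if self.fit is None else self.fit.to_dict(),
            "n_total": int(self.n_total),
            "n_complete_case": int(self.n_complete),
            "covariates_used": list(self.covariates_used),
            "flags": list(self.flags),
        }


def multivariate_analysis(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    clinical: pd.DataFrame,
    covariate_list: Sequence[str] = ("age", "gender", "stage_class"),
    use_count: bool = False,
) -> MultivariateReport:
    """Multivariate Cox: panel risk group (or 0-3 count) plus clinical covariates.

    Complete-case analysis: patients with an unknown level of any requested
    covariate are excluded (counts reported). Categorical covariates enter as
    indicator codes; rank deficiency or separation is flagged, never reported
    as a spurious estimate.
    """
    df = scores.join(covariates, how="inner").join(
        clinical[["os_months", "event"]], how="inner"
    )
    n_total = len(df)
    design: dict[str, np.ndarray] = {}
    if use_count:
        design["activation_count"] = df["activation_count"].to_numpy(float)
    else:
        design["panel_poor"] = (df["risk_group"] == POOR).to_numpy(float)

    known = np.ones(n_total, dtype=bool)
    for cov in covariate_list:
        if cov not in covariates.columns:
            raise InputError(f"unknown covariate {cov!r}")
        col = df[cov]
        if cov == "age":
            known &= col.notna().to_numpy()
            design["age"] = col.to_numpy(float)
        elif cov == "gender":
            known &= col.astype(str).isin(["male", "female"]).to_numpy()
            design["gender_male"] = (col == "male").to_numpy(float)
        elif cov == "stage_class":
            known &= (col != "unknown").to_numpy()
            design["stage_late"] = (col == "late").to_numpy(float)
        elif cov == "hpv":
            known &= (col != "unknown").to_numpy()
            design["hpv_positive"] = (col == "positive").to_numpy(float)
        elif cov == "site_class":
            known &= (col != "unknown").to_numpy()
            design["site_tbot"] = (col == "TBOT").to_numpy(float)
        else:
            raise InputError(f"unsupported covariate {cov!r}")

    X = np.column_stack([v for v in design.values()])[known]
    names = list(design)
    time = df["os_months"].to_numpy(float)[known]
    event = df["event"].to_numpy(int)[known]
    n_complete = int(known.sum())
    flags: list[str] = []
    if n_complete == 0:
        return MultivariateReport(None, n_total, 0, names, ["no complete cases"])
    try:
        fit = fit_cox(X, time, event, names=names)
    except (InputError, DegenerateDataError) as exc:
        return MultivariateReport(None, n_total, n_complete, names, [f"fit refused: {exc}"])
    if fit.monotone_likelihood:
        flags.append("monotone likelihood (separation); estimates unreliable")
    elif not fit.converged:
        flags.append("fit did not converge")
    return MultivariateReport(fit, n_total, n_complete, names, flags)
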