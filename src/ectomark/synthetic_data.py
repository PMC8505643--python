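"""Synthetic cohorts emulating the study's three data layers.

Three seeded generators produce (a) a normal-tissue expression panel with
planted germline/placenta-predominant genes that are silent in all somatic
tissues, (b) a tumour cohort in which a subset of ectopic candidate genes is
activated per patient and true prognostic activations raise the hazard under a
proportional-hazards model with exponential baseline, and (c) an
immunohistochemistry table whose staining scores are stochastically coupled to
the underlying activation truth. Every generator returns a full ground-truth
record so downstream stages can be tested as parameter-recovery problems.

Expression is log-normal in both states: a low "background" mode for silent
genes and a high "active" mode, mirroring the bimodal premise that lets an
activation threshold separate ectopic expression from background. Ordinary
(non-candidate) genes draw from a broad expressed distribution in all tissues.

One global seed is expanded into independent per-generator substreams, so
adding one generator to a pipeline never perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .io_formats import (
    ExpressionMatrix,
    NormalTissuePanel,
    RNASEQ_LIKE,
    TumorCohort,
    validate_clinical,
)

#: The three-marker panel of the study and the full candidate list it came from.
PANEL_GENES = ("AREG", "CCNA1", "DDX20")
FIFTEEN_GENE_CANDIDATES = (
    "AREG", "CCNA1", "CDKN3", "DDX20", "EFCAB11", "GMPS", "MMP10", "MRGBP",
    "NUP155", "PAPPA", "PSMC3IP", "PSMG1", "SUV39H2", "TDO2", "TRIP13",
)

# germline/placenta tissues first so small panels still contain them
_TISSUE_NAMES = (
    "testis", "placenta", "ovary",
    "adipose", "adrenal gland", "bladder", "bone marrow", "brain", "breast",
    "colon", "duodenum", "endometrium", "esophagus", "gallbladder", "heart",
    "kidney", "liver", "lung", "lymph node", "pancreas", "prostate", "rectum",
    "salivary gland", "skeletal muscle", "skin", "small intestine", "spleen",
    "stomach", "thyroid", "tonsil",
)

_STREAMS = {"normal_panel": 11, "tumor_cohort": 23, "ihc": 37}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the conditions the screen-recovery experiments run under:
    3 truly prognostic genes among 500 ectopic candidates, activation fraction
    0.4, hazard ratio 2.5 per activated prognostic gene, 400 patients, an
    exponential baseline hazard of 0.01 events/month, administrative censoring
    at 262 months (the follow-up ceiling of the IHC cohort) plus independent
    exponential dropout.
    """

    n_tissues: int = 30
    n_samples_per_tissue: int = 5
    n_genes: int = 500
    n_tissue_specific: int = 50
    germline_tissues: frozenset = frozenset({"testis", "ovary", "placenta"})
    n_patients: int = 400
    n_ectopic_candidates: int = 500
    n_true_prognostic: int = 3
    activation_fraction: float = 0.4
    log_hazard_per_activation: float = math.log(2.5)
    baseline_hazard: float = 0.008          # events per month
    censor_time: float = 262.0              # months, administrative cutoff
    dropout_rate: float = 0.005             # per month, independent censoring
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.02, "stage_late": 0.6}
    )
    background_log_mean: float = math.log(0.1)
    background_log_sd: float = 0.8
    active_log_mean: float = math.log(50.0)
    active_log_sd: float = 0.7
    expressed_log_mean: float = math.log(5.0)
    expressed_log_sd: float = 1.5
    ihc_coupling: float = 1.0               # 0 = scores independent of truth
    seed: int = 0

    _COVARIATE_KEYS = frozenset(
        {"age", "gender", "t_stage", "n_stage", "m_stage", "hpv", "site", "stage_late"}
    )

    def validate(self) -> "SimConfig":
        counts = {
            "n_tissues": self.n_tissues,
            "n_samples_per_tissue": self.n_samples_per_tissue,
            "n_genes": self.n_genes,
            "n_patients": self.n_patients,
        }
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ConfigurationError(f"{name} must be a positive integer (got {value!r})")
        for name in ("n_tissue_specific", "n_ectopic_candidates", "n_true_prognostic"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 0):
                raise ConfigurationError(f"{name} must be a non-negative integer (got {value!r})")
        if self.n_true_prognostic > self.n_ectopic_candidates:
            raise ConfigurationError(
                "n_true_prognostic must not exceed n_ectopic_candidates"
            )
        if self.n_ectopic_candidates > self.n_genes:
            raise ConfigurationError("n_ectopic_candidates must not exceed n_genes")
        if self.n_tissue_specific > self.n_genes:
            raise ConfigurationError("n_tissue_specific must not exceed n_genes")
        if not 0.0 < self.activation_fraction < 1.0:
            raise ConfigurationError("activation_fraction must lie in (0, 1)")
        if not self.baseline_hazard > 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if not self.censor_time > 0:
            raise ConfigurationError("censor_time must be > 0")
        if self.dropout_rate < 0:
            raise ConfigurationError("dropout_rate must be >= 0")
        for sd_name in ("background_log_sd", "active_log_sd", "expressed_log_sd"):
            if not getattr(self, sd_name) > 0:
                raise ConfigurationError(f"{sd_name} must be > 0")
        if not 0.0 <= self.ihc_coupling <= 1.0:
            raise ConfigurationError("ihc_coupling must lie in [0, 1]")
        unknown = set(self.covariate_effects) - self._COVARIATE_KEYS
        if unknown:
            raise ConfigurationError(f"covariate_effects has unknown keys {sorted(unknown)}")
        if self.n_tissues > len(_TISSUE_NAMES):
            raise ConfigurationError(
                f"n_tissues must be <= {len(_TISSUE_NAMES)} (named tissue panel)"
            )
        if not any(t in self.tissue_names() for t in self.germline_tissues):
            raise ConfigurationError(
                "germline_tissues must intersect the tissue panel"
            )
        return self

    def tissue_names(self) -> tuple:
        return _TISSUE_NAMES[: self.n_tissues]

    def gene_ids(self) -> list:
        width = max(5, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def patient_ids(self) -> list:
        width = max(4, len(str(self.n_patients)))
        return [f"P{i:0{width}d}" for i in range(1, self.n_patients + 1)]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["germline_tissues"] = sorted(self.germline_tissues)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "germline_tissues" in d:
            d["germline_tissues"] = frozenset(d["germline_tissues"])
        return cls(**d).validate()


@dataclass
class TruthRecord:
    """Ground truth of a simulated study, for parameter-recovery tests."""

    tissue_specific_genes: dict = field(default_factory=dict)  # gene -> home tissue
    true_prognostic_genes: frozenset = frozenset()
    ectopic_candidate_genes: tuple = ()
    activation_matrix_truth: Optional[pd.DataFrame] = None    # genes x patients, 0/1
    linear_predictor: Optional[pd.Series] = None              # patient -> true lp

    def to_dict(self) -> dict:
        return {
            "tissue_specific_genes": dict(sorted(self.tissue_specific_genes.items())),
            "true_prognostic_genes": sorted(self.true_prognostic_genes),
            "ectopic_candidate_genes": list(self.ectopic_candidate_genes),
            "activation_matrix_truth": (
                None
                if self.activation_matrix_truth is None
                else {
                    "genes": list(self.activation_matrix_truth.index),
                    "patients": list(self.activation_matrix_truth.columns),
                    "calls": self.activation_matrix_truth.to_numpy().astype(int).tolist(),
                }
            ),
            "linear_predictor": (
                None if self.linear_predictor is None else self.linear_predictor.to_dict()
            ),
        }


# ---------------------------------------------------------------------------
# (a) normal-tissue panel

def simulate_normal_tissue_matrix(config: SimConfig) -> tuple[NormalTissuePanel, TruthRecord]:
    """Normal-tissue panel with planted germline-predominant silent genes.

    The first ``n_tissue_specific`` genes are each homed in one germline
    tissue (cycling through ``germline_tissues``): their expression draws from
    the active log-normal mode in the home tissue's samples and from the low
    background mode everywhere else. All remaining genes draw from a broad
    expressed distribution in every tissue.
    """
    config.validate()
    rng = config.rng("normal_panel")
    tissues = config.tissue_names()
    genes = config.gene_ids()
    samples, tissue_of_sample = [], []
    for t in tissues:
        for i in range(1, config.n_samples_per_tissue + 1):
            samples.append(f"{t.replace(' ', '_')}_{i:02d}")
            tissue_of_sample.append(t)
    tissue_arr = np.asarray(tissue_of_sample)

    n_g, n_s = config.n_genes, len(samples)
    values = rng.lognormal(config.expressed_log_mean, config.expressed_log_sd, (n_g, n_s))

    germ = sorted(t for t in config.germline_tissues if t in tissues)
    homes: dict[str, str] = {}
    for k in range(config.n_tissue_specific):
        gene = genes[k]
        home = germ[k % len(germ)]
        homes[gene] = home
        in_home = tissue_arr == home
        values[k, ~in_home] = rng.lognormal(
            config.background_log_mean, config.background_log_sd, (~in_home).sum()
        )
        values[k, in_home] = rng.lognormal(
            config.active_log_mean, config.active_log_sd, in_home.sum()
        )
    panel = NormalTissuePanel(
        expression=ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=samples), platform=RNASEQ_LIKE
        ),
        tissue_of_sample=pd.Series(tissue_arr, index=samples),
        germline_tissues=frozenset(config.germline_tissues),
    )
    truth = TruthRecord(
        tissue_specific_genes=homes,
        ectopic_candidate_genes=tuple(genes[: config.n_ectopic_candidates]),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# (b) tumour cohort

def _encode_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding used inside the simulated hazard."""
    late = ((clinical["t_stage"] >= 3) | (clinical["n_stage"] >= 2)
            | (clinical["m_stage"] == 1)).astype(float)
    return pd.DataFrame(
        {
            "age": clinical["age"].astype(float) - 60.0,
            "gender": (clinical["gender"] == "male").astype(float),
            "t_stage": clinical["t_stage"].astype(float),
            "n_stage": clinical["n_stage"].astype(float),
            "m_stage": clinical["m_stage"].astype(float),
            "hpv": (clinical["hpv"] == "positive").astype(float),
            "site": (clinical["site"] == "TBOT").astype(float),
            "stage_late": late,
        },
        index=clinical.index,
    )


def simulate_tumor_cohort(config: SimConfig) -> tuple[TumorCohort, TruthRecord]:
    """Tumour cohort whose survival is driven by planted ectopic activations.

    Each of the first ``n_ectopic_candidates`` genes activates independently
    per patient with probability ``activation_fraction``; the first
    ``n_true_prognostic`` of them add ``log_hazard_per_activation`` to the log
    hazard when activated. Event times are exponential with hazard
    ``baseline_hazard * exp(lp)``; censoring is the minimum of an independent
    exponential dropout and the administrative cutoff.
    """
    config.validate()
    rng = config.rng("tumor_cohort")
    genes = config.gene_ids()
    patients = config.patient_ids()
    n_g, n_p = config.n_genes, config.n_patients
    n_c = config.n_ectopic_candidates

    # clinical covariates
    age = np.clip(rng.normal(60.0, 10.0, n_p), 25.0, 90.0)
    gender = np.where(rng.random(n_p) < 0.7, "male", "female")  # OSCC skews male
    t_stage = rng.choice([1, 2, 3, 4], size=n_p, p=[0.2, 0.35, 0.25, 0.2])
    n_stage = rng.choice([0, 1, 2, 3], size=n_p, p=[0.45, 0.2, 0.3, 0.05])
    m_stage = rng.choice([0, 1], size=n_p, p=[0.95, 0.05])
    hpv = np.where(rng.random(n_p) < 0.15, "positive", "negative")
    site = np.where(rng.random(n_p) < 0.25, "TBOT", "other")

    clinical = pd.DataFrame(
        {
            "age": age,
            "gender": gender,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "m_stage": m_stage,
            "hpv": hpv,
            "site": site,
            "grade": rng.choice(["I", "II", "III"], size=n_p, p=[0.3, 0.5, 0.2]),
        },
        index=pd.Index(patients, name="patient_id"),
    )

    # activations and expression
    active = np.zeros((n_g, n_p), dtype=bool)
    active[:n_c] = rng.random((n_c, n_p)) < config.activation_fraction
    values = rng.lognormal(config.expressed_log_mean, config.expressed_log_sd, (n_g, n_p))
    bg = rng.lognormal(config.background_log_mean, config.background_log_sd, (n_c, n_p))
    hi = rng.lognormal(config.active_log_mean, config.active_log_sd, (n_c, n_p))
    values[:n_c] = np.where(active[:n_c], hi, bg)

    # hazard: true prognostic activations plus clinical covariate effects
    beta = np.zeros(n_g)
    beta[: config.n_true_prognostic] = config.log_hazard_per_activation
    lp = beta[:n_c] @ active[:n_c].astype(float)
    enc = _encode_covariates(clinical)
    for cov, effect in config.covariate_effects.items():
        lp = lp + float(effect) * enc[cov].to_numpy()

    hazard = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, n_p)
    else:
        t_drop = np.full(n_p, np.inf)
    t_cens = np.minimum(t_drop, config.censor_time)
    os_months = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    clinical.insert(0, "os_months", os_months)
    clinical.insert(1, "event", event)
    clinical = validate_clinical(clinical.reset_index())

    cohort = TumorCohort(
        expression=ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=patients), platform=RNASEQ_LIKE
        ),
        clinical=clinical,
    )
    truth = TruthRecord(
        true_prognostic_genes=frozenset(genes[: config.n_true_prognostic]),
        ectopic_candidate_genes=tuple(genes[:n_c]),
        activation_matrix_truth=pd.DataFrame(
            active[:n_c].astype(int), index=genes[:n_c], columns=patients
        ),
        linear_predictor=pd.Series(lp, index=patients),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# (c) IHC table

_BASE_INTENSITY = np.array([0.45, 0.30, 0.18, 0.07])
_ACTIVE_INTENSITY = np.array([0.05, 0.15, 0.35, 0.45])


def simulate_ihc_table(
    config: SimConfig,
    activation_truth: pd.DataFrame,
    marker_genes: Optional[tuple] = None,
) -> pd.DataFrame:
    """Per-patient, per-marker staining intensity and percent-positive cells.

    The three antibody markers (AREG, CCNA1, DDX20) are each coupled to one
    gene of ``activation_truth``: by default the first three rows, otherwise
    the ``marker_genes`` triple. Activated markers are stochastically shifted
    toward high intensity and a high stained proportion;
    ``config.ihc_coupling`` interpolates between no coupling (0: scores
    independent of truth) and the default strong coupling.
    """
    config.validate()
    if marker_genes is None:
        if len(activation_truth.index) < len(PANEL_GENES):
            raise InputError("activation truth must cover the three panel markers")
        marker_genes = tuple(activation_truth.index[: len(PANEL_GENES)])
    missing = [g for g in marker_genes if g not in activation_truth.index]
    if missing:
        raise InputError(f"activation truth missing markers: {missing}")
    if len(marker_genes) != len(PANEL_GENES):
        raise InputError(f"exactly {len(PANEL_GENES)} marker genes required")
    rng = config.rng("ihc")
    s = float(config.ihc_coupling)
    int_active = (1 - s) * _BASE_INTENSITY + s * _ACTIVE_INTENSITY
    a_act, b_act = 1.2 + s * (6.0 - 1.2), 6.0 + s * (2.0 - 6.0)

    rows = []
    patients = list(activation_truth.columns)
    for marker, gene in zip(PANEL_GENES, marker_genes):
        truth_row = activation_truth.loc[gene].to_numpy().astype(bool)
        for j, patient in enumerate(patients):
            if truth_row[j]:
                intensity = int(rng.choice(4, p=int_active))
                percent = 100.0 * rng.beta(a_act, b_act)
            else:
                intensity = int(rng.choice(4, p=_BASE_INTENSITY))
                percent = 100.0 * rng.beta(1.2, 6.0)
            rows.append(
                {
                    "patient_id": patient,
                    "marker": marker,
                    "intensity": intensity,
                    "percent_positive": round(float(percent), 4),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "marker", "intensity", "percent_positive"])


def simulate_study(config: SimConfig):
    """Convenience wrapper: normal panel + tumour cohort + IHC table + merged truth."""
    panel, truth_panel = simulate_normal_tissue_matrix(config)
    cohort, truth_cohort = simulate_tumor_cohort(config)
    ihc = simulate_ihc_table(config, truth_cohort.activation_matrix_truth)
    truth = TruthRecord(
        tissue_specific_genes=truth_panel.tissue_specific_genes,
        true_prognostic_genes=truth_cohort.true_prognostic_genes,
        ectopic_candidate_genes=truth_cohort.ectopic_candidate_genes,
        activation_matrix_truth=truth_cohort.activation_matrix_truth,
        linear_predictor=truth_cohort.linear_predictor,
    )
    return panel, cohort, ihc, truth
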