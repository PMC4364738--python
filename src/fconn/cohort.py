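"""Synthetic two-group cohorts of modular BOLD-like ROI time series.

Each subject's ROI signals follow a band-limited factor model: for an ROI
in module m with within-module coherence fraction q (0 < q <= 1),

    y_roi(t) = a * (sqrt(q) * f_m(t) + sqrt(1-q) * h_roi(t))
               + b * g(t) + sigma * eps_roi(t)

with f_m a module-shared factor, h_roi an ROI-private factor, g a global
factor shared by all ROIs (all unit-variance and band-limited to
0.01-0.1 Hz) and eps white noise.  The factor construction guarantees a
positive-definite covariance at any number of ROIs, and because the
coherence split leaves every ROI's variance at a^2 + b^2 + sigma^2 the
population correlations are closed-form:

    within module m:  (q * a^2 + b^2) / (a^2 + b^2 + sigma^2)
    between modules:  b^2 / (a^2 + b^2 + sigma^2)

Group and covariate effects act on coherence, not on amplitude: patients
have q of one designated module multiplied by ``patient_effect**2`` (the
module-shared part of the loading scaled by ``patient_effect``), and every
subject's q is modulated by a hemoglobin-coupled factor.  Acting on q
leaves each ROI's variance — and therefore all between-module
correlations — untouched, so a weakened module cannot masquerade as
increased long-range connectivity after Pearson normalization.  At
q = 1 (no disease effect, hemoglobin at its group mean) the model reduces
to the plain shared-factor form y = a*f_m + b*g + sigma*eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "generate_subject_timeseries",
    "generate_cohort",
    "generate_clinical_table",
    "population_correlation",
]

# Table-1-style clinical distributions (means, SDs) used by the generator.
_PATIENT_HB = (95.4, 22.6)     # g/L
_CONTROL_HB = (135.0, 10.0)    # g/L, population-normal controls
_PATIENT_AGE = (38.0, 10.5)
_CONTROL_AGE = (42.1, 8.4)
_PATIENT_MALE_FRAC = 16 / 22
_CONTROL_MALE_FRAC = 19 / 29
_CALCIUM_MMOL = (2.25, 0.22)   # mmol/L
_ALBUMIN_GL = (38.0, 4.0)      # g/L
_DIALYSIS_MONTHS = (7.4, 2.2)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic two-group cohort (defaults: scaled-down study).

    128 ROIs in four modules of 40/31/36/21 nodes (proportional to a
    1,024-ROI parcellation split 317/250/289/168), 160 volumes at TR 3 s,
    22 patients vs 29 controls, and a patient effect that multiplies the
    intra-module loading of the largest module by 0.6.
    """

    n_patients: int = 22
    n_controls: int = 29
    n_rois: int = 128
    n_volumes: int = 160
    tr_seconds: float = 3.0
    module_sizes: tuple[int, ...] = (40, 31, 36, 21)
    intra_loading: float = 0.6
    inter_loading: float = 0.25
    patient_effect: float = 0.6
    affected_module: int = 0
    covariate_coupling: float = 0.15
    noise_sd: float = 0.7
    motion_step_trans_mm: float = 0.05
    motion_step_rot_deg: float = 0.02
    band: tuple[float, float] = (0.01, 0.1)
    seed: int = 0

    def validate(self) -> None:
        if sum(self.module_sizes) != self.n_rois:
            raise ValueError("module_sizes must sum to n_rois")
        if not 0 <= self.inter_loading <= self.intra_loading < 1:
            raise ValueError("require 0 <= inter_loading <= intra_loading < 1")
        if self.intra_loading > 0 and self.inter_loading >= self.intra_loading:
            raise ValueError("inter_loading must be strictly below intra_loading")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if not 0 < self.patient_effect <= 1:
            raise ValueError("patient_effect must lie in (0, 1]")
        if not 0 <= self.affected_module < len(self.module_sizes):
            raise ValueError("affected_module out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def module_labels(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "patient" | "control"
    timeseries: np.ndarray  # n_volumes x n_rois
    motion: np.ndarray      # n_volumes x 6 (3 translations mm, 3 rotations deg)
    confounds: np.ndarray   # n_volumes x 2 simulated WM / CSF signals
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isnan(self.timeseries).any():
            raise ValueError("time series contain missing values")
        if self.motion.shape[0] != self.timeseries.shape[0]:
            raise ValueError("motion must have one row per volume")


@dataclass
class GroundTruth:
    planted_partition: np.ndarray
    affected_module: int
    planted_effect: float
    covariate_slope: float


def band_limited_series(
    n: int,
    tr: float,
    rng: np.random.Generator,
    low: float = 0.01,
    high: float = 0.1,
) -> np.ndarray:
    """Unit-variance series with spectral support confined to [low, high] Hz.

    White Gaussian noise is masked in the frequency domain (hard mask; no
    filter transients) and rescaled to unit sample variance.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("band contains no frequency bins at this length/TR")
    return x / sd


def _orthonormalize(factors: np.ndarray, global_factor: np.ndarray):
    """Remove chance sample correlations among the shared factors.

    QR-orthogonalizes [f_1 .. f_M, g] (each column stays band-limited, as a
    linear combination of band-limited series) and rescales every column to
    unit sample variance, so planted between-module correlations are exact
    rather than perturbed by finite-length factor covariances.
    """
    stacked = np.column_stack([factors, global_factor])
    q, _ = np.linalg.qr(stacked)
    q = q / q.std(axis=0)
    return q[:, :-1], q[:, -1]


def _draw_covariates(spec: CohortSpec, group: str, rng: np.random.Generator) -> dict[str, float]:
    patient = group == "patient"
    age_mu, age_sd = _PATIENT_AGE if patient else _CONTROL_AGE
    hb_mu, hb_sd = _PATIENT_HB if patient else _CONTROL_HB
    male_frac = _PATIENT_MALE_FRAC if patient else _CONTROL_MALE_FRAC
    cov = {
        "age": float(np.clip(rng.normal(age_mu, age_sd), 18, 61)),
        "sex": float(rng.random() < male_frac),  # 1 = male
        "hemoglobin": float(np.clip(rng.normal(hb_mu, hb_sd), 40, 180)),
        "serum_calcium": float(np.clip(rng.normal(*_CALCIUM_MMOL), 1.5, 3.2)),
        "serum_albumin": float(np.clip(rng.normal(*_ALBUMIN_GL), 25, 50)),
    }
    cov["dialysis_months"] = (
        float(np.clip(rng.normal(*_DIALYSIS_MONTHS), 1, 12)) if patient else np.nan
    )
    return cov


def _coherence_scale(spec: CohortSpec, group: str, hemoglobin: float) -> float:
    """Hemoglobin-coupled within-module coherence fraction in (0, 1].

    Low hemoglobin degrades within-module coherence linearly; full
    coherence is reached one standard deviation above the group mean, so
    the modulation is effective across most of the hemoglobin range rather
    than saturating for half the cohort.  With zero coupling, q = 1.
    """
    mu, sd = _PATIENT_HB if group == "patient" else _CONTROL_HB
    z = (hemoglobin - mu) / sd
    q = 1.0 + spec.covariate_coupling * (z - 1.0) * (spec.covariate_coupling > 0)
    return float(np.clip(q, 0.05, 1.0))


def generate_subject_timeseries(
    spec: CohortSpec,
    group: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> SubjectRecord:
    """Simulate one subject (time series + motion + confounds + covariates)."""
    spec.validate()
    if group not in ("patient", "control"):
        raise ValueError("group must be 'patient' or 'control'")
    low, high = spec.band
    n, tr = spec.n_volumes, spec.tr_seconds
    covariates = _draw_covariates(spec, group, rng)
    q_subject = _coherence_scale(spec, group, covariates["hemoglobin"])

    raw = np.column_stack([
        band_limited_series(n, tr, rng, low, high)
        for _ in range(len(spec.module_sizes) + 1)
    ])
    factors, global_factor = _orthonormalize(raw[:, :-1], raw[:, -1])

    coherence = np.full(len(spec.module_sizes), q_subject)
    if group == "patient":
        coherence[spec.affected_module] *= spec.patient_effect**2

    labels = spec.module_labels()
    a, b = spec.intra_loading, spec.inter_loading
    q = coherence[labels]
    module_part = factors[:, labels] * np.sqrt(q)
    if np.any(q < 1.0):
        private = np.column_stack([
            band_limited_series(n, tr, rng, low, high)
            for _ in range(spec.n_rois)
        ])
        module_part = module_part + private * np.sqrt(1.0 - q)
    ts = (
        a * module_part
        + b * global_factor[:, None]
        + spec.noise_sd * rng.standard_normal((n, spec.n_rois))
    )

    steps = np.column_stack([
        rng.normal(0.0, spec.motion_step_trans_mm, size=(n, 3)),
        rng.normal(0.0, spec.motion_step_rot_deg, size=(n, 3)),
    ])
    motion = np.cumsum(steps, axis=0)
    motion -= motion[0]

    confounds = np.column_stack([
        band_limited_series(n, tr, rng, low, high) for _ in range(2)
    ])
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        timeseries=ts,
        motion=motion,
        confounds=confounds,
        covariates=covariates,
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Deterministically generate the full two-group cohort from spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for k in range(spec.n_patients):
        subjects.append(
            generate_subject_timeseries(spec, "patient", rng, subject_id=f"pat-{k:03d}")
        )
    for k in range(spec.n_controls):
        subjects.append(
            generate_subject_timeseries(spec, "control", rng, subject_id=f"con-{k:03d}")
        )
    truth = GroundTruth(
        planted_partition=spec.module_labels(),
        affected_module=spec.affected_module,
        planted_effect=spec.patient_effect,
        covariate_slope=spec.covariate_coupling,
    )
    return subjects, truth


def generate_clinical_table(
    subjects: list[SubjectRecord],
    missing_hb_patients: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One covariate row per subject; optionally blank hemoglobin for some
    patients (emulating incomplete clinical records)."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id, "group": s.group, **s.covariates}
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    if missing_hb_patients:
        if rng is None:
            rng = np.random.default_rng(0)
        pat_idx = table.index[table["group"] == "patient"]
        drop = rng.choice(pat_idx, size=missing_hb_patients, replace=False)
        table.loc[drop, "hemoglobin"] = np.nan
    return table


def population_correlation(spec: CohortSpec, group: str = "control") -> np.ndarray:
    """Closed-form population correlation matrix of the factor model.

    Evaluated at the group-mean hemoglobin (coherence 1); for patients the
    affected module's coherence is multiplied by the squared planted effect.
    """
    spec.validate()
    labels = spec.module_labels()
    coherence = np.ones(len(spec.module_sizes))
    if group == "patient":
        coherence[spec.affected_module] *= spec.patient_effect**2
    a, b = spec.intra_loading, spec.inter_loading
    var = a**2 + b**2 + spec.noise_sd**2
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, coherence[labels][:, None] * a**2, 0.0) + b**2
    r = cov / var
    np.fill_diagonal(r, 1.0)
    return r


def full_scale_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The 1,024-ROI configuration with module sizes 317/250/289/168."""
    base = CohortSpec(
        n_rois=1024, module_sizes=(317, 250, 289, 168), seed=seed
    )
    return replace(base, **overrides)
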