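"""Synthetic data generators: prostatectomy cohorts, multi-study expression
matrices, and uniform-intensity DAB image patches.

The cohort generator emulates a single-institution radical-prostatectomy
series. Its default parameters are the study conditions the analyses
assume: the grade mix (13.8 / 76.5 / 9.7 % low / intermediate / high),
a 30.4% pT3 rate, EPE and SVI confined to pT3 disease at marginal rates of
29.4% and 6%, log-normal prostate and tumour volumes parameterised by their
medians and IQRs (32.2 cc [24.2-43.5] and 2.6 cc [1.3-4.8]), and a serum
PSA built generatively as

    serum PSA = benign PSA (default deconvolution constants)
              + secretion(grade, stage) * tumour_volume * lognormal noise,

where the per-cc secretion sits on a log-linear aggressiveness grid
anchored at 4.01 ng/ml per cc (low-grade, organ-confined) and 1.71
(high-grade, invasive); intermediate cells interpolate geometrically.
Biochemical recurrence follows an exponential proportional-hazards model
with planted log-hazard-ratios (EPE ln 1.68, SVI ln 1.90, positive margins
ln 2.12, intermediate grade ln 1.97, high grade ln 5.28) and administrative
censoring at a horizon solved numerically so the expected event fraction
equals 23.2%.

Log-normal medians/IQRs convert to (mu, sigma) via mu = ln(median) and
sigma = ln(Q3/Q1) / (2 * 0.674490) (0.6745 = standard normal upper
quartile). A single seed spawns independent child streams per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import TpsadConstants
from .errors import CalibrationError, ValidationError
from .expression import COMPARATOR, HIGH_GRADE, ExpressionStudy
from .ihc import StainVectors, synthesize_rgb

_NORMAL_Q3 = 0.6744897501960817  # Phi^-1(0.75)

GRADES = ("low", "intermediate", "high")


def lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    """Log-scale sigma of a log-normal given its quartiles."""
    if not 0 < q1 < q3:
        raise ValidationError("need 0 < Q1 < Q3")
    return math.log(q3 / q1) / (2.0 * _NORMAL_Q3)


@dataclass(frozen=True)
class CohortSimParams:
    """Generative parameters of the synthetic prostatectomy cohort.

    Probabilities that the data tables anchor (grade mix, overall pT3, EPE,
    SVI, recurrence fraction, volume medians/IQRs, secretion anchors) are
    defaults here; free parameters (stage gradient across grades, margin
    rates, noise sigmas, baseline hazard) are fixed realistic choices
    documented in the methods note.
    """

    n_patients: int = 1108
    # grade mix: low / intermediate / high
    grade_probs: tuple = (0.138, 0.765, 0.097)
    # pT3 probability for low and high grade; intermediate is solved so the
    # grade-weighted overall pT3 rate hits target_pt3.
    pt3_prob_low: float = 0.08
    pt3_prob_high: float = 0.70
    target_pt3: float = 0.304
    # adverse features (conditional on stage)
    epe_rate: float = 0.294  # marginal; confined to pT3
    svi_rate: float = 0.06  # marginal; confined to pT3
    margin_prob_pt2: float = 0.20
    margin_prob_pt3: float = 0.35
    # volumes (cc), log-normal by median + IQR
    prostate_vol_median: float = 32.2
    prostate_vol_iqr: tuple = (24.2, 43.5)
    tumour_vol_median: float = 2.6
    tumour_vol_iqr: tuple = (1.3, 4.8)
    # grade-dependent multiplicative shift of the tumour-volume median; the
    # intermediate shift is solved so the probability-weighted mean log
    # shift is zero (overall median preserved).
    tumour_vol_shift_low: float = 0.6
    tumour_vol_shift_high: float = 2.0
    # serum PSA secretion anchors (ng/ml per cc) and per-patient noise
    secretion_low_confined: float = 4.01
    secretion_high_invasive: float = 1.71
    psa_noise_sigma: float = 0.3
    missing_psa_rate: float = 9.0 / 1228.0
    # deconvolution constants used to build the benign PSA component
    constants: TpsadConstants = field(default_factory=TpsadConstants)
    # age (years)
    age_median: float = 61.5
    age_sd: float = 6.5
    age_range: tuple = (40.2, 79.0)
    # Gleason pattern splits within grade groups
    intermediate_34_prob: float = 0.688  # GS 3+4 vs 4+3
    high_pattern_probs: tuple = (0.5, 0.25, 0.15, 0.10)  # (4,4),(4,5),(5,4),(5,5)
    index_fraction_beta: tuple = (8.0, 2.0)  # index/total tumour volume
    # proportional-hazards outcome model
    log_hr_epe: float = math.log(1.68)
    log_hr_svi: float = math.log(1.90)
    log_hr_margins: float = math.log(2.12)
    log_hr_grade_intermediate: float = math.log(1.97)
    log_hr_grade_high: float = math.log(5.28)
    log_hr_ln_tpsad: float = 0.0  # optional sensitivity plant
    baseline_hazard: float = 8e-4  # events per month for the reference patient
    target_event_fraction: float = 0.232
    max_horizon_months: float = 3600.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValidationError("grade probabilities must sum to 1")
        for p in (*self.grade_probs, self.pt3_prob_low, self.pt3_prob_high,
                  self.target_pt3, self.epe_rate, self.svi_rate,
                  self.margin_prob_pt2, self.margin_prob_pt3,
                  self.missing_psa_rate, self.target_event_fraction):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.psa_noise_sigma < 0:
            raise ValidationError("psa_noise_sigma must be >= 0")
        # solvability of the intermediate pT3 probability
        self.pt3_prob_intermediate  # noqa: B018

    @property
    def pt3_prob_intermediate(self) -> float:
        p_low, p_int_w, p_high = self.grade_probs
        residual = self.target_pt3 - p_low * self.pt3_prob_low - p_high * self.pt3_prob_high
        p = residual / p_int_w
        if not 0 <= p <= 1:
            raise CalibrationError(
                f"intermediate pT3 probability {p:.3f} outside [0, 1]; "
                "adjust pt3_prob_low/high or target_pt3"
            )
        return p

    @property
    def tumour_vol_shift_intermediate(self) -> float:
        """Solves sum_g p_g * ln(shift_g) = 0 so the overall median stays put."""
        p_low, p_int, p_high = self.grade_probs
        log_shift = -(
            p_low * math.log(self.tumour_vol_shift_low)
            + p_high * math.log(self.tumour_vol_shift_high)
        ) / p_int
        return math.exp(log_shift)

    def secretion(self, grade: str, stage: str) -> float:
        """ng/ml serum per cc of tumour on the log-linear aggressiveness grid.

        z = (grade index + pT3 flag) / 3 runs from 0 (low grade, organ
        confined) to 1 (high grade, invasive); secretion interpolates
        geometrically between the two printed anchors.
        """
        g = GRADES.index(grade)
        z = (g + (1 if stage == "pT3" else 0)) / 3.0
        lo, hi = self.secretion_low_confined, self.secretion_high_invasive
        return lo * (hi / lo) ** z


def _grade_vol_shifts(params: CohortSimParams) -> dict[str, float]:
    return {
        "low": params.tumour_vol_shift_low,
        "intermediate": params.tumour_vol_shift_intermediate,
        "high": params.tumour_vol_shift_high,
    }


def _linear_predictor(params: CohortSimParams, frame: pd.DataFrame) -> np.ndarray:
    lp = (
        params.log_hr_epe * frame["epe"].to_numpy(float)
        + params.log_hr_svi * frame["svi"].to_numpy(float)
        + params.log_hr_margins * frame["positive_margins"].to_numpy(float)
        + params.log_hr_grade_intermediate * (frame["grade_group"] == "intermediate").to_numpy(float)
        + params.log_hr_grade_high * (frame["grade_group"] == "high").to_numpy(float)
    )
    if params.log_hr_ln_tpsad != 0.0:
        lp = lp + params.log_hr_ln_tpsad * frame["_ln_true_tpsad"].to_numpy(float)
    return lp


def solve_censoring_horizon(params: CohortSimParams, rates: np.ndarray) -> float:
    """Administrative horizon tau with E[fraction of events by tau] = target.

    Under exponential event times with per-patient rates, the expected event
    fraction at tau is mean(1 - exp(-rate * tau)); solved by bisection.
    """
    target = params.target_event_fraction

    def expected_events(tau: float) -> float:
        return float(np.mean(-np.expm1(-rates * tau))) - target

    hi = params.max_horizon_months
    if expected_events(hi) < 0:
        raise CalibrationError(
            f"event fraction {target:.1%} unreachable within "
            f"{hi:g} months at baseline hazard {params.baseline_hazard:g}"
        )
    return float(optimize.brentq(expected_events, 1e-6, hi, xtol=1e-6))


def simulate_cohort(
    params: CohortSimParams | None = None, seed: Optional[int] = None
) -> pd.DataFrame:
    """Draw a synthetic prostatectomy cohort as a patient table.

    Column layout matches :data:`tpsad.cohort.COHORT_COLUMNS`. Fully
    reproducible: the same (params, seed) pair yields an identical table.
    ``seed`` overrides ``params.seed`` when given.
    """
    params = params or CohortSimParams()
    seed = seed if seed is not None else params.seed
    ss = np.random.SeedSequence(seed)
    rngs = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("grade", "stage", "features", "volumes", "psa", "outcome", "misc"),
            ss.spawn(7),
        )
    }
    n = params.n_patients
    if n < 1:
        raise ValidationError("n_patients must be >= 1")

    grade_idx = rngs["grade"].choice(3, size=n, p=list(params.grade_probs))
    grade = np.array(GRADES)[grade_idx]

    pt3_probs = np.array(
        [params.pt3_prob_low, params.pt3_prob_intermediate, params.pt3_prob_high]
    )[grade_idx]
    is_pt3 = rngs["stage"].random(n) < pt3_probs
    stage = np.where(is_pt3, "pT3", "pT2")

    # EPE/SVI confined to pT3 disease at the anchored marginal rates
    epe = is_pt3 & (rngs["features"].random(n) < params.epe_rate / params.target_pt3)
    svi = is_pt3 & (rngs["features"].random(n) < params.svi_rate / params.target_pt3)
    margin_p = np.where(is_pt3, params.margin_prob_pt3, params.margin_prob_pt2)
    margins = rngs["features"].random(n) < margin_p

    pv_sigma = lognormal_sigma_from_iqr(*params.prostate_vol_iqr)
    prostate_vol = np.exp(
        math.log(params.prostate_vol_median) + pv_sigma * rngs["volumes"].standard_normal(n)
    )
    tv_sigma = lognormal_sigma_from_iqr(*params.tumour_vol_iqr)
    shifts = _grade_vol_shifts(params)
    shift = np.array([shifts[g] for g in grade])
    tumour_vol = np.exp(
        math.log(params.tumour_vol_median)
        + np.log(shift)
        + tv_sigma * rngs["volumes"].standard_normal(n)
    )
    index_frac = rngs["volumes"].beta(*params.index_fraction_beta, size=n)
    index_vol = tumour_vol * index_frac

    secretion = np.array(
        [params.secretion(g, s) for g, s in zip(grade, stage)]
    )
    noise = np.exp(params.psa_noise_sigma * rngs["psa"].standard_normal(n))
    c = params.constants
    benign_vol = np.maximum(prostate_vol - tumour_vol, 0.0)
    benign_component = c.epithelial_fraction * c.benign_secretion * benign_vol
    tumour_component = secretion * tumour_vol * noise
    serum_psa = benign_component + tumour_component
    missing = rngs["psa"].random(n) < params.missing_psa_rate
    serum_psa = np.where(missing, np.nan, serum_psa)

    age = params.age_median + params.age_sd * rngs["misc"].standard_normal(n)
    age = np.clip(age, *params.age_range)

    primary = np.empty(n, dtype=int)
    secondary = np.empty(n, dtype=int)
    low_mask = grade == "low"
    primary[low_mask], secondary[low_mask] = 3, 3
    int_mask = grade == "intermediate"
    is_34 = rngs["misc"].random(n) < params.intermediate_34_prob
    primary[int_mask] = np.where(is_34[int_mask], 3, 4)
    secondary[int_mask] = np.where(is_34[int_mask], 4, 3)
    high_mask = grade == "high"
    patterns = np.array([(4, 4), (4, 5), (5, 4), (5, 5)])
    hp = rngs["misc"].choice(4, size=n, p=list(params.high_pattern_probs))
    primary[high_mask] = patterns[hp[high_mask], 0]
    secondary[high_mask] = patterns[hp[high_mask], 1]

    frame = pd.DataFrame(
        {
            "case_id": [f"P{i:06d}" for i in range(n)],
            "age": age,
            "serum_psa": serum_psa,
            "prostate_volume": prostate_vol,
            "gland_weight": prostate_vol,  # 1 g ~ 1 cc
            "total_tumour_volume": tumour_vol,
            "index_tumour_volume": index_vol,
            "gleason_primary": primary,
            "gleason_secondary": secondary,
            "stage": stage,
            "epe": epe,
            "svi": svi,
            "positive_margins": margins,
            "grade_group": grade,
            "_ln_true_tpsad": np.log(secretion * noise),
        }
    )

    rates = params.baseline_hazard * np.exp(_linear_predictor(params, frame))
    horizon = solve_censoring_horizon(params, rates)
    event_time = rngs["outcome"].exponential(1.0 / rates)
    recurrence = event_time <= horizon
    followup = np.minimum(event_time, horizon)

    frame["recurrence"] = recurrence
    frame["followup_time"] = followup

    from .cohort import COHORT_COLUMNS

    out = frame[COHORT_COLUMNS + ["grade_group"]].copy()
    out.attrs["censoring_horizon_months"] = horizon
    out.attrs["true_secretion"] = secretion
    return out


# ---------------------------------------------------------------------------
# Expression studies


@dataclass(frozen=True)
class ExpressionSimParams:
    """Multi-study log-scale expression simulation with a planted cassette.

    Each study draws Gaussian log2 expression around gene-specific baseline
    means; genes of the androgen-regulated cassette get a negative mean
    shift in the high-grade class, AR a positive one, all other genes none.
    """

    n_studies: int = 5
    n_genes: int = 1000
    samples_per_class: int = 20
    cassette_size: int = 25
    cassette_lfc: float = -2.0
    ar_lfc: float = 1.0
    noise_sigma: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValidationError("n_studies must be >= 1")
        if self.cassette_size + 1 > self.n_genes:
            raise ValidationError("cassette (+AR) must fit inside the gene list")
        if self.noise_sigma <= 0:
            raise ValidationError("noise_sigma must be > 0")

    @property
    def cassette_genes(self) -> list[str]:
        return [f"ARG{i:02d}" for i in range(1, self.cassette_size + 1)]

    @property
    def gene_names(self) -> list[str]:
        background = [
            f"G{i:05d}" for i in range(self.n_genes - self.cassette_size - 1)
        ]
        return self.cassette_genes + ["AR"] + background


def simulate_expression_studies(
    params: ExpressionSimParams | None = None, seed: Optional[int] = None
) -> list[ExpressionStudy]:
    """Draw the configured number of independent studies."""
    params = params or ExpressionSimParams()
    seed = seed if seed is not None else params.seed
    ss = np.random.SeedSequence(seed)
    genes = params.gene_names
    lfc = np.zeros(len(genes))
    lfc[: params.cassette_size] = params.cassette_lfc
    lfc[genes.index("AR")] = params.ar_lfc

    studies = []
    for s, child in enumerate(ss.spawn(params.n_studies), start=1):
        rng = np.random.default_rng(child)
        baseline = params.baseline_mean + params.baseline_sd * rng.standard_normal(len(genes))
        m = params.samples_per_class
        high = (
            baseline[:, None]
            + lfc[:, None]
            + params.noise_sigma * rng.standard_normal((len(genes), m))
        )
        comp = baseline[:, None] + params.noise_sigma * rng.standard_normal((len(genes), m))
        samples = [f"S{s}_H{i}" for i in range(m)] + [f"S{s}_C{i}" for i in range(m)]
        matrix = pd.DataFrame(np.hstack([high, comp]), index=genes, columns=samples)
        labels = pd.Series(
            [HIGH_GRADE] * m + [COMPARATOR] * m, index=samples, name="class"
        )
        studies.append(
            ExpressionStudy(study_id=f"study{s}", matrix=matrix, labels=labels)
        )
    return studies


# ---------------------------------------------------------------------------
# IHC image patches


def simulate_ihc_image(
    target_od: float,
    noise_sd: float = 2.0,
    size: tuple[int, int] = (256, 256),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Uniform-intensity 8-bit patch whose mean intensity encodes a target OD.

    Base intensity is 255 * 10**(-target_od); clipped Gaussian pixel noise
    is added before rounding to uint8. ODs implying a base intensity below
    1 cannot be represented in 8 bits and raise an error.
    """
    if target_od < 0:
        raise ValidationError("target OD must be >= 0")
    base = 255.0 * 10.0 ** (-target_od)
    if base < 1.0:
        raise ValidationError(
            f"target OD {target_od} implies intensity {base:.3f} < 1 (8-bit floor)"
        )
    rng = np.random.default_rng(seed)
    img = base + noise_sd * rng.standard_normal(size)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def simulate_ihc_rgb(
    dab_od: float,
    hema_od: float = 0.3,
    noise_sd: float = 0.01,
    size: tuple[int, int] = (256, 256),
    seed: Optional[int] = None,
    vectors: StainVectors | None = None,
) -> np.ndarray:
    """RGB patch synthesized through the forward stain model.

    Per-pixel stain amounts are the target ODs plus clipped Gaussian noise
    (on the absorbance scale); the RGB image follows from the stain-vector
    forward model, so deconvolution recovers the planted amounts.
    """
    if dab_od < 0 or hema_od < 0:
        raise ValidationError("stain ODs must be >= 0")
    rng = np.random.default_rng(seed)
    amounts = np.zeros((*size, 3))
    amounts[..., 0] = np.maximum(hema_od + noise_sd * rng.standard_normal(size), 0)
    amounts[..., 1] = np.maximum(dab_od + noise_sd * rng.standard_normal(size), 0)
    return synthesize_rgb(amounts, vectors)
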