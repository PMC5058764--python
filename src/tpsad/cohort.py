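"""The tumour-PSA-density (tPSAD) statistic and cohort eligibility rules.

Serum PSA in a man with localised prostate cancer is modelled as the sum of
a benign component, secreted by the epithelial fraction of the non-cancerous
gland, and a tumour-attributable component. The benign component is
estimated as

    benign PSA = epithelial_fraction * benign_secretion * benign_volume

with benign_volume = max(prostate_volume - tumour_volume, 0). Subtracting it
from total serum PSA leaves "cancer PSA", and dividing by the pathologically
measured tumour volume gives tPSAD (ng/ml of serum per cc of tumour), the
per-unit-volume secretion statistic. tPSAD is analysed on the natural-log
scale; cases where the benign estimate exceeds serum PSA (non-positive
cancer PSA) are retained but flagged as not log-transformable.

Cohort eligibility mirrors a prostatectomy-series design: cases with missing
pre-operative PSA, PSA above an occult-metastasis cut-off (default 20
ng/ml), or gland size above the cohort's empirical 95th percentile are
excluded, in that order, with first-match-wins attribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError

GradeGroup = Literal["low", "intermediate", "high"]
VolumeField = Literal["total", "index"]


@dataclass(frozen=True)
class TpsadConstants:
    """Constants of the benign-PSA deconvolution and eligibility filters.

    epithelial_fraction
        Fraction of benign prostate volume that is PSA-secreting epithelium.
    benign_secretion
        Serum PSA (ng/ml) contributed per cc of benign *epithelial* tissue.
    psa_exclusion_max
        Pre-operative serum PSA cut-off (ng/ml) above which cases are
        excluded (occult metastatic disease).
    gland_percentile_cut
        Empirical percentile of gland size above which cases are excluded
        (very large glands distort the benign estimate).
    """

    epithelial_fraction: float = 0.1
    benign_secretion: float = 0.30
    psa_exclusion_max: float = 20.0
    gland_percentile_cut: float = 95.0

    def __post_init__(self) -> None:
        if not 0 < self.epithelial_fraction <= 1:
            raise ValidationError(
                f"epithelial_fraction must be in (0, 1], got {self.epithelial_fraction}"
            )
        if self.benign_secretion < 0:
            raise ValidationError("benign_secretion must be >= 0")
        if not 0 < self.gland_percentile_cut <= 100:
            raise ValidationError("gland_percentile_cut must be in (0, 100]")


#: Sentinel allowing epithelial_fraction=0 (degenerates tPSAD to plain
#: PSA density, serum PSA / tumour volume). Constructed via object.__new__
#: because the standard constructor requires a positive fraction.
def constants_with_zero_epithelium(base: TpsadConstants | None = None) -> TpsadConstants:
    base = base or TpsadConstants()
    obj = object.__new__(TpsadConstants)
    for f in ("benign_secretion", "psa_exclusion_max", "gland_percentile_cut"):
        object.__setattr__(obj, f, getattr(base, f))
    object.__setattr__(obj, "epithelial_fraction", 0.0)
    return obj


@dataclass
class PatientRecord:
    """One prostatectomy case: clinical, pathological and outcome fields."""

    case_id: str
    age: float
    serum_psa: Optional[float]  # ng/ml; None when missing
    prostate_volume: float  # cc
    total_tumour_volume: float  # cc
    gleason_primary: int
    gleason_secondary: int
    stage: Literal["pT2", "pT3"]
    epe: bool
    svi: bool
    positive_margins: bool
    recurrence: bool
    followup_time: float  # months
    gland_weight: Optional[float] = None  # g
    index_tumour_volume: Optional[float] = None  # cc

    def __post_init__(self) -> None:
        for name in ("prostate_volume", "total_tumour_volume"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("gleason_primary", "gleason_secondary"):
            if getattr(self, name) not in (3, 4, 5):
                raise ValidationError(f"{name} must be 3, 4 or 5")
        if self.followup_time < 0:
            raise ValidationError("followup_time must be >= 0")
        if self.stage not in ("pT2", "pT3"):
            raise ValidationError(f"stage must be pT2 or pT3, got {self.stage!r}")


@dataclass
class TpsadResult:
    """Derived per-case quantities of the PSA deconvolution."""

    case_id: str
    benign_volume: float  # cc
    benign_psa: float  # ng/ml
    cancer_psa: float  # ng/ml
    tpsad: Optional[float]  # ng/ml per cc; None when tumour volume is 0
    ln_tpsad: Optional[float]
    valid_for_log: bool
    flags: list = field(default_factory=list)


def grade_group(gleason_primary: int, gleason_secondary: int) -> GradeGroup:
    """Three-tier grade group by Gleason sum: <=6 low, 7 intermediate, >=8 high."""
    for v in (gleason_primary, gleason_secondary):
        if v not in (3, 4, 5):
            raise ValidationError(f"Gleason component must be 3, 4 or 5, got {v}")
    total = gleason_primary + gleason_secondary
    if total <= 6:
        return "low"
    if total == 7:
        return "intermediate"
    return "high"


def benign_volume(prostate_volume: float, tumour_volume: float) -> float:
    """Benign tissue volume (cc): prostate minus tumour, clamped at zero.

    When the tumour comprises the whole gland the benign volume is zero.
    """
    if prostate_volume < 0 or tumour_volume < 0:
        raise ValidationError("volumes must be >= 0")
    return max(prostate_volume - tumour_volume, 0.0)


def benign_psa(benign_vol: float, constants: TpsadConstants | None = None) -> float:
    """Serum PSA (ng/ml) attributed to benign tissue.

    epithelial_fraction * benign_secretion * benign_volume; linear in each
    factor.
    """
    constants = constants or TpsadConstants()
    if benign_vol < 0:
        raise ValidationError("benign volume must be >= 0")
    return constants.epithelial_fraction * constants.benign_secretion * benign_vol


def cancer_psa(serum_psa: Optional[float], benign: float) -> float:
    """Tumour-attributable serum PSA: total minus benign estimate.

    Non-positive residuals are returned unmodified; the caller flags them as
    not log-transformable (no flooring, which would bias group means).
    """
    if serum_psa is None or (isinstance(serum_psa, float) and math.isnan(serum_psa)):
        raise MissingDataError("serum PSA is missing")
    return serum_psa - benign


def compute_tpsad(
    record: PatientRecord,
    constants: TpsadConstants | None = None,
    volume_field: VolumeField = "total",
) -> TpsadResult:
    """Full per-case deconvolution: benign volume -> benign PSA -> cancer PSA
    -> tPSAD -> ln(tPSAD).

    A zero tumour volume leaves tPSAD undefined; the case is returned with a
    ``zero_tumour_volume`` flag rather than dropped. Non-positive cancer PSA
    propagates to ``valid_for_log=False`` with no ln value.
    """
    constants = constants or TpsadConstants()
    flags: list[str] = []

    if volume_field == "total":
        tumour_vol = record.total_tumour_volume
    elif volume_field == "index":
        if record.index_tumour_volume is None or (
            isinstance(record.index_tumour_volume, float)
            and math.isnan(record.index_tumour_volume)
        ):
            raise MissingDataError(
                f"case {record.case_id}: index tumour volume is missing"
            )
        tumour_vol = record.index_tumour_volume
    else:
        raise ValidationError(f"volume_field must be 'total' or 'index', got {volume_field!r}")

    if record.prostate_volume < record.total_tumour_volume:
        flags.append("benign_volume_clamped")
    bvol = benign_volume(record.prostate_volume, record.total_tumour_volume)
    bpsa = benign_psa(bvol, constants)
    cpsa = cancer_psa(record.serum_psa, bpsa)

    if tumour_vol <= 0:
        flags.append("zero_tumour_volume")
        return TpsadResult(record.case_id, bvol, bpsa, cpsa, None, None, False, flags)

    tpsad_value = cpsa / tumour_vol
    if tpsad_value > 0:
        return TpsadResult(
            record.case_id, bvol, bpsa, cpsa, tpsad_value,
            math.log(tpsad_value), True, flags,
        )
    flags.append("non_positive_cancer_psa")
    return TpsadResult(record.case_id, bvol, bpsa, cpsa, tpsad_value, None, False, flags)


# ---------------------------------------------------------------------------
# Cohort (DataFrame) interface

COHORT_COLUMNS = [
    "case_id", "age", "serum_psa", "prostate_volume", "gland_weight",
    "total_tumour_volume", "index_tumour_volume", "gleason_primary",
    "gleason_secondary", "stage", "epe", "svi", "positive_margins",
    "recurrence", "followup_time",
]


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({c: getattr(r, c) for c in COHORT_COLUMNS})
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for opt in ("serum_psa", "gland_weight", "index_tumour_volume"):
            v = d.get(opt)
            if v is not None and isinstance(v, float) and math.isnan(v):
                d[opt] = None
        records.append(
            PatientRecord(
                case_id=str(d["case_id"]),
                age=float(d["age"]),
                serum_psa=None if d["serum_psa"] is None else float(d["serum_psa"]),
                prostate_volume=float(d["prostate_volume"]),
                gland_weight=None if d["gland_weight"] is None else float(d["gland_weight"]),
                total_tumour_volume=float(d["total_tumour_volume"]),
                index_tumour_volume=(
                    None if d["index_tumour_volume"] is None else float(d["index_tumour_volume"])
                ),
                gleason_primary=int(d["gleason_primary"]),
                gleason_secondary=int(d["gleason_secondary"]),
                stage=str(d["stage"]),
                epe=bool(d["epe"]),
                svi=bool(d["svi"]),
                positive_margins=bool(d["positive_margins"]),
                recurrence=bool(d["recurrence"]),
                followup_time=float(d["followup_time"]),
            )
        )
    return records


def compute_tpsad_cohort(
    cohort: pd.DataFrame,
    constants: TpsadConstants | None = None,
    volume_field: VolumeField = "total",
) -> pd.DataFrame:
    """Vectorised deconvolution over a cohort table.

    Returns one row per input case with the TpsadResult fields plus the
    grade group and a semicolon-joined flag column. Cases whose statistic is
    undefined (zero or missing tumour volume, missing PSA) are retained with
    NaN values and an explanatory flag.
    """
    constants = constants or TpsadConstants()
    pv = cohort["prostate_volume"].to_numpy(float)
    ttv = cohort["total_tumour_volume"].to_numpy(float)
    if np.any(pv < 0) or np.any(ttv[np.isfinite(ttv)] < 0):
        raise ValidationError("volumes must be >= 0")

    if volume_field == "total":
        tumour_vol = ttv
    else:
        tumour_vol = cohort["index_tumour_volume"].to_numpy(float)

    bvol = np.maximum(pv - ttv, 0.0)
    bpsa = constants.epithelial_fraction * constants.benign_secretion * bvol
    serum = cohort["serum_psa"].to_numpy(float)
    cpsa = serum - bpsa

    with np.errstate(divide="ignore", invalid="ignore"):
        tpsad_values = np.where(tumour_vol > 0, cpsa / tumour_vol, np.nan)
        ln_vals = np.where(tpsad_values > 0, np.log(tpsad_values), np.nan)

    valid_for_log = np.isfinite(ln_vals)
    flags = []
    missing_vol = ~np.isfinite(tumour_vol)
    for i in range(len(cohort)):
        f = []
        if pv[i] < ttv[i]:
            f.append("benign_volume_clamped")
        if not np.isfinite(serum[i]):
            f.append("missing_serum_psa")
        if missing_vol[i]:
            f.append("missing_tumour_volume")
        elif tumour_vol[i] <= 0:
            f.append("zero_tumour_volume")
        elif np.isfinite(cpsa[i]) and cpsa[i] <= 0:
            f.append("non_positive_cancer_psa")
        flags.append(";".join(f))

    grades = [
        grade_group(int(p), int(s))
        for p, s in zip(cohort["gleason_primary"], cohort["gleason_secondary"])
    ]
    return pd.DataFrame(
        {
            "case_id": cohort["case_id"].to_numpy(),
            "grade_group": grades,
            "benign_volume": bvol,
            "benign_psa": bpsa,
            "cancer_psa": cpsa,
            "tpsad": tpsad_values,
            "ln_tpsad": ln_vals,
            "valid_for_log": valid_for_log,
            "flags": flags,
        }
    )


# ---------------------------------------------------------------------------
# Eligibility filters

@dataclass
class ExclusionLog:
    """Per-rule exclusion accounting, in application order."""

    rules: list  # (rule name, n excluded, excluded case ids)
    n_input: int
    n_kept: int
    gland_size_cutoff: Optional[float] = None  # empirical percentile value

    @property
    def n_excluded(self) -> int:
        return sum(n for _, n, _ in self.rules)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(name, n) for name, n, _ in self.rules], columns=["rule", "n_excluded"]
        )


def apply_cohort_filters(
    cohort: pd.DataFrame,
    constants: TpsadConstants | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Sequential eligibility filtering with first-match-wins attribution.

    Rules, in order: (1) missing pre-operative serum PSA; (2) serum PSA
    above ``psa_exclusion_max``; (3) gland size above the remaining cohort's
    empirical ``gland_percentile_cut`` percentile (gland weight when
    available, else prostate volume at 1 g ~ 1 cc; percentile by linear
    interpolation between order statistics).
    """
    constants = constants or TpsadConstants()
    if len(cohort) == 0:
        raise ValidationError("cohort is empty")

    remaining = cohort.copy()
    rules = []

    missing = ~np.isfinite(remaining["serum_psa"].to_numpy(float))
    rules.append(("missing PSA", int(missing.sum()), list(remaining.loc[missing, "case_id"])))
    remaining = remaining.loc[~missing]

    high = remaining["serum_psa"].to_numpy(float) > constants.psa_exclusion_max
    rules.append(
        (
            f"PSA > {constants.psa_exclusion_max:g}",
            int(high.sum()),
            list(remaining.loc[high, "case_id"]),
        )
    )
    remaining = remaining.loc[~high]

    cutoff = None
    if len(remaining):
        gland = remaining.get("gland_weight")
        size = (
            gland.to_numpy(float)
            if gland is not None and np.isfinite(gland.to_numpy(float)).all()
            else remaining["prostate_volume"].to_numpy(float)
        )
        cutoff = float(np.percentile(size, constants.gland_percentile_cut))
        big = size > cutoff
        rules.append(
            (
                f"gland size > p{constants.gland_percentile_cut:g} ({cutoff:.1f})",
                int(big.sum()),
                list(remaining.loc[big, "case_id"]),
            )
        )
        remaining = remaining.loc[~big]

    if len(remaining) == 0:
        raise ValidationError("no cases remain after eligibility filtering")

    log = ExclusionLog(
        rules=rules, n_input=len(cohort), n_kept=len(remaining), gland_size_cutoff=cutoff
    )
    return remaining.reset_index(drop=True), log
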