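"""Cross-study rank meta-analysis of differential expression, plus count
preprocessing (CPM, expression filtering, TMM normalization factors).

The meta-analysis asks whether a gene is consistently up- or down-regulated
in high-grade tumours across several independent expression studies whose
platforms (and hence gene universes) differ. Within each study a two-sample
Student t-test compares high-grade samples against the comparator class and
yields one-sided p-values for each direction. Genes are ranked by p-value
within each study (rank 1 = most significant; ties get average ranks) and
ranks are rescaled to percentiles in (0, 1] so studies with different gene
counts are comparable. The cross-study summary is the median percentile,
and its significance is assessed against a permutation null in which each
study contributes an independent Uniform(0, 1] percentile: the permutation
p-value is the smoothed fraction of null medians at or below the observed
one, p = (1 + #{null <= obs}) / (n_perm + 1).

Count preprocessing follows the standard RNA-seq conventions: CPM
(counts-per-million of the library), a low-expression filter removing genes
with CPM below a threshold in more than a third of samples, and TMM
(trimmed mean of M-values) normalization factors computed against a
reference sample with double trimming and precision weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

Direction = Literal["up", "down"]

HIGH_GRADE = "high_grade"
COMPARATOR = "comparator"


@dataclass
class ExpressionStudy:
    """One study: genes x samples matrix with binary grade labels.

    ``matrix`` rows are genes (unique ids in the index), columns are sample
    ids; ``labels`` maps each sample to ``high_grade`` or ``comparator``.
    ``values_are_log`` declares whether the matrix is already on a log scale
    (the t-test requires log-scale values).
    """

    study_id: str
    matrix: pd.DataFrame
    labels: pd.Series
    values_are_log: bool = True

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValidationError(f"{self.study_id}: duplicate gene ids")
        self.labels = self.labels.reindex(self.matrix.columns)
        if self.labels.isna().any():
            raise ValidationError(f"{self.study_id}: samples without labels")
        bad = set(self.labels.unique()) - {HIGH_GRADE, COMPARATOR}
        if bad:
            raise ValidationError(f"{self.study_id}: unknown labels {sorted(bad)}")
        counts = self.labels.value_counts()
        if counts.get(HIGH_GRADE, 0) < 2 or counts.get(COMPARATOR, 0) < 2:
            raise ValidationError(f"{self.study_id}: need >= 2 samples per class")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# Count preprocessing


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size * 1e6, per sample (column)."""
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValidationError("every library size must be > 0")
    return counts / lib * 1e6


def cpm_filter(
    counts: pd.DataFrame,
    cpm_threshold: float = 1.0,
    max_low_fraction: float = 1.0 / 3.0,
) -> list:
    """Genes kept by the low-expression rule.

    A gene is removed when CPM < ``cpm_threshold`` in strictly more than
    ``max_low_fraction`` of samples; equality keeps the gene.
    """
    if counts.shape[1] < 1:
        raise ValidationError("need at least one sample")
    cpm_vals = cpm(counts)
    low_frac = (cpm_vals < cpm_threshold).sum(axis=1) / counts.shape[1]
    return list(counts.index[low_frac <= max_low_fraction])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
    weighted: bool = True,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M, binomial sampling
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 0.0

    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    if not weighted:
        return float(np.mean(m[keep]))
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: Optional[str] = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    Each sample's factor is 2**(doubly trimmed, precision-weighted mean of
    the M-values against the reference sample); genes with a zero count in
    either compared sample are excluded pairwise. The reference defaults to
    the sample whose 75th CPM percentile is closest to the mean across
    samples. With ``weighted=False`` the trimmed mean is unweighted, which
    makes the factors exactly invariant to rescaling any single library
    (the precision weights depend weakly on sequencing depth).
    """
    if counts.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValidationError("every library size must be > 0")

    if ref_sample is None:
        f75 = (counts / lib).quantile(0.75, axis=0)
        ref_sample = (f75 - f75.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    lib_ref = float(lib[ref_sample])

    log_factors = {}
    for sample in counts.columns:
        if sample == ref_sample:
            log_factors[sample] = 0.0
        else:
            log_factors[sample] = _tmm_pair(
                counts[sample].to_numpy(), ref, float(lib[sample]), lib_ref,
                logratio_trim, abs_trim, weighted,
            )
    factors = pd.Series({s: 2.0 ** f for s, f in log_factors.items()})[counts.columns]
    # rescale so factors multiply to 1 (comparability across runs)
    factors /= np.exp(np.mean(np.log(factors)))
    factors.name = "tmm_factor"
    return factors


# ---------------------------------------------------------------------------
# Per-study differential expression


def study_de_pvalues(study: ExpressionStudy, equal_var: bool = True) -> pd.DataFrame:
    """Per-gene one-sided t-test p-values, one per direction.

    Classical pooled-variance Student t by default (``equal_var=False``
    switches to Welch). ``p_up`` tests for higher expression in the
    high-grade class, ``p_down`` for lower; for a continuous t statistic
    p_up + p_down = 1. Genes with zero variance in both classes are
    unscorable: both p-values are set to 1 and the gene is flagged.
    """
    if not study.values_are_log:
        raise ValidationError(
            f"{study.study_id}: t-test requires log-scale values "
            "(use log_cpm for count matrices)"
        )
    high = study.matrix.loc[:, study.labels == HIGH_GRADE].to_numpy(float)
    comp = study.matrix.loc[:, study.labels == COMPARATOR].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        res_up = stats.ttest_ind(high, comp, axis=1, equal_var=equal_var, alternative="greater")
        res_down = stats.ttest_ind(high, comp, axis=1, equal_var=equal_var, alternative="less")

    p_up = np.asarray(res_up.pvalue, float)
    p_down = np.asarray(res_down.pvalue, float)
    t_stat = np.asarray(res_up.statistic, float)

    degenerate = ~np.isfinite(t_stat)
    p_up[degenerate] = 1.0
    p_down[degenerate] = 1.0
    return pd.DataFrame(
        {"t": t_stat, "p_up": p_up, "p_down": p_down, "degenerate": degenerate},
        index=study.matrix.index,
    )


def log_cpm(counts: pd.DataFrame, prior_count: float = 0.5) -> pd.DataFrame:
    """log2(CPM + prior) — the in-repo log-scale transform for count data."""
    return np.log2(cpm(counts) + prior_count)


# ---------------------------------------------------------------------------
# Cross-study rank meta-analysis


@dataclass
class MetaGeneResult:
    """Cross-study rank summary for one gene."""

    gene: str
    per_study_rank_up: dict  # study_id -> rank (1 = most significant)
    per_study_rank_down: dict
    n_genes_per_study: dict
    summary_rank_up: float  # median percentile rank, (0, 1]
    summary_rank_down: float
    perm_p_up: float
    perm_p_down: float

    @property
    def n_studies(self) -> int:
        return len(self.per_study_rank_up)


def _rank_percentiles(pvalues: pd.Series) -> pd.Series:
    ranks = stats.rankdata(pvalues.to_numpy())  # average ranks on ties
    return pd.Series(ranks / len(pvalues), index=pvalues.index)


def _null_medians(k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return np.median(rng.random((n_perm, k)), axis=1)


def _perm_p(observed: float, null: np.ndarray) -> float:
    return (1.0 + float(np.sum(null <= observed))) / (null.size + 1.0)


def meta_rank_enrichment(
    studies: Sequence[ExpressionStudy],
    gene: str,
    direction: Direction,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    equal_var: bool = True,
) -> MetaGeneResult:
    """Rank-enrichment test of one gene in one direction across studies.

    Convenience wrapper over :func:`meta_analysis`; see module docstring for
    the null model. Both directions are always computed (the other one comes
    for free).
    """
    if direction not in ("up", "down"):
        raise ValidationError(f"direction must be 'up' or 'down', got {direction!r}")
    results = meta_analysis(studies, [gene], n_perm=n_perm, seed=seed, equal_var=equal_var)
    return results[0]


def meta_analysis(
    studies: Sequence[ExpressionStudy],
    genes: Iterable[str],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    equal_var: bool = True,
) -> list[MetaGeneResult]:
    """Cross-study rank meta-analysis of a gene set, both directions.

    Per-study t-tests and rankings are computed once; each gene then gets
    its own independently seeded permutation null (independent uniforms per
    contributing study, median summary, +1 smoothing).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 (unstable null below that)")
    genes = list(genes)
    if not genes:
        raise ValidationError("empty gene list")

    per_study = {}
    for study in studies:
        de = study_de_pvalues(study, equal_var=equal_var)
        per_study[study.study_id] = {
            "rank_up": stats.rankdata(de["p_up"].to_numpy()),
            "rank_down": stats.rankdata(de["p_down"].to_numpy()),
            "index": de.index,
            "n_genes": len(de),
        }
        per_study[study.study_id]["pos"] = {g: i for i, g in enumerate(de.index)}

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(genes))

    results = []
    for gene, child in zip(genes, child_seeds):
        rank_up, rank_down, n_per_study = {}, {}, {}
        pct_up, pct_down = [], []
        for sid, data in per_study.items():
            pos = data["pos"].get(gene)
            if pos is None:
                continue
            n = data["n_genes"]
            rank_up[sid] = float(data["rank_up"][pos])
            rank_down[sid] = float(data["rank_down"][pos])
            n_per_study[sid] = n
            pct_up.append(rank_up[sid] / n)
            pct_down.append(rank_down[sid] / n)
        if not rank_up:
            raise ValidationError(f"gene {gene!r} absent from every study")

        k = len(pct_up)
        rng = np.random.default_rng(child)
        null = _null_medians(k, n_perm, rng)
        obs_up = float(np.median(pct_up))
        obs_down = float(np.median(pct_down))
        results.append(
            MetaGeneResult(
                gene=gene,
                per_study_rank_up=rank_up,
                per_study_rank_down=rank_down,
                n_genes_per_study=n_per_study,
                summary_rank_up=obs_up,
                summary_rank_down=obs_down,
                perm_p_up=_perm_p(obs_up, null),
                perm_p_down=_perm_p(obs_down, null),
            )
        )
    return results


def meta_results_frame(results: Sequence[MetaGeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_studies": [r.n_studies for r in results],
            "summary_rank_up": [r.summary_rank_up for r in results],
            "summary_rank_down": [r.summary_rank_down for r in results],
            "perm_p_up": [r.perm_p_up for r in results],
            "perm_p_down": [r.perm_p_down for r in results],
        }
    )


def geneset_direction_summary(
    results: Sequence[MetaGeneResult], alpha: float = 0.05
) -> tuple[int, int, int]:
    """(n_down_significant, n_up_significant, n_total) at level alpha."""
    if not results:
        raise ValidationError("empty result list")
    n_down = sum(1 for r in results if r.perm_p_down < alpha)
    n_up = sum(1 for r in results if r.perm_p_up < alpha)
    return n_down, n_up, len(results)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
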