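"""Clinical-validation design and inference statistics.

The screening arms are compared through a stratified validation design:
patients shortlisted by AI and/or EHR fall into three disjoint strata —
A1 (AI-shortlisted with an affirmative EHR result), A2 (AI-shortlisted,
negative EHR), B1 (affirmative EHR but not AI-shortlisted).  A random sample
from each stratum is expert-graded, giving a per-stratum positive predictive
value (PPV).  The expected eligible yield of a whole shortlist is then the
population-weighted sum of stratum PPVs:

    yield(target) = sum over covered strata s of  N_s * (x_s / n_s)

where the AI shortlist covers {A1, A2}, the EHR shortlist {A1, B1} and the
combined AI-EHR approach {A1}.  All confidence intervals are seeded
percentile bootstraps (default 10 000 resamples).  Method agreement between
graded FAF areas and OCT-derived areas is summarized by Bland-Altman limits
of agreement and the single-measurement, absolute-agreement, two-way
mixed-effects intraclass correlation coefficient (ICC(A,1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoverageError,
    InsufficientDataError,
    InvalidConfigError,
    SampleShortfallError,
    UndefinedStatisticError,
)
from .util import percent

STRATA = ("A1", "A2", "B1")

#: Strata contributing to each inference target.
TARGET_COVERAGE = {
    "ai": ("A1", "A2"),
    "ehr": ("A1", "B1"),
    "combined": ("A1",),
}

DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class StratumSample:
    """Graded validation sample from one stratum: x eligible of n sampled."""

    stratum: str
    n_sampled: int
    n_eligible: int

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise InvalidConfigError(f"unknown stratum {self.stratum!r}")
        if not 0 <= self.n_eligible <= self.n_sampled:
            raise InvalidConfigError(
                f"need 0 <= n_eligible <= n_sampled, got "
                f"{self.n_eligible}/{self.n_sampled}"
            )


@dataclass
class ValidationTable:
    """Per-stratum validation samples plus full-cohort stratum sizes."""

    samples: dict = field(default_factory=dict)  # stratum -> StratumSample
    populations: dict = field(default_factory=dict)  # stratum -> int

    def __post_init__(self) -> None:
        for s, sample in self.samples.items():
            pop = self.populations.get(s)
            if pop is not None and pop < sample.n_sampled:
                raise InvalidConfigError(
                    f"stratum {s}: population {pop} < sampled {sample.n_sampled}"
                )


@dataclass(frozen=True)
class AgreementPair:
    """Two area measurements of the same eye (mm^2), e.g. FAF vs OCT-AI."""

    measurement_a: float
    measurement_b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.measurement_a) and np.isfinite(self.measurement_b)):
            raise InvalidConfigError("measurements must be finite")
        if self.measurement_a < 0 or self.measurement_b < 0:
            raise InvalidConfigError("areas must be non-negative")


# ---------------------------------------------------------------------------
# Stratification and sampling
# ---------------------------------------------------------------------------


def assign_strata(ai_ids, ehr_ids) -> dict[str, str]:
    """Label every patient in (AI union EHR) with its validation stratum."""
    ai, ehr = set(ai_ids), set(ehr_ids)
    labels: dict[str, str] = {}
    for pid in ai | ehr:
        if pid in ai and pid in ehr:
            labels[pid] = "A1"
        elif pid in ai:
            labels[pid] = "A2"
        else:
            labels[pid] = "B1"
    return labels


def faf_available(patient, faf_window_days: int = 90) -> bool:
    """True when both eyes have a FAF acquired within the window of the OCT.

    The window is inclusive at exactly ``faf_window_days`` days on either
    side.
    """
    if len(patient.eyes) < 2:
        return False
    for eye in patient.eyes.values():
        if eye.faf_date is None:
            return False
        if abs((eye.faf_date - eye.oct_date).days) > faf_window_days:
            return False
    return True


def sample_for_validation(
    members: list,
    n: int,
    rng: np.random.Generator,
    faf_window_days: int = 90,
) -> list[str]:
    """Draw n patients uniformly without replacement from a stratum's pool.

    The pool is first restricted to patients with FAF imaging of both eyes
    within ``faf_window_days`` days of the OCT (inclusive).  Raises
    :class:`SampleShortfallError` when the filtered pool is smaller than n.
    """
    pool = sorted(
        p.patient_id for p in members if faf_available(p, faf_window_days)
    )
    if n > len(pool):
        raise SampleShortfallError(
            f"requested {n} but only {len(pool)} patients have in-window FAF"
        )
    picked = rng.choice(len(pool), size=n, replace=False)
    return sorted(pool[i] for i in picked)


# ---------------------------------------------------------------------------
# PPV and yield inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPVEstimate:
    point: float
    ci_low: float
    ci_high: float

    @property
    def point_pct(self) -> int:
        return percent(self.point)

    @property
    def ci_pct(self) -> tuple[int, int]:
        return (percent(self.ci_low), percent(self.ci_high))


def ppv(
    sample: StratumSample,
    n_boot: int = DEFAULT_N_BOOT,
    rng: np.random.Generator | None = None,
) -> PPVEstimate:
    """Positive predictive value of one stratum with a percentile-bootstrap CI.

    Resampling the n graded outcomes with replacement is equivalent to
    drawing the resampled eligible count from Binomial(n, x/n), which is how
    the bootstrap is vectorized here.
    """
    if sample.n_sampled == 0:
        raise UndefinedStatisticError("PPV undefined for an empty sample")
    p = sample.n_eligible / sample.n_sampled
    rng = rng if rng is not None else np.random.default_rng(0)
    boot = rng.binomial(sample.n_sampled, p, size=n_boot) / sample.n_sampled
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return PPVEstimate(point=p, ci_low=float(lo), ci_high=float(hi))


@dataclass(frozen=True)
class YieldEstimate:
    """Inferred eligible yield of a shortlist."""

    target: str
    count: float  # expected number of truly eligible patients
    rate: float  # count / shortlist size
    shortlist_size: int
    count_ci: tuple[float, float]
    rate_ci: tuple[float, float]

    @property
    def rate_pct(self) -> int:
        return percent(self.rate)


def estimate_cohort_yield(
    table: ValidationTable,
    target: str,
    n_boot: int = DEFAULT_N_BOOT,
    rng: np.random.Generator | None = None,
) -> YieldEstimate:
    """Infer a shortlist's eligible count and rate from stratified validation.

    The estimate is the weighted sum of stratum population sizes and sampled
    PPVs over the strata the target covers (ai: A1+A2; ehr: A1+B1;
    combined: A1).  The CI propagates independent binomial bootstrap
    resamples of each stratum's validation outcomes through the weighted
    sum.
    """
    if target not in TARGET_COVERAGE:
        raise InvalidConfigError(f"unknown target {target!r}")
    covered = TARGET_COVERAGE[target]
    for s in covered:
        if s not in table.samples or s not in table.populations:
            raise CoverageError(f"target {target!r} needs stratum {s}")

    rng = rng if rng is not None else np.random.default_rng(0)
    count = 0.0
    size = 0
    boot_counts = np.zeros(n_boot)
    for s in covered:
        sample = table.samples[s]
        pop = int(table.populations[s])
        if sample.n_sampled == 0:
            raise UndefinedStatisticError(f"stratum {s} has an empty sample")
        p = sample.n_eligible / sample.n_sampled
        count += pop * p
        size += pop
        boot_p = rng.binomial(sample.n_sampled, p, size=n_boot) / sample.n_sampled
        boot_counts += pop * boot_p
    rate = count / size
    c_lo, c_hi = np.percentile(boot_counts, [2.5, 97.5])
    return YieldEstimate(
        target=target,
        count=count,
        rate=rate,
        shortlist_size=size,
        count_ci=(float(c_lo), float(c_hi)),
        rate_ci=(float(c_lo) / size, float(c_hi) / size),
    )


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference (a - b) and 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int


def bland_altman(pairs: list[AgreementPair]) -> BlandAltmanResult:
    """Bland-Altman agreement between two measurement methods.

    Limits of agreement are mean +- 1.96 x sd of the pairwise differences
    (sample sd, n-1 denominator).
    """
    if len(pairs) < 2:
        raise InsufficientDataError("Bland-Altman needs at least 2 pairs")
    d = np.array([p.measurement_a - p.measurement_b for p in pairs])
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n=len(pairs),
    )


def _icc_a1(x: np.ndarray) -> np.ndarray:
    """ICC(A,1) from the two-way ANOVA decomposition.

    ``x`` has shape (..., n, k): n subjects rated by k raters.  Returns the
    single-measurement absolute-agreement two-way mixed-effects ICC
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)) broadcast over
    leading axes.  Degenerate denominators yield 0.
    """
    n, k = x.shape[-2], x.shape[-1]
    grand = x.mean(axis=(-2, -1), keepdims=True)
    row_mean = x.mean(axis=-1, keepdims=True)
    col_mean = x.mean(axis=-2, keepdims=True)
    msr = k * ((row_mean - grand) ** 2).sum(axis=(-2, -1)) / (n - 1)
    msc = n * ((col_mean - grand) ** 2).sum(axis=(-2, -1)) / (k - 1)
    resid = x - row_mean - col_mean + grand
    mse = (resid**2).sum(axis=(-2, -1)) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (msr - mse) / np.where(denom > 0, denom, 1.0), 0.0)
    return icc


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int


def icc_agreement(
    ratings: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    rng: np.random.Generator | None = None,
) -> ICCResult:
    """Single-measurement absolute-agreement two-way mixed-effects ICC.

    Parameters
    ----------
    ratings : array of shape (n_subjects, n_raters)
        Complete rating matrix (no missing cells).
    n_boot : int
        Subject-level bootstrap resamples for the percentile CI.
    rng : numpy.random.Generator, optional

    Notes
    -----
    A matrix with zero between-subject variance makes the ANOVA denominator
    degenerate; the ICC is then reported as 0 with a warning.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError("need >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("rating matrix has missing/non-finite cells")
    n, k = x.shape
    if np.ptp(x) == 0:
        warnings.warn(
            "constant ratings: ICC degenerate, reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return ICCResult(icc=0.0, ci_low=0.0, ci_high=0.0, n_subjects=n, n_raters=k)

    point = float(_icc_a1(x))
    rng = rng if rng is not None else np.random.default_rng(0)
    boot = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e7 / (n * k))))
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        idx = rng.integers(0, n, size=(m, n))
        boot[start : start + m] = _icc_a1(x[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ICCResult(
        icc=point, ci_low=float(lo), ci_high=float(hi), n_subjects=n, n_raters=k
    )


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def bootstrap_group_compare(
    group_a,
    group_b,
    statistic: str = "mean",
    n_boot: int = DEFAULT_N_BOOT,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided bootstrap p-value for a difference in means or proportions.

    Both groups are recentered to the pooled mean (the null of zero
    difference), resampled independently with replacement, and the p-value
    is the fraction of resampled |differences| at least as large as the
    observed one, with a +1/(n_boot+1) continuity correction so p is never
    exactly 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if statistic not in ("mean", "proportion"):
        raise InvalidConfigError(f"unknown statistic {statistic!r}")
    if statistic == "proportion" and not (
        np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()
    ):
        raise InvalidConfigError("proportion statistic requires 0/1 values")

    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + pooled
    b0 = b - b.mean() + pooled
    rng = rng if rng is not None else np.random.default_rng(0)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = a0[idx_a].mean(axis=1) - b0[idx_b].mean(axis=1)
    extreme = int((np.abs(diffs) >= abs(observed)).sum())
    return (extreme + 1) / (n_boot + 1)
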