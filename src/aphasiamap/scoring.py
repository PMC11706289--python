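"""Dimension scoring and psychometric validation of connected-speech ratings.

A trained rater scores 23 salient features of a naturalistic speech sample
on an ordinal 0-4 scale (higher = more impaired). Each feature belongs to
one or more of four explanatory dimensions — Paraphasia, Logopenia,
Agrammatism and Motor speech. A dimension score is the mean of its
features' ratings after rescaling to 0-100 (0->0, 1->25, 2->50, 3->75,
4->100); reverse-scored features are mirrored (rating r -> 100 - 25 r).

The module also implements the study-style eligibility/scorability filter
and the psychometrics used to validate the scores: interrater ICC(A,1)
with BCa bootstrap CIs, polyserial feature-dimension correlations, and
McDonald's omega-total internal-consistency coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DIMENSIONS",
    "FeatureDimensionMap",
    "RatingProfile",
    "EligibilityRecord",
    "ICCResult",
    "PolyserialEstimate",
    "OmegaResult",
    "default_feature_map",
    "rescale_rating",
    "dimension_scores",
    "eligibility_filter",
    "roster_from_exclusion_counts",
    "EXCLUSION_REASONS",
    "UNSCORABLE_REASONS",
    "icc_agreement",
    "bca_ci",
    "polyserial_corr",
    "omega_total",
    "agreement_label",
]

DIMENSIONS = ("Paraphasia", "Logopenia", "Agrammatism", "Motor speech")


def agreement_label(r: float) -> str:
    """Qualitative agreement bins: poor < .40 <= fair < .60 <= good < .75 <= excellent."""
    if r < 0.40:
        return "poor"
    if r < 0.60:
        return "fair"
    if r < 0.75:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Feature-dimension map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDimensionMap:
    """Assignment of rating features to dimensions with scoring signs.

    ``entries`` is a sequence of (feature, dimension, sign) triples; a
    feature may appear under several dimensions and contributes to each.
    sign -1 marks a reverse-scored feature.
    """

    entries: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        ent = tuple((str(f), str(d), int(s)) for f, d, s in self.entries)
        for f, d, s in ent:
            if d not in DIMENSIONS:
                raise ValueError(f"unknown dimension {d!r} for feature {f!r}")
            if s not in (-1, 1):
                raise ValueError(f"sign must be +1 or -1, got {s} for {f!r}")
        if len({(f, d) for f, d, _ in ent}) != len(ent):
            raise ValueError("duplicate (feature, dimension) pair in map")
        object.__setattr__(self, "entries", ent)

    @property
    def features(self) -> list[str]:
        """Unique feature names, in first-appearance order."""
        seen: dict[str, None] = {}
        for f, _, _ in self.entries:
            seen.setdefault(f)
        return list(seen)

    def by_dimension(self, dimension: str) -> list[tuple[str, int]]:
        return [(f, s) for f, d, s in self.entries if d == dimension]

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureDimensionMap":
        payload = json.loads(Path(path).read_text())
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "FeatureDimensionMap":
        return cls(tuple(
            (e["feature"], e["dimension"], e.get("sign", 1))
            for e in payload["entries"]
        ))


def default_feature_map() -> FeatureDimensionMap:
    """The packaged 29-entry map over 23 unique features (9/8/7/5 per dimension)."""
    payload = json.loads(
        resources.files("aphasiamap.data")
        .joinpath("feature_dimension_map.json")
        .read_text()
    )
    return FeatureDimensionMap._from_payload(payload)


# ---------------------------------------------------------------------------
# Ratings and dimension scores
# ---------------------------------------------------------------------------

@dataclass
class RatingProfile:
    """One rater's 0-4 ordinal ratings of one participant's speech sample."""

    participant_id: str
    rater_id: str
    ratings: dict[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for feat, r in self.ratings.items():
            clean[str(feat)] = _check_rating(r)
        self.ratings = clean


def _check_rating(rating) -> int:
    r = float(rating)
    if not r.is_integer() or not 0 <= r <= 4:
        raise ValueError(f"rating must be an integer in 0..4, got {rating!r}")
    return int(r)


def rescale_rating(rating: int, sign: int = 1) -> float:
    """Map an ordinal 0-4 rating to the 0-100 score scale.

    Positively signed features: 0->0, 1->25, 2->50, 3->75, 4->100.
    Reverse-scored features (sign -1) are mirrored: r -> 100 - 25 r.
    """
    r = _check_rating(rating)
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    return 25.0 * r if sign == 1 else 100.0 - 25.0 * r


def dimension_scores(
    profile: RatingProfile,
    fmap: FeatureDimensionMap | None = None,
) -> dict[str, float]:
    """Compute the four dimension scores from one rating profile.

    Each score is the arithmetic mean of the rescaled ratings of that
    dimension's features; a feature assigned to several dimensions
    contributes to each. Missing ratings are an error (no imputation).
    """
    fmap = fmap or default_feature_map()
    missing = [f for f in fmap.features if f not in profile.ratings]
    if missing:
        raise ValueError(
            f"profile {profile.participant_id!r} is missing ratings for: {missing}"
        )
    out: dict[str, float] = {}
    for dim in DIMENSIONS:
        items = fmap.by_dimension(dim)
        if not items:
            continue
        out[dim] = float(
            np.mean([rescale_rating(profile.ratings[f], s) for f, s in items])
        )
    return out


# ---------------------------------------------------------------------------
# Eligibility / scorability filter
# ---------------------------------------------------------------------------

#: Exclusion reasons in the fixed order in which they are tested.
EXCLUSION_REASONS = (
    "untestable",
    "above_qab_cutoff",
    "right_dominant",
    "sample_too_short",
    "rate_too_low",
    "jargon_only",
    "stereotypy_only",
    "unintelligible_only",
    "no_speech_attempt",
)

#: Reasons that make a speech sample unscorable (vs. study-level exclusions).
UNSCORABLE_REASONS = EXCLUSION_REASONS[3:]

QAB_APHASIA_CUTOFF = 8.9  # overall score out of 10; >= cutoff means no aphasia
MIN_SAMPLE_MINUTES = 3.0
MIN_WORDS_PER_MINUTE = 10.0


@dataclass
class EligibilityRecord:
    """Attributes that determine study inclusion and sample scorability."""

    participant_id: str
    testable: bool = True
    qab_overall: float = 5.0
    right_dominant: bool = False
    sample_minutes: float = 3.0
    words_per_minute: float = 10.0
    exclusive_jargon: bool = False
    exclusive_stereotypy: bool = False
    exclusive_unintelligible: bool = False
    no_speech_attempt: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.qab_overall <= 10.0:
            raise ValueError("qab_overall must lie in [0, 10]")
        if self.sample_minutes < 0 or self.words_per_minute < 0:
            raise ValueError("sample_minutes and words_per_minute must be non-negative")


def eligibility_filter(record: EligibilityRecord) -> tuple[str, str | None]:
    """Return ("included", None) or ("excluded", reason).

    Criteria are tested in the fixed EXCLUSION_REASONS order and the first
    failure is reported: testability, aphasia per the QAB cut-off (< 8.9 of
    10), left-hemisphere language dominance, then sample scorability (at
    least 3 minutes of speech at a minimum of 10 words per minute, not
    exclusively jargon / stereotypies / unintelligible productions, with an
    attempt at spoken language).
    """
    checks: list[tuple[str, bool]] = [
        ("untestable", not record.testable),
        ("above_qab_cutoff", record.qab_overall >= QAB_APHASIA_CUTOFF),
        ("right_dominant", record.right_dominant),
        ("sample_too_short", record.sample_minutes < MIN_SAMPLE_MINUTES),
        ("rate_too_low", record.words_per_minute < MIN_WORDS_PER_MINUTE),
        ("jargon_only", record.exclusive_jargon),
        ("stereotypy_only", record.exclusive_stereotypy),
        ("unintelligible_only", record.exclusive_unintelligible),
        ("no_speech_attempt", record.no_speech_attempt),
    ]
    for reason, failed in checks:
        if failed:
            return "excluded", reason
    return "included", None


def roster_from_exclusion_counts(
    n_included: int,
    exclusion_counts: dict[str, int],
) -> list[EligibilityRecord]:
    """Build a deterministic roster realizing exact inclusion/exclusion counts.

    Each excluded record fails exactly one criterion (the named one) and
    passes all earlier ones, so eligibility_filter reproduces the counts.
    """
    roster: list[EligibilityRecord] = []
    k = 0
    for _ in range(n_included):
        roster.append(EligibilityRecord(participant_id=f"p{k:04d}"))
        k += 1
    setters: dict[str, dict] = {
        "untestable": {"testable": False},
        "above_qab_cutoff": {"qab_overall": 9.5},
        "right_dominant": {"right_dominant": True},
        "sample_too_short": {"sample_minutes": 2.0},
        "rate_too_low": {"words_per_minute": 5.0},
        "jargon_only": {"exclusive_jargon": True},
        "stereotypy_only": {"exclusive_stereotypy": True},
        "unintelligible_only": {"exclusive_unintelligible": True},
        "no_speech_attempt": {"no_speech_attempt": True},
    }
    for reason, count in exclusion_counts.items():
        if reason not in setters:
            raise ValueError(f"unknown exclusion reason {reason!r}")
        for _ in range(count):
            roster.append(EligibilityRecord(participant_id=f"p{k:04d}", **setters[reason]))
            k += 1
    return roster


# ---------------------------------------------------------------------------
# Interrater agreement: two-way random-effects absolute-agreement ICC(A,1)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_participant: float
    ms_rater: float
    ms_residual: float
    label: str


def _icc_a1_from_matrix(m: np.ndarray) -> tuple[float, float, float, float]:
    """ICC(A,1) and the three ANOVA mean squares for a participants x raters matrix."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 0.0
    return icc, msr, msc, mse


def icc_agreement(
    ratings: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = 0,
) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC(A,1).

    ``ratings`` is a participants x raters matrix with no missing cells
    (pool (participant, feature) pairs as rows to get a joint across-feature
    coefficient). CI is a BCa bootstrap over rows; a non-positive point
    estimate is reported as 0 with a warning.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need a matrix with >=3 participants and >=2 raters")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    icc, msr, msc, mse = _icc_a1_from_matrix(m)
    if icc <= 0:
        if np.isclose(msr, mse) or icc < 0:
            warnings.warn("non-positive participant variance; ICC reported as 0",
                          stacklevel=2)
        icc = max(icc, 0.0)
    lo, hi = np.nan, np.nan
    if n_boot:
        def stat(rows: np.ndarray) -> float:
            return max(_icc_a1_from_matrix(rows)[0], 0.0)
        lo, hi = bca_ci(stat, m, n_iter=n_boot, level=level, seed=seed)
    return ICCResult(float(icc), float(lo), float(hi), float(msr), float(msc),
                     float(mse), agreement_label(float(icc)))


# ---------------------------------------------------------------------------
# BCa bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bca_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    n_iter: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval.

    ``data`` holds exchangeable units along axis 0; ``statistic`` maps a
    resampled array to a scalar. Bias correction z0 comes from the
    proportion of bootstrap replicates below the point estimate;
    acceleration from the jackknife skewness. Deterministic under a fixed
    seed. A statistic that is constant across replicates collapses the
    interval to a point (with a warning).
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    if n < 8:
        raise ValueError("need at least 8 exchangeable units")
    rng = np.random.default_rng(seed)
    theta = float(statistic(data))
    boot = np.empty(n_iter)
    for b in range(n_iter):
        boot[b] = statistic(data[rng.integers(0, n, size=n)])
    if np.ptp(boot) < 1e-14:
        if not np.isclose(boot[0], theta):
            warnings.warn("degenerate bootstrap distribution away from the estimate",
                          stacklevel=2)
        warnings.warn("statistic degenerate across replicates; point interval",
                      stacklevel=2)
        return theta, theta
    # bias correction
    prop = ((boot < theta).sum() + 0.5 * (boot == theta).sum()) / n_iter
    prop = min(max(prop, 0.5 / n_iter), 1 - 0.5 / n_iter)
    z0 = stats.norm.ppf(prop)
    # acceleration from jackknife
    jack = np.empty(n)
    for i in range(n):
        jack[i] = statistic(np.delete(data, i, axis=0))
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for z_alpha in (stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)):
        adj = stats.norm.cdf(z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Polyserial correlation (ordinal vs continuous, latent bivariate normal)
# ---------------------------------------------------------------------------

@dataclass
class PolyserialEstimate:
    rho_hat: float
    ci_low: float
    ci_high: float
    thresholds: np.ndarray


def polyserial_corr(
    ordinal: Sequence[int],
    continuous: Sequence[float],
    n_boot: int = 0,
    level: float = 0.95,
    seed: int | None = 0,
) -> PolyserialEstimate:
    """Two-step polyserial correlation under the latent bivariate-normal model.

    Step 1 fixes the ordinal thresholds at inverse-normal cumulative
    proportions; step 2 maximizes the conditional likelihood of the ordinal
    given the (standardized) continuous variable over rho. Optional BCa
    bootstrap CI over participants (n_boot > 0).
    """
    y = np.asarray(ordinal, dtype=int)
    x = np.asarray(continuous, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("ordinal and continuous must be 1D of equal length")
    if len(y) < 20:
        raise ValueError("need n >= 20")
    if len(np.unique(y)) < 3:
        raise ValueError("need at least 3 distinct ordinal levels observed")

    def fit_rho(yy: np.ndarray, xx: np.ndarray) -> tuple[float, np.ndarray]:
        levels = np.unique(yy)
        cum = np.cumsum([np.mean(yy == lv) for lv in levels])[:-1]
        tau = stats.norm.ppf(cum)
        xs = (xx - xx.mean()) / xx.std(ddof=0)
        tau_lo = np.concatenate(([-np.inf], tau))
        tau_hi = np.concatenate((tau, [np.inf]))
        codes = np.searchsorted(levels, yy)

        def nll(rho: float) -> float:
            s = np.sqrt(1.0 - rho * rho)
            upper = stats.norm.cdf((tau_hi[codes] - rho * xs) / s)
            lower = stats.norm.cdf((tau_lo[codes] - rho * xs) / s)
            p = np.clip(upper - lower, 1e-300, None)
            return -np.log(p).sum()

        res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded")
        return float(res.x), tau

    rho_hat, tau = fit_rho(y, x)
    lo, hi = np.nan, np.nan
    if n_boot:
        pairs = np.column_stack([y.astype(float), x])

        def stat(rows: np.ndarray) -> float:
            yy = rows[:, 0].astype(int)
            if len(np.unique(yy)) < 2 or rows[:, 1].std() == 0:
                return rho_hat  # degenerate resample: fall back to the estimate
            return fit_rho(yy, rows[:, 1])[0]

        lo, hi = bca_ci(stat, pairs, n_iter=n_boot, level=level, seed=seed)
    return PolyserialEstimate(rho_hat, float(lo), float(hi), tau)


# ---------------------------------------------------------------------------
# McDonald's omega-total via minimum-residual factor analysis
# ---------------------------------------------------------------------------

@dataclass
class OmegaResult:
    omega_t: float
    loadings: np.ndarray  # items x factors
    uniquenesses: np.ndarray
    converged: bool


def _minres_loadings(
    corr: np.ndarray, n_factors: int, max_iter: int = 1000, tol: float = 1e-9
) -> tuple[np.ndarray, bool]:
    """Minimum-residual factor extraction by iterated principal axes.

    Communalities start at the squared multiple correlations (falling back
    to the largest absolute row correlation when R is singular) and are
    iterated to a fixed point of the reduced-correlation eigenproblem,
    which minimizes the off-diagonal residuals of R - L L'.
    """
    p = corr.shape[0]
    try:
        rinv = np.linalg.inv(corr)
        comm = 1.0 - 1.0 / np.diag(rinv)
        if not np.all(np.isfinite(comm)) or comm.min() < 0 or comm.max() > 1:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        comm = np.abs(corr - np.diag(np.diag(corr))).max(axis=1)
    converged = False
    L = np.zeros((p, n_factors))
    for _ in range(max_iter):
        r0 = corr.copy()
        np.fill_diagonal(r0, comm)
        vals, vecs = np.linalg.eigh(r0)
        idx = np.argsort(vals)[::-1][:n_factors]
        L = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0.0, None))
        new_comm = (L ** 2).sum(axis=1)
        if np.max(np.abs(new_comm - comm)) < tol:
            converged = True
            comm = new_comm
            break
        comm = new_comm
    # resolve sign indeterminacy: make each factor's loading sum non-negative
    for f in range(n_factors):
        if L[:, f].sum() < 0:
            L[:, f] = -L[:, f]
    return L, converged


def omega_total(
    ratings: np.ndarray | None = None,
    corr: np.ndarray | None = None,
    n_factors: int = 1,
) -> OmegaResult:
    """McDonald's omega-total for a set of standardized items.

    omega_t = 1 - sum(uniquenesses) / Var(total), where Var(total) is the
    model-implied variance of the unit-weight sum of standardized items,
    sum_f (sum_i lambda_if)^2 + sum_i psi_i. Accepts either a
    participants x items data matrix or a correlation matrix directly.
    Heywood cases (communality > 1) are clipped to uniqueness 0 with a
    warning.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if corr is None:
        if ratings is None:
            raise ValueError("provide ratings or corr")
        m = np.asarray(ratings, dtype=float)
        if m.shape[0] <= m.shape[1]:
            raise ValueError("need more participants than items")
        corr = np.corrcoef(m, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    L, converged = _minres_loadings(corr, n_factors)
    if not converged:
        warnings.warn("minres factor extraction did not fully converge", stacklevel=2)
    comm = (L ** 2).sum(axis=1)
    if (comm > 1.0 + 1e-9).any():
        warnings.warn("Heywood case: uniqueness clipped to 0", stacklevel=2)
    psi = np.clip(1.0 - comm, 0.0, 1.0)
    var_total = float((L.sum(axis=0) ** 2).sum() + psi.sum())
    omega = 1.0 - psi.sum() / var_total
    return OmegaResult(float(np.clip(omega, 0.0, 1.0)), L, psi, converged)
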