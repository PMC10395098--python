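"""No-intercept model fitting of ROI signal changes and model comparison.

Per region of interest (ROI) and stimulus event, the data are
participant-level percent signal changes under four conditions —
Nesting 6 W, Nesting 4 W, Crossing 6 W, Crossing 4 W — each already
baselined by subtracting the Grouping condition at the same word count.
The model is a single-scale no-intercept line through the origin,

    y_c = a * e_c,

where ``e`` is a length-4 integer estimate vector composed from the
complexity calculus and ``a`` is fitted by least squares over the four
condition means.  The closed-form solution is

    a = sum(e_c * ybar_c) / sum(e_c**2).

Goodness of fit is summarized by the residual sum of squares (RSS), the
uncentered coefficient of determination ``1 - RSS / sum(ybar_c**2)``
(the centered value is also reported), and per-condition two-sided
one-sample t-tests of the participant values against the fitted value
(Bonferroni-corrected threshold alpha = 0.05 / 4 = 0.0125).

Competing estimate vectors are compared by a Gaussian likelihood ratio:
each model's log-likelihood uses the maximum-likelihood error variance
``RSS / n`` over the ``n`` fitted observations, giving

    LL = -(n / 2) * (log(2 * pi * RSS / n) + 1),

and the ratio of the alternative to the good model is
``exp(LL_alt - LL_good) = (RSS_good / RSS_alt) ** (n / 2)``.  ``n``
defaults to the four condition means and is exposed as a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ContrastProfile, all_contrasts
from .structures import (
    CROSSING,
    NESTING,
    PREDICATES,
    SUBJECTS_PLUS,
    word_count_label,
)

#: Fixed condition order of every estimate vector and data matrix:
#: Nesting first, then Crossing, 6 W before 4 W within each.
CONDITION_ORDER: tuple[tuple[str, int], ...] = (
    (NESTING, 3),
    (NESTING, 2),
    (CROSSING, 3),
    (CROSSING, 2),
)
CONDITION_LABELS = tuple(
    f"{dep} {word_count_label(n)}" for dep, n in CONDITION_ORDER
)

DEFAULT_ALPHA = 0.05 / 4  # Bonferroni over the four condition contrasts


@dataclass
class EstimateVector:
    """A length-4 predictor vector in fixed condition order."""

    values: np.ndarray
    label: str
    provenance: tuple[str, str, str] = ("", "", "")  # (primary, fallback, event)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (4,):
            raise ValueError("estimate vector must have exactly 4 components")
        if not np.any(self.values):
            raise ValueError("estimate vector must not be all zeros")

    @classmethod
    def from_values(cls, values: Sequence[float], **kwargs) -> "EstimateVector":
        values = np.asarray(values, dtype=float)
        label = ": ".join(
            str(int(v)) if float(v).is_integer() else str(v) for v in values
        )
        return cls(values=values, label=kwargs.pop("label", label), **kwargs)


@dataclass
class ROIDataset:
    """Participant × condition signal changes for one region and event.

    ``data`` is shaped (participants, 4) with columns in
    :data:`CONDITION_ORDER`; values are Grouping-baselined percent
    signal changes.
    """

    region: str
    event: str
    data: np.ndarray
    participant_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 4:
            raise ValueError("data must be a participants x 4 matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 participants")
        if np.isnan(self.data).any():
            raise ValueError("missing cells are not allowed")
        if not self.participant_ids:
            self.participant_ids = tuple(
                f"P{i + 1:02d}" for i in range(self.data.shape[0])
            )

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    def condition_means(self) -> np.ndarray:
        # Reduce along the contiguous axis so numpy's pairwise summation
        # applies; identical participant rows then average exactly, which
        # keeps the noise-free limit bit-for-bit recoverable downstream.
        return np.ascontiguousarray(self.data.T).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format CSV schema: one row per participant × condition."""
        rows = []
        for pid, row in zip(self.participant_ids, self.data):
            for (dep, n), value in zip(CONDITION_ORDER, row):
                rows.append(
                    {
                        "participant_id": pid,
                        "region": self.region,
                        "event": self.event,
                        "dependency": dep,
                        "word_count": word_count_label(n),
                        "signal_change": value,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, region: str, event: str
    ) -> "ROIDataset":
        sub = frame[(frame["region"] == region) & (frame["event"] == event)]
        if sub.empty:
            raise ValueError(f"no rows for region {region!r}, event {event!r}")
        pivot = sub.pivot(
            index="participant_id",
            columns=["dependency", "word_count"],
            values="signal_change",
        )
        cols = [(dep, word_count_label(n)) for dep, n in CONDITION_ORDER]
        missing = [c for c in cols if c not in pivot.columns]
        if missing:
            raise ValueError(f"missing conditions in CSV: {missing}")
        pivot = pivot[cols]
        return cls(
            region=region,
            event=event,
            data=pivot.to_numpy(),
            participant_ids=tuple(pivot.index),
        )


@dataclass
class FitResult:
    """A fitted no-intercept model and its goodness-of-fit summary."""

    estimates: EstimateVector
    scale: float
    fitted: np.ndarray
    rss: float
    r2: float
    r2_centered: float
    loglik: float
    n_loglik: int
    t_pvalues: np.ndarray
    alpha: float = DEFAULT_ALPHA

    @property
    def rejected_contrasts(self) -> np.ndarray:
        """Boolean mask of conditions where the model fit is rejected."""
        return self.t_pvalues < self.alpha


def compose_estimates(
    region_spec: tuple[str, str],
    event: str,
    contrasts: Optional[Mapping] = None,
) -> EstimateVector:
    """Compose the length-4 estimate vector for one region spec and event.

    ``region_spec`` is ``(primary_factor, fallback_factor)``.  For each
    condition in :data:`CONDITION_ORDER`, the Grouping-baselined
    contrast value of the primary factor is used when that factor
    applies to the condition and event; otherwise the fallback factor's
    value is used.  With the study's specs this yields ``4: 2: 2: 1``
    (search cost primary, Subjects+), ``2: 1: 4: 2`` (ordering cost
    primary, Predicates) and ``2: 1: 2: 1`` when no primary process
    applies.
    """
    primary, fallback = region_spec
    if contrasts is None:
        contrasts = all_contrasts()
    values = []
    for dep, n in CONDITION_ORDER:
        contrast: ContrastProfile = contrasts[(dep, n, event)]
        value = contrast.get(primary)
        if value is None:
            value = contrast.get(fallback)
        if value is None:
            raise ValueError(
                f"neither {primary!r} nor {fallback!r} applies to "
                f"{dep} {word_count_label(n)} during {event}"
            )
        values.append(value)
    return EstimateVector.from_values(
        values, provenance=(primary, fallback, event)
    )


def _t_pvalues(fitted: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Two-sided one-sample t-tests of participant values vs fitted values.

    Degenerate zero-variance conditions (noise-free synthetic data) get
    p = 1 when the mean equals the fitted value exactly and p = 0
    otherwise.
    """
    pvalues = np.empty(4)
    for c in range(4):
        column = data[:, c]
        if np.ptp(column) == 0.0:
            pvalues[c] = 1.0 if column[0] == fitted[c] else 0.0
            continue
        pvalues[c] = stats.ttest_1samp(column, popmean=fitted[c]).pvalue
    return pvalues


def gaussian_loglik(rss: float, n: int = 4) -> float:
    """Gaussian log-likelihood with maximum-likelihood error variance.

    ``LL = -(n/2) * (log(2*pi*rss/n) + 1)``.  A perfect fit (``rss <= 0``)
    has unbounded likelihood and is rejected.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if rss <= 0:
        raise ValueError("rss must be positive (a perfect fit has unbounded likelihood)")
    return -(n / 2.0) * (math.log(2.0 * math.pi * rss / n) + 1.0)


def fit_no_intercept(
    e: EstimateVector,
    data: ROIDataset,
    *,
    n_loglik: int = 4,
    alpha: float = DEFAULT_ALPHA,
) -> FitResult:
    """Least-squares fit of ``y = a * e`` to the four condition means."""
    ybar = data.condition_means()
    ee = float(e.values @ e.values)
    a = float(e.values @ ybar) / ee
    # Two steps of iterative refinement on the normal equation remove the
    # final-ulp rounding of the dot/division, so exactly proportional data
    # recover their generating scale bit-for-bit (and RSS comes out 0.0).
    for _ in range(2):
        a += float(e.values @ (ybar - a * e.values)) / ee
    fitted = a * e.values
    residuals = ybar - fitted
    rss = float(residuals @ residuals)
    total_uncentered = float(ybar @ ybar)
    total_centered = float(((ybar - ybar.mean()) ** 2).sum())
    r2 = 1.0 - rss / total_uncentered if total_uncentered > 0 else 1.0
    r2_centered = (
        1.0 - rss / total_centered if total_centered > 0 else float("nan")
    )
    # rss == 0 (noise-free data) gives an unbounded likelihood; represent
    # it as +inf so downstream ratios degenerate sensibly.
    loglik = gaussian_loglik(rss, n_loglik) if rss > 0 else math.inf
    return FitResult(
        estimates=e,
        scale=a,
        fitted=fitted,
        rss=rss,
        r2=r2,
        r2_centered=r2_centered,
        loglik=loglik,
        n_loglik=n_loglik,
        t_pvalues=_t_pvalues(fitted, data.data),
        alpha=alpha,
    )


def goodness_t_tests(fit: FitResult, data: ROIDataset) -> np.ndarray:
    """Per-condition one-sample t-test p-values against the fitted values.

    Raises on zero within-condition variance; use the p-values attached
    to the :class:`FitResult` for degenerate noise-free data.
    """
    if np.any(np.ptp(data.data, axis=0) == 0.0):
        raise ValueError("zero within-condition variance: t-test undefined")
    return _t_pvalues(fit.fitted, data.data)


@dataclass
class ModelComparison:
    """A good model, an alternative, and their likelihood ratio."""

    good: FitResult
    alternative: FitResult
    likelihood_ratio: float
    n_loglik: int


def compare_models(
    data: ROIDataset,
    good: EstimateVector,
    alternative: EstimateVector,
    n_loglik: int = 4,
    alpha: float = DEFAULT_ALPHA,
) -> ModelComparison:
    """Fit both vectors and form ``exp(LL_alt - LL_good)``.

    Identical vectors give a ratio of exactly 1.  Zero-RSS fits are
    degenerate limits: a perfect good model against an imperfect
    alternative yields 0, and conversely +inf.
    """
    fit_good = fit_no_intercept(good, data, n_loglik=n_loglik, alpha=alpha)
    fit_alt = fit_no_intercept(alternative, data, n_loglik=n_loglik, alpha=alpha)
    if fit_good.rss == 0.0 and fit_alt.rss == 0.0:
        ratio = 1.0
    elif fit_good.rss == 0.0:
        ratio = 0.0
    elif fit_alt.rss == 0.0:
        ratio = math.inf
    elif np.array_equal(fit_good.estimates.values, fit_alt.estimates.values):
        ratio = 1.0
    else:
        ratio = math.exp(fit_alt.loglik - fit_good.loglik)
    return ModelComparison(
        good=fit_good, alternative=fit_alt, likelihood_ratio=ratio,
        n_loglik=n_loglik,
    )


@dataclass
class DissociationReport:
    """Model-comparison table across regions × events plus the verdict."""

    table: pd.DataFrame
    dissociation: bool
    comparisons: dict = field(default_factory=dict)


def format_ratio(ratio: float) -> str:
    """Scientific notation with 2 significant digits (``9.1e-05`` style)."""
    if ratio == 1.0:
        return "1.0"
    return f"{ratio:.1e}"


def double_dissociation(
    datasets: Mapping[str, Mapping[str, ROIDataset]],
    specs: Mapping[str, tuple[str, str]],
    *,
    exchange: Optional[Mapping[str, str]] = None,
    n_loglik: int = 4,
    alpha: float = DEFAULT_ALPHA,
) -> DissociationReport:
    """Fit each region's own model against the exchanged-region model.

    ``datasets`` maps region -> event -> :class:`ROIDataset`; ``specs``
    maps region -> ``(primary_factor, fallback_factor)``.  ``exchange``
    names, for each region, the region whose spec provides the
    alternative model; with exactly two regions it defaults to swapping
    them.  A double dissociation is declared when, in every region and
    event, the region's own model dominates (alternative likelihood
    ratio < 1).
    """
    regions = list(datasets)
    if exchange is None:
        distinct = [r for r in regions if r in specs]
        if len(distinct) != 2:
            raise ValueError(
                "exchange mapping required unless exactly two regions are given"
            )
        exchange = {distinct[0]: distinct[1], distinct[1]: distinct[0]}
    for region in regions:
        if region not in specs or region not in exchange:
            raise ValueError(f"missing spec or exchange partner for {region!r}")

    contrasts = all_contrasts()
    rows = []
    comparisons = {}
    dominated_everywhere = True
    for region in regions:
        for event, dataset in datasets[region].items():
            good_vec = compose_estimates(specs[region], event, contrasts)
            alt_vec = compose_estimates(specs[exchange[region]], event, contrasts)
            comparison = compare_models(
                dataset, good_vec, alt_vec, n_loglik=n_loglik, alpha=alpha
            )
            comparisons[(region, event)] = comparison
            if not comparison.likelihood_ratio < 1.0:
                if not np.array_equal(good_vec.values, alt_vec.values):
                    dominated_everywhere = False
            for role, fit, ratio in (
                ("good", comparison.good, 1.0),
                ("alternative", comparison.alternative, comparison.likelihood_ratio),
            ):
                rows.append(
                    {
                        "region": region,
                        "event": event,
                        "model": role,
                        "estimates": fit.estimates.label,
                        "rss": fit.rss,
                        "r2": fit.r2,
                        **{
                            f"p_{label}": p
                            for label, p in zip(CONDITION_LABELS, fit.t_pvalues)
                        },
                        "loglik": fit.loglik,
                        "likelihood_ratio": ratio,
                    }
                )
    table = pd.DataFrame(rows)
    return DissociationReport(
        table=table, dissociation=dominated_everywhere, comparisons=comparisons
    )
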