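"""Spike-in validation: log-log regressions and the method-agreement ANOVA.

An internal reference strain of known addition carries a single-copy marker
gene, so its marker qPCR quantity times the 16S:marker copy ratio is an
independent expectation for the sequencing-derived absolute abundance.
Validation fits, all on log10-transformed quantities:

(a) 16S-equivalent marker expectation vs the integrated estimate, through
    the origin, with and without the lowest addition level (the level
    closest to the sequencing detection limit);
(b) marker qPCR quantity vs the nominal addition, with intercept — the
    calibration check that the marker assay tracks what was actually added.

The agreement test across quantification routes uses Levene's test for
homogeneity of variances, then one-way ANOVA with Tukey's HSD when
variances are homogeneous and Tamhane's T2 (Welch-type pairwise tests with
a Sidak correction) otherwise, summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit on log-transformed quantities.

    Both R-squared conventions are reported because they differ for
    through-origin fits: ``r2_centered`` compares residuals to deviations
    from the mean, ``r2_uncentered`` to raw sums of squares.
    """

    slope: float
    intercept: float
    r2_centered: float
    r2_uncentered: float
    n: int
    through_origin: bool
    subset: tuple[str, ...] = ()


@dataclass(frozen=True)
class SpikeExperiment:
    """A spike-in dilution series with paired marker qPCR and integrated estimates.

    ``treatments``: (id, nominal added CFU/g) in decreasing-addition order.
    ``marker_quant``: marker gene copies/g per treatment.
    ``ihaaq_estimates``: region -> treatment -> integrated 16S copies/g.
    ``copy_ratio``: 16S copies per genome over marker copies per genome.
    """

    treatments: tuple[tuple[str, float], ...]
    marker_quant: Mapping[str, float]
    ihaaq_estimates: Mapping[str, Mapping[str, float]]
    copy_ratio: float

    def __post_init__(self) -> None:
        if len(self.treatments) < 3:
            raise ValueError("need >= 3 treatments for a validation regression")
        if self.copy_ratio <= 0:
            raise ValueError("copy_ratio must be positive")
        ids = [t for t, _ in self.treatments]
        missing = [t for t in ids if t not in self.marker_quant]
        if missing:
            raise KeyError(f"marker quantities missing for treatments {missing}")
        for region, estimates in self.ihaaq_estimates.items():
            missing = [t for t in ids if t not in estimates]
            if missing:
                raise KeyError(
                    f"{region} integrated estimates missing for {missing}"
                )


@dataclass(frozen=True)
class SpikeValidationReport:
    calibration: RegressionResult  # marker vs nominal, with intercept
    agreement: dict[str, dict[str, RegressionResult]]  # region -> fit label
    passed: bool
    slope_range: tuple[float, float]
    r2_min: float


def log10_transform(values) -> np.ndarray:
    """Elementwise log10; rejects non-positive entries by index."""
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(
            f"log10 requires positive values; offending indices {bad.tolist()}"
        )
    return np.log10(arr)


def fit_validation_regression(
    x,
    y,
    through_origin: bool = False,
    ids: Sequence[str] | None = None,
    subset: Sequence[str] | None = None,
) -> RegressionResult:
    """OLS of y on x, optionally forced through the origin.

    ``ids`` labels the points; ``subset`` restricts the fit to the named
    points (the labels used are recorded on the result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length 1-D; got {x.shape}, {y.shape}")
    labels = tuple(ids) if ids is not None else tuple(str(i) for i in range(len(x)))
    if len(labels) != len(x):
        raise ValueError("ids length must match data length")
    if subset is not None:
        wanted = set(subset)
        keep = [i for i, lab in enumerate(labels) if lab in wanted]
        if len(keep) != len(wanted):
            raise KeyError(f"subset ids not all present: {sorted(wanted)}")
        x, y = x[keep], y[keep]
        labels = tuple(labels[i] for i in keep)

    n = len(x)
    if through_origin:
        if n < 1:
            raise ValueError("through-origin fit needs >= 1 point")
        sxx = float(np.dot(x, x))
        if sxx == 0:
            raise ValueError("all x are zero; slope undefined")
        slope = float(np.dot(x, y)) / sxx
        intercept = 0.0
        fitted = slope * x
    else:
        if n < 2:
            raise ValueError("fit with intercept needs >= 2 points")
        if np.ptp(x) == 0:
            raise ValueError("all x equal; slope undefined")
        design = np.column_stack([x, np.ones(n)])
        (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
        slope, intercept = float(slope), float(intercept)
        fitted = slope * x + intercept

    ss_res = float(np.sum((y - fitted) ** 2))
    ss_cen = float(np.sum((y - y.mean()) ** 2))
    ss_unc = float(np.sum(y**2))
    r2_centered = 1.0 - ss_res / ss_cen if ss_cen > 0 else 1.0
    r2_uncentered = 1.0 - ss_res / ss_unc if ss_unc > 0 else 1.0
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r2_centered=r2_centered,
        r2_uncentered=r2_uncentered,
        n=n,
        through_origin=through_origin,
        subset=labels,
    )


def validate_spikein(
    exp: SpikeExperiment,
    slope_range: tuple[float, float] = (0.9, 1.1),
    r2_min: float = 0.99,
) -> SpikeValidationReport:
    """Run the full validation fit battery for a spike-in experiment.

    The pass/fail verdict applies ``slope_range`` and ``r2_min`` to the
    with-intercept calibration fit (marker vs nominal); the through-origin
    agreement fits per region are reported for inspection.
    """
    ids = [t for t, _ in exp.treatments]
    nominal = np.array([n for _, n in exp.treatments])
    marker = np.array([exp.marker_quant[t] for t in ids])

    calibration = fit_validation_regression(
        log10_transform(nominal), log10_transform(marker), ids=ids
    )

    expected = marker * exp.copy_ratio  # 16S-equivalent expectation
    lowest = min(exp.treatments, key=lambda t: t[1])[0]
    without_lowest = [t for t in ids if t != lowest]
    agreement: dict[str, dict[str, RegressionResult]] = {}
    for region in sorted(exp.ihaaq_estimates):
        estimates = np.array([exp.ihaaq_estimates[region][t] for t in ids])
        x = log10_transform(expected)
        y = log10_transform(estimates)
        agreement[region] = {
            "all": fit_validation_regression(x, y, through_origin=True, ids=ids),
            "without_lowest": fit_validation_regression(
                x, y, through_origin=True, ids=ids, subset=without_lowest
            ),
        }

    lo, hi = slope_range
    passed = lo <= calibration.slope <= hi and calibration.r2_centered >= r2_min
    return SpikeValidationReport(
        calibration=calibration,
        agreement=agreement,
        passed=passed,
        slope_range=slope_range,
        r2_min=r2_min,
    )


# ---------------------------------------------------------------------------
# Method-agreement ANOVA chain


@dataclass(frozen=True)
class PairwiseComparison:
    groups: tuple[str, str]
    statistic: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class AnovaChainResult:
    levene_p: float
    method: str  # "tukey" or "tamhane"
    anova_p: float | None
    comparisons: tuple[PairwiseComparison, ...]
    letters: dict[str, str]
    alpha: float

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def _tamhane_t2(
    samples: dict[str, np.ndarray], alpha: float
) -> list[PairwiseComparison]:
    """Tamhane's T2: Welch pairwise t-tests, Sidak-adjusted for m comparisons."""
    names = list(samples)
    m = len(names) * (len(names) - 1) // 2
    out = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = samples[a], samples[b]
        va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
        se = np.sqrt(va + vb)
        if se == 0:
            t_stat = 0.0 if xa.mean() == xb.mean() else np.inf
            df = len(xa) + len(xb) - 2
        else:
            t_stat = (xa.mean() - xb.mean()) / se
            df = (va + vb) ** 2 / (
                va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1)
            )
        p_raw = 2 * stats.t.sf(abs(t_stat), df) if np.isfinite(t_stat) else 0.0
        p_adj = min(1.0, 1.0 - (1.0 - p_raw) ** m)
        out.append(
            PairwiseComparison(
                groups=(a, b),
                statistic=float(t_stat),
                p_value=float(p_adj),
                significant=p_adj < alpha,
            )
        )
    return out


def _tukey_hsd(
    samples: dict[str, np.ndarray], alpha: float
) -> list[PairwiseComparison]:
    names = list(samples)
    res = stats.tukey_hsd(*[samples[n] for n in names])
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        out.append(
            PairwiseComparison(
                groups=(names[i], names[j]),
                statistic=float(res.statistic[i, j]),
                p_value=p,
                significant=p < alpha,
            )
        )
    return out


def compact_letter_display(
    names: Sequence[str], comparisons: Sequence[PairwiseComparison]
) -> dict[str, str]:
    """Assign letters so that two groups share a letter iff not significantly
    different (insert-and-absorb algorithm)."""
    differ = {
        frozenset(c.groups) for c in comparisons if c.significant
    }
    # letter sets start as one letter covering everyone, then split on each
    # significant pair
    letter_sets: list[set[str]] = [set(names)]
    for pair in differ:
        a, b = tuple(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                letter_sets.extend([s - {a}, s - {b}])
    # absorb: drop sets contained in another
    letter_sets = [
        s
        for s in letter_sets
        if s and not any(s < t for t in letter_sets if t is not s)
    ]
    # deduplicate while preserving a canonical order (by first member index)
    uniq: list[set[str]] = []
    for s in letter_sets:
        if s not in uniq:
            uniq.append(s)
    order = {n: i for i, n in enumerate(names)}
    uniq.sort(key=lambda s: min(order[n] for n in s))
    alphabet = string.ascii_lowercase
    letters = {n: "" for n in names}
    for idx, s in enumerate(uniq):
        symbol = alphabet[idx % 26] * (idx // 26 + 1)
        for n in s:
            letters[n] += symbol
    return letters


def compare_methods_anova(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> AnovaChainResult:
    """Levene -> one-way ANOVA + Tukey HSD, or Tamhane's T2 when variances
    are heterogeneous; returns pairwise p-values and a compact letter display.
    """
    if not isinstance(groups, Mapping):
        groups = {f"group{i + 1}": g for i, g in enumerate(groups)}
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    for name, arr in samples.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")

    arrays = list(samples.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # every observation identical: nothing differs, degenerate tests
        comparisons = tuple(
            PairwiseComparison(groups=(a, b), statistic=0.0, p_value=1.0,
                               significant=False)
            for a, b in itertools.combinations(samples, 2)
        )
        return AnovaChainResult(
            levene_p=1.0,
            method="tukey",
            anova_p=1.0,
            comparisons=comparisons,
            letters=compact_letter_display(list(samples), comparisons),
            alpha=alpha,
        )

    levene_p = float(stats.levene(*arrays, center="mean").pvalue)
    if levene_p >= alpha:
        method = "tukey"
        anova_p = float(stats.f_oneway(*arrays).pvalue)
        comparisons = _tukey_hsd(samples, alpha)
    else:
        method = "tamhane"
        anova_p = None
        comparisons = _tamhane_t2(samples, alpha)

    letters = compact_letter_display(list(samples), comparisons)
    return AnovaChainResult(
        levene_p=levene_p,
        method=method,
        anova_p=anova_p,
        comparisons=tuple(comparisons),
        letters=letters,
        alpha=alpha,
    )
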