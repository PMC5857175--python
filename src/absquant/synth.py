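"""Synthetic spike-in experiments with known ground truth.

Emulates the full measurement chain of a soil spike-in study so the whole
pipeline can be exercised end to end without any sequencing data:

* a fixed background community (Dirichlet-distributed or explicit
  proportions) with a lognormal total 16S load per sample;
* a reference strain added at a gradient of nominal CFU/g, contributing
  ``CFU x c`` 16S copies/g (c = operon count) and ``CFU x k`` marker
  copies/g; community proportions are renormalised after the addition;
* sequencing as an ideal multinomial draw of ``depth`` reads per sample;
* qPCR as the standard curve evaluated at the per-reaction template amount
  with Gaussian Ct noise, in triplicate, plus an exact plasmid dilution
  series for curve fitting.

Defaults mirror a soil-scale experiment: background load with median
5.82e9 copies/g, six spike levels 7.0e9 down to 7.0e4 CFU/g (1 mL of a
2.1e11..2.1e6 CFU/mL suspension into 30 g soil), c=7 / k=1, 66,460 reads
per sample, 0.21 g extractions eluted in 100 uL with 1 uL template.

All randomness flows from one seed through per-component substreams, so
e.g. changing the number of taxa does not perturb the qPCR noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import qpcr
from .core import TotalQuant, integrate
from .qpcr import CtSet, StandardCurve, StandardSeries, fit_standard_curve
from .tables import RANKS, FeatureTable, TaxonLineage, to_relative
from .validation import SpikeExperiment, SpikeValidationReport, validate_spikein

SPIKE_TAXON = TaxonLineage(
    (
        "Bacteria",
        "Proteobacteria",
        "Gammaproteobacteria",
        "Enterobacteriales",
        "Enterobacteriaceae",
        "Escherichia-Shigella",
    )
)

#: Default spike gradient: 1 mL of 2.1e11..2.1e6 CFU/mL into 30 g soil.
DEFAULT_SPIKE_LEVELS = (
    ("E9", 7.0e9),
    ("E8", 7.0e8),
    ("E7", 7.0e7),
    ("E6", 7.0e6),
    ("E5", 7.0e5),
    ("E4", 7.0e4),
)

TOTAL_ASSAY = "16S_V4"
MARKER_ASSAY = "marker"


@dataclass(frozen=True)
class SyntheticConfig:
    n_taxa: int = 50
    base_proportions: tuple[float, ...] | None = None
    dirichlet_alpha: float = 0.5
    total_median: float = 5.82e9  # copies/g, background load
    total_log10_sd: float = 0.025  # ~6% CV, matching triplicate qPCR scatter
    spike_levels: tuple[tuple[str, float], ...] = DEFAULT_SPIKE_LEVELS
    spike_16s_copies: int = 7  # c: 16S operons per spike genome
    marker_copies: int = 1  # k: marker copies per spike genome
    depth: int = 66460  # reads per sample
    ct_noise_sd: float = 0.1
    n_ct_replicates: int = 3
    curve_slope: float = -3.3219  # 100% amplification efficiency
    curve_intercept: float = 37.0
    soil_mass: float = 0.21  # g per extraction
    elution_volume: float = 100.0  # uL
    template_volume: float = 1.0  # uL per reaction
    exact_counts: bool = False  # expected counts instead of multinomial draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.ct_noise_sd < 0 or self.total_log10_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.spike_16s_copies < 1 or self.marker_copies < 1:
            raise ValueError("copy numbers must be >= 1")
        if self.base_proportions is not None:
            p = np.asarray(self.base_proportions, dtype=float)
            if len(p) != self.n_taxa:
                raise ValueError("base_proportions length must equal n_taxa")
            if (p <= 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("base_proportions must be positive and sum to 1")
        if any(nominal < 0 for _, nominal in self.spike_levels):
            raise ValueError("nominal spike additions must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    samples: tuple[str, ...]
    proportions: np.ndarray = field(repr=False)  # sample x taxon, incl. spike
    totals: np.ndarray = field(repr=False)  # copies/g incl. spike contribution
    spike_copies: np.ndarray = field(repr=False)  # 16S copies/g from the spike
    marker_copies: np.ndarray = field(repr=False)  # marker copies/g

    def abundances(self) -> np.ndarray:
        """True per-taxon absolute abundances A_i = p_i * T (copies/g)."""
        return self.proportions * self.totals[:, None]


@dataclass(frozen=True)
class SyntheticExperiment:
    config: SyntheticConfig
    truth: SyntheticTruth
    feature_table: FeatureTable
    standards: dict[str, StandardSeries]
    ct_sets: tuple[CtSet, ...]


def _background_lineages(n: int) -> tuple[TaxonLineage, ...]:
    phyla = ("Acidobacteria", "Actinobacteria", "Bacteroidetes",
             "Chloroflexi", "Firmicutes")
    out = []
    for i in range(n):
        names = (
            "Bacteria",
            phyla[i % len(phyla)],
            f"Class_{i % 7}",
            f"Order_{i % 11}",
            f"Family_{i % 13}",
            f"Taxon_{i:03d}",
        )
        assert len(names) == len(RANKS)
        out.append(TaxonLineage(names))
    return tuple(out)


def _copies_per_rxn(copies_per_g: float, config: SyntheticConfig) -> float:
    # inverse of qpcr.copies_per_gram
    return (
        copies_per_g
        * config.template_volume
        * config.soil_mass
        / config.elution_volume
    )


def generate(config: SyntheticConfig) -> SyntheticExperiment:
    """Simulate one spike-in experiment; deterministic given ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_props, rng_totals, rng_reads, rng_ct = (
        np.random.default_rng(s) for s in streams
    )

    if config.base_proportions is not None:
        p_bg = np.asarray(config.base_proportions, dtype=float)
    else:
        p_bg = rng_props.dirichlet(np.full(config.n_taxa, config.dirichlet_alpha))
        # guard against zero-probability taxa from extreme Dirichlet draws
        p_bg = np.maximum(p_bg, 1e-12)
        p_bg /= p_bg.sum()

    samples = tuple(t for t, _ in config.spike_levels)
    n_samp = len(samples)
    nominal = np.array([n for _, n in config.spike_levels])

    log10_bg = np.log10(config.total_median) + rng_totals.normal(
        0.0, config.total_log10_sd, size=n_samp
    )
    t_bg = 10.0**log10_bg
    spike_copies = nominal * config.spike_16s_copies
    marker_copies = nominal * config.marker_copies
    totals = t_bg + spike_copies

    proportions = np.empty((n_samp, config.n_taxa + 1))
    proportions[:, :-1] = p_bg[None, :] * (t_bg / totals)[:, None]
    proportions[:, -1] = spike_copies / totals

    if config.exact_counts:
        counts = np.rint(proportions * config.depth).astype(np.int64)
    else:
        counts = np.vstack(
            [rng_reads.multinomial(config.depth, proportions[i])
             for i in range(n_samp)]
        )

    taxa = _background_lineages(config.n_taxa) + (SPIKE_TAXON,)
    feature_table = FeatureTable(samples, taxa, counts)

    # exact plasmid dilution series spanning 10^1..10^9 copies/uL
    standard_concs = 10.0 ** np.arange(1, 10)
    standards = {}
    for assay in (TOTAL_ASSAY, MARKER_ASSAY):
        pts = tuple(
            (float(c), config.curve_slope * np.log10(c) + config.curve_intercept)
            for c in standard_concs
        )
        standards[assay] = StandardSeries(points=pts, assay=assay)

    def ct_replicates(copies_rxn: float) -> tuple[float, ...]:
        true_ct = (
            config.curve_slope * np.log10(copies_rxn) + config.curve_intercept
        )
        noise = rng_ct.normal(0.0, config.ct_noise_sd, size=config.n_ct_replicates)
        if config.ct_noise_sd == 0:
            noise = np.zeros(config.n_ct_replicates)
        return tuple(float(true_ct + e) for e in noise)

    ct_sets = []
    for i, sample in enumerate(samples):
        ct_sets.append(
            CtSet(sample, TOTAL_ASSAY,
                  ct_replicates(_copies_per_rxn(totals[i], config)))
        )
        if marker_copies[i] > 0:
            ct_sets.append(
                CtSet(sample, MARKER_ASSAY,
                      ct_replicates(_copies_per_rxn(marker_copies[i], config)))
            )

    truth = SyntheticTruth(
        samples=samples,
        proportions=proportions,
        totals=totals,
        spike_copies=spike_copies,
        marker_copies=marker_copies,
    )
    return SyntheticExperiment(
        config=config,
        truth=truth,
        feature_table=feature_table,
        standards=standards,
        ct_sets=tuple(ct_sets),
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Pipeline output compared against the generator's ground truth."""

    samples: tuple[str, ...]
    relative_errors: np.ndarray = field(repr=False)  # |est-true|/true, NaN if true=0
    median_relative_error: float = float("nan")
    max_relative_error: float = float("nan")
    ci_coverage: float = float("nan")  # fraction of counts in 95% multinomial CIs
    estimated_totals: np.ndarray = field(repr=False, default=None)
    true_totals: np.ndarray = field(repr=False, default=None)
    spike_validation: SpikeValidationReport | None = None

    @property
    def spike_slope(self) -> float:
        return self.spike_validation.calibration.slope

    @property
    def spike_r2(self) -> float:
        return self.spike_validation.calibration.r2_centered


def recovery_report(exp: SyntheticExperiment) -> RecoveryReport:
    """Run the full pipeline on a synthetic experiment and score it.

    Standard-curve fitting -> Ct quantification -> relative abundances ->
    integration, then per-taxon relative error against the true A_i, the
    spike-in validation regression, and coverage of 95% multinomial
    confidence intervals for the observed read counts.
    """
    config = exp.config
    curves: dict[str, StandardCurve] = {
        assay: fit_standard_curve(series) for assay, series in exp.standards.items()
    }

    per_gram: dict[tuple[str, str], float] = {}
    for cts in exp.ct_sets:
        quant = qpcr.qc_quantify(cts, curves[cts.assay])
        per_gram[(cts.sample, cts.assay)] = qpcr.copies_per_gram(
            quant.copies_per_rxn,
            elution_volume=config.elution_volume,
            soil_mass=config.soil_mass,
            template_volume=config.template_volume,
        )

    totals = [
        TotalQuant(sample=s, region="V4", total_copies=per_gram[(s, TOTAL_ASSAY)])
        for s in exp.truth.samples
    ]
    rel = to_relative(exp.feature_table)
    abs_table = integrate(rel, totals, region="V4")

    true_a = exp.truth.abundances()
    est_a = abs_table.abundances
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(true_a > 0, np.abs(est_a - true_a) / true_a, np.nan)
    finite = rel_err[np.isfinite(rel_err)]

    # 95% normal-approximation multinomial CI per (sample, taxon) count
    expected = exp.truth.proportions * config.depth
    sd = np.sqrt(
        config.depth * exp.truth.proportions * (1.0 - exp.truth.proportions)
    )
    lo, hi = expected - 1.96 * sd, expected + 1.96 * sd
    counts = exp.feature_table.counts
    covered = (counts >= lo) & (counts <= hi)
    ci_coverage = float(covered.mean())

    # spike regression over treatments where the spike was added and seen
    spike_est = {
        s: float(est_a[i, -1]) for i, s in enumerate(exp.truth.samples)
    }
    usable = [
        (t, nom)
        for (t, nom), m in zip(config.spike_levels, exp.truth.marker_copies)
        if nom > 0 and m > 0 and spike_est[t] > 0
    ]
    spike_validation = None
    if len(usable) >= 3:
        spike_exp = SpikeExperiment(
            treatments=tuple(usable),
            marker_quant={
                t: per_gram[(t, MARKER_ASSAY)] for t, _ in usable
            },
            ihaaq_estimates={"V4": {t: spike_est[t] for t, _ in usable}},
            copy_ratio=config.spike_16s_copies / config.marker_copies,
        )
        spike_validation = validate_spikein(spike_exp)

    return RecoveryReport(
        samples=exp.truth.samples,
        relative_errors=rel_err,
        median_relative_error=float(np.median(finite)) if finite.size else float("nan"),
        max_relative_error=float(finite.max()) if finite.size else float("nan"),
        ci_coverage=ci_coverage,
        estimated_totals=np.array([t.total_copies for t in totals]),
        true_totals=exp.truth.totals,
        spike_validation=spike_validation,
    )
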