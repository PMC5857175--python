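"""qPCR standard curves, Ct-to-copies conversion, and replicate QC.

A standard curve is the least-squares line Ct = slope * log10(copies) +
intercept fitted to a plasmid dilution series.  Amplification efficiency
follows from the slope as E = 10^(-1/slope) - 1 (a perfect doubling per
cycle gives slope -1/log10(2) = -3.3219 and E = 1.0).  Unknowns are
quantified by interpolating their mean replicate Ct on the curve, with
flags for noisy replicates (SD above a limit), non-detects (mean Ct beyond
the most dilute standard), and extrapolation outside the standard range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardSeries:
    """A dilution series of known template amounts with measured Ct values."""

    points: tuple[tuple[float, float], ...]  # (copies per uL, Ct)
    assay: str = ""

    def __post_init__(self) -> None:
        if any(c <= 0 for c, _ in self.points):
            raise ValueError("standard concentrations must be positive")
        if len({c for c, _ in self.points}) < 3:
            raise ValueError("need >= 3 distinct standard concentrations")


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # Ct per log10(copies); negative
    intercept: float  # Ct at 1 copy
    r2: float
    loq_ct: float  # mean Ct of the most dilute standard
    range: tuple[float, float]  # (min, max) copies per uL spanned
    assay: str = ""

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 means perfect doubling."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def to_json(self, path) -> None:
        doc = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "loq_ct": self.loq_ct,
            "range": list(self.range),
            "assay": self.assay,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StandardCurve":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            slope=doc["slope"],
            intercept=doc["intercept"],
            r2=doc["r2"],
            loq_ct=doc["loq_ct"],
            range=tuple(doc["range"]),
            assay=doc.get("assay", ""),
        )


@dataclass(frozen=True)
class CtSet:
    """Replicate Ct measurements for one sample/assay (triplicate typical)."""

    sample: str
    assay: str
    replicate_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_cts) == 0:
            raise ValueError(f"{self.sample}/{self.assay}: no replicates")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.replicate_cts))

    @property
    def sd_ct(self) -> float:
        """Sample SD of replicates; 0 for a single replicate."""
        if len(self.replicate_cts) < 2:
            return 0.0
        return float(np.std(self.replicate_cts, ddof=1))


@dataclass(frozen=True)
class CopyQuant:
    """A quantified target with QC flags.

    ``copies_per_g`` is None until the reaction-scale quantity has been
    scaled by extraction volumes (see :func:`copies_per_gram`).
    """

    sample: str
    assay: str
    copies_per_rxn: float
    copies_per_g: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        return not self.flags


def fit_standard_curve(series: StandardSeries) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies) over a dilution series."""
    copies = np.array([c for c, _ in series.points], dtype=float)
    cts = np.array([ct for _, ct in series.points], dtype=float)
    log_c = np.log10(copies)
    if log_c.max() - log_c.min() < 2.0:
        raise ValueError("standards must span at least 2 log10 units")
    res = stats.linregress(log_c, cts)
    # loq: mean Ct at the lowest concentration (replicates averaged)
    cmin = copies.min()
    loq_ct = float(cts[np.isclose(copies, cmin)].mean())
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        loq_ct=loq_ct,
        range=(float(cmin), float(copies.max())),
        assay=series.assay,
    )


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10^((ct - intercept) / slope)."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def qc_quantify(
    cts: CtSet, curve: StandardCurve, sd_limit: float = 0.5
) -> CopyQuant:
    """Quantify from the mean replicate Ct and attach QC flags.

    Flags: ``high_replicate_sd`` when the replicate SD exceeds ``sd_limit``;
    ``below_loq`` when the mean Ct is beyond the most dilute standard's mean
    Ct (the target is not reliably detected); ``out_of_range`` when the
    implied copy number falls outside the standard range.
    """
    if curve.assay and cts.assay and curve.assay != cts.assay:
        raise ValueError(
            f"assay mismatch: curve {curve.assay!r} vs measurements {cts.assay!r}"
        )
    mean_ct = cts.mean_ct
    copies = ct_to_copies(mean_ct, curve)
    flags = set()
    if cts.sd_ct > sd_limit:
        flags.add("high_replicate_sd")
    if mean_ct > curve.loq_ct:
        flags.add("below_loq")
    # the low side of the range is already covered by below_loq
    elif not (curve.range[0] <= copies <= curve.range[1]):
        flags.add("out_of_range")
    return CopyQuant(
        sample=cts.sample,
        assay=cts.assay,
        copies_per_rxn=copies,
        flags=frozenset(flags),
    )


def copies_per_gram(
    copies_per_rxn: float,
    elution_volume: float,
    soil_mass: float,
    template_volume: float = 1.0,
) -> float:
    """Scale a per-reaction quantity to copies per gram of dry soil.

    copies/g = copies/rxn / template_volume(uL) * elution_volume(uL) / soil_mass(g)
    """
    for name, value in (
        ("template_volume", template_volume),
        ("elution_volume", elution_volume),
        ("soil_mass", soil_mass),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    if copies_per_rxn < 0:
        raise ValueError("copies_per_rxn must be non-negative")
    return copies_per_rxn / template_volume * elution_volume / soil_mass


def scale_quant(
    quant: CopyQuant,
    elution_volume: float,
    soil_mass: float,
    template_volume: float = 1.0,
) -> CopyQuant:
    """Return a copy of ``quant`` with ``copies_per_g`` filled in."""
    per_g = copies_per_gram(
        quant.copies_per_rxn, elution_volume, soil_mass, template_volume
    )
    return CopyQuant(
        sample=quant.sample,
        assay=quant.assay,
        copies_per_rxn=quant.copies_per_rxn,
        copies_per_g=per_g,
        flags=quant.flags,
    )


# ---------------------------------------------------------------------------
# CSV plumbing


def read_standards_csv(path) -> dict[str, StandardSeries]:
    """Standards CSV with columns assay, copies_per_ul, ct -> one series per assay."""
    df = pd.read_csv(path)
    required = {"assay", "copies_per_ul", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"standards CSV needs columns {sorted(required)}")
    out = {}
    for assay, grp in df.groupby("assay", sort=False):
        points = tuple(zip(grp["copies_per_ul"].astype(float), grp["ct"].astype(float)))
        out[str(assay)] = StandardSeries(points=points, assay=str(assay))
    return out


def read_runs_csv(path) -> list[CtSet]:
    """Run CSV with columns sample, assay, replicate, ct -> per sample/assay CtSets."""
    df = pd.read_csv(path)
    required = {"sample", "assay", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"runs CSV needs columns {sorted(required)}")
    out = []
    for (sample, assay), grp in df.groupby(["sample", "assay"], sort=False):
        out.append(
            CtSet(
                sample=str(sample),
                assay=str(assay),
                replicate_cts=tuple(grp["ct"].astype(float)),
            )
        )
    return out
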