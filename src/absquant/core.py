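"""Absolute abundance integration: A_i = p_i x T.

The quantification couples two measurements of the same sample: the
sequencing-derived proportion p_i of each taxon, and the qPCR-derived total
16S rRNA gene load T (copies per gram of dry soil, tagged by the amplified
variable region, V3 or V4).  The per-taxon absolute abundance is simply

    A_i = p_i * T          [16S copies / g dry soil]

which conserves the total (sum_i A_i = T) by construction.  Because rRNA
operon multiplicity varies across genomes, copies can optionally be divided
by per-taxon 16S copies-per-genome c_i to yield genome equivalents
G_i = A_i / c_i.  The smallest observable absolute abundance at a given
sequencing depth is L = (minimum detectable read count / depth) * T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tables import RelativeAbundanceTable, TaxonLineage

logger = logging.getLogger(__name__)

REGIONS = ("V3", "V4")


@dataclass(frozen=True)
class TotalQuant:
    """Total 16S copies per gram dry soil for one sample, one variable region."""

    sample: str
    region: str
    total_copies: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.total_copies <= 0:
            raise ValueError(
                f"{self.sample}/{self.region}: total_copies must be > 0"
            )


@dataclass
class AbsoluteAbundanceTable:
    """Per-taxon absolute abundances (copies or genome equivalents per g)."""

    samples: tuple[str, ...]
    taxa: tuple[TaxonLineage, ...]
    region: str
    abundances: np.ndarray = field(repr=False)
    units: str = "copies/g"

    def __post_init__(self) -> None:
        self.samples = tuple(self.samples)
        self.taxa = tuple(self.taxa)
        values = np.asarray(self.abundances, dtype=float)
        if values.shape != (len(self.samples), len(self.taxa)):
            raise ValueError(
                f"abundances shape {values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.taxa)} taxa"
            )
        if (values < 0).any():
            raise ValueError("abundances must be non-negative")
        self.abundances = values

    @property
    def sample_totals(self) -> np.ndarray:
        return self.abundances.sum(axis=1)

    def abundance_of(self, sample: str, taxon_name: str) -> float:
        i = self.samples.index(sample)
        for j, taxon in enumerate(self.taxa):
            if taxon.display_name == taxon_name or taxon.to_string() == taxon_name:
                return float(self.abundances[i, j])
        raise KeyError(f"taxon {taxon_name!r} not in table")

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# region={self.region} units={self.units}\n")
            fh.write("#Taxon\t" + "\t".join(self.samples) + "\n")
            for j, taxon in enumerate(self.taxa):
                row = "\t".join(f"{v:.6g}" for v in self.abundances[:, j])
                fh.write(f"{taxon.to_string()}\t{row}\n")


@dataclass(frozen=True)
class CopyNumberTable:
    """Per-taxon 16S copies per genome plus marker-gene copies per genome.

    ``entries`` maps a taxon or strain name to its 16S rRNA operon count c;
    ``markers`` maps a marker gene name to its copies per genome k.  The
    16S:marker ratio c/k converts single-copy-marker quantities to their
    16S-equivalent expectation.
    """

    entries: dict[str, int] = field(default_factory=dict)
    markers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, c in {**self.entries, **self.markers}.items():
            if int(c) != c or c < 1:
                raise ValueError(f"copy number for {name!r} must be an integer >= 1")

    def ratio(self, taxon: str, marker: str) -> Fraction:
        """16S-per-genome over marker-per-genome for a spike strain."""
        return Fraction(self.entries[taxon], self.markers[marker])

    @classmethod
    def from_tsv(cls, path) -> "CopyNumberTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"taxon_or_strain", "gene", "copies_per_genome"}
        if not required.issubset(df.columns):
            raise ValueError(f"copy-number TSV needs columns {sorted(required)}")
        entries, markers = {}, {}
        for _, row in df.iterrows():
            gene = str(row["gene"])
            copies = int(row["copies_per_genome"])
            if gene.lower() in ("16s", "16s rrna", "16s_rrna"):
                entries[str(row["taxon_or_strain"])] = copies
            else:
                markers[gene] = copies
        return cls(entries=entries, markers=markers)


@dataclass(frozen=True)
class DetectionLimit:
    sample: str
    region: str
    min_reads: int
    depth: int
    limit: float  # copies per g


def integrate(
    rel: RelativeAbundanceTable,
    totals: Iterable[TotalQuant],
    region: str | None = None,
) -> AbsoluteAbundanceTable:
    """Scale per-sample proportions by that sample's total 16S load.

    ``totals`` may mix regions; ``region`` selects which to use and may be
    omitted when the totals are unambiguous.  Every sample in ``rel`` must
    have a matching total for the chosen region.
    """
    totals = list(totals)
    regions = sorted({t.region for t in totals})
    if region is None:
        if len(regions) != 1:
            raise ValueError(
                f"totals cover regions {regions}; pass region= to choose one"
            )
        region = regions[0]
    by_sample = {t.sample: t for t in totals if t.region == region}
    missing = [s for s in rel.samples if s not in by_sample]
    if missing:
        raise KeyError(
            f"no {region} total for sample(s) {missing}; have {sorted(by_sample)}"
        )
    t_vec = np.array([by_sample[s].total_copies for s in rel.samples])
    abundances = rel.proportions * t_vec[:, None]
    return AbsoluteAbundanceTable(rel.samples, rel.taxa, region, abundances)


def expected_marker_copies(marker_quant: float, ratio_16s_to_marker) -> float:
    """16S-equivalent expectation for a spike strain from its marker qPCR.

    A strain with c 16S operons and k marker copies per genome measured at
    q marker copies/g is expected to contribute q * c/k 16S copies/g.
    """
    ratio = float(ratio_16s_to_marker)
    if ratio <= 0:
        raise ValueError(f"copy ratio must be positive, got {ratio_16s_to_marker}")
    if marker_quant < 0:
        raise ValueError("marker quantity must be non-negative")
    return marker_quant * ratio


def to_genome_equivalents(
    abs_table: AbsoluteAbundanceTable,
    copies: CopyNumberTable,
    default_c: int = 1,
) -> AbsoluteAbundanceTable:
    """Divide 16S copies by per-taxon operon counts: G_i = A_i / c_i.

    Taxa absent from the copy-number table fall back to ``default_c`` (a
    warning is logged), which with the default of 1 leaves them numerically
    unchanged.
    """
    if default_c < 1:
        raise ValueError("default_c must be >= 1")
    c_vec = np.empty(len(abs_table.taxa))
    unmatched = []
    for j, taxon in enumerate(abs_table.taxa):
        c = copies.entries.get(taxon.display_name)
        if c is None:
            c = copies.entries.get(taxon.to_string())
        if c is None:
            unmatched.append(taxon.display_name)
            c = default_c
        if c <= 0:
            raise ValueError(f"copy number for {taxon.display_name!r} must be > 0")
        c_vec[j] = c
    if unmatched:
        logger.warning(
            "no 16S copy number for %d taxa (e.g. %s); using default c=%d",
            len(unmatched), unmatched[:3], default_c,
        )
    return AbsoluteAbundanceTable(
        abs_table.samples,
        abs_table.taxa,
        abs_table.region,
        abs_table.abundances / c_vec[None, :],
        units="genomes/g",
    )


def detection_limit(min_reads: int, depth: int, total: TotalQuant) -> DetectionLimit:
    """Smallest absolute abundance observable at this sequencing depth."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 < min_reads <= depth:
        raise ValueError(f"min_reads must be in (0, depth]; got {min_reads}/{depth}")
    limit = min_reads / depth * total.total_copies
    return DetectionLimit(
        sample=total.sample,
        region=total.region,
        min_reads=int(min_reads),
        depth=int(depth),
        limit=limit,
    )


def mean_total(totals: Sequence[TotalQuant], sample: str | None = None) -> TotalQuant:
    """Pool replicate qPCR totals (e.g. triplicate extracts whose DNA was
    combined for sequencing) into a single mean TotalQuant."""
    totals = list(totals)
    if not totals:
        raise ValueError("no totals to pool")
    regions = {t.region for t in totals}
    if len(regions) != 1:
        raise ValueError(f"cannot pool across regions {sorted(regions)}")
    values = np.array([t.total_copies for t in totals])
    return TotalQuant(
        sample=sample if sample is not None else totals[0].sample,
        region=totals[0].region,
        total_copies=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    )


def read_totals_csv(path) -> list[TotalQuant]:
    """Totals CSV with columns sample, region, total_copies[, sd]."""
    df = pd.read_csv(path)
    required = {"sample", "region", "total_copies"}
    if not required.issubset(df.columns):
        raise ValueError(f"totals CSV needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            TotalQuant(
                sample=str(row["sample"]),
                region=str(row["region"]),
                total_copies=float(row["total_copies"]),
                sd=float(row["sd"]) if "sd" in df.columns else 0.0,
            )
        )
    return out
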