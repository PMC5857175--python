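"""Relative-vs-absolute community dynamics between two time points.

Scaling proportions by a total load can flip the apparent direction of
change: a taxon whose share of the community grows can still be shrinking
in copies per gram when the whole community contracts (and vice versa).
This module quantifies that discordance taxon by taxon.

Conventions: relative-abundance changes are differences of percentages
(percentage points); absolute-abundance changes are percent of the
baseline quantity.  A taxon is *discordant* when the two deltas have
opposite (nonzero) signs, *concordant* when they agree, and *unchanged*
when either delta is within ``eps`` of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import AbsoluteAbundanceTable
from .tables import RelativeAbundanceTable

TrendClass = Literal["concordant", "discordant", "unchanged"]


@dataclass(frozen=True)
class ChangeRecord:
    taxon: str
    rel_before: float
    rel_after: float
    abs_before: float
    abs_after: float
    rel_change_pp: float  # percentage points
    abs_change_pct: float | None  # percent of baseline; None if baseline 0
    trend_class: TrendClass


@dataclass(frozen=True)
class DiscordanceSummary:
    treatment: str
    region: str
    n_taxa: int
    n_concordant: int
    n_discordant: int
    n_unchanged: int
    records: tuple[ChangeRecord, ...] = field(repr=False)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "taxon\trel_before\trel_after\tabs_before\tabs_after\t"
                "rel_change_pp\tabs_change_pct\ttrend_class\n"
            )
            for r in self.records:
                abs_pct = "NA" if r.abs_change_pct is None else f"{r.abs_change_pct:.4f}"
                fh.write(
                    f"{r.taxon}\t{r.rel_before:.6g}\t{r.rel_after:.6g}\t"
                    f"{r.abs_before:.6g}\t{r.abs_after:.6g}\t"
                    f"{r.rel_change_pp:.4f}\t{abs_pct}\t{r.trend_class}\n"
                )

    def counts(self) -> dict[str, int]:
        return {
            "n_taxa": self.n_taxa,
            "n_concordant": self.n_concordant,
            "n_discordant": self.n_discordant,
            "n_unchanged": self.n_unchanged,
        }


def percent_change(before: float, after: float) -> float:
    """(after - before) / before * 100; negative values are decreases."""
    if before <= 0:
        raise ValueError(f"baseline must be positive, got {before}")
    if after < 0:
        raise ValueError(f"after must be non-negative, got {after}")
    return (after - before) / before * 100.0


def classify_trend_pair(
    rel_delta: float, abs_delta: float, eps: float = 0.0
) -> TrendClass:
    """Classify a (relative delta, absolute delta) pair by sign agreement.

    Deltas with magnitude <= eps count as zero.  Both zero, or exactly one
    zero, is ``unchanged``; matching nonzero signs is ``concordant``;
    opposite signs is ``discordant``.
    """
    rel_sign = 0 if abs(rel_delta) <= eps else int(math.copysign(1, rel_delta))
    abs_sign = 0 if abs(abs_delta) <= eps else int(math.copysign(1, abs_delta))
    if rel_sign == 0 or abs_sign == 0:
        return "unchanged"
    return "concordant" if rel_sign == abs_sign else "discordant"


def _single_sample_vector(table, kind: str) -> tuple[str, dict[str, float]]:
    if len(table.samples) != 1:
        raise ValueError(
            f"{kind} table must hold exactly one sample (a time point); "
            f"got {list(table.samples)}"
        )
    values = (
        table.proportions if isinstance(table, RelativeAbundanceTable)
        else table.abundances
    )
    return table.samples[0], {
        t.to_string(): float(values[0, j]) for j, t in enumerate(table.taxa)
    }


def count_discordant(
    rel0: RelativeAbundanceTable,
    rel1: RelativeAbundanceTable,
    abs0: AbsoluteAbundanceTable,
    abs1: AbsoluteAbundanceTable,
    eps: float = 0.0,
    treatment: str = "",
) -> DiscordanceSummary:
    """Per-taxon trend classification between two time points.

    Each table holds one sample (before/after).  Taxa are matched on the
    full lineage string over the union of all four tables; a taxon absent
    from a table contributes 0 there.  Records are ordered by taxon name.
    """
    if abs0.region != abs1.region:
        raise ValueError(
            f"region mismatch between time points: {abs0.region} vs {abs1.region}"
        )
    _, r0 = _single_sample_vector(rel0, "rel0")
    _, r1 = _single_sample_vector(rel1, "rel1")
    _, a0 = _single_sample_vector(abs0, "abs0")
    _, a1 = _single_sample_vector(abs1, "abs1")

    taxa = sorted(set(r0) | set(r1) | set(a0) | set(a1))
    records = []
    n_con = n_dis = n_unc = 0
    for taxon in taxa:
        rb, ra = r0.get(taxon, 0.0), r1.get(taxon, 0.0)
        ab, aa = a0.get(taxon, 0.0), a1.get(taxon, 0.0)
        rel_delta_pp = (ra - rb) * 100.0
        if ab > 0:
            abs_pct = percent_change(ab, aa)
        else:
            abs_pct = None  # newly appearing taxon: growth undefined as a percent
        abs_delta = aa - ab
        cls = classify_trend_pair(rel_delta_pp, abs_delta, eps=eps)
        if cls == "concordant":
            n_con += 1
        elif cls == "discordant":
            n_dis += 1
        else:
            n_unc += 1
        records.append(
            ChangeRecord(
                taxon=taxon,
                rel_before=rb,
                rel_after=ra,
                abs_before=ab,
                abs_after=aa,
                rel_change_pp=rel_delta_pp,
                abs_change_pct=abs_pct,
                trend_class=cls,
            )
        )
    return DiscordanceSummary(
        treatment=treatment,
        region=abs0.region,
        n_taxa=len(taxa),
        n_concordant=n_con,
        n_discordant=n_dis,
        n_unchanged=n_unc,
        records=tuple(records),
    )


# ---------------------------------------------------------------------------
# Sample clustering for heatmaps


@dataclass(frozen=True)
class ClusterResult:
    samples: tuple[str, ...]
    merges: np.ndarray = field(repr=False)  # scipy linkage matrix (n-1, 4)
    leaf_order: tuple[str, ...]

    def to_newick(self) -> str:
        n = len(self.samples)

        def node(i: int) -> str:
            if i < n:
                return self.samples[i]
            row = self.merges[i - n]
            height = row[2]
            left, right = int(row[0]), int(row[1])

            def branch(j: int) -> float:
                child_h = 0.0 if j < n else self.merges[j - n][2]
                return height - child_h

            return (
                f"({node(left)}:{branch(left):.6g},"
                f"{node(right)}:{branch(right):.6g})"
            )

        return node(2 * n - 2) + ";"


def cluster_samples(
    table,
    transform: str = "log10p1",
    metric: str = "euclidean",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative hierarchical clustering of samples for heatmap ordering.

    ``transform``: ``"log10p1"`` applies log10(x + 1) (sensible for absolute
    abundances spanning orders of magnitude), ``"none"`` uses raw values.
    Ties are broken deterministically by input order.
    """
    if isinstance(table, RelativeAbundanceTable):
        matrix = table.proportions
    elif isinstance(table, AbsoluteAbundanceTable):
        matrix = table.abundances
    else:
        raise TypeError(f"cannot cluster {type(table).__name__}")
    if len(table.samples) < 2:
        raise ValueError("clustering needs >= 2 samples")
    if transform == "log10p1":
        matrix = np.log10(matrix + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    distances = pdist(matrix, metric=metric)
    merges = hierarchy.linkage(distances, method=linkage)
    leaves = hierarchy.leaves_list(merges)
    return ClusterResult(
        samples=tuple(table.samples),
        merges=merges,
        leaf_order=tuple(table.samples[i] for i in leaves),
    )
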