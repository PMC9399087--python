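"""Reference TCR catalogs and clonotype distribution across lineages.

Four lineage catalogs are compiled by aggregating every clone detected in
samples of a given lineage — clones from different samples remain distinct
entries even when identical in sequence.  A clonotype's intra-lineage
frequency is the number of catalog clones encoding it divided by the
catalog size; its distribution across the catalogs normalizes those
frequencies to percentages summing to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .repertoire_core import CloneRecord, Clonotype, RepertoireSample


class ClonotypeNotFoundError(KeyError):
    """Clonotype absent from every catalog."""


@dataclass
class ReferenceCatalog:
    """Aggregated lineage-level clone pool (no cross-sample dedup)."""

    lineage_label: str
    clones: list[CloneRecord]

    @property
    def total_clones(self) -> int:
        return len(self.clones)

    def clonotype_count(self, clonotype: Clonotype) -> int:
        """Number of clones in the catalog encoding the clonotype."""
        return sum(1 for c in self.clones if c.clonotype == clonotype)

    def intra_lineage_frequency(self, clonotype: Clonotype) -> float:
        if self.total_clones == 0:
            return 0.0
        return self.clonotype_count(clonotype) / self.total_clones


@dataclass(frozen=True)
class CatalogDistribution:
    """One clonotype's normalized share across the four lineage catalogs."""

    clonotype: Clonotype
    labels: tuple[str, ...]
    intra_lineage_freq: tuple[float, ...]
    distribution_percent: tuple[float, ...]


def build_catalog(
    samples: Sequence[RepertoireSample], lineage_label: str
) -> ReferenceCatalog:
    """Aggregate all clones of same-lineage samples into one catalog.

    Samples must all carry the stated lineage; clone lists are concatenated
    without deduplication, so a clone observed in two mice contributes two
    entries.
    """
    if not samples:
        raise ValueError("cannot build a catalog from an empty sample list")
    mismatched = [
        s.sample_id for s in samples if s.lineage.value != str(lineage_label)
    ]
    if mismatched:
        raise ValueError(
            f"samples {mismatched} do not carry lineage {lineage_label!r}"
        )
    clones: list[CloneRecord] = []
    for s in samples:
        clones.extend(s.clones)
    return ReferenceCatalog(lineage_label=str(lineage_label), clones=clones)


def distribution_across_catalogs(
    clonotype: Clonotype, catalogs: Sequence[ReferenceCatalog]
) -> CatalogDistribution:
    """Normalize a clonotype's intra-lineage frequencies to percentages.

    ``distribution_percent[i] = 100 * freq_i / sum(freq)``; raises
    :class:`ClonotypeNotFoundError` when the clonotype occurs in no catalog.
    """
    if len(catalogs) != 4:
        raise ValueError(f"expected exactly 4 catalogs, got {len(catalogs)}")
    freqs = tuple(cat.intra_lineage_frequency(clonotype) for cat in catalogs)
    total = sum(freqs)
    if total == 0:
        raise ClonotypeNotFoundError(
            f"clonotype {clonotype} absent from all catalogs"
        )
    return CatalogDistribution(
        clonotype=clonotype,
        labels=tuple(cat.lineage_label for cat in catalogs),
        intra_lineage_freq=freqs,
        distribution_percent=tuple(100.0 * f / total for f in freqs),
    )
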