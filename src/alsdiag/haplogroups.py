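"""Multi-locus haplotype grouping with explicit heterozygote handling.

Samples that are homozygous at every configured locus are grouped by the
concatenated bases (e.g. ``ATCG``); samples with any 2-base ambiguity
code go into a single pooled ``heterozygous`` class, with every
phase-consistent haplotype listed so users can refine; gaps or >2-base
codes make a sample ``other``.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass

from .seq_core import GAP, AlignedSample, Alignment, expand_iupac

log = logging.getLogger(__name__)

HETEROZYGOUS = "heterozygous"
OTHER = "other"

#: Default loci: the four polymorphic positions in the 1770–1794 interval.
DEFAULT_LOCI = (1770, 1776, 1782, 1794)


@dataclass(frozen=True)
class HaploLocusSet:
    positions: tuple[int, ...] = DEFAULT_LOCI
    species_scope: str | None = None

    def __post_init__(self):
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("locus positions must be strictly increasing")


@dataclass(frozen=True)
class HaploAssignment:
    sample_id: str
    genotype: str
    group_label: str
    compatible_haplotypes: frozenset[str]
    reason: str = ""


def assign_haplogroup(
    sample: AlignedSample, alignment: Alignment, locus_set: HaploLocusSet
) -> HaploAssignment:
    if alignment.coord_map is None:
        raise ValueError("alignment has no coordinate map")
    for p in locus_set.positions:
        if p not in alignment.coord_map:
            raise ValueError(f"haplogroup locus {p} is not a mapped position")
    genotype = "".join(
        alignment.genotype_at(sample, p) for p in locus_set.positions
    )
    if GAP in genotype:
        return HaploAssignment(
            sample.sample_id, genotype, OTHER, frozenset(), reason="gap at locus"
        )
    expansions = [sorted(expand_iupac(ch)) for ch in genotype]
    if any(len(e) > 2 for e in expansions):
        return HaploAssignment(
            sample.sample_id, genotype, OTHER, frozenset(),
            reason=">2-fold ambiguity at locus",
        )
    if all(len(e) == 1 for e in expansions):
        return HaploAssignment(
            sample.sample_id, genotype, genotype, frozenset({genotype})
        )
    compatible = frozenset(
        "".join(combo) for combo in itertools.product(*expansions)
    )
    return HaploAssignment(
        sample.sample_id, genotype, HETEROZYGOUS, compatible
    )


def haplogroup_table(
    alignment: Alignment, locus_set: HaploLocusSet
) -> tuple[list[HaploAssignment], list[dict]]:
    """Assignments plus group × (species, origin) counts.

    Rows are sorted by group label then population; counts partition the
    scoped samples.
    """
    scoped = [
        s for s in alignment
        if locus_set.species_scope is None or s.species == locus_set.species_scope
    ]
    if not scoped:
        log.warning(
            "no samples in species scope %r", locus_set.species_scope
        )
        return [], []
    assignments = [assign_haplogroup(s, alignment, locus_set) for s in scoped]
    key_counts: Counter = Counter()
    for s, a in zip(scoped, assignments):
        key_counts[(a.group_label, s.species, s.origin)] += 1
    rows = [
        {"group": g, "species": sp, "origin": orig, "n_samples": n}
        for (g, sp, orig), n in sorted(key_counts.items())
    ]
    return assignments, rows
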