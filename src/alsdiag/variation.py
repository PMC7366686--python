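"""Heterozygote-aware site statistics, diagnostic SNPs and patristic summaries.

Conventions used throughout (they change counts, so read them):

* An ambiguity code contributes *each* of its resolved bases.  A single
  heterozygous sample therefore makes a site variable on its own, and at
  a parsimony-informative site it contributes one occurrence of each of
  its two bases.
* Gaps and ``N`` are excluded from allele sets and per-code counts
  (an ``N`` would trivially destroy diagnosticity).
* Diagnosticity is strict set-disjointness between the target species'
  resolved allele set and the union over all other species.  A relaxed
  "majority" verdict (disjoint after dropping codes seen in one sample
  only) is available separately and clearly labelled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seq_core import GAP, Alignment, Tree, expand_iupac

_EXCLUDED = {GAP, "N"}


@dataclass(frozen=True)
class SiteSummary:
    """Per-species IUPAC-code counts and resolved allele sets at one site."""

    reference_position: int
    counts: dict[str, Counter]
    allele_sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def species_string(self, species: str) -> str:
        """Compact ``C8/T4/Y12`` rendering of one species' counts."""
        c = self.counts.get(species, Counter())
        return "/".join(f"{code}{n}" for code, n in sorted(c.items()))


@dataclass(frozen=True)
class DiagnosticSite:
    reference_position: int
    target_species: str
    target_alleles: frozenset[str]
    complement_alleles: frozenset[str]
    verdict: str  # "diagnostic" | "not_diagnostic"

    @property
    def is_diagnostic(self) -> bool:
        return self.verdict == "diagnostic"


@dataclass(frozen=True)
class DistanceSummary:
    mean_interspecific: float
    mean_intraspecific: float
    n_inter_pairs: int
    n_intra_pairs: int


def _positions(alignment: Alignment) -> list[tuple[int, int]]:
    """(column, reported position) pairs; reference frame when mapped."""
    if alignment.coord_map is not None:
        return [(c, r) for c, r in alignment.coord_map.pairs]
    return [(c, c) for c in range(1, alignment.length + 1)]


def _resolved(code: str) -> frozenset[str]:
    if code in _EXCLUDED:
        return frozenset()
    return expand_iupac(code)


def site_summaries(alignment: Alignment) -> list[SiteSummary]:
    """One summary per mapped position; gaps and N never enter the counts."""
    if not all(s.species for s in alignment):
        missing = [s.sample_id for s in alignment if not s.species]
        raise ValueError(f"samples without species label: {missing}")
    out = []
    for col, ref in _positions(alignment):
        counts: dict[str, Counter] = {}
        alleles: dict[str, set[str]] = {}
        for sample in alignment:
            code = sample.sequence[col - 1]
            if code in _EXCLUDED:
                continue
            counts.setdefault(sample.species, Counter())[code] += 1
            alleles.setdefault(sample.species, set()).update(expand_iupac(code))
        out.append(
            SiteSummary(
                reference_position=ref,
                counts=counts,
                allele_sets={sp: frozenset(a) for sp, a in alleles.items()},
            )
        )
    return out


def variable_sites(alignment: Alignment) -> set[int]:
    """Positions with >=2 distinct resolved alleles across all samples."""
    if not alignment.samples:
        raise ValueError("empty alignment")
    out = set()
    for col, ref in _positions(alignment):
        alleles: set[str] = set()
        for code in alignment.column(col):
            alleles |= _resolved(code)
        if len(alleles) >= 2:
            out.add(ref)
    return out


def parsimony_informative_sites(alignment: Alignment) -> set[int]:
    """Positions where >=2 alleles each occur in >=2 samples.

    A heterozygous sample contributes one occurrence of each of its
    resolved bases.
    """
    if not alignment.samples:
        raise ValueError("empty alignment")
    out = set()
    for col, ref in _positions(alignment):
        occurrences: Counter = Counter()
        for code in alignment.column(col):
            for base in _resolved(code):
                occurrences[base] += 1
        if sum(1 for n in occurrences.values() if n >= 2) >= 2:
            out.add(ref)
    return out


def _verdicts(
    summaries: list[SiteSummary],
    target_species: str,
    drop_singletons: bool,
) -> list[DiagnosticSite]:
    all_species = {sp for s in summaries for sp in s.counts}
    if target_species not in all_species:
        raise ValueError(f"species {target_species!r} absent from summaries")
    if len(all_species) < 2:
        raise ValueError("need >=2 species for diagnostics")
    out = []
    for s in sorted(summaries, key=lambda s: s.reference_position):
        if drop_singletons:
            sets = {}
            for sp, cnt in s.counts.items():
                kept: set[str] = set()
                for code, n in cnt.items():
                    if n >= 2:
                        kept |= expand_iupac(code)
                sets[sp] = frozenset(kept)
        else:
            sets = s.allele_sets
        target = sets.get(target_species, frozenset())
        complement = frozenset().union(
            *(sets.get(sp, frozenset()) for sp in all_species if sp != target_species)
        )
        diagnostic = bool(target) and bool(complement) and not (target & complement)
        out.append(
            DiagnosticSite(
                reference_position=s.reference_position,
                target_species=target_species,
                target_alleles=target,
                complement_alleles=complement,
                verdict="diagnostic" if diagnostic else "not_diagnostic",
            )
        )
    return out


def find_diagnostic_sites(
    summaries: list[SiteSummary], target_species: str
) -> list[DiagnosticSite]:
    """Strict verdicts, sorted by position (one shared het kills a site)."""
    return _verdicts(summaries, target_species, drop_singletons=False)


def majority_diagnostic_sites(
    summaries: list[SiteSummary], target_species: str
) -> list[DiagnosticSite]:
    """Relaxed verdicts: codes seen in a single sample are dropped first.

    Operationally useful, but weaker than the strict report — label it as
    such in any output.
    """
    return _verdicts(summaries, target_species, drop_singletons=True)


def pairwise_difference_table(
    summaries: list[SiteSummary], species_a: str, species_b: str
) -> list[int]:
    """Positions where two species' resolved allele sets are disjoint."""
    all_species = {sp for s in summaries for sp in s.counts}
    for sp in (species_a, species_b):
        if sp not in all_species:
            raise ValueError(f"unknown species {sp!r}")
    out = []
    for s in sorted(summaries, key=lambda s: s.reference_position):
        a = s.allele_sets.get(species_a, frozenset())
        b = s.allele_sets.get(species_b, frozenset())
        if a and b and not (a & b):
            out.append(s.reference_position)
    return out


def patristic_summary(tree: Tree, species_of: dict[str, str]) -> DistanceSummary:
    """Mean within- and between-species leaf path-length sums.

    *species_of* maps every leaf label to its species; species sampled
    once contribute no within-species pairs.
    """
    leaves = tree.leaf_labels
    missing = [l for l in leaves if l not in species_of]
    if missing:
        raise ValueError(f"leaves without species metadata: {missing}")
    dists = tree.patristic_matrix()
    intra, inter = [], []
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            d = dists[(a, b)]
            (intra if species_of[a] == species_of[b] else inter).append(d)
    return DistanceSummary(
        mean_interspecific=sum(inter) / len(inter) if inter else float("nan"),
        mean_intraspecific=sum(intra) / len(intra) if intra else float("nan"),
        n_inter_pairs=len(inter),
        n_intra_pairs=len(intra),
    )
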