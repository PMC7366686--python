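"""Target-site ALS resistance genotyping from diploid IUPAC consensus codons.

The pipeline per catalog codon and sample:

1. extract the 3-character IUPAC genotype at the codon's reference
   positions;
2. enumerate every unordered diploid allele pair consistent with the
   genotype (``genotype_to_allele_pairs``);
3. pick one pair by the wild-type-preferring phasing rule
   (``select_phasing``);
4. translate both alleles and emit a :class:`SubstitutionCall` iff at
   least one allele encodes a non-wild amino acid.  Synonymous variants
   are suppressed, never reported.

Phasing rule: prefer the unique pair containing a synonymous wild-type
codon; among several wild-containing pairs prefer a mutant amino acid on
the previously-reported list; remaining ties are broken lexicographically
and flagged ``ambiguous_phasing`` only when the tied pairs disagree on
the call itself.  Substitutions absent from the previously-reported list
are flagged ``novel``.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field

import yaml
from Bio.Seq import Seq

from .seq_core import GAP, AlignedSample, Alignment, expand_iupac

log = logging.getLogger(__name__)

FLAG_NOVEL = "novel"
FLAG_AMBIGUOUS = "ambiguous_phasing"
FLAG_NO_WILD = "no_wild_allele"
FLAG_STOP = "stop_codon"


def translate(codon: str) -> str:
    """Standard-code translation of an unambiguous codon to one letter."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class CodonSpec:
    """One catalog entry: a standardized amino-acid position on the enzyme."""

    aa_number: int
    codon_start: int | None  # reference position of the first base; None = not locatable
    wild_codons: frozenset[str]
    wild_aa: str
    known_resistant: frozenset[str] = frozenset()
    enabled: bool = True
    note: str = ""

    def __post_init__(self):
        for c in self.wild_codons:
            if translate(c) != self.wild_aa:
                raise ValueError(
                    f"codon {self.aa_number}: wild codon {c} translates to "
                    f"{translate(c)}, not {self.wild_aa}"
                )

    @property
    def positions(self) -> tuple[int, int, int]:
        if self.codon_start is None:
            raise ValueError(f"codon {self.aa_number} has no coordinates")
        return (self.codon_start, self.codon_start + 1, self.codon_start + 2)


@dataclass
class ResistanceCatalog:
    codons: dict[int, CodonSpec]
    version: str = "builtin-1"

    def enabled(self) -> list[CodonSpec]:
        return [
            s for s in self.codons.values()
            if s.enabled and s.codon_start is not None
        ]

    def __getitem__(self, aa_number: int) -> CodonSpec:
        return self.codons[aa_number]


@dataclass(frozen=True)
class SubstitutionCall:
    sample_id: str
    species: str
    aa_number: int
    from_aa: str
    to_aa: str
    zygosity: str  # "homozygous" | "heterozygous"
    allele_pair: tuple[str, str]
    flags: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        return f"{self.from_aa}{self.aa_number}{self.to_aa}"


@dataclass(frozen=True)
class NoCall:
    """A codon that could not be genotyped, with the reason."""

    sample_id: str
    aa_number: int
    reason: str


@dataclass
class ResistanceSummary:
    per_species: dict[str, dict[str, int]]
    n_samples: int
    n_resistant: int
    n_calls: int
    n_het_calls: int
    frequencies: dict[str, float] = field(default_factory=dict)

    @property
    def het_fraction(self) -> float:
        return self.n_het_calls / self.n_calls if self.n_calls else float("nan")


def default_catalog() -> ResistanceCatalog:
    """Catalog of the standardized ALS resistance codons.

    Codons 122, 197, 574 and 653 carry reference coordinates for the two
    sequenced amplicons and are enabled.  205 and 654 have coordinates
    derived by codon offset from their neighbours and are disabled by
    default; 376 and 377 fall outside the amplicons and carry no
    coordinates at all.
    """
    aa = "ACGT"  # noqa: F841  (kept nearby for reading codon literals)
    codons = {
        122: CodonSpec(122, 349, frozenset({"GCA", "GCT"}), "A",
                       known_resistant=frozenset()),
        197: CodonSpec(197, 574, frozenset({"CCC", "CCT"}), "P",
                       known_resistant=frozenset({"S"})),
        205: CodonSpec(205, 598, frozenset({"GCA", "GCC", "GCG", "GCT"}), "A",
                       known_resistant=frozenset({"V"}), enabled=False,
                       note="coordinates derived by offset from codon 197"),
        376: CodonSpec(376, None, frozenset({"GAC", "GAT"}), "D",
                       known_resistant=frozenset({"E"}), enabled=False,
                       note="outside the sequenced amplicons"),
        377: CodonSpec(377, None, frozenset({"CGA", "CGC", "CGG", "CGT", "AGA", "AGG"}),
                       "R", known_resistant=frozenset({"H"}), enabled=False,
                       note="outside the sequenced amplicons"),
        574: CodonSpec(574, 1717, frozenset({"TGG"}), "W",
                       known_resistant=frozenset({"L"})),
        653: CodonSpec(653, 1954, frozenset({"AGC", "AGT"}), "S",
                       known_resistant=frozenset({"T", "N"})),
        654: CodonSpec(654, 1957, frozenset({"GGA", "GGC", "GGG", "GGT"}), "G",
                       known_resistant=frozenset({"E"}), enabled=False,
                       note="coordinates derived by offset from codon 653"),
    }
    return ResistanceCatalog(codons)


def load_catalog(path) -> ResistanceCatalog:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    codons = {}
    for entry in raw["codons"]:
        spec = CodonSpec(
            aa_number=int(entry["aa_number"]),
            codon_start=entry.get("codon_start"),
            wild_codons=frozenset(entry["wild_codons"]),
            wild_aa=entry["wild_aa"],
            known_resistant=frozenset(entry.get("known_resistant", [])),
            enabled=bool(entry.get("enabled", True)),
            note=entry.get("note", ""),
        )
        codons[spec.aa_number] = spec
    return ResistanceCatalog(codons, version=str(raw.get("version", "file")))


def dump_catalog(catalog: ResistanceCatalog, path) -> None:
    raw = {
        "version": catalog.version,
        "codons": [
            {
                "aa_number": s.aa_number,
                "codon_start": s.codon_start,
                "wild_codons": sorted(s.wild_codons),
                "wild_aa": s.wild_aa,
                "known_resistant": sorted(s.known_resistant),
                "enabled": s.enabled,
                "note": s.note,
            }
            for s in sorted(catalog.codons.values(), key=lambda s: s.aa_number)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


class UncallableGenotype(ValueError):
    """Genotype cannot be resolved into a diploid allele pair."""


def genotype_to_allele_pairs(genotype: str) -> frozenset[tuple[str, str]]:
    """All unordered diploid codon pairs consistent with an IUPAC genotype.

    Each position with a 2-base code can phase either way; a position
    with a 1-base code is fixed.  3- and 4-base codes are rejected: a
    diploid individual cannot carry three alleles, so they signal noise.
    """
    genotype = genotype.upper()
    if len(genotype) != 3:
        raise ValueError(f"genotype must be 3 characters, got {genotype!r}")
    if GAP in genotype:
        raise UncallableGenotype(f"gap in codon genotype {genotype!r}")
    per_pos = []
    for ch in genotype:
        bases = sorted(expand_iupac(ch))
        if len(bases) > 2:
            raise UncallableGenotype(
                f"{ch!r} in {genotype!r} resolves to >2 bases; "
                "not a diploid genotype"
            )
        per_pos.append(bases if len(bases) == 2 else bases * 2)
    pairs = set()
    # phase choice per position: which base goes on haplotype 1
    for choice in itertools.product((0, 1), repeat=3):
        h1 = "".join(per_pos[i][choice[i]] for i in range(3))
        h2 = "".join(per_pos[i][1 - choice[i]] for i in range(3))
        pairs.add(tuple(sorted((h1, h2))))
    return frozenset(pairs)


def _call_signature(pair: tuple[str, str], spec: CodonSpec):
    """What the call would be for one phasing, ignoring flags."""
    aas = tuple(translate(c) for c in pair)
    mutants = sorted({a for a in aas if a != spec.wild_aa})
    return tuple(mutants), tuple(sorted(aas))


def select_phasing(
    pairs: frozenset[tuple[str, str]], spec: CodonSpec
) -> tuple[tuple[str, str], frozenset[str]]:
    """Pick one allele pair by the wild-type-preferring rule; return flags."""
    if not pairs:
        raise ValueError("no allele pairs to phase")
    flags: set[str] = set()
    wild = [p for p in pairs if p[0] in spec.wild_codons or p[1] in spec.wild_codons]
    candidates = wild or sorted(pairs)
    if not wild:
        flags.add(FLAG_NO_WILD)
    if len(candidates) > 1:
        preferred = [
            p for p in candidates
            if any(
                translate(c) in spec.known_resistant
                for c in p if c not in spec.wild_codons
            )
        ]
        if preferred:
            candidates = preferred
    if len(candidates) > 1:
        # flag only if the surviving pairs disagree on the actual call
        if len({_call_signature(p, spec) for p in candidates}) > 1:
            flags.add(FLAG_AMBIGUOUS)
    chosen = min(candidates)
    return chosen, frozenset(flags)


def call_codon(
    sample: AlignedSample,
    alignment: Alignment,
    spec: CodonSpec,
) -> SubstitutionCall | NoCall | None:
    """Genotype one catalog codon for one sample.

    Returns a :class:`SubstitutionCall` for a nonsynonymous genotype, a
    :class:`NoCall` when the codon cannot be genotyped (gap, >2-fold
    code, unmapped positions), and ``None`` for wild-type or synonymous
    genotypes.
    """
    if alignment.coord_map is None:
        raise ValueError("alignment has no coordinate map")
    try:
        genotype = "".join(
            alignment.genotype_at(sample, p) for p in spec.positions
        )
    except KeyError as e:
        raise ValueError(
            f"codon {spec.aa_number} positions not in coordinate map: {e}"
        ) from None
    try:
        pairs = genotype_to_allele_pairs(genotype)
    except UncallableGenotype as e:
        log.info("no-call %s codon %d: %s", sample.sample_id, spec.aa_number, e)
        return NoCall(sample.sample_id, spec.aa_number, str(e))
    pair, flags = select_phasing(pairs, spec)
    aas = tuple(translate(c) for c in pair)
    mutants = sorted({a for a in aas if a != spec.wild_aa})
    if not mutants:
        return None  # wild type or synonymous variant — never emitted
    flags = set(flags)
    to_aa = mutants[0]
    if len(mutants) > 1:
        flags.add(FLAG_AMBIGUOUS)
    if "*" in mutants:
        to_aa = "*"
        flags.add(FLAG_STOP)
    if to_aa not in spec.known_resistant:
        flags.add(FLAG_NOVEL)
    zygosity = (
        "homozygous"
        if aas[0] == aas[1] and aas[0] != spec.wild_aa
        else "heterozygous"
    )
    return SubstitutionCall(
        sample_id=sample.sample_id,
        species=sample.species,
        aa_number=spec.aa_number,
        from_aa=spec.wild_aa,
        to_aa=to_aa,
        zygosity=zygosity,
        allele_pair=pair,
        flags=frozenset(flags),
    )


def call_dataset(
    alignment: Alignment,
    catalog: ResistanceCatalog,
    species_totals: dict[str, int] | None = None,
) -> tuple[list[SubstitutionCall], ResistanceSummary, list[NoCall]]:
    """Call every enabled catalog codon for every sample.

    A sample is counted resistant iff it has at least one substitution
    call.  *species_totals* (total samples sequenced per species, which
    may exceed the resistant panel) enables resistant-frequency output.
    """
    if not catalog.codons:
        raise ValueError("empty resistance catalog")
    calls: list[SubstitutionCall] = []
    nocalls: list[NoCall] = []
    for sample in alignment:
        for spec in sorted(catalog.enabled(), key=lambda s: s.aa_number):
            result = call_codon(sample, alignment, spec)
            if isinstance(result, SubstitutionCall):
                calls.append(result)
            elif isinstance(result, NoCall):
                nocalls.append(result)

    per_species: dict[str, dict[str, int]] = {}
    calls_by_sample = Counter((c.species, c.sample_id) for c in calls)
    for sample in alignment:
        row = per_species.setdefault(
            sample.species,
            {"n_samples": 0, "n_resistant": 0, "n_calls": 0,
             "n_het_calls": 0, "n_samples_with_two_or_more_calls": 0},
        )
        row["n_samples"] += 1
        n = calls_by_sample.get((sample.species, sample.sample_id), 0)
        if n >= 1:
            row["n_resistant"] += 1
        if n >= 2:
            row["n_samples_with_two_or_more_calls"] += 1
    for c in calls:
        per_species[c.species]["n_calls"] += 1
        if c.zygosity == "heterozygous":
            per_species[c.species]["n_het_calls"] += 1

    frequencies = {}
    if species_totals:
        for sp, total in species_totals.items():
            if sp in per_species and total > 0:
                frequencies[sp] = per_species[sp]["n_resistant"] / total

    summary = ResistanceSummary(
        per_species=per_species,
        n_samples=len(alignment),
        n_resistant=sum(r["n_resistant"] for r in per_species.values()),
        n_calls=len(calls),
        n_het_calls=sum(r["n_het_calls"] for r in per_species.values()),
        frequencies=frequencies,
    )
    return calls, summary, nocalls


def calls_to_rows(calls: list[SubstitutionCall]) -> list[dict]:
    """Tidy rows for TSV export, sorted by sample then codon."""
    return [
        {
            "sample_id": c.sample_id,
            "species": c.species,
            "aa_number": c.aa_number,
            "from_aa": c.from_aa,
            "to_aa": c.to_aa,
            "substitution": c.label,
            "zygosity": c.zygosity,
            "allele_1": c.allele_pair[0],
            "allele_2": c.allele_pair[1],
            "flags": ";".join(sorted(c.flags)),
        }
        for c in sorted(calls, key=lambda c: (c.sample_id, c.aa_number))
    ]
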