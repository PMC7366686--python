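"""Deterministic generator of alignments, metadata, trees and truth records.

The simulator plants exactly the structure the downstream stages look
for — fixed between-species differences, intraspecific polymorphism with
heterozygotes written as IUPAC codes, wild+mutant resistance diplotypes
at catalog codons, multi-locus haplotype groups — and emits a
:class:`SimTruth` record so every stage can be scored by exact
comparison.

Randomness comes from a single seed; each stage draws from its own
deterministically spawned substream, so adding a stage to a config never
perturbs the draws of earlier stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .haplogroups import HETEROZYGOUS, HaploAssignment
from .resistance import ResistanceCatalog, SubstitutionCall, translate
from .seq_core import (
    AlignedSample,
    Alignment,
    Tree,
    build_coord_map,
    collapse_to_iupac,
    tree_from_string,
    write_fasta,
    write_metadata_tsv,
)

log = logging.getLogger(__name__)

_STAGES = ("background", "polymorphism", "injections", "haplogroups", "tree")


@dataclass(frozen=True)
class SpeciesSpec:
    name: str
    n_samples: int
    populations: tuple[str, ...] = ("pop1",)


@dataclass(frozen=True)
class DiagnosticSiteSpec:
    """A site fixed to a different base in each species."""

    position: int
    base_by_species: dict[str, str]


@dataclass(frozen=True)
class PolymorphicSiteSpec:
    """Intraspecific polymorphism at one site of one species."""

    position: int
    species: str
    major: str
    minor: str
    minor_hom_freq: float
    het_freq: float


@dataclass(frozen=True)
class InjectionSpec:
    """A resistance mutation injected at a catalog codon."""

    aa_number: int
    mutant_codon: str
    zygosity: str  # "homozygous" | "heterozygous"
    species: str
    frequency: float
    population: str | None = None


@dataclass(frozen=True)
class HaplogroupSim:
    loci: tuple[int, ...]
    frequencies: dict[str, float]
    species: str
    het_fraction: float = 0.0


@dataclass(frozen=True)
class TreeSim:
    between_depth: float = 0.02
    within_depth: float = 0.001


@dataclass
class SimConfig:
    seed: int
    species: list[SpeciesSpec]
    length: int
    first_position: int = 1
    diagnostic_sites: list[DiagnosticSiteSpec] = field(default_factory=list)
    polymorphic_sites: list[PolymorphicSiteSpec] = field(default_factory=list)
    injections: list[InjectionSpec] = field(default_factory=list)
    haplogroups: HaplogroupSim | None = None
    catalog: ResistanceCatalog | None = None
    tree: TreeSim = field(default_factory=TreeSim)
    region_name: str = "sim"

    def validate(self) -> None:
        problems = []
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            problems.append("duplicate species names")
        lo, hi = self.first_position, self.first_position + self.length - 1

        def in_frame(pos):
            return lo <= pos <= hi

        for d in self.diagnostic_sites:
            if not in_frame(d.position):
                problems.append(f"diagnostic site {d.position} outside frame")
            for sp in d.base_by_species:
                if sp not in names:
                    problems.append(f"diagnostic site references unknown species {sp!r}")
        for p in self.polymorphic_sites:
            if not in_frame(p.position):
                problems.append(f"polymorphic site {p.position} outside frame")
            if p.species not in names:
                problems.append(f"polymorphic site references unknown species {p.species!r}")
            if not (0 <= p.minor_hom_freq <= 1 and 0 <= p.het_freq <= 1
                    and p.minor_hom_freq + p.het_freq <= 1):
                problems.append(f"polymorphic site {p.position}: bad frequencies")
        for inj in self.injections:
            if self.catalog is None or inj.aa_number not in self.catalog.codons:
                problems.append(f"injection references unknown codon {inj.aa_number}")
            else:
                spec = self.catalog[inj.aa_number]
                if spec.codon_start is None or not all(
                    in_frame(p) for p in spec.positions
                ):
                    problems.append(f"codon {inj.aa_number} outside frame")
                elif translate(inj.mutant_codon) == spec.wild_aa:
                    problems.append(
                        f"injection at codon {inj.aa_number} is synonymous"
                    )
            if not 0 <= inj.frequency <= 1:
                problems.append(f"injection frequency {inj.frequency} outside [0,1]")
            if inj.zygosity not in ("homozygous", "heterozygous"):
                problems.append(f"bad zygosity {inj.zygosity!r}")
            if inj.species not in names:
                problems.append(f"injection references unknown species {inj.species!r}")
        if self.haplogroups is not None:
            h = self.haplogroups
            if h.species not in names:
                problems.append(f"haplogroups reference unknown species {h.species!r}")
            if abs(sum(h.frequencies.values()) - 1.0) > 1e-9:
                problems.append("haplogroup frequencies must sum to 1")
            if not 0 <= h.het_fraction <= 1:
                problems.append("haplogroup het_fraction outside [0,1]")
            for pos in h.loci:
                if not in_frame(pos):
                    problems.append(f"haplogroup locus {pos} outside frame")
            lens = {len(hap) for hap in h.frequencies}
            if lens and lens != {len(h.loci)}:
                problems.append("haplotype strings must match the locus count")
        if self.tree.between_depth <= 2 * self.tree.within_depth:
            problems.append(
                "tree between_depth must exceed twice within_depth so "
                "intraspecific distances stay below interspecific ones"
            )
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class TruthSubstitution:
    aa_number: int
    to_aa: str
    zygosity: str


@dataclass
class TruthSample:
    species: str
    population: str
    haplogroup: str | None = None
    substitutions: list[TruthSubstitution] = field(default_factory=list)


@dataclass
class SimTruth:
    samples: dict[str, TruthSample]
    diagnostic_sites: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "samples": {k: asdict(v) for k, v in self.samples.items()},
                "diagnostic_sites": self.diagnostic_sites,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        raw = json.loads(text)
        samples = {}
        for sid, rec in raw["samples"].items():
            samples[sid] = TruthSample(
                species=rec["species"],
                population=rec["population"],
                haplogroup=rec["haplogroup"],
                substitutions=[
                    TruthSubstitution(**s) for s in rec["substitutions"]
                ],
            )
        return cls(samples=samples, diagnostic_sites=raw["diagnostic_sites"])


@dataclass
class SimResult:
    alignment: Alignment
    tree: Tree
    truth: SimTruth
    metadata: dict[str, dict[str, str]]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGES, children)}


def simulate(config: SimConfig) -> SimResult:
    """Generate one dataset; byte-identical for identical configs."""
    config.validate()
    rngs = _rngs(config.seed)
    lo = config.first_position

    bg = rngs["background"].choice(list("ACGT"), size=config.length)
    background = list("".join(bg))
    if config.catalog is not None:
        for spec in config.catalog.enabled():
            if lo <= spec.codon_start and spec.codon_start + 2 < lo + config.length:
                wild = min(spec.wild_codons)
                for off, base in enumerate(wild):
                    background[spec.codon_start - lo + off] = base

    # sample bookkeeping, ids stable in species order
    samples_meta: list[tuple[str, str, str]] = []  # id, species, population
    for sp in config.species:
        for k in range(sp.n_samples):
            pop = sp.populations[k % len(sp.populations)]
            sid = f"{sp.name.replace(' ', '_').replace('.', '')}_{k + 1:03d}"
            samples_meta.append((sid, sp.name, pop))

    seqs = {}
    truth_samples = {}
    for sid, species, pop in samples_meta:
        row = background.copy()
        for d in config.diagnostic_sites:
            if species in d.base_by_species:
                row[d.position - lo] = d.base_by_species[species]
        seqs[sid] = row
        truth_samples[sid] = TruthSample(species=species, population=pop)

    rng = rngs["polymorphism"]
    for p in config.polymorphic_sites:
        for sid, species, _pop in samples_meta:
            if species != p.species:
                continue
            u = rng.random()
            if u < p.het_freq:
                seqs[sid][p.position - lo] = collapse_to_iupac({p.major, p.minor})
            elif u < p.het_freq + p.minor_hom_freq:
                seqs[sid][p.position - lo] = p.minor
            else:
                seqs[sid][p.position - lo] = p.major

    rng = rngs["injections"]
    injected: set[tuple[str, int]] = set()
    for inj in config.injections:
        spec = config.catalog[inj.aa_number]
        for sid, species, pop in samples_meta:
            if species != inj.species:
                continue
            if inj.population is not None and pop != inj.population:
                continue
            if rng.random() >= inj.frequency:
                continue
            if (sid, inj.aa_number) in injected:
                continue
            injected.add((sid, inj.aa_number))
            start = spec.codon_start - lo
            wild = "".join(background[start : start + 3])
            for off in range(3):
                if inj.zygosity == "homozygous":
                    seqs[sid][start + off] = inj.mutant_codon[off]
                else:
                    seqs[sid][start + off] = collapse_to_iupac(
                        {wild[off], inj.mutant_codon[off]}
                    )
            truth_samples[sid].substitutions.append(
                TruthSubstitution(
                    aa_number=inj.aa_number,
                    to_aa=translate(inj.mutant_codon),
                    zygosity=inj.zygosity,
                )
            )

    rng = rngs["haplogroups"]
    if config.haplogroups is not None:
        h = config.haplogroups
        haplotypes = sorted(h.frequencies)
        probs = np.array([h.frequencies[x] for x in haplotypes])
        for sid, species, _pop in samples_meta:
            if species != h.species:
                continue
            hap1 = haplotypes[rng.choice(len(haplotypes), p=probs)]
            het = len(haplotypes) > 1 and rng.random() < h.het_fraction
            if het:
                others = [x for x in haplotypes if x != hap1]
                hap2 = others[rng.choice(len(others))]
            else:
                hap2 = hap1
            for pos, b1, b2 in zip(h.loci, hap1, hap2):
                seqs[sid][pos - lo] = collapse_to_iupac({b1, b2})
            truth_samples[sid].haplogroup = HETEROZYGOUS if het else hap1

    aligned = [
        AlignedSample(sid, species, pop, "".join(seqs[sid]))
        for sid, species, pop in samples_meta
    ]
    alignment = Alignment(aligned, region_name=config.region_name)
    alignment.coord_map = build_coord_map(alignment.samples[0], lo)

    tree = _simulate_tree(config, samples_meta, rngs["tree"])
    truth = SimTruth(
        samples=truth_samples,
        diagnostic_sites=sorted(d.position for d in config.diagnostic_sites),
    )
    metadata = {
        sid: {"species": species, "origin": pop}
        for sid, species, pop in samples_meta
    }
    log.info(
        "simulated %d samples x %d sites (%d injections)",
        len(aligned), config.length, len(injected),
    )
    return SimResult(alignment=alignment, tree=tree, truth=truth, metadata=metadata)


def _simulate_tree(config, samples_meta, rng) -> Tree:
    """Star-of-stars tree: species stems keep intra distances below inter."""
    within = config.tree.within_depth
    stem = config.tree.between_depth - within
    clades = []
    for sp in config.species:
        leaves = [
            f"{sid}:{within * (0.5 + 0.5 * rng.random()):.10f}"
            for sid, species, _pop in samples_meta
            if species == sp.name
        ]
        clades.append(f"({','.join(leaves)}):{stem:.10f}")
    return tree_from_string(f"({','.join(clades)});")


def write_outputs(result: SimResult, outdir) -> dict[str, str]:
    """Write FASTA / metadata TSV / newick / truth JSON; return the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "alignment.fasta"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "tree": os.path.join(outdir, "tree.nwk"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_fasta(result.alignment, paths["fasta"])
    write_metadata_tsv(result.alignment, paths["metadata"])
    with open(paths["tree"], "w") as fh:
        fh.write(result.tree.as_newick() + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write(result.truth.to_json() + "\n")
    return paths


@dataclass(frozen=True)
class RecoveryReport:
    precision: float
    recall: float
    zygosity_accuracy: float
    n_truth: int
    n_observed: int


def compare_substitution_calls(
    truth: SimTruth, calls: list[SubstitutionCall]
) -> RecoveryReport:
    """Exact-match scoring of calls against truth, keyed by (sample, codon)."""
    unknown = sorted({c.sample_id for c in calls} - set(truth.samples))
    if unknown:
        raise ValueError(f"calls reference unknown sample ids: {unknown}")
    truth_map = {
        (sid, s.aa_number): s
        for sid, rec in truth.samples.items()
        for s in rec.substitutions
    }
    call_map = {(c.sample_id, c.aa_number): c for c in calls}
    tp = [
        k for k, c in call_map.items()
        if k in truth_map and truth_map[k].to_aa == c.to_aa
    ]
    precision = len(tp) / len(call_map) if call_map else 1.0
    recall = len(tp) / len(truth_map) if truth_map else 1.0
    zyg_ok = sum(
        1 for k in tp if truth_map[k].zygosity == call_map[k].zygosity
    )
    zygosity_accuracy = zyg_ok / len(tp) if tp else 1.0
    return RecoveryReport(
        precision=precision,
        recall=recall,
        zygosity_accuracy=zygosity_accuracy,
        n_truth=len(truth_map),
        n_observed=len(call_map),
    )


def compare_diagnostic_sites(
    truth: SimTruth, found_positions: list[int] | set[int]
) -> RecoveryReport:
    found = set(found_positions)
    expected = set(truth.diagnostic_sites)
    tp = found & expected
    return RecoveryReport(
        precision=len(tp) / len(found) if found else 1.0,
        recall=len(tp) / len(expected) if expected else 1.0,
        zygosity_accuracy=float("nan"),
        n_truth=len(expected),
        n_observed=len(found),
    )


def compare_haplogroups(
    truth: SimTruth, assignments: list[HaploAssignment]
) -> RecoveryReport:
    unknown = sorted({a.sample_id for a in assignments} - set(truth.samples))
    if unknown:
        raise ValueError(f"assignments reference unknown sample ids: {unknown}")
    scored = [
        a for a in assignments
        if truth.samples[a.sample_id].haplogroup is not None
    ]
    ok = sum(
        1 for a in scored
        if a.group_label == truth.samples[a.sample_id].haplogroup
    )
    acc = ok / len(scored) if scored else 1.0
    return RecoveryReport(
        precision=acc, recall=acc, zygosity_accuracy=float("nan"),
        n_truth=len(scored), n_observed=len(assignments),
    )
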