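"""Sequence, metadata and tree I/O plus the IUPAC nucleotide algebra.

Everything downstream works in a shared coordinate frame: alignment
columns are 1-based, and a :class:`CoordinateMap` translates them to
1-based reference positions derived from one designated gap-bearing
reference sample (or supplied explicitly).  Reference positions are an
opaque frame — they are never computed from amino-acid numbers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: IUPAC nucleotide code -> set of resolved bases.  Gaps are not codes.
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COLLAPSE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPAND.items()}

GAP = "-"
ALPHABET = frozenset(IUPAC_EXPAND) | {GAP}


class AlphabetError(ValueError):
    """A character outside the IUPAC nucleotide alphabet (plus gap)."""


class AlignmentLengthError(ValueError):
    """Rows of one alignment have unequal lengths."""


def expand_iupac(code: str) -> frozenset[str]:
    """Resolve a single IUPAC code to its set of bases (``N`` -> all four)."""
    try:
        return IUPAC_EXPAND[code.upper()]
    except KeyError:
        raise AlphabetError(f"not an IUPAC nucleotide code: {code!r}") from None


def collapse_to_iupac(bases) -> str:
    """Inverse of :func:`expand_iupac`: the unique code for a base set."""
    key = frozenset(b.upper() for b in bases)
    if not key:
        raise AlphabetError("cannot collapse an empty base set")
    try:
        return IUPAC_COLLAPSE[key]
    except KeyError:
        raise AlphabetError(f"not a subset of {{A,C,G,T}}: {sorted(key)}") from None


@dataclass(frozen=True)
class AlignedSample:
    """One aligned sequence row with its sample metadata."""

    sample_id: str
    species: str
    origin: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        for i, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise AlphabetError(
                    f"sample {self.sample_id!r}: illegal character {ch!r} "
                    f"at column {i}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between non-gap alignment columns and reference positions.

    Both sides are 1-based; both sequences of coordinates are strictly
    increasing.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        cols = [c for c, _ in self.pairs]
        refs = [r for _, r in self.pairs]
        if cols != sorted(set(cols)) or refs != sorted(set(refs)):
            raise ValueError("coordinate map must be strictly increasing")
        object.__setattr__(self, "_col_to_ref", dict(self.pairs))
        object.__setattr__(self, "_ref_to_col", {r: c for c, r in self.pairs})

    def to_reference(self, column: int) -> int | None:
        """Reference position of an alignment column (None for gap columns)."""
        return self._col_to_ref.get(column)

    def to_column(self, reference_position: int) -> int:
        try:
            return self._ref_to_col[reference_position]
        except KeyError:
            raise KeyError(
                f"reference position {reference_position} is not mapped"
            ) from None

    def __contains__(self, reference_position: int) -> bool:
        return reference_position in self._ref_to_col

    def reference_positions(self) -> list[int]:
        return [r for _, r in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Alignment:
    """An ordered collection of equal-length :class:`AlignedSample` rows."""

    samples: list[AlignedSample]
    region_name: str = ""
    coord_map: CoordinateMap | None = None

    def __post_init__(self):
        if self.samples:
            n = len(self.samples[0])
            for s in self.samples:
                if len(s) != n:
                    raise AlignmentLengthError(
                        f"sample {s.sample_id!r} has length {len(s)}, "
                        f"expected {n}"
                    )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    @property
    def length(self) -> int:
        return len(self.samples[0]) if self.samples else 0

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def get(self, sample_id: str) -> AlignedSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def column(self, col: int) -> list[str]:
        """Characters of 1-based alignment column *col*, in sample order."""
        return [s.sequence[col - 1] for s in self.samples]

    def genotype_at(self, sample: AlignedSample, reference_position: int) -> str:
        if self.coord_map is None:
            raise ValueError("alignment has no coordinate map")
        return sample.sequence[self.coord_map.to_column(reference_position) - 1]

    def species_labels(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.species not in seen:
                seen.append(s.species)
        return seen


def build_coord_map(
    reference_sample: AlignedSample, first_reference_position: int = 1
) -> CoordinateMap:
    """Number the reference's non-gap columns consecutively from *first*."""
    pairs = []
    ref = first_reference_position
    for col, ch in enumerate(reference_sample.sequence, start=1):
        if ch != GAP:
            pairs.append((col, ref))
            ref += 1
    return CoordinateMap(tuple(pairs))


def _parse_header(header: str) -> tuple[str, str, str]:
    parts = header.split("|")
    sample_id = parts[0].strip()
    species = parts[1].strip() if len(parts) > 1 else ""
    origin = parts[2].strip() if len(parts) > 2 else ""
    return sample_id, species, origin


def read_fasta(path, region_name: str = "") -> Alignment:
    """Read an aligned FASTA; headers may carry ``sample_id|species|origin``."""
    samples = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sid, species, origin = _parse_header(rec.description)
        samples.append(AlignedSample(sid, species, origin, str(rec.seq)))
    log.info("read %d aligned records from %s", len(samples), path)
    return Alignment(samples, region_name=region_name)


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(
            Seq(s.sequence),
            id=f"{s.sample_id}|{s.species}|{s.origin}",
            description="",
        )
        for s in alignment
    ]
    SeqIO.write(records, str(path), "fasta")
    log.info("wrote %d aligned records to %s", len(records), path)


def read_metadata_tsv(path) -> dict[str, dict[str, str]]:
    """Read sample metadata (columns: sample_id, species, origin)."""
    out: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["sample_id"]] = {
                "species": row.get("species", "") or "",
                "origin": row.get("origin", "") or "",
            }
    log.info("read metadata for %d samples from %s", len(out), path)
    return out


def write_metadata_tsv(alignment: Alignment, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "species", "origin"])
        for s in alignment:
            w.writerow([s.sample_id, s.species, s.origin])


def apply_metadata(alignment: Alignment, metadata: dict[str, dict[str, str]]) -> Alignment:
    """Override FASTA-header metadata with a side table (table wins)."""
    samples = []
    for s in alignment:
        meta = metadata.get(s.sample_id)
        if meta is None:
            samples.append(s)
        else:
            samples.append(
                replace(s, species=meta["species"], origin=meta["origin"])
            )
    return Alignment(samples, alignment.region_name, alignment.coord_map)


@dataclass
class Tree:
    """A rooted or unrooted tree with non-negative branch lengths.

    Thin wrapper around a dendropy tree so callers never touch taxon
    namespaces directly.
    """

    _tree: dendropy.Tree = field(repr=False)

    def __post_init__(self):
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        defaulted = 0
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                edge.length = 0.0
                defaulted += 1
            elif edge.length < 0:
                raise ValueError(f"negative branch length {edge.length}")
        if defaulted:
            log.warning("defaulted %d missing branch lengths to 0", defaulted)

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def patristic_matrix(self) -> dict[tuple[str, str], float]:
        """All unordered leaf-pair path-length sums, keyed both ways."""
        pdm = self._tree.phylogenetic_distance_matrix()
        out: dict[tuple[str, str], float] = {}
        taxa = [leaf.taxon for leaf in self._tree.leaf_node_iter()]
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                d = pdm.patristic_distance(t1, t2)
                out[(t1.label, t2.label)] = d
                out[(t2.label, t1.label)] = d
        return out

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def read_newick(path) -> Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise ValueError(f"duplicate leaf labels in {path}: {e}") from None
    t = Tree(tree)
    log.info("read tree with %d leaves from %s", len(t.leaf_labels), path)
    return t


def tree_from_string(newick: str) -> Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    return Tree(tree)
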