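import random

import pytest

from alsdiag.seq_core import AlignedSample, Alignment, build_coord_map

IUPAC_2FOLD = "RYSWKM"


def make_alignment(columns, species=None, first_position=1):
    """Build an alignment from per-sample rows given as column tuples.

    *columns* is a list of per-site tuples (one character per sample).
    """
    n = len(columns[0])
    species = species or ["sp"] * n
    rows = ["".join(col[i] for col in columns) for i in range(n)]
    samples = [
        AlignedSample(f"s{i + 1}", species[i], "", rows[i]) for i in range(n)
    ]
    aln = Alignment(samples)
    aln.coord_map = build_coord_map(samples[0], first_position)
    return aln


def random_alignment(rng: random.Random, max_species=4, max_samples=6, length=20):
    """Random IUPAC alignment with species labels, gap-free reference."""
    n_species = rng.randint(2, max_species)
    samples = []
    sid = 0
    for sp in range(n_species):
        for _ in range(rng.randint(2, max_samples)):
            sid += 1
            seq = "".join(
                rng.choice("ACGTACGTACGT" + IUPAC_2FOLD + "N-")
                for _ in range(length)
            )
            samples.append(
                AlignedSample(f"s{sid}", f"species{sp}", "", seq)
            )
    # gap-free reference row keeps every column mapped
    samples[0] = AlignedSample(
        samples[0].sample_id, samples[0].species, "",
        "".join(rng.choice("ACGT") for _ in range(length)),
    )
    aln = Alignment(samples)
    aln.coord_map = build_coord_map(samples[0], 1)
    return aln


def random_tree_newick(rng: random.Random, n_leaves: int) -> str:
    """Random binary topology with uniform branch lengths."""
    nodes = [f"L{i}:{rng.uniform(0.01, 2.0):.6f}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        if len(nodes) == 0:
            nodes.append(f"({a},{b});")
        else:
            nodes.append(f"({a},{b}):{rng.uniform(0.01, 2.0):.6f}")
    return nodes[0] if nodes[0].endswith(";") else nodes[0] + ";"


@pytest.fixture
def rng():
    return random.Random(20240901)
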