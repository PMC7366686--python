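"""Bundled worked-example panels used by the test suite and documentation.

Two small hand-curated datasets, reconstructed from published per-site
genotype tallies, are emitted as ordinary :class:`~alsdiag.seq_core.Alignment`
objects in a gap-free reference frame starting at position 349:

* ``snp_comparison_panel`` — six closely related species (55 samples)
  with per-position IUPAC genotype counts at 41 polymorphic positions of
  two amplicons; everything else is constant background.
* ``resistance_panel`` — 25 resistant individuals of three species with
  their genotypes at the four callable resistance codons (122, 197, 574,
  653); all other positions are wild-type background.

Counts in the tally cells use the compact ``C8/T4/Y12`` dialect: a bare
code means every sample of that species carries it; a trailing integer
gives the sample count; a single unnumbered code absorbs the remainder.
"""

from __future__ import annotations

import re

from .seq_core import AlignedSample, Alignment, build_coord_map

FIRST_POSITION = 349

SPECIES = (
    ("A. tuberculatus", "tub", 24),
    ("A. arenicola", "are", 2),
    ("A. palmeri", "pal", 17),
    ("A. spinosus", "spi", 9),
    ("A. dubius", "dub", 1),
    ("A. hybridus", "hyb", 2),
)

# position -> per-species tally cells, ordered as SPECIES
SNP_PANEL_CELLS: dict[int, tuple[str, ...]] = {
    # amplicon covering codons 122/197/205
    351: ("T", "A", "A", "A", "A", "A"),
    363: ("C", "C", "C", "C", "Y", "T"),
    465: ("T", "C", "C", "C", "C", "C"),
    495: ("G/S1", "A/R", "A/R5", "A", "A", "A"),
    513: ("T", "T/C", "T/C3/Y8", "T", "T", "T"),
    516: ("C", "T", "T", "T", "T", "T"),
    520: ("T", "C", "C", "C", "C", "C"),
    531: ("A", "A/R", "A/R7/G2", "A", "A", "A"),
    549: ("G", "G", "G/T1/K2", "G", "K", "T"),
    552: ("T", "T/Y", "T/C3/Y6", "T", "T", "T"),
    574: ("C/M2", "Y/M", "C/Y2/M1", "C", "C", "C"),
    575: ("C", "C/Y", "C", "C", "C", "C"),
    576: ("T", "C", "C", "C", "C", "C"),
    579: ("G/A3/R3", "G", "G", "G", "G", "G"),
    603: ("T", "T/Y", "T/C3/Y6", "T", "T", "T"),
    615: ("T", "A", "A", "A", "A", "A"),
    636: ("A", "C", "C", "C", "C", "C"),
    642: ("T", "T", "T/C1/Y1", "T", "Y", "C"),
    678: ("C", "T", "T", "T", "T", "T"),
    # amplicon covering codons 653/654
    1435: ("A", "A", "G", "G", "G", "G"),
    1482: ("C8/T4/Y12", "T", "C", "C", "C", "C"),
    1503: ("C23/M1", "C", "C/T1/Y1", "C5/T4", "C", "C"),
    1551: ("A", "A", "A14/W3", "A4/T5", "W", "A"),
    1554: ("C", "C", "T16/Y1", "T", "T", "T"),
    1587: ("G17/A1/R6", "R", "G16/R1", "G", "G", "G"),
    1602: ("T23/Y1", "T", "T15/Y2", "C5/T4", "T", "T"),
    1611: ("T6/C7/Y11", "Y", "T", "T", "T", "T"),
    1656: ("G/R6", "R", "G", "G", "R", "A"),
    1770: ("T6/A11/W7", "W", "T", "T", "T", "T"),
    1776: ("T11/W8/A5", "W", "T", "T", "T", "T"),
    1782: ("C11/M8/A5", "M", "C", "C", "C", "C"),
    1794: ("G19/A3/R2", "G", "G", "G", "G", "G"),
    1809: ("T", "T", "C13/Y4", "C", "T", "T"),
    1836: ("C", "C", "T14/Y2/C1", "T", "C", "C"),
    1899: ("A", "A", "G", "G", "R", "G"),
    1955: ("G19/R4/C1", "R", "G", "G", "G", "G"),
    1956: ("C17/Y5/S1/T1", "Y", "C16/T1", "C", "C", "C"),
    1974: ("C18/T1/Y5", "Y", "C15/Y2", "C", "C", "C"),
    1980: ("C", "C", "C", "C", "M", "A"),
    1983: ("A", "A", "A12/T4/W1", "A", "A", "A"),
    2016: ("T", "T", "T11/C5/Y1", "T", "C", "T"),
}

# species, origin, sample id, codon genotypes at 122 / 197 / 574 / 653
RESISTANCE_PANEL_ROWS: tuple[tuple[str, str, str, str, str, str, str], ...] = (
    ("A. palmeri", "Beijing", "120914_7_pop7", "GCA", "CCC", "TKG", "AGC"),
    ("A. palmeri", "Beijing", "7229", "GCA", "CCC", "TTG", "AGC"),
    ("A. palmeri", "Beijing", "120914_11_pop8", "GCA", "YCC", "TGG", "AGC"),
    ("A. palmeri", "Beijing", "120914_12_pop8", "GCA", "YCC", "TGG", "AGC"),
    ("A. palmeri", "Beijing", "120914_16_pop10", "GCA", "YCC", "TGG", "AGC"),
    ("A. palmeri", "Guangxi", "19", "GCA", "CCC", "TKG", "AGC"),
    ("A. palmeri", "Hebei", "180910", "GCA", "YCC", "TGG", "AGC"),
    ("A. palmeri", "Jiangsu", "12167", "GCA", "MCC", "TGG", "AGC"),
    ("A. tuberculatus", "Fujian", "11963", "GCT", "CCT", "TKG", "AGY"),
    ("A. tuberculatus", "Fujian", "12010", "AAT", "CCT", "TGG", "AGC"),
    ("A. tuberculatus", "Fujian", "12008", "RMT", "CCT", "TKG", "AGC"),
    ("A. tuberculatus", "Fujian", "12011", "AAT", "CCT", "TGG", "AGC"),
    ("A. tuberculatus", "Fujian", "12012", "GCT", "CCT", "TKG", "AGT"),
    ("A. tuberculatus", "Fujian", "12015", "AAT", "CCT", "TGG", "AGC"),
    ("A. tuberculatus", "Fujian", "09-014", "GCT", "MCT", "TGG", "AGC"),
    ("A. tuberculatus", "Fujian", "12022", "RMT", "CCT", "TKG", "AGC"),
    ("A. tuberculatus", "Jiangsu", "6", "GCT", "CCT", "TGG", "ARS"),
    ("A. tuberculatus", "Jiangsu", "12194", "GCT", "CCT", "TKG", "ARY"),
    ("A. tuberculatus", "Jiangsu", "12165", "GCT", "MCT", "TKG", "AGC"),
    ("A. tuberculatus", "Jiangsu", "2012009", "GCT", "CCT", "TGG", "ACC"),
    ("A. tuberculatus", "Jiangsu", "2012021", "GCT", "CCT", "TGG", "ARC"),
    ("A. tuberculatus", "Shandong", "12571", "GCT", "CCT", "TTG", "AGC"),
    ("A. tuberculatus", "Shandong", "12575", "GCT", "CCT", "TKG", "ARC"),
    ("A. tuberculatus", "Shandong", "12576", "GCT", "CCT", "TKG", "AGC"),
    ("A. arenicola", "Hebei", "HB", "GCA", "MYC", "TGG", "ASY"),
)

#: Total samples sequenced per species, the denominators behind
#: resistant-biotype frequencies (16/29, 8/29, 1/1).
RESISTANCE_PANEL_SPECIES_TOTALS = {
    "A. tuberculatus": 29,
    "A. palmeri": 29,
    "A. arenicola": 1,
}

_CODON_STARTS = (349, 574, 1717, 1954)

_TOKEN = re.compile(r"^([ACGTRYSWKMBDHVN])(\d*)$")


def parse_tally_cell(cell: str, n_samples: int) -> list[tuple[str, int]]:
    """Expand a ``C8/T4/Y12`` tally cell into explicit (code, count) pairs.

    Unnumbered codes share the remainder after numbered codes are taken,
    as evenly as possible with earlier codes taking the excess.
    """
    tokens = []
    for tok in cell.split("/"):
        m = _TOKEN.match(tok)
        if not m:
            raise ValueError(f"bad tally token {tok!r} in cell {cell!r}")
        code, num = m.groups()
        tokens.append((code, int(num) if num else None))
    fixed = sum(n for _, n in tokens if n is not None)
    free = [i for i, (_, n) in enumerate(tokens) if n is None]
    remainder = n_samples - fixed
    if remainder < 0 or (free and remainder < len(free)) or (not free and remainder):
        raise ValueError(
            f"cell {cell!r} inconsistent with {n_samples} samples"
        )
    out = [list(t) for t in tokens]
    for rank, i in enumerate(free):
        share = remainder // len(free) + (1 if rank < remainder % len(free) else 0)
        out[i][1] = share
    return [(code, n) for code, n in out if n]


def _frame_length() -> int:
    return max(SNP_PANEL_CELLS) - FIRST_POSITION + 1


def snp_comparison_panel() -> Alignment:
    """Six-species alignment realizing the per-site genotype tallies."""
    length = _frame_length()
    samples = []
    for species, prefix, n in SPECIES:
        rows = [["A"] * length for _ in range(n)]
        for pos, cells in SNP_PANEL_CELLS.items():
            cell = cells[[s[0] for s in SPECIES].index(species)]
            col = pos - FIRST_POSITION
            i = 0
            for code, count in parse_tally_cell(cell, n):
                for _ in range(count):
                    rows[i][col] = code
                    i += 1
        for k, row in enumerate(rows, start=1):
            samples.append(
                AlignedSample(f"{prefix}{k:02d}", species, "", "".join(row))
            )
    aln = Alignment(samples, region_name="ALS")
    aln.coord_map = build_coord_map(aln.samples[0], FIRST_POSITION)
    return aln


def resistance_panel() -> Alignment:
    """25-sample alignment carrying the resistance-codon genotypes.

    Background outside the four codons is a constant wild-type filler;
    the codon triplets are written verbatim from the curated rows.
    """
    length = 1956 - FIRST_POSITION + 1
    samples = []
    for species, origin, sid, g122, g197, g574, g653 in RESISTANCE_PANEL_ROWS:
        row = ["A"] * length
        for start, genotype in zip(_CODON_STARTS, (g122, g197, g574, g653)):
            for offset, ch in enumerate(genotype):
                row[start - FIRST_POSITION + offset] = ch
        samples.append(AlignedSample(sid, species, origin, "".join(row)))
    aln = Alignment(samples, region_name="ALS")
    aln.coord_map = build_coord_map(aln.samples[0], FIRST_POSITION)
    return aln
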