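"""Promoter cis-regulatory element scanning and aggregation.

A local stand-in for web-database promoter annotation: 1000-bp upstream
sequences are scanned against a dictionary of IUPAC consensus motifs, one
or more consensus strings per element class (abscisic-acid responsive,
MYB binding site, light responsive, ...), and occurrence counts are
aggregated per gene and hexaploid-wheat genome set (A/B/D chromosome
groups) into a summary table with marginal sums.

Matching rules (fixed, since database semantics are undocumented):
occurrences may overlap; both strands are scanned; a palindromic
consensus (equal to its own IUPAC reverse complement) is counted once per
position, not once per strand; ``N`` in a *sequence* never matches
anything, while ``N`` in a *motif* matches any base.

The bundled :data:`DEFAULT_MOTIF_CLASSES` dictionary covers the sixteen
element classes with curated PlantCARE-style consensus strings.  It is an
approximation assembled for local scanning; counts from live database
versions will differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "DEFAULT_MOTIF_CLASSES",
    "PromoterRecord",
    "MotifSummary",
    "reverse_complement",
    "is_palindromic",
    "validate_dictionary",
    "parse_promoters",
    "write_promoters",
    "scan_motifs",
    "aggregate_summary",
    "read_motif_tsv",
    "write_motif_tsv",
    "read_plantcare_export",
]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# Curated IUPAC consensus strings for the sixteen element classes reported
# in wheat antioxidant-gene promoters.  PlantCARE-style approximations.
DEFAULT_MOTIF_CLASSES: dict[str, tuple[str, ...]] = {
    "circadian control": ("CAANNNNATC",),
    "endosperm expression": ("TGAGTCA", "GTCAT"),
    "abscisic acid responsive": ("TACGTG",),
    "auxin-responsive": ("AACGAC", "GGTCCAT"),
    "cell cycle regulation": ("CAACGGATA",),
    "defense and stress responsive": ("ATTTTCTTCA",),
    "ethylene-responsive": ("ATTTCAAA",),
    "fungal elicitor": ("TTGACC",),
    "gibberellin-responsive": ("TCTGTTG", "CCTTTTG", "TATCCCA"),
    "heat stress responsive": ("AAAAAATTTC",),
    "light responsive": ("GATAAGATT", "GGTTAA", "ATCTATTCGTAT"),
    "low-temperature responsive": ("CCGAAA",),
    "MeJA-responsive": ("CGTCA",),
    "meristem specific activation": ("GCCACT",),
    "MYB binding site": ("CAACTG", "CAACCA"),
    "salicylic acid responsive": ("CCATCTTTTT",),
}

_HEADER_RE = re.compile(r"^([^|]+)\|(\d+)([ABD])\|(.+)$")


def reverse_complement(motif: str) -> str:
    """IUPAC-aware reverse complement of a consensus string."""
    return "".join(_COMPLEMENT[c] for c in reversed(motif.upper()))


def is_palindromic(motif: str) -> bool:
    """True if the consensus equals its own IUPAC reverse complement."""
    return motif.upper() == reverse_complement(motif)


def validate_dictionary(dictionary: dict) -> None:
    seen = set()
    for cls, motifs in dictionary.items():
        if cls in seen:
            raise ValueError(f"duplicate element class {cls!r}")
        seen.add(cls)
        for motif in motifs:
            bad = set(motif.upper()) - set(IUPAC_CODES)
            if bad:
                raise ValueError(
                    f"motif {motif!r} of class {cls!r} has non-IUPAC symbols {bad}"
                )


@dataclass(frozen=True)
class PromoterRecord:
    """One upstream promoter sequence with its genomic provenance."""

    gene: str
    chromosome: str
    seq_id: str
    sequence: str

    @property
    def genome_set(self) -> str:
        return self.chromosome[-1]

    def header(self) -> str:
        return f"{self.gene}|{self.chromosome}|{self.seq_id}"


def parse_promoters(source) -> list[PromoterRecord]:
    """Read promoter FASTA with ``>GENE|5A|id`` headers.

    ``source`` is a path or open text handle.  Raises ``ValueError`` with
    the record index on an unparseable header or non-DNA sequence.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(source, "fasta"), start=1):
        m = _HEADER_RE.match(rec.description.strip())
        if not m:
            raise ValueError(
                f"record {i}: header {rec.description!r} does not match "
                "'GENE|<chromosome e.g. 5A>|<id>'"
            )
        gene, chrom_num, genome, seq_id = m.groups()
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"record {i} ({rec.id}): non-DNA symbols {bad}")
        records.append(
            PromoterRecord(
                gene=gene, chromosome=f"{chrom_num}{genome}",
                seq_id=seq_id, sequence=seq,
            )
        )
    return records


def write_promoters(records, path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.header(), description="") for r in records
    ]
    SeqIO.write(seq_records, path, "fasta")


def _motif_regex(motif: str) -> re.Pattern:
    # N in the sequence must never match, so character classes list concrete
    # bases only; lookahead makes overlapping occurrences countable.
    body = "".join(f"[{IUPAC_CODES[c]}]" for c in motif.upper())
    return re.compile(f"(?=({body}))")


def count_occurrences(sequence: str, motif: str) -> int:
    """Occurrences of one IUPAC consensus in a sequence, both strands.

    Overlaps allowed; palindromic consensi counted once per position.
    """
    seq = sequence.upper()
    n_fwd = len(_motif_regex(motif).findall(seq))
    if is_palindromic(motif):
        return n_fwd
    n_rev = len(_motif_regex(reverse_complement(motif)).findall(seq))
    return n_fwd + n_rev


def scan_motifs(record_or_seq, dictionary: dict) -> dict[str, int]:
    """Per-class occurrence counts for one promoter sequence."""
    validate_dictionary(dictionary)
    seq = (
        record_or_seq.sequence
        if isinstance(record_or_seq, PromoterRecord)
        else str(record_or_seq)
    )
    return {
        cls: sum(count_occurrences(seq, m) for m in motifs)
        for cls, motifs in dictionary.items()
    }


@dataclass
class MotifSummary:
    """Counts per (gene, genome set, element class) with marginal sums."""

    counts: pd.DataFrame  # tidy: gene, genome_set, element_class, count
    classes: tuple[str, ...]

    def to_table(self) -> pd.DataFrame:
        """Wide table: rows (gene, genome set) plus per-gene Sum rows,
        columns element classes plus a Sum column."""
        wide = (
            self.counts.pivot_table(
                index=["gene", "genome_set"],
                columns="element_class",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(columns=list(self.classes), fill_value=0)
        )
        blocks = []
        for gene, block in wide.groupby(level="gene", sort=True):
            total = block.sum(axis=0).to_frame().T
            total.index = pd.MultiIndex.from_tuples(
                [(gene, "Sum")], names=["gene", "genome_set"]
            )
            blocks.append(pd.concat([block, total]))
        table = pd.concat(blocks)
        table["Sum"] = table.sum(axis=1)
        return table

    def gene_totals(self) -> pd.Series:
        return self.counts.groupby("gene")["count"].sum()


def aggregate_summary(records, per_record_counts, classes=None) -> MotifSummary:
    """Group per-sequence counts by (gene, genome set).

    ``per_record_counts`` is one class->count mapping per record, in
    record order; the result is invariant to that order.
    """
    if classes is None:
        classes = tuple(per_record_counts[0]) if per_record_counts else ()
    rows = []
    for rec, counts in zip(records, per_record_counts, strict=True):
        for cls in classes:
            rows.append(
                {
                    "gene": rec.gene,
                    "genome_set": rec.genome_set,
                    "element_class": cls,
                    "count": int(counts.get(cls, 0)),
                }
            )
    tidy = (
        pd.DataFrame(rows, columns=["gene", "genome_set", "element_class", "count"])
        .groupby(["gene", "genome_set", "element_class"], as_index=False, sort=True)
        .sum()
    )
    return MotifSummary(counts=tidy, classes=tuple(classes))


def read_motif_tsv(path) -> dict[str, tuple[str, ...]]:
    """Read a ``class<TAB>IUPAC`` dictionary; repeated classes accumulate."""
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'class<TAB>motif'")
        cls, motif = parts[0].strip(), parts[1].strip().upper()
        out.setdefault(cls, []).append(motif)
    dictionary = {cls: tuple(motifs) for cls, motifs in out.items()}
    validate_dictionary(dictionary)
    return dictionary


def write_motif_tsv(dictionary: dict, path) -> None:
    lines = [
        f"{cls}\t{motif}" for cls, motifs in dictionary.items() for motif in motifs
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_plantcare_export(path, class_map: dict) -> pd.DataFrame:
    """Ingest a PlantCARE-style export instead of scanning.

    Expected tab-separated columns: ``sequence_id``, ``site``,
    ``position``, ``strand`` (header row required).  ``class_map`` maps
    site names to element classes; unmapped sites are dropped.  Returns a
    tidy frame with columns sequence_id, element_class, count.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"sequence_id", "site"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"PlantCARE export missing columns: {sorted(missing)}")
    table = table[table["site"].isin(class_map)]
    table = table.assign(element_class=table["site"].map(class_map))
    return (
        table.groupby(["sequence_id", "element_class"])
        .size()
        .rename("count")
        .reset_index()
    )
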