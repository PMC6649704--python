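"""Genetic codes, CDS containers and readers for the formats the pipeline consumes.

The analyses downstream (repeat detection, phase classification, constraint
calculus) all operate on in-frame protein-coding sequences.  This module
provides the invariant-checked container for one CDS, the genetic-code object
with its degeneracy-class partition, and pooled codon/dipeptide statistics.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: all 64 codons in lexicographic order
CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")

STOP_SYMBOL = "*"


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T}."""


class FrameError(ValueError):
    """Sequence length or content is inconsistent with a single reading frame."""


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of a strict-ACGT DNA string."""
    if not set(seq) <= DNA_ALPHABET:
        bad = sorted(set(seq) - DNA_ALPHABET)
        raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid map with its synonymous-family partition.

    Parameters
    ----------
    table_id
        NCBI translation table number.  The default throughout the package
        is table 5, the invertebrate mitochondrial code (ATA→Met, AGA/AGG→Ser,
        TGA→Trp; stops TAA/TAG).
    """

    table_id: int
    codon_to_aa: Mapping[str, str] = field(repr=False)
    stop_codons: frozenset = field(repr=False)

    @classmethod
    def from_ncbi(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: aa for c, aa in table.forward_table.items()}
        for stop in table.stop_codons:
            mapping[stop] = STOP_SYMBOL
        if len(mapping) != 64:
            raise ValueError(f"incomplete codon table {table_id}")
        return cls(
            table_id=table_id,
            codon_to_aa=dict(mapping),
            stop_codons=frozenset(table.stop_codons),
        )

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in CODONS if c not in self.stop_codons)

    @property
    def amino_acids(self) -> tuple:
        return tuple(sorted({aa for aa in self.codon_to_aa.values() if aa != STOP_SYMBOL}))

    def family(self, aa: str) -> tuple:
        """Synonymous codon family of one amino acid, in CODONS order."""
        fam = tuple(c for c in CODONS if self.codon_to_aa[c] == aa)
        if not fam:
            raise ValueError(f"amino acid {aa!r} not encodable in table {self.table_id}")
        return fam

    @property
    def degeneracy_classes(self) -> dict:
        """Map family size -> list of amino acids with that many synonymous codons."""
        out: dict = {}
        for aa in self.amino_acids:
            out.setdefault(len(self.family(aa)), []).append(aa)
        return out

    def translate(self, seq: str, allow_terminal_stop: bool = True) -> str:
        """Codon-by-codon translation of an in-frame CDS.

        An internal stop raises :class:`FrameError` — it identifies the CDS as
        mis-framed.  A single terminal stop is tolerated by default and
        rendered as ``*``.
        """
        if len(seq) % 3:
            raise FrameError(f"length {len(seq)} not divisible by 3")
        if not set(seq) <= DNA_ALPHABET:
            raise AlphabetError("non-ACGT characters in CDS")
        aas = [self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3)]
        internal = aas[:-1] if allow_terminal_stop else aas
        if STOP_SYMBOL in internal:
            pos = internal.index(STOP_SYMBOL)
            raise FrameError(f"internal stop codon at codon {pos}")
        if not allow_terminal_stop and aas and aas[-1] == STOP_SYMBOL:
            raise FrameError("terminal stop codon present")
        return "".join(aas)


def translate(seq: str, code: GeneticCode, allow_terminal_stop: bool = True) -> str:
    """Functional wrapper around :meth:`GeneticCode.translate`."""
    return code.translate(seq, allow_terminal_stop=allow_terminal_stop)


@dataclass(eq=False)  # identity semantics: records serve as dict keys in scans
class CdsRecord:
    """One protein-coding gene, always stored as the coding strand in frame 0.

    ``genome_coords`` is 0-based half-open on the source genome; GenBank input
    (1-based inclusive) is converted on read.
    """

    species: str
    gene: str
    seq: str
    genome_coords: tuple | None = None  # (start, end, strand)
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not set(self.seq) <= DNA_ALPHABET:
            raise AlphabetError(f"{self.species}/{self.gene}: ambiguity codes in CDS")
        if len(self.seq) % 3:
            raise FrameError(f"{self.species}/{self.gene}: length {len(self.seq)} not a codon multiple")

    @property
    def codons(self) -> list:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def validate(self, code: GeneticCode) -> None:
        code.translate(self.seq)


def _trim_to_frame(seq: str) -> str:
    """Drop a trailing incomplete codon (mitochondrial T / TA truncated stops)."""
    return seq[: len(seq) - len(seq) % 3]


def _cds_from_parts(species: str, gene: str, raw: str, coords, code: GeneticCode) -> CdsRecord | None:
    raw = raw.upper().replace("U", "T")
    if not set(raw) <= DNA_ALPHABET:
        logger.warning("%s/%s: ambiguity codes present, record excluded", species, gene)
        return None
    seq = _trim_to_frame(raw)
    if not seq:
        logger.warning("%s/%s: empty after frame trimming, excluded", species, gene)
        return None
    rec = CdsRecord(species=species, gene=gene, seq=seq, genome_coords=coords)
    try:
        rec.validate(code)
    except FrameError as exc:
        logger.warning("%s/%s: %s; record excluded", species, gene, exc)
        return None
    return rec


def read_cds_set(
    path: str | Path,
    coord_table: str | Path | None = None,
    code: GeneticCode | None = None,
    species: str | None = None,
) -> list:
    """Read CDS records from a GenBank flat file or a FASTA + gene table pair.

    With only ``path`` given, the file is parsed as GenBank and every CDS
    feature is extracted (minus-strand genes reverse-complemented, so the
    stored sequence is always the coding strand).  With ``coord_table`` given,
    ``path`` is a FASTA genome and the table is a TSV with columns
    ``seq_id, gene, start, end, strand`` (start/end 1-based inclusive, as in
    GenBank; strand ``+``/``-``).

    Records whose length cannot be reduced to a codon multiple, that carry
    ambiguity codes, or that contain internal stops are excluded with a
    logged warning.
    """
    code = code or GeneticCode.from_ncbi(5)
    path = Path(path)
    records: list = []
    if coord_table is None:
        for gb in SeqIO.parse(str(path), "genbank"):
            organism = species or gb.annotations.get("organism", gb.id)
            for feat in gb.features:
                if feat.type != "CDS":
                    continue
                gene = (
                    feat.qualifiers.get("gene", feat.qualifiers.get("product", ["?"]))
                )[0]
                raw = str(feat.location.extract(gb.seq))
                strand = "-" if feat.location.strand == -1 else "+"
                coords = (int(feat.location.start), int(feat.location.end), strand)
                rec = _cds_from_parts(organism, gene, raw, coords, code)
                if rec is not None:
                    records.append(rec)
    else:
        genome = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        table = pd.read_csv(coord_table, sep="\t", comment="#")
        for row in table.itertuples(index=False):
            contig = genome[str(row.seq_id)]
            start, end = int(row.start) - 1, int(row.end)  # to 0-based half-open
            raw = contig[start:end]
            if str(row.strand) == "-":
                raw = reverse_complement(raw)
            label = species or str(row.seq_id)
            rec = _cds_from_parts(label, str(row.gene), raw, (start, end, str(row.strand)), code)
            if rec is not None:
                records.append(rec)
    return records


def write_cds_fasta(records: Iterable[CdsRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species}|{rec.gene}\n{rec.seq}\n")


@dataclass
class CodonUsage:
    """Pooled codon counts with frequencies normalized over sense codons."""

    counts: Mapping[str, int]
    code: GeneticCode

    @property
    def frequencies(self) -> dict:
        sense = {c: self.counts.get(c, 0) for c in self.code.sense_codons}
        total = sum(sense.values())
        if total == 0:
            raise ValueError("no sense codons counted")
        return {c: n / total for c, n in sense.items()}

    def family_conditional(self, aa: str) -> dict:
        """P(codon | amino acid) within one synonymous family.

        A family with zero observed codons is treated as uniform (logged).
        """
        fam = self.code.family(aa)
        sub = {c: self.counts.get(c, 0) for c in fam}
        total = sum(sub.values())
        if total == 0:
            logger.debug("family of %s unobserved; using uniform within-family frequencies", aa)
            return {c: 1.0 / len(fam) for c in fam}
        return {c: n / total for c, n in sub.items()}


@dataclass
class DipeptideTable:
    """Frequencies of the 400 ordered amino-acid pairs."""

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-9:
            raise ValueError(f"dipeptide frequencies sum to {total}, expected 1")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("negative dipeptide frequency")


def codon_usage(cds_set: Iterable[CdsRecord], code: GeneticCode | None = None) -> CodonUsage:
    """Codon counts pooled over all records; stop codons excluded from counts."""
    code = code or GeneticCode.from_ncbi(5)
    counts: Counter = Counter()
    n_records = 0
    for rec in cds_set:
        n_records += 1
        for codon in rec.codons:
            if codon not in code.stop_codons:
                counts[codon] += 1
    if n_records == 0:
        raise ValueError("empty CDS set")
    return CodonUsage(counts=dict(counts), code=code)


def dipeptide_frequencies(
    cds_set: Iterable[CdsRecord], code: GeneticCode | None = None
) -> DipeptideTable:
    """Adjacent amino-acid pair frequencies, pooled across records.

    Pairs never span record boundaries; a terminal stop contributes no pair.
    """
    code = code or GeneticCode.from_ncbi(5)
    counts: Counter = Counter()
    n_records = 0
    for rec in cds_set:
        n_records += 1
        aa = code.translate(rec.seq).rstrip(STOP_SYMBOL)
        for i in range(len(aa) - 1):
            counts[aa[i : i + 2]] += 1
    if n_records == 0:
        raise ValueError("empty CDS set")
    total = sum(counts.values())
    return DipeptideTable(frequencies={k: v / total for k, v in counts.items()})
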