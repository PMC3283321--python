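"""Input/output layer: annotated genomes, proteomes, expression tables.

Coordinates are 1-based closed intervals throughout, matching GenBank.
Chromosomes are circular; genes may wrap the coordinate origin, in which
case ``end < start`` and the span is computed modulo the chromosome length.
Coding sequences in the data model exclude the terminal stop codon, so the
translation invariant (CDS -> protein under the bacterial code, no internal
stops) holds uniformly; :func:`parse_genome` strips the stop from real
GenBank CDS features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ctoevol")

#: NCBI translation table used for all bacterial CDS translation.
BACTERIAL_TABLE = 11

STOP_CODONS = {"TAA", "TAG", "TGA"}


class GenomeParseError(ValueError):
    """Raised when an annotation file cannot be interpreted."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a circular chromosome.

    ``start``/``end`` are 1-based inclusive; ``end < start`` only for genes
    wrapping the coordinate origin. ``cds`` excludes the stop codon and
    translates exactly to ``protein`` under the bacterial code.
    """

    gene_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    cds: str
    protein: str

    def span(self, chromosome_length: int) -> int:
        """Gene length in bp on the circle (stop codon included)."""
        return (self.end - self.start) % chromosome_length + 1

    def midpoint(self, chromosome_length: int) -> float:
        """Circular midpoint of the gene, in [1, length]. Used as the gene's
        single position for all replichore geometry."""
        half = (self.span(chromosome_length) - 1) / 2.0
        return (self.start - 1 + half) % chromosome_length + 1


@dataclass
class GenomeAnnotation:
    """A circular chromosome: identity, replication landmarks, gene list.

    ``sequence`` is optional; it is needed only by the GC-skew locator and
    by GenBank emission.
    """

    genome_id: str
    length: int
    ori: int
    ter: int
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.ori <= self.length) or not (1 <= self.ter <= self.length):
            raise ValueError(
                f"{self.genome_id}: ori/ter must lie in [1, {self.length}], "
                f"got ori={self.ori}, ter={self.ter}"
            )
        if self.ori == self.ter:
            raise ValueError(f"{self.genome_id}: ori and ter coincide at {self.ori}")

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._index()[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r} in genome {self.genome_id}")

    def _index(self) -> dict[str, GeneRecord]:
        idx = getattr(self, "_gene_index", None)
        if idx is None or len(idx) != len(self.genes):
            idx = {g.gene_id: g for g in self.genes}
            object.__setattr__(self, "_gene_index", idx)
        return idx


def translate_cds(cds: str) -> str:
    """Translate a stop-free CDS under the bacterial code.

    Raises ``ValueError`` on internal stops or length not divisible by 3.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds).translate(table=BACTERIAL_TABLE))
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    return protein


def _validate_record(rec: GeneRecord, length: int) -> None:
    if rec.strand not in "+-":
        raise ValueError(f"{rec.gene_id}: bad strand {rec.strand!r}")
    if not (1 <= rec.start <= length and 1 <= rec.end <= length):
        raise ValueError(f"{rec.gene_id}: coordinates outside [1, {length}]")
    if translate_cds(rec.cds) != rec.protein:
        raise ValueError(f"{rec.gene_id}: CDS does not translate to protein")


def parse_genome(
    genbank_file: str | Path,
    ori: int,
    ter: int,
    genome_id: str | None = None,
) -> GenomeAnnotation:
    """Read a GenBank flat file into a :class:`GenomeAnnotation`.

    One :class:`GeneRecord` is produced per protein-coding CDS feature
    carrying a locus tag and a translation. Pseudogenes, CDSs without a
    translation and CDSs violating the translation invariant are skipped
    and counted in the log. Ori/Ter are explicit inputs (the pipeline never
    guesses them); only the first record of a multi-record file is used and
    additional replicons are ignored with a warning.
    """
    path = Path(genbank_file)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # malformed file
        raise GenomeParseError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"{path}: no GenBank records found")
    if len(records) > 1:
        logger.warning(
            "%s: %d replicons found; using the first, ignoring the rest",
            path.name,
            len(records),
        )
    record = records[0]
    length = len(record.seq)
    if length == 0:
        raise GenomeParseError(f"{path}: empty sequence")

    genes: list[GeneRecord] = []
    skipped = 0
    for feat in record.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        if "pseudo" in quals or "pseudogene" in quals or "translation" not in quals:
            skipped += 1
            continue
        locus = quals.get("locus_tag", quals.get("gene", [None]))[0]
        if locus is None:
            skipped += 1
            continue
        try:
            cds = str(feat.extract(record.seq)).upper()
            if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
                cds = cds[:-3]
            protein = translate_cds(cds)
            declared = quals["translation"][0]
            # GenBank translations may start with M where the codon is an
            # alternative start; accept either.
            if protein != declared and not (
                len(protein) == len(declared) and protein[1:] == declared[1:]
            ):
                raise ValueError("translation mismatch with annotation")
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "+" if feat.location.strand != -1 else "-"
            rec = GeneRecord(locus, start, end, strand, cds, protein)
            _validate_record(rec, length)
        except ValueError as exc:
            logger.warning("skipping CDS %s: %s", locus, exc)
            skipped += 1
            continue
        genes.append(rec)
    if skipped:
        logger.info("%s: skipped %d CDS features", path.name, skipped)
    return GenomeAnnotation(
        genome_id=genome_id or record.id or path.stem,
        length=length,
        ori=ori,
        ter=ter,
        genes=genes,
        sequence=str(record.seq).upper(),
    )


def write_proteomes(annotation: GenomeAnnotation, out: str | Path) -> Path:
    """Write one FASTA record per gene (header = gene id)."""
    if not annotation.genes:
        raise ValueError(f"{annotation.genome_id}: no genes to write")
    ids = [g.gene_id for g in annotation.genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(g.protein), id=g.gene_id, description="")
        for g in annotation.genes
    ]
    SeqIO.write(records, str(out), "fasta")
    return out


def write_genbank(annotation: GenomeAnnotation, out: str | Path) -> Path:
    """Emit an annotation (with sequence) as a GenBank flat file.

    Used by the simulator so synthetic genomes go through the same reader
    as real ones. Synthetic CDSs carry no terminal stop codon, so the
    feature span equals the gene span exactly.
    """
    from Bio.SeqFeature import FeatureLocation, SeqFeature

    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    record = SeqRecord(
        Seq(annotation.sequence),
        id=annotation.genome_id,
        name=annotation.genome_id[:16],
        description="synthetic circular chromosome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for g in annotation.genes:
        loc = FeatureLocation(g.start - 1, g.end, 1 if g.strand == "+" else -1)
        feat = SeqFeature(
            loc,
            type="CDS",
            qualifiers={"locus_tag": [g.gene_id], "translation": [g.protein]},
        )
        record.features.append(feat)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write([record], str(out), "genbank")
    return out


def read_expression_table(tsv: str | Path) -> pd.DataFrame:
    """Read a gene x condition expression table (TSV, first column = gene id).

    Values must be numeric; empty cells are permitted and propagate as NaN.
    Duplicate gene ids and non-numeric cells are errors.
    """
    df = pd.read_csv(tsv, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene id rows: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric value at gene {row!r}, column {col!r}")
        df[col] = coerced
    return df


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-column gene list (e.g. essential genes); '#' comments allowed."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line.split("\t")[0])
    return out


def genes_by_id(annotations: Iterable[GenomeAnnotation]) -> dict[str, dict[str, GeneRecord]]:
    """Map genome_id -> gene_id -> record for a set of annotations."""
    return {a.genome_id: {g.gene_id: g for g in a.genes} for a in annotations}
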