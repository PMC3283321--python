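"""One-to-one ortholog detection by reciprocal best BLASTP hits.

Candidate orthologs are reciprocal best hits (RBH) between two proteomes,
retained only when both directions satisfy strict thresholds: E-value
< 1e-5 and amino-acid identity > 50%. Three-way one-to-one groups are the
closed triangles of the pairwise RBH graph. Groups whose members include
any CDS shorter than 420 bp (140 codons) are discarded so that terminal
(50+20 codons) and middle regions can be compared within every gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .genome_io import GenomeAnnotation

logger = logging.getLogger("ctoevol")

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 50.0
DEFAULT_MIN_CDS_LENGTH = 420  # bp = 140 codons


@dataclass(frozen=True)
class HitRecord:
    """One row of a BLAST tabular (outfmt 6) file, best HSP per pair."""

    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")


@dataclass(frozen=True)
class OrthologGroup:
    """Matched gene ids across 2 or 3 genomes, with the supporting hits."""

    members: Mapping[str, str]  # genome_id -> gene_id
    evidence: tuple[HitRecord, ...] = field(default_factory=tuple)

    def gene_in(self, genome_id: str) -> str:
        return self.members[genome_id]


def read_hits(tabular_file: str | Path) -> list[HitRecord]:
    """Parse a 12-column BLAST outfmt-6 file.

    All rows are read, including self-hits (they are removed by the
    best-hit reduction downstream, since RBH compares distinct proteomes).
    A row with the wrong column count raises with its line number.
    """
    hits: list[HitRecord] = []
    with open(tabular_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{tabular_file}: line {lineno}: expected 12 columns, got {len(cols)}"
                )
            hits.append(
                HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
    return hits


def _best_hit_per_query(hits: Sequence[HitRecord]) -> dict[str, HitRecord]:
    """Reduce a hit list to the single best hit per query.

    Ordering: max bitscore, then min E-value, then lexicographically
    smallest subject id — a total order, so runs are reproducible.
    Multiple HSPs for the same query/subject pair collapse onto the
    best-scoring row by the same rule.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query_id] = h
    return best


def _hit_key(h: HitRecord) -> tuple:
    return (-h.bitscore, h.evalue, h.subject_id)


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    genome_a: str,
    genome_b: str,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[OrthologGroup]:
    """Reciprocal best hits between proteomes A and B.

    A pair (a, b) is kept iff b is a's best hit in B, a is b's best hit in
    A, and both directions pass the strict thresholds (evalue < max_evalue,
    identity > min_identity). Each gene appears in at most one pair.
    """
    best_ab = _best_hit_per_query(hits_ab)
    best_ba = _best_hit_per_query(hits_ba)
    pairs: list[OrthologGroup] = []
    for a, fwd in sorted(best_ab.items()):
        rev = best_ba.get(fwd.subject_id)
        if rev is None or rev.subject_id != a:
            continue
        if not all(
            h.evalue < max_evalue and h.pct_identity > min_identity for h in (fwd, rev)
        ):
            continue
        pairs.append(
            OrthologGroup(
                members={genome_a: a, genome_b: fwd.subject_id},
                evidence=(fwd, rev),
            )
        )
    return pairs


def three_way_one_to_one(
    pairs_ab: Sequence[OrthologGroup],
    pairs_bc: Sequence[OrthologGroup],
    pairs_ac: Sequence[OrthologGroup],
) -> list[OrthologGroup]:
    """Closed triangles of the pairwise RBH graph.

    A triple (a, b, c) is kept iff a-b, b-c and a-c are all RBH pairs and
    mutually consistent; open triangles (a-b, b-c present but a linked to a
    different c) are rejected.
    """

    def _genomes(pairs: Sequence[OrthologGroup]) -> tuple[str, str]:
        gs = sorted(pairs[0].members)
        return gs[0], gs[1]

    if not (pairs_ab and pairs_bc and pairs_ac):
        return []
    ga1, gb1 = _genomes(pairs_ab)
    gb2, gc1 = _genomes(pairs_bc)
    ga2, gc2 = _genomes(pairs_ac)
    shared_b = ({ga1, gb1} & {gb2, gc1}).pop()
    genome_a = ({ga1, gb1} - {shared_b}).pop()
    genome_c = ({gb2, gc1} - {shared_b}).pop()
    if {ga2, gc2} != {genome_a, genome_c}:
        raise ValueError("pair lists do not cover a consistent genome triple")

    ab = {p.members[genome_a]: p for p in pairs_ab}
    bc = {p.members[shared_b]: p for p in pairs_bc}
    ac = {p.members[genome_a]: p for p in pairs_ac}
    triples: list[OrthologGroup] = []
    for a, p_ab in sorted(ab.items()):
        b = p_ab.members[shared_b]
        p_bc = bc.get(b)
        p_ac = ac.get(a)
        if p_bc is None or p_ac is None:
            continue
        if p_bc.members[genome_c] != p_ac.members[genome_c]:
            continue  # open triangle
        triples.append(
            OrthologGroup(
                members={
                    genome_a: a,
                    shared_b: b,
                    genome_c: p_ac.members[genome_c],
                },
                evidence=tuple(p_ab.evidence) + tuple(p_bc.evidence) + tuple(p_ac.evidence),
            )
        )
    return triples


def length_filter(
    groups: Sequence[OrthologGroup],
    annotations: Sequence[GenomeAnnotation],
    min_cds_length: int = DEFAULT_MIN_CDS_LENGTH,
) -> list[OrthologGroup]:
    """Drop any group with a member CDS shorter than ``min_cds_length`` bp.

    Exactly ``min_cds_length`` is kept (the rule is "shorter than"). The
    whole group is dropped if any member fails, so every retained group is
    analyzable in all genomes. Unknown gene ids raise.
    """
    by_genome = {a.genome_id: a for a in annotations}
    kept: list[OrthologGroup] = []
    dropped = 0
    for grp in groups:
        ok = True
        for genome_id, gene_id in grp.members.items():
            try:
                ann = by_genome[genome_id]
            except KeyError:
                raise KeyError(f"no annotation for genome {genome_id!r}")
            if len(ann.gene(gene_id).cds) < min_cds_length:
                ok = False
                break
        if ok:
            kept.append(grp)
        else:
            dropped += 1
    if dropped:
        logger.info("length filter: dropped %d/%d groups (< %d bp)", dropped, len(groups), min_cds_length)
    return kept


def read_orthologs_tsv(path: str | Path) -> list[OrthologGroup]:
    """Read back a TSV written by :func:`write_orthologs_tsv` (evidence is
    not reconstructed; checkpoint re-runs only need the memberships)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    genome_cols = [(i, c[: -len("_gene")]) for i, c in enumerate(header) if c.endswith("_gene")]
    groups = []
    for line in lines[1:]:
        cols = line.split("\t")
        groups.append(OrthologGroup(members={g: cols[i] for i, g in genome_cols}))
    return groups


def write_orthologs_tsv(groups: Sequence[OrthologGroup], out: str | Path) -> Path:
    """Write groups as TSV: one gene column per genome, plus identity/evalue
    of the supporting hits (minimum identity, maximum evalue over evidence)."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    if not groups:
        out.write_text("")
        return out
    genomes = sorted(groups[0].members)
    with open(out, "w") as fh:
        fh.write("\t".join([f"{g}_gene" for g in genomes] + ["min_identity", "max_evalue"]) + "\n")
        for grp in groups:
            ident = min((h.pct_identity for h in grp.evidence), default=float("nan"))
            ev = max((h.evalue for h in grp.evidence), default=float("nan"))
            fh.write(
                "\t".join([grp.members[g] for g in genomes] + [f"{ident:.2f}", f"{ev:.3g}"]) + "\n"
            )
    return out
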