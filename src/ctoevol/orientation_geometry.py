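"""Replichore geometry and orientation classification on the circular chromosome.

The bidirectional replication origin (Ori) and terminus (Ter) split the
circle into two replichores. Replichore 1 is the arc traversed from Ori in
increasing coordinates (mod length) to Ter; the fork on it moves with
increasing coordinates, so a ``+``-strand gene there is co-oriented with
replication and a ``-``-strand gene is transcribed head-on into the fork.
Replichore 2 is the complementary arc with the opposite convention.
Positions exactly at Ori or Ter are assigned to replichore 1.

Orientation conservation between genomes is called on the raw annotated
strand in each genome's deposited coordinate frame: a changed-orientation
gene (COG) has different strands in the two genomes, a same-orientation
gene (SOG) the same strand. For three genomes with one outgroup, the
strand triple is classified by parsimony into conserved (all equal),
ingroup-stem-or-outgroup change, or a species-specific change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GenomeAnnotation

COG = "COG"
SOG = "SOG"
HEAD_ON = "head-on"
CO_ORIENTED = "co-oriented"

#: Lineage labels for the strand triple (ingroup1, ingroup2, outgroup).
CONSERVED = "ESK"          # never changed orientation in any lineage
INGROUP_OR_OUTGROUP = "ES/K"  # change on the ingroup stem or the outgroup branch
SPECIES_ONLY = "{species}-only"


@dataclass(frozen=True)
class ReplichoreMap:
    """Circle length with Ori/Ter landmarks (1-based positions)."""

    length: int
    ori: int
    ter: int

    def __post_init__(self) -> None:
        if not (1 <= self.ori <= self.length and 1 <= self.ter <= self.length):
            raise ValueError("ori/ter outside chromosome")
        if self.ori == self.ter:
            raise ValueError("ori == ter")

    @classmethod
    def of(cls, annotation: GenomeAnnotation) -> "ReplichoreMap":
        return cls(annotation.length, annotation.ori, annotation.ter)


def _check_position(position: float, map: ReplichoreMap) -> None:
    if not (1 <= position <= map.length):
        raise ValueError(f"position {position} outside [1, {map.length}]")


def replichore_of(position: float, map: ReplichoreMap) -> int:
    """Which replichore a position lies on (1 or 2; Ori/Ter themselves -> 1)."""
    _check_position(position, map)
    arc1 = (map.ter - map.ori) % map.length
    offset = (position - map.ori) % map.length
    return 1 if offset <= arc1 else 2


def confrontation_status(strand: str, position: float, map: ReplichoreMap) -> str:
    """Head-on vs co-oriented transcription relative to the replication fork."""
    if strand not in "+-":
        raise ValueError(f"bad strand {strand!r}")
    fork_forward = replichore_of(position, map) == 1
    if (strand == "+") == fork_forward:
        return CO_ORIENTED
    return HEAD_ON


def classify_orientation_pair(strand_a: str, strand_b: str) -> str:
    """COG iff the annotated strands differ between the two genomes."""
    for s in (strand_a, strand_b):
        if s not in "+-":
            raise ValueError(f"bad strand {s!r}")
    return COG if strand_a != strand_b else SOG


def classify_lineage(
    strand_in1: str,
    strand_in2: str,
    strand_out: str,
    names: tuple[str, str, str] = ("ECO", "STM", "KPN"),
) -> str:
    """Parsimony classification of a strand triple (two ingroups + outgroup).

    all equal -> conserved; ingroups equal but outgroup differs -> the
    change is unplaceable between the ingroup stem and the outgroup branch;
    one ingroup differs from the other two -> a change specific to that
    species.
    """
    for s in (strand_in1, strand_in2, strand_out):
        if s not in "+-":
            raise ValueError(f"bad strand {s!r}")
    if strand_in1 == strand_in2 == strand_out:
        return CONSERVED
    if strand_in1 == strand_in2:
        return INGROUP_OR_OUTGROUP
    if strand_in2 == strand_out:
        return SPECIES_ONLY.format(species=names[0])
    return SPECIES_ONLY.format(species=names[1])


def circular_distance_to_ter(position: float, map: ReplichoreMap) -> float:
    """Shortest distance along the circle from a position to Ter (bp)."""
    _check_position(position, map)
    d = abs(position - map.ter)
    return min(d, map.length - d)


def locate_ter_by_gc_skew(
    annotation: GenomeAnnotation, window: int = 10_000
) -> tuple[int, int, bool]:
    """Estimate (Ori, Ter) from the cumulative GC skew of the chromosome.

    The (G-C)/(G+C) skew is computed in non-overlapping windows and
    cumulated; on a typical bacterial chromosome the leading strand is
    G-rich, so the cumulative curve attains its minimum near Ori and its
    maximum near Ter. Returns (ori_estimate, ter_estimate, reliable);
    ``reliable`` is False when the curve is essentially flat. This is a
    convenience locator only — the pipeline requires explicitly configured
    Ori/Ter and never substitutes these estimates silently.
    """
    if annotation.sequence is None:
        raise ValueError("annotation carries no sequence")
    seq = annotation.sequence
    n_windows = len(seq) // window
    if n_windows < 10:
        raise ValueError(
            f"sequence of {len(seq)} bp gives {n_windows} windows of {window} bp; need >= 10"
        )
    arr = np.frombuffer(seq[: n_windows * window].encode(), dtype=np.uint8)
    g = (arr == ord("G")).reshape(n_windows, window).sum(axis=1)
    c = (arr == ord("C")).reshape(n_windows, window).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), 0.0)
    cum = np.cumsum(skew)
    ori_idx = int(np.argmin(cum))
    ter_idx = int(np.argmax(cum))
    # window boundary after the extremum window, mapped into [1, len]
    ori_est = ((ori_idx + 1) * window - 1) % len(seq) + 1
    ter_est = ((ter_idx + 1) * window - 1) % len(seq) + 1
    reliable = bool(np.ptp(cum) > 0.5)  # flat curve -> unreliable
    return int(ori_est), int(ter_est), reliable


def geometry_table(
    groups,
    annotations: list[GenomeAnnotation],
    flips: dict[str, bool] | None = None,
    outgroup: str | None = None,
) -> pd.DataFrame:
    """Per-group geometry: strand, midpoint, replichore, confrontation and
    distance-to-Ter for every member, plus the orientation (and, with three
    genomes, lineage) call.

    With three genomes the lineage call treats ``outgroup`` (default: the
    last annotation) as the outgroup and the other two, in annotation
    order, as the ingroups; the pairwise orientation call compares the two
    ingroups. ``flips`` optionally marks genomes deposited in the flipped
    frame; a flipped genome has its strands inverted before comparison.
    """
    flips = flips or {}
    by_genome = {a.genome_id: a for a in annotations}
    order = [a.genome_id for a in annotations]
    if outgroup is not None:
        if outgroup not in order:
            raise ValueError(f"outgroup {outgroup!r} not among the annotations")
        order = [g for g in order if g != outgroup] + [outgroup]
    rows = []
    for i, grp in enumerate(groups):
        gids = [g for g in order if g in grp.members]
        strands = {}
        for genome_id in gids:
            ann = by_genome[genome_id]
            gene = ann.gene(grp.members[genome_id])
            strand = gene.strand
            if flips.get(genome_id):
                strand = "+" if strand == "-" else "-"
            strands[genome_id] = strand
            rmap = ReplichoreMap.of(ann)
            mid = gene.midpoint(ann.length)
            rows.append(
                {
                    "group_id": f"og{i:05d}",
                    "genome": genome_id,
                    "gene_id": gene.gene_id,
                    "strand": strand,
                    "midpoint": mid,
                    "replichore": replichore_of(mid, rmap),
                    "confrontation": confrontation_status(strand, mid, rmap),
                    "distance_to_ter": circular_distance_to_ter(mid, rmap),
                }
            )
        n = len(gids)
        call = classify_orientation_pair(strands[gids[0]], strands[gids[1]])
        if n == 2:
            lineage = ""
        else:
            lineage = classify_lineage(
                strands[gids[0]], strands[gids[1]], strands[gids[2]],
                names=(gids[0], gids[1], gids[2]),
            )
        for r in rows[-n:]:
            r["orientation_call"] = call
            r["lineage_call"] = lineage
    return pd.DataFrame(rows)
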