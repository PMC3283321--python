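"""Ground-truth genome-evolution simulator.

Generates circular chromosomes with non-overlapping protein-coding genes,
applies inversion events (preferentially symmetric about Ori or Ter, the
dominant geometry of rearrangements between closely related bacteria),
and diverges the coding sequences under per-gene rate multipliers:

* a distance-to-Ter gradient (mutation rate highest at Ter, decaying
  linearly to 1 at Ori),
* a head-on multiplier for genes transcribed against the replication fork,
* a CTO multiplier for genes whose transcriptional orientation changed
  (inverted an odd number of times on that lineage).

Nucleotide changes are proposed per site at the configured synonymous
intensity; synonymous proposals are always accepted, nonsynonymous ones
with probability ``omega_true``, and changes creating stop codons are
rejected. This proposal/acceptance scheme is not a full continuous-time
codon model, but it controls the realized dN/dS transparently and its
parameters map one-to-one onto the hypotheses under test.

Every dataset carries a truth table (ancestral and final strands,
inversion parity, realized multipliers, true orientation class and
confrontation status before/after), so each pipeline stage can be scored
against known ground truth. Everything is deterministic under the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_io import BACTERIAL_TABLE, GeneRecord, GenomeAnnotation, write_genbank, write_proteomes
from .orientation_geometry import (
    ReplichoreMap,
    circular_distance_to_ter,
    confrontation_status,
)

logger = logging.getLogger("ctoevol")

# codon machinery (built once from the bacterial code)
_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_AA = {c: str(Seq(c).translate(table=BACTERIAL_TABLE)) for c in _ALL_CODONS}
SENSE_CODONS = [c for c in _ALL_CODONS if _AA[c] != "*"]
_CODON_INDEX = {c: i for i, c in enumerate(_ALL_CODONS)}
_SENSE_IDX = np.array([_CODON_INDEX[c] for c in SENSE_CODONS])
_AA_CODE = np.array([-1 if _AA[c] == "*" else ord(_AA[c]) for c in _ALL_CODONS])
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated comparison.

    ``mu`` is the expected number of synonymous substitutions per site on
    one lineage branch (a two-genome comparison therefore targets a
    pairwise dS of about ``2 * mu``). Multipliers are relative rates
    (1 = no effect). ``n_inversions`` is the number of inversion events
    applied per lineage branch.
    """

    seed: int = 0
    chromosome_length: int = 500_000
    n_genes: int = 200
    min_gene_codons: int = 140
    max_gene_codons: int = 300
    ori: int = 1
    ter: int = 250_001
    n_inversions: int = 3
    p_symmetric: float = 0.8
    symmetric_center: Literal["ori", "ter", "both"] = "both"
    min_half_width: int = 2_000
    max_half_width: int = 30_000
    mu: float = 0.15  # per-branch synonymous substitutions/site (pairwise ~0.30)
    delta_cto: float = 1.0
    delta_headon: float = 1.0
    ter_gradient: float = 1.0  # rate multiplier at Ter, decaying to 1 at Ori
    omega_true: float = 0.05
    expr_log2_mean: float = 8.0
    expr_log2_sd: float = 2.0
    expr_rate_spearman: float = 0.0
    gc_skew: float = 0.0  # intergenic (G-C)/(G+C) excess on replichore 1

    def __post_init__(self) -> None:
        for name in ("delta_cto", "delta_headon", "ter_gradient", "mu"):
            if getattr(self, name) < 0 or (name != "mu" and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.min_gene_codons < 140:
            raise ValueError("min_gene_codons must be >= 140")
        if not 0 <= self.p_symmetric <= 1:
            raise ValueError("p_symmetric must be in [0, 1]")


def null_config(**overrides) -> SimulationConfig:
    """Null mode: orientation changes happen but have no rate effect."""
    return SimulationConfig(**overrides)


def cto_effect_config(delta_cto: float = 2.0, **overrides) -> SimulationConfig:
    """Orientation change multiplies the mutation rate; selection unchanged."""
    return SimulationConfig(delta_cto=delta_cto, **overrides)


def location_only_config(
    ter_gradient: float = 3.0, **overrides
) -> SimulationConfig:
    """Rate depends only on distance to Ter, with COGs clustered near Ter
    by Ter-symmetric inversions (the classic confounding geometry)."""
    overrides.setdefault("symmetric_center", "ter")
    overrides.setdefault("p_symmetric", 1.0)
    overrides.setdefault("max_half_width", 120_000)
    return SimulationConfig(ter_gradient=ter_gradient, **overrides)


@dataclass(frozen=True)
class InversionEvent:
    """One applied inversion: circular arc [start, end], 1-based inclusive."""

    start: int
    end: int
    mode: str  # "symmetric-ori", "symmetric-ter", "uniform"


@dataclass
class SimulatedComparison:
    """A simulated two- or three-genome dataset with its ground truth."""

    config: SimulationConfig
    ancestor: GenomeAnnotation
    genomes: dict[str, GenomeAnnotation]
    events: dict[str, list[InversionEvent]]
    truth: pd.DataFrame

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)


# ---------------------------------------------------------------------------
# ancestor generation


def _random_cds(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """Codon-index array drawn uniformly from the 61 sense codons."""
    return _SENSE_IDX[rng.integers(0, len(_SENSE_IDX), size=n_codons)]


def _cds_string(codon_idx: np.ndarray) -> str:
    return "".join(_ALL_CODONS[i] for i in codon_idx)


def _protein_string(codon_idx: np.ndarray) -> str:
    return "".join(chr(c) for c in _AA_CODE[codon_idx])


def generate_ancestor(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomeAnnotation:
    """Ancestral chromosome: non-overlapping CDSs with random strands.

    Genes are laid out in coordinate order with random intergenic gaps
    (>= 10 bp each, so inversion endpoints always have somewhere to land);
    no gene wraps the coordinate origin. Codons are uniform over the 61
    sense codons, so no internal stops exist by construction.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lengths = rng.integers(
        config.min_gene_codons, config.max_gene_codons + 1, size=config.n_genes
    )
    total_bp = int(3 * lengths.sum())
    min_gap = 10
    free = config.chromosome_length - total_bp - min_gap * (config.n_genes + 1)
    if free < 0:
        raise ValueError(
            f"cannot place {config.n_genes} genes totalling {total_bp} bp on a "
            f"{config.chromosome_length} bp chromosome; reduce the gene count"
        )
    extra = rng.multinomial(free, np.full(config.n_genes + 1, 1.0 / (config.n_genes + 1)))
    genes: list[GeneRecord] = []
    pos = 1
    for i, n_cod in enumerate(lengths):
        pos += min_gap + int(extra[i])
        codons = _random_cds(rng, int(n_cod))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = pos, pos + 3 * int(n_cod) - 1
        genes.append(
            GeneRecord(
                gene_id=f"anc_{i:04d}",
                start=start,
                end=end,
                strand=strand,
                cds=_cds_string(codons),
                protein=_protein_string(codons),
            )
        )
        pos = end + 1
    return GenomeAnnotation(
        genome_id="ancestor",
        length=config.chromosome_length,
        ori=config.ori,
        ter=config.ter,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# inversions


def _arc_offsets(p: int, a: int, length: int) -> int:
    return (p - a) % length


def _segment_relation(gene: GeneRecord, a: int, seg_len: int, length: int) -> str:
    """'inside', 'outside' or 'split' for a gene vs the arc starting at a."""
    s = _arc_offsets(gene.start, a, length)
    e = _arc_offsets(gene.end, a, length)
    if s > e:  # gene straddles the segment start point
        return "split"
    if e < seg_len:
        return "inside"
    if s >= seg_len:
        return "outside"
    return "split"


def _reflect(p: int, a: int, seg_len: int, length: int) -> int:
    """Reflect a 1-based position through the arc [a, a+seg_len-1]."""
    off = _arc_offsets(p, a, length)
    return (a - 1 + (seg_len - 1 - off)) % length + 1


def apply_inversions(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_events: int | None = None,
) -> tuple[GenomeAnnotation, list[InversionEvent], dict[str, int]]:
    """Apply inversion events; returns (new annotation, log, flip counts).

    Each event picks an arc symmetric about Ori or Ter with probability
    ``p_symmetric`` (center per ``symmetric_center``), otherwise a uniform
    arc containing neither landmark. Arcs that would split a gene, or
    uniform arcs containing Ori/Ter, are redrawn (bounded retries; an
    exhausted event is skipped with a warning). Genes inside an arc have
    coordinates reflected, strand flipped and CDS reverse-complemented.
    Flip counts are keyed by gene id (gene ids survive inversions).
    """
    length = annotation.length
    genes = list(annotation.genes)
    flip_counts: dict[str, int] = {g.gene_id: 0 for g in genes}
    events: list[InversionEvent] = []
    n_events = config.n_inversions if n_events is None else n_events
    for _ in range(n_events):
        for _try in range(200):
            if rng.random() < config.p_symmetric:
                if config.symmetric_center == "both":
                    center = annotation.ori if rng.random() < 0.5 else annotation.ter
                else:
                    center = annotation.ori if config.symmetric_center == "ori" else annotation.ter
                mode = "symmetric-ori" if center == annotation.ori else "symmetric-ter"
                w = int(rng.integers(config.min_half_width, config.max_half_width + 1))
                a = (center - w - 1) % length + 1
                seg_len = 2 * w + 1
            else:
                mode = "uniform"
                a = int(rng.integers(1, length + 1))
                seg_len = int(rng.integers(2 * config.min_half_width, 2 * config.max_half_width + 1))
                # uniform arcs must not contain Ori or Ter (landmarks are fixed loci)
                if (
                    _arc_offsets(annotation.ori, a, length) < seg_len
                    or _arc_offsets(annotation.ter, a, length) < seg_len
                ):
                    continue
            if seg_len >= length:
                continue
            relations = [_segment_relation(g, a, seg_len, length) for g in genes]
            if any(r == "split" for r in relations):
                continue
            new_genes = []
            for g, rel in zip(genes, relations):
                if rel == "inside":
                    flip_counts[g.gene_id] += 1
                    # the CDS field is strand-relative, so it is invariant
                    # under inversion; only coordinates and strand change
                    new_genes.append(
                        replace(
                            g,
                            start=_reflect(g.end, a, seg_len, length),
                            end=_reflect(g.start, a, seg_len, length),
                            strand="+" if g.strand == "-" else "-",
                        )
                    )
                else:
                    new_genes.append(g)
            genes = new_genes
            events.append(InversionEvent(start=a, end=(a - 1 + seg_len - 1) % length + 1, mode=mode))
            break
        else:
            logger.warning("inversion event skipped: no valid arc found in 200 tries")
    reordered = sorted(genes, key=lambda g: g.start)
    new_ann = GenomeAnnotation(
        genome_id=annotation.genome_id,
        length=length,
        ori=annotation.ori,
        ter=annotation.ter,
        genes=reordered,
    )
    return new_ann, events, flip_counts


# ---------------------------------------------------------------------------
# sequence divergence


def _ter_gradient_multiplier(dist_ter: float, length: int, gradient: float) -> float:
    """Linear gradient: ``gradient`` at Ter decaying to 1 at Ori."""
    return 1.0 + (gradient - 1.0) * (1.0 - dist_ter / (length / 2.0))


def _evolve_cds(
    codon_idx: np.ndarray,
    intensity: float,
    omega_true: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Propose/accept nucleotide changes at the given synonymous intensity.

    ``intensity`` is the expected number of proposals per nucleotide site,
    which equals the expected synonymous substitutions per synonymous site
    (synonymous proposals are always accepted). Stop-creating changes are
    rejected outright.
    """
    codons = codon_idx.copy()
    n_sites = 3 * codons.size
    n_proposals = rng.poisson(intensity * n_sites)
    if n_proposals == 0:
        return codons
    which = rng.integers(0, codons.size, size=n_proposals)
    pos = rng.integers(0, 3, size=n_proposals)
    alt = rng.integers(1, 4, size=n_proposals)  # offset from current nt, mod 4
    accept_draw = rng.random(n_proposals)
    for k in range(n_proposals):
        c = int(codons[which[k]])
        shift = (2 - int(pos[k])) * 2
        cur_nt = (c >> shift) & 3
        new_nt = (cur_nt + int(alt[k])) % 4
        new_c = (c & ~(3 << shift)) | (new_nt << shift)
        aa_old, aa_new = _AA_CODE[c], _AA_CODE[new_c]
        if aa_new == -1:
            continue  # would create a stop
        if aa_new != aa_old and accept_draw[k] >= omega_true:
            continue  # nonsynonymous change rejected by selection
        codons[which[k]] = new_c
    return codons


def evolve_lineage(
    annotation: GenomeAnnotation,
    flips: dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    genome_id: str,
    mu_branch: float | None = None,
) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Diverge all CDSs of one lineage under the configured multipliers.

    Per gene, the synonymous intensity is
    ``mu x gradient(distance to Ter) x delta_headon^[head-on] x
    delta_cto^[orientation changed]``, evaluated at the gene's
    post-inversion position and strand. Returns the evolved annotation
    (gene ids prefixed with ``genome_id``) and a per-gene frame of
    realized multipliers and geometry.
    """
    mu = config.mu if mu_branch is None else mu_branch
    rmap = ReplichoreMap.of(annotation)
    genes: list[GeneRecord] = []
    rows = []
    for g in annotation.genes:
        n_flips = flips.get(g.gene_id, 0)
        mid = g.midpoint(annotation.length)
        dist = circular_distance_to_ter(mid, rmap)
        conf = confrontation_status(g.strand, mid, rmap)
        multiplier = _ter_gradient_multiplier(dist, annotation.length, config.ter_gradient)
        if conf == "head-on":
            multiplier *= config.delta_headon
        inverted = bool(n_flips % 2)
        if inverted:
            multiplier *= config.delta_cto
        idx = np.array([_CODON_INDEX[g.cds[i : i + 3]] for i in range(0, len(g.cds), 3)])
        evolved = _evolve_cds(idx, mu * multiplier, config.omega_true, rng)
        anc_index = int(g.gene_id.split("_")[-1])
        new_id = f"{genome_id}_{anc_index:04d}"
        genes.append(
            replace(g, gene_id=new_id, cds=_cds_string(evolved), protein=_protein_string(evolved))
        )
        rows.append(
            {
                "gene_index": anc_index,
                f"gene_{genome_id}": new_id,
                f"strand_{genome_id}": g.strand,
                f"inverted_{genome_id}": inverted,
                f"n_flips_{genome_id}": int(n_flips),
                f"midpoint_{genome_id}": mid,
                f"dist_ter_{genome_id}": dist,
                f"confrontation_{genome_id}": conf,
                f"multiplier_{genome_id}": multiplier,
            }
        )
    evolved_ann = GenomeAnnotation(
        genome_id=genome_id,
        length=annotation.length,
        ori=annotation.ori,
        ter=annotation.ter,
        genes=genes,
    )
    return evolved_ann, pd.DataFrame(rows).set_index("gene_index")


# ---------------------------------------------------------------------------
# top-level scenarios


def _ancestor_truth(ancestor: GenomeAnnotation) -> pd.DataFrame:
    rmap = ReplichoreMap.of(ancestor)
    rows = []
    for g in ancestor.genes:
        mid = g.midpoint(ancestor.length)
        rows.append(
            {
                "gene_index": int(g.gene_id.split("_")[-1]),
                "ancestral_strand": g.strand,
                "confrontation_ancestor": confrontation_status(g.strand, mid, rmap),
                "n_codons": len(g.cds) // 3,
            }
        )
    return pd.DataFrame(rows).set_index("gene_index")


def simulate_pair(
    config: SimulationConfig, genome_ids: tuple[str, str] = ("GA", "GB")
) -> SimulatedComparison:
    """Two lineages diverging from a common ancestor.

    Each lineage receives ``n_inversions`` events and ``mu`` expected
    synonymous substitutions per site, so the pairwise divergence is about
    ``2 * mu``. The truth table marks a gene COG iff its final strands
    differ (equivalently: odd total inversion parity across lineages).
    """
    rng = np.random.default_rng(config.seed)
    ancestor = generate_ancestor(config, rng)
    truth = _ancestor_truth(ancestor)
    genomes: dict[str, GenomeAnnotation] = {}
    events: dict[str, list[InversionEvent]] = {}
    for gid in genome_ids:
        inverted_ann, evs, flips = apply_inversions(ancestor, config, rng)
        evolved, frame = evolve_lineage(inverted_ann, flips, config, rng, gid)
        genomes[gid] = evolved
        events[gid] = evs
        truth = truth.join(frame, how="left")
    a, b = genome_ids
    truth["orientation_class"] = np.where(
        truth[f"strand_{a}"] != truth[f"strand_{b}"], "COG", "SOG"
    )
    truth["pair_multiplier"] = 0.5 * (
        truth[f"multiplier_{a}"] + truth[f"multiplier_{b}"]
    )
    return SimulatedComparison(config, ancestor, genomes, events, truth.reset_index())


def simulate_triple(
    config: SimulationConfig,
    genome_ids: tuple[str, str, str] = ("ECO", "STM", "KPN"),
) -> SimulatedComparison:
    """Two ingroup lineages plus an outgroup.

    Topology: ancestor -> outgroup branch (length ``mu``), and ancestor ->
    ingroup stem (length ``mu/2``, with its own inversions) -> two terminal
    branches (length ``mu/2`` each). Ingroup pairwise divergence is thus
    about ``mu`` and ingroup-outgroup about ``2 * mu``.
    """
    rng = np.random.default_rng(config.seed)
    in1, in2, out = genome_ids
    ancestor = generate_ancestor(config, rng)
    truth = _ancestor_truth(ancestor)
    genomes: dict[str, GenomeAnnotation] = {}
    events: dict[str, list[InversionEvent]] = {}

    # outgroup branch (genomes dict is ordered ingroup1, ingroup2, outgroup)
    out_ann, out_evs, out_flips = apply_inversions(ancestor, config, rng)
    out_genome, frame = evolve_lineage(out_ann, out_flips, config, rng, out, mu_branch=config.mu)
    events[out] = out_evs
    truth = truth.join(frame, how="left")

    # ingroup stem (sequence evolution on the stem is folded into the
    # terminal branch lengths; strand history is what matters for lineage calls)
    stem_ann, stem_evs, stem_flips = apply_inversions(ancestor, config, rng)
    events["stem"] = stem_evs
    for gid in (in1, in2):
        term_ann, term_evs, term_flips = apply_inversions(stem_ann, config, rng)
        total_flips = {
            gene_id: stem_flips.get(gene_id, 0) + n for gene_id, n in term_flips.items()
        }
        evolved, frame = evolve_lineage(
            term_ann, total_flips, config, rng, gid, mu_branch=0.5 * config.mu
        )
        genomes[gid] = evolved
        events[gid] = term_evs
        truth = truth.join(frame, how="left")
    genomes[out] = out_genome

    truth["orientation_class"] = np.where(
        truth[f"strand_{in1}"] != truth[f"strand_{in2}"], "COG", "SOG"
    )
    truth["pair_multiplier"] = 0.5 * (
        truth[f"multiplier_{in1}"] + truth[f"multiplier_{in2}"]
    )
    return SimulatedComparison(config, ancestor, genomes, events, truth.reset_index())


# ---------------------------------------------------------------------------
# expression, hit tables, dataset emission


def generate_expression(
    sim: SimulatedComparison,
    genome_id: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Log2-scale expression values for one genome, two growth phases.

    Values are Gaussian on the log2 scale (the distribution of log-scale
    microarray intensities). When ``expr_rate_spearman`` is non-zero the
    values are coupled to the gene's realized rate multiplier through a
    Gaussian copula, so the sample Spearman correlation matches the
    configured target (highly expressed genes evolving slowly corresponds
    to a negative setting).
    """
    config = sim.config
    truth = sim.truth.set_index("gene_index")
    mult = truth[f"multiplier_{genome_id}"].to_numpy(dtype=float)
    gene_ids = truth[f"gene_{genome_id}"].tolist()
    n = mult.size
    rho_s = config.expr_rate_spearman
    # Pearson correlation of the Gaussian copula giving the target Spearman
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    from scipy import stats as sps

    z_mult = sps.norm.ppf((sps.rankdata(mult) - 0.5) / n)
    cols = {}
    for phase in ("log_phase", "stationary_phase"):
        noise = rng.standard_normal(n)
        z = r * z_mult + np.sqrt(max(0.0, 1.0 - r**2)) * noise
        cols[phase] = config.expr_log2_mean + config.expr_log2_sd * z
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))


def _protein_identity(p1: str, p2: str) -> float:
    same = sum(a == b for a, b in zip(p1, p2))
    return 100.0 * same / max(len(p1), len(p2))


def make_hit_tables(
    sim: SimulatedComparison, genome_a: str, genome_b: str
) -> tuple[list[str], list[str]]:
    """Exact-match BLAST-style tabular rows for a genome pair (both
    directions), so orthology runs without an external search.

    Identity is the true ungapped protein identity; the E-value and
    bitscore are nominal values consistent with a strong full-length hit.
    """
    truth = sim.truth
    genes_a = {g.gene_id: g for g in sim.genomes[genome_a].genes}
    genes_b = {g.gene_id: g for g in sim.genomes[genome_b].genes}
    ab: list[str] = []
    ba: list[str] = []
    for _, row in truth.iterrows():
        ga, gb = row[f"gene_{genome_a}"], row[f"gene_{genome_b}"]
        a, b = genes_a[ga], genes_b[gb]
        ident = _protein_identity(a.protein, b.protein)
        alen = len(a.protein)
        mism = round(alen * (100.0 - ident) / 100.0)
        bits = 2.0 * alen
        ab.append(
            f"{ga}\t{gb}\t{ident:.2f}\t{alen}\t{mism}\t0\t1\t{alen}\t1\t{alen}\t1e-180\t{bits:.1f}"
        )
        ba.append(
            f"{gb}\t{ga}\t{ident:.2f}\t{alen}\t{mism}\t0\t1\t{alen}\t1\t{alen}\t1e-180\t{bits:.1f}"
        )
    return ab, ba


def assemble_sequence(
    annotation: GenomeAnnotation,
    rng: np.random.Generator,
    gc_skew: float = 0.0,
) -> GenomeAnnotation:
    """Fill intergenic regions with random nucleotides and attach the full
    chromosome sequence.

    With ``gc_skew`` s > 0, intergenic bases on replichore 1 are drawn with
    P(G) = 0.25 + s/2 and P(C) = 0.25 - s/2 (reversed on replichore 2),
    producing the cumulative GC-skew signature the Ori/Ter locator expects.
    """
    length = annotation.length
    seq = np.full(length, -1, dtype=np.int8)
    nt = np.array(list("ACGT"))
    rmap = ReplichoreMap.of(annotation)
    for g in annotation.genes:
        cds = g.cds if g.strand == "+" else g.cds.translate(_COMPLEMENT)[::-1]
        idx = np.arange(g.start - 1, g.start - 1 + len(cds)) % length
        seq[idx] = [("ACGT").index(c) for c in cds]
    free = np.flatnonzero(seq < 0)
    if free.size:
        from .orientation_geometry import replichore_of

        positions = free + 1
        rep1 = np.array([replichore_of(int(p), rmap) == 1 for p in positions])
        s = gc_skew / 2.0
        p1 = np.array([0.25, 0.25 - s, 0.25 + s, 0.25])  # A, C, G, T on replichore 1
        p2 = np.array([0.25, 0.25 + s, 0.25 - s, 0.25])
        draws1 = rng.choice(4, size=int(rep1.sum()), p=p1)
        draws2 = rng.choice(4, size=int((~rep1).sum()), p=p2)
        fill = np.empty(free.size, dtype=np.int8)
        fill[rep1] = draws1
        fill[~rep1] = draws2
        seq[free] = fill
    annotation.sequence = "".join(nt[seq])
    return annotation


def write_dataset(sim: SimulatedComparison, outdir: str | Path) -> dict:
    """Emit the dataset in the formats the real pipeline reads.

    Writes one GenBank file and one protein FASTA per genome, exact-match
    hit tables for every genome pair (both directions), one expression TSV
    per genome, the truth table TSV and a manifest with SHA-256 checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.config.seed + 1)
    files: dict[str, str] = {}

    for gid, ann in sim.genomes.items():
        if ann.sequence is None:
            assemble_sequence(ann, rng, sim.config.gc_skew)
        gb = write_genbank(ann, outdir / f"{gid}.gbk")
        fa = write_proteomes(ann, outdir / f"{gid}.faa")
        files[f"genome_{gid}"] = gb.name
        files[f"proteome_{gid}"] = fa.name
        expr = generate_expression(sim, gid, rng)
        expr_path = outdir / f"{gid}_expression.tsv"
        expr.to_csv(expr_path, sep="\t")
        files[f"expression_{gid}"] = expr_path.name

    ids = sim.genome_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            ab, ba = make_hit_tables(sim, a, b)
            p_ab = outdir / f"hits_{a}_vs_{b}.tsv"
            p_ba = outdir / f"hits_{b}_vs_{a}.tsv"
            p_ab.write_text("\n".join(ab) + "\n")
            p_ba.write_text("\n".join(ba) + "\n")
            files[f"hits_{a}_vs_{b}"] = p_ab.name
            files[f"hits_{b}_vs_{a}"] = p_ba.name

    truth_path = outdir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    files["truth"] = truth_path.name

    manifest = {
        "seed": sim.config.seed,
        "genomes": ids,
        "ori": sim.config.ori,
        "ter": sim.config.ter,
        "files": files,
        "sha256": {
            name: hashlib.sha256((outdir / fname).read_bytes()).hexdigest()
            for name, fname in files.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
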