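"""Codon alignments and NG86 evolutionary-rate estimation.

Rates are estimated by Nei–Gojobori (1986) counting. Per codon, synonymous
site counts are the fraction of the nine single-nucleotide neighbours that
preserve the amino acid (changes to stop codons count as nonsynonymous, so
sites per codon always sum to 3). Between two codons differing at k
positions, the k! single-step mutation paths are enumerated; paths passing
through a stop codon are excluded and the synonymous/nonsynonymous step
counts are averaged over the remaining paths (over all paths if every path
hits a stop — a rare degenerate pair). Proportions pN = Nd/N and pS = Sd/S
are corrected for multiple hits with the Jukes–Cantor formula
d = -(3/4)·ln(1 - (4/3)·p), undefined at p >= 3/4 (saturation).

Site and difference counts are averaged over the two sequences, so the
estimate is symmetric in its arguments.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genome_io import BACTERIAL_TABLE

logger = logging.getLogger("ctoevol")

NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NT)}
GAP_CODON = "---"

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# codon tables


def _codon_of(idx: int) -> str:
    return NT[idx >> 4] + NT[(idx >> 2) & 3] + NT[idx & 3]


def _index_of(codon: str) -> int:
    return (_NT_INDEX[codon[0]] << 4) | (_NT_INDEX[codon[1]] << 2) | _NT_INDEX[codon[2]]


@lru_cache(maxsize=1)
def _tables() -> dict:
    """Precompute NG86 lookup tables over all 64 codons.

    Returns amino acid per codon (None for stops), per-codon synonymous
    site counts, and 64x64 arrays of path-averaged synonymous and
    nonsynonymous difference counts.
    """
    aa = []
    for i in range(64):
        codon = _codon_of(i)
        trans = str(Seq(codon).translate(table=BACTERIAL_TABLE))
        aa.append(None if trans == "*" else trans)

    syn_sites = np.zeros(64)
    for i in range(64):
        if aa[i] is None:
            continue
        codon = _codon_of(i)
        syn = 0.0
        for pos in range(3):
            for nt in NT:
                if nt == codon[pos]:
                    continue
                j = _index_of(codon[:pos] + nt + codon[pos + 1 :])
                if aa[j] is not None and aa[j] == aa[i]:
                    syn += 1.0
        syn_sites[i] = syn / 3.0

    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i in range(64):
        if aa[i] is None:
            continue
        for j in range(i + 1, 64):
            if aa[j] is None:
                continue
            ci, cj = _codon_of(i), _codon_of(j)
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if not diff:
                continue
            paths: list[tuple[float, float]] = []
            fallback: list[tuple[float, float]] = []
            for order in itertools.permutations(diff):
                cur = ci
                s = n = 0.0
                through_stop = False
                for pos in order:
                    nxt = cur[:pos] + cj[pos] + cur[pos + 1 :]
                    a_cur, a_nxt = aa[_index_of(cur)], aa[_index_of(nxt)]
                    if a_nxt is None:
                        through_stop = True
                        n += 1.0  # counted only on the fallback branch
                    elif a_cur is not None and a_cur == a_nxt:
                        s += 1.0
                    else:
                        n += 1.0
                    cur = nxt
                (fallback if through_stop else paths).append((s, n))
            use = paths if paths else fallback
            s_avg = sum(p[0] for p in use) / len(use)
            n_avg = sum(p[1] for p in use) / len(use)
            sd[i, j] = sd[j, i] = s_avg
            nd[i, j] = nd[j, i] = n_avg

    sense = np.array([a is not None for a in aa])
    return {"aa": aa, "syn_sites": syn_sites, "sd": sd, "nd": nd, "sense": sense}


def _encode_codons(codons: str) -> np.ndarray:
    """Encode a codon string into indices; -1 for gap/ambiguous codons."""
    n = len(codons) // 3
    out = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        c = codons[3 * k : 3 * k + 3]
        if c[0] in _NT_INDEX and c[1] in _NT_INDEX and c[2] in _NT_INDEX:
            out[k] = _index_of(c)
    return out


# ---------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class CodonAlignment:
    """Two aligned codon sequences; gap codon '---' allowed."""

    gene_a: str
    gene_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("aligned codon sequences differ in length")
        if len(self.codons_a) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(self.codons_a) // 3

    def columns(self, idx: "np.ndarray | list[int]") -> "CodonAlignment":
        """Sub-alignment restricted to the given codon columns (kept in order)."""
        a = "".join(self.codons_a[3 * i : 3 * i + 3] for i in idx)
        b = "".join(self.codons_b[3 * i : 3 * i + 3] for i in idx)
        return CodonAlignment(self.gene_a, self.gene_b, a, b)


@dataclass(frozen=True)
class RatesResult:
    """NG86 site and difference counts with Jukes–Cantor corrected rates.

    ``dN``/``dS`` are None when the corresponding proportion is saturated
    (p >= 3/4); ``omega`` is None unless dS is defined and > 0.
    """

    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    omega: float | None
    n_codons: int

    @property
    def saturated(self) -> bool:
        return self.dS is None or self.dN is None


@dataclass(frozen=True)
class RegionRates:
    """Terminal vs sampled-middle rates for one gene and their differences."""

    terminal: RatesResult
    middle_sampled: RatesResult
    delta_dN: float | None
    delta_dS: float | None
    delta_omega: float | None
    seed: int


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_kept: int
    n_high_ds: int
    n_saturated: int


# ---------------------------------------------------------------------------
# alignment


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        a.mode = "global"
        _ALIGNER = a
    return _ALIGNER


def align_proteins_global(protein_a: str, protein_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, gap open 10 / extend 0.5).

    Deterministic: among co-optimal alignments the aligner's canonical
    first traceback is taken. Returns the two gapped sequences.
    """
    for p in (protein_a, protein_b):
        if not p:
            raise ValueError("empty protein sequence")
        bad = set(p) - AMINO_ACIDS
        if bad:
            raise ValueError(f"illegal amino-acid characters: {sorted(bad)}")
    aln = _aligner().align(protein_a, protein_b)[0]
    return str(aln[0]), str(aln[1])


def back_translate(
    aligned_a: str,
    aligned_b: str,
    cds_a: str,
    cds_b: str,
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Replace each aligned amino acid by its source codon, gaps by '---'.

    Each CDS must translate exactly to its ungapped protein (terminal stop
    already stripped); a mismatch raises naming the offending position.
    """
    out = []
    for name, aligned, cds in ((gene_a, aligned_a, cds_a), (gene_b, aligned_b, cds_b)):
        ungapped = aligned.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{name}: CDS length {len(cds)} does not match protein length {len(ungapped)}"
            )
        codons = []
        k = 0
        for col, aachar in enumerate(aligned):
            if aachar == "-":
                codons.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            trans = str(Seq(codon).translate(table=BACTERIAL_TABLE))
            if trans == "*":
                raise ValueError(f"{name}: internal stop codon at codon {k + 1}")
            if trans != aachar and not (k == 0 and aachar == "M"):
                raise ValueError(
                    f"{name}: codon {codon} at position {k + 1} translates to "
                    f"{trans}, aligned protein has {aachar}"
                )
            codons.append(codon)
            k += 1
        out.append("".join(codons))
    return CodonAlignment(gene_a, gene_b, out[0], out[1])


# ---------------------------------------------------------------------------
# NG86


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None at saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_pair_counts(idx_a: np.ndarray, idx_b: np.ndarray) -> tuple[float, float, float, float, int]:
    """(N, S, Nd, Sd, n_codons) over encoded codon index arrays.

    Columns where either codon is not a sense codon (gap, ambiguity, stop)
    are excluded entirely.
    """
    t = _tables()
    valid = (idx_a >= 0) & (idx_b >= 0)
    ia, ib = idx_a[valid], idx_b[valid]
    sense = t["sense"][ia] & t["sense"][ib]
    ia, ib = ia[sense], ib[sense]
    n_codons = int(ia.size)
    if n_codons == 0:
        return 0.0, 0.0, 0.0, 0.0, 0
    s_sites = 0.5 * (t["syn_sites"][ia].sum() + t["syn_sites"][ib].sum())
    total_sites = 3.0 * n_codons
    sd = t["sd"][ia, ib].sum()
    nd = t["nd"][ia, ib].sum()
    return total_sites - s_sites, s_sites, nd, sd, n_codons


def ng86_rates(alignment: CodonAlignment) -> RatesResult:
    """NG86 dN/dS estimate for one pairwise codon alignment."""
    idx_a = _encode_codons(alignment.codons_a)
    idx_b = _encode_codons(alignment.codons_b)
    N, S, Nd, Sd, n_codons = ng86_pair_counts(idx_a, idx_b)
    if n_codons == 0:
        raise ValueError("no comparable (both-ungapped sense) codons in alignment")
    pN = Nd / N if N > 0 else 0.0
    pS = Sd / S if S > 0 else 0.0
    if S <= 0 and Sd > 0:
        raise AssertionError("synonymous differences without synonymous sites")
    dN = jukes_cantor(pN)
    dS = jukes_cantor(pS)
    if dS is None and Sd > 0:
        logger.debug("%s/%s: saturated pS=%.3f, omega undefined", alignment.gene_a, alignment.gene_b, pS)
    omega = dN / dS if (dN is not None and dS is not None and dS > 0) else None
    return RatesResult(N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS, omega=omega, n_codons=n_codons)


def ds_filter(
    results: dict[str, RatesResult], max_ds: float = 3.0
) -> tuple[dict[str, RatesResult], FilterReport]:
    """Keep results with a defined dS strictly below ``max_ds``.

    Saturated (undefined-dS) results are removed and counted separately
    from the defined-but-too-high ones.
    """
    kept: dict[str, RatesResult] = {}
    n_high = n_sat = 0
    for gid, r in results.items():
        if r.dS is None:
            n_sat += 1
        elif r.dS >= max_ds:
            n_high += 1
        else:
            kept[gid] = r
    report = FilterReport(len(results), len(kept), n_high, n_sat)
    if n_high or n_sat:
        logger.info(
            "dS filter: kept %d/%d (removed %d with dS >= %g, %d saturated)",
            report.n_kept, report.n_input, n_high, max_ds, n_sat,
        )
    return kept, report


# ---------------------------------------------------------------------------
# terminal vs middle regions


def partition_terminal_middle(
    alignment: CodonAlignment, head: int = 50, tail: int = 20
) -> tuple[CodonAlignment, CodonAlignment]:
    """Split alignment columns into terminal (first ``head`` + last ``tail``
    codons of sequence 1) and middle (everything else).

    Column membership is indexed on sequence 1's ungapped codons; columns
    where sequence 1 has a gap carry no codon index and fall to the middle
    (they are excluded from rate counting regardless).
    """
    cod_a = alignment.codons_a
    n_cols = alignment.n_columns
    seq1_idx = np.full(n_cols, -1, dtype=np.int64)
    k = 0
    for col in range(n_cols):
        if cod_a[3 * col : 3 * col + 3] != GAP_CODON:
            seq1_idx[col] = k
            k += 1
    n1 = k
    if n1 < head + tail:
        raise ValueError(f"sequence 1 has {n1} codons; need >= {head + tail}")
    is_term = (seq1_idx >= 0) & ((seq1_idx < head) | (seq1_idx >= n1 - tail))
    term_cols = np.nonzero(is_term)[0]
    mid_cols = np.nonzero(~is_term)[0]
    return alignment.columns(term_cols), alignment.columns(mid_cols)


def derive_gene_seed(global_seed: int, gene_id: str) -> int:
    """Per-gene sampling seed: global seed XOR a stable hash of the gene id,
    so gene-level results do not depend on processing order."""
    return (int(global_seed) ^ zlib.crc32(gene_id.encode())) & 0x7FFFFFFF


def sample_middle_and_delta(
    alignment: CodonAlignment,
    n: int = 70,
    head: int = 50,
    tail: int = 20,
    seed: int = 0,
) -> RegionRates | None:
    """Rates on the terminal region vs a random ``n``-codon middle sample.

    The sample is drawn uniformly without replacement with the per-gene
    seed derived from ``seed`` and the gene id. Returns None (logged) when
    the middle region has fewer than ``n`` columns. Deltas are terminal
    minus sample; a delta is None when either side is saturated.
    """
    terminal, middle = partition_terminal_middle(alignment, head=head, tail=tail)
    if middle.n_columns < n:
        logger.info(
            "%s/%s excluded from delta analysis: middle region %d < %d codons",
            alignment.gene_a, alignment.gene_b, middle.n_columns, n,
        )
        return None
    gene_seed = derive_gene_seed(seed, alignment.gene_a)
    rng = np.random.default_rng(gene_seed)
    cols = np.sort(rng.choice(middle.n_columns, size=n, replace=False))
    sample = middle.columns(cols)
    r_term = ng86_rates(terminal)
    r_mid = ng86_rates(sample)

    def _delta(x: float | None, y: float | None) -> float | None:
        return None if x is None or y is None else x - y

    return RegionRates(
        terminal=r_term,
        middle_sampled=r_mid,
        delta_dN=_delta(r_term.dN, r_mid.dN),
        delta_dS=_delta(r_term.dS, r_mid.dS),
        delta_omega=_delta(r_term.omega, r_mid.omega),
        seed=gene_seed,
    )


def rates_for_pair(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str,
    gene_a: str = "a", gene_b: str = "b",
) -> tuple[CodonAlignment, RatesResult]:
    """Convenience: align proteins, back-translate and estimate NG86 rates."""
    al_a, al_b = align_proteins_global(protein_a, protein_b)
    codon_aln = back_translate(al_a, al_b, cds_a, cds_b, gene_a, gene_b)
    return codon_aln, ng86_rates(codon_aln)
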