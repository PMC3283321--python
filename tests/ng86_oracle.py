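"""Independent NG86 counting oracle (exact Fraction arithmetic).

Written directly from the counting definitions — synonymous site fractions
from single-nucleotide neighbours, path-averaged difference counts with
stop-passing paths excluded — without reference to the package's
implementation. Used to certify the fast table-based estimator.
"""

import itertools
from fractions import Fraction

from Bio.Seq import Seq

ALL_CODONS = ["".join(c) for c in itertools.product("TCAG", repeat=3)]


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


SENSE_CODONS = [c for c in ALL_CODONS if aa_of(c) != "*"]


def oracle_syn_sites(codon: str) -> Fraction:
    syn = Fraction(0)
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            neighbour = codon[:pos] + nt + codon[pos + 1 :]
            if aa_of(neighbour) != "*" and aa_of(neighbour) == aa_of(codon):
                syn += 1
    return syn / 3


def oracle_pair_diffs(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """Average (synonymous, nonsynonymous) steps over minimal mutation
    paths, excluding paths through stop codons (falling back to all paths
    when every ordering hits a stop)."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    clean, blocked = [], []
    for order in itertools.permutations(diff):
        cur, s, n, hit_stop = c1, Fraction(0), Fraction(0), False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if aa_of(nxt) == "*":
                hit_stop = True
                n += 1
            elif aa_of(cur) != "*" and aa_of(cur) == aa_of(nxt):
                s += 1
            else:
                n += 1
            cur = nxt
        (blocked if hit_stop else clean).append((s, n))
    paths = clean or blocked
    k = len(paths)
    return (sum(p[0] for p in paths) / k, sum(p[1] for p in paths) / k)


def oracle_rates(codons_a: list[str], codons_b: list[str]):
    N = S = Nd = Sd = Fraction(0)
    for ca, cb in zip(codons_a, codons_b):
        s_sites = (oracle_syn_sites(ca) + oracle_syn_sites(cb)) / 2
        S += s_sites
        N += 3 - s_sites
        s, n = oracle_pair_diffs(ca, cb)
        Sd += s
        Nd += n
    return N, S, Nd, Sd
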