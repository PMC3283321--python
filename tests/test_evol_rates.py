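"""Codon alignment machinery and NG86 estimation against an exhaustive oracle."""

import math

import numpy as np
import pytest

import ctoevol as ce
from ctoevol import evol_rates as er

from ng86_oracle import SENSE_CODONS as ORACLE_SENSE, oracle_rates

# ---------------------------------------------------------------------------


def test_ng86_single_codon_example():
    r = ce.ng86_rates(ce.CodonAlignment("a", "b", "TTT", "TTA"))
    assert (r.Nd, r.Sd) == (1.0, 0.0)
    assert r.S == pytest.approx(0.5)
    assert r.N == pytest.approx(2.5)


def test_ng86_identical_sequences_have_zero_rates():
    cds = "ATGAAAGTTCCC"
    r = ce.ng86_rates(ce.CodonAlignment("a", "b", cds, cds))
    assert (r.Nd, r.Sd, r.dN, r.dS) == (0.0, 0.0, 0.0, 0.0)


@pytest.mark.parametrize("seed", [0, 1])
def test_ng86_matches_oracle_on_random_codon_pairs(seed):
    rng = np.random.default_rng(seed)
    codons_a = [ORACLE_SENSE[i] for i in rng.integers(0, 61, size=30)]
    codons_b = [ORACLE_SENSE[i] for i in rng.integers(0, 61, size=30)]
    N, S, Nd, Sd = oracle_rates(codons_a, codons_b)
    r = ce.ng86_rates(ce.CodonAlignment("a", "b", "".join(codons_a), "".join(codons_b)))
    assert r.N == pytest.approx(float(N), abs=1e-12)
    assert r.S == pytest.approx(float(S), abs=1e-12)
    assert r.Nd == pytest.approx(float(Nd), abs=1e-12)
    assert r.Sd == pytest.approx(float(Sd), abs=1e-12)
    # JC correction follows the counting
    if r.pS < 0.75:
        assert r.dS == pytest.approx(-0.75 * math.log(1 - 4 * r.pS / 3))


def test_ng86_is_symmetric_and_concatenation_invariant():
    rng = np.random.default_rng(3)
    a = "".join(ORACLE_SENSE[i] for i in rng.integers(0, 61, size=40))
    b = "".join(ORACLE_SENSE[i] for i in rng.integers(0, 61, size=40))
    r1 = ce.ng86_rates(ce.CodonAlignment("a", "b", a, b))
    r2 = ce.ng86_rates(ce.CodonAlignment("b", "a", b, a))
    assert (r1.N, r1.S, r1.Nd, r1.Sd, r1.dN, r1.dS) == (r2.N, r2.S, r2.Nd, r2.Sd, r2.dN, r2.dS)
    rcat = ce.ng86_rates(ce.CodonAlignment("a", "b", a + a, b + b))
    assert rcat.Nd == pytest.approx(2 * r1.Nd)
    assert rcat.dN == pytest.approx(r1.dN)
    assert rcat.dS == pytest.approx(r1.dS)


def test_ng86_sites_sum_to_three_per_comparable_codon():
    aln = ce.CodonAlignment("a", "b", "ATG---AAANNNTTT", "ATGCCCAAGTTTTTC")
    r = ce.ng86_rates(aln)
    # comparable codons: ATG/ATG, AAA/AAG, TTT/TTC (gap and N columns excluded)
    assert r.n_codons == 3
    assert r.N + r.S == pytest.approx(9.0)


def test_ng86_saturation_reported_as_undefined():
    # maximally different codons across many columns drive pN/pS past 3/4
    a = "TTT" * 30
    b = "AGG" * 30
    r = ce.ng86_rates(ce.CodonAlignment("a", "b", a, b))
    assert r.dN is None or r.dS is None
    assert r.omega is None
    with pytest.raises(ValueError, match="no comparable"):
        ce.ng86_rates(ce.CodonAlignment("a", "b", "---", "AAA"))


def test_ds_filter_boundaries():
    def res(ds):
        return er.RatesResult(1, 1, 0, 0, 0, 0, 0.0, ds, None, 1)

    results = {"keep": res(2.99), "drop": res(3.0), "sat": res(None)}
    kept, report = ce.ds_filter(results, max_ds=3.0)
    assert set(kept) == {"keep"}
    assert (report.n_high_ds, report.n_saturated) == (1, 1)


def test_protein_alignment_examples():
    a, b = ce.align_proteins_global("MKVL", "MKVL")
    assert (a, b) == ("MKVL", "MKVL")
    a, b = ce.align_proteins_global("MKV", "MV")
    assert (a, b) == ("MKV", "M-V")
    with pytest.raises(ValueError, match="illegal"):
        ce.align_proteins_global("MKX1", "MKV")


def test_alignment_score_is_optimal_against_hand_alignments():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    p1, p2 = "MKVLWAAL", "MKLWAL"

    def score(a1, a2):
        s, gap_open = 0.0, False
        for x, y in zip(a1, a2):
            if x == "-" or y == "-":
                s += -0.5 if gap_open else -10.0
                gap_open = True
            else:
                s += blosum[x, y]
                gap_open = False
        return s

    a1, a2 = ce.align_proteins_global(p1, p2)
    optimal = score(a1, a2)
    hand = [("MKVLWAAL", "MK-LWA-L"), ("MKVLWAAL", "MKLWAL--"), ("MKVLWAAL", "--MKLWAL")]
    assert all(optimal >= score(x, y) for x, y in hand)


def test_back_translate_construction_and_roundtrip():
    aln = ce.back_translate("M-K", "MGK", "ATGAAA", "ATGGGCAAG", "a", "b")
    assert aln.codons_a == "ATG---AAA"
    assert aln.codons_b == "ATGGGCAAG"
    assert aln.codons_a.replace("-", "") == "ATGAAA"
    with pytest.raises(ValueError, match="codon 2"):
        ce.back_translate("MK", "MK", "ATGTAA", "ATGAAA", "a", "b")  # internal stop
    with pytest.raises(ValueError, match="position 2"):
        ce.back_translate("MK", "MK", "ATGCCC", "ATGAAA", "a", "b")  # P where K aligned


def test_partition_terminal_middle_sizes():
    n = 140
    cds = "ATG" * n
    aln = ce.CodonAlignment("a", "b", cds, cds)
    term, mid = ce.partition_terminal_middle(aln)
    assert (term.n_columns, mid.n_columns) == (70, 70)
    aln200 = ce.CodonAlignment("a", "b", "ATG" * 200, "ATG" * 200)
    _, mid200 = ce.partition_terminal_middle(aln200)
    assert mid200.n_columns == 130
    with pytest.raises(ValueError, match="need >="):
        ce.partition_terminal_middle(ce.CodonAlignment("a", "b", "ATG" * 60, "ATG" * 60))


def test_partition_gap_columns_do_not_count_toward_the_head():
    # gap in sequence 1 inside the first 50 codons: column goes to middle,
    # and the 50th sequence-1 codon still lands in the terminal region
    n = 150
    codons_a = ["ATG"] * 10 + ["---"] + ["ATG"] * (n - 10)
    codons_b = ["ATG"] * (n + 1)
    aln = ce.CodonAlignment("a", "b", "".join(codons_a), "".join(codons_b))
    term, mid = ce.partition_terminal_middle(aln)
    assert term.n_columns == 70  # 50 head + 20 tail sequence-1 codons
    assert mid.n_columns == aln.n_columns - 70


def test_middle_sampling_is_seeded_and_exhaustive_at_exact_size():
    cds = "".join(ORACLE_SENSE[i % 61] for i in range(140))
    aln = ce.CodonAlignment("g1", "g1b", cds, cds)
    r1 = ce.sample_middle_and_delta(aln, seed=5)
    r2 = ce.sample_middle_and_delta(aln, seed=5)
    assert r1.delta_dS == r2.delta_dS == 0.0
    # middle region exactly 70 codons -> the sample is the whole middle
    assert r1.middle_sampled.n_codons == 70
    r3 = ce.sample_middle_and_delta(aln, seed=6)
    assert r3.middle_sampled.n_codons == 70

    short = ce.CodonAlignment("g2", "g2b", "ATG" * 141, "ATG" * 141)
    # middle has 71 columns -> sampling differs between seeds only in choice,
    # but a 250-codon middle request is impossible
    assert ce.sample_middle_and_delta(short, n=200) is None


def test_uniform_divergence_gives_unbiased_deltas(small_pair):
    """Terminal and middle regions cut from uniformly diverged sequences
    should show no systematic rate difference."""
    genes_a = {g.gene_id: g for g in small_pair.genomes["GA"].genes}
    genes_b = {g.gene_id: g for g in small_pair.genomes["GB"].genes}
    deltas = []
    for _, t in small_pair.truth.iterrows():
        ga, gb = genes_a[t["gene_GA"]], genes_b[t["gene_GB"]]
        rr = ce.sample_middle_and_delta(
            ce.CodonAlignment(ga.gene_id, gb.gene_id, ga.cds, gb.cds), seed=1
        )
        if rr is not None and rr.delta_dS is not None:
            deltas.append(rr.delta_dS)
    deltas = np.asarray(deltas)
    se = deltas.std(ddof=1) / math.sqrt(deltas.size)
    assert abs(deltas.mean()) < 3 * se + 1e-9
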