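"""Reciprocal-best-hit orthology: parsing, thresholds, triangles, lengths."""

import itertools

import pytest

import ctoevol as ce
from ctoevol.orthology import HitRecord, read_orthologs_tsv, write_orthologs_tsv


def _hit(q, s, ident=90.0, ev=1e-50, bits=500.0):
    return HitRecord(q, s, ident, ev, bits)


def test_read_hits_outfmt6(tmp_path):
    p = tmp_path / "hits.tsv"
    rows = [
        "a1\tb1\t90.00\t100\t10\t0\t1\t100\t1\t100\t1e-180\t500",
        "a1\tb2\t40.00\t100\t60\t0\t1\t100\t1\t100\t0.001\t80",
        "a2\tb2\t88.00\t100\t12\t0\t1\t100\t1\t100\t2e-60\t450",
        "a2\ta2\t100.0\t100\t0\t0\t1\t100\t1\t100\t0.0\t600",
        "a3\tb3\t70.00\t100\t30\t0\t1\t100\t1\t100\t1e-30\t300",
    ]
    p.write_text("\n".join(rows) + "\n")
    hits = ce.read_hits(p)
    assert len(hits) == 5  # self-hits retained at parse time
    assert hits[0].evalue == pytest.approx(1e-180)

    bad = tmp_path / "bad.tsv"
    bad.write_text(rows[0] + "\n" + "\t".join(rows[1].split("\t")[:11]) + "\n")
    with pytest.raises(ValueError, match="line 2"):
        ce.read_hits(bad)


@pytest.mark.parametrize(
    "ident, ev, kept",
    [
        (90.0, 1e-50, True),
        (45.0, 1e-50, False),   # identity must exceed 50%
        (50.0, 1e-50, False),   # strict inequality
        (90.0, 1e-5, False),    # E-value must be below 1e-5, strictly
        (90.0, 9e-6, True),
    ],
)
def test_rbh_thresholds_are_strict(ident, ev, kept):
    ab = [_hit("a1", "b1", ident, ev)]
    ba = [_hit("b1", "a1", ident, ev)]
    pairs = ce.reciprocal_best_hits(ab, ba, "A", "B")
    assert bool(pairs) is kept


def test_rbh_requires_reciprocity_and_is_a_matching():
    ab = [_hit("a1", "b1", bits=500), _hit("a2", "b1", bits=400)]
    ba = [_hit("b1", "a2", bits=400)]  # b1 prefers a2, a1 is left out
    pairs = ce.reciprocal_best_hits(ab, ba, "A", "B")
    assert [p.members for p in pairs] == [{"A": "a2", "B": "b1"}]
    used = list(itertools.chain.from_iterable(p.members.values() for p in pairs))
    assert len(used) == len(set(used))


def test_rbh_is_symmetric_in_the_two_hit_files(small_pair):
    from ctoevol.synthetic_data import make_hit_tables
    import tempfile, pathlib

    ab_rows, ba_rows = make_hit_tables(small_pair, "GA", "GB")
    with tempfile.TemporaryDirectory() as d:
        pa, pb = pathlib.Path(d, "ab.tsv"), pathlib.Path(d, "ba.tsv")
        pa.write_text("\n".join(ab_rows) + "\n")
        pb.write_text("\n".join(ba_rows) + "\n")
        ab, ba = ce.read_hits(pa), ce.read_hits(pb)
    fwd = ce.reciprocal_best_hits(ab, ba, "GA", "GB")
    rev = ce.reciprocal_best_hits(ba, ab, "GB", "GA")
    assert {tuple(sorted(p.members.values())) for p in fwd} == {
        tuple(sorted(p.members.values())) for p in rev
    }


def test_rbh_recall_is_complete_on_simulator_truth(small_pair):
    from ctoevol.synthetic_data import make_hit_tables
    import tempfile, pathlib

    ab_rows, ba_rows = make_hit_tables(small_pair, "GA", "GB")
    with tempfile.TemporaryDirectory() as d:
        pa, pb = pathlib.Path(d, "ab.tsv"), pathlib.Path(d, "ba.tsv")
        pa.write_text("\n".join(ab_rows) + "\n")
        pb.write_text("\n".join(ba_rows) + "\n")
        pairs = ce.reciprocal_best_hits(
            ce.read_hits(pa), ce.read_hits(pb), "GA", "GB"
        )
    truth_pairs = {
        (r["gene_GA"], r["gene_GB"]) for _, r in small_pair.truth.iterrows()
    }
    found = {(p.members["GA"], p.members["GB"]) for p in pairs}
    assert found == truth_pairs  # recall (and precision) = 100%


def _pairs(links, ga, gb):
    return [ce.OrthologGroup(members={ga: a, gb: b}) for a, b in links]


def test_three_way_closed_triangles():
    ab = _pairs([("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a4", "b4")], "A", "B")
    bc = _pairs([("b1", "c1"), ("b2", "c2"), ("b3", "c3")], "B", "C")
    ac = _pairs([("a1", "c1"), ("a2", "c2"), ("a3", "c9")], "A", "C")
    triples = ce.three_way_one_to_one(ab, bc, ac)
    # a3's triangle is open (a3-c9 vs b3-c3); a4 has no B-C link
    assert [t.members for t in triples] == [
        {"A": "a1", "B": "b1", "C": "c1"},
        {"A": "a2", "B": "b2", "C": "c2"},
    ]


def test_three_way_count_matches_bruteforce_triangle_enumeration():
    # 10 genes per genome, a hand-built link graph with exactly 3 closed triangles
    links_ab = [(f"a{i}", f"b{i}") for i in range(10)]
    links_bc = [(f"b{i}", f"c{i}") for i in (0, 1, 2, 5, 6)]
    links_ac = [(f"a{i}", f"c{i}") for i in (0, 1, 2, 7)]
    ab = _pairs(links_ab, "A", "B")
    bc = _pairs(links_bc, "B", "C")
    ac = _pairs(links_ac, "A", "C")
    # independent brute force over all (a, b, c) combinations
    sab, sbc, sac = set(links_ab), set(links_bc), set(links_ac)
    expected = sum(
        1
        for a, b in links_ab
        for b2, c in links_bc
        if b2 == b and (a, c) in sac
    )
    assert expected == 3
    assert len(ce.three_way_one_to_one(ab, bc, ac)) == expected


def test_length_filter_drops_group_when_any_member_is_short():
    def genome(gid, lengths):
        genes = []
        pos = 1
        for i, ncod in enumerate(lengths):
            cds = "ATG" + "AAA" * (ncod - 1)
            genes.append(
                ce.GeneRecord(f"{gid}_{i}", pos, pos + 3 * ncod - 1, "+", cds, "M" + "K" * (ncod - 1))
            )
            pos += 3 * ncod + 10
        return ce.GenomeAnnotation(gid, 100_000, 1, 50_000, genes)

    ga = genome("A", [150, 150, 140])
    gb = genome("B", [150, 139, 140])  # A_1/B_1 pair: B side is 417 bp < 420
    groups = [
        ce.OrthologGroup(members={"A": "A_0", "B": "B_0"}),
        ce.OrthologGroup(members={"A": "A_1", "B": "B_1"}),
        ce.OrthologGroup(members={"A": "A_2", "B": "B_2"}),  # exactly 420 bp: kept
    ]
    kept = ce.length_filter(groups, [ga, gb])
    assert [g.members["A"] for g in kept] == ["A_0", "A_2"]
    with pytest.raises(KeyError, match="unknown gene id"):
        ce.length_filter([ce.OrthologGroup(members={"A": "nope", "B": "B_0"})], [ga, gb])


def test_orthologs_tsv_roundtrip(tmp_path):
    groups = _pairs([("a1", "b1"), ("a2", "b2")], "A", "B")
    path = write_orthologs_tsv(groups, tmp_path / "orth.tsv")
    back = read_orthologs_tsv(path)
    assert [g.members for g in back] == [g.members for g in groups]
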