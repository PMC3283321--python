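"""Shared fixtures: toy GenBank files and small simulated comparisons."""

from pathlib import Path

import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

import ctoevol as ce


def _toy_record() -> SeqRecord:
    """120-bp toy chromosome: 2 valid CDSs (one minus-strand), 1 pseudogene,
    1 CDS whose span is not a codon multiple (skipped by the parser)."""
    seq = ["c"] * 120

    def put(s, start):  # 1-based
        for i, ch in enumerate(s):
            seq[start - 1 + i] = ch

    put("atgaaagtttaa", 4)  # tg_0001 (+): MKV + stop
    put(str(Seq("atgggtgcatga").reverse_complement()).lower(), 31)  # tg_0002 (-): MGA + stop
    put("atgtga", 61)  # pseudo span
    record = SeqRecord(Seq("".join(seq).upper()), id="TOY00001", name="TOY00001",
                       annotations={"molecule_type": "DNA", "topology": "circular"})
    record.features = [
        SeqFeature(FeatureLocation(3, 15, 1), type="CDS",
                   qualifiers={"locus_tag": ["tg_0001"], "translation": ["MKV"]}),
        SeqFeature(FeatureLocation(30, 42, -1), type="CDS",
                   qualifiers={"locus_tag": ["tg_0002"], "translation": ["MGA"]}),
        SeqFeature(FeatureLocation(60, 66, 1), type="CDS",
                   qualifiers={"locus_tag": ["tg_0003"], "pseudo": [""]}),
        SeqFeature(FeatureLocation(90, 101, 1), type="CDS",
                   qualifiers={"locus_tag": ["tg_0004"], "translation": ["MSL"]}),
    ]
    return record


@pytest.fixture()
def toy_genbank(tmp_path: Path) -> Path:
    p = tmp_path / "toy.gbk"
    SeqIO.write([_toy_record()], str(p), "genbank")
    return p


@pytest.fixture(scope="session")
def small_pair() -> ce.SimulatedComparison:
    """A small simulated two-genome comparison used across modules."""
    cfg = ce.null_config(seed=42, n_genes=40, chromosome_length=150_000, ter=75_001)
    return ce.simulate_pair(cfg)


@pytest.fixture(scope="session")
def small_triple() -> ce.SimulatedComparison:
    cfg = ce.null_config(seed=43, n_genes=40, chromosome_length=150_000, ter=75_001)
    return ce.simulate_triple(cfg)
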