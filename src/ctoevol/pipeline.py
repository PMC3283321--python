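"""End-to-end orchestration: config, staged runs, replicate harnesses.

A run reproduces the study design: parse annotated genomes, find
one-to-one orthologs (reciprocal best hits, then the 420-bp length
filter), classify orientation conservation and replichore geometry,
estimate NG86 rates with the dS < 3 filter, and compare COG vs SOG rates
overall and within confounder strata. Every stage writes a plain TSV
checkpoint and logs its in/out gene counts, so the bookkeeping of how
many groups survive each filter is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evol_rates, genome_io, orientation_geometry as geom, orthology, stats
from .synthetic_data import SimulatedComparison, SimulationConfig, simulate_pair

logger = logging.getLogger("ctoevol")


@dataclass
class GenomeEntry:
    id: str
    annotation: str
    ori: int
    ter: int
    flip: bool = False


@dataclass
class Thresholds:
    max_evalue: float = 1e-5
    min_identity: float = 50.0
    min_cds_length: int = 420
    max_ds: float = 3.0
    head_codons: int = 50
    tail_codons: int = 20
    middle_sample: int = 70
    top_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("max_evalue", "min_identity", "min_cds_length", "max_ds",
                     "head_codons", "tail_codons", "middle_sample", "top_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    genomes: list[GenomeEntry]
    hits: dict[str, list[str]] = field(default_factory=dict)  # "A-B" -> [ab, ba]
    expression: dict[str, str] = field(default_factory=dict)  # genome id -> tsv
    essential_genes: str | None = None
    outgroup: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "ctoevol_out"
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        genomes = [GenomeEntry(**g) for g in raw["genomes"]]
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            genomes=genomes,
            hits={k: list(v) for k, v in raw.get("hits", {}).items()},
            expression=dict(raw.get("expression", {})),
            essential_genes=raw.get("essential_genes"),
            outgroup=raw.get("outgroup"),
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir", "ctoevol_out"),
            base_dir=path.parent,
        )

    def resolve(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q


def _pair_key(a: str, b: str) -> str:
    return f"{a}-{b}"


def load_annotations(config: RunConfig) -> list[genome_io.GenomeAnnotation]:
    annotations = []
    for entry in config.genomes:
        ann = genome_io.parse_genome(
            config.resolve(entry.annotation), ori=entry.ori, ter=entry.ter, genome_id=entry.id
        )
        annotations.append(ann)
    if len(annotations) not in (2, 3):
        raise ValueError("pipeline supports 2 or 3 genomes")
    return annotations


def compute_orthologs(
    config: RunConfig, annotations: list[genome_io.GenomeAnnotation]
) -> tuple[list[orthology.OrthologGroup], dict]:
    """RBH per genome pair, three-way closure when three genomes, then the
    length filter. Writes ``orthologs.tsv``."""
    th = config.thresholds
    ids = [a.genome_id for a in annotations]
    counts: dict = {}
    pair_lists = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            try:
                f_ab, f_ba = config.hits[_pair_key(a, b)]
            except KeyError:
                f_ba, f_ab = config.hits[_pair_key(b, a)]
            hits_ab = orthology.read_hits(config.resolve(f_ab))
            hits_ba = orthology.read_hits(config.resolve(f_ba))
            pairs = orthology.reciprocal_best_hits(
                hits_ab, hits_ba, a, b,
                max_evalue=th.max_evalue, min_identity=th.min_identity,
            )
            pair_lists[(a, b)] = pairs
            counts[f"rbh_{a}_{b}"] = len(pairs)
    if len(ids) == 3:
        groups = orthology.three_way_one_to_one(
            pair_lists[(ids[0], ids[1])],
            pair_lists[(ids[1], ids[2])],
            pair_lists[(ids[0], ids[2])],
        )
    else:
        groups = pair_lists[(ids[0], ids[1])]
    counts["ortholog_groups"] = len(groups)
    groups = orthology.length_filter(groups, annotations, th.min_cds_length)
    counts["groups_after_length_filter"] = len(groups)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    orthology.write_orthologs_tsv(groups, outdir / "orthologs.tsv")
    return groups, counts


def compute_geometry(
    config: RunConfig,
    annotations: list[genome_io.GenomeAnnotation],
    groups: list[orthology.OrthologGroup],
) -> pd.DataFrame:
    """Strand/replichore/confrontation/distance table; writes ``geometry.tsv``."""
    flips = {e.id: e.flip for e in config.genomes}
    geo = geom.geometry_table(groups, annotations, flips, outgroup=config.outgroup)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo.to_csv(outdir / "geometry.tsv", sep="\t", index=False)
    return geo


def compute_rates(
    config: RunConfig,
    annotations: list[genome_io.GenomeAnnotation],
    groups: list[orthology.OrthologGroup],
    geo: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, evol_rates.CodonAlignment], dict]:
    """Align, back-translate and NG86-estimate the primary genome pair
    (the first two configured genomes); apply the dS filter. Writes
    ``rates.tsv``."""
    th = config.thresholds
    outdir = Path(config.outdir)
    counts: dict = {}
    ids = [a.genome_id for a in annotations]
    a, b = ids[0], ids[1]
    by_id = genome_io.genes_by_id(annotations)
    results: dict[str, evol_rates.RatesResult] = {}
    alignments: dict[str, evol_rates.CodonAlignment] = {}
    group_ids = []
    for i, grp in enumerate(groups):
        gid = f"og{i:05d}"
        group_ids.append(gid)
        ga = by_id[a][grp.members[a]]
        gb = by_id[b][grp.members[b]]
        aln, res = evol_rates.rates_for_pair(
            ga.protein, gb.protein, ga.cds, gb.cds, ga.gene_id, gb.gene_id
        )
        alignments[gid] = aln
        results[gid] = res
    kept, filt = evol_rates.ds_filter(results, th.max_ds)
    counts["ds_filter"] = {
        "input": filt.n_input, "kept": filt.n_kept,
        "removed_high": filt.n_high_ds, "removed_saturated": filt.n_saturated,
    }

    geo_primary = geo[geo["genome"] == a].set_index("group_id")
    rates_df = pd.DataFrame(
        {
            "group_id": list(kept),
            "dN": [kept[g].dN for g in kept],
            "dS": [kept[g].dS for g in kept],
            "omega": [kept[g].omega for g in kept],
            "N": [kept[g].N for g in kept],
            "S": [kept[g].S for g in kept],
            "Nd": [kept[g].Nd for g in kept],
            "Sd": [kept[g].Sd for g in kept],
        }
    ).set_index("group_id")
    rates_df["orientation_call"] = geo_primary["orientation_call"]
    rates_df["lineage_call"] = geo_primary.get("lineage_call")
    rates_df["distance_to_ter"] = geo_primary["distance_to_ter"]
    rates_df["confrontation"] = geo_primary["confrontation"]
    rates_df["gene_a"] = geo_primary["gene_id"]
    gene_b_col = geo[geo["genome"] == b].set_index("group_id")["gene_id"]
    rates_df["gene_b"] = gene_b_col
    rates_df.to_csv(outdir / "rates.tsv", sep="\t")
    kept_alignments = {g: alignments[g] for g in kept}
    return rates_df, kept_alignments, counts


def compute_deltas(
    config: RunConfig, alignments: dict[str, evol_rates.CodonAlignment]
) -> pd.DataFrame:
    """Terminal-vs-sampled-middle rate differences; writes ``region_deltas.tsv``."""
    th = config.thresholds
    outdir = Path(config.outdir)
    delta_rows = []
    for gid in alignments:
        rr = evol_rates.sample_middle_and_delta(
            alignments[gid], n=th.middle_sample,
            head=th.head_codons, tail=th.tail_codons, seed=config.seed,
        )
        if rr is None:
            continue
        delta_rows.append(
            {
                "group_id": gid,
                "delta_dN": rr.delta_dN,
                "delta_dS": rr.delta_dS,
                "delta_omega": rr.delta_omega,
                "seed": rr.seed,
            }
        )
    deltas = pd.DataFrame(delta_rows)
    deltas.to_csv(outdir / "region_deltas.tsv", sep="\t", index=False)
    return deltas


def compute_comparisons(
    config: RunConfig, rates_df: pd.DataFrame, n_genomes: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """COG-vs-SOG comparisons (overall and per confounder stratum) and the
    distance-controlled partial-correlation table. Writes
    ``comparisons.tsv`` and ``partial_correlations.tsv``."""
    th = config.thresholds
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    a = config.genomes[0].id
    reports: list[stats.ComparisonReport] = []
    reports += stats.grouped_rate_comparison(rates_df)

    if config.essential_genes:
        essential = genome_io.read_gene_list(config.resolve(config.essential_genes))
        strata = rates_df["gene_a"].map(
            lambda g: "essential" if g in essential else "nonessential"
        )
        reports += stats.grouped_rate_comparison(rates_df, strata)

    for genome_id, expr_path in config.expression.items():
        if genome_id != a:
            continue  # expression strata follow the primary genome of the pair
        expr = genome_io.read_expression_table(config.resolve(expr_path))
        expr = expr.dropna()
        if expr.shape[1] >= 2:
            expr = stats.quantile_normalize(expr)
        for phase in expr.columns:
            std = pd.Series(
                stats.standardize_expression(expr[phase].to_numpy()), index=expr.index
            )
            highly, _ = stats.stratify_top_quantile(std, th.top_fraction)
            strata = rates_df["gene_a"].map(
                lambda g: f"highly ({phase})" if g in highly else f"non-highly ({phase})"
            )
            strata[~rates_df["gene_a"].isin(expr.index)] = np.nan
            reports += stats.grouped_rate_comparison(rates_df, strata)

    reports += stats.grouped_rate_comparison(rates_df, rates_df["confrontation"])
    if n_genomes == 3 and rates_df["lineage_call"].notna().any():
        reports += stats.grouped_rate_comparison(rates_df, rates_df["lineage_call"])

    report_df = stats.report_frame(reports)
    report_df.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)

    # --- partial correlations (type vs rate, distance to Ter controlled)
    pc_rows = []
    type_code = (rates_df["orientation_call"] == "COG").astype(float)
    for metric in ("dN", "dS", "omega"):
        vals = rates_df[metric]
        mask = vals.notna()
        if mask.sum() >= 4 and type_code[mask].nunique() > 1:
            rho_m, p_m = stats.spearman_rho(type_code[mask], vals[mask])
            rho_p, p_p = stats.partial_spearman(
                type_code[mask], vals[mask], rates_df["distance_to_ter"][mask]
            )
        else:
            rho_m = p_m = rho_p = p_p = float("nan")
        pc_rows.append(
            {
                "metric": metric,
                "marginal_rho": rho_m, "marginal_p": p_m,
                "partial_rho_given_distance": rho_p, "partial_p": p_p,
            }
        )
    partial_df = pd.DataFrame(pc_rows)
    partial_df.to_csv(outdir / "partial_correlations.tsv", sep="\t", index=False)
    return report_df, partial_df


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns a bundle of frames and counts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = load_annotations(config)
    counts: dict = {f"genes_{a.genome_id}": len(a.genes) for a in annotations}
    groups, c = compute_orthologs(config, annotations)
    counts.update(c)
    geo = compute_geometry(config, annotations, groups)
    rates_df, alignments, c = compute_rates(config, annotations, groups, geo)
    counts.update(c)
    deltas = compute_deltas(config, alignments)
    counts["delta_analysis_genes"] = len(deltas)
    report_df, partial_df = compute_comparisons(config, rates_df, n_genomes=len(annotations))
    (outdir / "counts.json").write_text(json.dumps(counts, indent=2) + "\n")
    logger.info("pipeline complete: %s", json.dumps(counts))
    return {
        "outdir": str(outdir),
        "counts": counts,
        "rates": rates_df,
        "comparisons": report_df,
        "partial_correlations": partial_df,
        "deltas": deltas,
    }


# ---------------------------------------------------------------------------
# simulation-backed harnesses (used by tests and the acceptance script)


def rates_from_simulation(
    sim: SimulatedComparison,
    max_ds: float = 3.0,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Per-gene NG86 rates for a simulated pair, joined with geometry.

    The simulator introduces no indels, so the codon sequences of the two
    lineages are already aligned column-for-column and are fed to the NG86
    estimator directly (the protein-alignment step would be an identity).
    Orientation calls are made by the pipeline's classifier from the final
    strands, not read from the truth labels.
    """
    a, b = sim.genome_ids[:2]
    genes_a = {g.gene_id: g for g in sim.genomes[a].genes}
    genes_b = {g.gene_id: g for g in sim.genomes[b].genes}
    rows = []
    for _, t in sim.truth.iterrows():
        ga, gb = genes_a[t[f"gene_{a}"]], genes_b[t[f"gene_{b}"]]
        aln = evol_rates.CodonAlignment(ga.gene_id, gb.gene_id, ga.cds, gb.cds)
        r = evol_rates.ng86_rates(aln)
        rows.append(
            {
                "gene_index": int(t["gene_index"]),
                "orientation_call": geom.classify_orientation_pair(ga.strand, gb.strand),
                "dN": r.dN, "dS": r.dS, "omega": r.omega,
                "distance_to_ter": t[f"dist_ter_{a}"],
                "confrontation": t[f"confrontation_{a}"],
                "true_class": t["orientation_class"],
                "true_multiplier": t["pair_multiplier"],
            }
        )
    df = pd.DataFrame(rows).set_index("gene_index")
    if apply_filter:
        defined = df["dS"].notna() & (df["dS"] < max_ds)
        df = df[defined]
    return df


def cog_sog_replicates(
    base_config: SimulationConfig,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Replicate COG-vs-SOG Wilcoxon p-values over fresh simulated pairs.

    Each replicate draws its own simulator seed from a seed sequence
    spawned from ``seed``; replicates without at least 2 genes in each
    orientation class are recorded with NaN p-values.
    """
    from dataclasses import replace as dc_replace

    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for k in range(n_replicates):
        cfg = dc_replace(base_config, seed=int(rep_seeds[k]))
        sim = simulate_pair(cfg)
        df = rates_from_simulation(sim)
        cog = df[df["orientation_call"] == "COG"]
        sog = df[df["orientation_call"] == "SOG"]
        row = {"replicate": k, "n_cog": len(cog), "n_sog": len(sog)}
        for metric in ("dN", "dS", "omega"):
            xc = cog[metric].dropna()
            xs = sog[metric].dropna()
            if len(xc) >= 2 and len(xs) >= 2:
                _, p = stats.wilcoxon_rank_sum(xc, xs)
            else:
                p = float("nan")
            row[f"p_{metric}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
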