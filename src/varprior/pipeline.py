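"""High-level workflows tying the modules together: build a scored
background database, score a target VCF against it, and run the synthetic
end-to-end benchmark (simulate -> train impact -> build -> score -> evaluate).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .background import BackgroundIndex, build_frequency_index
from .evaluation import EvalSummary, LabeledScore, evaluate, score_vs_frequency
from .impact import ImpactTable, estimate_tables, training_observations
from .io import (CODING, NON_CODING, ConservationTrack, GeneModels, RegionMask,
                 read_variants, variant_key)
from .percentile import assign_percentiles, build_index_crds
from .scoring import ScoreResult, score_variant
from .simulate import SimConfig, simulate_all


def train_impact_table(disease_vcf, population_vcf,
                       conservation: Optional[ConservationTrack] = None,
                       n_bins: int = 2, pseudocount: float = 1.0) -> ImpactTable:
    """Estimate empirical impact tables from annotated training VCFs."""
    disease = training_observations(read_variants(disease_vcf, conservation=conservation))
    population = training_observations(read_variants(population_vcf, conservation=conservation))
    return estimate_tables(disease, population, n_bins=n_bins, pseudocount=pseudocount)


def build_background(population_vcf,
                     conservation: Optional[ConservationTrack] = None,
                     gene_models: Optional[GeneModels] = None,
                     region_mask: Optional[RegionMask] = None,
                     impact_table: Optional[ImpactTable] = None,
                     min_gene_variants: int = 10,
                     ) -> tuple[BackgroundIndex, list[ScoreResult]]:
    """Build the full background database: allele counts, then het-state raw
    scores of every background variant grouped into per-gene CRDs.

    Returns the index and the scored background (useful for score-frequency
    profiles). The impact mode used here is recorded and enforced at query
    time.
    """
    table = impact_table if impact_table is not None else ImpactTable.off()
    index = build_frequency_index(population_vcf, region_mask=region_mask)
    records = read_variants(population_vcf, region_mask=region_mask,
                            conservation=conservation)
    scored = [score_variant(rec, index, table, gene_models=gene_models)
              for rec in records]
    build_index_crds(index, scored, min_gene_variants=min_gene_variants)
    index.metadata["impact_mode"] = table.mode
    return index, scored


def score_file(target_vcf, index: BackgroundIndex, table: ImpactTable,
               conservation: Optional[ConservationTrack] = None,
               gene_models: Optional[GeneModels] = None,
               region_mask: Optional[RegionMask] = None) -> list[ScoreResult]:
    """Score every variant of a target VCF and fill percentile ranks.

    The impact mode must match the one the background CRDs were built with;
    a mismatch would make raw scores incommensurable with the CRDs.
    """
    built_mode = index.metadata.get("impact_mode")
    if built_mode is not None and built_mode != table.mode:
        raise ValueError(f"impact mode mismatch: index built with {built_mode!r}, "
                         f"scoring requested with {table.mode!r}")
    results = []
    for rec in read_variants(target_vcf, region_mask=region_mask,
                             conservation=conservation):
        res = score_variant(rec, index, table, gene_models=gene_models)
        assign_percentiles(res, index)
        results.append(res)
    return results


@dataclass
class BenchmarkResult:
    """Everything the synthetic end-to-end benchmark produces."""
    config: SimConfig
    paths: dict
    index: BackgroundIndex
    impact_table: ImpactTable
    results: list
    labeled_raw: list                 # LabeledScore on raw het scores
    background_scored: list           # het/hom ScoreResults of the background
    summary_raw: EvalSummary
    summary_coding_pct: Optional[EvalSummary]
    summary_noncoding_pct: Optional[EvalSummary]
    frequency_profile: pd.DataFrame   # mean background raw score per AF bin


def _labeled(results, labels: pd.DataFrame, attr: str,
             groups: Optional[set] = None) -> list[LabeledScore]:
    by_key = {r.variant_key: r for r in results}
    out = []
    for row in labels.itertuples():
        key = variant_key(row.chrom, int(row.pos), row.ref, row.alt)
        res = by_key.get(key)
        if res is None:
            out.append(LabeledScore(score=None, label=row.label,
                                    frequency=row.frequency))
            continue
        if groups is not None and res.effect_group not in groups:
            continue
        score = getattr(res, attr)
        out.append(LabeledScore(score=None if pd.isna(score) else float(score),
                                label=row.label, group=res.effect_group,
                                frequency=row.frequency))
    return out


def run_benchmark(config: Optional[SimConfig] = None, workdir=None) -> BenchmarkResult:
    """Run the full synthetic pipeline and evaluate it.

    The headline summary uses raw het-state scores (comparable across effect
    classes); per-class summaries use percentile scores, which are only
    comparable within a class.
    """
    import tempfile
    config = config if config is not None else SimConfig()
    if workdir is None:
        workdir = tempfile.mkdtemp(prefix="varprior_bench_")
    paths = simulate_all(config, workdir)
    conservation = ConservationTrack.from_bedgraph(paths["conservation"])
    gene_models = GeneModels.from_gff3(paths["genes"])
    table = train_impact_table(paths["disease_train"], paths["population_train"],
                               conservation=conservation)
    index, background_scored = build_background(
        paths["population"], conservation=conservation,
        gene_models=gene_models, impact_table=table)
    results = score_file(paths["test"], index, table, conservation=conservation,
                         gene_models=gene_models)
    labels = pd.read_csv(paths["labels"], sep="\t")

    labeled_raw = _labeled(results, labels, "raw_het")
    summary_raw = evaluate(labeled_raw)
    def _pct_summary(group):
        data = _labeled(results, labels, "percentile_het", groups={group})
        try:
            return evaluate(data)
        except ValueError:
            return None
    summary_coding = _pct_summary(CODING)
    summary_noncoding = _pct_summary(NON_CODING)

    freq_data = [LabeledScore(score=r.raw_het, label="benign",
                              frequency=r.counts_used.x_u / r.counts_used.n_b)
                 for r in background_scored if r.counts_used.x_u > 0]
    profile = score_vs_frequency(freq_data)

    return BenchmarkResult(config=config, paths=paths, index=index,
                           impact_table=table, results=results,
                           labeled_raw=labeled_raw,
                           background_scored=background_scored,
                           summary_raw=summary_raw,
                           summary_coding_pct=summary_coding,
                           summary_noncoding_pct=summary_noncoding,
                           frequency_profile=profile)
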