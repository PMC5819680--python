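"""Composite likelihood-ratio scoring of single variants.

The null model says the proband and the background population share one
allele frequency; the alternative gives each its own frequency. With MLE
plug-in frequencies the log likelihood ratio is non-negative and grows as
the proband's genotype becomes less compatible with the population
frequency — i.e. rare variants score high. The log impact ratio ln(a/h)
adds the change-type and conservation evidence:

    lambda = [l(x_u; n_b, p_u) + l(x_a; n_t, p_a) - l(x; n, p)] + ln(a/h)

where l is the binomial log likelihood without its constant n-choose-x term,
x = x_u + x_a, n = n_b + n_t, and p, p_u, p_a are the pooled, population and
proband allele-frequency MLEs. Scores are reported for both the heterozygous
(x_a = 1) and homozygous (x_a = 2) state of a single diploid proband.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import pandas as pd
import pysam
from scipy.special import xlogy

from .background import AlleleCounts, BackgroundIndex, query_counts
from .impact import ImpactTable, change_type_of, impact_ratio
from .io import INTERGENIC, VariantRecord


class GenotypeState(NamedTuple):
    """Proband chromosomes bearing the variant (x_a) out of n_t."""
    x_a: int
    n_t: int = 2


HET = GenotypeState(1, 2)
HOM = GenotypeState(2, 2)


def binomial_loglik(x: int, n: int, p: float) -> float:
    """x*ln(p) + (n-x)*ln(1-p), with 0*ln(0) = 0; the n-choose-x constant is
    omitted. Impossible observations (p=0 with x>0, p=1 with x<n) return
    -inf rather than raising."""
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"need 0 <= p <= 1, got p={p}")
    return float(xlogy(x, p) + xlogy(n - x, 1.0 - p))


def raw_score(counts: AlleleCounts, genotype: GenotypeState,
              impact_ratio_value: float) -> float:
    """The variant's raw score (lambda) for one genotype state.

    Finite for all valid inputs: the MLE plug-in frequencies never put zero
    probability on an observed count.
    """
    if counts.n_b <= 0:
        raise ValueError("background chromosome count n_b must be positive")
    if impact_ratio_value <= 0:
        raise ValueError("impact ratio must be strictly positive")
    x_u, n_b = counts
    x_a, n_t = genotype
    x, n = x_u + x_a, n_b + n_t
    p = x / n
    p_u = x_u / n_b
    p_a = x_a / n_t
    lik_alt = binomial_loglik(x_u, n_b, p_u) + binomial_loglik(x_a, n_t, p_a)
    lik_null = binomial_loglik(x, n, p)
    return lik_alt - lik_null + math.log(impact_ratio_value)


@dataclass
class ScoreResult:
    """Raw and percentile scores for one variant, both genotype states."""
    variant_key: tuple
    gene_id: Optional[str]
    effect_group: str
    winning_transcript: Optional[str]
    raw_het: float
    raw_hom: float
    percentile_het: float = float("nan")
    percentile_hom: float = float("nan")
    impact_ratio_used: float = 1.0
    counts_used: AlleleCounts = AlleleCounts(0, 1)
    crd_fallback: bool = False


def score_variant(record: VariantRecord, index: BackgroundIndex,
                  table: ImpactTable, gene_models=None) -> ScoreResult:
    """Score one variant in het and hom state.

    Each transcript annotation is scored with its own change type; the
    reported result takes the transcript maximizing the het-state score.
    Unannotated records score with impact 1; their gene and effect group come
    from ``gene_models`` when provided, else they fall to intergenic.
    """
    counts = query_counts(index, record.key)
    if record.annotations:
        best = None
        for ann in record.annotations:
            ct = change_type_of(ann, record.ref, record.alt)
            ratio = impact_ratio(table, ct, record.conservation)
            het = raw_score(counts, HET, ratio)
            if best is None or het > best[0]:
                best = (het, ann, ratio)
        het, ann, ratio = best
        hom = raw_score(counts, HOM, ratio)
        return ScoreResult(record.key, ann.gene_id, ann.effect_group,
                           ann.transcript_id, het, hom,
                           impact_ratio_used=ratio, counts_used=counts)
    gene_id, group = (None, INTERGENIC)
    if gene_models is not None:
        located_gene, region = gene_models.locate(record.chrom, record.pos)
        if located_gene is not None:
            gene_id, group = located_gene, region
    het = raw_score(counts, HET, 1.0)
    hom = raw_score(counts, HOM, 1.0)
    return ScoreResult(record.key, gene_id, group, None, het, hom,
                       impact_ratio_used=1.0, counts_used=counts)


# ---------------------------------------------------------------------------
# Tabular / VCF output

_INFO_KEYS = (
    ("VPS_RAW_HET", "Float", "Raw het-state likelihood-ratio score"),
    ("VPS_RAW_HOM", "Float", "Raw hom-state likelihood-ratio score"),
    ("VPS_PCT_HET", "Float", "Het-state percentile score"),
    ("VPS_PCT_HOM", "Float", "Hom-state percentile score"),
    ("VPS_GROUP", "String", "Effect group used for percentile normalization"),
    ("VPS_GENE", "String", "Gene of the winning transcript"),
)


def results_to_dataframe(results) -> pd.DataFrame:
    rows = []
    for r in results:
        chrom, pos, ref, alt = r.variant_key
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": r.gene_id, "group": r.effect_group,
            "transcript": r.winning_transcript,
            "raw_het": r.raw_het, "raw_hom": r.raw_hom,
            "pct_het": r.percentile_het, "pct_hom": r.percentile_hom,
            "impact_ratio": r.impact_ratio_used,
            "x_u": r.counts_used.x_u, "n_b": r.counts_used.n_b,
            "crd_fallback": r.crd_fallback,
        })
    return pd.DataFrame(rows)


def write_scored_vcf(results, template_vcf, out_path) -> None:
    """Write one VCF record per scored allele, with score INFO keys, using
    the template's contigs. Re-reading reproduces the variant keys."""
    template = pysam.VariantFile(str(template_vcf))
    header = pysam.VariantHeader()
    for contig in template.header.contigs.values():
        header.contigs.add(contig.name, length=contig.length)
    for key, typ, desc in _INFO_KEYS:
        header.info.add(key, 1, typ, desc)
    with pysam.VariantFile(str(out_path), "w", header=header) as out:
        for r in results:
            chrom, pos, ref, alt = r.variant_key
            rec = out.new_record(contig=chrom, start=pos - 1,
                                 alleles=(ref, alt))
            rec.info["VPS_RAW_HET"] = float(r.raw_het)
            rec.info["VPS_RAW_HOM"] = float(r.raw_hom)
            if not math.isnan(r.percentile_het):
                rec.info["VPS_PCT_HET"] = float(r.percentile_het)
                rec.info["VPS_PCT_HOM"] = float(r.percentile_hom)
            rec.info["VPS_GROUP"] = r.effect_group
            if r.gene_id:
                rec.info["VPS_GENE"] = r.gene_id
            out.write(rec)
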