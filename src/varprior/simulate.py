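"""Synthetic study-system generator.

Emits a self-contained, mutually consistent set of inputs for the whole
pipeline: a multi-sample background population VCF with VEP-style CSQ
annotations, GFF3 gene models, a per-base conservation bedGraph, impact
training sets, and a labeled pathogenic/benign test set with a truth table.

The emulated structure: genes differ in variation burden (log-normal rate
multipliers); non-coding variants are denser than coding ones; allele
frequencies follow a rare-heavy truncated Beta spectrum with Hardy-Weinberg
genotypes; coding positions are more conserved than non-coding, which are
more conserved than intergenic; pathogenic variants are rare, sit at
conserved coding positions, and carry damaging change types (truncating,
frameshifting, low-BLOSUM missense, splice), while benign variants are
drawn from the background spectrum. Every generator is a pure function of
its config: one seed gives byte-identical files.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CHROM = "chr1"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CSQ_FORMAT = "Allele|Consequence|Gene|Feature|Amino_acids"

_CODING_TERMS = ["missense_variant", "synonymous_variant", "stop_gained",
                 "splice_donor_variant", "inframe_deletion",
                 "frameshift_variant", "stop_lost", "start_lost"]
_CODING_PROBS = [0.53, 0.20, 0.06, 0.04, 0.05, 0.08, 0.02, 0.02]
_NONCODING_TERMS = ["intron_variant", "5_prime_UTR_variant", "3_prime_UTR_variant"]
_NONCODING_PROBS = [0.70, 0.15, 0.15]
_DAMAGING_TERMS = ["stop_gained", "frameshift_variant", "missense_variant",
                   "splice_donor_variant"]
_DAMAGING_PROBS = [0.30, 0.30, 0.30, 0.10]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic system (defaults are the standard
    benchmark configuration)."""
    seed: int = 1
    n_individuals: int = 500
    n_genes: int = 50
    gene_length: int = 3000
    intergenic_length: int = 2000
    coding_fraction: float = 0.4
    variant_density_coding: float = 12.0     # variants per kb
    variant_density_noncoding: float = 24.0  # must exceed the coding density
    variant_density_intergenic: float = 4.0
    af_alpha: float = 0.2                    # Beta spectrum, rare-heavy
    af_beta: float = 4.0
    burden_sigma: float = 0.4                # log-normal gene rate multiplier
    pathogenic_af_max: float = 1e-3
    n_pathogenic: int = 500
    n_benign: int = 500
    n_disease_train: int = 400
    n_population_train: int = 2000
    cons_coding: tuple = (6.0, 2.0)          # Beta parameters per region
    cons_noncoding: tuple = (2.0, 6.0)
    cons_intergenic: tuple = (1.0, 9.0)
    pathogenic_min_conservation: float = 0.6

    def __post_init__(self):
        for name in ("n_individuals", "n_genes", "gene_length", "intergenic_length",
                     "n_pathogenic", "n_benign", "n_disease_train",
                     "n_population_train"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.coding_fraction < 1.0:
            raise ValueError("coding_fraction must be in (0, 1)")
        for name in ("variant_density_coding", "variant_density_noncoding",
                     "variant_density_intergenic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variant_density_noncoding <= self.variant_density_coding:
            raise ValueError("non-coding variant density must exceed coding density")
        if not 0.0 < self.pathogenic_af_max < 0.5:
            raise ValueError("pathogenic_af_max must be in (0, 0.5)")


@dataclass
class _Gene:
    gene_id: str
    start: int
    end: int
    cds_start: int
    cds_end: int


@dataclass
class _Genome:
    genes: list
    conservation: np.ndarray  # per-base, NaN where undefined (intergenic)
    length: int

    def cons_at(self, pos: int) -> float:
        v = self.conservation[pos - 1]
        return float(v) if not math.isnan(v) else 0.0

    def cons_span_max(self, pos: int, length: int) -> float:
        return max(self.cons_at(pos + k) for k in range(max(length, 1)))


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _genome(config: SimConfig) -> _Genome:
    """Deterministic genome plan + per-base conservation for gene bodies."""
    rng = _rng(config, 0)
    genes = []
    pos = config.intergenic_length + 1
    for g in range(config.n_genes):
        start, end = pos, pos + config.gene_length - 1
        cds_len = int(round(config.gene_length * config.coding_fraction))
        cds_start = start + (config.gene_length - cds_len) // 2
        genes.append(_Gene(f"G{g + 1:03d}", start, end, cds_start,
                           cds_start + cds_len - 1))
        pos = end + config.intergenic_length + 1
    length = pos + 200
    cons = np.full(length, np.nan)
    for gene in genes:
        a, b = config.cons_noncoding
        cons[gene.start - 1:gene.end] = rng.beta(a, b, gene.end - gene.start + 1)
        a, b = config.cons_coding
        cons[gene.cds_start - 1:gene.cds_end] = rng.beta(
            a, b, gene.cds_end - gene.cds_start + 1)
    return _Genome(genes=genes, conservation=cons, length=length)


def _draw_alleles(rng, so_term: str) -> tuple[str, str, Optional[str]]:
    """(ref, alt, aa field) for one variant of the given consequence."""
    bases = "ACGT"
    ref_base = bases[rng.integers(4)]
    if so_term == "inframe_deletion":
        tail = "".join(bases[i] for i in rng.integers(0, 4, 3))
        return ref_base + tail, ref_base, None
    if so_term == "frameshift_variant":
        k = int(rng.integers(1, 3))
        tail = "".join(bases[i] for i in rng.integers(0, 4, k))
        return ref_base + tail, ref_base, None
    alt = bases[(bases.index(ref_base) + 1 + int(rng.integers(3))) % 4]
    aa = None
    if so_term == "missense_variant":
        i, j = rng.choice(len(AMINO_ACIDS), 2, replace=False)
        aa = f"{AMINO_ACIDS[i]}/{AMINO_ACIDS[j]}"
    elif so_term in ("stop_gained", "stop_lost", "start_lost"):
        i = int(rng.integers(len(AMINO_ACIDS)))
        aa = f"{AMINO_ACIDS[i]}/*" if so_term == "stop_gained" else f"*/{AMINO_ACIDS[i]}"
    elif so_term == "synonymous_variant":
        i = int(rng.integers(len(AMINO_ACIDS)))
        aa = f"{AMINO_ACIDS[i]}/{AMINO_ACIDS[i]}"
    return ref_base, alt, aa


_DRASTIC_PAIRS = None


def _drastic_missense_pairs() -> list[tuple[str, str]]:
    """Amino-acid substitutions with BLOSUM62 score <= -2 (drastic)."""
    global _DRASTIC_PAIRS
    if _DRASTIC_PAIRS is None:
        from Bio.Align import substitution_matrices
        m = substitution_matrices.load("BLOSUM62")
        _DRASTIC_PAIRS = sorted(
            (r, a) for r in AMINO_ACIDS for a in AMINO_ACIDS
            if r != a and m[r, a] <= -2)
    return _DRASTIC_PAIRS


def _csq(alt: str, so_term: str, gene_id: str, aa: Optional[str]) -> str:
    return f"{alt}|{so_term}|{gene_id}|{gene_id}T1|{aa or ''}"


# ---------------------------------------------------------------------------
# Background population

def _background_variants(config: SimConfig, genome: _Genome) -> pd.DataFrame:
    rng = _rng(config, 1)
    burden = rng.lognormal(mean=0.0, sigma=config.burden_sigma,
                           size=config.n_genes)
    rows = []

    def add_region(positions_pool, density, burden_factor, region, gene_id, terms, probs):
        expected = density * len(positions_pool) / 1000.0 * burden_factor
        n = min(int(rng.poisson(expected)), len(positions_pool))
        if n == 0:
            return
        positions = np.sort(rng.choice(positions_pool, size=n, replace=False))
        term_idx = rng.choice(len(terms), size=n, p=probs)
        for pos, ti in zip(positions, term_idx):
            term = terms[ti]
            ref, alt, aa = _draw_alleles(rng, term)
            f = float(np.clip(rng.beta(config.af_alpha, config.af_beta),
                              1.0 / (2 * config.n_individuals), 0.5))
            geno = rng.binomial(2, f, size=config.n_individuals)
            ac = int(geno.sum())
            if ac == 0:
                continue
            rows.append({
                "chrom": CHROM, "pos": int(pos), "ref": ref, "alt": alt,
                "gene": gene_id, "region": region, "so_term": term, "aa": aa,
                "true_frequency": f, "ac": ac,
                "an": 2 * config.n_individuals,
                "conservation": genome.cons_span_max(int(pos), len(ref)),
                "genotypes": geno,
            })

    for gi, gene in enumerate(genome.genes):
        coding = np.arange(gene.cds_start, gene.cds_end - 4)
        noncoding = np.concatenate([np.arange(gene.start, gene.cds_start),
                                    np.arange(gene.cds_end + 1, gene.end - 4)])
        add_region(coding, config.variant_density_coding, burden[gi],
                   "coding", gene.gene_id, _CODING_TERMS, _CODING_PROBS)
        add_region(noncoding, config.variant_density_noncoding, burden[gi],
                   "noncoding", gene.gene_id, _NONCODING_TERMS, _NONCODING_PROBS)

    # intergenic gaps
    gaps = []
    prev_end = 0
    for gene in genome.genes:
        gaps.append((prev_end + 1, gene.start - 1))
        prev_end = gene.end
    gaps.append((prev_end + 1, genome.length - 10))
    for lo, hi in gaps:
        if hi <= lo:
            continue
        pool = np.arange(lo, hi - 4)
        add_region(pool, config.variant_density_intergenic, 1.0,
                   "intergenic", "", ["intergenic_variant"], [1.0])

    df = pd.DataFrame(rows).sort_values(["pos", "alt"]).reset_index(drop=True)
    # conservation for intergenic variant positions (gene bodies already set)
    a, b = config.cons_intergenic
    for _, row in df[df["region"] == "intergenic"].iterrows():
        p = int(row["pos"])
        if math.isnan(genome.conservation[p - 1]):
            genome.conservation[p - 1] = rng.beta(a, b)
    df.loc[df["region"] == "intergenic", "conservation"] = [
        genome.cons_span_max(int(r.pos), len(r.ref))
        for r in df[df["region"] == "intergenic"].itertuples()]
    return df


# ---------------------------------------------------------------------------
# File writers

def _vcf_header(config: SimConfig, genome: _Genome, with_samples: bool) -> list[str]:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM},length={genome.length}>",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
        f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        f'Format: {_CSQ_FORMAT}">',
    ]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if with_samples:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        cols += ["FORMAT"] + [f"S{i + 1:04d}" for i in range(config.n_individuals)]
    lines.append("\t".join(cols))
    return lines


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def _write_population_vcf(path, config: SimConfig, genome: _Genome,
                          truth: pd.DataFrame) -> None:
    lines = _vcf_header(config, genome, with_samples=True)
    for row in truth.itertuples():
        af = row.ac / row.an
        info = (f"AC={row.ac};AN={row.an};AF={af:.6g};"
                f"CSQ={_csq(row.alt, row.so_term, row.gene, row.aa)}"
                if row.gene else
                f"AC={row.ac};AN={row.an};AF={af:.6g};"
                f"CSQ={_csq(row.alt, row.so_term, 'NONE', row.aa)}")
        gts = "\t".join(_GT[g] for g in row.genotypes)
        lines.append(f"{CHROM}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_sites_vcf(path, config: SimConfig, genome: _Genome, rows) -> None:
    lines = _vcf_header(config, genome, with_samples=False)
    for row in sorted(rows, key=lambda r: (r["pos"], r["alt"])):
        gene = row.get("gene") or "NONE"
        info = f"CSQ={_csq(row['alt'], row['so_term'], gene, row.get('aa'))}"
        lines.append(f"{CHROM}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_gff3(path, genome: _Genome) -> None:
    lines = ["##gff-version 3"]
    for g in genome.genes:
        lines.append(f"{CHROM}\tsim\tgene\t{g.start}\t{g.end}\t.\t+\t.\tID={g.gene_id}")
        lines.append(f"{CHROM}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t+\t.\t"
                     f"ID={g.gene_id}T1;Parent={g.gene_id}")
        lines.append(f"{CHROM}\tsim\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t+\t0\t"
                     f"ID={g.gene_id}T1.cds;Parent={g.gene_id}T1")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_bedgraph(path, genome: _Genome) -> None:
    """Per-base (1-bp interval) conservation for every defined position."""
    idx = np.flatnonzero(~np.isnan(genome.conservation))
    vals = genome.conservation[idx]
    lines = [f"{CHROM}\t{i}\t{i + 1}\t{v:.6f}" for i, v in zip(idx, vals)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Public generators

def simulate_background(config: SimConfig, out_dir) -> pd.DataFrame:
    """Write population.vcf, genes.gff3, conservation.bedgraph and truth.tsv;
    return the background truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = _genome(config)
    truth = _background_variants(config, genome)
    _write_population_vcf(out_dir / "population.vcf", config, genome, truth)
    _write_gff3(out_dir / "genes.gff3", genome)
    _write_bedgraph(out_dir / "conservation.bedgraph", genome)
    out = truth.drop(columns=["genotypes"]).copy()
    out.insert(4, "label", "background")
    out.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth


def simulate_labeled_set(config: SimConfig, truth: pd.DataFrame,
                         out_dir) -> pd.DataFrame:
    """Write test.vcf and labels.tsv: rare damaging pathogenic variants at
    conserved coding positions plus benign variants drawn from the
    background; returns the labels table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = _genome(config)
    rng = _rng(config, 2)
    used = set(int(p) for p in truth["pos"])

    pool = []
    for gene in genome.genes:
        for p in range(gene.cds_start, gene.cds_end - 4):
            if p not in used and genome.cons_at(p) >= config.pathogenic_min_conservation:
                pool.append((p, gene.gene_id))
    if len(pool) < config.n_pathogenic:
        raise ValueError(
            f"only {len(pool)} conserved unused coding positions available "
            f"for {config.n_pathogenic} pathogenic variants")
    chosen = rng.choice(len(pool), size=config.n_pathogenic, replace=False)
    drastic = _drastic_missense_pairs()
    rows = []
    for ci in chosen:
        pos, gene_id = pool[int(ci)]
        term = _DAMAGING_TERMS[int(rng.choice(len(_DAMAGING_TERMS), p=_DAMAGING_PROBS))]
        ref, alt, aa = _draw_alleles(rng, term)
        if term == "missense_variant":
            r, a = drastic[int(rng.integers(len(drastic)))]
            aa = f"{r}/{a}"
        low = min(1.0 / (20 * config.n_individuals), config.pathogenic_af_max / 2)
        f = float(rng.uniform(low, config.pathogenic_af_max))
        rows.append({"chrom": CHROM, "pos": pos, "ref": ref, "alt": alt,
                     "label": "pathogenic", "frequency": f, "so_term": term,
                     "aa": aa, "gene": gene_id,
                     "conservation": genome.cons_span_max(pos, len(ref))})

    if config.n_benign > len(truth):
        raise ValueError("n_benign exceeds the number of background variants")
    benign_idx = rng.choice(len(truth), size=config.n_benign, replace=False)
    for bi in np.sort(benign_idx):
        row = truth.iloc[int(bi)]
        rows.append({"chrom": CHROM, "pos": int(row["pos"]), "ref": row["ref"],
                     "alt": row["alt"], "label": "benign",
                     "frequency": row["ac"] / row["an"],
                     "so_term": row["so_term"], "aa": row["aa"],
                     "gene": row["gene"], "conservation": row["conservation"]})

    _write_sites_vcf(out_dir / "test.vcf", config, genome, rows)
    labels = pd.DataFrame(rows).drop(columns=["aa"]) \
        .sort_values(["pos", "alt"]).reset_index(drop=True)
    labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    return labels


def simulate_impact_training(config: SimConfig, out_dir) -> None:
    """Write disease_train.vcf (damaging types at conserved coding sites) and
    population_train.vcf (mirrors the background type distribution)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = _genome(config)
    rng = _rng(config, 3)
    drastic = _drastic_missense_pairs()

    coding_pool = np.concatenate([np.arange(g.cds_start, g.cds_end - 4)
                                  for g in genome.genes])
    conserved = np.array([p for p in coding_pool
                          if genome.cons_at(int(p)) >= config.pathogenic_min_conservation])
    gene_of = {}
    for g in genome.genes:
        for p in range(g.start, g.end + 1):
            gene_of[p] = g.gene_id

    disease_rows = []
    n_dis = min(config.n_disease_train, len(conserved))
    for p in rng.choice(conserved, size=n_dis, replace=False):
        term = _DAMAGING_TERMS[int(rng.choice(len(_DAMAGING_TERMS), p=_DAMAGING_PROBS))]
        ref, alt, aa = _draw_alleles(rng, term)
        if term == "missense_variant":
            r, a = drastic[int(rng.integers(len(drastic)))]
            aa = f"{r}/{a}"
        disease_rows.append({"pos": int(p), "ref": ref, "alt": alt,
                             "so_term": term, "aa": aa, "gene": gene_of[int(p)]})

    noncoding_pool = np.concatenate(
        [np.concatenate([np.arange(g.start, g.cds_start),
                         np.arange(g.cds_end + 1, g.end - 4)])
         for g in genome.genes])
    lc, ln = len(coding_pool), len(noncoding_pool)
    li = config.intergenic_length * (config.n_genes + 1)
    weights = np.array([config.variant_density_coding * lc,
                        config.variant_density_noncoding * ln,
                        config.variant_density_intergenic * li], float)
    weights /= weights.sum()
    pop_rows = []
    seen = set()
    a_ig, b_ig = config.cons_intergenic
    while len(pop_rows) < config.n_population_train:
        region = int(rng.choice(3, p=weights))
        if region == 0:
            p = int(rng.choice(coding_pool))
            term = _CODING_TERMS[int(rng.choice(len(_CODING_TERMS), p=_CODING_PROBS))]
            gene = gene_of[p]
        elif region == 1:
            p = int(rng.choice(noncoding_pool))
            term = _NONCODING_TERMS[int(rng.choice(len(_NONCODING_TERMS),
                                                   p=_NONCODING_PROBS))]
            gene = gene_of[p]
        else:
            p = int(rng.integers(1, config.intergenic_length))
            term, gene = "intergenic_variant", ""
        ref, alt, aa = _draw_alleles(rng, term)
        if (p, alt) in seen:
            continue
        seen.add((p, alt))
        pop_rows.append({"pos": p, "ref": ref, "alt": alt, "so_term": term,
                         "aa": aa, "gene": gene})

    _write_sites_vcf(out_dir / "disease_train.vcf", config, genome, disease_rows)
    _write_sites_vcf(out_dir / "population_train.vcf", config, genome, pop_rows)


def simulate_all(config: SimConfig, out_dir) -> dict:
    """Generate the complete synthetic input set; returns the file paths."""
    out_dir = Path(out_dir)
    truth = simulate_background(config, out_dir)
    simulate_labeled_set(config, truth, out_dir)
    simulate_impact_training(config, out_dir)
    return {name: out_dir / f"{name}.{ext}" for name, ext in [
        ("population", "vcf"), ("genes", "gff3"),
        ("conservation", "bedgraph"), ("truth", "tsv"),
        ("test", "vcf"), ("labels", "tsv"),
        ("disease_train", "vcf"), ("population_train", "vcf")]}
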