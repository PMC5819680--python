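"""Background population database: per-variant allele counts plus, once the
background has been scored, the per-gene/effect-group percentile lookups.

The on-disk format is a plain versioned TSV with a JSON header line — sorted,
diffable, and exactly round-trippable.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pysam

from .io import variant_key
from .percentile import CRD

FORMAT_VERSION = 1
_MAGIC = "#VARPRIOR_INDEX"


class AlleleCounts(NamedTuple):
    """Alternate-allele chromosomes (x_u) out of total chromosomes (n_b)."""
    x_u: int
    n_b: int


@dataclass
class BackgroundIndex:
    """Population allele counts keyed by normalized variant, plus CRDs."""
    counts: dict
    default_n_b: int
    crds: dict = field(default_factory=dict)        # (gene_id, group) -> CRD
    pooled_crds: dict = field(default_factory=dict)  # group -> CRD (fallback)
    intergenic_crd: Optional[CRD] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.default_n_b <= 0:
            raise ValueError("default_n_b must be positive")


def _counts_from_genotypes(rec, alt_index: int) -> AlleleCounts:
    x_u = 0
    an = 0
    for sample in rec.samples.values():
        gt = sample.get("GT")
        if gt is None:
            continue
        for allele in gt:
            if allele is None:
                continue
            an += 1
            if allele == alt_index:
                x_u += 1
    return AlleleCounts(x_u, an)


def build_frequency_index(population_vcf, region_mask=None,
                          default_n_b: Optional[int] = None) -> BackgroundIndex:
    """Compile per-variant allele counts from a population VCF.

    AC/AN INFO fields are preferred; otherwise alt alleles are counted over
    called genotypes (AN = called alleles, no-calls excluded). Sites with
    AN = 0 are skipped with a warning. ``default_n_b`` (used for variants
    absent from the index) defaults to the median AN over all sites.
    """
    counts: dict = {}
    n_bs: list[int] = []
    vf = pysam.VariantFile(str(population_vcf))
    for rec in vf:
        alts = rec.alts or ()
        ac = rec.info.get("AC") if "AC" in rec.info else None
        an = rec.info.get("AN") if "AN" in rec.info else None
        if ac is not None and an is not None:
            an = int(an[0] if isinstance(an, tuple) else an)
            acs = list(ac) if isinstance(ac, tuple) else [ac]
            per_alt = [AlleleCounts(int(a), an) for a in acs]
        else:
            per_alt = [_counts_from_genotypes(rec, i + 1) for i in range(len(alts))]
            an = per_alt[0].n_b if per_alt else 0
        if an <= 0:
            warnings.warn(f"site {rec.chrom}:{rec.pos} has AN=0; skipped")
            continue
        for alt, c in zip(alts, per_alt):
            if alt is None:
                continue
            if c.x_u < 0 or c.x_u > c.n_b:
                raise ValueError(f"invalid counts {c} at {rec.chrom}:{rec.pos}")
            key = variant_key(rec.chrom, rec.pos, rec.ref, alt)
            if region_mask is not None and region_mask.covers(rec.chrom, key[1]):
                continue
            counts[key] = c
            n_bs.append(c.n_b)
    if default_n_b is None:
        default_n_b = int(np.median(n_bs)) if n_bs else 1000
    return BackgroundIndex(counts=counts, default_n_b=default_n_b,
                           metadata={"source": str(population_vcf),
                                     "n_sites": len(counts)})


def query_counts(index: BackgroundIndex, key) -> AlleleCounts:
    """Stored counts, or (0, default_n_b) for variants never seen in the
    background: unseen variants are treated as absent from the sample."""
    chrom, pos, ref, alt = key
    norm = variant_key(chrom, pos, ref, alt)
    got = index.counts.get(norm)
    if got is not None:
        return got
    return AlleleCounts(0, index.default_n_b)


# ---------------------------------------------------------------------------
# Serialization

def _fmt_floats(values) -> str:
    return "\t".join(repr(float(v)) for v in values)


def _crd_lines(name1: str, name2: str, crd: CRD) -> list[str]:
    return [
        f"#CRD\t{name1}\t{name2}\t{crd.n}\t{int(crd.fallback)}",
        _fmt_floats(crd.scores),
        _fmt_floats(crd.percentiles),
    ]


def save_index(index: BackgroundIndex, path) -> None:
    header = {"default_n_b": index.default_n_b, "metadata": index.metadata}
    lines = [f"{_MAGIC}\t{FORMAT_VERSION}\t{json.dumps(header, sort_keys=True)}"]
    lines.append(f"#COUNTS\t{len(index.counts)}")
    for (chrom, pos, ref, alt), c in sorted(index.counts.items()):
        lines.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{c.x_u}\t{c.n_b}")
    for (gene, group), crd in sorted(index.crds.items()):
        lines.extend(_crd_lines(gene, group, crd))
    for group, crd in sorted(index.pooled_crds.items()):
        lines.extend(_crd_lines("*POOLED*", group, crd))
    if index.intergenic_crd is not None:
        lines.extend(_crd_lines("*INTERGENIC*", "intergenic", index.intergenic_crd))
    lines.append("#END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_index(path) -> BackgroundIndex:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(_MAGIC):
        raise ValueError(f"{path} is not a varprior index file")
    _, version, header_json = lines[0].split("\t", 2)
    if int(version) != FORMAT_VERSION:
        raise ValueError(f"index format version {version} unsupported "
                         f"(expected {FORMAT_VERSION})")
    if not lines or lines[-1] != "#END":
        raise ValueError(f"{path} is truncated (missing #END marker)")
    header = json.loads(header_json)
    i = 1
    if not lines[i].startswith("#COUNTS\t"):
        raise ValueError("missing #COUNTS section")
    n_counts = int(lines[i].split("\t")[1])
    i += 1
    counts = {}
    for _ in range(n_counts):
        chrom, pos, ref, alt, x_u, n_b = lines[i].split("\t")
        counts[(chrom, int(pos), ref, alt)] = AlleleCounts(int(x_u), int(n_b))
        i += 1
    index = BackgroundIndex(counts=counts, default_n_b=int(header["default_n_b"]),
                            metadata=header.get("metadata", {}))
    while lines[i] != "#END":
        if not lines[i].startswith("#CRD\t"):
            raise ValueError(f"unexpected line {i + 1} in {path}")
        _, name1, name2, n, fallback = lines[i].split("\t")
        scores = np.array([float(v) for v in lines[i + 1].split("\t")] if lines[i + 1] else [])
        pcts = np.array([float(v) for v in lines[i + 2].split("\t")] if lines[i + 2] else [])
        crd = CRD(scores=scores, percentiles=pcts, n=int(n), fallback=bool(int(fallback)))
        if name1 == "*INTERGENIC*":
            index.intergenic_crd = crd
        elif name1 == "*POOLED*":
            index.pooled_crds[name2] = crd
        else:
            index.crds[(name1, name2)] = crd
        i += 3
    return index
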