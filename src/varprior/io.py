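"""Variant I/O: VCF reading, consequence-annotation parsing, interval tracks.

All genomic coordinate conversions happen here. VCF positions are 1-based
inclusive; BED and bedGraph intervals are half-open. Variants are normalized
to a minimal representation (shared suffix, then shared prefix, trimmed) so
that the same allele written two ways maps to one key.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

VALID_BASES = frozenset("ACGTN")

CODING = "coding"
NON_CODING = "non_coding"
INTERGENIC = "intergenic"

#: Sequence Ontology consequence term -> effect group. Coding covers
#: protein-altering and splice-site consequences; synonymous, intronic and
#: UTR changes are non-coding; everything outside gene bodies is intergenic.
EFFECT_GROUP_TABLE: dict[str, str] = {
    # coding
    "missense_variant": CODING,
    "stop_gained": CODING,
    "stop_lost": CODING,
    "start_lost": CODING,
    "frameshift_variant": CODING,
    "inframe_insertion": CODING,
    "inframe_deletion": CODING,
    "protein_altering_variant": CODING,
    "splice_acceptor_variant": CODING,
    "splice_donor_variant": CODING,
    "splice_region_variant": CODING,
    "coding_sequence_variant": CODING,
    "incomplete_terminal_codon_variant": CODING,
    "transcript_ablation": CODING,
    # non-coding (within gene bodies)
    "synonymous_variant": NON_CODING,
    "stop_retained_variant": NON_CODING,
    "start_retained_variant": NON_CODING,
    "intron_variant": NON_CODING,
    "5_prime_UTR_variant": NON_CODING,
    "3_prime_UTR_variant": NON_CODING,
    "non_coding_transcript_variant": NON_CODING,
    "non_coding_transcript_exon_variant": NON_CODING,
    "mature_miRNA_variant": NON_CODING,
    # intergenic
    "intergenic_variant": INTERGENIC,
    "upstream_gene_variant": INTERGENIC,
    "downstream_gene_variant": INTERGENIC,
    "regulatory_region_variant": INTERGENIC,
    "TF_binding_site_variant": INTERGENIC,
}

# consequence terms whose annotation may legitimately carry an aa change
_AA_ALTERING = {"missense_variant", "stop_gained", "stop_lost", "start_lost",
                "protein_altering_variant"}


def classify_effect_group(so_term: str) -> str:
    """Map a Sequence Ontology consequence term to its effect group.

    Total function: unrecognized terms fall through to ``intergenic`` with a
    warning, so that arbitrary annotations never abort scoring.
    """
    group = EFFECT_GROUP_TABLE.get(so_term)
    if group is None:
        warnings.warn(f"unknown consequence term {so_term!r}; treating as intergenic",
                      stacklevel=2)
        return INTERGENIC
    return group


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal allele representation: trim shared suffix, then shared prefix.

    Keeps at least one base on each allele. Prefix trimming advances ``pos``.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    pos, ref, alt = normalize_variant(pos, ref.upper(), alt.upper())
    return (chrom, pos, ref, alt)


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """One transcript-level consequence of a variant."""
    gene_id: str
    transcript_id: str
    so_term: str
    aa_change: Optional[tuple[str, str]] = None
    effect_group: str = field(default="")

    def __post_init__(self):
        if not self.effect_group:
            object.__setattr__(self, "effect_group", classify_effect_group(self.so_term))


@dataclass
class VariantRecord:
    """One normalized alternate allele at a genomic position."""
    chrom: str
    pos: int  # 1-based, after normalization
    ref: str
    alt: str
    annotations: list[ConsequenceAnnotation] = field(default_factory=list)
    conservation: float = 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def unannotated(self) -> bool:
        return not self.annotations


# ---------------------------------------------------------------------------
# CSQ (VEP-style) consequence parsing

_FIELD_ALIASES = {
    "gene": {"gene", "gene_id", "symbol"},
    "transcript": {"feature", "transcript", "transcript_id"},
    "consequence": {"consequence", "so_term"},
    "aa": {"amino_acids", "aa", "aa_change", "amino_acid_change"},
    "allele": {"allele"},
}


def _field_indices(csq_format: Sequence[str]) -> dict[str, int]:
    lowered = [f.strip().lower() for f in csq_format]
    out: dict[str, int] = {}
    for role, aliases in _FIELD_ALIASES.items():
        for i, name in enumerate(lowered):
            if name in aliases:
                out[role] = i
                break
    missing = {"gene", "transcript", "consequence"} - out.keys()
    if missing:
        raise ValueError(f"CSQ format lacks required fields: {sorted(missing)}")
    return out


def parse_consequences(info_value, csq_format: Sequence[str]) -> list[ConsequenceAnnotation]:
    """Parse a VEP-style CSQ INFO value into consequence annotations.

    ``info_value`` may be the raw comma-joined string or the tuple of entry
    strings pysam exposes. Entries with the wrong field count are skipped
    with a warning. A ``None`` value yields an empty list (the variant is
    still scorable, with impact 1 and the intergenic group).
    """
    if info_value is None:
        return []
    if isinstance(info_value, str):
        entries = info_value.split(",")
    else:
        entries = list(info_value)
    idx = _field_indices(csq_format)
    nfields = len(csq_format)
    out: list[ConsequenceAnnotation] = []
    for entry in entries:
        parts = entry.split("|")
        if len(parts) != nfields:
            warnings.warn(f"CSQ entry has {len(parts)} fields, expected {nfields}; skipped",
                          stacklevel=2)
            continue
        so_term = parts[idx["consequence"]].split("&")[0].strip()
        aa_change = None
        if "aa" in idx:
            aa = parts[idx["aa"]].strip()
            if "/" in aa:
                r, a = aa.split("/", 1)
                if r and a and r != a and so_term in _AA_ALTERING:
                    aa_change = (r, a)
        out.append(ConsequenceAnnotation(
            gene_id=parts[idx["gene"]].strip(),
            transcript_id=parts[idx["transcript"]].strip(),
            so_term=so_term,
            aa_change=aa_change,
        ))
    return out


def csq_format_from_header(header: pysam.VariantHeader) -> Optional[list[str]]:
    """Extract the CSQ sub-field layout from the VCF header description."""
    rec = header.info.get("CSQ")
    if rec is None or not rec.description:
        return None
    desc = rec.description
    marker = "Format:"
    if marker not in desc:
        return None
    return [f.strip() for f in desc.split(marker, 1)[1].strip().strip('"').split("|")]


# ---------------------------------------------------------------------------
# Interval tracks

def _per_chrom_arrays(df: pd.DataFrame, value_col: Optional[str] = None):
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        arrs = [sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)]
        if value_col is not None:
            arrs.append(sub[value_col].to_numpy(float))
        out[str(chrom)] = tuple(arrs)
    return out


class RegionMask:
    """BED-defined exclusion regions; a POS inside [start, end) is masked."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._ivals = intervals

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str})
        # merge overlaps so a single searchsorted probe suffices
        merged = {}
        for chrom, (starts, ends) in _per_chrom_arrays(df).items():
            ms, me = [], []
            for s, e in zip(starts, ends):
                if ms and s <= me[-1]:
                    me[-1] = max(me[-1], e)
                else:
                    ms.append(s)
                    me.append(e)
            merged[chrom] = (np.asarray(ms, np.int64), np.asarray(me, np.int64))
        return cls(merged)

    def covers(self, chrom: str, pos: int) -> bool:
        ival = self._ivals.get(chrom)
        if ival is None:
            return False
        starts, ends = ival
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]


class ConservationTrack:
    """Per-base conservation values in [0, 1] from bedGraph intervals."""

    def __init__(self, intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 default_value: float = 0.0):
        for chrom, (s, e, v) in intervals.items():
            if len(v) and (v.min() < 0.0 or v.max() > 1.0):
                raise ValueError(f"conservation values outside [0,1] on {chrom}")
        if not 0.0 <= default_value <= 1.0:
            raise ValueError("default_value must be in [0,1]")
        self._ivals = intervals
        self.default_value = float(default_value)

    @classmethod
    def from_bedgraph(cls, path, default_value: float = 0.0) -> "ConservationTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"], dtype={0: str})
        return cls(_per_chrom_arrays(df, "value"), default_value)

    @classmethod
    def from_intervals(cls, intervals, default_value: float = 0.0) -> "ConservationTrack":
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end", "value"])
        return cls(_per_chrom_arrays(df, "value"), default_value)

    def value_at(self, chrom: str, pos: int) -> float:
        """Conservation at a single 1-based position."""
        ival = self._ivals.get(chrom)
        if ival is None:
            return self.default_value
        starts, ends, values = ival
        p = pos - 1
        i = int(np.searchsorted(starts, p, side="right")) - 1
        if i >= 0 and p < ends[i]:
            return float(values[i])
        return self.default_value

    def span_max(self, chrom: str, pos: int, length: int) -> float:
        """Max conservation over the reference span of a (possibly multi-base) allele."""
        return max(self.value_at(chrom, pos + k) for k in range(max(length, 1)))


# ---------------------------------------------------------------------------
# Gene models

class GeneModels:
    """Gene and CDS extents from GFF3, for locating unannotated variants."""

    def __init__(self, genes: dict, cds: dict):
        self._genes = genes  # chrom -> (starts, ends, ids); GFF3 1-based inclusive
        self._cds = cds

    @classmethod
    def from_gff3(cls, path) -> "GeneModels":
        import gffutils
        db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                                merge_strategy="create_unique")
        g_rows, c_rows = [], []
        for feat in db.features_of_type("gene"):
            g_rows.append((feat.seqid, feat.start, feat.end, feat.id))
        for feat in db.features_of_type("CDS"):
            c_rows.append((feat.seqid, feat.start, feat.end, feat.id))
        def pack(rows):
            out = {}
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
            for chrom, sub in df.groupby("chrom", sort=False):
                sub = sub.sort_values("start")
                out[str(chrom)] = (sub["start"].to_numpy(np.int64),
                                   sub["end"].to_numpy(np.int64),
                                   sub["id"].to_list())
            return out
        return cls(pack(g_rows), pack(c_rows))

    @staticmethod
    def _hit(table, chrom, pos):
        ival = table.get(chrom)
        if ival is None:
            return None
        starts, ends, ids = ival
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos <= ends[i]:
            return ids[i]
        return None

    def locate(self, chrom: str, pos: int) -> tuple[Optional[str], str]:
        """Return (gene_id or None, region in {coding, non_coding, intergenic})."""
        if self._hit(self._cds, chrom, pos) is not None:
            gene = self._hit(self._genes, chrom, pos)
            return gene, CODING
        gene = self._hit(self._genes, chrom, pos)
        if gene is not None:
            return gene, NON_CODING
        return None, INTERGENIC


# ---------------------------------------------------------------------------
# VCF reading

def read_variants(vcf_source,
                  region_mask: Optional[RegionMask] = None,
                  conservation: Optional[ConservationTrack] = None,
                  csq_format: Optional[Sequence[str]] = None,
                  ) -> Iterator[VariantRecord]:
    """Stream normalized single-alt VariantRecords from a VCF.

    Multi-allelic rows are split into one record per alternate allele;
    symbolic alleles are skipped with a warning. Records whose POS falls in a
    mask interval are dropped. Consequence annotations are parsed from the
    CSQ INFO key using ``csq_format`` or the layout declared in the header.
    """
    vf = pysam.VariantFile(str(vcf_source))
    fmt = list(csq_format) if csq_format is not None else csq_format_from_header(vf.header)
    nrec = 0
    try:
        for rec in vf:
            nrec += 1
            raw_csq = rec.info.get("CSQ") if "CSQ" in rec.info else None
            annotations_all = parse_consequences(raw_csq, fmt) if (raw_csq is not None and fmt) else []
            raw_entries = ([raw_csq] if isinstance(raw_csq, str) else list(raw_csq)) if raw_csq is not None else []
            alts = rec.alts or ()
            for alt in alts:
                if alt is None or not set(alt.upper()) <= VALID_BASES:
                    warnings.warn(f"symbolic/invalid ALT {alt!r} at {rec.chrom}:{rec.pos}; skipped")
                    continue
                if not rec.ref or not set(rec.ref.upper()) <= VALID_BASES:
                    warnings.warn(f"invalid REF {rec.ref!r} at {rec.chrom}:{rec.pos}; skipped")
                    continue
                pos, ref, a = normalize_variant(rec.pos, rec.ref.upper(), alt.upper())
                if region_mask is not None and region_mask.covers(rec.chrom, pos):
                    continue
                anns = _annotations_for_alt(annotations_all, raw_entries, fmt, alt, a)
                cons = (conservation.span_max(rec.chrom, pos, len(ref))
                        if conservation is not None else 0.0)
                yield VariantRecord(rec.chrom, pos, ref, a, anns, cons)
    except ValueError as exc:
        raise ValueError(f"malformed VCF record near record {nrec + 1} "
                         f"of {vcf_source}: {exc}") from exc


def _annotations_for_alt(annotations, raw_entries, fmt, raw_alt, norm_alt):
    """Restrict CSQ entries to one alt via the Allele sub-field, if present."""
    if not annotations or fmt is None:
        return list(annotations)
    lowered = [f.strip().lower() for f in fmt]
    try:
        allele_idx = next(i for i, f in enumerate(lowered) if f in _FIELD_ALIASES["allele"])
    except StopIteration:
        return list(annotations)
    keep, alleles = [], []
    for ann, entry in zip(annotations, raw_entries if len(raw_entries) == len(annotations) else [None] * len(annotations)):
        if entry is None:
            return list(annotations)
        parts = entry.split("|")
        alleles.append(parts[allele_idx].strip().upper() if len(parts) > allele_idx else "")
    matched = [ann for ann, al in zip(annotations, alleles)
               if al in (raw_alt.upper(), norm_alt.upper())]
    return matched if matched else list(annotations)
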