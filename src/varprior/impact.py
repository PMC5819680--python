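"""Impact parameters: how often each type of sequence change occurs among
known disease-causing variants (a) versus the general population (h).

The ratio a/h multiplies the frequency likelihood ratio, so change types
over-represented among disease alleles push scores up. Three modes:

* ``empirical`` — a and h estimated from user-supplied disease and population
  training sets, stratified by conservation bin, with additive smoothing;
* ``blosum`` — missense impact from BLOSUM62 substitution scores (monotone
  decreasing in the score), fixed ratios for non-missense types;
* ``off`` — every ratio is exactly 1, reducing the score to frequency alone.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .io import CODING, INTERGENIC, NON_CODING, ConsequenceAnnotation

#: every change-type kind the model distinguishes
KINDS = (
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_site",
    "synonymous",
    "inframe_indel",
    "frameshift_indel",
    "non_coding_change",
    "intergenic_change",
)

_SPLICE_TERMS = {"splice_acceptor_variant", "splice_donor_variant",
                 "splice_region_variant"}

#: fixed non-missense ratios for blosum mode, reflecting the usual severity
#: ordering (truncating > splice > in-frame > synonymous).
BLOSUM_NON_MISSENSE = {
    "stop_gained": 8.0,
    "stop_lost": 4.0,
    "start_lost": 6.0,
    "splice_site": 6.0,
    "synonymous": 0.5,
    "inframe_indel": 3.0,
    "frameshift_indel": 8.0,
    "non_coding_change": 1.0,
    "intergenic_change": 1.0,
}


@dataclass(frozen=True)
class ChangeType:
    kind: str
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown change-type kind {self.kind!r}")


def change_type_of(annotation: ConsequenceAnnotation, ref: str, alt: str) -> ChangeType:
    """Deterministic change type from consequence term, aa change and allele
    lengths; coding indel kind is decided by |len(ref) - len(alt)| mod 3."""
    term = annotation.so_term
    # synonymous and splice terms name their own change type even though
    # their effect groups (for percentile normalization) differ
    if term == "synonymous_variant":
        return ChangeType("synonymous")
    if term in _SPLICE_TERMS:
        return ChangeType("splice_site")
    group = annotation.effect_group
    if group == INTERGENIC:
        return ChangeType("intergenic_change")
    if group == NON_CODING:
        return ChangeType("non_coding_change")
    # coding
    if len(ref) != len(alt):
        diff = abs(len(ref) - len(alt))
        return ChangeType("inframe_indel" if diff % 3 == 0 else "frameshift_indel")
    if term == "missense_variant":
        aa = annotation.aa_change or (None, None)
        return ChangeType("missense", aa[0], aa[1])
    if term in ("stop_gained", "stop_lost", "start_lost"):
        return ChangeType(term)
    # remaining coding terms (e.g. protein_altering_variant) treated as missense
    aa = annotation.aa_change or (None, None)
    return ChangeType("missense", aa[0], aa[1])


def conservation_bin(conservation: float, n_bins: int) -> int:
    """floor(c * n_bins), clamped to the last bin at c = 1."""
    return min(int(conservation * n_bins), n_bins - 1)


@dataclass
class ImpactTable:
    """a and h values per (change-type kind, conservation bin)."""
    mode: str  # empirical | blosum | off
    n_bins: int = 2
    a: dict = None
    h: dict = None
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.mode not in ("empirical", "blosum", "off"):
            raise ValueError(f"unknown impact mode {self.mode!r}")
        if self.mode == "empirical":
            if not self.a or not self.h:
                raise ValueError("empirical mode requires estimated a and h tables")
            for table in (self.a, self.h):
                if any(v < 0 for v in table.values()):
                    raise ValueError("a and h must be non-negative")
                # zero cells only arise without smoothing
                if self.pseudocount > 0 and any(v == 0 for v in table.values()):
                    raise ValueError("a and h must be strictly positive when smoothed")

    @classmethod
    def off(cls) -> "ImpactTable":
        return cls(mode="off", n_bins=1)

    @classmethod
    def blosum(cls) -> "ImpactTable":
        return cls(mode="blosum", n_bins=1)


def _cell_counts(observations: Iterable[tuple[ChangeType, float]], n_bins: int) -> tuple[dict, int]:
    counts = {(kind, b): 0 for kind in KINDS for b in range(n_bins)}
    total = 0
    for ct, cons in observations:
        counts[(ct.kind, conservation_bin(cons, n_bins))] += 1
        total += 1
    return counts, total


def training_observations(records) -> list[tuple[ChangeType, float]]:
    """(ChangeType, conservation) pairs from VariantRecords, one per distinct
    variant key, using each record's first annotation."""
    seen = set()
    out = []
    for rec in records:
        if rec.key in seen or rec.unannotated:
            continue
        seen.add(rec.key)
        out.append((change_type_of(rec.annotations[0], rec.ref, rec.alt),
                    rec.conservation))
    return out


def estimate_tables(disease_observations, population_observations,
                    n_bins: int = 2, pseudocount: float = 1.0) -> ImpactTable:
    """Empirical impact table from training observations.

    a(type, bin) = (count in disease set + pc) / (|disease set| + pc * K),
    with K the number of (type, bin) cells; h analogous over the population
    set. The pseudocount keeps every cell strictly positive.
    """
    disease = list(disease_observations)
    population = list(population_observations)
    if not disease or not population:
        raise ValueError("both training sets must be non-empty")
    K = len(KINDS) * n_bins

    def table(observations):
        counts, total = _cell_counts(observations, n_bins)
        denom = total + pseudocount * K
        return {cell: (c + pseudocount) / denom for cell, c in counts.items()}

    return ImpactTable(mode="empirical", n_bins=n_bins, a=table(disease),
                       h=table(population), pseudocount=pseudocount)


_BLOSUM62 = None


def _blosum_score(aa_ref: Optional[str], aa_alt: Optional[str]) -> float:
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    if not aa_ref or not aa_alt:
        return 0.0
    try:
        return float(_BLOSUM62[aa_ref.upper()[0], aa_alt.upper()[0]])
    except (KeyError, IndexError):
        return 0.0


def impact_ratio(table: ImpactTable, change_type: ChangeType,
                 conservation: float) -> float:
    """The a/h factor for one variant; strictly positive and finite."""
    if table.mode == "off":
        return 1.0
    if table.mode == "blosum":
        if change_type.kind == "missense":
            # monotone decreasing in the substitution score; drastic
            # substitutions (negative scores) weigh more than conservative ones
            ratio = math.exp(-_blosum_score(change_type.aa_ref, change_type.aa_alt) / 2.0)
            return min(max(ratio, 0.1), 10.0)
        return BLOSUM_NON_MISSENSE[change_type.kind]
    cell = (change_type.kind, conservation_bin(conservation, table.n_bins))
    if table.h[cell] == 0 or table.a[cell] == 0:
        raise ValueError(f"cell {cell} unobserved in an unsmoothed table; "
                         f"estimate with a positive pseudocount")
    return table.a[cell] / table.h[cell]


# ---------------------------------------------------------------------------
# Serialization (TSV with a commented header)

def save_impact_table(table: ImpactTable, path) -> None:
    lines = [f"#mode\t{table.mode}", f"#bins\t{table.n_bins}",
             f"#pseudocount\t{table.pseudocount!r}"]
    if table.mode == "empirical":
        lines.append("kind\tbin\ta\th")
        for kind in KINDS:
            for b in range(table.n_bins):
                lines.append(f"{kind}\t{b}\t{table.a[(kind, b)]!r}\t{table.h[(kind, b)]!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_impact_table(path) -> ImpactTable:
    meta = {}
    a, h = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, val = line[1:].split("\t")
                meta[key] = val
            elif line and not line.startswith("kind\t"):
                kind, b, av, hv = line.split("\t")
                a[(kind, int(b))] = float(av)
                h[(kind, int(b))] = float(hv)
    mode = meta["mode"]
    if mode != "empirical":
        return ImpactTable(mode=mode, n_bins=int(meta["bins"]))
    return ImpactTable(mode=mode, n_bins=int(meta["bins"]), a=a, h=h,
                       pseudocount=float(meta["pseudocount"]))
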