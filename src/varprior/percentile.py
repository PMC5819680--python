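"""Gene-wise percentile normalization via cumulative rank distributions.

A CRD maps raw likelihood-ratio scores to percentile ranks in [0, 100]
against the background variants of one gene and effect group. Percentiles
use mid-ranks (ties share the average rank), which makes the mean percentile
of a background set scored against its own CRD exactly 50, with linear
interpolation between distinct background scores and saturation at 0/100
outside the observed range.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .io import CODING, NON_CODING, INTERGENIC


@dataclass
class CRD:
    """Cumulative rank distribution over distinct background raw scores."""
    scores: np.ndarray       # distinct, strictly increasing
    percentiles: np.ndarray  # matching mid-rank percentiles, non-decreasing
    n: int                   # number of contributing background variants
    fallback: bool = False   # true when empty or a pooled substitute

    def __post_init__(self):
        self.scores = np.asarray(self.scores, float)
        self.percentiles = np.asarray(self.percentiles, float)
        if np.any(np.diff(self.scores) <= 0):
            raise ValueError("CRD scores must be strictly increasing")
        if np.any(np.diff(self.percentiles) < 0):
            raise ValueError("CRD percentiles must be non-decreasing")


def build_crd(raw_scores: Iterable[float]) -> CRD:
    """Build a CRD from background raw scores (empty input -> fallback CRD).

    The percentile of a score s among n background scores is
    ``100 * (#{< s} + 0.5 * #{= s}) / n``.
    """
    arr = np.sort(np.asarray(list(raw_scores), float))
    n = arr.size
    if n == 0:
        return CRD(scores=np.empty(0), percentiles=np.empty(0), n=0, fallback=True)
    distinct, counts = np.unique(arr, return_counts=True)
    less = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pcts = 100.0 * (less + 0.5 * counts) / n
    return CRD(scores=distinct, percentiles=pcts, n=n, fallback=False)


def percentile(crd: CRD, raw: float) -> float:
    """Percentile rank of ``raw`` against a CRD.

    Below the background range -> 0; above -> 100; at a background score ->
    its mid-rank percentile; between distinct scores -> linear interpolation.
    """
    if crd.n == 0:
        raise ValueError("cannot take a percentile from an empty (fallback) CRD")
    if raw < crd.scores[0]:
        return 0.0
    if raw > crd.scores[-1]:
        return 100.0
    return float(np.interp(raw, crd.scores, crd.percentiles))


def build_index_crds(index, scored_background, min_gene_variants: int = 10) -> None:
    """Fill an index's CRDs from het-state raw scores of the background.

    Coding and non-coding variants group per (gene, effect group); intergenic
    variants pool into one CRD. Pooled per-group CRDs are kept as fallbacks
    for genes with fewer than ``min_gene_variants`` background variants.
    """
    per_gene: dict = {}
    pooled: dict = {CODING: [], NON_CODING: []}
    intergenic: list[float] = []
    for res in scored_background:
        if res.effect_group == INTERGENIC or res.gene_id is None:
            intergenic.append(res.raw_het)
        else:
            per_gene.setdefault((res.gene_id, res.effect_group), []).append(res.raw_het)
            pooled[res.effect_group].append(res.raw_het)
    index.crds = {k: build_crd(v) for k, v in per_gene.items()}
    index.pooled_crds = {g: build_crd(v) for g, v in pooled.items()}
    index.intergenic_crd = build_crd(intergenic)
    index.metadata["min_gene_variants"] = int(min_gene_variants)


def _resolve_crd(index, gene_id: Optional[str], group: str,
                 min_gene_variants: int) -> tuple[Optional[CRD], bool]:
    """Pick the CRD for (gene, group); returns (crd, used_pooled_fallback)."""
    if group == INTERGENIC or gene_id is None:
        crd = index.intergenic_crd
        return (crd, False) if crd is not None and not crd.fallback else (None, False)
    crd = index.crds.get((gene_id, group))
    if crd is None:
        warnings.warn(f"gene {gene_id!r} absent from background CRDs; "
                      f"using pooled {group} CRD")
    used_fallback = False
    if crd is None or crd.fallback or crd.n < min_gene_variants:
        crd = index.pooled_crds.get(group)
        used_fallback = True
    if crd is None or crd.fallback:
        return None, used_fallback
    return crd, used_fallback


def assign_percentiles(result, index, min_gene_variants: Optional[int] = None):
    """Fill a ScoreResult's percentile fields from the index CRDs.

    Both het and hom raw scores map through the same CRD. When the gene CRD
    is too sparse the pooled effect-group CRD is used and the result is
    flagged as a fallback.
    """
    if min_gene_variants is None:
        min_gene_variants = int(index.metadata.get("min_gene_variants", 10))
    crd, used_fallback = _resolve_crd(index, result.gene_id, result.effect_group,
                                      min_gene_variants)
    if crd is None:
        warnings.warn(f"no usable CRD for {result.variant_key}; percentiles unset")
        return result
    result.percentile_het = percentile(crd, result.raw_het)
    result.percentile_hom = percentile(crd, result.raw_hom)
    result.crd_fallback = used_fallback
    return result
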