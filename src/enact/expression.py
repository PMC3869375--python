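"""RNA-seq expression quantification and dependence analysis.

Expression per gene is RPKM over the exon union.  A gene is *expressed*
at RPKM > 1 in at least one sample of the contrast under analysis.
Regulation (up/down between two time points) and MLL4 dependence
(knockout vs control) both use an "over 2.5-fold" ratio rule on
pseudo-count-stabilized RPKM; the boundary (exactly 2.5-fold) is
excluded.  Enrichment of dependent genes among up-regulated genes is the
hypergeometric upper tail, computed with the strict-inequality
convention of R's phyper upper tail (the convention the published
worked-example statistics follow).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .colocal_stats import log10_hypergeom_tail, wilcoxon_rank_sum, RankSumResult
from .chromatin_state import RegulatoryElement
from .genome_core import GeneModel, TagLibrary, TSSRecord, nearest_tss

__all__ = [
    "ExpressionParams",
    "ExpressionRecord",
    "compute_rpkm",
    "count_exonic_tags",
    "quantify_samples",
    "classify_regulation",
    "classify_dependence",
    "dependence_enrichment",
    "assign_enhancers_to_genes",
    "GeneCategory",
    "group_foldchange_summary",
]


@dataclass(frozen=True)
class ExpressionParams:
    """``expressed_rpkm`` — expression threshold (RPKM > 1);
    ``fc_cutoff`` — the "over 2.5-fold" regulation/dependence cutoff;
    ``pseudo_rpkm`` — stabilizer added to both terms of every ratio."""

    expressed_rpkm: float = 1.0
    fc_cutoff: float = 2.5
    pseudo_rpkm: float = 0.1

    def __post_init__(self) -> None:
        if self.fc_cutoff <= 1:
            raise ValueError("fc_cutoff must exceed 1")
        if self.expressed_rpkm <= 0 or self.pseudo_rpkm <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ExpressionRecord:
    """Per-gene counts and RPKM across samples with analysis calls."""

    gene_id: str
    counts: Dict[str, int] = field(default_factory=dict)
    rpkm: Dict[str, float] = field(default_factory=dict)
    regulation: Optional[str] = None      # up / down / unchanged
    dependence: Optional[str] = None      # MLL4_dependent / independent
    category: Optional[str] = None        # enhancer-derived TF category
    mll4_status: Optional[str] = None     # MLL4+ / MLL4-


def compute_rpkm(exonic_count: int, exonic_length: int, mapped_total: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exonic_length <= 0:
        raise ValueError("exonic_length must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    return exonic_count / ((exonic_length / 1_000) * (mapped_total / 1_000_000))


def count_exonic_tags(gene: GeneModel, tags: TagLibrary) -> int:
    """Tags whose position falls in the gene's exon union.  A tag in a
    region shared by several genes counts for each of them."""
    return sum(tags.count_in(iv.chrom, iv.start, iv.end)
               for iv in gene.exon_union)


def quantify_samples(
    genes: Sequence[GeneModel],
    libraries: Mapping[str, TagLibrary],
) -> Dict[str, ExpressionRecord]:
    """Exonic counts and RPKM for every gene in every sample."""
    records: Dict[str, ExpressionRecord] = {}
    totals = {s: lib.total_count for s, lib in libraries.items()}
    for gene in genes:
        rec = ExpressionRecord(gene.gene_id)
        for sample, lib in libraries.items():
            c = count_exonic_tags(gene, lib)
            rec.counts[sample] = c
            rec.rpkm[sample] = compute_rpkm(c, gene.exonic_length, totals[sample])
        records[gene.gene_id] = rec
    return records


def _stab_ratio(num: float, den: float, params: ExpressionParams) -> float:
    return (num + params.pseudo_rpkm) / (den + params.pseudo_rpkm)


def classify_regulation(rpkm_before: float, rpkm_after: float,
                        params: ExpressionParams = ExpressionParams()) -> str:
    """'up' if after/before exceeds the cutoff, 'down' if before/after
    does, else 'unchanged'; ratios are pseudo-count stabilized and the
    boundary (exactly cutoff-fold) is excluded."""
    if _stab_ratio(rpkm_after, rpkm_before, params) > params.fc_cutoff:
        return "up"
    if _stab_ratio(rpkm_before, rpkm_after, params) > params.fc_cutoff:
        return "down"
    return "unchanged"


def classify_dependence(rpkm_control: float, rpkm_deficient: float,
                        params: ExpressionParams = ExpressionParams()) -> str:
    """MLL4_dependent iff expression drops more than cutoff-fold in the
    knockout relative to control."""
    if _stab_ratio(rpkm_control, rpkm_deficient, params) > params.fc_cutoff:
        return "MLL4_dependent"
    return "independent"


def is_expressed(rpkms: Iterable[float],
                 params: ExpressionParams = ExpressionParams()) -> bool:
    """Expressed = RPKM above threshold in at least one sample of the
    contrast."""
    return any(r > params.expressed_rpkm for r in rpkms)


def dependence_enrichment(
    expressed: Set[str],
    dependent: Set[str],
    upregulated: Set[str],
) -> Tuple[Tuple[int, int, int, int], float]:
    """Hypergeometric enrichment of dependent genes among up-regulated
    genes.

    Returns ``((N, K, n, k), log10_p)`` with N = expressed, K = dependent,
    n = up-regulated, k = dependent-and-up-regulated; the p-value is the
    strict upper tail P(X > k), the phyper upper-tail convention the
    published worked-example statistics follow.
    """
    if not dependent <= expressed:
        raise ValueError("dependent genes must be a subset of expressed genes")
    if not upregulated <= expressed:
        raise ValueError("up-regulated genes must be a subset of expressed genes")
    N, K, n = len(expressed), len(dependent), len(upregulated)
    k = len(dependent & upregulated)
    return (N, K, n, k), log10_hypergeom_tail(N, K, n, k, strict=True)


# ---------------------------------------------------------------------------
# enhancer-to-gene assignment
# ---------------------------------------------------------------------------

@dataclass
class GeneCategory:
    gene_id: str
    category: str            # CEBP+PPARG-, CEBP-PPARG+, CEBP+PPARG+
    mll4_status: str          # MLL4+ / MLL4-
    enhancers: List[RegulatoryElement] = field(default_factory=list)


def assign_enhancers_to_genes(
    enhancers: Sequence[RegulatoryElement],
    tss: Sequence[TSSRecord],
    max_dist: int = 1_000_000,
) -> Dict[str, GeneCategory]:
    """Assign each grouped enhancer to its nearest TSS within ``max_dist``
    (1,000 kb) and resolve each gene's TF category.

    A gene is CEBP+PPARG+ if at least one associated enhancer is; with no
    double-positive enhancer, the category of the nearest associated
    single-TF enhancer wins.  MLL4 status is MLL4+ if any associated
    enhancer is MLL4+, else MLL4-.
    """
    per_gene: Dict[str, List[Tuple[int, RegulatoryElement]]] = {}
    for el in enhancers:
        if el.group is None:
            raise ValueError("enhancers must carry a lineage group label")
        hit = nearest_tss((el.interval.chrom, el.center), tss, max_dist)
        if hit is None:
            continue
        gene_id, dist = hit
        per_gene.setdefault(gene_id, []).append((abs(dist), el))

    out: Dict[str, GeneCategory] = {}
    for gene_id, pairs in per_gene.items():
        pairs.sort(key=lambda p: p[0])
        els = [el for _, el in pairs]
        if any(el.group == "CEBP+PPARG+" for el in els):
            category = "CEBP+PPARG+"
        else:
            category = els[0].group  # nearest single-TF enhancer decides
        mll4 = "MLL4+" if any(el.has_mll4 for el in els) else "MLL4-"
        out[gene_id] = GeneCategory(gene_id, category, mll4, els)
    return out


def group_foldchange_summary(
    gene_groups: Mapping[str, Sequence[str]],
    log2_fc: Mapping[str, float],
    params: ExpressionParams = ExpressionParams(),
) -> Dict:
    """Summarize log2 fold changes per gene group.

    Per group: median, quartiles and the induced fraction (fold change
    over the cutoff, i.e. log2 FC > log2(cutoff)); plus pairwise
    rank-sum p-values between groups.  Empty groups are omitted.
    """
    import math as _math

    summary: Dict[str, Dict] = {}
    values: Dict[str, np.ndarray] = {}
    log2_cutoff = _math.log2(params.fc_cutoff)
    for label, genes in gene_groups.items():
        vals = np.array([log2_fc[g] for g in genes if g in log2_fc])
        if vals.size == 0:
            continue
        values[label] = vals
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summary[label] = {
            "n": int(vals.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "induced_fraction": float(np.mean(vals > log2_cutoff)),
        }
    comparisons: Dict[str, RankSumResult] = {}
    labels = sorted(values)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            comparisons[f"{la} vs {lb}"] = wilcoxon_rank_sum(values[la], values[lb])
    return {"groups": summary, "rank_sum": comparisons}
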