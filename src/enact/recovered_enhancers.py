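"""Recovery analysis of C/EBPbeta-dependent enhancer establishment.

Starting from a reference set of C/EBPbeta+ MLL4+ active enhancers
(identified during differentiation), the chain asks which of them are
re-established when C/EBPbeta is ectopically expressed in undifferentiated
cells: bound by ectopic C/EBPbeta, then also by MLL4, then carrying both
H3K4me1 and H3K27ac ("recovered").  Recovered enhancers split into
*premarked* (MLL4-bound already in vector-control cells) and *de novo*
(MLL4 recruited only upon C/EBPbeta expression).  A final test asks what
fraction of recovered enhancers loses H3K4me1 when MLL4 is deleted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

from .genome_core import GenomicInterval, TagLibrary, _IntervalIndex
from .island_caller import Island, bh_adjust_log10, log_poisson_sf

__all__ = ["RecoveryResult", "recovery_chain", "mll4_dependence_of_me1"]

_LN10 = math.log(10.0)


@dataclass
class RecoveryResult:
    """Counts along the recovery chain (each stage a subset of the last)."""

    n_reference: int
    n_bound: int
    n_mll4: int
    n_recovered: int
    n_premarked: int
    n_de_novo: int
    recovered: List[GenomicInterval] = field(default_factory=list)
    premarked: List[GenomicInterval] = field(default_factory=list)
    de_novo: List[GenomicInterval] = field(default_factory=list)
    fraction_me1_decreased: float = float("nan")


def _filter_overlapping(
    ivs: Sequence[GenomicInterval],
    islands: Sequence[Island],
) -> List[GenomicInterval]:
    index = _IntervalIndex([i.interval for i in islands])
    return [iv for iv in ivs if index.query(iv)]


def recovery_chain(
    reference: Sequence[GenomicInterval],
    oe_cebpb: Sequence[Island],
    oe_mll4: Sequence[Island],
    oe_me1: Sequence[Island],
    oe_k27ac: Sequence[Island],
    vector_mll4: Sequence[Island],
) -> RecoveryResult:
    """Sequential >= 1-bp overlap filters over the reference enhancers.

    reference -> bound by ectopic C/EBPbeta -> MLL4-bound -> H3K4me1- and
    H3K27ac-marked (recovered); recovered enhancers overlapping an MLL4
    island from vector-control cells are premarked, the rest de novo.
    """
    reference = list(reference)
    bound = _filter_overlapping(reference, oe_cebpb)
    mll4 = _filter_overlapping(bound, oe_mll4)
    recovered = _filter_overlapping(_filter_overlapping(mll4, oe_me1), oe_k27ac)
    vec_index = _IntervalIndex([i.interval for i in vector_mll4])
    premarked = [iv for iv in recovered if vec_index.query(iv)]
    de_novo = [iv for iv in recovered if not vec_index.query(iv)]
    return RecoveryResult(
        n_reference=len(reference),
        n_bound=len(bound),
        n_mll4=len(mll4),
        n_recovered=len(recovered),
        n_premarked=len(premarked),
        n_de_novo=len(de_novo),
        recovered=recovered,
        premarked=premarked,
        de_novo=de_novo,
    )


def mll4_dependence_of_me1(
    recovered: Sequence[GenomicInterval],
    me1_control_tags: TagLibrary,
    me1_deficient_tags: TagLibrary,
    fdr: float = 1e-3,
) -> float:
    """Fraction of recovered enhancers with significantly decreased
    H3K4me1 in MLL4-deficient cells.

    Per enhancer: one-sided Poisson test of the control-cell H3K4me1 tag
    count exceeding the depth-scaled deficient-cell count (pseudo-count
    1), Benjamini-Hochberg across enhancers, fraction below ``fdr``.
    """
    if not recovered:
        raise ValueError("no recovered enhancers supplied")
    if me1_deficient_tags.total_count == 0:
        raise ValueError("deficient-cell H3K4me1 library is empty")
    ratio = me1_control_tags.total_count / me1_deficient_tags.total_count
    log10_ps = []
    for iv in recovered:
        ctrl = me1_control_tags.count_in(iv.chrom, iv.start, iv.end)
        defi = me1_deficient_tags.count_in(iv.chrom, iv.start, iv.end)
        expected = max(defi * ratio, 1.0)
        log10_ps.append(log_poisson_sf(ctrl, expected) / _LN10)
    adj = bh_adjust_log10(log10_ps)
    cutoff = math.log10(fdr)
    return float((adj < cutoff).mean())
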