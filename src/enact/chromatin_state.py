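"""Chromatin-state classification of regulatory elements.

Four mutually exclusive element classes are defined from histone marks:

* active promoter  — TSS window overlapping H3K4me3 and H3K27ac islands
* silent promoter  — TSS window overlapping H3K4me3 but not H3K27ac
* active enhancer  — distal H3K4me1 island (center beyond the promoter
  radius of every TSS, no H3K4me3 overlap) overlapping H3K27ac
* silent enhancer  — distal H3K4me1 island without H3K27ac

Promoter assignment is evaluated first: an H3K4me1 island inside promoter
territory yields no enhancer.  Lineage enhancer groups are formed from TF
occupancy on active enhancers (C/EBP = merged union of C/EBPalpha and
C/EBPbeta binding regions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .genome_core import (
    GenomicInterval,
    TSSRecord,
    _IntervalIndex,
    check_disjoint,
    interval_center,
    merge_intervals,
)
from .island_caller import Island

__all__ = [
    "ClassifierParams",
    "RegulatoryElement",
    "ELEMENT_CLASSES",
    "classify_elements",
    "distribute_peaks",
    "group_lineage_enhancers",
]

ELEMENT_CLASSES = (
    "active_promoter",
    "silent_promoter",
    "active_enhancer",
    "silent_enhancer",
)


@dataclass(frozen=True)
class ClassifierParams:
    """``promoter_radius`` (bp around a TSS counting as promoter
    territory) defaults to 2,500, the customary distal cutoff."""

    promoter_radius: int = 2_500

    def __post_init__(self) -> None:
        if self.promoter_radius <= 0:
            raise ValueError("promoter_radius must be positive")


@dataclass(frozen=True)
class RegulatoryElement:
    """A classified regulatory element.

    ``center`` is the TSS for promoters and the H3K4me1-island midpoint
    for enhancers.  Occupancy flags are filled by
    :func:`group_lineage_enhancers`.
    """

    interval: GenomicInterval
    element_class: str
    center: int
    gene_id: Optional[str] = None
    has_cebp: bool = False
    has_pparg: bool = False
    has_myod: bool = False
    has_mll4: bool = False
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")

    @property
    def is_promoter(self) -> bool:
        return self.element_class.endswith("promoter")

    @property
    def is_active(self) -> bool:
        return self.element_class.startswith("active")


def _island_intervals(islands: Sequence[Island]) -> List[GenomicInterval]:
    return [i.interval for i in islands]


def classify_elements(
    me1: Sequence[Island],
    me3: Sequence[Island],
    k27ac: Sequence[Island],
    tss: Sequence[TSSRecord],
    params: ClassifierParams = ClassifierParams(),
) -> List[RegulatoryElement]:
    """Classify promoters (per TSS) and enhancers (per H3K4me1 island)
    into the four mutually exclusive chromatin-state classes."""
    if not tss:
        raise ValueError("empty TSS list")
    me1_iv = _island_intervals(me1)
    me3_iv = _island_intervals(me3)
    k27_iv = _island_intervals(k27ac)
    for ivs, label in ((me1_iv, "H3K4me1"), (me3_iv, "H3K4me3"), (k27_iv, "H3K27ac")):
        check_disjoint(ivs, label)
    me3_index = _IntervalIndex(me3_iv)
    k27_index = _IntervalIndex(k27_iv)

    elements: List[RegulatoryElement] = []
    r = params.promoter_radius

    # promoters first: one element per TSS whose window overlaps H3K4me3
    tss_by_chrom: Dict[str, List[int]] = {}
    for rec in tss:
        tss_by_chrom.setdefault(rec.chrom, []).append(rec.tss)
        window = GenomicInterval(rec.chrom, max(0, rec.tss - r), rec.tss + r)
        if not me3_index.query(window):
            continue
        cls = "active_promoter" if k27_index.query(window) else "silent_promoter"
        elements.append(RegulatoryElement(window, cls, center=rec.tss,
                                          gene_id=rec.gene_id))
    for positions in tss_by_chrom.values():
        positions.sort()

    # enhancers: distal H3K4me1 islands free of H3K4me3
    import bisect
    for iv in me1_iv:
        center = interval_center(iv)
        positions = tss_by_chrom.get(iv.chrom, [])
        if positions:
            j = bisect.bisect_left(positions, center)
            near = min(
                (abs(positions[i] - center) for i in (j - 1, j)
                 if 0 <= i < len(positions)),
                default=None,
            )
            if near is not None and near <= r:
                continue  # inside promoter territory
        if me3_index.query(iv):
            continue
        cls = "active_enhancer" if k27_index.query(iv) else "silent_enhancer"
        elements.append(RegulatoryElement(iv, cls, center=center))
    return elements


def distribute_peaks(
    peaks: Sequence[Island],
    elements: Sequence[RegulatoryElement],
) -> Dict[str, int]:
    """Assign each peak to one element class by overlap.

    A peak overlapping elements of several classes is counted once, in
    the first class of the priority order active_promoter >
    silent_promoter > active_enhancer > silent_enhancer; peaks
    overlapping no element fall in "other".
    """
    indexes = {}
    for cls in ELEMENT_CLASSES:
        ivs = [el.interval for el in elements if el.element_class == cls]
        indexes[cls] = _IntervalIndex(ivs)
    counts: Counter = Counter({cls: 0 for cls in ELEMENT_CLASSES})
    counts["other"] = 0
    for peak in peaks:
        for cls in ELEMENT_CLASSES:
            if indexes[cls].query(peak.interval):
                counts[cls] += 1
                break
        else:
            counts["other"] += 1
    return dict(counts)


def group_lineage_enhancers(
    active_enhancers: Sequence[RegulatoryElement],
    cebpa: Sequence[Island],
    cebpb: Sequence[Island],
    pparg: Sequence[Island],
    mll4: Sequence[Island] = (),
    myod: Sequence[Island] = (),
) -> Dict[str, List[RegulatoryElement]]:
    """Group TF-bound active enhancers by occupancy pattern.

    C/EBP binding is the merged union of the C/EBPalpha and C/EBPbeta
    island sets; an enhancer joins a group by >= 1 bp overlap.  Groups
    ("CEBP+PPARG-", "CEBP-PPARG+", "CEBP+PPARG+") are disjoint and cover
    every C/EBP- or PPARgamma-bound active enhancer.  Each returned
    element carries occupancy flags including MLL4 (and MyoD when
    supplied; MyoD-bound active enhancers are the myogenic analog).
    """
    cebp_union = merge_intervals(
        _island_intervals(cebpa) + _island_intervals(cebpb))
    cebp_index = _IntervalIndex(cebp_union)
    pparg_index = _IntervalIndex(_island_intervals(pparg))
    mll4_index = _IntervalIndex(_island_intervals(mll4))
    myod_index = _IntervalIndex(_island_intervals(myod))

    groups: Dict[str, List[RegulatoryElement]] = {
        "CEBP+PPARG-": [], "CEBP-PPARG+": [], "CEBP+PPARG+": []
    }
    for el in active_enhancers:
        if el.element_class != "active_enhancer":
            raise ValueError("group_lineage_enhancers expects active enhancers")
        has_cebp = bool(cebp_index.query(el.interval))
        has_pparg = bool(pparg_index.query(el.interval))
        if not (has_cebp or has_pparg):
            continue
        group = ("CEBP+PPARG+" if has_cebp and has_pparg
                 else "CEBP+PPARG-" if has_cebp else "CEBP-PPARG+")
        groups[group].append(replace(
            el,
            has_cebp=has_cebp,
            has_pparg=has_pparg,
            has_mll4=bool(mll4_index.query(el.interval)),
            has_myod=bool(myod_index.query(el.interval)),
            group=group,
        ))
    return groups
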