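"""Seeded synthetic ChIP-seq / RNA-seq datasets with ground truth.

The generator emulates the statistical structure of a differentiation
ChIP-seq/RNA-seq study on one synthetic chromosome: regulatory elements
(promoters at gene TSSs, distal enhancers) are planted on a jittered grid,
TF and MLL4 occupancy is drawn per active enhancer, and each (target,
condition) tag library is sampled as uniform background plus
uniform-within-peak enrichment around occupied element centers.  Knockout
libraries retain MLL4-dependent signal at a configurable fraction;
antibody-artifact sites carry full signal in both genotypes and exist to
exercise the knockout-based specificity filter.  Expression counts are
negative-binomial around a log-normal baseline, with genes assigned (by
nearest TSS) to MLL4+ double-positive enhancers induced during
differentiation and knocked down in MLL4-deficient cells.

Every draw flows from ``SimConfig.seed`` through fixed per-library
substreams, so identical configs give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .genome_core import (
    GeneModel,
    GenomicInterval,
    TSSRecord,
    nearest_tss,
    write_annotation,
    write_bed,
)

__all__ = ["SimConfig", "SimElement", "SimAnnotation",
           "simulate_annotation", "simulate_chip_tags",
           "simulate_expression", "write_fixtures"]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic dataset.

    Defaults give a 10-Mb chromosome carrying 500 genes and 450 enhancers
    with 200k tags per library — enough power for island calling while the
    whole pipeline runs in seconds.
    """

    seed: int = 42
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000})
    n_genes: int = 500
    n_active_enhancers: int = 300
    n_silent_enhancers: int = 150
    n_active_promoters: int = 300
    n_silent_promoters: int = 200
    n_artifact_sites: int = 50
    # occupancy of active enhancers
    p_cebp: float = 0.6
    p_pparg: float = 0.25
    p_both: float = 0.15
    p_myod: float = 0.3
    mll4_given_tf: float = 0.6
    # tag libraries
    tags_per_library: int = 200_000
    enrichment_fold: float = 50.0
    peak_width: int = 600
    fragment_size: int = 150
    read_length: int = 50
    ko_effect: float = 0.1
    promoter_radius: int = 2_500
    # recovery chain (C/EBPbeta overexpression in undifferentiated cells)
    p_oe_bound: float = 0.65
    p_oe_mll4: float = 0.25
    p_oe_active: float = 0.9
    p_premarked: float = 0.35
    # expression
    rna_reads: int = 200_000
    expr_effect: float = 4.0
    ko_expr_fold: float = 8.0
    expr_dispersion: float = 0.04
    max_assign_dist: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("p_cebp", "p_pparg", "p_both", "p_myod", "mll4_given_tf",
                     "p_oe_bound", "p_oe_mll4", "p_oe_active", "p_premarked",
                     "ko_effect"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_both > min(self.p_cebp, self.p_pparg):
            raise ValueError("p_both cannot exceed the marginal probabilities")
        if self.enrichment_fold < 1 or self.expr_effect < 1 or self.ko_expr_fold < 1:
            raise ValueError("fold parameters must be >= 1")
        if self.n_active_promoters + self.n_silent_promoters > self.n_genes:
            raise ValueError("more promoters than genes")


@dataclass
class SimElement:
    """Ground truth for one planted element."""

    element_id: str
    kind: str           # active_enhancer / silent_enhancer /
                        # active_promoter / silent_promoter / artifact
    chrom: str
    center: int
    gene_id: Optional[str] = None
    has_cebpa: bool = False
    has_cebpb: bool = False
    has_pparg: bool = False
    has_myod: bool = False
    has_mll4: bool = False
    # recovery-chain flags (reference = active enhancer with C/EBPb + MLL4)
    is_reference: bool = False
    oe_bound: bool = False
    oe_mll4: bool = False
    oe_active: bool = False
    premarked: bool = False

    @property
    def has_cebp(self) -> bool:
        return self.has_cebpa or self.has_cebpb


@dataclass
class SimAnnotation:
    """Planted annotation: genes, TSSs and ground-truth elements."""

    config: SimConfig
    genes: List[GeneModel]
    elements: List[SimElement]

    @property
    def tss_records(self) -> List[TSSRecord]:
        return [g.tss_record() for g in self.genes]

    def elements_of(self, *kinds: str) -> List[SimElement]:
        return [e for e in self.elements if e.kind in kinds]

    @property
    def mll4_sites(self) -> List[SimElement]:
        """True MLL4 binding sites (artifacts excluded)."""
        return [e for e in self.elements if e.has_mll4]

    def induced_genes(self) -> List[str]:
        """Genes assigned by nearest TSS to an MLL4+ C/EBP+PPARG+ active
        enhancer; these are induced during differentiation and
        MLL4-dependent."""
        tss = self.tss_records
        out = set()
        for el in self.elements:
            if (el.kind == "active_enhancer" and el.has_mll4
                    and el.has_cebp and el.has_pparg):
                hit = nearest_tss((el.chrom, el.center), tss,
                                  self.config.max_assign_dist)
                if hit is not None:
                    out.add(hit[0])
        return sorted(out)


# stream ids keep every library on its own reproducible substream
_STREAMS = {
    "annotation": 0, "expression": 1,
    "h3k4me1": 10, "h3k4me2": 11, "h3k4me3": 12, "h3k27ac": 13,
    "mll4": 14, "cebpa": 15, "cebpb": 16, "pparg": 17, "myod": 18,
    "med1": 19, "polii": 20, "input": 21,
}
_CONDITIONS = {"control": 0, "ko": 1, "oe_cebpb": 2, "oe_ko": 3,
               "vector": 4, "input": 5}


def _rng(config: SimConfig, stream: str, condition: str = "control") -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, _STREAMS[stream], _CONDITIONS[condition]])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimConfig) -> SimAnnotation:
    """Plant genes and elements on a jittered grid.

    Elements are non-overlapping and enhancers sit farther than the
    promoter radius from every TSS by construction.
    """
    rng = _rng(config, "annotation")
    (chrom, length), = list(config.chrom_lengths.items())[:1]
    if len(config.chrom_lengths) != 1:
        raise ValueError("the generator uses a single synthetic chromosome")

    n_enh = config.n_active_enhancers + config.n_silent_enhancers
    n_slots = config.n_genes + n_enh + config.n_artifact_sites
    spacing = length // n_slots
    margin = config.promoter_radius + config.peak_width + 500
    jitter = (spacing - margin) // 2
    if jitter < 0:
        raise ValueError(
            f"infeasible packing: {n_slots} elements on {length} bp need "
            f"spacing >= {margin} bp")
    centers = (np.arange(n_slots) * spacing + spacing // 2
               + rng.integers(-jitter, jitter + 1, size=n_slots))
    roles = rng.permutation(
        ["gene"] * config.n_genes
        + ["active_enhancer"] * config.n_active_enhancers
        + ["silent_enhancer"] * config.n_silent_enhancers
        + ["artifact"] * config.n_artifact_sites)

    genes: List[GeneModel] = []
    elements: List[SimElement] = []
    gene_no = enh_no = art_no = 0
    promoter_classes = (["active_promoter"] * config.n_active_promoters
                        + ["silent_promoter"] * config.n_silent_promoters
                        + ["none"] * (config.n_genes - config.n_active_promoters
                                      - config.n_silent_promoters))
    promoter_classes = list(rng.permutation(promoter_classes))

    n_exons, exon_len, exon_step = 4, 400, 1_000
    for center, role in zip(centers.tolist(), roles.tolist()):
        if role == "gene":
            gene_id = f"gene_{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            extent = (n_exons - 1) * exon_step + exon_len
            if center < extent:
                strand = "+"
            elif center + extent >= length:
                strand = "-"
            if strand == "+":
                exons = tuple(
                    GenomicInterval(chrom, center + i * exon_step,
                                    center + i * exon_step + exon_len)
                    for i in range(n_exons))
            else:
                exons = tuple(
                    GenomicInterval(chrom, center + 1 - i * exon_step - exon_len,
                                    center + 1 - i * exon_step)
                    for i in range(n_exons))
            genes.append(GeneModel(gene_id, chrom, strand, exons))
            pcls = promoter_classes[gene_no]
            if pcls != "none":
                elements.append(SimElement(
                    f"prom_{gene_no:04d}", pcls, chrom, center, gene_id=gene_id))
            gene_no += 1
        elif role == "artifact":
            elements.append(SimElement(
                f"artifact_{art_no:03d}", "artifact", chrom, center))
            art_no += 1
        else:
            el = SimElement(f"enh_{enh_no:04d}", role, chrom, center)
            if role == "active_enhancer":
                u = rng.random()
                if u < config.p_both:
                    cebp, pparg = True, True
                elif u < config.p_cebp:
                    cebp, pparg = True, False
                elif u < config.p_cebp + config.p_pparg - config.p_both:
                    cebp, pparg = False, True
                else:
                    cebp, pparg = False, False
                if cebp:
                    el.has_cebpa = rng.random() < 0.7
                    el.has_cebpb = rng.random() < 0.7
                    if not (el.has_cebpa or el.has_cebpb):
                        el.has_cebpb = True
                el.has_pparg = pparg
                el.has_myod = rng.random() < config.p_myod
                if cebp or pparg:
                    el.has_mll4 = rng.random() < config.mll4_given_tf
            elements.append(el)
            enh_no += 1

    # recovery-chain flags on reference enhancers (C/EBPb+ MLL4+ active)
    for el in elements:
        if (el.kind == "active_enhancer" and el.has_cebpb and el.has_mll4):
            el.is_reference = True
            el.oe_bound = rng.random() < config.p_oe_bound
            if el.oe_bound:
                el.oe_mll4 = rng.random() < config.p_oe_mll4
                if el.oe_mll4:
                    el.oe_active = rng.random() < config.p_oe_active
                    el.premarked = rng.random() < config.p_premarked
    return SimAnnotation(config, genes, elements)


# ---------------------------------------------------------------------------
# ChIP tag libraries
# ---------------------------------------------------------------------------

def _site_weights(ann: SimAnnotation, target: str, condition: str
                  ) -> List[Tuple[int, float]]:
    """Peak centers and relative weights for a (target, condition) library."""
    cfg = ann.config
    ko = cfg.ko_effect
    sites: List[Tuple[int, float]] = []

    def add(el: SimElement, w: float = 1.0) -> None:
        if w > 0:
            sites.append((el.center, w))

    if target == "input" or condition == "input":
        return []
    for el in ann.elements:
        k = el.kind
        if target == "h3k4me1":
            if condition in ("control",) and k.endswith("enhancer"):
                add(el)
            elif condition == "ko" and k.endswith("enhancer"):
                add(el, ko if el.has_mll4 else 1.0)
            elif condition == "oe_cebpb" and el.oe_active:
                add(el)
            elif condition == "oe_ko" and el.oe_active:
                add(el, ko if el.has_mll4 else 1.0)
        elif target == "h3k4me2":
            if condition == "control" and k.endswith("enhancer"):
                add(el)
        elif target == "h3k4me3":
            if k.endswith("promoter"):
                add(el)
        elif target == "h3k27ac":
            if condition == "control" and k in ("active_enhancer", "active_promoter"):
                add(el)
            elif condition == "oe_cebpb" and el.oe_active:
                add(el)
        elif target == "mll4":
            if condition == "control":
                if el.has_mll4 or k == "artifact":
                    add(el)
            elif condition == "ko":
                if el.has_mll4:
                    add(el, ko)
                elif k == "artifact":
                    add(el)
            elif condition == "oe_cebpb":
                if el.oe_mll4 or k == "artifact":
                    add(el)
            elif condition == "vector":
                if el.premarked or k == "artifact":
                    add(el)
        elif target == "cebpa":
            if condition == "control" and el.has_cebpa:
                add(el)
        elif target == "cebpb":
            if condition == "control" and el.has_cebpb:
                add(el)
            elif condition == "oe_cebpb" and el.oe_bound:
                add(el)
        elif target == "pparg":
            if condition == "control" and el.has_pparg:
                add(el)
        elif target == "myod":
            if condition == "control" and el.has_myod:
                add(el)
        elif target in ("med1", "polii"):
            if condition in ("control", "ko") and k in ("active_enhancer",
                                                        "active_promoter"):
                add(el)
        else:
            raise ValueError(f"unknown ChIP target {target!r}")
    return sites


def simulate_chip_tags(
    config: SimConfig,
    ann: SimAnnotation,
    target: str,
    condition: str = "control",
) -> List[GenomicInterval]:
    """Sample one ChIP (or input) read library as stranded BED reads.

    Background reads are uniform over the chromosome; each occupied site
    adds ``(enrichment_fold - 1) * weight * peak_width`` relative mass
    spread uniformly over ``peak_width`` around its center.  Reads are
    emitted so that 5'-end shifting by fragment_size/2 recovers the
    fragment midpoint.
    """
    rng = _rng(config, target if target != "input" else "input", condition)
    (chrom, length), = list(config.chrom_lengths.items())[:1]
    sites = _site_weights(ann, target, condition)

    bg_mass = float(length)
    site_mass = np.array(
        [(config.enrichment_fold - 1.0) * w * config.peak_width
         for _, w in sites])
    masses = np.concatenate(([bg_mass], site_mass)) if sites else np.array([bg_mass])
    probs = masses / masses.sum()
    alloc = rng.multinomial(config.tags_per_library, probs)

    half_pw = config.peak_width // 2
    mids = [rng.integers(0, length, size=int(alloc[0]))]
    for (center, _w), n in zip(sites, alloc[1:].tolist()):
        if n:
            mids.append(rng.integers(center - half_pw, center + half_pw, size=n))
    mid = np.concatenate(mids)
    half_frag = config.fragment_size // 2
    mid = np.clip(mid, half_frag, length - half_frag - 1)
    plus = rng.random(mid.size) < 0.5

    reads: List[GenomicInterval] = []
    rl = config.read_length
    for m, is_plus in zip(mid.tolist(), plus.tolist()):
        if is_plus:
            start = m - half_frag
            reads.append(GenomicInterval(chrom, start, start + rl, strand="+"))
        else:
            end = m + half_frag
            reads.append(GenomicInterval(chrom, end - rl, end, strand="-"))
    return reads


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

EXPRESSION_SAMPLES = ("control_d0", "control_d2", "ko_d0", "ko_d2")


def simulate_expression(
    config: SimConfig,
    ann: SimAnnotation,
) -> Tuple[Dict[str, List[GenomicInterval]], Dict[str, object]]:
    """Sample exonic RNA reads for the four expression samples.

    Baseline expression is log-normal; planted induced genes (see
    :meth:`SimAnnotation.induced_genes`) rise ``expr_effect``-fold at
    "day 2" in control cells and sit ``ko_expr_fold`` below that in the
    knockout.  Counts are negative-binomial; reads are placed uniformly
    over each gene's exon union.

    Returns ``(reads_per_sample, truth)`` where truth records the induced
    (= MLL4-dependent) gene set and per-gene baselines.
    """
    rng = _rng(config, "expression")
    genes = ann.genes
    induced = set(ann.induced_genes())

    base = np.exp(rng.normal(math.log(5.0), 1.0, size=len(genes)))
    lengths = np.array([g.exonic_length for g in genes], dtype=float)
    level = {s: base.copy() for s in EXPRESSION_SAMPLES}
    for i, g in enumerate(genes):
        if g.gene_id in induced:
            level["control_d2"][i] = base[i] * config.expr_effect
            level["ko_d2"][i] = base[i] * config.expr_effect / config.ko_expr_fold

    reads_per_sample: Dict[str, List[GenomicInterval]] = {}
    disp = config.expr_dispersion
    for sample in EXPRESSION_SAMPLES:
        mass = level[sample] * lengths
        mu = config.rna_reads * mass / mass.sum()
        if disp > 0:
            r = 1.0 / disp
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        reads: List[GenomicInterval] = []
        for g, n in zip(genes, counts.tolist()):
            if n == 0:
                continue
            union = g.exon_union
            lens = np.array([iv.length for iv in union], dtype=float)
            which = rng.choice(len(union), size=n, p=lens / lens.sum())
            offsets = rng.random(n)
            for w, off in zip(which.tolist(), offsets.tolist()):
                iv = union[w]
                m = iv.start + int(off * iv.length)
                reads.append(_read_at(g.chrom, m, config, rng))
        reads_per_sample[sample] = reads

    truth = {
        "induced_genes": sorted(induced),
        "dependent_genes": sorted(induced),
        "baseline": {g.gene_id: float(b) for g, b in zip(genes, base)},
    }
    return reads_per_sample, truth


def _read_at(chrom: str, mid: int, config: SimConfig,
             rng: np.random.Generator) -> GenomicInterval:
    half_frag = config.fragment_size // 2
    rl = config.read_length
    if rng.random() < 0.5:
        start = max(0, mid - half_frag)
        return GenomicInterval(chrom, start, start + rl, strand="+")
    end = mid + half_frag
    return GenomicInterval(chrom, max(0, end - rl), end, strand="-")


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

CHIP_LIBRARIES = (
    ("input", "input"),
    ("h3k4me1", "control"), ("h3k4me1", "ko"),
    ("h3k4me2", "control"),
    ("h3k4me3", "control"),
    ("h3k27ac", "control"),
    ("mll4", "control"), ("mll4", "ko"),
    ("cebpa", "control"), ("cebpb", "control"), ("pparg", "control"),
    ("myod", "control"), ("med1", "control"), ("polii", "control"),
    ("cebpb", "oe_cebpb"), ("mll4", "oe_cebpb"),
    ("h3k4me1", "oe_cebpb"), ("h3k4me1", "oe_ko"),
    ("h3k27ac", "oe_cebpb"),
    ("mll4", "vector"),
)


def write_fixtures(config: SimConfig, outdir) -> Dict[str, str]:
    """Generate and write the complete fixture set.

    Writes chrom.sizes, the gene annotation, every ChIP/RNA tag BED and
    the ground-truth tables; returns a manifest of role -> path.
    """
    outdir = Path(outdir)
    (outdir / "tags").mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(config)
    manifest: Dict[str, str] = {}

    path = outdir / "chrom.sizes"
    with open(path, "w") as fh:
        for chrom, size in config.chrom_lengths.items():
            fh.write(f"{chrom}\t{size}\n")
    manifest["chrom_sizes"] = str(path)

    path = outdir / "genes.tsv"
    write_annotation(ann.genes, path)
    manifest["annotation"] = str(path)

    for target, condition in CHIP_LIBRARIES:
        reads = simulate_chip_tags(config, ann, target, condition)
        role = f"{target}_{condition}"
        path = outdir / "tags" / f"{role}.bed"
        write_bed(reads, path)
        manifest[role] = str(path)

    rna, truth = simulate_expression(config, ann)
    for sample, reads in rna.items():
        role = f"rna_{sample}"
        path = outdir / "tags" / f"{role}.bed"
        write_bed(reads, path)
        manifest[role] = str(path)

    path = outdir / "truth_elements.tsv"
    with open(path, "w") as fh:
        fh.write("element_id\tkind\tchrom\tcenter\tgene_id\thas_cebpa\t"
                 "has_cebpb\thas_pparg\thas_myod\thas_mll4\tis_reference\t"
                 "oe_bound\toe_mll4\toe_active\tpremarked\n")
        for el in ann.elements:
            fh.write("\t".join(str(x) for x in (
                el.element_id, el.kind, el.chrom, el.center,
                el.gene_id or ".", int(el.has_cebpa), int(el.has_cebpb),
                int(el.has_pparg), int(el.has_myod), int(el.has_mll4),
                int(el.is_reference), int(el.oe_bound), int(el.oe_mll4),
                int(el.oe_active), int(el.premarked))) + "\n")
    manifest["truth_elements"] = str(path)

    path = outdir / "truth_genes.tsv"
    with open(path, "w") as fh:
        fh.write("gene_id\tinduced\tdependent\tbaseline\n")
        induced = set(truth["induced_genes"])
        for g in ann.genes:
            fh.write(f"{g.gene_id}\t{int(g.gene_id in induced)}\t"
                     f"{int(g.gene_id in induced)}\t"
                     f"{truth['baseline'][g.gene_id]:.4f}\n")
    manifest["truth_genes"] = str(path)
    return manifest
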