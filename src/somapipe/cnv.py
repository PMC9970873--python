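"""Copy-number classification and the actionability decision tree: log2-ratio
bands, focality, second hits, LOH review and reciprocal-overlap artifact removal.

The loss band is <-1.0 so that the three classification bands (normal 0+/-0.2,
gain >0.5, loss <-1.0) never overlap; the decision-tree category thresholds
(-2.0 / -0.85 / 0.85 / 2.3) form a second, stricter layer applied only to
focal events over actionable genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .filters import VariantRecord
from .intervals import GenomicInterval

NORMAL_BAND = 0.2
GAIN_LOG2 = 0.5
LOSS_LOG2 = -1.0
HOMDEL_LOG2 = -2.0
HETDEL_LOG2 = -0.85
HIGH_GAIN_LOG2 = 0.85
AMP_LOG2 = 2.3
FOCAL_MAX_BP = 5_000_000
LOH_MIN_BP = 10_000_000
ARTIFACT_RECIPROCAL_OVERLAP = 0.95


@dataclass
class CnvSegment:
    interval: GenomicInterval
    log2_ratio: float
    genes: list[str] = field(default_factory=list)
    copies_estimate: float | None = None

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def focal(self) -> bool:
        return self.length < FOCAL_MAX_BP


def classify_segment(segment: CnvSegment) -> str:
    """Coarse band: normal |log2|<=0.2, gain >0.5, loss <-1.0, else subthreshold."""
    r = segment.log2_ratio
    if abs(r) <= NORMAL_BAND:
        return "normal"
    if r > GAIN_LOG2:
        return "gain"
    if r < LOSS_LOG2:
        return "loss"
    return "subthreshold"


def actionable_cnv(segment: CnvSegment) -> dict:
    """Decision-tree category for a segment over an actionable gene.

    Focal (<5 Mb) events are categorised by log2 ratio: homozygous deletion
    <-2.0, heterozygous deletion <-0.85, amplification >2.3 (more than ten
    copies), high gain >0.85 (more than four copies). Non-focal events get
    category 'none' here but remain available to second-hit review.
    """
    r = segment.log2_ratio
    focal = segment.focal
    category = "none"
    if focal:
        if r < HOMDEL_LOG2:
            category = "homozygous_del"
        elif r < HETDEL_LOG2:
            category = "het_del"
        elif r > AMP_LOG2:
            category = "amplification"
        elif r > HIGH_GAIN_LOG2:
            category = "high_gain"
    return {"category": category, "focal": focal}


def second_hit(
    gene: str,
    snv_indel_hits: Iterable[VariantRecord],
    segments: Iterable[CnvSegment],
    gene_interval: GenomicInterval | None = None,
) -> list[tuple[VariantRecord, CnvSegment]]:
    """Pair deleterious small variants in a tumor-suppressor gene with an
    overlapping deletion — focal or a sizable segment / whole chromosome."""
    pairs = []
    losses = [s for s in segments if s.log2_ratio < HETDEL_LOG2]
    for v in snv_indel_hits:
        if v.gene != gene:
            continue
        for s in losses:
            # gene annotation, the gene's own span, or positional overlap all
            # qualify — whole-chromosome losses carry no gene list
            if (
                gene in s.genes
                or s.interval.contains(v.chrom, v.pos)
                or (gene_interval is not None and s.interval.overlap_length(gene_interval) > 0)
            ):
                pairs.append((v, s))
    return pairs


def loh_actionable(
    loh_regions: Iterable[GenomicInterval],
    actionable_genes: dict[str, GenomicInterval],
) -> list[tuple[GenomicInterval, list[str]]]:
    """Keep LOH regions longer than 10 Mb that overlap an actionable gene."""
    out = []
    for region in loh_regions:
        if region.length <= LOH_MIN_BP:
            continue
        hit = [g for g, iv in actionable_genes.items() if region.overlap_length(iv) > 0]
        if hit:
            out.append((region, sorted(hit)))
    return out


def artifact_overlap_filter(
    segments: Sequence[CnvSegment],
    known_artifacts: Sequence[GenomicInterval],
    min_reciprocal: float = ARTIFACT_RECIPROCAL_OVERLAP,
) -> list[CnvSegment]:
    """Drop segments with >=95% reciprocal overlap to a recurrent technical
    artifact or common population variant."""
    return [
        s
        for s in segments
        if not any(s.interval.reciprocal_overlap(a) >= min_reciprocal for a in known_artifacts)
    ]


def copies_from_log2(log2: float, purity: float = 1.0) -> float:
    """Purity-adjusted absolute copies: (2*2^log2 - 2(1-purity)) / purity."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    return (2 * 2**log2 - 2 * (1 - purity)) / purity


def log2_from_copies(copies: float, purity: float = 1.0) -> float:
    import math

    return math.log2((purity * copies + 2 * (1 - purity)) / 2)
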