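"""Variant filter cascades: germline hard filters, panel somatic exclusion and
quality rules, WGS somatic quality filter, trio subtraction, population-frequency
classification, splice-window annotation and splice-prediction aggregation.

Every threshold is a module-level constant with the pipeline's clinical default;
missing caller metrics skip the corresponding rule rather than failing it, so a
record is only excluded for evidence actually present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval

SUBSTITUTION = "substitution"
INDEL = "indel"

# germline GATK-style hard filters: (metric, comparator, cutoff)
GERMLINE_SNV_RULES = [
    ("QD", "<", 2.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
    ("SOR", ">", 30.0),
]
GERMLINE_INDEL_RULES = [
    ("QD", "<", 2.0),
    ("FS", ">", 200.0),
    ("ReadPosRankSum", "<", -20.0),
    ("SOR", ">", 10.0),
]

PON_FREQ_CUTOFF = 0.01
HIGH_QUALITY_SNV_VAF = 0.05
HIGH_QUALITY_SNV_DEPTH = 50
HIGH_QUALITY_INDEL_VAF = 0.10
REPORT_VAF_SNV = 0.05
REPORT_VAF_INDEL = 0.10
WGS_MIN_DEPTH = 10
WGS_UNIQUE_MAPPING_MIN = 0.70
WGS_DUST_MAX = 60.0
WGS_DEPTH_RATIO_MAX = 3.0  # "excessively high" vs chromosome average; not quantified upstream
SPLICE_WINDOW_SNV = 10
SPLICE_WINDOW_INDEL = 20


@dataclass
class VariantRecord:
    """One called variant: locus, alleles, per-sample depths/VAF, caller metrics
    and annotations. The atom of filtering, TMB and evolution analysis."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    variant_class: str = SUBSTITUTION
    tumor_alt_depth: int | None = None
    tumor_ref_depth: int | None = None
    normal_alt_depth: int | None = None
    normal_ref_depth: int | None = None
    tumor_vaf: float | None = None
    normal_vaf: float | None = None
    caller_metrics: dict = field(default_factory=dict)
    caller_pass: bool = False
    locus_metrics: dict = field(default_factory=dict)
    population_frequency: float | None = None
    gene: str | None = None
    consequence: str | None = None
    actionable_flag: bool = False
    actionable_exception: bool = False
    hr_pathway_flag: bool = False
    driver_flag: bool = False

    def __post_init__(self) -> None:
        if self.tumor_vaf is None and self.tumor_alt_depth is not None and self.tumor_ref_depth is not None:
            d = self.tumor_alt_depth + self.tumor_ref_depth
            self.tumor_vaf = self.tumor_alt_depth / d if d else 0.0
        if self.normal_vaf is None and self.normal_alt_depth is not None and self.normal_ref_depth is not None:
            d = self.normal_alt_depth + self.normal_ref_depth
            self.normal_vaf = self.normal_alt_depth / d if d else 0.0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_depth(self) -> int | None:
        if self.tumor_alt_depth is None or self.tumor_ref_depth is None:
            return None
        return self.tumor_alt_depth + self.tumor_ref_depth

    @property
    def normal_depth(self) -> int | None:
        if self.normal_alt_depth is None or self.normal_ref_depth is None:
            return None
        return self.normal_alt_depth + self.normal_ref_depth


@dataclass
class FilterVerdict:
    kept: bool
    reasons: list[str] = field(default_factory=list)
    quality_class: str = "not_applicable"
    reportable: bool = False

    def __post_init__(self) -> None:
        if not self.kept and not self.reasons:
            raise ValueError("excluded verdict must carry reasons")


def filter_germline(record: VariantRecord, variant_class: str | None = None) -> FilterVerdict:
    """Apply the class-specific germline hard filters; any triggered rule excludes."""
    vclass = variant_class or record.variant_class
    if vclass == SUBSTITUTION:
        rules = GERMLINE_SNV_RULES
    elif vclass == INDEL:
        rules = GERMLINE_INDEL_RULES
    else:
        raise ValueError(f"unknown variant class: {vclass}")
    reasons = []
    for metric, op, cutoff in rules:
        value = record.caller_metrics.get(metric)
        if value is None:
            continue  # missing metric: rule not applied
        if (op == "<" and value < cutoff) or (op == ">" and value > cutoff):
            reasons.append(f"{metric}{op}{cutoff}")
    return FilterVerdict(kept=not reasons, reasons=reasons)


def exclude_panel_somatic_snv(
    record: VariantRecord, pon_frequencies: Mapping[tuple, float] | None = None
) -> FilterVerdict:
    """Panel somatic substitution exclusion rules.

    A record is excluded if any rule fires: tumor alt depth <10; germline alt
    depth >=3; germline ref depth <=50 together with tumor VAF <0.01; panel-of-
    normals frequency >=0.01; both tumor and germline total depth <10 unless the
    caller passed the variant through all its internal filters.
    """
    reasons: list[str] = []
    if record.tumor_alt_depth is not None and record.tumor_alt_depth < 10:
        reasons.append("tumor_alt_depth<10")
    if record.normal_alt_depth is not None and record.normal_alt_depth >= 3:
        reasons.append("normal_alt_depth>=3")
    if (
        record.normal_ref_depth is not None
        and record.tumor_vaf is not None
        and record.normal_ref_depth <= 50
        and record.tumor_vaf < 0.01
    ):
        reasons.append("normal_ref_depth<=50_and_tumor_vaf<0.01")
    if pon_frequencies is None:
        pass  # control-cohort table absent: frequency rule skipped
    elif pon_frequencies.get(record.key, 0.0) >= PON_FREQ_CUTOFF:
        reasons.append("pon_frequency>=0.01")
    nd, td = record.normal_depth, record.tumor_depth
    if nd is not None and td is not None and nd < 10 and td < 10 and not record.caller_pass:
        reasons.append("low_depth_both_samples")
    return FilterVerdict(kept=not reasons, reasons=reasons)


def classify_panel_quality(record: VariantRecord) -> str:
    """'high' / 'low' quality class for a kept panel somatic variant."""
    if record.variant_class == SUBSTITUTION:
        ok = (
            record.caller_pass
            and record.tumor_vaf is not None
            and record.tumor_vaf >= HIGH_QUALITY_SNV_VAF
            and (record.tumor_depth or 0) >= HIGH_QUALITY_SNV_DEPTH
            and (record.normal_depth or 0) >= HIGH_QUALITY_SNV_DEPTH
        )
    elif record.variant_class == INDEL:
        ok = (
            record.tumor_vaf is not None
            and record.tumor_vaf >= HIGH_QUALITY_INDEL_VAF
            and (record.tumor_alt_depth or 0) > 10
            and (record.normal_ref_depth or 0) > 50
            and (record.normal_alt_depth if record.normal_alt_depth is not None else 99) <= 2
        )
    else:
        raise ValueError(f"unknown variant class: {record.variant_class}")
    return "high" if ok else "low"


def reportable(record: VariantRecord) -> bool:
    """Clinical reporting threshold: VAF >=5% (substitutions) / >=10% (indels),
    with an explicit exception pathway for actionable variants below threshold."""
    threshold = REPORT_VAF_SNV if record.variant_class == SUBSTITUTION else REPORT_VAF_INDEL
    if record.tumor_vaf is not None and record.tumor_vaf >= threshold:
        return True
    return bool(record.actionable_flag and record.actionable_exception)


def wgs_somatic_filter(
    record: VariantRecord,
    pon_set: set | None = None,
    depth_ratio_max: float = WGS_DEPTH_RATIO_MAX,
    dust_max: float = WGS_DUST_MAX,
) -> FilterVerdict:
    """Genome-wide somatic quality filter.

    Requires >=10x depth in tumor and normal with zero variant-supporting reads
    in the normal; removes panel-of-normals hits and loci failing at least two
    of four mapping-quality cutoffs (unique-mapping fraction <70%, multimapping
    clusters in tumor and normal, depth above ``depth_ratio_max`` times the
    chromosome average, DUST score > ``dust_max``).
    """
    reasons: list[str] = []
    td, nd = record.tumor_depth, record.normal_depth
    if td is not None and td < WGS_MIN_DEPTH:
        reasons.append("tumor_depth<10")
    if nd is not None and nd < WGS_MIN_DEPTH:
        reasons.append("normal_depth<10")
    if record.normal_alt_depth is not None and record.normal_alt_depth > 0:
        reasons.append("variant_reads_in_normal")
    if pon_set is not None and record.key in pon_set:
        reasons.append("panel_of_normals")
    lm = record.locus_metrics
    flags = []
    if lm.get("unique_mapping_fraction") is not None and lm["unique_mapping_fraction"] < WGS_UNIQUE_MAPPING_MIN:
        flags.append("nonunique_mapping")
    if lm.get("multimapping_cluster_in_both"):
        flags.append("multimapping_cluster")
    if lm.get("depth_vs_chrom_average") is not None and lm["depth_vs_chrom_average"] > depth_ratio_max:
        flags.append("excessive_depth")
    if lm.get("dust") is not None and lm["dust"] > dust_max:
        flags.append("low_complexity")
    if len(flags) >= 2:
        reasons.append("mapping_quality:" + "+".join(flags))
    return FilterVerdict(kept=not reasons, reasons=reasons)


def trio_subtract(
    tumor_vs_mother: Iterable[VariantRecord | tuple],
    tumor_vs_father: Iterable[VariantRecord | tuple],
) -> dict:
    """Intersect the two parent-subtracted call sets.

    Variants common to both tumor-vs-mother and tumor-vs-father comparisons are
    true somatic calls; a variant seen in only one comparison was inherited from
    the other parent and is excluded.
    """

    def keyed(records):
        return {(r.key if isinstance(r, VariantRecord) else tuple(r)): r for r in records}

    m, f = keyed(tumor_vs_mother), keyed(tumor_vs_father)
    somatic = sorted(set(m) & set(f))
    return {
        "somatic": [m[k] for k in somatic],
        "inherited_maternal": sorted(set(f) - set(m)),  # absent vs mother => from mother
        "inherited_paternal": sorted(set(m) - set(f)),
    }


def classify_population_frequency(freq: float | None) -> str:
    """>5% benign; 2-5% likely benign; otherwise not classified by frequency."""
    if freq is None or freq <= 0.02:
        return "not_classified_by_frequency"
    if freq > 0.05:
        return "benign"
    return "likely_benign"


def splice_window_annotate(
    record: VariantRecord, exons: Sequence[GenomicInterval]
) -> dict:
    """Distance to the nearest exon edge and whether the variant falls in the
    reportable splice window (10 bp intronic for substitutions, 20 bp for indels)."""
    window = SPLICE_WINDOW_SNV if record.variant_class == SUBSTITUTION else SPLICE_WINDOW_INDEL
    pos = record.pos
    for ex in exons:
        if ex.contains(record.chrom, pos):
            return {"in_window": True, "distance": 0}
    dists = [
        min(abs(pos - (ex.end - 1)), abs(ex.start - pos))
        for ex in exons
        if ex.chrom == record.chrom
    ]
    if not dists:
        return {"in_window": False, "distance": -1}
    d = min(dists)
    return {"in_window": d <= window, "distance": d}


def aggregate_splice_predictions(scores: Sequence[float]) -> bool:
    """Disruptive iff >=3 programs score >30% each, or the scores sum to >=100%."""
    return sum(1 for s in scores if s > 30) >= 3 or sum(scores) >= 100
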