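"""Tumor mutational burden: targeted-panel, whole-genome and in-silico-panel
estimates, hypermutation banding and cross-platform concordance."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .filters import VariantRecord
from .intervals import GenomicInterval, pad_intervals, point_in_intervals

PANEL_SIZE_MB = 3.012823  # exonic target regions +/- 10 bp
GENOME_SIZE_MB = 2897.310462  # interrogatable reference genome
PANEL_TMB_VAF = 0.10
TMB_ACTIONABLE = 5.0
SV_HIGH_COUNT = 200


@dataclass(frozen=True)
class TmbResult:
    variant_count: int
    denominator_mb: float
    platform: str
    vaf_threshold: float | None = None

    @property
    def tmb(self) -> float:
        return self.variant_count / self.denominator_mb

    @property
    def tmb_display(self) -> float:
        return round(self.tmb, 2)


def panel_tmb(
    variants: Iterable[VariantRecord],
    targets: Sequence[GenomicInterval],
    vaf_threshold: float = PANEL_TMB_VAF,
    include_indels: bool = True,
    pad: int = 0,
) -> TmbResult:
    """Panel TMB: qualifying variants (VAF >= 10%) on the padded exonic targets,
    divided by the fixed panel size of 3.012823 Mb — each on-target variant
    contributes ~0.33 mutations per Mb."""
    if not targets:
        raise ValueError("empty target set")
    if pad:
        targets = pad_intervals(targets, pad)
    count = 0
    for v in variants:
        if not include_indels and v.variant_class != "substitution":
            continue
        if v.tumor_vaf is None or v.tumor_vaf < vaf_threshold:
            continue
        if point_in_intervals(v.chrom, v.pos, targets):
            count += 1
    return TmbResult(count, PANEL_SIZE_MB, "panel", vaf_threshold)


def wgs_tmb(variant_count: int) -> TmbResult:
    """Whole-genome TMB: substitution count over the 2,897.310462 Mb genome."""
    return TmbResult(int(variant_count), GENOME_SIZE_MB, "wgs")


def sv_burden_high(sv_count: int) -> bool:
    """Structural variant burden is reported as a raw count; 'high' above 200."""
    return sv_count > SV_HIGH_COUNT


def insilico_panel_tmb(
    exome_variants: Iterable[VariantRecord],
    panel_targets: Sequence[GenomicInterval],
    vaf_threshold: float = PANEL_TMB_VAF,
) -> TmbResult:
    """Exome/genome calls intersected with the panel intervals, divided by the
    panel size — the in-silico analogue of the panel measurement."""
    if not panel_targets:
        raise ValueError("empty target set")
    count = sum(
        1
        for v in exome_variants
        if (v.tumor_vaf is None or v.tumor_vaf >= vaf_threshold)
        and point_in_intervals(v.chrom, v.pos, panel_targets)
    )
    return TmbResult(count, PANEL_SIZE_MB, "insilico_panel", vaf_threshold)


def classify_tmb(tmb: float) -> dict:
    """Hypermutation bands: [0,5) normal, [5,10) hypermutant-low,
    [10,100) hypermutant-high, >=100 ultra; actionable at TMB >= 5."""
    if tmb < 5:
        category = "normal"
    elif tmb < 10:
        category = "hypermutant-low"
    elif tmb < 100:
        category = "hypermutant-high"
    else:
        category = "ultra-hypermutant"
    return {"category": category, "actionable": tmb >= TMB_ACTIONABLE}


def tmb_concordance(pairs: Sequence[tuple[float, float]]) -> dict:
    """Cross-platform agreement for (panel, genome-wide) TMB pairs.

    Pairs are stratified by panel TMB into bands <5, 5-10, >10; each band
    reports mean |panel - wgs|, mean signed difference (panel - wgs) and the
    fraction of samples it holds.
    """
    bands = {"<5": [], "5-10": [], ">10": []}
    for panel, wgs in pairs:
        if panel < 5:
            bands["<5"].append((panel, wgs))
        elif panel <= 10:
            bands["5-10"].append((panel, wgs))
        else:
            bands[">10"].append((panel, wgs))
    total = len(pairs)
    out = {}
    for name, members in bands.items():
        diffs = np.array([p - w for p, w in members]) if members else np.array([])
        out[name] = {
            "mean_abs_difference": float(np.mean(np.abs(diffs))) if len(diffs) else 0.0,
            "mean_signed_difference": float(np.mean(diffs)) if len(diffs) else 0.0,
            "fraction_of_samples": len(members) / total if total else 0.0,
            "n": len(members),
        }
    return out
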