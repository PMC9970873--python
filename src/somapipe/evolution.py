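"""Serial-sample clonal evolution: private/shared mutation accounting, the
five-category driver-change classification, actionability-change flagging,
linear-vs-parallel pair classification and low-cellularity exclusion.

VAF-change thresholds are absolute VAF points (an increase of >0.20 marks an
expanded clone, a decrease of >=0.20 a diminished one), not relative fold
changes; a driver is called absent only when its locus was sequenced deep
enough to support the negative (depth >= ``ABSENT_MIN_DEPTH``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .filters import VariantRecord

DETECT_VAF = 0.10  # strict > for detection
SHARED_VAF = 0.05  # strict > for sharing in another sample
EXPANDED_DELTA = 0.20  # strict > increase
DIMINISHED_DELTA = 0.20  # >= decrease
LINEAR_SHARED_FRACTION = 0.75  # strict > for linear evolution
ABSENT_VAF = 0.01
ABSENT_MIN_DEPTH = 50


@dataclass
class SampleTimepoint:
    sample_id: str
    days_since_first: int
    disease_state: str  # diagnosis | relapse | progression | metastasis
    variants: list[VariantRecord] = field(default_factory=list)
    copy_profile_flat: bool = False
    tmb: float = 0.0

    def vaf_of(self, key: tuple) -> float | None:
        for v in self.variants:
            if v.key == key:
                return v.tumor_vaf
        return None

    def depth_of(self, key: tuple) -> int | None:
        for v in self.variants:
            if v.key == key:
                return v.tumor_depth
        return None


@dataclass(frozen=True)
class DriverChange:
    key: tuple
    category: str  # new_actionable | lost_driver | expanded | diminished | new_nonactionable
    vaf_before: float | None
    vaf_after: float | None


def private_shared(samples: Sequence[SampleTimepoint]) -> dict[str, dict]:
    """Per-sample detected / shared / private SNV counts for one tumor.

    A variant is detected at VAF > 0.10 and counts as shared when any other
    sample of the same tumor carries it at VAF > 0.05; samples with nothing
    above the detection threshold report empty counts.
    """
    if len(samples) < 2:
        raise ValueError("private/shared analysis needs at least two samples")
    out = {}
    for s in samples:
        detected = [v for v in s.variants if v.tumor_vaf is not None and v.tumor_vaf > DETECT_VAF]
        shared = 0
        for v in detected:
            for other in samples:
                if other is s:
                    continue
                vaf = other.vaf_of(v.key)
                if vaf is not None and vaf > SHARED_VAF:
                    shared += 1
                    break
        n = len(detected)
        out[s.sample_id] = {
            "detected": n,
            "shared": shared,
            "private": n - shared,
            "shared_fraction": shared / n if n else None,
        }
    return out


def _presence(sample: SampleTimepoint, key: tuple) -> str:
    """'present' / 'absent' / 'unassessable' for a driver locus in a sample."""
    vaf = sample.vaf_of(key)
    if vaf is not None and vaf >= ABSENT_VAF:
        return "present"
    depth = sample.depth_of(key)
    if vaf is not None and vaf < ABSENT_VAF and (depth is None or depth >= ABSENT_MIN_DEPTH):
        return "absent"
    if vaf is None:
        # not listed at all: treat as assayed-negative (caller emits no record)
        return "absent"
    return "unassessable"


def classify_driver_changes(
    baseline: SampleTimepoint, later: SampleTimepoint
) -> list[DriverChange]:
    """Assign each driver variant at most one of the five change categories
    across a baseline -> later transition.

    (1) new_actionable: actionable driver newly detected; (2) lost_driver: a
    previously seen driver absent at the later timepoint (clone displacement);
    (3) expanded: VAF up by >20 points; (4) diminished: VAF down by >=20
    points; (5) new_nonactionable: new driver without therapeutic relevance.
    Drivers count at any VAF.
    """
    changes: list[DriverChange] = []
    driver_keys: dict[tuple, VariantRecord] = {}
    for s in (baseline, later):
        for v in s.variants:
            if v.driver_flag:
                driver_keys.setdefault(v.key, v)
    for key, rec in sorted(driver_keys.items()):
        before, after = baseline.vaf_of(key), later.vaf_of(key)
        p_before, p_after = _presence(baseline, key), _presence(later, key)
        if p_before != "present" and p_after == "present":
            cat = "new_actionable" if rec.actionable_flag else "new_nonactionable"
            changes.append(DriverChange(key, cat, before, after))
        elif p_before == "present" and p_after == "absent":
            changes.append(DriverChange(key, "lost_driver", before, after))
        elif p_before == "present" and p_after == "present":
            delta = (after or 0.0) - (before or 0.0)
            if delta > EXPANDED_DELTA:
                changes.append(DriverChange(key, "expanded", before, after))
            elif -delta >= DIMINISHED_DELTA:
                changes.append(DriverChange(key, "diminished", before, after))
    return changes


def actionability_change_flag(samples: Sequence[SampleTimepoint]) -> bool:
    """True when any transition in the course gains a new actionable driver or
    loses a previously detected driver (categories 1 and 2)."""
    if len(samples) < 2:
        return False
    ordered = sorted(samples, key=lambda s: s.days_since_first)
    baseline = ordered[0]
    for later in ordered[1:]:
        for change in classify_driver_changes(baseline, later):
            if change.category in ("new_actionable", "lost_driver"):
                return True
    return False


def pair_evolution_class(initial: SampleTimepoint, relapse: SampleTimepoint) -> dict:
    """Linear vs parallel evolution of an initial/relapse pair: linear when
    strictly more than 75% of the initial sample's detected SNVs persist."""
    detected = [
        v for v in initial.variants if v.tumor_vaf is not None and v.tumor_vaf > DETECT_VAF
    ]
    if not detected:
        return {"class": "parallel", "shared_fraction": None}
    shared = sum(
        1
        for v in detected
        if (relapse.vaf_of(v.key) or 0.0) > SHARED_VAF
    )
    frac = shared / len(detected)
    return {"class": "linear" if frac > LINEAR_SHARED_FRACTION else "parallel", "shared_fraction": frac}


def exclude_low_cellularity(sample: SampleTimepoint) -> bool:
    """Flat copy-number profile together with TMB = 0 suggests low tumor
    cellularity; such samples are excluded from evolution analysis."""
    return sample.copy_profile_flat and sample.tmb == 0
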