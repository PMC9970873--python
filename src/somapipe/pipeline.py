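"""Stage orchestration over the synthetic cohort: runs the requested analysis
stages in dependency order, writes per-stage TSVs plus a run manifest (version,
config hash, seed), and renders a cohort summary table."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .cnv import actionable_cnv, artifact_overlap_filter, classify_segment, loh_actionable
from .cohort import attribute_signatures, cohort_enrichment
from .evolution import (
    actionability_change_flag,
    classify_driver_changes,
    exclude_low_cellularity,
    pair_evolution_class,
    private_shared,
)
from .filters import trio_subtract
from .fusion import validate_fusions
from .simulate import (
    CohortConfig,
    make_clonal_timecourse,
    make_cnv_profile,
    make_fusion_readset,
    make_signature_counts,
    make_tmb_pairs,
    make_trio_and_tumor,
)
from .tmb import classify_tmb, panel_tmb, tmb_concordance, wgs_tmb

STAGES = ("trio", "tmb", "fusion", "cnv", "evolve", "cohort")


def config_hash(config: CohortConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# somapipe {__version__} config={chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: CohortConfig, outdir, stages=STAGES) -> dict:
    """Run the selected stages on a synthetic cohort generated from ``config``.

    Deterministic under the seed: repeated runs produce byte-identical outputs.
    Returns the in-memory results keyed by stage.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    results: dict = {}

    if "trio" in stages:
        trio = make_trio_and_tumor(config)
        subtracted = trio_subtract(trio["tumor_vs_mother"], trio["tumor_vs_father"])
        df = pd.DataFrame(
            [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "tumor_vaf": round(v.tumor_vaf, 4)}
                for v in subtracted["somatic"]
            ]
        )
        _write(df, outdir / "trio_somatic.tsv", chash)
        results["trio"] = {"somatic": subtracted["somatic"], "truth": trio["truth"]}

    if "tmb" in stages:
        pairs = make_tmb_pairs(config)
        rows, tmb_pairs = [], []
        for s in pairs["samples"]:
            p = panel_tmb(s["panel"], pairs["panel_intervals"])
            w = wgs_tmb(len(s["genome"]))
            band = classify_tmb(p.tmb)
            rows.append(
                {"sample": s["sample_id"], "panel_tmb": p.tmb_display,
                 "wgs_tmb": w.tmb_display, "category": band["category"],
                 "actionable": band["actionable"], "true_rate": s["true_rate"]}
            )
            tmb_pairs.append((p.tmb, w.tmb))
        _write(pd.DataFrame(rows), outdir / "tmb.tsv", chash)
        results["tmb"] = {"rows": rows, "concordance": tmb_concordance(tmb_pairs)}

    if "fusion" in stages:
        fset = make_fusion_readset(config)
        validated = validate_fusions(
            fset["candidates"], fset["genes"], fset["genome"],
            fset["tumor_reads"], fset["normal_reads"],
        )
        df = pd.DataFrame(
            [
                {"candidate": c.candidate_id,
                 "validated": c.validation.get("validated", False),
                 "score": c.score,
                 "truth": fset["truth"].labels[c.candidate_id]}
                for c in validated
            ]
        )
        _write(df, outdir / "fusions.tsv", chash)
        results["fusion"] = {"candidates": validated, "truth": fset["truth"]}

    if "cnv" in stages:
        prof = make_cnv_profile(config)
        kept = artifact_overlap_filter(prof["segments"], prof["known_artifacts"])
        rows = []
        for seg in kept:
            act = actionable_cnv(seg)
            rows.append(
                {"chrom": seg.interval.chrom, "start": seg.interval.start,
                 "end": seg.interval.end, "log2": seg.log2_ratio,
                 "class": classify_segment(seg), "category": act["category"],
                 "focal": act["focal"]}
            )
        loh = loh_actionable(prof["loh_regions"], prof["actionable_genes"])
        _write(pd.DataFrame(rows), outdir / "cnv.tsv", chash)
        results["cnv"] = {"rows": rows, "loh": loh, "truth": prof["truth"]}

    if "evolve" in stages:
        tc = make_clonal_timecourse(config)
        samples = [s for s in tc["samples"] + [tc["decoy"]] if not exclude_low_cellularity(s)]
        changes = classify_driver_changes(samples[0], samples[-1])
        pair = pair_evolution_class(samples[0], samples[-1])
        ps = private_shared(samples)
        df = pd.DataFrame(
            [{"variant": "_".join(map(str, c.key)), "category": c.category,
              "vaf_before": c.vaf_before, "vaf_after": c.vaf_after} for c in changes]
        )
        _write(df, outdir / "driver_changes.tsv", chash)
        results["evolve"] = {
            "changes": changes,
            "pair_class": pair,
            "private_shared": ps,
            "actionability_changed": actionability_change_flag(samples),
            "truth": tc["truth"],
        }

    if "cohort" in stages:
        sig = make_signature_counts(config)
        attributions = {
            sid: attribute_signatures(sig["counts"][sid].to_numpy(), sig["catalog"], sid)
            for sid in sig["counts"].columns
        }
        groups = {}
        for grp in config.hr_group_sizes:
            members = [s for s, g in sig["hr_labels"].items() if g == grp]
            pos = sum(attributions[s].sbs3_positive for s in members)
            groups[grp] = (pos, len(members))
        enrich = cohort_enrichment(groups)
        df = pd.DataFrame(
            [{"sample": s, "sbs3_attributed": round(a.attributed_counts.get("SBS3", 0.0), 1),
              "sbs3_positive": a.sbs3_positive, "group": sig["hr_labels"][s]}
             for s, a in attributions.items()]
        )
        _write(df, outdir / "signatures.tsv", chash)
        results["cohort"] = {"attributions": attributions, "groups": groups,
                             "enrichment": enrich, "truth": sig["truth"]}

    manifest = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "stages": list(stages),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results


def render_summary(results: dict) -> pd.DataFrame:
    """Cohort summary table: one row per sample in chronological order with
    actionability flags and private/shared fractions where available."""
    rows = []
    evolve = results.get("evolve")
    if evolve:
        ps = evolve["private_shared"]
        for sid, stats in ps.items():
            rows.append(
                {"sample": sid, "detected": stats["detected"], "shared": stats["shared"],
                 "private": stats["private"],
                 "shared_fraction": stats["shared_fraction"],
                 "actionability_changed": evolve["actionability_changed"]}
            )
    tmb = results.get("tmb")
    if tmb:
        for r in tmb["rows"]:
            rows.append({"sample": r["sample"], "panel_tmb": r["panel_tmb"],
                         "tmb_actionable": r["actionable"]})
    return pd.DataFrame(rows)
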