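"""Synthetic cohort generation with known ground truth.

Every input the pipeline consumes — trio genotypes with embedded somatic
variants, multi-timepoint clonal VAF dynamics, chimeric-transcript read sets
with planted artifacts and a normal-sample panel, segmented copy-number
profiles with LOH, and signature-mixture mutation counts with configurable
SBS3 enrichment — can be generated here deterministically from a seed, so
every downstream stage is testable without access-controlled patient data.

Each generator draws from its own RNG stream (cohort seed + stage tag), so
stages can be regenerated independently and in any order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import fusion as fusion_mod
from .cnv import CnvSegment
from .filters import VariantRecord
from .fusion import Breakpoint, reconstruct_chimera
from .genes import GeneModel
from .intervals import GenomicInterval
from .evolution import SampleTimepoint
from .seq import revcomp
from .tmb import GENOME_SIZE_MB

BASES = np.array(list("ACGT"))

# default serial-sampling clone tree: (parent, name, per-timepoint VAFs)
DEFAULT_CLONE_TREE = [
    (None, "trunk", (0.55, 0.60)),
    ("trunk", "expanding", (0.20, 0.45)),
    ("trunk", "shrinking", (0.50, 0.25)),
    ("trunk", "displaced", (0.30, 0.00)),
    ("trunk", "emerging_actionable", (0.00, 0.35)),
    ("trunk", "emerging_passenger", (0.00, 0.22)),
]


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Group sizes and SBS3 enrichment defaults mirror the cohort structure the
    pipeline's statistics were designed for: 25 HR-germline, 26 HR-somatic and
    242 HR-negative samples with SBS3-positive fractions 0.48 / 0.308 / 0.231,
    compared against an external reference of 2,780 samples at 0.133.
    """

    seed: int = 0
    n_genes: int = 12
    genome_length: int = 60_000
    n_samples: int = 8
    clone_tree: list = field(default_factory=lambda: list(DEFAULT_CLONE_TREE))
    timepoint_days: tuple = (0, 180)
    read_length: int = 100
    coverage: float = 20.0
    error_rate: float = 0.0
    sbs3_enrichment: dict = field(
        default_factory=lambda: {"germline": 0.48, "somatic": 0.308, "negative": 0.231}
    )
    hr_group_sizes: dict = field(
        default_factory=lambda: {"germline": 25, "somatic": 26, "negative": 242}
    )
    # trio composition
    n_somatic: int = 25
    n_inherited_maternal: int = 30
    n_inherited_paternal: int = 30
    n_shared_population: int = 20
    # fusion read-set composition
    n_true_fusions: int = 10
    n_artifact_fusions: int = 5
    n_read_throughs: int = 2
    n_normal_samples: int = 8

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        vafs_by_name = {name: np.asarray(v, dtype=float) for _, name, v in self.clone_tree}
        for parent, name, vafs in self.clone_tree:
            v = np.asarray(vafs, dtype=float)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"clone {name}: VAFs outside [0, 1]")
            if parent is not None:
                if parent not in vafs_by_name:
                    raise ValueError(f"clone {name}: unknown parent {parent}")
                if np.any(v > vafs_by_name[parent] + 1e-9):
                    raise ValueError(f"clone {name}: VAF exceeds parent {parent}")


@dataclass
class GroundTruth:
    true_somatic_variants: set = field(default_factory=set)
    true_fusions: list = field(default_factory=list)
    planted_artifacts: list = field(default_factory=list)
    driver_change_labels: dict = field(default_factory=dict)
    signature_weights: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)


def _rng(config: CohortConfig, tag: str) -> np.random.Generator:
    return np.random.default_rng([config.seed % 2**31, zlib.crc32(tag.encode()) % 2**31])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------- reference


def make_reference(config: CohortConfig) -> dict:
    """Random genome plus gene models: multi-exon genes on both strands with
    canonical GT..AG introns, at least one gene each of biotype miRNA, snoRNA
    and rRNA, and a mitochondrial contig. Deterministic under the seed."""
    if config.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if config.genome_length < config.n_genes * 2000:
        raise ValueError("infeasible packing: genome too short for gene count")
    rng = _rng(config, "reference")
    genome = {"chr1": list(_random_seq(rng, config.genome_length)),
              "chrM": list(_random_seq(rng, 2000))}
    genes: list[GeneModel] = []
    slot = config.genome_length // config.n_genes
    special = {config.n_genes - 3: "miRNA", config.n_genes - 2: "snoRNA", config.n_genes - 1: "rRNA"}
    for i in range(config.n_genes):
        # first four genes on '+' so adjacent same-strand read-through pairs exist
        strand = "+" if i < 4 else ("+" if rng.random() < 0.5 else "-")
        biotype = special.get(i, "protein_coding")
        n_exons = 2 if biotype != "protein_coding" else int(rng.integers(2, 5))
        pos = i * slot + int(rng.integers(50, 150))
        exons = []
        for e in range(n_exons):
            exon_len = int(rng.integers(120, 301))
            exons.append(GenomicInterval("chr1", pos, pos + exon_len, strand))
            pos += exon_len
            if e < n_exons - 1:
                intron_len = int(rng.integers(120, 401))
                istart, iend = pos, pos + intron_len
                if strand == "+":
                    genome["chr1"][istart : istart + 2] = list("GT")
                    genome["chr1"][iend - 2 : iend] = list("AG")
                else:
                    genome["chr1"][istart : istart + 2] = list("CT")
                    genome["chr1"][iend - 2 : iend] = list("AC")
                pos = iend
        if pos >= (i + 1) * slot:
            raise ValueError("infeasible packing: gene overflows its slot")
        genes.append(GeneModel(f"GENE{i + 1:02d}", "chr1", strand, biotype, exons))
    mt_exons = [GenomicInterval("chrM", 100, 500, "+"), GenomicInterval("chrM", 700, 1100, "+")]
    genes.append(GeneModel("MT-GENE1", "chrM", "+", "protein_coding", mt_exons))
    return {"genome": {k: "".join(v) for k, v in genome.items()}, "genes": genes}


def write_reference(reference: dict, fasta_path, gtf_path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .genes import write_gtf

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference["genome"].items()]
    SeqIO.write(records, fasta_path, "fasta")
    write_gtf(reference["genes"], gtf_path)


# ---------------------------------------------------------------- trio


def make_trio_and_tumor(config: CohortConfig) -> dict:
    """Trio comparison call sets with planted inheritance structure.

    Emits maternally/paternally inherited variants (one parent + tumor),
    shared-population variants (both parents + tumor germline) and true
    somatic variants (tumor only), then derives the two parent-subtracted
    comparison sets the trio-subtraction step consumes.
    """
    rng = _rng(config, "trio")
    total = (
        config.n_somatic
        + config.n_inherited_maternal
        + config.n_inherited_paternal
        + config.n_shared_population
    )
    positions = rng.choice(np.arange(1000, config.genome_length - 1000), size=total, replace=False)
    positions.sort()
    labels = (
        ["somatic"] * config.n_somatic
        + ["inherited_maternal"] * config.n_inherited_maternal
        + ["inherited_paternal"] * config.n_inherited_paternal
        + ["shared_population"] * config.n_shared_population
    )
    rng.shuffle(labels)

    def rec(pos, ref, alt, vaf, depth):
        alt_d = int(round(vaf * depth))
        return VariantRecord(
            "chr1", int(pos), ref, alt,
            tumor_alt_depth=alt_d, tumor_ref_depth=depth - alt_d,
        )

    truth = GroundTruth()
    tumor_vs_mother, tumor_vs_father = [], []
    tables = {"mother": [], "father": [], "tumor": []}
    for pos, label in zip(positions, labels):
        ref = "ACGT"[int(rng.integers(0, 4))]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        depth = int(rng.integers(50, 120))
        vaf = float(np.clip(rng.normal(0.5, 0.03), 0.3, 0.7))
        if label == "somatic":
            vaf = float(rng.uniform(0.08, 0.6))
        key = ("chr1", int(pos), ref, alt)
        truth.labels[key] = label
        if label in ("inherited_maternal", "shared_population"):
            tables["mother"].append(key)
        if label in ("inherited_paternal", "shared_population"):
            tables["father"].append(key)
        tables["tumor"].append(key)
        # comparison sets: tumor variant survives subtraction vs a parent
        # lacking it
        if label in ("somatic", "inherited_paternal"):
            tumor_vs_mother.append(rec(pos, ref, alt, vaf, depth))
        if label in ("somatic", "inherited_maternal"):
            tumor_vs_father.append(rec(pos, ref, alt, vaf, depth))
        if label == "somatic":
            truth.true_somatic_variants.add(key)
    return {
        "tumor_vs_mother": tumor_vs_mother,
        "tumor_vs_father": tumor_vs_father,
        "tables": tables,
        "truth": truth,
    }


# ---------------------------------------------------------------- timecourse


# whether a clone's drivers are therapeutically actionable
_CLONE_ACTIONABLE = {
    "trunk": True,
    "expanding": False,
    "shrinking": False,
    "displaced": True,
    "emerging_actionable": True,
    "emerging_passenger": False,
}
_EXPECTED_LABELS = {
    "expanding": "expanded",
    "shrinking": "diminished",
    "displaced": "lost_driver",
    "emerging_actionable": "new_actionable",
    "emerging_passenger": "new_nonactionable",
}


def make_clonal_timecourse(
    config: CohortConfig,
    depth: int | None = None,
    drivers_per_clone: int = 12,
    passengers_per_clone: int = 4,
) -> dict:
    """Serial tumor samples whose driver VAFs follow the configured clone tree.

    Ground-truth driver-change labels follow the same five-category definitions
    the evolution module recovers. ``depth=None`` emits noiseless VAFs;
    otherwise alt counts are binomially sampled at that depth. A flat-profile,
    zero-mutation decoy sample (low tumor cellularity) is appended.
    """
    rng = _rng(config, "timecourse")
    n_t = len(config.timepoint_days)
    truth = GroundTruth()
    variant_defs = []  # (key, vafs, is_driver, actionable, clone, gene)
    pos = 5000
    for parent, name, vafs in config.clone_tree:
        vafs = list(vafs)
        if len(vafs) != n_t:
            raise ValueError("clone VAF vector does not match timepoint count")
        actionable = _CLONE_ACTIONABLE.get(name, False)
        for d in range(drivers_per_clone):
            key = ("chr1", pos, "C", "T")
            gene = f"{name.upper()}_DRV{d + 1}"
            variant_defs.append((key, vafs, True, actionable, name, gene))
            pos += 997
        for p in range(passengers_per_clone):
            key = ("chr1", pos, "G", "A")
            variant_defs.append((key, vafs, False, False, name, None))
            pos += 1009
    samples = []
    for t, day in enumerate(config.timepoint_days):
        variants = []
        for key, vafs, is_driver, actionable, clone, gene in variant_defs:
            true_vaf = vafs[t]
            if depth is None:
                alt = None
                vaf = true_vaf
                d = 1000
            else:
                alt = int(rng.binomial(depth, true_vaf))
                d = depth
                vaf = alt / depth
            variants.append(
                VariantRecord(
                    key[0], key[1], key[2], key[3],
                    tumor_alt_depth=int(round(vaf * d)), tumor_ref_depth=d - int(round(vaf * d)),
                    tumor_vaf=vaf, gene=gene,
                    driver_flag=is_driver, actionable_flag=actionable,
                )
            )
        samples.append(
            SampleTimepoint(
                sample_id=f"T{t}",
                days_since_first=int(day),
                disease_state="diagnosis" if t == 0 else "relapse",
                variants=variants,
                copy_profile_flat=False,
                tmb=1.5,
            )
        )
    for key, vafs, is_driver, actionable, clone, gene in variant_defs:
        if is_driver and clone in _EXPECTED_LABELS:
            truth.driver_change_labels[key] = _EXPECTED_LABELS[clone]
    decoy = SampleTimepoint("DECOY", int(config.timepoint_days[-1]) + 30, "relapse",
                            variants=[], copy_profile_flat=True, tmb=0.0)
    truth.labels["DECOY"] = "low_cellularity_excludable"
    return {"samples": samples, "decoy": decoy, "truth": truth}


# ---------------------------------------------------------------- fusions


def _sequencing_reads(rng, template: str, read_length: int, coverage: float, error_rate: float,
                      span_pos: int | None = None) -> list[str]:
    n_reads = int(np.ceil(coverage * len(template) / read_length))
    starts = rng.integers(0, max(1, len(template) - read_length + 1), size=n_reads)
    if span_pos is not None:
        # guarantee junction-spanning coverage regardless of draw
        lo = max(0, span_pos - read_length + 10)
        hi = max(lo + 1, min(len(template) - read_length, span_pos - 10) + 1)
        forced = rng.integers(lo, hi, size=max(4, n_reads // 10))
        starts = np.concatenate([starts, forced])
    reads = []
    for s in starts:
        read = list(template[int(s) : int(s) + read_length])
        if error_rate > 0:
            errs = np.nonzero(rng.random(len(read)) < error_rate)[0]
            for e in errs:
                read[e] = rng.choice([b for b in "ACGT" if b != read[e]])
        reads.append("".join(read))
    return reads


def make_fusion_readset(config: CohortConfig, reference: dict | None = None) -> dict:
    """Candidate fusion breakpoints plus tumor/normal read sets.

    Plants (i) true fusions with junction-spanning reads at the configured
    coverage and error rate, (ii) artifact chimeras recurrently supported in
    more than three normal samples, (iii) read-through candidates between
    adjacent same-strand genes, (iv) one candidate whose chimera also occurs
    elsewhere in the genome at 100% identity over more than 50 bases, and
    (v) candidates involving excluded biotypes.
    """
    rng = _rng(config, "fusion")
    ref = reference or make_reference(config)
    genome = dict(ref["genome"])
    genes = [g for g in ref["genes"]]
    coding = [g for g in genes if g.biotype == "protein_coding" and g.chrom == "chr1"]
    small = [g for g in genes if g.biotype in ("miRNA", "snoRNA")]
    truth = GroundTruth()
    candidates: list[tuple[str, Breakpoint, Breakpoint]] = []

    def exon_end_bp(gene: GeneModel, which: str) -> Breakpoint:
        """Breakpoint at an internal exon boundary, strand-aware."""
        if which == "5":
            edge = gene.exons[0].end if gene.strand == "+" else gene.exons[-1].start
        else:
            edge = gene.exons[-1].start if gene.strand == "+" else gene.exons[0].end
        return Breakpoint(gene.chrom, edge, gene.strand, gene.name)

    # duplicated-region decoy partners are reserved so the planted repeat
    # cannot fall inside a true fusion's flank
    decoy5, decoy3 = coding[-1], coding[-3]
    reserved = {decoy5.name, decoy3.name}

    # (i) true fusions between non-adjacent coding genes
    pair_pool = [
        (a, b)
        for ia, a in enumerate(coding)
        for ib, b in enumerate(coding)
        if a is not b and abs(ia - ib) > 1
        and a.name not in reserved and b.name not in reserved
    ]
    order = rng.permutation(len(pair_pool))
    used: set[str] = set()
    n_true = 0
    for idx in order:
        if n_true >= config.n_true_fusions:
            break
        a, b = pair_pool[int(idx)]
        if a.name in used or b.name in used:
            continue
        used.add(a.name)
        used.add(b.name)
        candidates.append((f"TRUE{n_true + 1}", exon_end_bp(a, "5"), exon_end_bp(b, "3")))
        truth.labels[f"TRUE{n_true + 1}"] = "true_fusion"
        n_true += 1
    if n_true < config.n_true_fusions:
        # reuse genes when the pool is exhausted
        for i in range(n_true, config.n_true_fusions):
            a, b = pair_pool[int(order[i % len(order)])]
            candidates.append((f"TRUE{i + 1}", exon_end_bp(a, "5"), exon_end_bp(b, "3")))
            truth.labels[f"TRUE{i + 1}"] = "true_fusion"

    # (ii) recurrent artifacts: mid-exon chimeras supported by the normal panel
    for i in range(config.n_artifact_fusions):
        a, b = coding[i % len(coding)], coding[(i + 3) % len(coding)]
        bp5 = Breakpoint(a.chrom, a.exons[0].start + 60 + 7 * i, a.strand, a.name)
        bp3 = Breakpoint(b.chrom, b.exons[-1].start + 40 + 5 * i, b.strand, b.name)
        cid = f"ARTIFACT{i + 1}"
        candidates.append((cid, bp5, bp3))
        truth.labels[cid] = "recurrent_artifact"
        truth.planted_artifacts.append(cid)

    # (iii) read-throughs: adjacent same-strand '+' gene pairs
    rt_pairs = [(coding[0], coding[1]), (coding[2], coding[3])][: config.n_read_throughs]
    for i, (a, b) in enumerate(rt_pairs):
        cid = f"READTHROUGH{i + 1}"
        candidates.append((cid, exon_end_bp(a, "5"), exon_end_bp(b, "3")))
        truth.labels[cid] = "read_through"

    # (iv) duplicated-region decoy: copy 60 bases of its 5' flank elsewhere
    a, b = decoy5, decoy3
    bp5 = Breakpoint(a.chrom, a.exons[1].end, a.strand, a.name)
    bp3 = exon_end_bp(b, "3")
    flank_seq, _, _ = fusion_mod._flank_sequences(genome, bp5, bp3, fusion_mod.FLANK)
    dup = flank_seq[80:140]
    insert_at = config.genome_length - 500
    genome["chr1"] = genome["chr1"][:insert_at] + dup + genome["chr1"][insert_at + 60 :]
    candidates.append(("DUPDECOY", bp5, bp3))
    truth.labels["DUPDECOY"] = "duplicated_region"

    # (v) excluded-biotype candidates
    for i, g in enumerate(small[:2]):
        cid = f"BIOTYPE{i + 1}"
        partner = coding[5 + i]
        candidates.append((cid, exon_end_bp(partner, "5"),
                           Breakpoint(g.chrom, g.exons[-1].start, g.strand, g.name)))
        truth.labels[cid] = "biotype_excluded"

    built = [reconstruct_chimera(genome, bp5, bp3, cid) for cid, bp5, bp3 in candidates]

    tumor_reads: dict[str, list[str]] = {}
    for cand in built:
        label = truth.labels[cand.candidate_id]
        if label in ("true_fusion", "recurrent_artifact", "duplicated_region"):
            tumor_reads[cand.candidate_id] = _sequencing_reads(
                rng, cand.chimera, config.read_length, config.coverage,
                config.error_rate, span_pos=cand.junction_index,
            )
        if label == "true_fusion":
            truth.true_fusions.append(cand.candidate_id)

    normal_reads: dict[str, list[str]] = {
        f"NORM{i + 1}": [] for i in range(config.n_normal_samples)
    }
    chr1 = genome["chr1"]
    for sample, reads in normal_reads.items():
        for _ in range(20):  # background genomic reads
            s = int(rng.integers(0, len(chr1) - config.read_length))
            reads.append(chr1[s : s + config.read_length])
    artifact_chimeras = {c.candidate_id: c for c in built
                         if truth.labels[c.candidate_id] == "recurrent_artifact"}
    sample_names = list(normal_reads)
    for cand in artifact_chimeras.values():
        j = cand.junction_index
        for k in range(5):  # 5 junction-spanning perfect reads in 5 samples
            offset = 20 + 6 * k
            read = cand.chimera[j - offset : j - offset + config.read_length]
            normal_reads[sample_names[k % len(sample_names)]].append(read)

    return {
        "genome": genome,
        "genes": genes,
        "candidates": built,
        "tumor_reads": tumor_reads,
        "normal_reads": normal_reads,
        "truth": truth,
    }


# ---------------------------------------------------------------- CNV


def make_cnv_profile(config: CohortConfig) -> dict:
    """Segmented copy-number profile with planted actionable events.

    Includes a focal homozygous deletion, a focal heterozygous deletion, a
    high gain, an amplification, a >5 Mb non-focal deletion, LOH regions above
    and below the 10 Mb review threshold, a recurrent-artifact segment and
    neutral filler segments.
    """
    rng = _rng(config, "cnv")
    mb = 1_000_000

    def seg(chrom, s_mb, e_mb, log2, genes=(), label=None):
        segment = CnvSegment(GenomicInterval(chrom, int(s_mb * mb), int(e_mb * mb)),
                             float(log2), list(genes))
        return segment, label

    planted = [
        seg("chr1", 10, 13, -2.5, ["CDKN2A"], "homozygous_del"),
        seg("chr1", 30, 32, -1.2, ["SMARCB1"], "het_del"),
        seg("chr2", 5, 6, 1.2, ["MYCN"], "high_gain"),
        seg("chr2", 20, 20.5, 2.5, ["EGFR"], "amplification"),
        seg("chr3", 10, 16, -2.5, ["RB1"], "non_focal"),
        seg("chr1", 60, 61, 0.8, [], "artifact"),
    ]
    truth = GroundTruth()
    segments = []
    for segment, label in planted:
        segments.append(segment)
        truth.labels[(segment.interval.chrom, segment.interval.start, segment.interval.end)] = label
    for chrom in ("chr1", "chr2", "chr3"):  # neutral filler
        for k in range(3):
            s = 70 + 8 * k
            segment = CnvSegment(GenomicInterval(chrom, s * mb, (s + 5) * mb),
                                 float(rng.normal(0.0, 0.05)))
            segments.append(segment)
            truth.labels[(chrom, s * mb, (s + 5) * mb)] = "neutral"
    known_artifacts = [GenomicInterval("chr1", 60 * mb, 61 * mb)]
    loh_regions = [
        GenomicInterval("chr3", 40 * mb, 52 * mb),  # 12 Mb over PTEN -> actionable
        GenomicInterval("chr2", 40 * mb, 49 * mb),  # 9 Mb -> below threshold
        GenomicInterval("chr1", 70 * mb, 85 * mb),  # 15 Mb, no actionable gene
    ]
    truth.labels[("chr3", 40 * mb, 52 * mb)] = "loh_actionable"
    actionable_genes = {
        "CDKN2A": GenomicInterval("chr1", int(11.2 * mb), int(11.25 * mb)),
        "SMARCB1": GenomicInterval("chr1", int(30.5 * mb), int(30.55 * mb)),
        "MYCN": GenomicInterval("chr2", int(5.3 * mb), int(5.32 * mb)),
        "EGFR": GenomicInterval("chr2", int(20.1 * mb), int(20.15 * mb)),
        "RB1": GenomicInterval("chr3", int(12 * mb), int(12.1 * mb)),
        "PTEN": GenomicInterval("chr3", int(45 * mb), int(45.1 * mb)),
    }
    # second-hit scenario: germline truncating variant under the het deletion
    second_hit_variants = [
        VariantRecord("chr1", int(30.51 * mb), "C", "A", gene="SMARCB1",
                      consequence="stop_gained", tumor_vaf=0.52,
                      tumor_alt_depth=52, tumor_ref_depth=48)
    ]
    return {
        "segments": segments,
        "known_artifacts": known_artifacts,
        "loh_regions": loh_regions,
        "actionable_genes": actionable_genes,
        "second_hit_variants": second_hit_variants,
        "truth": truth,
    }


# ---------------------------------------------------------------- signatures


SIGNATURE_NAMES = ("SBS1", "SBS3", "SBS5", "SBS13", "SBS18")
_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}" for sub in _SUBS for five in "ACGT" for three in "ACGT"
)


def make_signature_catalog() -> "pd.DataFrame":
    """Fixed synthetic 96-channel catalog: five well-separated signatures, each
    concentrating ~90% of its mass on its own block of channels (plus a uniform
    floor), so supervised refitting is well conditioned. Real COSMIC profiles
    (SBS3 in particular is near-flat) are less separable; see the methods note.
    """
    import pandas as pd

    rng = np.random.default_rng(20210301)
    n_sig = len(SIGNATURE_NAMES)
    mat = np.full((96, n_sig), 0.1 / 96)
    blocks = rng.permutation(96)
    per = 96 // n_sig
    for s in range(n_sig):
        home = blocks[s * per : (s + 1) * per]
        weights = rng.dirichlet(np.full(len(home), 0.8))
        mat[home, s] += 0.9 * weights
    mat /= mat.sum(axis=0, keepdims=True)
    return pd.DataFrame(mat, index=list(CHANNELS_96), columns=list(SIGNATURE_NAMES))


def make_signature_counts(config: CohortConfig, burden_range: tuple = (1500, 5000)) -> dict:
    """Per-sample 96-channel mutation counts from a signature mixture.

    Within each HR group, a sample carries SBS3 activity with the configured
    enrichment probability; counts are Poisson around catalog @ weights *
    burden. Returns counts, true weights, burdens and HR labels.
    """
    import pandas as pd

    rng = _rng(config, "signatures")
    catalog = make_signature_catalog()
    sbs3_col = list(catalog.columns).index("SBS3")
    rows, truth = [], GroundTruth()
    sample_ids, hr_labels = [], {}
    for group, n in config.hr_group_sizes.items():
        p_active = config.sbs3_enrichment[group]
        for i in range(n):
            sid = f"{group[:4].upper()}{i + 1:03d}"
            active = rng.random() < p_active
            w = rng.dirichlet(np.full(len(catalog.columns) - 1, 1.0))
            weights = np.insert(w, sbs3_col, 0.0)
            if active:
                sbs3_w = rng.uniform(0.15, 0.45)
                weights = weights * (1 - sbs3_w)
                weights[sbs3_col] = sbs3_w
            burden = int(rng.integers(*burden_range))
            lam = catalog.to_numpy() @ (weights * burden)
            counts = rng.poisson(lam)
            rows.append(counts)
            sample_ids.append(sid)
            hr_labels[sid] = group
            truth.signature_weights[sid] = dict(zip(catalog.columns, weights * burden))
            truth.labels[sid] = "sbs3_active" if active else "sbs3_inactive"
    counts96 = pd.DataFrame(np.array(rows).T, index=list(CHANNELS_96), columns=sample_ids)
    return {"counts": counts96, "catalog": catalog, "hr_labels": hr_labels, "truth": truth}


# ---------------------------------------------------------------- TMB pairs


def make_tmb_pairs(
    config: CohortConfig,
    rates_per_mb: tuple = (0.5, 1.0, 2.0, 3.0, 6.0, 8.0, 15.0, 30.0),
    platform_private: int = 0,
) -> dict:
    """Paired (panel-restricted, genome-wide) variant sets per sample.

    Variants fall uniformly on a virtual genome of the interrogatable size;
    the panel set is the genome set intersected with panel target intervals
    (plus ``platform_private`` panel-only variants per sample).
    """
    rng = _rng(config, "tmb")
    genome_bp = int(GENOME_SIZE_MB * 1e6)
    panel_bp = int(3.012823 * 1e6)
    n_iv = 1000
    iv_len = panel_bp // n_iv
    spacing = genome_bp // n_iv
    panel = [GenomicInterval("chr1", i * spacing, i * spacing + iv_len) for i in range(n_iv)]
    samples = []
    truth = GroundTruth()
    for i, rate in enumerate(rates_per_mb[: max(config.n_samples, 1)]):
        n_var = rng.poisson(rate * GENOME_SIZE_MB)
        positions = np.sort(rng.integers(0, genome_bp, size=n_var))
        genome_vars = [
            VariantRecord("chr1", int(p), "C", "T", tumor_vaf=0.4,
                          tumor_alt_depth=40, tumor_ref_depth=60)
            for p in positions
        ]
        # targets are regularly spaced: on-target iff offset within the interval
        on_target = (positions % spacing < iv_len) & (positions // spacing < n_iv)
        panel_vars = [v for v, hit in zip(genome_vars, on_target) if hit]
        for k in range(platform_private):
            iv = panel[int(rng.integers(0, n_iv))]
            panel_vars.append(
                VariantRecord("chr1", int(rng.integers(iv.start, iv.end)), "G", "A",
                              tumor_vaf=0.4, tumor_alt_depth=40, tumor_ref_depth=60)
            )
        samples.append({"sample_id": f"S{i + 1}", "genome": genome_vars,
                        "panel": panel_vars, "true_rate": rate})
        truth.labels[f"S{i + 1}"] = rate
    return {"samples": samples, "panel_intervals": panel, "truth": truth}
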