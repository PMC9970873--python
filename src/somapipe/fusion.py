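"""Candidate fusion-transcript validation.

A candidate enters as a breakpoint pair; it is reconstructed into a chimeric
transcript (200 bases each side of the junction), screened against a panel of
normal transcriptomes, confirmed by two independent breakpoint reconstructions
(de novo contig assembly and k-mer gap filling across an artificial 5-base gap),
checked for genomic misalignment/low-complexity/breakpoint-overhang artifacts,
and finally annotated and scored on splice and frame features.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .genes import GeneModel, nearest_downstream_neighbor
from .intervals import GenomicInterval
from .seq import dust_score, exact_match_runs, kmerize, local_align, revcomp

FLANK = 200
NORMAL_MIN_OVERLAP = 10
NORMAL_MAX_READS = 3
NORMAL_MAX_SAMPLES = 3
CONTIG_JUNCTION_OVERLAP = 3  # bases required on each side of the junction
CONTIG_MAX_MISMATCH = 1
GAP_LEN = 5
GAP_LEFT_OFFSET = 2  # gap removes chimera[junction-2 : junction+3)
GAPFILL_MIN_EDGE = 3
GAPFILL_MAX_DELTA = 1
GAPFILL_KMER_FRACTION = 0.85
GAPFILL_MIN_KMERS = 2
MISALIGN_MIN_RUN = 50  # strictly more than 50 bp at 100% identity
BREAKPOINT_MAX_OFFSET = 10
BREAKPOINT_MIN_IDENTITY = 0.99
DUST_THRESHOLD = 60.0
EXCLUDED_BIOTYPES = {"miRNA", "snoRNA", "rRNA"}
MITO_CONTIGS = {"chrM", "MT", "chrMT"}

DEFAULT_WEIGHTS = {
    "cds_both": 2,
    "splice_junction_both": 2,
    "splice_major": 2,
    "splice_minor": 1,
    "in_frame": 2,
    "artifact_flag": -3,
}


@dataclass(frozen=True)
class Breakpoint:
    chrom: str
    pos: int  # 0-based; the half-open boundary of the retained segment
    strand: str
    gene: str | None = None


@dataclass
class CandidateFusion:
    candidate_id: str
    bp5: Breakpoint
    bp3: Breakpoint
    chimera: str = ""
    junction_index: int = 0
    source_spans: list[GenomicInterval] = field(default_factory=list)
    features: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    score: float = 0.0


def _flank_sequences(genome: Mapping[str, str], bp5: Breakpoint, bp3: Breakpoint, flank: int):
    for bp in (bp5, bp3):
        if bp.chrom not in genome or not (0 <= bp.pos <= len(genome[bp.chrom])):
            raise ValueError(f"breakpoint off contig: {bp.chrom}:{bp.pos}")
    c5, c3 = genome[bp5.chrom], genome[bp3.chrom]
    if bp5.strand == "+":
        s5 = c5[max(0, bp5.pos - flank) : bp5.pos]
        span5 = GenomicInterval(bp5.chrom, max(0, bp5.pos - flank), max(bp5.pos, 1))
    else:
        s5 = revcomp(c5[bp5.pos : bp5.pos + flank])
        span5 = GenomicInterval(bp5.chrom, bp5.pos, min(len(c5), bp5.pos + flank))
    if bp3.strand == "+":
        s3 = c3[bp3.pos : bp3.pos + flank]
        span3 = GenomicInterval(bp3.chrom, bp3.pos, min(len(c3), bp3.pos + flank))
    else:
        s3 = revcomp(c3[max(0, bp3.pos - flank) : bp3.pos])
        span3 = GenomicInterval(bp3.chrom, max(0, bp3.pos - flank), max(bp3.pos, 1))
    return s5, s3, [span5, span3]


def reconstruct_chimera(
    genome: Mapping[str, str],
    bp5: Breakpoint,
    bp3: Breakpoint,
    candidate_id: str = "fusion",
    flank: int = FLANK,
) -> CandidateFusion:
    """Strand-aware 5' + 3' flank concatenation (up to ``flank`` bases each,
    truncated at contig ends); the junction index is the 5' flank length."""
    s5, s3, spans = _flank_sequences(genome, bp5, bp3, flank)
    return CandidateFusion(
        candidate_id=candidate_id,
        bp5=bp5,
        bp3=bp3,
        chimera=s5 + s3,
        junction_index=len(s5),
        source_spans=spans,
    )


def prefilter_candidates(
    candidates: Sequence[CandidateFusion], genes: Sequence[GeneModel]
) -> tuple[list[CandidateFusion], dict[str, str]]:
    """Remove candidates with excluded biotypes (miRNA/snoRNA/rRNA/mitochondrial
    partners) and potential read-throughs (same chromosome and strand, 3'
    partner the nearest downstream neighbor of the 5' gene).

    Returns (retained candidates, {candidate_id: removal reason}).
    """
    by_name = {g.name: g for g in genes}
    gene_list = list(genes)
    kept, removed = [], {}
    for cand in candidates:
        reason = None
        for bp in (cand.bp5, cand.bp3):
            g = by_name.get(bp.gene) if bp.gene else None
            if bp.chrom in MITO_CONTIGS or (g and g.chrom in MITO_CONTIGS):
                reason = "mitochondrial"
            elif g and g.biotype in EXCLUDED_BIOTYPES:
                reason = f"biotype:{g.biotype}"
        g5 = by_name.get(cand.bp5.gene) if cand.bp5.gene else None
        g3 = by_name.get(cand.bp3.gene) if cand.bp3.gene else None
        if (
            reason is None
            and g5 is not None
            and g3 is not None
            and g5.chrom == g3.chrom
            and g5.strand == g3.strand
        ):
            neighbor = nearest_downstream_neighbor(g5, gene_list)
            if neighbor is not None and neighbor.name == g3.name:
                reason = "read_through"
        if reason:
            cand.validation["prefilter_removed"] = reason
            removed[cand.candidate_id] = reason
        else:
            kept.append(cand)
    return kept, removed


def normal_panel_filter(
    candidate: CandidateFusion, normal_read_sets: Mapping[str, Sequence[str]]
) -> dict:
    """Screen the chimera against normal-sample reads.

    A normal read supports the chimera when it matches perfectly with at least
    10 bases of overlap AND spans the junction; the candidate is removed when
    more than 3 supporting reads come from more than 3 samples.
    """
    chimera = candidate.chimera
    j = candidate.junction_index
    total_reads = 0
    supporting_samples = 0
    for sample, reads in normal_read_sets.items():
        n = 0
        for read in reads:
            if len(read) < NORMAL_MIN_OVERLAP:
                continue
            start = 0
            while True:
                p = chimera.find(read, start)
                if p < 0:
                    break
                if p < j < p + len(read):
                    n += 1
                    break
                start = p + 1
        if n:
            supporting_samples += 1
            total_reads += n
    removed = total_reads > NORMAL_MAX_READS and supporting_samples > NORMAL_MAX_SAMPLES
    candidate.validation["normal_panel_removed"] = removed
    return {"removed": removed, "supporting": (total_reads, supporting_samples)}


def assemble_contigs(
    reads: Sequence[str], k_ladder: Sequence[int] = (31, 41, 51), min_multiplicity: int = 2
) -> list[str]:
    """De Bruijn assembly over a ladder of k values.

    For each k, k-mers seen at least ``min_multiplicity`` times form the graph
    and maximal non-branching paths (unitigs) are emitted; the union of unitigs
    at least as long as the shortest read is returned, deduplicated, in
    deterministic (length-descending, then lexicographic) order.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    min_read = min(len(r) for r in reads)
    usable = [k for k in k_ladder if k <= min_read]
    if not usable:
        raise ValueError("all reads shorter than the smallest assembly k")
    contigs: set[str] = set()
    for k in usable:
        counts: Counter[str] = Counter()
        for r in reads:
            for i in range(len(r) - k + 1):
                counts[r[i : i + k]] += 1
        kmers = [km for km, c in counts.items() if c >= min_multiplicity]
        out_edges: dict[str, list[str]] = {}
        in_deg: Counter[str] = Counter()
        for km in kmers:
            u, v = km[:-1], km[1:]
            out_edges.setdefault(u, []).append(v)
            in_deg[v] += 1
        for u in out_edges:
            out_edges[u].sort()
        visited: set[tuple[str, str]] = set()

        def branching(node: str) -> bool:
            return len(out_edges.get(node, [])) != 1 or in_deg[node] != 1

        for u in sorted(out_edges):
            if not branching(u):
                continue
            for v in out_edges[u]:
                if (u, v) in visited:
                    continue
                visited.add((u, v))
                path = u + v[-1]
                node = v
                while not branching(node):
                    nxt = out_edges[node][0]
                    if (node, nxt) in visited:
                        break
                    visited.add((node, nxt))
                    path += nxt[-1]
                    node = nxt
                contigs.add(path)
    contigs = {c for c in contigs if len(c) >= min_read}
    return sorted(contigs, key=lambda c: (-len(c), c))


def contig_validate(contig: str, candidate: CandidateFusion) -> bool:
    """A contig validates the breakpoint when it aligns across the junction
    with at least 3 bases on each side and at most one mismatched base."""
    j = candidate.junction_index
    for aln in local_align(contig, candidate.chimera, min_seed=11):
        if (
            aln.target_start <= j - CONTIG_JUNCTION_OVERLAP
            and aln.target_end >= j + CONTIG_JUNCTION_OVERLAP
            and aln.mismatches <= CONTIG_MAX_MISMATCH
        ):
            return True
    return False


def gapfill_validate(
    candidate: CandidateFusion,
    reads: Sequence[str],
    fraction: float = GAPFILL_KMER_FRACTION,
    anchor: int = 12,
    max_fill: int = 15,
) -> dict:
    """Validate a candidate by closing an artificial 5-base gap at the junction.

    The chimera bases [junction-2, junction+3) are removed; read k-mers (85% of
    read length) anchored on the gap edges vote base-by-base, a base being
    accepted when covered by at least two k-mers. The candidate validates when
    the gap closes with >=3 bases rebuilt from each edge and the reconstructed
    length differs from the original chimera by at most 1 base.
    """
    j = candidate.junction_index
    chimera = candidate.chimera
    left = chimera[: max(0, j - GAP_LEFT_OFFSET)]
    right = chimera[j - GAP_LEFT_OFFSET + GAP_LEN :]
    result = {
        "validated": False,
        "left_overlap": 0,
        "right_overlap": 0,
        "reconstructed_length_delta": None,
        "reason": None,
    }
    if not reads:
        result["reason"] = "no coverage"
        candidate.validation["gap_filled"] = False
        return result
    kmers: list[str] = []
    for r in reads:
        if len(r) >= 3:
            kmers.extend(kmerize(r, fraction))
    a_left, a_right = left[-anchor:], right[:anchor]
    left_votes: dict[int, Counter] = {}
    right_votes: dict[int, Counter] = {}
    for km in kmers:
        start = 0
        while (q := km.find(a_left, start)) >= 0:
            proj = km[q + anchor :]
            for i, base in enumerate(proj[:max_fill]):
                left_votes.setdefault(i, Counter())[base] += 1
            start = q + 1
        start = 0
        while (q := km.find(a_right, start)) >= 0:
            proj = km[:q]
            for i in range(1, min(len(proj), max_fill) + 1):
                right_votes.setdefault(i, Counter())[proj[-i]] += 1
            start = q + 1

    def consensus(votes: dict[int, Counter]) -> str:
        built = []
        for i in range(max_fill):
            c = votes.get(i if votes is left_votes else i + 1)
            if not c:
                break
            base, count = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if count < GAPFILL_MIN_KMERS:
                break
            built.append(base)
        return "".join(built)

    left_fill = consensus(left_votes)
    right_fill = consensus(right_votes)[::-1]  # was built junction-outward
    l, r = len(left_fill), len(right_fill)
    result["left_overlap"], result["right_overlap"] = l, r
    if l < GAPFILL_MIN_EDGE or r < GAPFILL_MIN_EDGE:
        result["reason"] = "gap not closed"
        candidate.validation["gap_filled"] = False
        return result
    w_left = a_left + left_fill
    w_right = right_fill + a_right
    for o in range(min(len(w_left), len(w_right)), 0, -1):
        if w_left[-o:] == w_right[:o]:
            gap_len = l + r - o
            if gap_len < 0:
                continue
            delta = gap_len - GAP_LEN
            result["reconstructed_length_delta"] = delta
            if abs(delta) <= GAPFILL_MAX_DELTA:
                result["validated"] = True
            else:
                result["reason"] = "length mismatch"
            break
    else:
        result["reason"] = "gap not closed"
    candidate.validation["gap_filled"] = result["validated"]
    return result


def genomic_artifact_check(
    candidate: CandidateFusion,
    genome: Mapping[str, str],
    dust_threshold: float = DUST_THRESHOLD,
) -> dict:
    """Genomic realignment artifact screen.

    misalignment: the chimera matches another genomic locus (outside its own
    source flanks) over more than 50 bases at 100% identity, either strand.
    low_complexity: some 64-base chimera window has DUST score above threshold.
    breakpoint_artifact: a genomic alignment at >99% identity spans the
    junction with more than 10 bases of overhang on either side, meaning the
    'fusion' sequence is contiguous in the genome.
    """
    chimera = candidate.chimera
    j = candidate.junction_index
    flags = {"misalignment": False, "low_complexity": False, "breakpoint_artifact": False}
    source = candidate.source_spans
    for contig, seq in genome.items():
        for query, orient in ((chimera, "+"), (revcomp(chimera), "-")):
            for run in exact_match_runs(query, seq, MISALIGN_MIN_RUN + 1):
                hit = GenomicInterval(contig, run.target_start, run.target_end)
                if not any(hit.chrom == s.chrom and hit.overlap_length(s) > 0 for s in source):
                    flags["misalignment"] = True
        for aln in local_align(chimera, seq, min_seed=16):
            if aln.identity <= BREAKPOINT_MIN_IDENTITY:
                continue
            # overhang of the flank alignment past the junction: the 5'-side
            # alignment should end at the junction and the 3'-side one start
            # there; >10 bases of high-identity read-through means the
            # "fusion" is contiguous in the genome
            mid = (aln.query_start + aln.query_end) / 2
            overhang = (aln.query_end - j) if mid < j else (j - aln.query_start)
            if overhang > BREAKPOINT_MAX_OFFSET:
                flags["breakpoint_artifact"] = True
    for i in range(0, max(1, len(chimera) - 63)):
        if dust_score(chimera[i : i + 64]) > dust_threshold:
            flags["low_complexity"] = True
            break
    candidate.validation.update(flags)
    return flags


def _splice_dinucleotides(genome: Mapping[str, str], bp5: Breakpoint, bp3: Breakpoint):
    c5, c3 = genome[bp5.chrom], genome[bp3.chrom]
    if bp5.strand == "+":
        donor = c5[bp5.pos : bp5.pos + 2]
    else:
        donor = revcomp(c5[bp5.pos - 2 : bp5.pos])
    if bp3.strand == "+":
        acceptor = c3[bp3.pos - 2 : bp3.pos]
    else:
        acceptor = revcomp(c3[bp3.pos : bp3.pos + 2])
    return donor.upper(), acceptor.upper()


def splice_class_of(donor: str, acceptor: str) -> str:
    if (donor, acceptor) == ("GT", "AG"):
        return "major"
    if (donor, acceptor) in (("GC", "AG"), ("AT", "AC")):
        return "minor"
    return "noncanonical"


def annotate_and_score(
    candidate: CandidateFusion,
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    weights: Mapping[str, float] = DEFAULT_WEIGHTS,
) -> CandidateFusion:
    """Feature annotation and ordinal scoring.

    Splice class comes from the intron-side dinucleotides adjacent to each
    breakpoint (GT-AG major; GC-AG / AT-AC minor); frame is phase arithmetic:
    in frame when the 5' segment's cumulative coding bases and the 3'
    breakpoint's coding offset agree modulo 3. The score is an additive,
    configurable ordinal: +2 both breakpoints in CDS, +2 both at splice
    junctions, +2 major / +1 minor splice pattern, +2 in frame, -3 per
    genomic artifact flag.
    """
    by_name = {g.name: g for g in genes}
    g5 = by_name.get(candidate.bp5.gene) if candidate.bp5.gene else None
    g3 = by_name.get(candidate.bp3.gene) if candidate.bp3.gene else None
    f = candidate.features
    f["cds5"] = bool(g5 and g5.coding and g5.start < candidate.bp5.pos <= g5.end) if candidate.bp5.strand == "+" else bool(g5 and g5.coding and g5.start <= candidate.bp5.pos < g5.end)
    f["cds3"] = bool(g3 and g3.coding and g3.start <= candidate.bp3.pos < g3.end) if candidate.bp3.strand == "+" else bool(g3 and g3.coding and g3.start < candidate.bp3.pos <= g3.end)
    if g5:
        edges5 = {e.end for e in g5.exons} if candidate.bp5.strand == "+" else {e.start for e in g5.exons}
        f["at_splice_junction5"] = candidate.bp5.pos in edges5
    else:
        f["at_splice_junction5"] = False
    if g3:
        edges3 = {e.start for e in g3.exons} if candidate.bp3.strand == "+" else {e.end for e in g3.exons}
        f["at_splice_junction3"] = candidate.bp3.pos in edges3
    else:
        f["at_splice_junction3"] = False
    donor, acceptor = _splice_dinucleotides(genome, candidate.bp5, candidate.bp3)
    f["splice_class"] = splice_class_of(donor, acceptor)
    if g5 and g3 and g5.coding and g3.coding:
        cb5 = g5.coding_bases_before(candidate.bp5.pos)
        cb3 = g3.coding_bases_before(candidate.bp3.pos)
        f["in_frame"] = (cb5 % 3) == (cb3 % 3)
    else:
        f["in_frame"] = None
    score = 0.0
    if f["cds5"] and f["cds3"]:
        score += weights["cds_both"]
    if f["at_splice_junction5"] and f["at_splice_junction3"]:
        score += weights["splice_junction_both"]
    if f["splice_class"] == "major":
        score += weights["splice_major"]
    elif f["splice_class"] == "minor":
        score += weights["splice_minor"]
    if f["in_frame"]:
        score += weights["in_frame"]
    for flag in ("misalignment", "breakpoint_artifact", "low_complexity"):
        if candidate.validation.get(flag):
            score += weights["artifact_flag"]
    candidate.score = score
    return candidate


def validate_fusions(
    candidates: Sequence[CandidateFusion],
    genes: Sequence[GeneModel],
    genome: Mapping[str, str],
    tumor_reads: Mapping[str, Sequence[str]],
    normal_read_sets: Mapping[str, Sequence[str]],
) -> list[CandidateFusion]:
    """Run the full validation cascade; each candidate ends with a boolean
    ``validation['validated']`` requiring junction confirmation by both contig
    assembly and gap filling, no normal-panel removal and no misalignment or
    breakpoint artifact."""
    retained, _ = prefilter_candidates(candidates, genes)
    for cand in candidates:
        if cand.validation.get("prefilter_removed"):
            cand.validation["validated"] = False
            continue
        npf = normal_panel_filter(cand, normal_read_sets)
        if npf["removed"]:
            cand.validation["validated"] = False
            continue
        reads = list(tumor_reads.get(cand.candidate_id, ()))
        contig_ok = False
        if reads:
            try:
                contigs = assemble_contigs(reads)
            except ValueError:
                contigs = []
            contig_ok = any(contig_validate(c, cand) for c in contigs)
        cand.validation["contig_validated"] = contig_ok
        gap = gapfill_validate(cand, reads)
        flags = genomic_artifact_check(cand, genome)
        annotate_and_score(cand, genes, genome)
        cand.validation["validated"] = (
            contig_ok
            and gap["validated"]
            and not flags["misalignment"]
            and not flags["breakpoint_artifact"]
        )
    return list(candidates)
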