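"""Minimal gene models and GTF I/O for the synthetic references the pipeline
consumes. Coordinates are 0-based half-open internally; GTF lines are written
and read 1-based inclusive."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomicInterval


@dataclass
class GeneModel:
    name: str
    chrom: str
    strand: str
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)  # genomic order

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def coding(self) -> bool:
        return self.biotype == "protein_coding"

    def exon_boundaries(self) -> set[int]:
        """Genomic positions that are exon edges (half-open: starts and ends)."""
        out = set()
        for ex in self.exons:
            out.add(ex.start)
            out.add(ex.end)
        return out

    def coding_bases_before(self, pos: int) -> int:
        """Cumulative coding bases 5' of ``pos`` in transcription order.

        ``pos`` follows the breakpoint convention: on '+' it is the half-open
        end of the 5' segment, on '-' the (inclusive-start) genomic position
        where the retained segment begins.
        """
        total = 0
        if self.strand == "+":
            for ex in self.exons:
                total += max(0, min(pos, ex.end) - ex.start)
        else:
            for ex in self.exons:
                total += max(0, ex.end - max(pos, ex.start))
        return total


def nearest_downstream_neighbor(gene: GeneModel, genes: list[GeneModel]) -> GeneModel | None:
    """Closest same-chromosome gene starting after ``gene`` ends (genomic order)."""
    candidates = [g for g in genes if g.chrom == gene.chrom and g.start >= gene.end and g is not gene]
    return min(candidates, key=lambda g: g.start) if candidates else None


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.name}"; gene_name "{g.name}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tsomapipe\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsomapipe\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def read_gtf(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";")
                if kv.strip()
            )
            name = attrs["gene_id"]
            g = genes.setdefault(
                name, GeneModel(name, f[0], f[6], attrs.get("gene_biotype", "protein_coding"))
            )
            g.exons.append(GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]))
    for g in genes.values():
        g.exons.sort(key=lambda e: e.start)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start))
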