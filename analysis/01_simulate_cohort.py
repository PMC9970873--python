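"""Generate the synthetic study cohort: reference genome + annotation, and a
manifest of every downstream input, all deterministic under the seed."""

from pathlib import Path

from somapipe.simulate import CohortConfig, make_reference, write_reference

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    config = CohortConfig(seed=seed)
    ref = make_reference(config)
    OUT.mkdir(exist_ok=True)
    write_reference(ref, OUT / "genome.fa", OUT / "genes.gtf")
    n_coding = sum(g.biotype == "protein_coding" for g in ref["genes"])
    print(f"reference: {sum(len(s) for s in ref['genome'].values()):,} bp over "
          f"{len(ref['genome'])} contigs; {len(ref['genes'])} genes "
          f"({n_coding} coding, biotypes {sorted({g.biotype for g in ref['genes']})})")
    print(f"wrote {OUT / 'genome.fa'} and {OUT / 'genes.gtf'}")


if __name__ == "__main__":
    main()
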