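"""Compile the demo sample and fetch a region at base resolution.

Generates the bundled synthetic yeast-like sample (FASTA + SAM + GTF),
compiles it into a track store, then queries a 101 bp window around the
sharp coverage peak on chrI.
"""

import tempfile

import basecov as bc

with tempfile.TemporaryDirectory() as work:
    fx = bc.demo_sample(f"{work}/fixture")
    manifest, stats = bc.compile_sample(
        "demo", fx.sam_path, fx.fasta_path, fx.gtf_path, f"{work}/store"
    )
    print(f"compiled {stats.processed} reads into {len(manifest.chromosomes)} chromosomes")

    with bc.open_store(f"{work}/store/demo") as store:
        result = bc.query_region(store, "chrI", 10000, 10100)
        print(f"level used: {result.level_used} (base resolution)")
        print("pos\ttotal\t+\t-\t%mis")
        for p in list(result.records())[38:44]:
            print(
                f"{p.span_start}\t{p.total}\t{p.pos_strand}"
                f"\t{p.neg_strand}\t{p.mis_rate:.1f}"
            )

# Each row is one genomic base: its total read depth, the split between
# forward- and reverse-strand reads, and the percentage of overlapping
# reads that mismatch the reference there (useful for spotting SNPs).
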