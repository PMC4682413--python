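"""Gene-name resolution, auto-completion and bedGraph export.

Shows the stage-2 conveniences: type-ahead completion over every gene
name/alias in the compiled index, querying by gene instead of coordinates,
and exporting the result as a bedGraph track.
"""

import tempfile

import basecov as bc

with tempfile.TemporaryDirectory() as work:
    fx = bc.demo_sample(f"{work}/fixture")
    bc.compile_sample("demo", fx.sam_path, fx.fasta_path, fx.gtf_path, f"{work}/store")

    with bc.open_store(f"{work}/store/demo") as store:
        print("completions for 'Snord':", bc.complete_gene("Snord", store.gene_index))

        chrom, start, end = bc.resolve_region(store, gene="snord11")
        print(f"Snord11 resolves to {chrom}:{start}-{end} (case-insensitive)")

        result = bc.query_region(store, chrom, start, end, max_points=10)
        print(f"{result.n_points} points over the gene (budget 10):")
        for line in bc.export_region(result, "bedgraph", track="total"):
            print(line)

# The bedGraph rows are 0-based half-open; each value is the *maximum*
# total depth over its span, so peaks are never averaged away when zoomed out.
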