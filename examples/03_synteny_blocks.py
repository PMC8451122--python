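"""Call synteny blocks between two annotated genomes from a homology table.

Plants a 6-gene syntenic run (with two internal gaps) between two 25-gene
genomes, then applies the recognition rule: at least five consecutive
syntenic genes separated by at most four non-syntenic genes.
"""

import phageadapt as pa
from phageadapt import simulate as sim

genes_a, genes_b, hits, truth = sim.make_synteny_pair(
    n_a=25, n_b=25, planted_blocks=[(4, 6, "0,2,0,1,0")], seed=11
)
pairing = pa.pair_homologs(hits, genes_a, genes_b, min_aln_bp=10, max_evalue=1e-5)
blocks = pa.call_blocks(genes_a, genes_b, pairing, min_run=5, max_gap=4)

print(f"genomes: {len(genes_a)} vs {len(genes_b)} genes, {len(hits)} hits")
print(f"planted block: {truth['blocks'][0]}")
for b in blocks:
    print(
        f"called block: A genes {b.a_range[0]}-{b.a_range[1]}, "
        f"B genes {b.b_range[0]}-{b.b_range[1]}, "
        f"{b.n_syntenic} syntenic, max internal gap {b.max_internal_gap}"
    )

# A block's ranges span the first to last syntenic gene in each genome's
# gene order; interspersed non-syntenic genes (here up to 2 in a row) do
# not break the chain as long as each gap stays at 4 or below.
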