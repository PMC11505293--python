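"""Over-representation analysis of the curated interactome genes.

Tests the packaged 140-gene interactome list against the packaged 16
KEGG-style pathway sets, using a genome-scale reference universe, then
summarizes the significant pathways with a weighted set cover.
"""

import pcosnet as p

genes = p.load_curated_genes()
pathways = p.load_pathways()

# pad the annotation universe to a genome-like reference size
universe = set(pathways.member_union()) | {f"REF{i:05d}" for i in range(8000)}
results = p.hypergeom_ora(set(genes.symbols()), pathways, universe=universe)
significant = p.significant_results(results, fdr_threshold=0.05)
cover = p.weighted_set_cover(significant, max_sets=5)
table = p.enrichment_report(results, cover)

print(f"{len(results)} pathway sets tested, {len(significant)} significant at FDR < 0.05")
print(table[["name", "k", "K", "enrichment_ratio", "q_value", "selected"]]
      .head(8).to_string(index=False))
print(f"set cover picked {len(cover.selected)} representative sets "
      f"covering {100 * cover.coverage_fraction:.0f}% of the annotated study genes")
# k is the observed overlap, K the pathway size; enrichment_ratio is
# observed/expected overlap, so values far above 1 mean the pathway is
# strongly over-represented in the interactome genes.
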