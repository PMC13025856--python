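"""Expression filtering, TMM normalization and gene-set over-representation.

Genes expressed at CPM >= 1 form the background universe; genes whose
nearest TSS sits within 3 kb of a consensus region are the selected set;
each gene set is tested with a hypergeometric upper tail + BH correction.
"""

from rloopscape import (
    Annotator,
    SimulationConfig,
    associate_genes,
    call_common_regions,
    expression_summary,
    filter_expressed,
    ora,
    tmm_factors,
)
from rloopscape.synthetic_data import simulate_all

sim = simulate_all(SimulationConfig(seed=42))
regions = call_common_regions(sim.peaks.collection, genome=sim.genome.genome)
annotator = Annotator(sim.expression.genes)

expressed = filter_expressed(sim.expression.counts)
counts = sim.expression.counts.loc[expressed]
factors = tmm_factors(counts)
associated = associate_genes(regions, annotator) & set(expressed)

summary = expression_summary(counts, factors, associated)
print(f"expressed genes: {len(expressed)}; associated: {len(associated)}")
print("TMM factors:", factors.round(3).to_dict())
print(
    "mean CV associated vs others: "
    f"{summary[summary['associated']]['cv'].mean():.3f} vs "
    f"{summary[~summary['associated']]['cv'].mean():.3f}"
)

result = ora(sorted(associated), sim.expression.gene_sets, expressed)
print(result[["term", "overlap", "fold_enrichment", "p", "q", "significant"]]
      .head(3).round(4).to_string(index=False))
# The planted set (drawn preferentially from locus-adjacent genes) should
# rank first with a tiny p; the random sets should not pass p<0.01 & q<0.05.
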