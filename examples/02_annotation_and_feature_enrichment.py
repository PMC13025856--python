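"""Annotate consensus regions against gene models.

Each region gets one category by its midpoint (promoter > UTR > exon >
TTS > intron > intergenic) and the observed category mix is compared
with the genomic background as a log2 ratio.
"""

from rloopscape import (
    Annotator,
    SimulationConfig,
    call_common_regions,
    feature_enrichment,
)
from rloopscape.genome_annotation import annotations_to_frame
from rloopscape.synthetic_data import simulate_all

sim = simulate_all(SimulationConfig(seed=42))
regions = call_common_regions(sim.peaks.collection, genome=sim.genome.genome)

annotator = Annotator(sim.expression.genes)
annotations = annotator.annotate_all(regions.regions)

print(annotations_to_frame(annotations)["category"].value_counts().to_string())
print()
df = feature_enrichment(annotations, sim.genome.genome, annotator)
print(df.round(3).to_string(index=False))
# log2_enrichment > 0 means the category holds more regions than its share
# of the genome predicts; associated genes sit on loci, so promoters score high.
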