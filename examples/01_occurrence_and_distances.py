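"""Build an occurrence matrix, filter genomes and compare genome contents.

Generates a genome metadata table with flagged removals, collapses raw
per-genome superfamily assignments into a binary occurrence matrix and
computes the two binary dissimilarities used for whole-genome trees.
"""

from foldspace import (
    bray_curtis_distance,
    build_matrix,
    contingency,
    distance_matrix,
    filter_genomes,
    jaccard_distance,
)
from foldspace.synth import synthetic_genome_table

# a metadata table shaped like the full study: 1,496 genomes with 407
# pathogens, 31 candidatus taxa and 44 manual removals flagged
records = synthetic_genome_table(seed=1)
kept = filter_genomes(records)
print(f"genomes kept after filtering: {len(kept)} of {len(records)}")

# raw (genome, superfamily) assignments collapse to presence/absence
pairs = [
    ("g1", "sf_a"), ("g1", "sf_a"), ("g1", "sf_b"),
    ("g2", "sf_a"), ("g3", "sf_b"), ("g3", "sf_c"),
]
m = build_matrix(pairs, ["g1", "g2", "g3"])
print("\noccurrence matrix (rows = superfamilies):")
print(m.df)

cc = contingency(m, "g1", "g3")
print(f"\ng1 vs g3 shared/unique counts: a={cc.a} b={cc.b} c={cc.c}")
print(f"Jaccard distance:     {jaccard_distance(cc):.3f}")
print(f"Bray-Curtis distance: {bray_curtis_distance(cc):.3f}")
# both are 0 for identical repertoires and 1 for disjoint ones;
# Bray-Curtis down-weights shared content less severely

D = distance_matrix(m, metric="jaccard")
print("\nall-pairs Jaccard distances:")
print(D.df.round(3))
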