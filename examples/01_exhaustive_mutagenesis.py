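"""Enumerate every coding single-base substitution of a small annotated genome.

Builds a synthetic circular mtDNA-like genome (plus- and minus-strand CDSs,
an overlapping gene pair, one incomplete terminal codon), then simulates all
3 alternatives at every coding position and reports the protein consequence
of each.
"""

from mitobias import simulate
from mitobias.mutagenesis import (
    collapse_by_position,
    enumerate_substitutions,
    parse_annotated_genome,
)

genome = parse_annotated_genome(simulate.generate_toy_genome(seed=7))
print(f"genome: {len(genome)} bp, {len(genome.features)} CDS features")
for f in genome.features:
    strand = "+" if f.strand == 1 else "-"
    print(f"  {f.gene:<5} {f.start}..{f.end} ({strand}) "
          f"{f.n_complete_codons} codons")

subs, log = enumerate_substitutions(genome)
print(f"\n{log['n_records']} substitution records "
      f"({log['skipped_partial_codons']} partial terminal codon skipped)")
print(f"synonymous: {subs['is_synonymous'].sum()}  "
      f"non-synonymous: {(~subs['is_synonymous']).sum()}")

collapsed = collapse_by_position(subs)
overlap = collapsed[collapsed["n_genes"] > 1]
print(f"\n{len(collapsed)} distinct genomic changes; "
      f"{len(overlap)} fall in the ATP8/ATP6 overlap and are classified "
      "synonymous only if synonymous in both frames")
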