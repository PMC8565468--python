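"""Annotated-genome parsing and exhaustive single-nucleotide mutagenesis.

Parses an annotated circular mtDNA GenBank record and enumerates every
possible single-base substitution within its protein-coding sequences,
reporting the protein consequence of each.  Coordinates are 1-based and
inclusive on the reference (heavy) strand throughout, matching both GenBank
and the ``chrM:<pos>`` convention of population variant tables.

Overlapping CDSs yield one record per gene; a genome-wide collapsed view
(synonymous only if synonymous in *every* overlapping gene) is available via
:func:`collapse_by_position`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from . import code

logger = logging.getLogger(__name__)

#: CDS names required of a complete mammalian mtDNA record.
REQUIRED_MT_GENES = frozenset(
    {
        "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
        "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
    }
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SUBSTITUTION_COLUMNS = [
    "position", "ref_base", "alt_base", "gene", "codon_index",
    "codon_position", "ref_codon", "alt_codon", "ref_aa", "alt_aa",
    "is_synonymous", "sub_type",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted as an annotated genome."""


class MissingGenesError(GenomeParseError):
    """Record lacks required CDS annotations (carries the missing names)."""

    def __init__(self, accession: str, missing: set[str]):
        self.accession = accession
        self.missing = frozenset(missing)
        super().__init__(
            f"record {accession} is missing required CDS annotations: "
            f"{', '.join(sorted(missing))}"
        )


@dataclass(frozen=True)
class CdsFeature:
    """A CDS on the annotated genome.

    ``genome_positions`` lists the 1-based reference coordinates of the coding
    sequence in coding order (reversed relative to the genome for minus-strand
    genes, and wrapping through the origin for circular features).
    """

    gene: str
    start: int  # 1-based inclusive, reference strand
    end: int
    strand: int  # +1 or -1
    genome_positions: tuple[int, ...]
    coding_sequence: str

    @property
    def n_complete_codons(self) -> int:
        return len(self.coding_sequence) // 3

    @property
    def incomplete_codon_bases(self) -> int:
        return len(self.coding_sequence) % 3


@dataclass
class AnnotatedGenome:
    accession: str
    sequence: str  # reference (heavy) strand, positions 1..len
    features: list[CdsFeature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Reference-strand base at a 1-based coordinate."""
        return self.sequence[position - 1]

    def feature(self, gene: str) -> CdsFeature:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(gene)


def normalize_gene_name(name: str) -> str:
    """Uppercase and map common mitochondrial gene-name synonyms."""
    name = name.strip().upper()
    synonyms = {
        "COI": "COX1", "COII": "COX2", "COIII": "COX3",
        "CO1": "COX1", "CO2": "COX2", "CO3": "COX3",
        "MT-CYB": "CYTB", "CYB": "CYTB", "COB": "CYTB",
    }
    if name.startswith("MT-"):
        name = name[3:]
    return synonyms.get(name, name)


def _feature_gene_name(feat) -> str | None:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return normalize_gene_name(feat.qualifiers[key][0])
    return None


def parse_annotated_genome(
    genbank_text: str,
    required_genes: frozenset[str] | set[str] = frozenset(),
) -> AnnotatedGenome:
    """Parse one GenBank flat-file record into an :class:`AnnotatedGenome`.

    CDS features on the complementary strand and circular wrap-around
    features (compound locations through the origin) are supported.  When
    ``required_genes`` is non-empty and any name is absent the record is
    rejected with :class:`MissingGenesError` listing the missing genes.
    """
    try:
        record = SeqIO.read(io.StringIO(genbank_text), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on malformed text
        raise GenomeParseError(f"could not parse GenBank record: {exc}") from exc

    sequence = str(record.seq).upper()
    features: list[CdsFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type != "CDS":
            continue
        gene = _feature_gene_name(feat)
        if gene is None:
            logger.warning("CDS without a gene/product qualifier skipped")
            continue
        if gene in seen:
            raise GenomeParseError(
                f"duplicate CDS annotation for gene {gene} in {record.id}"
            )
        seen.add(gene)
        # 0-based genome indices of the coding sequence, in coding order
        idx = [int(i) for i in feat.location]  # Biopython yields coding order
        positions = tuple(i + 1 for i in idx)
        coding = "".join(sequence[i] for i in idx)
        if feat.location.strand == -1:
            coding = coding.translate(_COMPLEMENT)
        features.append(
            CdsFeature(
                gene=gene,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand=feat.location.strand or 1,
                genome_positions=positions,
                coding_sequence=coding,
            )
        )

    if required_genes:
        missing = set(required_genes) - seen
        if missing:
            raise MissingGenesError(record.id, missing)
    return AnnotatedGenome(accession=record.id, sequence=sequence, features=features)


def enumerate_substitutions(
    genome: AnnotatedGenome,
) -> tuple[pd.DataFrame, dict]:
    """Enumerate every single-base substitution in every CDS of ``genome``.

    Returns ``(table, run_log)``: one row per (gene, coding position,
    alternative base), so positions shared by overlapping CDSs appear once
    per gene.  Incomplete terminal codons and codons containing non-ACGT
    characters are skipped and counted in ``run_log``.

    Rows are ordered by (position, alt_base, gene) for reproducible diffs.
    """
    rows: list[tuple] = []
    skipped_partial = 0
    skipped_ambiguous = 0
    for feat in genome.features:
        if feat.incomplete_codon_bases:
            skipped_partial += 1
            logger.info(
                "gene %s: %d-base incomplete terminal codon skipped",
                feat.gene, feat.incomplete_codon_bases,
            )
        for ci in range(feat.n_complete_codons):
            ref_codon = feat.coding_sequence[3 * ci : 3 * ci + 3]
            if any(b not in "ACGT" for b in ref_codon):
                skipped_ambiguous += 1
                logger.warning(
                    "gene %s codon %d contains non-ACGT base; skipped",
                    feat.gene, ci + 1,
                )
                continue
            ref_aa = code.translate(ref_codon)
            for cp in range(3):
                coding_ref = ref_codon[cp]
                genome_pos = feat.genome_positions[3 * ci + cp]
                for coding_alt in "ACGT":
                    if coding_alt == coding_ref:
                        continue
                    alt_codon = ref_codon[:cp] + coding_alt + ref_codon[cp + 1 :]
                    alt_aa = code.translate(alt_codon)
                    if feat.strand == -1:
                        ref_base = coding_ref.translate(_COMPLEMENT)
                        alt_base = coding_alt.translate(_COMPLEMENT)
                    else:
                        ref_base, alt_base = coding_ref, coding_alt
                    rows.append(
                        (
                            genome_pos, ref_base, alt_base, feat.gene,
                            ci + 1, cp + 1, ref_codon, alt_codon,
                            ref_aa, alt_aa, ref_aa == alt_aa,
                            code.substitution_type(ref_base, alt_base),
                        )
                    )
    table = pd.DataFrame(rows, columns=SUBSTITUTION_COLUMNS)
    table = table.sort_values(
        ["position", "alt_base", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    run_log = {
        "n_records": len(table),
        "skipped_partial_codons": skipped_partial,
        "skipped_ambiguous_codons": skipped_ambiguous,
    }
    return table, run_log


def collapse_by_position(subs: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-gene substitution records to one row per genomic change.

    A substitution is classified synonymous only if it is synonymous in every
    CDS that contains it; this conservative rule keeps a non-synonymous
    consequence in an overlapping gene from being hidden.
    """
    grouped = subs.groupby(["position", "ref_base", "alt_base"], sort=True)
    out = grouped.agg(
        is_synonymous=("is_synonymous", "all"),
        sub_type=("sub_type", "first"),
        n_genes=("gene", "nunique"),
        genes=("gene", lambda g: ",".join(sorted(set(g)))),
    ).reset_index()
    return out


def write_substitutions_tsv(subs: pd.DataFrame, path) -> None:
    subs.to_csv(path, sep="\t", index=False)


def read_substitutions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"ref_base": str, "alt_base": str, "gene": str}
    )
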