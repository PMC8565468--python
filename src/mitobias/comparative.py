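"""Cross-species P3 analysis: alignments, base frequencies, I-P3 sites.

Works on per-gene codon alignments (FASTA, coding strand, gap ``-``) that
are first *ungapped on the reference*: every column where the reference row
carries a gap is deleted, so downstream coordinates are reference codon
indices.  An I-P3 is an alignment codon site whose first and second codon
positions are identical (and gap-free) in every taxon and whose encoded
amino acid / tRNA family is therefore constant; its observed third-position
base set across taxa measures how much of the family's synonymous base set
is actually used over the phylogeny.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import code
from .mutagenesis import (
    REQUIRED_MT_GENES,
    AnnotatedGenome,
    GenomeParseError,
    MissingGenesError,
    parse_annotated_genome,
)

logger = logging.getLogger(__name__)

IP3_COLUMNS = [
    "gene", "codon_index", "amino_acid", "trna_family", "degeneracy_class",
    "observed_p3_bases", "fully_degenerate",
]


@dataclass(frozen=True)
class CodonAlignment:
    """An aligned set of coding-strand sequences for one gene."""

    gene: str
    taxa: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows of unequal length in {self.gene}")
        if self.reference_id not in self.taxa:
            raise ValueError(
                f"reference {self.reference_id!r} absent from alignment {self.gene}"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]


def read_alignment_fasta(path, gene: str, reference_id: str) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return CodonAlignment(
        gene=gene,
        taxa=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
        reference_id=reference_id,
    )


def write_alignment_fasta(alignment: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(alignment.taxa, alignment.rows):
            fh.write(f">{taxon}\n{row}\n")


def ungap_on_reference(alignment: CodonAlignment) -> CodonAlignment:
    """Delete every alignment column where the reference row has a gap."""
    ref = alignment.row(alignment.reference_id)
    keep = [i for i, b in enumerate(ref) if b != "-"]
    rows = tuple("".join(r[i] for i in keep) for r in alignment.rows)
    return replace(alignment, rows=rows)


def load_and_filter_records(
    genbank_texts: dict[str, str],
    required_genes: frozenset[str] = REQUIRED_MT_GENES,
    drop_duplicates: bool = True,
) -> tuple[list[AnnotatedGenome], pd.DataFrame]:
    """Parse a set of GenBank records, keeping complete, unique ones.

    A record is retained only if it carries every required CDS; with
    ``drop_duplicates``, every member of any group of records sharing a
    byte-identical CDS nucleotide sequence is removed.  Returns the retained
    genomes and a per-record filter report.
    """
    parsed: dict[str, AnnotatedGenome] = {}
    report_rows = []
    for label, text in genbank_texts.items():
        try:
            g = parse_annotated_genome(text, required_genes=required_genes)
        except MissingGenesError as exc:
            report_rows.append((label, "missing_genes", ",".join(sorted(exc.missing))))
            continue
        except GenomeParseError as exc:
            report_rows.append((label, "parse_error", str(exc)))
            continue
        parsed[label] = g
        report_rows.append((label, "parsed", ""))

    dropped: set[str] = set()
    if drop_duplicates:
        by_cds: dict[str, list[str]] = {}
        for label, g in parsed.items():
            for f in g.features:
                by_cds.setdefault(f.coding_sequence, []).append(label)
        for labels in by_cds.values():
            if len(set(labels)) > 1:
                dropped.update(labels)

    genomes = [g for label, g in parsed.items() if label not in dropped]
    report = pd.DataFrame(report_rows, columns=["record", "status", "detail"])
    report.loc[report["record"].isin(dropped), "status"] = "duplicate_cds"
    if not genomes:
        raise GenomeParseError("no records retained after filtering")
    return genomes, report


def _codon_iter(alignment: CodonAlignment):
    if alignment.length % 3:
        raise ValueError(
            f"gene {alignment.gene}: ungapped alignment length {alignment.length} "
            "is not a multiple of 3 (frame violation)"
        )
    for ci in range(alignment.length // 3):
        yield ci + 1, [row[3 * ci : 3 * ci + 3] for row in alignment.rows]


def p3_base_frequencies(alignments: list[CodonAlignment]) -> pd.DataFrame:
    """Third-position base counts and frequencies per tRNA family.

    Counts run over all taxa x codon sites; codons containing gaps,
    ambiguity characters or stops are excluded from the denominators.
    Frequencies sum to 1 within each family.
    """
    counts: dict[tuple[str, str, str], int] = {}
    for aln in alignments:
        for _, codons in _codon_iter(aln):
            for codon in codons:
                if any(b not in "ACGT" for b in codon) or codon in code.STOP_CODONS:
                    continue
                aa, fam, cls = code.degeneracy_class(codon)
                key = (fam, cls, codon[2])
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {"trna_family": fam, "degeneracy_class": cls, "base": b, "count": n}
        for (fam, cls, b), n in sorted(counts.items())
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        df["frequency"] = []
        return df
    df["frequency"] = df["count"] / df.groupby("trna_family")["count"].transform("sum")
    df["amino_acid"] = [code.degeneracy_class(_any_codon(f))[0]
                        for f in df["trna_family"]]
    return df


def _any_codon(family: str) -> str:
    from .code import _FAMILIES, _third_bases  # internal table

    prefix = _FAMILIES[family][1]
    return prefix + _third_bases(family)[0]


_FAMILY_P3_SET = {
    code.FOURFOLD: frozenset("ACGT"),
    code.TWOFOLD_PURINE: frozenset("AG"),
    code.TWOFOLD_PYRIMIDINE: frozenset("CT"),
}


def identify_ip3_sites(
    alignments: list[CodonAlignment],
    exclude_leucine: bool = True,
    with_columns: bool = False,
) -> pd.DataFrame:
    """Find I-P3 sites: codon positions 1-2 identical and gap-free in all taxa.

    Requires the encoded amino acid (tRNA family) to be constant across taxa,
    which also resolves serine sites to S1 (TCN) or S2 (AGY); sites where any
    taxon carries a stop codon are rejected.  Leucine sites are excluded by
    default because first-position degeneracy mixes the L1/L2 families.
    Gaps or ambiguity characters at P3 exclude that taxon from the observed
    base set without disqualifying the site.

    With ``with_columns`` the result carries a ``column`` field (taxon ->
    P3 base or None) for direct TSS computation.
    """
    rows = []
    for aln in alignments:
        for ci, codons in _codon_iter(aln):
            prefixes = {c[:2] for c in codons}
            if len(prefixes) != 1 or any(ch in "-N" for ch in next(iter(prefixes))):
                continue
            fams = set()
            stop_seen = False
            for c in codons:
                if c in code.STOP_CODONS:
                    stop_seen = True
                    break
                if c[2] in "ACGT":
                    fams.add(code.degeneracy_class(c)[1])
            if stop_seen or len(fams) != 1 or not fams:
                continue
            fam = fams.pop()
            aa, _, cls = code.degeneracy_class(_any_codon(fam))
            if exclude_leucine and aa == "Leu":
                continue
            observed = frozenset(c[2] for c in codons if c[2] in "ACGT")
            row = {
                "gene": aln.gene,
                "codon_index": ci,
                "amino_acid": aa,
                "trna_family": fam,
                "degeneracy_class": cls,
                "observed_p3_bases": "".join(sorted(observed)),
                "fully_degenerate": observed == _FAMILY_P3_SET[cls],
            }
            if with_columns:
                row["column"] = {
                    t: (c[2] if c[2] in "ACGT" else None)
                    for t, c in zip(aln.taxa, codons)
                }
            rows.append(row)
    cols = IP3_COLUMNS + (["column"] if with_columns else [])
    return pd.DataFrame(rows, columns=cols)
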