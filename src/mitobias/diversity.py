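"""Third-codon-position (P3) degeneracy and population-diversity summaries.

Answers, for an annotated genome crossed with a population variant table:
which fraction of twofold- and fourfold-degenerate P3 sites has diverged at
all in the population, how many fourfold P3s carry all four bases, how SSNEs
distribute over amino acids and substitution types, and whether population
counts of synonymous changes differ between transitions and transversions.

Site-level summaries (divergence, all-four occupancy) use the amino acids
with a single degeneracy mode: leucine and serine, whose codons split
between twofold and fourfold tRNA families, are excluded by default.
SSNE-composition and count-distribution summaries instead use the eight
amino acids owning a fourfold codon box (Leu/Ser included via their
families).
"""

from __future__ import annotations

import pandas as pd

from . import code
from .mutagenesis import AnnotatedGenome
from .stats import KSResult, ks_two_sample
from .variants import MergedVariantTable

P3_SITE_COLUMNS = [
    "gene", "codon_index", "ref_codon", "amino_acid", "trna_family",
    "degeneracy_class", "p3_position",
]


def site_degeneracy_table(
    genome: AnnotatedGenome, exclude_leu_ser: bool = True
) -> pd.DataFrame:
    """One row per complete sense codon of every CDS with its P3 degeneracy.

    ``p3_position`` is the reference-strand genome coordinate of the codon's
    third position.  Stop codons are excluded always; Leu/Ser codons when
    ``exclude_leu_ser`` (dual-degeneracy amino acids).
    """
    rows = []
    for feat in genome.features:
        for ci in range(feat.n_complete_codons):
            codon = feat.coding_sequence[3 * ci : 3 * ci + 3]
            if any(b not in "ACGT" for b in codon) or codon in code.STOP_CODONS:
                continue
            aa, fam, cls = code.degeneracy_class(codon)
            if exclude_leu_ser and aa in ("Leu", "Ser"):
                continue
            rows.append(
                (feat.gene, ci + 1, codon, aa, fam, cls,
                 feat.genome_positions[3 * ci + 2])
            )
    return pd.DataFrame(rows, columns=P3_SITE_COLUMNS)


def _synonymous_p3_observed(merged: MergedVariantTable) -> pd.DataFrame:
    """Synonymous P3 substitution rows with the coding-strand alternative base."""
    t = merged.table
    syn3 = t[
        (t["codon_position"] == 3)
        & t["is_synonymous"]
        & (t["ref_aa"] != code.STOP)  # stop<->stop changes are not P3 synonymy
    ].copy()
    syn3["p3_alt_coding"] = syn3["alt_codon"].str[2]
    syn3["degeneracy_class"] = [
        code.degeneracy_class(c)[2] for c in syn3["ref_codon"]
    ]
    return syn3


def divergence_summary(
    sites: pd.DataFrame, merged: MergedVariantTable
) -> pd.DataFrame:
    """Per degeneracy class: fraction of P3 sites diverged in the population.

    A site is *diverged* when at least one synonymous P3 change from the
    reference has a nonzero carrier count; a fourfold site shows *all four*
    bases when all three synonymous alternatives are carried.  Returns one
    row per degeneracy class with numerators and denominators.
    """
    syn3 = _synonymous_p3_observed(merged)
    seen = syn3[syn3["total_count"] > 0]
    n_seen = (
        seen.groupby(["gene", "codon_index"])["p3_alt_coding"]
        .nunique()
        .rename("n_alt_bases_seen")
    )
    sites = sites.merge(
        n_seen, left_on=["gene", "codon_index"], right_index=True, how="left"
    )
    sites["n_alt_bases_seen"] = sites["n_alt_bases_seen"].fillna(0).astype(int)
    sites["diverged"] = sites["n_alt_bases_seen"] > 0
    sites["all_four"] = (sites["degeneracy_class"] == code.FOURFOLD) & (
        sites["n_alt_bases_seen"] == 3
    )
    out = []
    for cls, grp in sites.groupby("degeneracy_class", observed=True):
        n = len(grp)
        row = {
            "degeneracy_class": cls,
            "n_sites": n,
            "n_diverged": int(grp["diverged"].sum()),
            "fraction_diverged": grp["diverged"].mean() if n else float("nan"),
        }
        if cls == code.FOURFOLD:
            row["n_all_four"] = int(grp["all_four"].sum())
            row["fraction_all_four"] = grp["all_four"].mean() if n else float("nan")
        out.append(row)
    return pd.DataFrame(out)


def ssne_composition(merged: MergedVariantTable) -> pd.DataFrame:
    """SSNE counts per amino acid, split by transition/transversion.

    Restricted to synonymous P3 substitutions; the handful of synonymous
    first-position changes (Leu TTR<->CTR) is returned as an ``"(Leu-P1)"``
    row so totals reconcile with the global SSNE count.
    """
    t = merged.table
    ssne = t[t["is_ssne"] & (t["ref_aa"] != code.STOP)]
    p3 = ssne[ssne["codon_position"] == 3]
    counts = (
        p3.groupby(["ref_aa", "sub_type"], observed=True)
        .size()
        .unstack("sub_type", fill_value=0)
        .reindex(columns=["transition", "transversion"], fill_value=0)
        .reset_index()
        .rename(columns={"ref_aa": "amino_acid"})
    )
    n_p1 = int((ssne["codon_position"] != 3).sum())
    if n_p1:
        p1 = ssne[ssne["codon_position"] != 3]
        counts.loc[len(counts)] = [
            "(Leu-P1)",
            int((p1["sub_type"] == "transition").sum()),
            int((p1["sub_type"] == "transversion").sum()),
        ]
    counts["total"] = counts["transition"] + counts["transversion"]
    return counts


def fourfold_ssne_transversion_share(merged: MergedVariantTable) -> float:
    """Fraction of P3 SSNEs at fourfold-capable amino acids that are transversions."""
    t = merged.table
    ssne = t[
        t["is_ssne"]
        & (t["codon_position"] == 3)
        & t["ref_aa"].isin(code.FOURFOLD_CAPABLE_AMINO_ACIDS)
    ]
    if ssne.empty:
        return float("nan")
    return float((ssne["sub_type"] == "transversion").mean())


def variant_count_by_substitution_type(
    merged: MergedVariantTable, amino_acid: str | None = None
) -> tuple[pd.Series, pd.Series, KSResult | None]:
    """Population-count distributions of encountered synonymous P3 changes.

    Returns ``(transition_counts, transversion_counts, ks)`` for synonymous
    P3 substitutions with nonzero carriers at ``amino_acid`` (or pooled over
    all eight fourfold-capable amino acids when ``None``).  The KS result is
    ``None`` when either group has fewer than two observations.
    """
    syn3 = _synonymous_p3_observed(merged)
    seen = syn3[syn3["total_count"] > 0]
    if amino_acid is None:
        seen = seen[seen["ref_aa"].isin(code.FOURFOLD_CAPABLE_AMINO_ACIDS)]
    else:
        seen = seen[seen["ref_aa"] == amino_acid]
    ts = seen.loc[seen["sub_type"] == "transition", "total_count"]
    tv = seen.loc[seen["sub_type"] == "transversion", "total_count"]
    ks = ks_two_sample(ts, tv) if len(ts) >= 2 and len(tv) >= 2 else None
    return ts.reset_index(drop=True), tv.reset_index(drop=True), ks


def synonymous_vs_nonsynonymous_ks(
    merged: MergedVariantTable,
) -> tuple[pd.Series, pd.Series, KSResult]:
    """Compare population counts of synonymous vs non-synonymous substitutions.

    Uses the collapsed one-row-per-genomic-change view (synonymous only if
    synonymous in every overlapping gene).  Returns the two count series and
    the two-sample KS result.
    """
    from .mutagenesis import collapse_by_position

    t = merged.table
    collapsed = collapse_by_position(t)
    counts = t.groupby(["position", "ref_base", "alt_base"])["total_count"].first()
    collapsed = collapsed.merge(
        counts, left_on=["position", "ref_base", "alt_base"], right_index=True
    )
    syn = collapsed.loc[collapsed["is_synonymous"], "total_count"]
    nonsyn = collapsed.loc[~collapsed["is_synonymous"], "total_count"]
    return (
        syn.reset_index(drop=True),
        nonsyn.reset_index(drop=True),
        ks_two_sample(syn, nonsyn),
    )


def estimate_kappa_fourfold(merged: MergedVariantTable) -> float:
    """Estimate the transition/transversion rate ratio from fourfold P3 counts.

    At a fourfold-degenerate P3 the one transition and two transversions are
    equally synonymous, so selection cancels and the carrier totals estimate
    the mutational bias directly: kappa_hat = sum(ts counts) / (sum(tv
    counts) / 2).
    """
    syn3 = _synonymous_p3_observed(merged)
    four = syn3[syn3["degeneracy_class"] == code.FOURFOLD]
    ts_total = four.loc[four["sub_type"] == "transition", "total_count"].sum()
    tv_total = four.loc[four["sub_type"] == "transversion", "total_count"].sum()
    if tv_total == 0:
        return float("inf")
    return float(ts_total / (tv_total / 2.0))
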