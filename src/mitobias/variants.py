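"""Population variant-table parsing, merging, frequency classes and SSNEs.

Reads a HelixMTdb-dialect TSV (``locus`` column like ``chrM:8602``, a
bracketed ``alleles`` list, homoplasmic/heteroplasmic carrier counts), joins
it to the exhaustive substitution table on (position, ref, alt), assigns
population-frequency classes and flags SSNEs — synonymous substitutions
never encountered in the database.

The carrier count of a variant is ``counts_hom + counts_het`` (heteroplasmic
carriers count as carriers); ``hom_only=True`` switches the merge to
homoplasmic counts only.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: HelixMTdb release size used for the published frequency classes.
DEFAULT_N_SAMPLES = 195983

FREQUENCY_CLASSES = ["absent", "ultra_rare", "rare", "low_frequency", "common"]

_LOCUS_RE = re.compile(r"^(?:chr)?(?:MT?|chrM)?:?(\d+)$")


class VariantFormatError(ValueError):
    """Raised when the variant table lacks a required column or structure."""


@dataclass(frozen=True)
class VariantRow:
    position: int
    ref_base: str
    alt_base: str
    counts_hom: int
    counts_het: int

    @property
    def total_count(self) -> int:
        return self.counts_hom + self.counts_het


@dataclass
class MergedVariantTable:
    """Substitution table joined to population counts.

    ``table`` has one row per substitution record with ``counts_hom``,
    ``counts_het``, ``total_count``, ``frequency_class`` and ``is_ssne``
    columns appended.  ``residual`` lists parsed variants that matched no
    substitution (non-coding positions or reference-base mismatches).
    """

    table: pd.DataFrame
    n_samples: int
    residual: pd.DataFrame = field(default_factory=pd.DataFrame)

    def ssne(self) -> pd.DataFrame:
        return self.table[self.table["is_ssne"]]


def _parse_alleles(raw: str) -> list[str] | None:
    raw = raw.strip()
    try:
        alleles = json.loads(raw.replace("'", '"'))
    except json.JSONDecodeError:
        return None
    if not isinstance(alleles, list) or not all(isinstance(a, str) for a in alleles):
        return None
    return [a.upper() for a in alleles]


def parse_variant_db(
    tsv_text: str,
) -> tuple[list[VariantRow], dict[str, int]]:
    """Parse HelixMTdb-dialect TSV text into biallelic SNV rows.

    Returns ``(rows, skip_report)``.  Indels, multi-nucleotide and
    multi-allelic rows are skipped and tallied in the report; lines starting
    with ``#`` are treated as comments.
    """
    from io import StringIO

    df = pd.read_csv(StringIO(tsv_text), sep="\t", comment="#", dtype=str)
    required = {"locus", "alleles", "counts_hom", "counts_het"}
    missing = required - set(df.columns)
    if missing:
        raise VariantFormatError(
            f"variant table is missing required column(s): {', '.join(sorted(missing))}"
        )

    rows: list[VariantRow] = []
    skip = {"indel_or_mnv": 0, "multiallelic": 0, "unparsable": 0}
    for locus, alleles_raw, hom, het in zip(
        df["locus"], df["alleles"], df["counts_hom"], df["counts_het"]
    ):
        m = _LOCUS_RE.match(str(locus).strip())
        alleles = _parse_alleles(str(alleles_raw))
        if m is None or alleles is None:
            skip["unparsable"] += 1
            continue
        if len(alleles) != 2:
            skip["multiallelic"] += 1
            continue
        ref, alt = alleles
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            skip["indel_or_mnv"] += 1
            continue
        try:
            rows.append(
                VariantRow(int(m.group(1)), ref, alt, int(float(hom)), int(float(het)))
            )
        except (TypeError, ValueError):
            skip["unparsable"] += 1
    return rows, skip


def frequency_class(total_count: int, n_samples: int) -> str:
    """Classify a carrier count into the published frequency classes.

    absent: 0 carriers; ultra-rare: frequency < 0.01%; rare: 0.01% <= f < 1%;
    low-frequency: 1% <= f < 5%; common: f >= 5%.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if total_count < 0 or total_count > n_samples:
        raise ValueError(
            f"total_count {total_count} outside [0, n_samples={n_samples}]"
        )
    if total_count == 0:
        return "absent"
    f = total_count / n_samples
    if f < 0.0001:
        return "ultra_rare"
    if f < 0.01:
        return "rare"
    if f < 0.05:
        return "low_frequency"
    return "common"


def _classify_vector(total: np.ndarray, n_samples: int) -> pd.Categorical:
    f = total / n_samples
    labels = np.select(
        [total == 0, f < 0.0001, f < 0.01, f < 0.05],
        ["absent", "ultra_rare", "rare", "low_frequency"],
        default="common",
    )
    return pd.Categorical(labels, categories=FREQUENCY_CLASSES, ordered=True)


def merge_and_classify(
    subs: pd.DataFrame,
    variants: list[VariantRow],
    n_samples: int = DEFAULT_N_SAMPLES,
    hom_only: bool = False,
) -> MergedVariantTable:
    """Join population counts onto the substitution table.

    Join key is (position, ref_base, alt_base); substitutions with no match
    get zero counts.  Variants matching no substitution — non-coding
    positions, or rows whose stated reference base disagrees with the
    substitution table's reference — are excluded from the join and returned
    in the ``residual`` frame with a reason column.
    """
    vdf = pd.DataFrame(
        [(v.position, v.ref_base, v.alt_base, v.counts_hom, v.counts_het)
         for v in variants],
        columns=["position", "ref_base", "alt_base", "counts_hom", "counts_het"],
    )
    if not vdf.empty:
        dup = vdf.duplicated(["position", "ref_base", "alt_base"], keep=False)
        if dup.any():
            vdf = (
                vdf.groupby(["position", "ref_base", "alt_base"], as_index=False)
                .sum()
            )
    merged = subs.merge(vdf, on=["position", "ref_base", "alt_base"], how="left")
    for col in ("counts_hom", "counts_het"):
        merged[col] = (
            pd.to_numeric(merged[col], errors="coerce").fillna(0).astype(int)
        )
    count_col = merged["counts_hom"] if hom_only else (
        merged["counts_hom"] + merged["counts_het"]
    )
    merged["total_count"] = count_col.astype(int)
    merged["frequency_class"] = _classify_vector(
        merged["total_count"].to_numpy(), n_samples
    )
    merged["is_ssne"] = merged["is_synonymous"] & (merged["total_count"] == 0)

    if vdf.empty:
        residual = vdf.assign(reason=pd.Series(dtype=str))
    else:
        key = ["position", "ref_base", "alt_base"]
        matched = vdf.merge(subs[key].drop_duplicates(), on=key, how="left",
                            indicator=True)
        residual = matched[matched["_merge"] == "left_only"].drop(columns="_merge")
        # distinguish a wrong reference base from a genuinely non-coding position
        ref_by_pos = subs.drop_duplicates("position").set_index("position")["ref_base"]
        pos_known = residual["position"].isin(ref_by_pos.index)
        residual = residual.assign(
            reason=np.where(pos_known, "ref_mismatch", "non_coding")
        )
    return MergedVariantTable(table=merged, n_samples=n_samples,
                              residual=residual.reset_index(drop=True))


def heteroplasmy_profile(
    merged: MergedVariantTable, min_samples: int = 10
) -> pd.DataFrame:
    """Per-variant heteroplasmic fraction for well-sampled variants.

    Restricted to variants carried by at least ``min_samples`` individuals;
    ``het_fraction = counts_het / total_count``.  Uses the collapsed
    one-row-per-genomic-change view so overlapping genes do not double-count
    a variant, with the conservative all-genes synonymy rule.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    t = merged.table
    per_variant = (
        t.groupby(["position", "ref_base", "alt_base"], as_index=False)
        .agg(
            counts_hom=("counts_hom", "first"),
            counts_het=("counts_het", "first"),
            total_count=("total_count", "first"),
            is_synonymous=("is_synonymous", "all"),
        )
    )
    # total_count from merge may be hom-only; recompute the carrier total here
    carriers = per_variant["counts_hom"] + per_variant["counts_het"]
    per_variant = per_variant[carriers >= min_samples].copy()
    per_variant["het_fraction"] = per_variant["counts_het"] / (
        per_variant["counts_hom"] + per_variant["counts_het"]
    )
    return per_variant.sort_values(
        ["total_count", "position"], kind="mergesort"
    ).reset_index(drop=True)
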