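"""End-to-end orchestration: run the human and mammal analyses, write TSVs.

Every stage output is a TSV with fixed column order; a ``manifest.json``
records input/output SHA-256 digests, configuration and per-stage row
counts, so identical inputs reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, diversity
from .ancestral import (
    tss_amino_acid_comparison,
    tss_frequency_association,
    tss_table,
)
from .comparative import CodonAlignment, identify_ip3_sites, p3_base_frequencies
from .mutagenesis import AnnotatedGenome, enumerate_substitutions, parse_annotated_genome
from .trees import RootedTree
from .variants import (
    DEFAULT_N_SAMPLES,
    MergedVariantTable,
    heteroplasmy_profile,
    merge_and_classify,
    parse_variant_db,
)

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


class PipelineError(RuntimeError):
    pass


def run_human_analysis(
    genome: AnnotatedGenome | str,
    variant_tsv_text: str,
    out_dir,
    n_samples: int = DEFAULT_N_SAMPLES,
    hom_only: bool = False,
) -> MergedVariantTable:
    """Mutagenesis -> merge -> diversity -> heteroplasmy, written to ``out_dir``.

    ``genome`` may be an :class:`AnnotatedGenome` or GenBank flat-file text.
    Emits substitutions, merged and SSNE tables, degeneracy-class divergence
    summary, SSNE composition, transition-vs-transversion count comparison,
    syn-vs-nonsyn count comparison, heteroplasmy profile and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts = {}
    try:
        if isinstance(genome, str):
            genome = parse_annotated_genome(genome)
        subs, run_log = enumerate_substitutions(genome)
        stage_counts["substitutions"] = len(subs)
        _write(subs, out / "substitutions.tsv")

        variants, skip_report = parse_variant_db(variant_tsv_text)
        stage_counts["variants_parsed"] = len(variants)
        merged = merge_and_classify(subs, variants, n_samples, hom_only=hom_only)
        _write(merged.table, out / "merged.tsv")
        _write(merged.ssne(), out / "ssne.tsv")
        _write(merged.residual, out / "residual_variants.tsv")
        stage_counts["merged"] = len(merged.table)
        stage_counts["ssne"] = int(merged.table["is_ssne"].sum())

        sites = diversity.site_degeneracy_table(genome)
        div = diversity.divergence_summary(sites, merged)
        _write(div, out / "divergence_summary.tsv")
        comp = diversity.ssne_composition(merged)
        _write(comp, out / "ssne_composition.tsv")

        ts, tv, ks = diversity.variant_count_by_substitution_type(merged)
        tstv = pd.DataFrame(
            {"sub_type": ["transition"] * len(ts) + ["transversion"] * len(tv),
             "total_count": pd.concat([ts, tv], ignore_index=True)}
        )
        _write(tstv, out / "tstv_counts.tsv")

        syn, nonsyn, fig1_ks = diversity.synonymous_vs_nonsynonymous_ks(merged)
        tests = pd.DataFrame(
            [
                {"comparison": "syn_vs_nonsyn_counts", "n1": fig1_ks.n1,
                 "n2": fig1_ks.n2, "d": fig1_ks.d_statistic,
                 "p": fig1_ks.p_value},
            ]
            + (
                [{"comparison": "ts_vs_tv_counts_fourfold_aa", "n1": ks.n1,
                  "n2": ks.n2, "d": ks.d_statistic, "p": ks.p_value}]
                if ks is not None else []
            )
        )
        _write(tests, out / "ks_tests.tsv")

        het = heteroplasmy_profile(merged)
        _write(het, out / "heteroplasmy.tsv")
    except Exception as exc:
        raise PipelineError(f"human analysis failed: {exc}") from exc

    manifest = {
        "tool": f"mitobias {__version__}",
        "analysis": "human",
        "n_samples": n_samples,
        "hom_only": hom_only,
        "mutagenesis_log": run_log,
        "variant_skip_report": skip_report,
        "stage_row_counts": stage_counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return merged


def run_mammal_analysis(
    alignments: list[CodonAlignment],
    tree: RootedTree,
    out_dir,
    merged_human: MergedVariantTable | None = None,
    method: str = "fitch",
    kappa: float = 2.0,
    base_frequencies=(0.25, 0.25, 0.25, 0.25),
) -> pd.DataFrame:
    """Base frequencies -> I-P3 identification -> TSS -> association tests.

    The tree's leaf set must equal the alignment taxa; a mismatch aborts
    with the symmetric difference.  Returns the TSS table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    taxa = set()
    for aln in alignments:
        taxa.update(aln.taxa)
    leaves = set(tree.leaf_names)
    if taxa != leaves:
        diff = sorted(taxa.symmetric_difference(leaves))
        raise PipelineError(
            f"tree leaves and alignment taxa differ: {', '.join(diff)}"
        )

    try:
        freqs = p3_base_frequencies(alignments)
        _write(freqs, out / "p3_base_frequencies.tsv")

        ip3 = identify_ip3_sites(alignments, with_columns=True)
        _write(ip3.drop(columns=["column"]), out / "ip3_sites.tsv")

        tss = tss_table(ip3, tree, method=method, kappa=kappa,
                        base_frequencies=base_frequencies)
        _write(tss, out / "tss.tsv")

        aa_matrix = tss_amino_acid_comparison(tss)
        _write(aa_matrix, out / "tss_amino_acid_tests.tsv")

        if merged_human is not None:
            assoc = tss_frequency_association(tss, merged_human)
            _write(assoc, out / "tss_frequency_tests.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"mammal analysis failed: {exc}") from exc

    manifest = {
        "tool": f"mitobias {__version__}",
        "analysis": "mammal",
        "method": method,
        "stage_row_counts": {
            "alignments": len(alignments),
            "ip3_sites": len(ip3),
            "tss": len(tss),
        },
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return tss
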