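"""Shared fixtures: synthetic genomes, variant tables and evolution runs."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitobias import simulate
from mitobias.mutagenesis import enumerate_substitutions, parse_annotated_genome
from mitobias.variants import merge_and_classify, parse_variant_db


def make_genbank(sequence: str, features: list[tuple]) -> str:
    """Hand-build a GenBank record; features are (gene, location) pairs where
    location is (start0, end0, strand) or a list of such parts (a join)."""
    record = SeqRecord(Seq(sequence), id="TEST01", name="TEST01",
                       description="handmade test record")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    record.annotations["date"] = "01-JAN-2000"
    for gene, loc in features:
        if isinstance(loc, list):
            parts = [SimpleLocation(s, e, strand=st) for s, e, st in loc]
            location = CompoundLocation(parts)
        else:
            s, e, st = loc
            location = SimpleLocation(s, e, strand=st)
        feat = SeqFeature(location, type="CDS")
        feat.qualifiers["gene"] = [gene]
        record.features.append(feat)
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


@pytest.fixture(scope="session")
def toy_genome_text() -> str:
    return simulate.generate_toy_genome(seed=7)


@pytest.fixture(scope="session")
def toy_genome(toy_genome_text):
    return parse_annotated_genome(toy_genome_text)


@pytest.fixture(scope="session")
def toy_substitutions(toy_genome):
    return enumerate_substitutions(toy_genome)


@pytest.fixture(scope="session")
def biased_config() -> simulate.SimulationConfig:
    """The default planted-bias study conditions (kappa=20, strong selection)."""
    return simulate.SimulationConfig(seed=11, kappa=20.0)


@pytest.fixture(scope="session")
def biased_merged(toy_genome, toy_substitutions, biased_config):
    subs, _ = toy_substitutions
    tsv, _ = simulate.simulate_variant_db(toy_genome, biased_config)
    rows, _ = parse_variant_db(tsv)
    return merge_and_classify(subs, rows, biased_config.n_samples)


@pytest.fixture(scope="session")
def evolution_run():
    """12-taxon low-divergence evolution with truth (session-scoped for speed)."""
    rng = np.random.default_rng(21)
    tree = simulate.random_rooted_tree(12, rng, mean_branch_length=0.05)
    config = simulate.SimulationConfig(seed=21, kappa=4.0)
    alignment, truth = simulate.simulate_evolution(tree, 501, config)
    return tree, alignment, truth


def site_columns(alignment) -> pd.DataFrame:
    """Per-site leaf->base columns of a gap-free alignment."""
    cols = [
        {t: row[s] for t, row in zip(alignment.taxa, alignment.rows)}
        for s in range(alignment.length)
    ]
    return pd.DataFrame({"site": np.arange(1, alignment.length + 1),
                         "column": cols})
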