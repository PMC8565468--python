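"""Synthetic inputs with known ground truth.

Three generators stand in for the pipeline's external inputs:

* :func:`generate_toy_genome` — a small annotated circular genome in GenBank
  flat-file format, with plus- and minus-strand CDSs and an overlapping gene
  pair, mimicking the architecture of mammalian mtDNA;
* :func:`simulate_variant_db` — a population variant table in the same TSV
  dialect as the human database, with a planted transition/transversion rate
  ratio kappa and planted purifying selection on non-synonymous changes;
* :func:`simulate_evolution` — sequence evolution along a supplied rooted
  tree under an HKY process, with every substitution event recorded per
  site, giving exact truth for Total Substitution Scores.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give byte-identical outputs.
Generated text files record the seed and a config hash in ``#`` header
comments.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio import SeqIO

from . import code
from .comparative import CodonAlignment
from .mutagenesis import (
    AnnotatedGenome,
    collapse_by_position,
    enumerate_substitutions,
    reverse_complement,
)
from .trees import RootedTree

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Base composition loosely modelled on the mtDNA coding (light) strand.
DEFAULT_COMPOSITION = (0.31, 0.31, 0.13, 0.25)  # A, C, G, T


@dataclass(frozen=True)
class GeneSpec:
    name: str
    n_codons: int
    strand: int = 1
    overlap_with: str | None = None  # start inside that gene's last codons, +1 frame
    overlap_codons: int = 0
    incomplete_stop_bases: int = 0  # 0, 1 or 2 extra bases (partial terminal codon)


DEFAULT_GENES = (
    GeneSpec("ND1", 100),
    GeneSpec("COX1", 120),
    GeneSpec("ATP8", 50),
    GeneSpec("ATP6", 90, overlap_with="ATP8", overlap_codons=10),
    GeneSpec("ND6", 80, strand=-1),
    GeneSpec("CYTB", 110, incomplete_stop_bases=1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic variant table and evolution runs."""

    seed: int = 0
    kappa: float = 20.0            # transition/transversion rate ratio
    n_samples: int = 195983        # population size of the variant table
    sel_nonsyn: float = 0.95       # P(a non-synonymous carrier is removed)
    site_intensity: float = 10.0   # mean carriers per coding site (lambda)
    transition_only: bool = False
    het_decay_scale: float = 20.0  # drift-age proxy: het fraction decays with count
    het_base: float = 0.9
    het_floor: float = 0.02
    composition: tuple[float, float, float, float] = DEFAULT_COMPOSITION

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_sense_codons(rng: np.random.Generator, n: int, composition) -> str:
    """Random sense codons (no stops) from a per-base composition."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list(BASES), p=composition, size=3))
        if codon not in code.STOP_CODONS:
            out.append(codon)
    return "".join(out)


def generate_toy_genome(
    seed: int = 0,
    genes: tuple[GeneSpec, ...] = DEFAULT_GENES,
    spacer: int = 30,
    composition=DEFAULT_COMPOSITION,
) -> str:
    """Emit a small annotated circular genome as GenBank flat-file text.

    Genes are laid out left to right with ``spacer`` intergenic bases; a
    gene with ``overlap_with`` starts ``overlap_codons`` codons before the
    end of its partner, shifted one base into a different reading frame
    (the ATP8/ATP6 arrangement).  Minus-strand genes are inserted as the
    reverse complement of their coding sequence.  Deterministic per seed.
    """
    rng = _rng(seed)
    comp = list(composition)
    seq_parts: list[str] = []
    features: list[tuple[str, int, int, int]] = []  # name, start0, end0, strand
    cursor = 0

    def pad(n: int):
        nonlocal cursor
        seq_parts.append("".join(rng.choice(list(BASES), p=comp, size=n)))
        cursor += n

    placed: dict[str, tuple[int, int]] = {}
    for spec in genes:
        if spec.overlap_with is None:
            pad(spacer)
            length = 3 * spec.n_codons + spec.incomplete_stop_bases
            coding = _random_sense_codons(rng, spec.n_codons, comp)
            coding += "".join(rng.choice(list(BASES), p=comp,
                                         size=spec.incomplete_stop_bases))
            insert = coding if spec.strand == 1 else reverse_complement(coding)
            start = cursor
            seq_parts.append(insert)
            cursor += length
            features.append((spec.name, start, cursor, spec.strand))
            placed[spec.name] = (start, cursor)
        else:
            if spec.overlap_with not in placed:
                raise ValueError(
                    f"gene {spec.name} overlaps unknown gene {spec.overlap_with}"
                )
            host_start, host_end = placed[spec.overlap_with]
            start = host_end - 3 * spec.overlap_codons + 1  # +1 shifts the frame
            if start <= host_start:
                raise ValueError(
                    f"overlap of {spec.name} extends beyond {spec.overlap_with}"
                )
            already = cursor - start
            extra = 3 * spec.n_codons + spec.incomplete_stop_bases - already
            if extra < 0:
                raise ValueError(f"gene {spec.name} shorter than its overlap")
            pad(extra)
            features.append((spec.name, start, cursor, spec.strand))
            placed[spec.name] = (start, cursor)
    pad(spacer)

    sequence = "".join(seq_parts)
    record = SeqRecord(
        Seq(sequence),
        id="SYNMT01",
        name="SYNMT01",
        description=f"synthetic circular mtDNA-like genome (seed={seed})",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    record.annotations["date"] = "01-JAN-2000"  # fixed for byte-identical output
    record.annotations["data_file_division"] = "SYN"
    for name, s, e, strand in features:
        feat = SeqFeature(SimpleLocation(s, e, strand=strand), type="CDS")
        feat.qualifiers["gene"] = [name]
        record.features.append(feat)
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


def substitution_rates(config: SimulationConfig) -> tuple[float, float]:
    """Per-substitution mean carrier counts (transition, transversion).

    The per-site intensity lambda is split over the one transition and two
    transversions reachable from a base with relative rates kappa : 1 : 1.
    """
    k = config.kappa
    mu_ts = config.site_intensity * k / (k + 2.0)
    mu_tv = 0.0 if config.transition_only else config.site_intensity / (k + 2.0)
    return mu_ts, mu_tv


def simulate_variant_db(
    genome: AnnotatedGenome, config: SimulationConfig
) -> tuple[str, pd.DataFrame]:
    """Simulate a population variant table over ``genome``'s coding positions.

    Each possible substitution receives a Poisson carrier count with mean
    proportional to kappa for transitions and 1 for transversions;
    non-synonymous carriers (by the conservative all-overlapping-genes rule)
    are thinned with probability ``sel_nonsyn``.  Carriers are split into
    homoplasmic/heteroplasmic by a drift-age proxy in which the
    heteroplasmic fraction decays with population count.  Returns the TSV
    text (HelixMTdb dialect) and the per-variant truth table.
    """
    if config.n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = _rng(config.seed)
    subs, _ = enumerate_substitutions(genome)
    collapsed = collapse_by_position(subs)
    mu_ts, mu_tv = substitution_rates(config)
    mu = np.where(collapsed["sub_type"] == "transition", mu_ts, mu_tv)
    carriers = rng.poisson(mu)
    nonsyn = ~collapsed["is_synonymous"].to_numpy()
    surviving = np.where(
        nonsyn, rng.binomial(carriers, 1.0 - config.sel_nonsyn), carriers
    )
    surviving = np.minimum(surviving, config.n_samples)

    p_het = np.clip(
        config.het_base * np.exp(-surviving / config.het_decay_scale)
        + config.het_floor,
        0.0, 1.0,
    )
    counts_het = rng.binomial(surviving, p_het)
    counts_hom = surviving - counts_het

    truth = collapsed.copy()
    truth["mu"] = mu
    truth["true_carriers"] = surviving
    truth["planted_kappa"] = config.kappa
    truth["planted_sel_nonsyn"] = config.sel_nonsyn

    lines = [
        f"# mitobias synthetic variant table seed={config.seed} "
        f"config={config.hash()}",
        "locus\talleles\tgene\tcounts_hom\tcounts_het",
    ]
    for (pos, ref, alt, genes), hom, het in zip(
        collapsed[["position", "ref_base", "alt_base", "genes"]].itertuples(
            index=False
        ),
        counts_hom,
        counts_het,
    ):
        if hom + het == 0:
            continue  # a database tabulates only encountered variants
        lines.append(
            f"chrM:{pos}\t[\"{ref}\",\"{alt}\"]\t{genes}\t{hom}\t{het}"
        )
    return "\n".join(lines) + "\n", truth


def genome_from_sequence(sequence: str, gene: str = "SIM1") -> str:
    """Wrap a bare coding sequence as a one-CDS GenBank record.

    Used to treat the reference row of a simulated alignment as an annotated
    genome so human-style variant integration can run on the same
    coordinates.
    """
    record = SeqRecord(
        Seq(sequence),
        id="SYNREF01",
        name="SYNREF01",
        description=f"synthetic single-CDS genome for gene {gene}",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular"
    record.annotations["date"] = "01-JAN-2000"
    feat = SeqFeature(SimpleLocation(0, len(sequence), strand=1), type="CDS")
    feat.qualifiers["gene"] = [gene]
    record.features.append(feat)
    buf = io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# sequence evolution along a tree


def random_rooted_tree(
    n_leaves: int,
    rng: np.random.Generator,
    mean_branch_length: float = 0.1,
) -> RootedTree:
    """A random rooted binary tree with exponential branch lengths (for tests
    and simulations; topology by random sequential joining)."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    subtrees = [f"T{i}" for i in range(n_leaves)]

    def bl() -> float:
        return float(rng.exponential(mean_branch_length))

    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a}:{bl():.6f},{b}:{bl():.6f})")
    return RootedTree.from_newick(subtrees[0] + ";")


def _hky_jump_rates(kappa: float, composition) -> np.ndarray:
    """Off-diagonal HKY rates scaled to 1 expected event per unit length."""
    pi = np.asarray(composition, dtype=float)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            r = pi[j] * (kappa if code.is_transition(BASES[i], BASES[j]) else 1.0)
            q[i, j] = r
    mu = float((pi * q.sum(axis=1)).sum())
    return q / mu if mu > 0 else q


def simulate_evolution(
    tree: RootedTree,
    n_sites: int,
    config: SimulationConfig,
    gene: str = "SIM1",
) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve a root sequence along ``tree`` under HKY, recording every event.

    Branch lengths are in expected substitutions per site.  The root
    sequence is drawn codon-wise without stop codons (``n_sites`` must be a
    multiple of 3).  Returns a gap-free :class:`CodonAlignment` over the
    leaves (in tree order, reference = first leaf) and a truth table with
    the exact per-site substitution-event count summed over all branches.
    """
    if n_sites % 3:
        raise ValueError("n_sites must be a multiple of 3")
    rng = _rng(config.seed)
    comp = list(config.composition)
    root_seq = np.array(
        [_BASE_INDEX[b] for b in _random_sense_codons(rng, n_sites // 3, comp)],
        dtype=np.int8,
    )
    rates = _hky_jump_rates(config.kappa, comp)
    exit_rate = rates.sum(axis=1)

    ts_pair = np.array([[code.is_transition(a, b) for b in BASES] for a in BASES])
    states = {tree.root: root_seq}
    events = np.zeros(n_sites, dtype=np.int64)
    ts_events = np.zeros(n_sites, dtype=np.int64)
    for v in tree.preorder:
        if v == tree.root:
            continue
        seq = states[tree.parent[v]].copy()
        t_branch = tree.edge_length[v]
        if t_branch > 0:
            for s in range(n_sites):
                t = 0.0
                while True:
                    b = seq[s]
                    r = exit_rate[b]
                    if r <= 0:
                        break
                    t += rng.exponential(1.0 / r)
                    if t >= t_branch:
                        break
                    new = rng.choice(4, p=rates[b] / r)
                    if ts_pair[b, new]:
                        ts_events[s] += 1
                    seq[s] = new
                    events[s] += 1
        states[v] = seq
    leaves = tree.leaves
    taxa = tuple(tree.name[v] or f"leaf_{v}" for v in leaves)
    rows = tuple("".join(BASES[i] for i in states[v]) for v in leaves)
    alignment = CodonAlignment(gene=gene, taxa=taxa, rows=rows,
                               reference_id=taxa[0])
    truth = pd.DataFrame(
        {
            "gene": gene,
            "site": np.arange(1, n_sites + 1),
            "codon_index": np.arange(n_sites) // 3 + 1,
            "codon_position": np.arange(n_sites) % 3 + 1,
            "true_events": events,
            "true_ts_events": ts_events,
        }
    )
    return alignment, truth
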