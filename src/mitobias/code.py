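"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The vertebrate mitochondrial code differs from the standard code at four
codons: AGA/AGG are stops (not Arg), ATA is Met (not Ile) and TGA is Trp
(not stop).  Every amino acid is read by a single mitochondrial tRNA except
leucine and serine, which each use two tRNAs:

* L1 reads TTR leucine codons, L2 reads the fourfold CTN box;
* S1 reads the fourfold TCN box, S2 reads AGY serine codons.

Degeneracy is therefore a property of the tRNA *family*, not of the amino
acid.  Each of the 60 sense codons belongs to exactly one family, and each
family is either fourfold degenerate at the third codon position (P3) or
twofold degenerate with either a purine pair (A/G) or a pyrimidine pair
(C/T) at P3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

__all__ = [
    "STOP",
    "STOP_CODONS",
    "SENSE_CODONS",
    "FOURFOLD",
    "TWOFOLD_PURINE",
    "TWOFOLD_PYRIMIDINE",
    "FOURFOLD_CAPABLE_AMINO_ACIDS",
    "CodonTable",
    "codon_table",
    "translate",
    "degeneracy_class",
    "substitution_type",
    "is_transition",
    "normalize_codon",
    "synonymous_p3_bases",
]

STOP = "*"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = "ACGT"

FOURFOLD = "fourfold"
TWOFOLD_PURINE = "twofold_purine"
TWOFOLD_PYRIMIDINE = "twofold_pyrimidine"

# family id -> (amino acid, first two codon bases, degeneracy class)
# Fourfold boxes: the 8 amino acids Leu(L2), Val, Ser(S1), Pro, Thr, Ala, Arg, Gly.
_FAMILIES: dict[str, tuple[str, str, str]] = {
    "F": ("Phe", "TT", TWOFOLD_PYRIMIDINE),
    "L1": ("Leu", "TT", TWOFOLD_PURINE),
    "L2": ("Leu", "CT", FOURFOLD),
    "I": ("Ile", "AT", TWOFOLD_PYRIMIDINE),
    "M": ("Met", "AT", TWOFOLD_PURINE),
    "V": ("Val", "GT", FOURFOLD),
    "S1": ("Ser", "TC", FOURFOLD),
    "P": ("Pro", "CC", FOURFOLD),
    "T": ("Thr", "AC", FOURFOLD),
    "A": ("Ala", "GC", FOURFOLD),
    "Y": ("Tyr", "TA", TWOFOLD_PYRIMIDINE),
    "H": ("His", "CA", TWOFOLD_PYRIMIDINE),
    "Q": ("Gln", "CA", TWOFOLD_PURINE),
    "N": ("Asn", "AA", TWOFOLD_PYRIMIDINE),
    "K": ("Lys", "AA", TWOFOLD_PURINE),
    "D": ("Asp", "GA", TWOFOLD_PYRIMIDINE),
    "E": ("Glu", "GA", TWOFOLD_PURINE),
    "C": ("Cys", "TG", TWOFOLD_PYRIMIDINE),
    "W": ("Trp", "TG", TWOFOLD_PURINE),
    "S2": ("Ser", "AG", TWOFOLD_PYRIMIDINE),
    "R": ("Arg", "CG", FOURFOLD),
    "G": ("Gly", "GG", FOURFOLD),
}

STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: The eight amino acids that own at least one fourfold-degenerate codon box.
FOURFOLD_CAPABLE_AMINO_ACIDS = frozenset(
    {"Leu", "Val", "Ser", "Pro", "Thr", "Ala", "Arg", "Gly"}
)


def _third_bases(family: str) -> str:
    cls = _FAMILIES[family][2]
    if cls == FOURFOLD:
        return "ACGT"
    if cls == TWOFOLD_PURINE:
        return "AG"
    return "CT"


@dataclass(frozen=True)
class CodonTable:
    """The 64-codon vertebrate mitochondrial code with family/degeneracy annotation."""

    codon_to_aa: dict[str, str]
    codon_to_family: dict[str, str]
    family_to_degeneracy: dict[str, str]

    def synonymous_codons(self, codon: str) -> frozenset[str]:
        """All sense codons in the same tRNA family (including ``codon`` itself)."""
        fam = self.codon_to_family[codon]
        prefix = _FAMILIES[fam][1]
        return frozenset(prefix + b for b in _third_bases(fam))


def _build_table() -> CodonTable:
    codon_to_aa: dict[str, str] = {}
    codon_to_family: dict[str, str] = {}
    for fam, (aa, prefix, cls) in _FAMILIES.items():
        for b in _third_bases(fam):
            codon = prefix + b
            codon_to_aa[codon] = aa
            codon_to_family[codon] = fam
    for codon in STOP_CODONS:
        codon_to_aa[codon] = STOP
    assert len(codon_to_aa) == 64
    return CodonTable(
        codon_to_aa=codon_to_aa,
        codon_to_family=codon_to_family,
        family_to_degeneracy={f: v[2] for f, v in _FAMILIES.items()},
    )


_TABLE = _build_table()

SENSE_CODONS = frozenset(_TABLE.codon_to_family)


def codon_table() -> CodonTable:
    """Return the shared vertebrate mitochondrial :class:`CodonTable`."""
    return _TABLE


def normalize_codon(codon: str) -> str:
    """Uppercase a triplet and map RNA U to DNA T; reject anything else.

    Raises ``ValueError`` for non-triplets or characters outside {A,C,G,T,U}.
    """
    if not isinstance(codon, str) or len(codon) != 3:
        raise ValueError(f"codon must be a 3-letter string, got {codon!r}")
    norm = codon.upper().replace("U", "T")
    if any(b not in BASES for b in norm):
        raise ValueError(f"codon contains non-nucleotide characters: {codon!r}")
    return norm


def translate(codon: str) -> str:
    """Translate a triplet under NCBI table 2; stops return ``"*"``."""
    return _TABLE.codon_to_aa[normalize_codon(codon)]


def degeneracy_class(codon: str) -> tuple[str, str, str]:
    """Return ``(amino_acid, trna_family, degeneracy_class)`` for a sense codon.

    Raises ``ValueError`` for the four mitochondrial stop codons, which carry
    no tRNA family or degeneracy class.
    """
    norm = normalize_codon(codon)
    if norm in STOP_CODONS:
        raise ValueError(f"{norm} is a stop codon and has no degeneracy class")
    fam = _TABLE.codon_to_family[norm]
    return _TABLE.codon_to_aa[norm], fam, _TABLE.family_to_degeneracy[fam]


def is_transition(ref_base: str, alt_base: str) -> bool:
    a, b = ref_base.upper(), alt_base.upper()
    return (a in PURINES) == (b in PURINES)


def substitution_type(ref_base: str, alt_base: str) -> str:
    """Classify a base change as ``"transition"`` or ``"transversion"``.

    A transition keeps the purine/pyrimidine character (A<->G or C<->T);
    a transversion crosses it.
    """
    a, b = ref_base.upper(), alt_base.upper()
    if a not in BASES or b not in BASES:
        raise ValueError(f"bases must be in ACGT, got {ref_base!r}, {alt_base!r}")
    if a == b:
        raise ValueError(f"ref and alt base are identical: {ref_base!r}")
    return "transition" if is_transition(a, b) else "transversion"


@lru_cache(maxsize=None)
def synonymous_p3_bases(codon: str) -> frozenset[str]:
    """The set of third-position bases synonymous with a sense codon (incl. its own)."""
    norm = normalize_codon(codon)
    if norm in STOP_CODONS:
        raise ValueError(f"{norm} is a stop codon")
    return frozenset(c[2] for c in _TABLE.synonymous_codons(norm))


def load_reference_table_text() -> str:
    """The packaged plain-text copy of the annotated code table (for diffing)."""
    return (
        resources.files("mitobias").joinpath("data/mt_codon_table.tsv").read_text()
    )
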