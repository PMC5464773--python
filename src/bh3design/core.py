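"""Core domain types for BH3 peptide library work.

BH3 motifs are short amphipathic helices named here by a heptad convention:
each residue carries a label like ``2a`` or ``3f`` composed of a helix-turn
index (1-4) and a heptad letter (a-g).  Labels are stable across peptides of
different lengths and are the coordinate system used by scoring matrices and
library designs.  Degenerate codons are triplets of IUPAC nucleotide symbols
(e.g. ``NNK``) that encode sets of concrete codons and hence amino-acid sets.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache, total_ordering

from Bio.Seq import Seq
from Bio.SeqIO import parse as _fasta_parse, write as _fasta_write
from Bio.SeqRecord import SeqRecord

HEPTAD_LETTERS = "abcdefg"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: IUPAC nucleotide degeneracy alphabet.
IUPAC_NT = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

STOP = "*"

#: standard nuclear genetic code, codon -> 1-letter amino acid or '*'
GENETIC_CODE = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product("ACGT", repeat=3)
}

N_TERM_MODS = ("none", "acetyl", "fluorescein", "acrylamide")
C_TERM_MODS = ("none", "amide")


@total_ordering
@dataclass(frozen=True)
class HeptadPosition:
    """One helix position, e.g. turn 3, letter 'f' -> '3f'."""

    turn: int
    letter: str

    def __post_init__(self):
        if self.letter not in HEPTAD_LETTERS:
            raise ValueError(f"heptad letter must be a-g, got {self.letter!r}")
        if self.turn not in (1, 2, 3, 4):
            raise ValueError(f"helix turn must be 1-4, got {self.turn}")

    @classmethod
    def parse(cls, label: str) -> "HeptadPosition":
        if len(label) != 2 or not label[0].isdigit():
            raise ValueError(f"cannot parse heptad label {label!r}")
        return cls(int(label[0]), label[1])

    @property
    def rank(self) -> int:
        """N->C ordinal: consecutive positions differ by 1."""
        return self.turn * 7 + HEPTAD_LETTERS.index(self.letter)

    def shift(self, offset: int) -> "HeptadPosition":
        r = self.rank + offset
        return HeptadPosition(r // 7, HEPTAD_LETTERS[r % 7])

    def __lt__(self, other):
        return self.rank < other.rank

    def __str__(self):
        return f"{self.turn}{self.letter}"


@dataclass(frozen=True)
class BH3Peptide:
    """A BH3 peptide with a contiguous heptad register.

    ``register_start`` anchors sequence index 0; index i then maps to the
    heptad position ``register_start + i`` (contiguous, order-preserving).
    """

    name: str
    sequence: str
    register_start: HeptadPosition
    n_term_mod: str = "none"
    c_term_mod: str = "none"

    def __post_init__(self):
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues in {self.name}: {sorted(bad)}")
        if self.n_term_mod not in N_TERM_MODS:
            raise ValueError(f"unknown N-terminal modification {self.n_term_mod!r}")
        if self.c_term_mod not in C_TERM_MODS:
            raise ValueError(f"unknown C-terminal modification {self.c_term_mod!r}")
        # the last residue must still lie on a legal heptad position
        self.register_start.shift(len(self.sequence) - 1)

    def __len__(self):
        return len(self.sequence)

    def heptad_label(self, index: int) -> HeptadPosition:
        """Heptad position of residue ``index`` (0-based)."""
        if not 0 <= index < len(self.sequence):
            raise IndexError(f"index {index} outside peptide of length {len(self)}")
        return self.register_start.shift(index)

    def index_of(self, label: HeptadPosition | str) -> int:
        """Sequence index carrying heptad position ``label``."""
        if isinstance(label, str):
            label = HeptadPosition.parse(label)
        idx = label.rank - self.register_start.rank
        if not 0 <= idx < len(self.sequence):
            raise KeyError(f"heptad position {label} outside register of {self.name}")
        return idx

    def residue_at(self, label: HeptadPosition | str) -> str:
        return self.sequence[self.index_of(label)]

    @property
    def positions(self) -> list[HeptadPosition]:
        return [self.register_start.shift(i) for i in range(len(self.sequence))]

    def with_substitutions(self, subs: dict[HeptadPosition | str, str],
                           name: str | None = None) -> "BH3Peptide":
        seq = list(self.sequence)
        for label, aa in subs.items():
            seq[self.index_of(label)] = aa
        return BH3Peptide(name or f"{self.name}_mut", "".join(seq),
                          self.register_start, self.n_term_mod, self.c_term_mod)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sequence": self.sequence,
            "register_start": str(self.register_start),
            "n_term_mod": self.n_term_mod,
            "c_term_mod": self.c_term_mod,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BH3Peptide":
        return cls(d["name"], d["sequence"],
                   HeptadPosition.parse(d["register_start"]),
                   d.get("n_term_mod", "none"), d.get("c_term_mod", "none"))


@dataclass(frozen=True)
class DegenerateCodon:
    """Three IUPAC degeneracy symbols, e.g. 'NNK' or 'VHA'."""

    letters: str

    def __post_init__(self):
        if len(self.letters) != 3:
            raise ValueError(f"degenerate codon needs 3 symbols, got {self.letters!r}")
        for sym in self.letters:
            if sym not in IUPAC_NT:
                raise ValueError(f"invalid IUPAC nucleotide symbol {sym!r} in {self.letters!r}")

    @property
    def size(self) -> int:
        """Number of concrete codons (product of per-letter degeneracies)."""
        n = 1
        for sym in self.letters:
            n *= len(IUPAC_NT[sym])
        return n

    def codons(self) -> list[str]:
        return _codons_cached(self.letters)

    def amino_acid_counts(self) -> Counter:
        """Multiset of encoded amino acids; stops counted under '*'."""
        return Counter(_aa_counts_cached(self.letters))

    def amino_acids(self) -> frozenset:
        """Distinct encoded amino acids, stops excluded."""
        return _amino_acids_cached(self.letters)

    def n_stops(self) -> int:
        return _aa_counts_cached(self.letters).get(STOP, 0)

    def __str__(self):
        return self.letters


@lru_cache(maxsize=None)
def _codons_cached(letters: str) -> list:
    return ["".join(c) for c in itertools.product(*(IUPAC_NT[s] for s in letters))]


@lru_cache(maxsize=None)
def _aa_counts_cached(letters: str) -> dict:
    counts = Counter(GENETIC_CODE[c] for c in _codons_cached(letters))
    return dict(counts)


@lru_cache(maxsize=None)
def _amino_acids_cached(letters: str) -> frozenset:
    return frozenset(aa for aa in _aa_counts_cached(letters) if aa != STOP)


def expand_degenerate_codon(codon: DegenerateCodon | str):
    """Expand a degenerate codon into concrete codons and encoded residues.

    Returns ``(codons, amino_acid_multiset, n_stops)``; stop codons are
    reported separately and never appear in the amino-acid multiset.
    """
    if isinstance(codon, str):
        codon = DegenerateCodon(codon)
    concrete = codon.codons()
    counts = codon.amino_acid_counts()
    stops = counts.pop(STOP, 0)
    return concrete, counts, stops


# --- default PUMA BH3 template -------------------------------------------
# 23-mer spanning heptad 1f-4g, anchored so that W sits at 1g, the conserved
# leucine at 3a and the conserved aspartate of the LxxxxD core at 3f.
PUMA_BH3 = BH3Peptide(
    "PUMA_BH3",
    "QWAREIGAQLRRMADDLNAQYER",
    HeptadPosition(1, "f"),
    n_term_mod="acetyl",
    c_term_mod="amide",
)

#: heptad positions varied in the Bfl-1-targeted PUMA library
PUMA_VARIABLE_POSITIONS = tuple(
    HeptadPosition.parse(s) for s in ("2a", "2e", "2g", "3d", "3g", "4a", "4e")
)

#: degenerate codons of the Bfl-1-targeted PUMA library, in scan order
PUMA_BFL1_CODONS = ("VHA", "KVT", "NDC", "NBC", "VWK", "NHT", "NYT")

#: codon-level DNA template for the PUMA BH3 insert (wild-type residues)
PUMA_BH3_DNA = (
    "CAATGGGCACGTGAAATTGGTGCCCAACTGCGTCGCATGGCGGATGATCTGAATGCCCAATATGAACGT"
)


# --- FASTA / JSON I/O -----------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in _fasta_parse(path, "fasta")]


def write_fasta(path, records) -> None:
    """Write (id, sequence) pairs to FASTA."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    _fasta_write(recs, path, "fasta")


def read_peptides_json(path) -> list[BH3Peptide]:
    with open(path) as fh:
        data = json.load(fh)
    return [BH3Peptide.from_dict(d) for d in data]


def write_peptides_json(path, peptides) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in peptides], fh, indent=1)


def translate(dna: str) -> str:
    """Translate a DNA string with the standard code ('*' for stops)."""
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} is not a multiple of 3")
    return "".join(GENETIC_CODE[dna[i:i + 3]] for i in range(0, len(dna), 3))


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())
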