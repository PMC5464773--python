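"""Additive per-position scoring of BH3 peptides against receptor models.

Two kinds of model are supported, both reduced to a (heptad position,
amino acid) -> score table:

* ``pssm`` — a position-specific scoring matrix derived from peptide-array
  binding intensities, normalized so that the reference (wild-type) residue
  scores 0 at every covered position.  Variants are compared on raw scores.
* ``potential`` — per-position scores from a structure-based statistical
  potential.  Variants are compared on z-scores against a background
  distribution of scores for random length-matched sequence windows.

Specificity for one receptor over a paralog is the difference of scores
(pssm) or of z-scores (potential).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, BH3Peptide, HeptadPosition

#: sentinel for matrix entries with no measurement
MISSING = float("nan")


class MissingEntryError(KeyError):
    """A peptide residue has no score in the model matrix."""


@dataclass(frozen=True)
class ScoringModel:
    """Per-position amino-acid score table for one receptor paralog."""

    receptor: str
    kind: str  # 'pssm' | 'potential'
    matrix: dict  # (HeptadPosition, aa) -> float (may be NaN for missing)
    reference: BH3Peptide
    covered_positions: tuple

    def __post_init__(self):
        if self.kind not in ("pssm", "potential"):
            raise ValueError(f"model kind must be pssm|potential, got {self.kind!r}")
        for pos in self.covered_positions:
            for aa in AMINO_ACIDS:
                if (pos, aa) not in self.matrix:
                    raise ValueError(f"matrix lacks entry for ({pos}, {aa})")
        if self.kind == "pssm":
            for pos in self.covered_positions:
                ref_aa = self.reference.residue_at(pos)
                v = self.matrix[(pos, ref_aa)]
                if not math.isclose(v, 0.0, abs_tol=1e-9):
                    raise ValueError(
                        f"pssm not normalized: reference residue {ref_aa} at {pos} "
                        f"scores {v}, expected 0")

    def entry(self, pos: HeptadPosition, aa: str) -> float:
        v = self.matrix[(pos, aa)]
        if math.isnan(v):
            raise MissingEntryError(
                f"{self.receptor} model has no score for residue {aa} at position {pos}")
        return v

    def to_frame(self) -> pd.DataFrame:
        rows = {str(p): {aa: self.matrix[(p, aa)] for aa in AMINO_ACIDS}
                for p in self.covered_positions}
        return pd.DataFrame.from_dict(rows, orient="index")[list(AMINO_ACIDS)]


@dataclass(frozen=True)
class BackgroundDistribution:
    """Mean/sd of model scores over a declared background sequence set."""

    mean: float
    sd: float
    source: str
    n: int

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"background sd must be > 0, got {self.sd}")
        if self.n < 100:
            raise ValueError(f"background needs >= 100 samples, got {self.n}")


def normalize_pssm(matrix: dict, reference: BH3Peptide, positions) -> dict:
    """Shift each position's column so the reference residue scores 0."""
    out = dict(matrix)
    for pos in positions:
        ref = matrix[(pos, reference.residue_at(pos))]
        for aa in AMINO_ACIDS:
            out[(pos, aa)] = matrix[(pos, aa)] - ref
    return out


def score_peptide(model: ScoringModel, peptide: BH3Peptide) -> float:
    """Additive model score: sum of matrix entries over covered positions."""
    total = 0.0
    for pos in model.covered_positions:
        total += model.entry(pos, peptide.residue_at(pos))
    return total


def zscore(model: ScoringModel, peptide: BH3Peptide,
           bg: BackgroundDistribution) -> float:
    """(raw - background mean) / background sd."""
    return (score_peptide(model, peptide) - bg.mean) / bg.sd


def build_background(model: ScoringModel, background_sequences, n: int,
                     seed: int, source: str = "user") -> BackgroundDistribution:
    """Score ``n`` seeded random length-matched windows of the background set.

    ``background_sequences`` is a list of plain amino-acid strings (e.g.
    proteome entries); windows the length of the model's covered span are
    sampled uniformly over sequences and offsets.  If it is None, windows
    are i.i.d. uniform residues (declared fallback background).
    """
    if n < 100:
        raise ValueError(f"n >= 100 required for a stable sd, got {n}")
    # windows must span the whole covered register (which may have gaps)
    k = model.covered_positions[-1].rank - model.covered_positions[0].rank + 1
    rng = np.random.default_rng(seed)
    start = model.covered_positions[0]
    scores = np.empty(n)
    if background_sequences is None:
        aa_arr = np.array(list(AMINO_ACIDS))
        for i in range(n):
            window = "".join(rng.choice(aa_arr, size=k))
            pep = BH3Peptide("bg", window, start)
            scores[i] = score_peptide(model, pep)
        source = source if source != "user" else "iid-uniform"
    else:
        usable = [s for s in background_sequences if len(s) >= k]
        if not usable:
            raise ValueError(f"no background sequence is >= {k} residues long")
        for i in range(n):
            s = usable[rng.integers(len(usable))]
            off = rng.integers(len(s) - k + 1)
            pep = BH3Peptide("bg", s[off:off + k], start)
            scores[i] = score_peptide(model, pep)
    sd = float(scores.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate background: all windows score identically")
    return BackgroundDistribution(float(scores.mean()), sd, source, n)


def specificity_score(target: ScoringModel, offtarget: ScoringModel,
                      peptide: BH3Peptide, bgs: dict | None = None) -> float:
    """Target-minus-offtarget score difference.

    pssm models are compared on raw normalized scores; potential models on
    z-scores (``bgs`` maps receptor name -> BackgroundDistribution).
    Mixing model kinds is refused.
    """
    if target.kind != offtarget.kind:
        raise ValueError(
            f"cannot mix model kinds: {target.kind} vs {offtarget.kind}")
    if target.kind == "pssm":
        return score_peptide(target, peptide) - score_peptide(offtarget, peptide)
    if bgs is None or target.receptor not in bgs or offtarget.receptor not in bgs:
        raise ValueError("potential models need background distributions for both receptors")
    return (zscore(target, peptide, bgs[target.receptor])
            - zscore(offtarget, peptide, bgs[offtarget.receptor]))


def score_correlation(model_a: ScoringModel, model_b: ScoringModel,
                      peptides) -> float:
    """Pearson correlation of the two models' scores over a peptide set."""
    if len(peptides) < 3:
        raise ValueError("need at least 3 peptides for a correlation")
    a = np.array([score_peptide(model_a, p) for p in peptides])
    b = np.array([score_peptide(model_b, p) for p in peptides])
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance score vector: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# --- file formats ---------------------------------------------------------

def write_model(model: ScoringModel, tsv_path, meta_path) -> None:
    """TSV matrix (rows = heptad labels, columns = amino acids) + JSON sidecar."""
    model.to_frame().to_csv(tsv_path, sep="\t", index_label="position")
    meta = {
        "receptor": model.receptor,
        "kind": model.kind,
        "reference": model.reference.to_dict(),
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_model(tsv_path, meta_path) -> ScoringModel:
    with open(meta_path) as fh:
        meta = json.load(fh)
    df = pd.read_csv(tsv_path, sep="\t", index_col="position")
    positions = tuple(HeptadPosition.parse(str(p)) for p in df.index)
    matrix = {}
    for p, row in zip(positions, df.itertuples(index=False)):
        for aa, v in zip(df.columns, row):
            matrix[(p, aa)] = float(v)
    return ScoringModel(meta["receptor"], meta["kind"], matrix,
                        BH3Peptide.from_dict(meta["reference"]), positions)
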