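"""Degenerate-codon combinatorial library design.

The design pipeline mirrors how focused BH3 libraries are built in practice:

1. score every single substitution at the scanned helix positions against the
   target receptor's models and classify each (position, residue) pair as
   *required*, *preferred*, *disruptive* or *neutral*;
2. enumerate all 15^3 degenerate codons per variable position and keep those
   that encode every required residue, no disruptive residue and no stop, and
   more than ``min_variants`` distinct amino acids;
3. pick exactly one codon per position by integer linear programming,
   maximizing the number of library members composed entirely of
   preferred/required residues, subject to a DNA-level library size cap
   (the product constraint becomes linear in log space);
4. audit the result: DNA/protein sizes, membership tests and score
   distributions over the encoded peptides.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, milp

from .core import (AMINO_ACIDS, IUPAC_NT, BH3Peptide, DegenerateCodon,
                   HeptadPosition)
from .scoring import ScoringModel, score_peptide, specificity_score

LABELS = ("required", "preferred", "disruptive", "neutral")

#: all 3375 degenerate codons, lexicographic
ALL_DEGENERATE_CODONS = tuple(
    DegenerateCodon("".join(c)) for c in itertools.product(sorted(IUPAC_NT), repeat=3)
)


class InfeasibleDesignError(ValueError):
    """No codon combination satisfies the constraints/cap."""


@dataclass
class ResidueClassification:
    """Label per (heptad position, amino acid) with rule provenance."""

    labels: dict  # (HeptadPosition, aa) -> label
    provenance: dict  # (HeptadPosition, aa) -> str

    def label(self, pos: HeptadPosition, aa: str) -> str:
        return self.labels.get((pos, aa), "neutral")

    def residues_with(self, pos: HeptadPosition, label: str) -> frozenset:
        return frozenset(aa for aa in AMINO_ACIDS if self.label(pos, aa) == label)

    def allowed_count(self, pos: HeptadPosition, codon: DegenerateCodon) -> int:
        """Number of preferred-or-required amino acids the codon encodes at pos."""
        good = (self.residues_with(pos, "preferred")
                | self.residues_with(pos, "required"))
        return len(codon.amino_acids() & good)


def classify_residues(models_target, models_offtarget, reference: BH3Peptide,
                      scan_positions, manual_required=None,
                      specificity_quantile: float = 0.9,
                      disruptive_sd: float = 1.0,
                      bgs: dict | None = None) -> ResidueClassification:
    """Classify substitutions at the scanned positions.

    ``models_target`` are the target receptor's scoring models (typically one
    pssm and one potential); ``models_offtarget`` the paralog models used for
    specificity.  Rules, applied over all single substitutions of
    ``reference`` at ``scan_positions``:

    * disruptive — scores more than ``disruptive_sd`` standard deviations of
      the single-mutant score distribution below the reference, on either
      target model;
    * preferred — strictly above the median single-mutant score on either
      target model, or above the ``specificity_quantile`` of per-position
      specificity scores against any off-target model of matching kind;
      disruptive takes precedence (labels are exclusive);
    * required — the manual list (``{position: set of residues}``), rejected
      with an error if any member is also disruptive;
    * neutral — everything else.

    Entries missing from a model matrix (NaN) are skipped for that model.
    """
    scan_positions = tuple(scan_positions)
    manual_required = manual_required or {}

    # single-mutant score tables per target model
    mut_scores = []  # per model: {(pos, aa): score}
    for m in models_target:
        ref_score = score_peptide(m, reference)
        tab = {}
        for pos in scan_positions:
            ref_aa = reference.residue_at(pos)
            ref_entry = m.matrix[(pos, ref_aa)]
            for aa in AMINO_ACIDS:
                v = m.matrix[(pos, aa)]
                if math.isnan(v) or math.isnan(ref_entry):
                    continue
                tab[(pos, aa)] = ref_score - ref_entry + v
        mut_scores.append((m, ref_score, tab))

    labels, prov = {}, {}

    # disruptive first: > disruptive_sd below reference on either model
    for m, ref_score, tab in mut_scores:
        vals = np.array(list(tab.values()))
        sd = vals.std(ddof=1)
        for key, s in tab.items():
            if s < ref_score - disruptive_sd * sd:
                labels[key] = "disruptive"
                prov[key] = f"sd rule ({m.receptor}/{m.kind})"

    # preferred: above median on either model
    for m, ref_score, tab in mut_scores:
        med = float(np.median(list(tab.values())))
        for key, s in tab.items():
            if labels.get(key) == "disruptive":
                continue
            if s > med:
                labels[key] = "preferred"
                prov.setdefault(key, f"median rule ({m.receptor}/{m.kind})")

    # specificity additions: top quantile of per-position specificity scores
    for m, ref_score, tab in mut_scores:
        for o in models_offtarget:
            if o.kind != m.kind:
                continue
            for pos in scan_positions:
                ref_aa = reference.residue_at(pos)
                specs = {}
                for aa in AMINO_ACIDS:
                    if (pos, aa) not in tab:
                        continue
                    pep = reference.with_substitutions({pos: aa})
                    try:
                        specs[aa] = specificity_score(m, o, pep, bgs)
                    except (ValueError, KeyError):
                        continue
                if len(specs) < 2:
                    continue
                cut = float(np.quantile(list(specs.values()), specificity_quantile))
                for aa, sp in specs.items():
                    key = (pos, aa)
                    if labels.get(key) == "disruptive":
                        continue
                    if sp > cut and labels.get(key) != "preferred":
                        labels[key] = "preferred"
                        prov[key] = f"specificity rule ({m.receptor} vs {o.receptor})"

    # manual required: must not be disruptive
    for pos, aas in manual_required.items():
        for aa in aas:
            key = (pos, aa)
            if labels.get(key) == "disruptive":
                raise ValueError(
                    f"required residue {aa} at {pos} is classified disruptive "
                    f"({prov[key]}): contradictory specification")
            labels[key] = "required"
            prov[key] = "manual"

    return ResidueClassification(labels, prov)


def candidate_codons(position: HeptadPosition,
                     classification: ResidueClassification,
                     min_variants: int = 3,
                     count_dna_variants: bool = False) -> list[DegenerateCodon]:
    """Admissible degenerate codons at one position.

    A codon qualifies iff it encodes every required residue, no disruptive
    residue, no stop codon, and more than ``min_variants`` distinct amino
    acids (or concrete codons, with ``count_dna_variants``).  The search
    space is all 15^3 degenerate codons.
    """
    required = classification.residues_with(position, "required")
    disruptive = classification.residues_with(position, "disruptive")
    out = []
    for codon in ALL_DEGENERATE_CODONS:
        aas = codon.amino_acids()
        if codon.n_stops():
            continue
        if not required <= aas:
            continue
        if aas & disruptive:
            continue
        n = codon.size if count_dna_variants else len(aas)
        if n <= min_variants:
            continue
        out.append(codon)
    return out


@dataclass(frozen=True)
class LibraryDesign:
    """Template peptide + one degenerate codon per variable position."""

    template: BH3Peptide
    variable_positions: tuple
    codon_choice: dict  # HeptadPosition -> DegenerateCodon
    cap_dna: int | None = None

    def __post_init__(self):
        for pos in self.variable_positions:
            if pos not in self.codon_choice:
                raise ValueError(f"no codon chosen for variable position {pos}")
            self.template.index_of(pos)  # must lie in the register

    @property
    def dna_count(self) -> int:
        n = 1
        for pos in self.variable_positions:
            n *= self.codon_choice[pos].size
        return n

    @property
    def protein_count(self) -> int:
        n = 1
        for pos in self.variable_positions:
            n *= len(self.codon_choice[pos].amino_acids())
        return n

    def allowed_sets(self) -> list[frozenset]:
        """Per-residue allowed amino-acid sets; fixed positions are singletons."""
        sets = []
        var = set(self.variable_positions)
        for i, aa in enumerate(self.template.sequence):
            pos = self.template.heptad_label(i)
            if pos in var:
                sets.append(self.codon_choice[pos].amino_acids())
            else:
                sets.append(frozenset(aa))
        return sets

    def membership_distance(self, sequence: str) -> int:
        """Number of residues falling outside the per-position encoded sets."""
        if len(sequence) != len(self.template):
            raise ValueError(
                f"length mismatch: {len(sequence)} vs template {len(self.template)}")
        return sum(aa not in allowed
                   for aa, allowed in zip(sequence, self.allowed_sets()))

    def contains(self, sequence: str) -> bool:
        return self.membership_distance(sequence) == 0

    def sample_members(self, n: int, seed: int) -> list[str]:
        """Uniform seeded sample of encoded protein sequences."""
        rng = np.random.default_rng(seed)
        choices = [sorted(s) for s in self.allowed_sets()]
        cols = [[c[i] for i in rng.integers(len(c), size=n)] for c in choices]
        return ["".join(row) for row in zip(*cols)]

    def enumerate_members(self):
        """Iterator over every encoded protein sequence (use only when small)."""
        for combo in itertools.product(*(sorted(s) for s in self.allowed_sets())):
            yield "".join(combo)

    def to_dict(self) -> dict:
        return {
            "template": self.template.to_dict(),
            "variable_positions": [str(p) for p in self.variable_positions],
            "codons": {str(p): str(self.codon_choice[p])
                       for p in self.variable_positions},
            "cap_dna": self.cap_dna,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LibraryDesign":
        positions = tuple(HeptadPosition.parse(p) for p in d["variable_positions"])
        codons = {p: DegenerateCodon(d["codons"][str(p)]) for p in positions}
        return cls(BH3Peptide.from_dict(d["template"]), positions, codons,
                   d.get("cap_dna"))


def write_design(design: LibraryDesign, path) -> None:
    with open(path, "w") as fh:
        json.dump(design.to_dict(), fh, indent=1)


def read_design(path) -> LibraryDesign:
    with open(path) as fh:
        return LibraryDesign.from_dict(json.load(fh))


def library_size(design: LibraryDesign) -> tuple[int, int]:
    """(DNA-level size, protein-level size) of the design."""
    return design.dna_count, design.protein_count


def membership(design: LibraryDesign, peptide) -> int:
    """Distance of a peptide to the library (0 = exact member)."""
    seq = peptide.sequence if isinstance(peptide, BH3Peptide) else peptide
    return design.membership_distance(seq)


# --- ILP optimizer --------------------------------------------------------

# distinct integer products of codon counts differ by >= ~1/product in log;
# products are bounded by the DNA cap, so this slack separates true ties from
# solver/floating-point noise without merging distinct objective values.
_LOG_SLACK = 5e-8


def _solve(c, A_eq_rows, n, extra_constraints, integrality=1):
    constraints = list(A_eq_rows) + list(extra_constraints)
    res = milp(c=c, constraints=constraints,
               integrality=np.full(n, integrality),
               bounds=(0, 1), options={"mip_rel_gap": 0})
    return res


def _pareto_candidates(codons, classification, pos):
    """Keep, for each allowed-residue count, the codon(s) that can matter.

    A codon is dominated if another candidate encodes at least as many
    allowed (preferred/required) residues with no more concrete codons.  One
    representative per (count, size) suffices for the optimum; equal pairs
    resolve to the lexicographically smallest codon so the downstream
    tie-break stays deterministic.
    """
    best = {}  # (count, size) -> codon
    for codon in sorted(codons, key=str):
        key = (classification.allowed_count(pos, codon), codon.size)
        best.setdefault(key, codon)
    items = sorted(best.items(), key=lambda kv: (-kv[0][0], kv[0][1], str(kv[1])))
    front = []
    for (cnt, size), codon in items:
        if any(c2 >= cnt and s2 <= size for (c2, s2), _ in front):
            continue
        front.append(((cnt, size), codon))
    return [codon for _, codon in front]


def optimize_library(template: BH3Peptide, candidates_per_position: dict,
                     classification: ResidueClassification,
                     cap_dna: int) -> LibraryDesign:
    """Choose one codon per variable position by integer linear programming.

    Maximizes the number of library members composed entirely of
    preferred/required residues — the product over positions of the count of
    allowed amino acids encoded, linearized as a sum of logs over binary
    codon-selection variables — subject to the DNA-level size cap (also a
    product, hence a linear log constraint).  Ties are broken toward smaller
    DNA size, then lexicographically smallest codon per position in scan
    order, via sequential restricted solves.  Dominated candidates (fewer
    allowed residues at no smaller DNA size) are pruned before the solve;
    this cannot change the optimum or the tie-broken choice.
    """
    positions = tuple(candidates_per_position)
    for pos in positions:
        if not candidates_per_position[pos]:
            raise InfeasibleDesignError(f"no admissible codon at position {pos}")

    idx = []  # flat var index -> (position, codon)
    reduced = {}
    for pos in positions:
        reduced[pos] = _pareto_candidates(candidates_per_position[pos],
                                          classification, pos)
        for codon in sorted(reduced[pos], key=str):
            idx.append((pos, codon))
    n = len(idx)

    obj = np.empty(n)
    dna_log = np.empty(n)
    for j, (pos, codon) in enumerate(idx):
        cnt = classification.allowed_count(pos, codon)
        obj[j] = math.log(cnt) if cnt > 0 else -1e6  # zero allowed residues
        dna_log[j] = math.log(codon.size)

    # exactly one codon per position
    eq_rows = []
    for pos in positions:
        row = np.array([1.0 if p == pos else 0.0 for p, _ in idx])
        eq_rows.append(LinearConstraint(row, 1, 1))
    cap_con = LinearConstraint(dna_log, -np.inf, math.log(cap_dna) + _LOG_SLACK)

    res = _solve(-obj, eq_rows, n, [cap_con])
    if not res.success:
        minimal = 1
        for pos in positions:
            minimal *= min(c.size for c in candidates_per_position[pos])
        raise InfeasibleDesignError(
            f"no codon combination fits the cap of {cap_dna} DNA sequences; "
            f"minimal achievable DNA size is {minimal}")
    v_star = float(obj @ np.round(res.x))

    # tie-break 1: minimal DNA size at (numerically) equal objective
    obj_con = LinearConstraint(obj, v_star - _LOG_SLACK, np.inf)
    res2 = _solve(dna_log, eq_rows, n, [cap_con, obj_con])
    d_star = float(dna_log @ np.round(res2.x))
    dna_con = LinearConstraint(dna_log, -np.inf, d_star + _LOG_SLACK)

    # tie-break 2: lexicographically smallest codon per position, in order
    fixed: dict = {}
    for pos in positions:
        for codon in sorted(reduced[pos], key=str):
            trial = dict(fixed)
            trial[pos] = codon
            fix_rows = []
            for p, c in trial.items():
                row = np.array([1.0 if (pp == p and cc == c) else 0.0
                                for pp, cc in idx])
                fix_rows.append(LinearConstraint(row, 1, 1))
            r = _solve(np.zeros(n), eq_rows, n, [cap_con, obj_con, dna_con] + fix_rows)
            if r.success:
                fixed = trial
                break
        else:  # pragma: no cover - tie-break must always find the incumbent
            raise RuntimeError(f"tie-breaking failed at position {pos}")

    design = LibraryDesign(template, positions, fixed, cap_dna)
    if design.dna_count > cap_dna:  # exact integer check of the log constraint
        raise InfeasibleDesignError(
            f"optimizer returned DNA size {design.dna_count} > cap {cap_dna}")
    return design


def all_preferred_count(design: LibraryDesign,
                        classification: ResidueClassification) -> int:
    """Members composed entirely of preferred/required residues (the ILP
    objective, recomputed by direct integer counting on the design)."""
    n = 1
    for pos in design.variable_positions:
        n *= classification.allowed_count(pos, design.codon_choice[pos])
    return n


# --- library characterization --------------------------------------------

def library_score_summary(design: LibraryDesign, target_model: ScoringModel,
                          offtarget_models, reference_peptide: BH3Peptide,
                          sample_size: int, seed: int,
                          bgs: dict | None = None) -> dict:
    """Score/specificity distributions over library members.

    Enumerates the library when ``protein_count <= sample_size``, otherwise
    draws a seeded uniform sample.  Reports the fraction of members scoring
    at least as well as the reference and the fraction more selective than
    the reference (against each off-target), with binomial standard errors
    when sampled.
    """
    if design.protein_count <= sample_size:
        seqs = list(design.enumerate_members())
        sampled = False
    else:
        seqs = design.sample_members(sample_size, seed)
        sampled = True
    peps = [BH3Peptide(f"m{i}", s, design.template.register_start)
            for i, s in enumerate(seqs)]

    scores = np.array([score_peptide(target_model, p) for p in peps])
    ref_score = score_peptide(target_model, reference_peptide)
    out = {
        "n": len(seqs),
        "sampled": sampled,
        "scores": scores,
        "reference_score": ref_score,
        "fraction_ge_reference": float((scores >= ref_score).mean()),
        "specificity": {},
        "fraction_more_selective": {},
    }
    if sampled:
        f = out["fraction_ge_reference"]
        out["fraction_ge_reference_se"] = math.sqrt(f * (1 - f) / len(seqs))
    for o in offtarget_models:
        spec = np.array([specificity_score(target_model, o, p, bgs) for p in peps])
        ref_spec = specificity_score(target_model, o, reference_peptide, bgs)
        key = o.receptor
        out["specificity"][key] = spec
        out["fraction_more_selective"][key] = float((spec > ref_spec).mean())
    return out
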