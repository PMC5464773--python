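"""Ground-truth-annotated synthetic inputs for every pipeline stage.

The generators emulate the statistical structure of the real study inputs:

* paralog scoring matrices whose scores over random peptides show a
  controlled cross-receptor Pearson correlation (the strong correlation
  between predicted affinities for different Bcl-2 paralogs is the central
  obstacle the design procedure works against);
* multi-round sort pools in which library members are resampled with
  selection weights tied to a latent binding score, written as barcoded
  paired-end FASTQ with injected base-call errors and a two-state
  (good/bad-cycle) Phred profile;
* competition-polarization titrations and exponential crosslinking time
  courses with Gaussian readout noise.

Every generator is bit-reproducible under a fixed seed and records enough
ground truth to score any downstream stage without re-deriving it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import (CompetitionCurve, KineticsTimeCourse,
                      competitive_fraction_bound, readout_from_fraction)
from .core import (AMINO_ACIDS, GENETIC_CODE, BH3Peptide, DegenerateCodon,
                   HeptadPosition, PUMA_BH3, reverse_complement)
from .deepseq import ReadPair, write_fastq_pairs
from .libdesign import LibraryDesign
from .scoring import (BackgroundDistribution, ScoringModel, build_background,
                      normalize_pssm, score_peptide)


@dataclass
class GeneratorConfig:
    """Knobs of the sort-series simulator.

    depth is reads per round (>= 1000 for stable fractions);
    selection_strength is the logistic slope tying the latent binding score
    to survival; sub_rate is the per-base substitution error rate;
    bad_cycle_rate drives the two-state quality model.
    """

    seed: int = 0
    paralog_correlation: float = 0.8
    n_rounds: int = 4
    depth: int = 100_000
    selection_strength: float = 1.0
    sub_rate: float = 0.001
    bad_cycle_rate: float = 0.02
    contaminant_rate: float = 0.05
    members_per_library: int = 300
    quality_good: int = 38
    quality_bad: int = 11

    def __post_init__(self):
        if not -1 < self.paralog_correlation < 1:
            raise ValueError("|paralog_correlation| must be < 1")
        for r in (self.sub_rate, self.bad_cycle_rate, self.contaminant_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")


# --- scoring-model generator ---------------------------------------------

def _standardize(v):
    v = v - v.mean()
    return v / v.std()


def gen_scoring_models(seed: int, positions, receptors,
                       reference: BH3Peptide = PUMA_BH3,
                       kind: str = "pssm",
                       paralog_correlation: float = 0.8,
                       scale: float = 1.0,
                       background_n: int = 10_000):
    """Correlated per-position score matrices for a set of receptor paralogs.

    The first receptor's per-position score column is a standardized Gaussian
    vector z; every other receptor mixes z with an explicitly orthogonalized
    independent component, so the matrix-level correlation per position is
    the target exactly and the peptide-level correlation over random
    peptides deviates only by peptide-sampling noise.

    Returns ``(models, backgrounds)``; backgrounds (receptor -> distribution)
    are built from i.i.d. uniform-residue windows and are only attached for
    ``kind="potential"`` models.
    """
    if not -1 < paralog_correlation < 1:
        raise ValueError("|paralog_correlation| must be < 1")
    rng = np.random.default_rng(seed)
    positions = tuple(positions)
    rho = paralog_correlation
    n_aa = len(AMINO_ACIDS)

    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    columns = {rec: {} for rec in receptors}
    for pos in positions:
        z = _standardize(rng.normal(size=n_aa))
        columns[receptors[0]][pos] = z
        for rec in receptors[1:]:
            e = rng.normal(size=n_aa)
            e = e - (e @ z) / (z @ z) * z       # orthogonalize against z
            e = _standardize(e)
            columns[rec][pos] = rho * z + math.sqrt(1 - rho ** 2) * e
        # scanned positions of a viable motif tolerate substitution: pin the
        # wild-type residue to the 60th percentile of its column (the same
        # index swap on every receptor preserves the pairing, hence rho)
        i_ref = aa_index[reference.residue_at(pos)]
        j = int(np.argsort(columns[receptors[0]][pos])[int(0.6 * n_aa)])
        for rec in receptors:
            col = columns[rec][pos]
            col[i_ref], col[j] = col[j], col[i_ref]

    models = {}
    backgrounds = {}
    for rec in receptors:
        matrix = {(pos, aa): scale * columns[rec][pos][i]
                  for pos in positions for i, aa in enumerate(AMINO_ACIDS)}
        if kind == "pssm":
            matrix = normalize_pssm(matrix, reference, positions)
        model = ScoringModel(rec, kind, matrix, reference, positions)
        models[rec] = model
        if kind == "potential":
            backgrounds[rec] = build_background(
                model, None, background_n, seed=seed + 1)
    return models, backgrounds


def random_peptides(n: int, positions_or_length, seed: int,
                    register_start=None) -> list[BH3Peptide]:
    """Uniform random peptides over the canonical alphabet (for checks)."""
    if isinstance(positions_or_length, int):
        k = positions_or_length
        start = register_start or HeptadPosition(1, "f")
    else:
        pos = tuple(positions_or_length)
        k = pos[-1].rank - pos[0].rank + 1
        start = pos[0]
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    return [BH3Peptide(f"r{i}", "".join(rng.choice(aa, size=k)), start)
            for i in range(n)]


# --- sort-series generator ------------------------------------------------

#: per-amino-acid preferred codon for reverse translation of off-design residues
_AA_TO_CODON = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    _AA_TO_CODON.setdefault(_aa, _codon)

#: default pool barcodes (pairwise Hamming distance >= 2)
DEFAULT_BARCODES = ("ACGTAC", "CAGACG", "GTACGA", "TGCTGT", "ACACTG", "GTGTCA")

DEFAULT_ANCHOR5 = "GGTACCGGATCCGGTGGC"
DEFAULT_ANCHOR3 = "GGCGGCCGCGATTATAAAGATGATGATGATAAATAA"


def _reverse_translate(design: LibraryDesign, sequence: str, rng) -> str:
    """DNA for a peptide on the design's frame, preferring library codons."""
    var = {p: design.codon_choice[p] for p in design.variable_positions}
    out = []
    for i, aa in enumerate(sequence):
        pos = design.template.heptad_label(i)
        codon = None
        if pos in var:
            options = sorted(c for c in var[pos].codons() if GENETIC_CODE[c] == aa)
            if options:
                codon = options[rng.integers(len(options))]
        if codon is None:
            codon = _AA_TO_CODON[aa]
        out.append(codon)
    return "".join(out)


def _phred_batch(m, n, rng, cfg: GeneratorConfig):
    """Two-state (good/bad cycle) quality model, vectorized over m reads.

    The bad state is sticky (escape probability 0.3 per cycle), so low-quality
    stretches span several bases, as on a real sequencer.
    """
    quals = np.empty((m, n), dtype=np.int64)
    bad = rng.random(m) < cfg.bad_cycle_rate
    for i in range(n):
        base_q = np.where(bad, cfg.quality_bad, cfg.quality_good)
        quals[:, i] = np.clip(base_q + rng.integers(-2, 3, size=m), 2, 41)
        u = rng.random(m)
        bad = np.where(bad, u >= 0.3, u < cfg.bad_cycle_rate)
    return quals


def _inject_errors(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    bases = "ACGT"
    out = list(seq)
    for i in rng.choice(len(seq), size=k, replace=False):
        alt = [b for b in bases if b != out[i]]
        out[i] = alt[rng.integers(3)]
    return "".join(out)


def gen_sort_series(designs: dict, target_model: ScoringModel,
                    config: GeneratorConfig, outdir,
                    read_length: int = 75,
                    barcodes: dict | None = None):
    """Simulate a multi-round FACS sort series and write barcoded FASTQ.

    ``designs`` maps library label -> LibraryDesign (the first is the focal
    library only by convention; selection acts through ``target_model``
    scores, not labels).  Round 0 is a uniform multinomial over a seeded
    sample of members from every design plus off-design contaminants; each
    later round resamples with weights proportional to
    ``logistic(selection_strength * (score - median score))``.

    All rounds are written into one multiplexed FASTQ pair (forward mate
    starts with the round's pool barcode), plus a barcode table TSV and a
    ground-truth count table per round.  Returns the run directory paths
    and the truth table as a DataFrame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    labels = list(designs)
    if barcodes is None:
        round_names = ["naive"] + [f"FL{i + 1}" for i in range(config.n_rounds)]
        barcodes = {name: DEFAULT_BARCODES[i % len(DEFAULT_BARCODES)]
                    for i, name in enumerate(round_names)}
    round_names = list(barcodes)

    # unique peptide pool with true library-of-origin labels
    pool_seqs, pool_labels = [], []
    seen = set()
    for lab in labels:
        for s in designs[lab].sample_members(config.members_per_library,
                                             int(rng.integers(2 ** 31))):
            if s not in seen:
                seen.add(s)
                pool_seqs.append(s)
                pool_labels.append(lab)
    # contaminants: single random substitutions of members (PCR/synthesis noise)
    n_cont = int(round(config.contaminant_rate * len(pool_seqs)))
    aa = list(AMINO_ACIDS)
    for _ in range(n_cont):
        src = pool_seqs[rng.integers(len(pool_seqs))]
        i = int(rng.integers(len(src)))
        sub = aa[rng.integers(20)]
        mut = src[:i] + sub + src[i + 1:]
        if mut not in seen:
            seen.add(mut)
            pool_seqs.append(mut)
            pool_labels.append("contaminant")

    template = next(iter(designs.values())).template
    peps = [BH3Peptide(f"p{i}", s, template.register_start)
            for i, s in enumerate(pool_seqs)]
    scores = np.array([score_peptide(target_model, p) for p in peps])
    s0 = float(np.median(scores))
    weights = 1.0 / (1.0 + np.exp(-config.selection_strength * (scores - s0)))

    # fixed DNA per unique peptide so error-free reads are deterministic
    first_design = next(iter(designs.values()))
    inserts = [_reverse_translate(first_design, s, rng) for s in pool_seqs]

    probs = np.full(len(pool_seqs), 1.0 / len(pool_seqs))
    truth_rows = []
    all_reads = []
    counts_by_round = {}
    for r, name in enumerate(round_names):
        counts = rng.multinomial(config.depth, probs)
        counts_by_round[name] = counts
        bc = barcodes[name]
        for i, c in enumerate(counts):
            if c:
                truth_rows.append({"round": name, "peptide": pool_seqs[i],
                                   "label": pool_labels[i], "count": int(c),
                                   "score": float(scores[i])})
        round_reads = []
        for i in np.nonzero(counts)[0]:
            amplicon = bc + DEFAULT_ANCHOR5 + inserts[i] + DEFAULT_ANCHOR3
            for j in range(counts[i]):
                obs = _inject_errors(amplicon, rng, config.sub_rate)
                fwd = obs[:read_length]
                rev_src = obs[-read_length:] if len(obs) >= read_length else obs
                rev = reverse_complement(rev_src)
                round_reads.append((f"{name}:{i}:{j}", fwd, rev))
        fq = _phred_batch(len(round_reads), read_length, rng, config)
        rq = _phred_batch(len(round_reads), read_length, rng, config)
        for (rid, fwd, rev), q1, q2 in zip(round_reads, fq, rq):
            all_reads.append(ReadPair(rid, fwd, tuple(q1[:len(fwd)]),
                                      rev, tuple(q2[:len(rev)])))
        # selection for the next round
        p = probs * weights
        probs = p / p.sum()

    # deterministic shuffle so rounds are interleaved as on a real lane
    order = rng.permutation(len(all_reads))
    all_reads = [all_reads[i] for i in order]

    fwd_path = outdir / "reads_R1.fastq"
    rev_path = outdir / "reads_R2.fastq"
    write_fastq_pairs(all_reads, fwd_path, rev_path)
    bc_path = outdir / "barcodes.tsv"
    pd.DataFrame({"pool": round_names,
                  "barcode": [barcodes[n] for n in round_names]}
                 ).to_csv(bc_path, sep="\t", index=False)
    truth = pd.DataFrame(truth_rows)
    truth_path = outdir / "ground_truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    meta = {
        "amplicon_length": len(barcodes[round_names[0]]) + len(DEFAULT_ANCHOR5)
        + len(inserts[0]) + len(DEFAULT_ANCHOR3),
        "insert_length": len(inserts[0]),
        "read_length": read_length,
        "anchor5": DEFAULT_ANCHOR5,
        "anchor3": DEFAULT_ANCHOR3,
        "rounds": round_names,
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return {"fwd": fwd_path, "rev": rev_path, "barcodes": bc_path,
            "truth": truth_path, "meta": meta, "truth_frame": truth}


# --- titration / time-course generators -----------------------------------

def gen_fp_curve(R_T: float, L_T: float, Kd_L: float, Ki: float, doses,
                 noise_sd: float, seed: int,
                 readout_free: float = 0.05,
                 readout_bound: float = 0.25) -> CompetitionCurve:
    """Noisy competition-polarization titration from the exact forward model."""
    doses = np.asarray(doses, float)
    rng = np.random.default_rng(seed)
    f = competitive_fraction_bound(R_T, L_T, Kd_L, doses, Ki)
    y = readout_from_fraction(f, readout_free, readout_bound)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(doses))
    return CompetitionCurve(R_T, L_T, Kd_L, doses, y)


#: gel-shift sampling grid (minutes)
GELSHIFT_TIMES = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0)


def gen_timecourse(C: float, k: float, times=GELSHIFT_TIMES,
                   noise_sd: float = 0.0, seed: int = 0) -> KineticsTimeCourse:
    """Noisy y = C*(1 - exp(-k t)) crosslinking time course."""
    if k <= 0:
        raise ValueError("rate k must be > 0")
    t = np.asarray(times, float)
    rng = np.random.default_rng(seed)
    y = C * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    return KineticsTimeCourse(t, y)


def gen_depolarization_plate(doses, ec50: float, hill: float, times,
                             noise_sd: float, seed: int):
    """JC-1 fluorescence series per dose plus DMSO/FCCP control wells.

    Each well's fluorescence decays from the DMSO trace toward the FCCP
    trace by the logistic depolarization fraction at its dose; the true
    percent depolarization equals that fraction times 100.
    """
    t = np.asarray(times, float)
    rng = np.random.default_rng(seed)
    dmso = 1000.0 + 0.0 * t
    fccp = 1000.0 * np.exp(-t / (t[-1] / 3.0))
    wells = {}
    for d in doses:
        frac = 1.0 / (1.0 + (ec50 / d) ** hill)
        series = dmso - frac * (dmso - fccp)
        if noise_sd > 0:
            series = series + rng.normal(0.0, noise_sd, size=len(t))
        wells[d] = series
    return t, wells, dmso, fccp
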