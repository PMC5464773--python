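"""Sort-seq read processing: from multiplexed paired-end amplicon reads to
filtered peptide counts, library assignments and enrichment trajectories.

Stages (each conserves read accounting — kept + every failure category
equals reads in):

1. demultiplex by exact pool barcode with a strict per-base Phred filter;
2. merge mate pairs anchored by the known amplicon length, resolving
   disagreements toward the higher-quality base;
3. locate the construct's flanking anchors, check frame and stops, translate;
4. drop peptides observed fewer than ``min_count`` times;
5. assign each peptide to the design library within one mutation, or label
   it ambiguous/other.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import AMINO_ACIDS, reverse_complement, translate
from .libdesign import LibraryDesign


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with per-base Phred qualities (integers)."""

    id: str
    fwd_seq: str
    fwd_qual: tuple
    rev_seq: str
    rev_qual: tuple

    def __post_init__(self):
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


@dataclass
class ConstructTemplate:
    """Fixed flanks and reading frame of the display-cassette amplicon."""

    anchor5: str
    anchor3: str
    insert_length: int | None = None  # nt, optional extra check


@dataclass
class SortPool:
    """Filtered, translated, counted peptides for one sort round."""

    round_label: str
    counts: dict               # peptide -> read count
    assignments: dict = field(default_factory=dict)  # peptide -> label
    provenance: dict = field(default_factory=dict)   # filter statistics


# --- FASTQ I/O ------------------------------------------------------------

def _open(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_fastq_pairs(fwd_path, rev_path) -> list[ReadPair]:
    """Read mate FASTQ files (Phred+33, gzip-transparent) into ReadPairs."""
    pairs = []
    with _open(fwd_path) as fh1, _open(rev_path) as fh2:
        for r1, r2 in zip(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq")):
            if r1.id != r2.id:
                raise ValueError(f"mate id mismatch: {r1.id} vs {r2.id}")
            pairs.append(ReadPair(
                r1.id, str(r1.seq), tuple(r1.letter_annotations["phred_quality"]),
                str(r2.seq), tuple(r2.letter_annotations["phred_quality"])))
    return pairs


def write_fastq_pairs(pairs, fwd_path, rev_path) -> None:
    with _open(fwd_path, "wt") as fh1, _open(rev_path, "wt") as fh2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.fwd_qual)
            q2 = "".join(chr(q + 33) for q in p.rev_qual)
            fh1.write(f"@{p.id}\n{p.fwd_seq}\n+\n{q1}\n")
            fh2.write(f"@{p.id}\n{p.rev_seq}\n+\n{q2}\n")


# --- demultiplexing -------------------------------------------------------

def validate_barcode_table(barcode_table: dict) -> None:
    """Barcodes must be same-length and pairwise Hamming distance >= 2."""
    items = list(barcode_table.items())
    lengths = {len(b) for _, b in items}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            d = sum(a != b for a, b in zip(items[i][1], items[j][1]))
            if d < 2:
                raise ValueError(
                    f"barcodes {items[i][0]} and {items[j][0]} differ by {d} < 2 bases")


def demultiplex_and_filter(readpairs, barcode_table: dict,
                           min_phred: int = 20):
    """Split reads by pool barcode (leading bases of the forward read).

    A read is kept iff its barcode matches a table entry exactly and every
    barcode base has quality strictly greater than ``min_phred``.
    Returns ``(pools, stats)`` where pools maps pool name to kept ReadPairs
    (barcode trimmed off the forward mate) and stats conserves accounting.
    """
    validate_barcode_table(barcode_table)
    blen = len(next(iter(barcode_table.values())))
    by_barcode = {b: name for name, b in barcode_table.items()}
    pools = {name: [] for name in barcode_table}
    stats = Counter(reads_in=len(readpairs), kept=0,
                    barcode_mismatch=0, barcode_low_quality=0)
    for pair in readpairs:
        bc = pair.fwd_seq[:blen]
        if bc not in by_barcode:
            stats["barcode_mismatch"] += 1
            continue
        if any(q <= min_phred for q in pair.fwd_qual[:blen]):
            stats["barcode_low_quality"] += 1
            continue
        trimmed = ReadPair(pair.id, pair.fwd_seq[blen:], pair.fwd_qual[blen:],
                           pair.rev_seq, pair.rev_qual)
        pools[by_barcode[bc]].append(trimmed)
        stats["kept"] += 1
    return pools, dict(stats)


# --- pair merging ---------------------------------------------------------

MIN_OVERLAP = 10


def merge_pair(pair: ReadPair, expected_amplicon_length: int):
    """Merge mates into a consensus of the known amplicon length.

    The reverse mate is reverse-complemented and placed at the amplicon 3'
    end; the overlap is therefore fixed by the expected length rather than
    searched.  Agreeing bases pass through; disagreements take the
    higher-quality base; an equal-quality disagreement fails the merge.

    Returns ``(consensus or None, reason)`` with reason ``"ok"`` on success.
    """
    L = expected_amplicon_length
    nf, nr = len(pair.fwd_seq), len(pair.rev_seq)
    overlap = nf + nr - L
    if overlap < MIN_OVERLAP:
        return None, "overlap-too-short"
    if overlap > min(nf, nr):
        return None, "overlap-too-long"
    rseq = reverse_complement(pair.rev_seq)
    rqual = pair.rev_qual[::-1]
    roff = L - nr  # amplicon coordinate where the reverse mate starts
    out = []
    for i in range(L):
        in_f = i < nf
        in_r = i >= roff
        if in_f and not in_r:
            out.append(pair.fwd_seq[i])
        elif in_r and not in_f:
            out.append(rseq[i - roff])
        else:
            bf, qf = pair.fwd_seq[i], pair.fwd_qual[i]
            br, qr = rseq[i - roff], rqual[i - roff]
            if bf == br:
                out.append(bf)
            elif qf > qr:
                out.append(bf)
            elif qr > qf:
                out.append(br)
            else:
                return None, "ambiguous-disagreement"
    return "".join(out), "ok"


# --- peptide extraction ---------------------------------------------------

def extract_peptide(consensus: str, construct: ConstructTemplate):
    """Locate the construct anchors and translate the in-frame insert.

    Returns ``(peptide or None, reason)``; failure reasons are
    ``anchor5-not-found``, ``anchor3-not-found``, ``wrong-insert-length``,
    ``frameshift`` and ``internal-stop``.
    """
    i = consensus.find(construct.anchor5)
    if i < 0:
        return None, "anchor5-not-found"
    start = i + len(construct.anchor5)
    j = consensus.find(construct.anchor3, start)
    if j < 0:
        return None, "anchor3-not-found"
    insert = consensus[start:j]
    if construct.insert_length is not None and len(insert) != construct.insert_length:
        return None, "wrong-insert-length"
    if len(insert) % 3:
        return None, "frameshift"
    pep = translate(insert)
    if "*" in pep:
        return None, "internal-stop"
    return pep, "ok"


# --- counting and filtering ----------------------------------------------

def count_filter(counts: dict, min_count: int = 20):
    """Drop peptides observed fewer than ``min_count`` times.

    Returns ``(filtered counts, removed read mass)``.
    """
    kept = {pep: c for pep, c in counts.items() if c >= min_count}
    removed = sum(counts.values()) - sum(kept.values())
    return kept, removed


# --- library assignment ---------------------------------------------------

def assign_to_libraries(peptides, designs: dict, max_distance: int = 1):
    """Label each peptide by its originating design library.

    ``designs`` maps label -> LibraryDesign.  A peptide gets the label of
    the unique design at minimal membership distance <= ``max_distance``;
    a distance tie across designs is labelled ``"ambiguous"``; no design in
    range (or a length mismatch) gives ``"other"``.
    Returns ``(labels dict, warnings dict)``.
    """
    labels = {}
    warnings = Counter()
    for pep in peptides:
        dists = {}
        for name, design in designs.items():
            try:
                dists[name] = design.membership_distance(pep)
            except ValueError:
                warnings["length_mismatch"] += 1
        in_range = {n: d for n, d in dists.items() if d <= max_distance}
        if not in_range:
            labels[pep] = "other"
            continue
        dmin = min(in_range.values())
        best = [n for n, d in in_range.items() if d == dmin]
        labels[pep] = best[0] if len(best) == 1 else "ambiguous"
    return labels, dict(warnings)


# --- full per-pool pipeline ----------------------------------------------

def process_pool(round_label: str, readpairs, construct: ConstructTemplate,
                 amplicon_length: int, designs: dict | None = None,
                 min_count: int = 20, max_distance: int = 1) -> SortPool:
    """Merge, extract, count-filter and assign one demultiplexed pool."""
    stats = Counter(reads_in=len(readpairs))
    counts = Counter()
    for pair in readpairs:
        consensus, reason = merge_pair(pair, amplicon_length)
        if consensus is None:
            stats[f"merge:{reason}"] += 1
            continue
        pep, reason = extract_peptide(consensus, construct)
        if pep is None:
            stats[f"extract:{reason}"] += 1
            continue
        counts[pep] += 1
        stats["translated"] += 1
    kept, removed = count_filter(dict(counts), min_count)
    stats["count_filtered_reads"] = removed
    stats["kept_reads"] = sum(kept.values())
    assignments = {}
    if designs:
        assignments, warn = assign_to_libraries(kept, designs, max_distance)
        for k, v in warn.items():
            stats[f"assign:{k}"] = v
    return SortPool(round_label, kept, assignments, dict(stats))


# --- enrichment and composition ------------------------------------------

def enrichment_trajectory(pools) -> pd.DataFrame:
    """Per-round composition by assignment label.

    Returns a tidy DataFrame with columns (round, label, read_fraction,
    unique_fraction); fractions sum to 1 within each round.
    """
    if len(pools) < 2:
        raise ValueError("need at least 2 pools for a trajectory")
    rows = []
    for pool in pools:
        total_reads = sum(pool.counts.values())
        total_unique = len(pool.counts)
        if total_reads == 0:
            raise ValueError(f"pool {pool.round_label} is empty")
        by_label_reads = Counter()
        by_label_unique = Counter()
        for pep, c in pool.counts.items():
            lab = pool.assignments.get(pep, "other")
            by_label_reads[lab] += c
            by_label_unique[lab] += 1
        for lab in sorted(set(by_label_reads)):
            rows.append({
                "round": pool.round_label,
                "label": lab,
                "read_fraction": by_label_reads[lab] / total_reads,
                "unique_fraction": by_label_unique[lab] / total_unique,
            })
    return pd.DataFrame(rows)


def logo_frequencies(peptides, weights=None) -> pd.DataFrame:
    """Position x amino-acid frequency matrix (rows sum to 1).

    Default weighting counts each unique peptide once; pass read counts in
    ``weights`` (same order as ``peptides``) for read-weighted frequencies.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides")
    n = len(peptides[0])
    if any(len(p) != n for p in peptides):
        raise ValueError("mixed peptide lengths")
    if weights is None:
        weights = np.ones(len(peptides))
    weights = np.asarray(weights, float)
    mat = pd.DataFrame(0.0, index=range(n), columns=list(AMINO_ACIDS))
    for pep, w in zip(peptides, weights):
        for i, aa in enumerate(pep):
            mat.loc[i, aa] += w
    return mat.div(mat.sum(axis=1), axis=0)


def nondesigned_fraction(pool: SortPool, design: LibraryDesign):
    """Fraction of unique peptides off-design (distance >= 1), with SE."""
    uniques = list(pool.counts)
    if not uniques:
        return 0.0, 0.0
    n_off = sum(design.membership_distance(p) >= 1 for p in uniques
                if len(p) == len(design.template))
    n = len(uniques)
    f = n_off / n
    return f, float(np.sqrt(f * (1 - f) / n))
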