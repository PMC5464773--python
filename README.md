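# bh3design

Design and analysis of degenerate-codon BH3 peptide libraries targeting a
single anti-apoptotic Bcl-2 paralog.

Anti-apoptotic Bcl-2 family proteins (Bcl-2, Bcl-x_L, Bcl-w, Mcl-1, Bfl-1)
bind short α-helical BH3 motifs from pro-apoptotic partners. Selective BH3
peptide inhibitors of one paralog — for example Bfl-1, implicated in
melanoma and chemoresistant leukemia — are valuable cell-profiling reagents
and therapeutic leads, but native BH3 motifs are promiscuous and the
sequence space of a 23-mer (20²³ > 10²⁹) cannot be screened exhaustively.
This package implements the computational workflow around such a campaign:
focusing a combinatorial library of ~10⁷ candidates with scoring models,
analyzing the deep-sequenced FACS sort rounds, and fitting the downstream
binding and functional assays. It is aimed at protein engineers running
yeast-display specificity screens.

## What it computes

**Scoring and specificity** (`bh3design.scoring`). Peptide variants are
scored additively over heptad-labeled helix positions p,

    S(x) = Σ_p M[p, x_p],

with two model kinds: a PSSM normalized so the wild-type residue scores 0 at
every position, and a statistical-potential score compared as a z-score
against a background of random length-matched windows. Specificity for a
target paralog over an off-target is the difference of scores (PSSM) or of
z-scores (potential).

**Library design** (`bh3design.libdesign`). Substitutions are classified
*preferred* (above the median single-mutant score, or large specificity),
*disruptive* (more than 1 SD worse than wild type) or *required* (manual).
Candidate degenerate codons per variable position must encode all required
residues, no disruptive residue, no stop, and more than three distinct amino
acids. One codon per position is then chosen by integer linear programming to
maximize the number of library members built entirely from preferred
residues, Π_p n_pref(c_p), linearized as Σ_p log n_pref(c_p) over binary
selection variables, subject to Π_p n_DNA(c_p) ≤ 10⁷.

**Sort-seq analysis** (`bh3design.deepseq`). Multiplexed paired-end amplicon
reads are demultiplexed by pool barcode (every barcode base Phred > 20),
merged at the known amplicon length with quality-resolved disagreements,
translated between the construct's flanking anchors, filtered at ≥ 20
observations, and assigned to the design library within one amino-acid
mutation. Per-round enrichment fractions and position frequency (logo)
matrices follow.

**Binding analytics** (`bh3design.binding`). The competition
fluorescence-polarization model is the exact three-species equilibrium (one
receptor, fluorescent tracer, unlabeled competitor): the mass balance yields
a cubic in free receptor solved in closed trigonometric form, and K_i is fit
directly — no Cheng–Prusoff approximation. Also: crosslinking kinetics
y = C·(1 − e^(−kt)) with half-life ln 2/k, JC-1 depolarization AUC
normalized between DMSO (0%) and FCCP (100%) controls, four-parameter
logistic EC₅₀, and cytochrome-c release
1 − (MFI_sample − MFI_alam)/(MFI_DMSO − MFI_alam).

**Synthetic data** (`bh3design.synthetic`). Seeded generators produce
paralog scoring matrices with a controlled cross-receptor score correlation,
multi-round sort pools with selection tied to a latent binding score
(written as barcoded FASTQ with injected errors and a two-state quality
profile, plus ground-truth sidecars), and noisy titrations/time courses.

## Worked example

The published Bfl-1-targeted PUMA library uses one degenerate codon at each
of seven variable heptad positions (2a, 2e, 2g, 3d, 3g, 4a, 4e):

```
>>> python examples/01_library_size_audit.py
position  codon  DNA-codons  amino-acids  encoded set
      2a    VHA           9            9  AEIKLPQTV
      2e    KVT           6            6  ACDGSY
      2g    NDC          12           12  CDFGHILNRSVY
      3d    NBC          12           11  ACFGILPRSTV
      3g    VWK          12           10  DEHIKLMNQV
      4a    NHT          12           12  ADFHILNPSTVY
      4e    NYT           8            8  AFILPSTV

DNA-level size:     8,957,952  (cap 10,000,000; OK)
protein-level size: 6,842,880  (~6.84 million unique peptides)
```

The protein-level size 9·6·12·11·10·12·8 = 6,842,880 is the number of
distinct 23-mer peptides the display library can present; the DNA-level
size stays under the 10⁷ oligo-synthesis cap. `examples/04_binding_analytics.py`
fits a synthetic titration at the assay conditions (50 nM receptor, 25 nM
tracer, competitor to 10 μM) and recovers K_i = 14.79 nM from a generator
truth of 15 nM at realistic noise.

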