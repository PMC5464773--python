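"""Audit the Bfl-1-targeted PUMA library encoded by seven degenerate codons.

Expands each printed codon, then multiplies the per-position counts into the
DNA- and protein-level library sizes and checks the 1e7 DNA cap.
"""

from bh3design import PUMA_BFL1_DESIGN, expand_degenerate_codon, library_size

design = PUMA_BFL1_DESIGN
print("position  codon  DNA-codons  amino-acids  encoded set")
for pos in design.variable_positions:
    codon = design.codon_choice[pos]
    codons, aa_counts, stops = expand_degenerate_codon(codon)
    assert stops == 0
    print(f"{pos!s:>8}  {codon!s:>5}  {len(codons):>10}  {len(aa_counts):>11}"
          f"  {''.join(sorted(aa_counts))}")

dna, protein = library_size(design)
print(f"\nDNA-level size:     {dna:,}  (cap {design.cap_dna:,};"
      f" {'OK' if dna <= design.cap_dna else 'EXCEEDED'})")
print(f"protein-level size: {protein:,}  (~{protein/1e6:.2f} million unique peptides)")
print("\nEach sort round must oversample this diversity; the protein count is")
print("the number of distinct 23-mer variants the display library can show.")
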