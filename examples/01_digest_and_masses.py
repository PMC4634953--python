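"""Digest a collagen-like peptide region with trypsin/P and print peptide
masses with and without the modifications typical of ancient collagen."""

from paleocollagen import ModificationSet, mz_from_mass, peptide_mass, tryptic_digest

sequence = "GPAGPKGDRGEAGPAGPKGNDGAKGERGAPGPMGPR"

print("peptide            start  missed  [M]        [M+H]+")
for pep in tryptic_digest(sequence, max_missed=1):
    mass = peptide_mass(pep.sequence)
    print(f"{pep.sequence:<18s} {pep.start:>5d} {pep.missed_cleavages:>7d} "
          f"{mass:10.4f} {mz_from_mass(mass, 1):10.4f}")

hydroxylated = ModificationSet(n_oxidation=2)
base = peptide_mass("GPAGPK")
print(f"\nGPAGPK unmodified: {base:.4f} Da; "
      f"with 2 P/K hydroxylations (+15.994915 each): "
      f"{peptide_mass('GPAGPK', hydroxylated):.4f} Da")
print("Each line is one tryptic fragment; hydroxylation shifts, not cleavage,")
print("distinguish ancient collagen peptides from their database masses.")
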