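"""Putative annotation of feature m/z values by multi-adduct exact mass.

Cold-plasma ionization yields several adduct types per neutral molecule
([M+H]+, [M]+, [M-H]+, [M-OH]+, [M+NH4]+), so one observed m/z can match
many (compound, adduct) combinations; every match within 10 ppm is a
putative annotation.
"""

import breathomics as b

db = b.default_compound_db()  # synthetic stand-in for an HMDB/HBDB export

features = [59.0491, 69.0698, 87.0441, 137.1324]
hits = b.annotate(features, db, tol_ppm=10.0)

print(f"{len(hits)} putative annotations for {len(features)} features:")
for h in hits:
    print(f"  m/z {h.feature_mz:9.4f} -> {h.compound.name:<28s} {h.adduct.name:>9s} "
          f"theo {h.theoretical_mz:9.4f}  {h.ppm_error:+5.2f} ppm  ({h.compound.source_db})")
# ppm_error is the relative deviation between observed and theoretical
# m/z; annotation is putative because isomers share an exact mass.

# Formula arithmetic underneath: note the electron-mass correction.
print(f"\n[M+H]+ of C10H16  = {b.adduct_mz('C10H16', '[M+H]+'):.5f} "
      f"(rounds to 137.132 only because the electron mass is subtracted)")
print(f"neutral-loss ladder: O {b.monoisotopic_mass('O'):.3f}, "
      f"CH2 {b.monoisotopic_mass('CH2'):.3f}, H2 {b.monoisotopic_mass('H2'):.3f} Da")
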