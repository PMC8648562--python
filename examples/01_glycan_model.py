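"""Glycan compositions, canonical tree strings and modified saccharide units.

Builds a few glycans by hand, prints the reference oxonium (B-ion) masses
used as glycopeptide-diagnostic ions, and expands a small database with
ammonia-adducted hexoses (aH = Hex + NH3, the modified unit found on yeast
high-mannose and O-Man glycans).
"""

from glycofirst.glycan import (
    GlycanDB,
    oxonium_mz,
    parse_composition,
    parse_structure,
)

# --- compositions and the diagnostic oxonium ions --------------------------
for name in ("N(1)", "H(1)", "H(1)N(1)", "aH(1)"):
    comp = parse_composition(name)
    print(f"{name:10s} residue mass {comp.mass:9.4f} Da   oxonium {oxonium_mz(comp):8.3f} m/z")
# N(1) at 204.087 m/z is the default glycopeptide-diagnostic ion;
# 163.060 / 366.139 validate Hex-containing assignments;
# aH(1) at 180.087 is the signature of an ammonia-adducted hexose.

delta = parse_composition("F(2)").mass - parse_composition("A(1)").mass
print(f"\nFuc(2) - NeuAc(1) = {delta:.4f} Da  (a ~1 Da near-isobar: the reason")
print("co-identified NeuAc(1)/Fuc(2) precursors are chimera-filtered)\n")

# --- canonical tree strings -------------------------------------------------
core = parse_structure("(N(N(H(H)(H))))")  # chitobiose + trimannosyl core
print("trimannosyl core:", core.canonical_string(), "=", core.composition)

# --- modified-unit expansion ------------------------------------------------
db = GlycanDB.from_entries([core.canonical_string()], glyco_type="N")
expanded = db.expand_modified_units("H", "aH", max_per_glycan=2)
print(f"\nafter H->aH expansion (max 2 per glycan): {len(expanded.entries)} entries")
for e in expanded.entries:
    print("  ", e.structure.canonical_string(), "=", e.composition)
# note the branching vs terminal Hex substitutions stay distinct structures,
# while the two symmetric terminal positions collapse to one canonical string
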