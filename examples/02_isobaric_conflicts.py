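"""Modification masses and isobaric conflicts.

Prints the composition-derived monoisotopic deltas of the stock
modifications, then searches for pairs of modification (multi)sets whose
masses coincide.  The headline case: a mono-methylated lysine that also
receives a propionyl label carries exactly the mass of a butyrylated lysine
(both are C4H6O), so the two biologies become indistinguishable by mass.
"""

from histoscope import default_registry, find_isobaric_conflicts

registry = default_registry()

print(f"{'modification':16s} {'delta (Da)':>12s}  targets")
for spec in registry:
    targets = "".join(sorted(t for t in spec.targets if len(t) == 1))
    if "N-term" in spec.targets:
        targets += " +N-term"
    print(f"{spec.name:16s} {spec.delta_mass:12.5f}  {targets} ({spec.origin})")

print("\nExact-composition conflicts (multisets up to size 2):")
for c in find_isobaric_conflicts(registry, max_set_size=2, tolerance_da=0.001):
    if c.exact:
        print(f"  {c}")

print("\nNear-isobars within 0.05 Da (single modifications):")
for c in find_isobaric_conflicts(registry, max_set_size=1, tolerance_da=0.05):
    print(f"  {c}")

print("\nAn 'exact' conflict can never be resolved by mass accuracy alone;")
print("a near-isobar like trimethyl vs acetyl (36 mDa) needs ~high-res MS.")
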