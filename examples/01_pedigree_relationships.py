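"""Build a small pedigree and inspect additive relationships.

The additive relationship matrix A holds twice the kinship coefficient for
every pair: 0.5 for parent-offspring and full sibs, 0.25 for half sibs,
and a diagonal of 1 + F (inbreeding coefficient).
"""

from pedvar import additive_relationship, kinship, validate_pedigree

ped = validate_pedigree([
    ("sire1", "", ""), ("dam1", "", ""), ("dam2", "", ""),
    ("kid_a", "sire1", "dam1"),
    ("kid_b", "sire1", "dam1"),   # full sib of kid_a
    ("kid_c", "sire1", "dam2"),   # paternal half sib of kid_a
    ("inbred", "kid_a", "kid_b"),  # full-sib mating
])

A = additive_relationship(ped)
print("pedigree order:", ", ".join(ped.ids))
print(f"parent-offspring  a(sire1, kid_a) = {A.loc('sire1', 'kid_a'):.3f}")
print(f"full sibs         a(kid_a, kid_b) = {A.loc('kid_a', 'kid_b'):.3f}")
print(f"paternal half sibs a(kid_a, kid_c) = {A.loc('kid_a', 'kid_c'):.3f}")
print(f"inbred diagonal   a(inbred, inbred) = {A.loc('inbred', 'inbred'):.3f}"
      f"  (F = {A.inbreeding('inbred'):.3f})")
print(f"independent check: 2 x kinship(kid_a, kid_b) = "
      f"{2 * kinship(ped, 'kid_a', 'kid_b'):.3f}")
# The 0.5 / 0.25 entries are the textbook fractions of shared additive
# variance; the 1.25 diagonal shows the offspring of full sibs is 25% inbred.
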