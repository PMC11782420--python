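"""Parse LinearCode glycans and derive Oxford-style compositional tags.

A LinearCode string writes a glycan with the reducing end rightmost; the
compositional tag collapses structural isomers (same composition, different
arm) onto one name, which is how experimental glycoprofiles report species.
"""

from glycokin import parse_linear_code

codes = [
    "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",      # Man9GlcNAc2
    "GNb2Ma3(GNb2Ma6)Mb4GNb4(Fa6)GN",             # core-fucosylated biantennary
    "Ab4GNb2Ma3(GNb2Ma6)Mb4GNb4(Fa6)GN",          # galactose on the a1-3 arm
    "GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",          # galactose on the a1-6 arm
]

for code in codes:
    glycan = parse_linear_code(code)
    composition = ", ".join(f"{k}:{v}" for k, v in glycan.composition.items())
    print(f"{glycan.tag:<8} {composition:<40} {code}")

# The last two structures print the same tag (FA2G1): one compositional tag,
# two LinearCode isomorphs -- the many-to-one mapping that makes the
# tag -> network-node lookup return node *sets*.
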