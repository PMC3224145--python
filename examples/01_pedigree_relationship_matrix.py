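"""Build a numerator relationship matrix from a small pedigree.

The additive relationship matrix A (twice the kinship coefficient) is the
covariance structure of the polygenic effect in the animal model.  Diagonal
entries are 1 + F (F = inbreeding coefficient); full sibs share 0.5.
"""

import io

from dupgwas import build_nrm, read_pedigree, truncate_pedigree

PEDIGREE = """\
animal sire dam breed herd
S1 0 0 Angus h1
D1 0 0 Angus h1
D2 0 0 Angus h1
X  S1 D1 Angus h1
Y  S1 D1 Angus h1
Z  S1 D2 Angus h1
W  X  D2 Angus h1
"""

ped = read_pedigree(io.StringIO(PEDIGREE))
nrm = build_nrm(ped)

print("animals:", " ".join(nrm.animals))
for a, row in zip(nrm.animals, nrm.values):
    print(f"{a:>2}", " ".join(f"{v:5.3f}" for v in row))

print()
print("full sibs X,Y:        A =", nrm.loc("X", "Y"), "(expected 0.500)")
print("half sibs X,Z:        A =", nrm.loc("X", "Z"), "(expected 0.250)")
print("W with grandsire S1:  A =", nrm.loc("W", "S1"), "(expected 0.250)")

# truncation: ancestors beyond the requested generation depth become founders
trunc = truncate_pedigree(ped, depth=1, probands=["W"])
print()
print("depth-1 truncation above W keeps:", trunc.animals)
print("W's parents after truncation:", trunc.parents("W"))
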