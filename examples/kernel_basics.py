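"""Convolution tree kernels on two tiny parse trees.

Builds two bracketed trees that differ in one word, enumerates their shared
fragments explicitly, and shows that the dynamic program returns the same
counts.
"""

from lxre import KernelConfig, read_bracketed, tree_kernel
from lxre.kernel import enumerate_fragments

t1, t2 = read_bracketed("(S (A a) (B b))\n(S (A a) (B c))\n")

for variant in ("ST", "SST"):
    cfg = KernelConfig(variant, decay=1.0, normalize=False)
    print(f"{variant}: K(t1,t1) = {tree_kernel(t1, t1, cfg):g}   "
          f"K(t1,t2) = {tree_kernel(t1, t2, cfg):g}")
    frags1 = enumerate_fragments(t1, variant)
    frags2 = enumerate_fragments(t2, variant)
    shared = sorted(set(frags1) & set(frags2))
    print(f"  {variant} fragments of t1: {sorted(frags1)}")
    print(f"  shared with t2: {shared}")

print()
print("K(t1,t1) counts fragment pairs t1 shares with itself: every ST "
      "fragment is a complete subtree (3 of them), while SST also counts "
      "partially expanded fragments (6 in total).  The trees share only "
      "the fragments that avoid the differing word, so K(t1,t2) drops to "
      "1 (ST) and 3 (SST).")
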