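"""Scoring RNA secondary-structure potential with the Nussinov-style DP.

The fold score is the maximum total pair weight (GC=3, AU=2, GU=1, hairpin
loops >= 3 nt) over all nested pairings; its negation is the pseudo-energy
used to give synthetic 5'UTRs internally consistent folding energies.
"""

from ribostruct import fold_score

for seq in ("AAAA", "GGGAAACCC", "GCGCUUCGGCGC",
            "ACGUACGUACGUACGUACGU"):
    res = fold_score(seq)
    n_pairs = int((res.pairs >= 0).sum()) // 2
    print(f"{seq:24s} score {res.score:3d}  pseudo-energy {res.pseudo_energy:6.1f}"
          f"  pairs {n_pairs}")
print()
print("Hairpins of GC pairs score highest; an A-only sequence cannot pair.")
print("This is a combinatorial stand-in for thermodynamic folding: measured")
print("folding-energy tables for real transcriptomes are used unchanged.")
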