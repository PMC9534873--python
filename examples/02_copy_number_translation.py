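"""Translate structural-haplotype dosages into C4 copy-number dosages.

Copy-number channels are a linear map of haplotype dosages through the
composition table (gene content per haplotype).  Ambiguous haplotypes,
known only as isotype totals, are split long/short by the consensus that
~95% of C4A copies are long.
"""

import pandas as pd

from c4cn import compute_cn_dosages, decompose_long_short, load_composition

# explicit haplotype dosages for three individuals
haps = pd.DataFrame(
    {"AL-BL": [2.0, 1.0, 0.0], "AL-BS": [0.0, 1.0, 1.0], "BS": [0.0, 0.0, 1.0]},
    index=["ind1", "ind2", "ind3"],
)
cn = compute_cn_dosages(haps)
print("copy-number profile:")
print(cn.round(2).to_string())
# ind1 (two AL-BL chromosomes) carries 2 C4A + 2 C4B genes, all long,
# hence 4 HERV-K insertions; ind3 (AL-BS + BS) carries 1 C4A and 2 C4B
# genes but only one HERV-K.

# an ambiguous haplotype: one C4A, one C4B, one HERV-K
print("\nconsensus split of totals (C4A=1, C4B=1, HERV-K=1):")
print(dict(zip(["al", "as", "bl", "bs"], decompose_long_short(1, 1, 1))))
# the HERV-K copy is assigned to C4A with probability 0.95, giving
# fractional expected copy counts (0.95, 0.05, 0.05, 0.95)

# the same rule applied while loading a composition table of isotype totals
table = pd.DataFrame({"name": ["AL-BS?"], "c4a": [1], "c4b": [1], "hervk": [1]})
comp = load_composition(table)[0]
print(f"\nloaded composition {comp.name}: al={comp.al}, as={comp.as_}, "
      f"bl={comp.bl}, bs={comp.bs}")
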