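"""Delta notation and functional-group assignment.

Converts raw isotope ratios to the per-mil delta scale and looks up the
functional group of a few high-rank soil taxa.
"""

from isoniche import assign_functional_group, delta_from_ratios

VPDB = 0.0112372  # 13C/12C of the Vienna PeeDee Belemnite standard

ratio = 0.0111248  # a typical depleted animal-tissue carbon ratio
d13c = delta_from_ratios(ratio, VPDB)
print(f"13C/12C = {ratio} vs VPDB -> d13C = {d13c:.4f} permil")
# ~ -10 permil: the sample holds ~1% less 13C than the standard

for taxon in ["Collembola", "Araneae", "Lumbricina", "Coleoptera", "Mesotigmata"]:
    print(f"{taxon:>14s} -> {assign_functional_group(taxon)}")
# springtails are microbivores, spiders predators, earthworms
# detritivores; beetles span feeding modes ("mixed"); the last entry is
# a recognized spelling variant of Mesostigmata
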