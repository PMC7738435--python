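# Lineage keywords for taxonomy-based guild assignment.
# Matching is case-insensitive substring over the full SILVA lineage string,
# so family-level keywords (Syntrophaceae) and genus-level keywords
# (Smithella) both work. Edit or extend freely; sections must stay disjoint.
[syntrophs]
Syntrophomonas
Syntrophobacter
Pelotomaculum
Smithella
Syntrophorhabdus
Syntrophaceae
Syntrophus
Syntrophomonadaceae
Syntrophorhabdaceae
[methanogens]
Methanosaeta
Methanosarcina
Methanobacterium
Methanomassiliicoccus
Methanofastidiosum
Methanolinea
Methanospirillum
Methanoculleus
Methanoregula
Methanobrevibacter
Methanothrix
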