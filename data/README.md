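# Data

- `cycad_backbone.nwk` — genus-level backbone topology of the ten extant
  cycad genera, following the multi-locus molecular phylogeny of
  Salas-Leiva et al. (2013, Ann. Bot. 112:1263-1278): Cycadaceae
  (*Cycas*) sister to Zamiaceae (all other genera). Topology only, no
  branch lengths; the analyses estimate lengths from the morphological
  data.
- `study_matrix.nex` — *not distributed*. The 11-taxon x
  15-character leaf morphology/cuticle matrix scored for the extant
  genera plus the fossil *Dioonopsis* lives in a journal supplement and
  must be placed here by the user to run the real-data analysis. All
  tests and examples otherwise use synthetic matrices generated by
  `fossilplace.simulate`.
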