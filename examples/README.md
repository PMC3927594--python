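# Example motif files

Thermodynamic-matcher motifs in the `rfamforge` text DSL, usable with
`rfamforge tdm --motif <file> --db genomes.fa`.

* `asd_three_hairpins.motif` — three consecutive hairpins, each
  enforcing the anti-Shine-Dalgarno loop motif CCUCCUCCC in a 9-12 nt
  loop over a 4-8 bp stem (the SmelA075-style architecture; the
  four-hairpin variant is the same module `x4`).
* `gaugua_hairpin.motif` / `ggaugua_hairpin.motif` — a single hairpin
  enforcing the conserved SmelB053-style loop motif.  Published
  descriptions give the motif both as GAUGUA and as GGAUGUA; both
  variants are shipped and the choice is left to the user — the longer
  motif is the stricter matcher.
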