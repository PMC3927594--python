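# rfamforge

Construction of **RNA family models (RFMs)** for trans-encoded bacterial
small RNAs (sRNAs): starting from a single experimentally defined
transcript, collect homologous loci across related genomes, assess them
with sequence, structure, synteny and phylogeny evidence, and attach a
search model that finds further members.

Trans-encoded sRNAs regulate their targets by imperfect base pairing,
and their hallmark is that *secondary structure outlives sequence*:
stems accumulate compensatory substitutions while the fold (and often a
short loop motif, e.g. an anti-Shine-Dalgarno CCUCCUCCC) is conserved.
A plain sequence search therefore loses members exactly where the
interesting biology starts.  `rfamforge` implements the two
complementary family-model types used in this situation:

* **covariance models (CMs)** — profile stochastic context-free
  grammars over an alignment plus consensus structure, scoring joint
  sequence/structure conservation (CYK log-odds bits);
* **thermodynamic matchers (TDMs)** — constrained-folding scanners for
  an explicit structural motif, giving no weight to stem sequences but
  enforcing loop motifs, scored by folding energy.

Around these sit the full pipeline: word-seeded and semi-global
homology search with empirically calibrated Karlin–Altschul E-values
(stringent E < 10⁻⁵, ≤ 3 iterations), a Sankoff-style
sequence–structure alignment score *loc*, the structure conservation
index SCI = E_consensus / mean(E_single), *pointed shapes* (abstract
shape + hairpin centers (i+j)/2) as a fast structure-equality test, a
candidate funnel (0.33·loc(S,S) prefilter; auto-accept at
loc > 0.75·loc(S,S), SCI > 0.9, pointed-shape equality; flanking-gene
synteny at E ≤ 10⁻⁶; replicon/phylogeny plausibility; alignment outlier
pruning), CM refinement (best 50 hits, ≤ 3 cycles, 25%-of-max score
cutoff in the last), and microsynteny classification (types I–IV).

A first-class synthetic-data module generates the test bed: designed
multi-hairpin sRNA ancestors, homologs evolved with compensatory
substitutions, genomes with planted members, flanking marker genes,
shuffled decoys, and a truth table.  See `docs/methods.md` for the
models, defaults and their rationale.

## Worked example

```python
from rfamforge.synthetic import make_default_dataset
from rfamforge.cli import run_pipeline, recovery_stats, PipelineConfig

ds = make_default_dataset(seed=18)          # 3 families x 6 genomes
res = run_pipeline(ds.pivots, ds.genomes, ds.annotations, ds.taxonomy,
                   PipelineConfig())
print(res.report.to_string(index=False))
print(recovery_stats(res.families, ds.truth))
```

prints:

```
      family  members  genomes  max_copies_per_genome      sci microsynteny
RFM_SmelfamC        6        6                      1 2.506250            I
RFM_SmelfamA        6        6                      1 1.399351            I
RFM_SmelfamB        6        6                      1 1.838649            I
{'members_planted': 18, 'members_recovered': 18, 'member_recovery': 1.0,
 'decoys_planted': 18, 'decoys_discarded': 18, 'decoy_discard': 1.0}
```

Each family model lists one accepted member per genome (the planted
homolog) and complete microsynteny (type I: both flanking marker genes
conserved in every member).  The family SCI is 1 when the common
structure is exactly as stable as the individual folds; values above 1
indicate compensatory covariation, and under this package's covariance
bonus the most diverged (most covaried) family scores highest — famC
at divergence 0.4 reaches 2.5.  All 18 shuffled decoys were discarded
by the funnel.  The three families are planted at
divergences 0.1/0.25/0.4; the third carries a CCUCCUCCC loop motif in
all three hairpins and its diverged members are beyond the reach of the
round-1 sequence search — they enter through the thermodynamic-matcher
route plus synteny evidence, which is the complementarity the two model
types exist for.

The same stages are scriptable from the shell:

```bash
rfamforge simulate --families 3 --genomes 6 --seed 18 --out fixtures/
rfamforge search --pivot fixtures/pivots.fa --db fixtures/genomes.fa --out cand.tsv
rfamforge fold --fasta fixtures/pivots.fa
rfamforge run --pivots fixtures/pivots.fa --db fixtures/genomes.fa \
              --gff fixtures/annotations.gff3 --taxa fixtures/taxonomy.tsv \
              --outdir out/
```

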