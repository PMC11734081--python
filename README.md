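# nlrkit

Domain-architecture analysis of plant **NLR** (nucleotide-binding,
leucine-rich-repeat) resistance proteins.

Plant genomes defend themselves with large families of intracellular
immune receptors whose canonical architecture combines a central
NB-ARC nucleotide-binding domain (**N**, InterPro IPR002182) with
leucine-rich repeats (**L**, tracked here as four InterPro entries
L1–L4: IPR001611, IPR011713, IPR013210, IPR025875), optionally preceded
by an N-terminal coiled-coil (**C**) or a Toll/interleukin-1-receptor
homology domain (**T**). `nlrkit` implements the full genome-wide
survey workflow for this family:

* **Mining** — select candidate proteins from InterProScan-style
  annotation tables by tracked InterPro accession, deduplicate exact
  amino-acid sequences within species, and summarise per-species
  protein/gene counts.
* **Classification** — reduce each candidate to presence/absence flags
  for N, L (with subtype), C and T and assign one of nine classes
  (N, CN, TN, L, CL, TL, NL, CNL, TNL); audit database-asserted classes
  against the derived architecture.
* **Co-occurrence** — exact UpSet-style counting of every observed
  subset of {N, L1–L4}, per species and pooled, with declarative
  absence assertions (e.g. "N never co-occurs with L3").
* **Set operations** — per-group unique-domain sets, unions, k-way
  intersections, group-exclusive domains and membership matrices.
* **Diversity** — pairwise *difference scores* (the proportion of
  aligned sites at which two sequences differ) from a built-in
  center-star aligner or imported alignments, embedded by classical
  (Torgerson) metric MDS: double-center −D²/2, eigendecompose, scale
  eigenvectors by √λ; cluster separation quantified by mean silhouette.
* **Genome summaries** — NLR gene density in fixed chromosome windows
  and Pearson correlations with two-sided t-based p-values.
* **Simulation** — a seeded synthetic proteome generator that plants
  known architectures, decoy domains, transcript fan-out and class- and
  species-specific sequence motifs, so every stage can be validated
  against ground truth offline.

The package ships small text fixtures transcribed from a published
nine-species Fabaceae NLR survey (per-species unique-domain lists,
count and class tables, checksum-verified on load), so the published
set-operation and count analyses run with no downloads.

## Worked example

```python
import nlrkit as nk
from nlrkit import datasets

# nine-species unique-domain lists shipped with the package
coll = datasets.fabaceae_unique_domains()
print(len(nk.union_all(coll)))              # 212 distinct InterPro domains
print(len(nk.intersect_all(coll)))          # 24 shared by all nine species
excl = nk.exclusive_domains(coll)
print(excl["Phaseolus vulgaris"])           # ('IPR031691',)

# synthetic proteome -> classify -> co-occurrence
spec = nk.emulate_survey_shape(factor=0.1, seed=1)
data = nk.generate(spec)
roles = nk.DomainRoleConfig.default()
candidates = nk.deduplicate(nk.select_candidates(data.annotations, roles))
classes = nk.classify_all(candidates, roles)
profiles = nk.presence_profiles(candidates, roles)
print(nk.combination_counts(profiles).head(3))
```

Output of the last statement (seed 1, factor 0.1):

```
  combination  count    percent
0           N    287  31.747788
1          L3    150  16.592920
2          L4    142  15.707965
```

i.e. of the 904 mined candidates, 287 (31.7 %) carry only the NB-ARC
domain — close to the real survey's 31.1 % N-only share, which the
preset's class proportions mirror — while the single-subtype LRR
combinations follow from the generator's uniform subtype choice.

The same stages are available from a shell:

```sh
nlrkit simulate --factor 0.1 --seed 1 --out-dir demo/
nlrkit classify --annotations demo/Glycine_max.tsv --species "Glycine max" --out classes.tsv
nlrkit setops --fixtures fabaceae9 --out-prefix fab9
nlrkit run-all --config run.yaml
```

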