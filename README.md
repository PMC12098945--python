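# unigroup

Build **universal, highly conserved gene groups** across a clade of species
and grade their **taxon-specificity** — entirely from per-species peptide
FASTA files, ortholog tables, and (optionally) genome FASTA + GFF3
annotations.

A *universal group* holds exactly one peptide per species, all matching a
shared profile well. The pipeline:

1. **Seeds** candidate groups from the ortholog tables of two reference
   species, after collapsing near-identical (>90 % bidirectional identity)
   reference peptides into clusters.
2. **Assigns** every candidate peptide exclusively to one group (ortholog
   confidence, then similarity).
3. **Prunes** groups covering too few species and reassigns their members.
4. **Optimizes** membership: for each species, an alternative candidate
   replaces the member only if it improves its relative profile score *R*
   by more than 0.01; the profile is rebuilt after each substitution.
5. **Rescues** missing members, first from unassigned annotated peptides,
   then from genome sequence via a pluggable gene-finder adapter (a
   built-in six-frame single-exon ORF finder is included), with novelty
   checked against annotated exon coordinates.
6. **Finalizes**: a group is universal iff every species has a member and
   the lowest member *R* ≥ 0.65.
7. **Scores specificity**: *S* = (lowest member *R*) − (highest outgroup
   *R*) at three taxonomic depths; groups with *S* > 0.25 are classified
   (deepest level first) as grass-, commelinid- or monocot-specific.
8. **Screens**: associate peptides (non-members with *R* > 0.65),
   supergroups (mutual all-member hits), and validation matching of
   external proteomes/genomes.

The relative score *R* is a profile alignment bit score normalized by the
score of the profile's own consensus sequence, so *R* = 1 means
consensus-perfect and *R* is comparable across groups. Profile
construction (match states at ≥ 0.5 column occupancy, uniform-background
pseudocounts) and glocal Viterbi scoring are implemented internally and
verified against an exhaustive path-enumeration oracle in the tests.

A first-class **simulator** (`unigroup.synthetic_data`) generates complete
truth-labelled inputs — an ingroup clade over a balanced binary tree with
planted universal families, decoy families, duplicated family pairs,
splice variants, genomes + GFF3 with controllable annotation dropout, and
outgroup panels at three divergence depths — so every stage is testable
offline.

## Command line

```bash
# generate a synthetic dataset plus a ready-to-run config
unigroup simulate --seed 1 --out demo --species 8 --families 30

# run the whole pipeline (writes demo/results/)
unigroup run-all --config demo/config.yaml

# stages can be skipped or re-entered from written tables
unigroup run-all --config demo/config.yaml --skip rescue
unigroup specificity --config demo/config.yaml
unigroup associates  --config demo/config.yaml
unigroup supergroups --config demo/config.yaml
unigroup validate    --config demo/config.yaml
```

Outputs under `results/`: `membership.tsv`, `specificity.tsv`,
`substitutions.tsv`, `discarded.tsv`, `associates.tsv`,
`supergroups.tsv`, per-group MSAs (`msa/`) and plain-text profiles
(`profiles/`), plus `manifest.json` (config snapshot, input digests,
stage timings and counters). All outputs are deterministic given the
config and inputs.

The config file is YAML: species list (fixed order), two reference
species, per-species peptide/ortholog/genome/annotation paths, outgroup
FASTA paths tagged with taxonomic level
(`non_grass_commelinid` / `non_commelinid_monocot` / `non_monocot`), and a
`thresholds:` block accepting any `PipelineConfig` field
(`r_min`, `delta_improve`, `cluster_identity_pct`, `min_present_fraction`,
`max_rescued`, `specificity_cutoff`, `min_raw_bits`, penalty bits,
`max_passes`, …). Exit codes: 0 success, 2 config error, 3 stage failure.

## Python API

```python
from unigroup.synthetic_data import SimConfig, simulate_dataset
from unigroup.cli import PipelineInputs, run_stages
from unigroup.group_builder import PipelineConfig

ds = simulate_dataset(SimConfig(seed=1))
cfg = PipelineConfig(species_order=ds.config.species,
                     reference_species=ds.config.reference_species)
result = run_stages(PipelineInputs(pepsets=ds.pepsets,
                                   ortholog_tables=ds.ortholog_tables,
                                   genomes=ds.genomes,
                                   annotations=ds.annotations,
                                   outgroup_panel=ds.outgroup_panel), cfg)
for g in result.universal():
    print(g.group_id, round(g.min_R, 3))
```

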