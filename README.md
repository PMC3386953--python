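# exonsplice

Exon-microarray analysis toolkit that separates transcription-level
regulation from alternative-splicing regulation, with a synthetic
exon-array generator so the whole pipeline is testable offline.

The pipeline:

1. **synthetic** — generate probe-level intensity matrices with planted
   expression changes, exon-inclusion (PSI) changes, probe affinities,
   cross-hybridizing probes, and additive background, plus ground truth
   for recovery scoring.
2. **preprocess** — per-sample background subtraction against dedicated
   background probes, cross-hybridizer removal, median-polish probe-affinity
   estimation/correction, and present/absent calls
   (mean + z·SD of background, ≥ *k* of *n* replicates).
3. **expression** — transcript expression as the mean log2 of its probes;
   empirical-Bayes moderated-t differential expression (variance prior
   fitted by digamma/trigamma moment matching) with an inclusive 2-fold
   cutoff; Venn partitioning of presence/call sets.
4. **splicing** — per-probe splicing index
   `SI(p,s) = log2 I(p,s) − E(t(p),s)` (expression-normalized exon
   signal); two independent probeset-level tests — one-way ANOVA across
   conditions and a moderated t between two conditions — combined by the
   conjunction rule: a probeset is called alternatively spliced only when
   **both** raw p-values fall below α (default 0.01).
5. **enrichment** — splicing-factor "footprint" tests (hypergeometric
   upper-tail overlap of a target gene set with the alternatively spliced
   genes), GMT-based over-representation with a minimum-set-size filter
   (default ≥ 10 genes in the universe) and Benjamini–Hochberg correction,
   and a process-by-analysis cross-tabulation with uniqueness flags.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(hypergeometric and BH oracles, test identities and limits, null
calibration, planted-event recovery, determinism).

## CLI

```sh
exonsplice simulate   --config sim.yaml --out data/ --seed 1
exonsplice preprocess --intensities data/intensities.tsv \
                      --annotation data/annotation.tsv \
                      --design data/design.tsv --out prep/
exonsplice expression --corrected prep/corrected.tsv --annotation data/annotation.tsv \
                      --design data/design.tsv --contrast TCR_CD28:TCR \
                      --fold 2 --alpha 0.05 --expr-out de.tsv
exonsplice splicing   --corrected prep/corrected.tsv --annotation data/annotation.tsv \
                      --design data/design.tsv --contrast TCR_CD28:TCR \
                      --alpha 0.01 --presence prep/presence.tsv --out as_calls.tsv
exonsplice enrich     --query as_genes.txt --sets go.gmt \
                      --universe present_genes.txt --min-genes 10 --out enr.tsv
exonsplice footprint  --targets targets.gmt --query as_genes.txt \
                      --universe present_genes.txt --out fp.tsv
exonsplice run-all    --config pipeline.yaml --seed 1
```

Exit codes: 0 success, 2 configuration error, 3 data-format/integrity
error.

A `run-all` YAML config names either a `simulation:` section (see
`exonsplice.synthetic.SimulationConfig` for fields) or
`intensities`/`annotation`/`design` paths, plus thresholds
(`fold_threshold`, `alpha_expression`, `alpha_splicing`, `z_threshold`,
`min_genes`) and `contrasts: ["TCR_CD28:TCR", ...]`. Every run writes its
resolved config and a JSON run report beside the outputs; identical
config + seed reproduces byte-identical outputs.

## File formats

All tabular I/O is TSV with a header row and `\n` line endings. Gene sets
use standard GMT (name, description, members). Ortholog maps are
two-column TSV (`source_id`, `target_id`). Intensity matrices have a
`probe_id` first column and one column per sample; annotation tables carry
`probe_id, probeset_id, transcript_id, gene_id, exon_index,
cross_hyb_flag, probe_kind` with `probe_kind ∈ {genomic, background}`.
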