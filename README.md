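# heurosplice

Rule-based assessment of splice-altering variants (SAVs): a
splicing-requirements checklist for splice-site viability, donor/acceptor
disruption decision trees with quantified spliceogenicity, deep-intronic
pseudoexon mechanism attribution with partner-splice-site search, and
re-estimation of spliceogenicity and outcome statistics from labeled
variant tables.

## What it does

* **`transcript_model`** — strand-aware transcript coordinates, the
  `+k / -k / E+k / E-k` relative-position nomenclature (the first exon base
  is `E+1`, the third intron base after a donor is `+3`), sense-strand
  sequence windows around splice sites, and ref→alt context editing.
  Readers for GENCODE-dialect GTF, simple exon tables, FASTA (pyfaidx),
  VCF, and BED interval lists for U12 introns.
* **`site_strength`** — splice-site strength in log2 bits: a bundled
  first-order position-weight model (9-mer donor `E-3..+6`, 23-mer acceptor
  `-20..E+3`) plus a maximum-entropy scorer compatible with the standard
  matrix distribution layout (optional plug-in directory). Exact model
  maxima (per-position for the PWM, table/DP for maxent) and GT/AG
  candidate-site scanning.
* **`checklist`** — the splicing-requirements checklist, manual and
  in-silico modes: canonical dinucleotides, polypyrimidine tract (≥9
  pyrimidines in `-24..-5`; strong = ≥12 consecutive or ≥17 total in
  `-24..-4`), branchpoint `TNA` within 17–50 nt (absence is indeterminate,
  never a failure), AG-exclusion zone `-13..-6` with `-5` tolerated,
  flanking introns ≥80 nt, exon minima 30/31/119 nt (first/internal/last),
  and the spacing-derived theoretical intron minima (62 nt absolute,
  77 nt low-risk).
* **`heuristics`** — the DD1–DD12 / DA1–DA9 decision trees as a
  declarative rule engine over a fixed predicate vocabulary (base
  cascades such as `G>A>C>T` at `E-1`, dinucleotide creation, context
  bases, PPT strength, branchpoint proximity). Rules and per-subgroup
  spliceogenicity annotations (p, 95% CI, n) ship in
  `src/heurosplice/data/rules.json`; every assignment carries a
  predicate-by-predicate trace. SNVs get one primary assignment per site
  class; indels are decomposed per affected position with a
  maximum-spliceogenicity summary. U12 introns, deep-intronic and
  mid-exonic variants are explicitly flagged, never silently dropped.
* **`pseudoexon`** — deep-intronic mechanism attribution (created GT/AG >
  strengthened pre-existing site > candidate only in alt > unresolved) and
  partner-site search: implied exons of 31–750 nt whose partner scores
  ≥75% of the model maximum, or ≥3 bits within 200 nt.
* **`evidence`** — spliceogenicity re-estimation (clamped Wald 95% CI)
  from SpliceVarDB-like labeled tables, subgroup validity rules (n ≥ 10;
  ≥15-point context/standard separation), and multi-label outcome
  profiles gated at >20 reported SAVs.
* **`synthetic`** — deterministic fixture generators: checklist-compliant
  transcripts sampled from the consensus frequency tables, a designed
  six-exon transcript reaching every narrated subgroup, targeted variant
  panels (the inverse of classification), and labeled tables with known
  ground truth. Text-only outputs (FASTA/GTF/VCF/TSV).

## CLI

```bash
heurosplice annotate --vcf in.vcf --gtf ann.gtf --fasta ref.fa \
    --out-tsv report.tsv --out-vcf annotated.vcf
heurosplice checklist --gtf ann.gtf --fasta ref.fa --transcript TX1
heurosplice pseudoexon-scan --vcf in.vcf --gtf ann.gtf --fasta ref.fa
heurosplice estimate --evidence table.tsv
heurosplice simulate --seed 7 --transcripts 3 --out fixtures/
```

Exit codes: 0 success, 1 usage/config error, 2 data error; per-record
problems (e.g. REF mismatches) are warnings that flag the record.

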