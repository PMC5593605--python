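# pedmeth

DNA methylation dynamics of long noncoding RNA (lncRNA) versus
protein-coding genes across pre-implantation embryonic development (PED),
rebuilt as a tested, reusable analysis pipeline over synthetic data with
known ground truth.

Human pre-implantation embryos erase and re-establish most of their DNA
methylation: sperm arrives highly methylated, the methylome bottoms out
around the 2-cell stage, and re-methylation follows implantation. Reduced
representation bisulfite sequencing (RRBS) captures this as per-CpG
methylated/unmethylated read counts per sample. This package implements the
analyses needed to ask how lncRNA genes behave through that wave compared
with protein-coding genes:

- **Tile methylation** — per-CpG level `m = M/(M+U)` restricted to ≥5×
  coverage; 100-bp tiles pool the counts of their covered CpGs; stage
  levels are arithmetic means of biological replicates; local CpG density
  counts CpGs within ±50 bp.
- **Gamete-specific DMRs (G-DMRs)** — tiles with mean level >75% in one
  gamete and <25% in the other, with a per-tile two-sample t-test and
  Benjamini–Hochberg FDR < 0.05; trajectories clustered by k-means (k = 6);
  annotation enrichment by the hypergeometric upper tail; parental
  (sperm/oocyte) bias per gene class with a chi-square test.
- **Developmental-specific DMRs (D-DMRs)** — Shannon-entropy specificity of
  the stage profile: `p_s = (m_s+ε)/Σ(m_t+ε)`, `H = −Σ p_s log₂ p_s`,
  minimized over the raw and reflected orientation so both one-stage peaks
  and one-stage dips score as specific; tiles with `H` below the threshold
  (4.22 bits for a 32-sample design, rescaled as `4.22·log₂S/5`) are called.
- **Methylation–expression coupling** — per-stage Pearson `r` between
  regional methylation (promoter = TSS ± 1 kb; gene body excluding the
  promoter) and `log₂(FPKM+1)` across genes.
- **Coding–noncoding (CNC) network** — genes filtered by expression
  (max FPKM > 5, variance in the top 75%), all-pairs Pearson `r` with
  Fisher-asymptotic p (`t = r√(n−2)/√(1−r²)`, df = n−2), edges gated at
  `|r| > 0.8`, `p < 0.05`, and ≥1 endpoint carrying a promoter D-DMR;
  topology and hypergeometric gene-set enrichment of network members.

A first-class synthetic-data module generates the study-shaped inputs
(Bismark coverage files, GTF/BED annotation, FPKM matrix) with planted
G-DMRs, D-DMRs, negative promoter coupling, and co-expression modules, and
emits ground-truth tables so every caller can be scored for recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic fixture (two chromosomes totalling 1.2 Mb, 200 genes, 9 stages ×
2 RRBS replicates, 72 expression samples), writing tables to `results/`:

```bash
cd analysis
python 01_simulate_fixture.py
python 02_quantify_methylation.py
...
python 07_cnc_network.py
```

`02_quantify_methylation.py` prints the demethylation wave:

```
stage               mean_level  frac_low  frac_high
sperm                   0.4976    0.2067     0.1744
oocyte                  0.3631    0.2550     0.0114
2cell                   0.2006    0.5147     0.0030
postimplantation        0.4747    0.2040     0.0946
demethylation wave bottoms at: 2cell
```

i.e. global methylation is highest in sperm, halves by the 2-cell stage
(where the fraction of lowly methylated tiles peaks at 51%), and recovers
after implantation. `05_call_ddmrs.py` reports the entropy caller:

```
tested 7432 tiles at threshold 2.675 bits; called 140 D-DMR tiles
recovery vs 30 planted regions: sensitivity 100.00%,
constant-background false-call rate 0.069%
```

and `06_methylation_expression.py` the regulatory coupling — promoter
methylation represses expression at every stage (r from −0.12 at the 2-cell
nadir to −0.44 in sperm) while gene-body methylation correlates positively
(mean r = +0.13). `07_cnc_network.py` builds the CNC network (24 nodes,
44 edges on the default seed) in which every edge falls inside a planted
co-expression module.

The same pipeline runs from a single config, or as one command:

```bash
pedmeth demo --out run_dir --seed 0      # simulate + full pipeline + recovery report
pedmeth run -c config.yaml               # on your own coverage/GTF/FPKM inputs
```

Stage subcommands (`simulate`, `quant`, `tssprofile`, `gdmr`, `ddmr`,
`correlate`, `network`, `enrich`) resume a run directory and execute up to
their stage. Exit codes: 0 ok, 2 config error, 3 data error.

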