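# codoncontext

Condition-specific codon optimization for heterologous gene expression.

Classical codon optimizers recode a gene using a whole-genome codon usage
table (CUTG-style frequencies) and emit a single "best" sequence. But codon
usage is not one-size-fits-all: the genes a cell expresses highly under a
*specific* growth condition (constitutive high expression, stationary phase,
a stress response) show measurably different codon and codon-pair
preferences than the genome-wide average. `codoncontext` implements the
alternative workflow: derive the codon model only from the genes up-regulated
or highly expressed under the target condition, keep track of **codon pairs**
(codon context) rather than isolated codons, and design genes
**probabilistically**, producing a family of variants to screen instead of a
single argmax design.

The package is aimed at metabolic and protein engineers who have (or can
simulate) expression data for their host, and at anyone studying codon-usage
bias quantitatively.

## The model

For a set of coding sequences, count every adjacent codon pair (stop codons
excluded — trailing stops are stripped before counting). The **codon context
matrix** is the 61 × 61 table

```
P(c2 | c1, aa(c2)) = n(c1, c2) / Σ_{c2' syn c2} n(c1, c2')
```

the probability of sense codon *c2* as the second codon of a pair, given the
first codon *c1* and the second amino acid. Columns for Met (ATG) and Trp
(TGG) — amino acids without synonyms — are 1 wherever the context was
observed.

**Probabilistic design** walks a target protein left to right: the first
codon is drawn from the training marginal of the first amino acid (forced
ATG for the universal Met start), and each subsequent codon is drawn from
`P(previous codon, ·)` restricted to the current amino acid's synonym group.
If 60 % of observed Met–Cys pairs were `ATGTGT` and 40 % `ATGTGC`, the
designer emits `ATGTGT` for a Met–Cys step 60 % of the time. Every design is
a pure function of (protein, matrix, seed).

**Drift** between two conditions is the Frobenius norm of the difference of
their context matrices, ‖A − B‖_F (identical matrices drift 0). The
random-subsampling experiment establishes the noise baseline: mean drift of
random *n*-gene subsets from the whole-genome matrix falls off as a power
law *y = A·xᵇ* (fitted by least squares on log–log axes); a condition set
whose drift sits above that baseline at its size carries genuinely distinct
codon usage.

## Worked example

Everything below runs offline on simulated data with known ground truth: a
1,000-gene genome in which 100 "highly expressed" genes are drawn from a
second generator with distinct codon-pair bias.

```bash
codoncontext simulate genome --n 1000 --len 200 --seed 7 \
    --bias-fraction 0.1 --out genome.fasta --biased-out biased.txt
codoncontext simulate expression --genome genome.fasta \
    --biased biased.txt --seed 7 --out expr.tsv

# condition-specific gene set: the 100 most highly expressed genes
codoncontext select --expression expr.tsv --mode top --n 100 --out top100.txt
codoncontext fetch --ids top100.txt --genome genome.fasta --out top100.fasta

codoncontext build-matrix --cds genome.fasta  --out control.tsv
codoncontext build-matrix --cds top100.fasta --out high.tsv

codoncontext drift --a control.tsv --b high.tsv
# 18.0411556524

codoncontext subsample --genome genome.fasta --reference control.tsv \
    --seed 7 --out curve.tsv
cat curve.tsv
# size  mean_norm           sd_norm
# 30    13.75857540772652   0.13931572112943702
# 50    10.385985265530154  0.22901886475531705
# 100   6.616910683750118   0.16755731642526678
# 150   5.129047812895324   0.09581190827645991
# 200   4.294215518545491   0.06324687960066397
# 250   3.7508180713074575  0.08922570571803394
# 300   3.2247539379747727  0.07922059228129509
cat curve.json
# {"fit_A": 118.81183207986189, "fit_b": -0.6279340808131297, "seed": 7}
```

Read: random 100-gene subsets drift 6.62 ± 0.17 from the whole-genome
matrix, and that baseline decays as *y ≈ 119·x^−0.63*; the top-100
high-expression set drifts 18.04 — nearly 3× the random baseline at the same
size — because its codon-pair usage really is different. That surplus is the
signal condition-specific optimization exploits.

Design three variants of a protein against the high-expression matrix:

```bash
codoncontext design --protein protein.faa --matrix high.tsv \
    --n 3 --seed 17 --out variants.fasta
head -2 variants.fasta
# >eGFP_like method=matrix_probabilistic source=top100.fasta seed=17 fallback_events=0
# ATGAGCAAGGGAGAAGAATTATTCACGGGCGTTGTACCAATTCTTGTAGAGTTAGACGGG
```

All variants back-translate exactly to the input protein; re-running with
the same seed reproduces the FASTA byte-for-byte. The same operations are
available as a library (`import codoncontext`): `build_context_matrix`,
`design_variants`, `frobenius_drift`, `subsample_drift`, `fit_power_law`, …
See `docs/methods.md` for the modelling details and design choices.

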