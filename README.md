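# pgenmi

Probabilistic integration of multi-omic cis-regulatory evidence with
transcriptome-wide association statistics, to identify transcription
factors (TFs) that regulate inter-individual variation in a quantitative
phenotype — the pGENMi model, together with the evidence-construction
pipeline around it and synthetic-data generators that make the whole
system testable offline.

## Who this is for

Pharmacogenomics and regulatory-genomics analysts who have, for a panel of
individuals (e.g. lymphoblastoid cell lines):

* genotype dosages (0/1/2) and/or CpG methylation beta values,
* gene expression,
* a quantitative phenotype per individual (e.g. drug EC50),
* TF ChIP peak tracks (BED), and gene TSS annotations,

and want a ranked, statistically principled list of (TF, phenotype)
associations with a mechanistic interpretation: the TF's binding sites
harbour expression-linked genetic or epigenetic variants near genes whose
expression tracks the phenotype.

## The model

For one TF and one phenotype, every gene *g* carries an observed TWAS
p-value *p<sub>g</sub>* (partial-regression test of phenotype on the
gene's expression) and binary regulatory evidence
*r<sub>gm</sub>* ∈ {0,1} for each of *M* evidence channels — here, the
presence of a significant cis-eQTL (channel 1) or cis-eQTM (channel 2)
inside a ChIP peak of the TF within the gene's 50-kb upstream window.
A latent indicator *z<sub>g</sub>* marks whether the gene mediates the
TF's influence on the phenotype:

```
Pr(z_g = 1 | r_g) = σ(w0 + Σ_m w_m r_gm)          (logistic prior)
p_g | z_g = 0  ~  Uniform(0, 1)
p_g | z_g = 1  ~  Beta(α, 1),   α ∈ (0, 1]        (enriched near 0)
```

Parameters (α, w) are estimated by expectation–maximization; the evidence
weights *w<sub>m</sub>* are learned, so each channel contributes in
proportion to its information. The TF is scored by the log2 likelihood
ratio against the null model in which *w<sub>1..M</sub>* are removed:

```
LLR = log2 P(p | r, H=1) − log2 P(p | H=0)
```

with an approximate p-value from χ²<sub>M</sub> applied to 2·ln2·LLR.
A post-processing step classifies each fit by the signs of the learned
evidence weights: all positive → `predicted` (evidence raises the
mediation prior, as a genuine regulator should), all negative →
`spurious` (absence of evidence is the better marker; discarded),
otherwise `mixed`.

## Worked example

Simulate a 200-individual, 2000-gene population with one causal TF
(peaks over planted eQTL/eQTM variants of 40 mediator genes) and four
decoy TFs, build evidence, and fit every TF:

```python
import pgenmi as pg
from pgenmi.simulate import PopulationSimConfig

study = pg.run_simulated_study(PopulationSimConfig(seed=42), modes=("eQTL+M",))
df = study.tables["eQTL+M"].df
print(df[["tf", "llr", "chisq_p", "alpha", "w1", "w2", "classification"]]
      .round(3).to_string(index=False))
```

prints

```
        tf    llr  chisq_p  alpha     w1     w2 classification
TF_causal1 63.186    0.000  0.280 15.460 24.280      predicted
 TF_decoy1  4.450    0.046  0.596  2.731  0.819      predicted
 TF_decoy4  0.255    0.838  0.564 -0.266 -7.638       spurious
 TF_decoy2  0.227    0.855  0.589  0.294  0.864      predicted
 TF_decoy3  0.203    0.869  0.561 -0.510 -1.581       spurious
```

The causal TF is top-ranked with an LLR of 63 bits, a small fitted Beta
shape (α = 0.28, strong TWAS enrichment among its evidence-bearing genes)
and large positive evidence weights; decoys sit near LLR 0. Recovery of
the planted in-peak evidence:

```python
sens, fpr = pg.evidence_recovery(study.truth, study.evidence, study.evidence_details)
# sensitivity=0.993, false-positive rate=0.044  (scan threshold p <= 0.05)
```

The same pipeline is available from the shell:

```bash
pgenmi simulate --out data/ --seed 42
pgenmi build-evidence --data-dir data/ --out ev/
pgenmi fit-rank --evidence-dir ev/ --out assoc/      # eQTL, eQTM, eQTL+M tables
pgenmi compare --table-a assoc/associations_eQTLplusM.tsv \
               --table-b assoc/associations_eQTL.tsv --universe 3552
```

Every command writes a JSON manifest (input hashes, configuration, seed)
sufficient to reproduce its outputs bit-for-bit.

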