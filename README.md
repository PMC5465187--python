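# palmshell

Fruit-form prediction from *SHELL* gene genotypes in oil palm
(*Elaeis guineensis*).

## The problem

Shell thickness is the fundamental selection trait in oil-palm breeding:
thin-shelled **tenera** (the commercial fruit form, from dura × pisifera
crosses) yields roughly 30% more oil than thick-shelled **dura**, while
shell-less **pisifera** is typically female-sterile. The trait is
monogenic and co-dominant, controlled by loss-of-function mutations in the
*SHELL* MADS-box transcription factor on chromosome 2 (CM002082.1). The
mechanism is haploinsufficiency: with *c* ∈ {0, 1, 2} functional gene
copies per diploid genome,

```
c = 2  →  dura        c = 1  →  tenera        c = 0  →  pisifera
```

where a haplotype counts as functional iff it carries the wildtype
(sh^DeliDura) nucleotide at **every** causal site. Five causal point
mutations are known — sh^MPOB (M1, T→C, Leu→Pro), sh^AVROS (M2, A→T,
Lys→Asn), sh^MPOB2, sh^MPOB3 and sh^MPOB4 — spanning 55 bp
(3,078,125–3,078,180).

In a pure accession where a single variant segregates, a one-site KASP
assay predicts the form exactly. In introgressive hybrids (e.g. AVROS-SP ×
Ekona) two variants co-segregate and single-marker prediction fails:
trans-compound heterozygotes (one mutation on each chromosome, c = 0) are
pisifera that each single assay calls tenera. Unphased assays also cannot
distinguish trans from *cis* compounds (both mutations on one chromosome,
c = 1, tenera), so multi-het calls carry an explicit ambiguity flag.

`palmshell` implements, for breeders and genotyping labs:

- the five-variant panel registry and a TSV panel file format;
- functional-copy counting with sharp [min, max] bounds over phasings;
- single-marker and functional-copy predictors (trans/cis phase policy);
- Mendelian cross distributions over the fully-linked haplotype block;
- per-accession concordance reports and the two-stage
  Concordant/Corrected/Miss rectification workflow;
- a synthetic cohort generator (accession pools, stratified fruit-form
  counts, explicit crosses, phenotyping error, hidden un-assayed
  mutations) with full truth tables;
- VCF / call-table / phenotype-TSV I/O and a `palmshell` CLI
  (`predict`, `evaluate`, `rectify`, `cross`, `simulate`).

## Worked example

Thirteen palms (five two-site discrepancies plus eight controls) re-tested
at all five sites, rectified against the classical two-site panel:

```python
from palmshell import builtin_panel, rectify
from palmshell.synthetic import retest_fixture

panel = builtin_panel()
cohort = retest_fixture()
outcome = rectify(cohort, panel.restrict(["sh_MPOB", "sh_AVROS"]), panel)
print({k.value: v for k, v in outcome.counts().items()})
for s in outcome.samples:
    if s.status.value != "Concordant":
        print(s.sample_id, s.accession, s.initial.form.value, "→",
              s.extended.form.value, f"[{s.observed_form.value} observed]",
              s.status.value)
```

prints

```
{'Concordant': 8, 'Corrected': 3, 'Miss': 2}
C2 AVROS dura → tenera [tenera observed] Corrected
C1 AVROS tenera → pisifera [pisifera observed] Corrected
C3 AVROS tenera → pisifera [pisifera observed] Corrected
V927 Cameroon x Congo dura → dura [tenera observed] Miss
V599 Cameroon x Congo tenera → tenera [pisifera observed] Miss
```

The three AVROS discrepancies are explained by sh^MPOB2 (alone for the
tenera C2; in trans with sh^AVROS for the pisifera C1 and C3), taking that
accession to 100.00% accuracy; V927 and V599 stay discordant on all five
sites and point to a further, un-assayed mutation. The corresponding
hybrid cross from the shell:

```
$ palmshell cross "WT|sh_AVROS" "sh_MPOB|WT"
genotype	probability	fruit_form
sh_MPOB | WT	0.25	tenera
sh_MPOB | sh_AVROS	0.25	pisifera
WT | WT	0.25	dura
WT | sh_AVROS	0.25	tenera

fruit_form	probability
dura	0.25
tenera	0.5
pisifera	0.25
```

— the 1:2:1 segregation whose pisifera quarter is invisible to any single
marker.

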