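# Methods

## Model

Shell thickness in oil palm is treated as strictly monogenic and
co-dominant through haploinsufficiency of the *SHELL* MADS-box gene. Over
a panel of causal sites, a haplotype is *functional* iff it is wildtype at
every site; a diploid palm carries `c ∈ {0, 1, 2}` functional copies and
its fruit form is the deterministic map `2 → dura, 1 → tenera,
0 → pisifera`. Any non-wildtype allele at a panel site is treated as
loss-of-function: catalogued alleles are "known mutants", others are
flagged "novel" but still counted (all reported *SHELL* variants are
loss-of-function, so this is the conservative reading for pisifera
detection; it also covers sh_MPOB3, whose mutant nucleotide is not
catalogued in the panel).

KASP-style assays give unphased per-site calls, so `c` is only known up to
phase when two or more sites are heterozygous. The bounds are computed by
enumerating the ≤ 2^h phase orientations of the h unphased heterozygous
sites (h ≤ 5, so enumeration is exact and cheap); calls supplied as
phased (`|`) are pinned to their stated orientation. For fully unphased
genotypes this reduces to a closed form — any hom-mutant site gives
(0, 0); otherwise h = 0 → (2, 2), h = 1 → (1, 1), h ≥ 2 → (0, 1) — and the
test suite proves the enumeration and the closed form agree on all
3^5 = 243 zygosity states.

The default phase policy is **trans** (minimum copies): compound
heterozygotes are called pisifera, the observed situation in introgressive
hybrids, while the cis interpretation (tenera) is surfaced as
`ambiguous=True` with an `alternative_form` rather than as a second call,
because cis-compound palms remain unconfirmed in the field. The `cis`
policy swaps the roles; `both` is `trans` with the alternative always
reported.

## Prediction methods and accuracy

`predict_single_marker` is the classical one-site rule. `evaluate`'s
`auto` method chooses per accession: single-marker when exactly one panel
variant segregates in that accession, the copy model otherwise (including
fully monomorphic accessions, where the two rules coincide). Records with
a missing phenotype or an unscorable genotype are excluded from accuracy,
never guessed. Accuracies are percentages rounded half-up to two
decimals; the pooled ("global") accuracy divides summed concordant counts
by summed evaluated counts across accessions — it is not a mean of
accession accuracies. Ambiguous calls are scored on their trans-policy
form and tallied in `n_ambiguous`.

`rectify` labels each palm by comparing the copy-model call on an initial
panel (default: the two classical sites sh_MPOB and sh_AVROS) and on an
extended panel: `Concordant` if the initial call already matches the
phenotype (regardless of the extended call), `Corrected` if the extended
panel resolves an initial mismatch, `Miss` otherwise. Misses are
annotated as expecting another (un-assayed) heterozygous mutation; a
phenotyping error is the alternative explanation and cannot be
distinguished from genotype data alone.

## Crosses

The five sites span 55 bp, so recombination within the block is
negligible: each parent transmits one haplotype intact with probability
1/2. Offspring distributions are the product of the two gamete
distributions collapsed over unordered diplotype identity (haplotypes
sorted lexicographically for deterministic reporting); selfing is
permitted. Fruit-form marginals follow by classifying each offspring's
copy count.

## Synthetic cohorts

The generator emulates accession-structured plantation material in which
the phenotype is produced deterministically by the true phased copy count,
so discordance arises only from the two injected mechanisms:

- **phenotyping error** — each palm's observed form flips, with the
  configured probability, to one of the other two forms uniformly
  (modelling visual fruit-census mistakes);
- **hidden mutation** — an un-assayed sixth loss-of-function site on the
  same linked block, carried independently by each founder haplotype with
  the configured frequency. It contributes to the true copy count but is
  excluded from emitted genotypes, so carriers surface as rectification
  misses.

Family specifications: *stratified* accession blocks hit their
dura/tenera/pisifera counts exactly by construction (dura = wildtype
homozygote; tenera = one het mutation, drawn uniformly among the
accession's one or two segregating variants; pisifera = mutant homozygote
for one segregating variant, trans-compound heterozygote for two) rather
than by rejection sampling, so fixture sizes are deterministic; *draw*
families sample two founder haplotypes i.i.d. from an accession pool; and
*cross* families sample offspring of two explicit parent diplotypes.
Builtin accession pools put the origin's own mutant haplotype at frequency
0.5 — the expectation within tenera × tenera breeding material — since
true per-accession haplotype frequencies are not published. Cis-compound
founder haplotypes default to frequency 0 (existence unconfirmed) but can
be supplied explicitly in a config pool. Fertility labels are attached
uniformly at random to observed pisifera only; they are metadata with no
genotype linkage, reflecting the absence of any detected association
between the *SHELL* sites and pisifera fertility.

The packaged `first_validation_config` reproduces the four-accession study
design exactly: AVROS (25 families, 73/197/84 D/T/P, segregating
sh_AVROS), AVROS × SP (15 families, 12/70/58, sh_AVROS), AVROS-SP × Ekona
(1 family, 23/24/10, both variants), Ekona (1 family, 12/14/10, sh_MPOB) —
587 palms, 120/305/162 overall. All randomness flows from a single
`numpy.random.default_rng(seed)`, so outputs (VCF, phenotype and truth
TSVs) are byte-identical given the seed.

What passing tests on these cohorts do **not** show about real data: the
generator has no genotyping error, no population structure or relatedness
beyond the family labels, exact Mendelian families, and a phenotype that
is a pure function of the *SHELL* genotype — so perfect copy-model
accuracy on noise-free synthetic cohorts validates the logic, not
field-level performance.

## Numerical and design choices

- Coordinates are 1-based on CM002082.1 (VCF convention); allele letters
  are taken literally as assayed, with KASP strand assumed to be the
  genome strand.
- Accuracy rounding is decimal half-up (not banker's), two places.
- Offspring probabilities are exact binary fractions; the distribution
  invariant (sum to 1) is asserted at tolerance 1e-12 in tests.
- Missing data policy is centralized: a missing call at any panel site
  makes copy bounds undefined; predictions become "unknown" and are
  excluded downstream. Half-missing diploid calls and non-diploid VCF
  genotypes are rejected as malformed.
- Monomorphic panel sites are written to VCF with ALT `.`; REF mismatches
  against the panel wildtype warn and defer to the file's alleles, which
  the classifier then flags as mutant.
- Simulation problem sizes used in the tests (cohorts of 200–2,000;
  10 seeds for the noise-free recovery check; 10^5 draws for the
  segregation goodness-of-fit) were chosen to keep binomial standard
  errors well inside the asserted 3·SE bands while the whole suite runs
  in seconds.

## Known limitations

- Exactly diploid calls are assumed; hemizygosity and ploidy anomalies
  are out of scope.
- No statistical phasing or imputation: phase ambiguity is reported, not
  resolved, and missing calls are never filled in.
- Quantitative shell thickness, fertility prediction and genome-wide
  analyses (array QC, PCA stratification) are out of scope.
- Multi-generation pedigree simulation with selection is not modelled;
  cross families are single-generation.
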