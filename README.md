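# hybridrad

Downstream analysis of ddRADseq genotyping for ongoing hybridization
between two parental tree species — holm oak (*Quercus ilex*) and cork
oak (*Q. suber*) — in a mixed stand with adult hybrids and their
open-pollinated progenies.

Reduced-representation genotyping of this species pair has a structural
quirk: a mutated or methylated restriction site in one species silently
removes a locus from its libraries. Heterozygous carriers of such a
**null allele** look homozygous and homozygous carriers look missing, so
naive missing-data filtering throws away exactly the loci that separate
the species best. `hybridrad` turns that missingness signature into
information and carries it through to individual-level introgression
estimates.

## What it does

- **Ingestion** (`core_data`): merged multi-sample VCF + sample metadata
  (species ∈ {ilex, suber, hybrid}, cohort ∈ {adult, seedling}, mother
  tree) into a diploid genotype matrix over alleles {REF, ALT₁..ALTₖ,
  NULL}; total-depth filter (default DP ≥ 6,000 across samples);
  round-trippable serialization with per-genotype provenance.
- **Imputation scenarios** (`scenario_engine`): per-locus missingness md
  among adults of each parental species; loci with md < 0.05 in one
  species and md > 0.90 in the other get a null allele imputed into the
  high-md species (Scenario I: MISSING → {NULL,NULL}, homozygote {X,X} →
  {X,NULL}). Scenario II thins to one imputed locus per gene or 10-kb
  intergenic fragment; Scenario III reverts all imputed alleles;
  Scenario IV simply drops all md > 0.90 loci. Seedling genotypes are
  then checked for Mendelian compatibility with their mother tree and
  recoded or blanked.
- **Introgression estimation** (`ancestry`): the suber genomic
  contribution q_s of each individual under the admixed
  Hardy–Weinberg model. With parental allele frequencies p_S, p_I fixed
  from the adult reference populations, each allele copy is drawn from
  π_h(a) = h·p_S(a) + (1−h)·p_I(a); the likelihood of an unordered
  genotype {a,b} is (2−δ_ab)·π_h(a)·π_h(b). Three routes to the same
  unimodal optimum: grid + golden-section maximum likelihood (hybrid
  index), per-allele-copy EM (supervised two-population admixture), and
  a Gibbs sampler with posterior mean and 90% credible interval. Family
  summaries and offspring/mother ratios r = q_s(o)/q_s(m) read off the
  likely pollen donor (r > 1 → cork oak, r < 1 → holm oak).
- **Marker classification** (`marker_class`): discriminant loci (major
  allele ≥ 0.9 in one species, ≤ 0.2 in the other — NULL counts like any
  allele), hybrid-pattern loci (adult-hybrid frequencies near one
  parent, far from the other), high imputed-allele frequency in hybrids
  (≥ 0.75); per-scenario marker database as TSV with an optional SQLite
  mirror.
- **Linkage anchoring** (`linkage_anchor`): per-linkage-group OLS
  bp → cM maps fitted from anchor SNPs; best-hit placement of markers
  from 12-column tabular homology files; per-group counts and density.
- **Simulation** (`synthetic_data`): a forward pedigree simulator
  (parental pools with planted diagnostic and dropout loci, 20 pedigree
  categories from pure species through F1/F2/backcrosses,
  open-pollinated families with a configurable pollen cloud, a dropout
  observation model, reference panels at 1%/10% hybrid prevalence) that
  emits VCF, metadata, truth tables and toy annotation so the entire
  pipeline is testable without any external data.

## Worked example

Simulate a study, ingest it, build all four scenarios and estimate
admixture for the adult hybrids:

```sh
hybridrad simulate --out sim --seed 42 --n-loci 300
hybridrad ingest --vcf sim/sim.vcf --meta sim/meta.tsv --dp-min 6000 --out work
hybridrad scenarios --in work --gff sim/genes.gff3 --scenario all
hybridrad ancestry --in work --scenario I --method em
```

prints

```
300 loci read, 280 kept at DP >= 6000; matrix written to work/matrix.vcf
ScnI: 280 loci, 63 imputed
ScnIII: 280 loci, 0 imputed
ScnIV: 214 loci, 0 imputed
ScnII: 263 loci, 46 imputed
sample scenario      q_s       method      loglik  n_loci
HY0001        I 0.661106 admixture_em -320.591782     271
HY0002        I 0.653412 admixture_em -314.147681     272
HY0003        I 0.660533 admixture_em -313.805798     272
HY0004        I 0.655885 admixture_em -314.448795     273
```

Reading this: 20 planted low-coverage loci fail the DP filter; the
missingness screen imputes a null allele at 63 loci (the planted
dropout loci that survived filtering), and fragment thinning keeps 46
of them in Scenario II. Scenario IV, which discards high-missingness
loci instead of imputing them, loses 66 loci relative to Scenario I.
The adult hybrids are simulated F1s (true h = 0.5); their q_s
estimates sit above 0.5 here because at imputed loci an F1's maternal
null allele hides behind the visible paternal allele, making the
uncorrected call look homozygous for the cork-oak allele — the same
scenario-dependent shift the imputation scenarios exist to expose
(see `docs/methods.md`).

The same operations are available as library functions
(`hybridrad.scenario_engine.build_all_scenarios`,
`hybridrad.ancestry.admixture_em`, ...) on in-memory matrices.

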