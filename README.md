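# mitocommon

Forensic mitogenome analysis behind the most common West Eurasian mtDNA
control-region haplotype.

## The problem

The forensic gold standard for mitochondrial DNA is to sequence only the
~1.1 kbp control region (CR, nps 16024–16569 and 1–576 of the rCRS). The
most common West Eurasian CR haplotype (the **MCH**, motif
`263G 315.1C 16519C`, haplogroup H) occurs at ~4–6% in European
populations, so a CR match carries almost no evidential weight for these
samples. Sequencing the complete mitogenome recovers the coding-region
(codR) diversity hidden behind the identical control regions and can turn
a useless match into a near-exclusion.

`mitocommon` is a toolkit for exactly this analysis, aimed at forensic and
population geneticists working with EMPOP-style haplotype tables:

- parse/validate/serialise rCRS-relative variant notation
  (`263G`, `315.1C`, `6253Y`, `524.1a`, `249DEL`), with IUPAC point
  heteroplasmy (PHP) codes and region classification (CR/codR, HVS-I/II/III);
- screen haplotypes for the MCH under forensic conventions (heteroplasmy
  and poly-C stretch length variation are not preclusive);
- build identity partitions in which a heteroplasmic sample may match two
  otherwise distinct haplotypes, under four double-match scenarios;
- compute forensic summary statistics and exact binomial intervals;
- assign haplogroups on a signature tree by transparent weighted parsimony
  with most-recent-common-ancestor (MRCA) fallback for near-ties, and
  evaluate the rapid 3-SNP H1/H3/H7 panel;
- summarise point/length heteroplasmy and build the per-position variant
  spectrum behind circular mitogenome plots;
- generate seeded synthetic MCH populations with ground truth for
  validating every stage.

## The statistics

For an identity partition with group sizes $n_i$ over $N$ samples:

$$\mathrm{RMP} = \sum_i \left(\frac{n_i}{N}\right)^2,\qquad
\mathrm{HD} = \frac{N}{N-1}\left(1-\sum_i \left(\frac{n_i}{N}\right)^2\right),\qquad
\mathrm{DC} = \frac{k}{N},$$

where RMP is the random match probability, HD the haplotype diversity
(used interchangeably with the power of discrimination, PD), and DC the
discrimination capacity for $k$ distinct haplotypes. Under the
double-match convention a heteroplasmic sample belongs to every group it
matches, so $\sum_i n_i$ may exceed $N$ while the denominator stays at the
number of physical samples.

Binomial proportions carry two-sided exact (Clopper–Pearson) confidence
intervals from Beta quantiles, and an observed MCH sample of size $n$ at
population frequency $f$ represents $n/f$ screened individuals (the count
CI inverts the frequency CI).

## Worked example

Reconstruct the 216-mitogenome identity structure of the bundled study
fixture (one septet and a pair bridged by a heteroplasmic 6253Y sample,
two quintets, two quartets, seven triplets, 20 pairs, 131 singletons) and
compute its forensic parameters:

```python
import json
from mitocommon.fixtures import paper_partition_dataset
from mitocommon.matching import build_identity_partition
from mitocommon.stats import forensic_params

hs = paper_partition_dataset()           # 216 haplotypes, CR-identical
p = build_identity_partition(hs)         # double-match convention
print(json.dumps(forensic_params(p).summary(), indent=2))
```

prints

```json
{
  "N": 216,
  "haplotypes": 163,
  "unique_haplotypes": 131,
  "RMP_percent": 0.9,
  "PD_percent": 99.6,
  "DC": 0.755,
  "DC_percent": 75.5,
  "unique_sample_percent": 60.6,
  "non_unique_members": 86
}
```

i.e. among 216 mitogenomes that are *identical* across the control region,
163 distinct haplotypes emerge at full resolution: the random match
probability drops to 0.9% and the power of discrimination rises to 99.6%.
The discrimination capacity is 75.5%, with 131 unique haplotypes covering
60.6% of samples and 86 sample memberships in shared groups (one sample is
double-assigned through its point heteroplasmy).

The same analyses are available from the shell:

```bash
mitocommon simulate --seed 42 --n 216 --out pop.tsv --truth truth.tsv
mitocommon screen-mch --in pop.tsv --out mch.tsv
mitocommon partition --in pop.tsv --out partition.json
mitocommon stats --partition partition.json --out params.json
mitocommon assign --in pop.tsv --out calls.tsv
mitocommon ci --k 631 --n 15782
mitocommon extrapolate --n 216 --freq 0.040 --ci 0.037,0.043
mitocommon run-all --in pop.tsv --out report/
```

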