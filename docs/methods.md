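# Methods

This note documents the conventions, defaults and design choices behind
`mitocommon`, in the spirit of a model description: what each component
assumes, which knobs matter, and what the synthetic data can and cannot
show.

## Nomenclature and coordinates

Haplotypes are sets of rCRS-relative differences at 1-based nucleotide
positions (nps) on the 16,569-np circular molecule. The token grammar is
`<np><base>` for substitutions (IUPAC two-state ambiguity codes R/Y/W/S/K/M
denote point heteroplasmies, PHPs), `<np>.<k><base>` for the k-th inserted
base after an np (lowercase marks heteroplasmic length events such as
`524.1a`), and `<np>DEL` for deletions (`del` is accepted on input and
serialised uppercase). Sequenced ranges are inclusive interval pairs; a
start greater than the end encodes a range wrapping the origin, and the
full genome is canonicalised to 1..16569.

Regions: control region CR = 16024–16569 ∪ 1–576, coding region
codR = 577–16023; hypervariable segments HVS-I 16024–16365, HVS-II 73–340,
HVS-III 340–576. Every np is in exactly one of CR/codR. np 340 belongs to
both HVS-II and HVS-III exactly as the segment definitions are cited in
the forensic literature; region queries return label sets, so no
tie-break is imposed.

`@`-prefixed tokens (back mutations, e.g. `@16037`) are accepted only in
haplogroup-tree signatures, where they cancel a variant accumulated on the
root path; they are not valid observed-haplotype tokens.

## Reference sequence

Reference-base information is needed in two places: deciding whether a PHP
is compatible with the reference allele, and orienting major/minor bases.
The bundled FASTA is a **synthetic stand-in** for the rCRS (see its header
and `mitocommon/_synthetic.py`): pseudo-random bases with the real
NC_012920.1 base imposed at every position used by the bundled fixtures,
the heteroplasmy catalogue, the panel markers, the poly-C tracts and the
documented examples. Analyses touching only those positions are identical
to runs against the real reference; for arbitrary real data, load the real
rCRS FASTA. Reference validation of observed tokens warns rather than
fails, because tokens in the wild omit reference bases.

## Forensic comparison rules

Following forensic practice, neither point heteroplasmy nor poly-C stretch
length variation precludes a match. Before any comparison a haplotype is
normalised to its *comparable* variant set:

- insertions at the length-variant anchor nps
  {309, 315, 455, 463, 573, 960, 965, 5899, 8276, 16193} are stripped,
  except `315.1C` itself, which is part of the MCH motif;
- insertions and deletions in the 523/524 AC dinucleotide repeat are
  stripped;
- heteroplasmic length events (lowercase indel tokens) are stripped;
- PHP substitutions are retained and handled by the match predicates.

Two haplotypes covering the same range match when their comparable sets
agree at every (np, insertion index): two entries agree when their IUPAC
component sets intersect; a variant present on one side only is tolerated
when it is a PHP whose components include the reference base. A fixed
deletion never matches a substitution or an absence.

MCH screening requires the CR-restricted comparable set to equal
`{263G, 315.1C, 16519C}` exactly, with PHPs tolerated when compatible with
the motif base (at motif nps) or the reference base (elsewhere). A fixed
CR variant outside the motif always precludes MCH status, even at
PHP-prone nps.

## Identity partitions and the double-match scenarios

With heteroplasmy, matching is reflexive and symmetric but not transitive:
a PHP carrier can match two haplotypes that differ by a full difference at
that np. Groups are therefore built as equivalence classes of PHP-free
comparable haplotypes; every PHP carrier is attached to each class it
matches (carriers matching no class are grouped among themselves by mutual
match, in input order). A carrier matching two or more classes is handled
by scenario:

- `double_match` (default, used for headline values): member of every
  matched class; N stays at the number of physical samples, so group sizes
  may sum to N+1 or more;
- `inflate_total`: same groups, N incremented per extra membership;
- `assign_to_major` / `assign_to_minor`: the carrier joins only the
  largest / smallest matched class.

Forensic parameters are computed from group sizes with denominator N as
defined by the scenario; RMP = Σnᵢ²/N², HD = (N/(N−1))(1−RMP), DC = k/N.
All internal arithmetic is unrounded; presentation rounding is
half-away-from-zero to one decimal for percentages and three decimals for
proportions.

## Confidence intervals and screening equivalents

Binomial CIs are exact (Clopper–Pearson) from Beta quantiles:
lower = BetaInv(α/2; k, n−k+1) (0 at k=0), upper = BetaInv(1−α/2; k+1, n−k)
(1 at k=n), computed with `scipy.stats.beta`; the test suite checks them
against an independent bisection on binomial tail sums.

A sample of n screened-positive individuals at population frequency f
represents round(n/f) screened individuals; the count interval inverts the
frequency interval (lower count from the upper frequency). When the input
frequencies are printed at one-decimal-percent precision the last digit of
a bound can be unstable (e.g. 216/0.037 = 5837.8 rounds to 5838, while an
unrounded frequency just below 3.7% would give 5837); the function flags
this case in a note rather than guessing intent, and likewise
216/0.056 = 3857.1 is reported as 3857 by round-to-nearest.

## Haplogroup assignment

The tree format is one clade per line (`name<TAB>parent<TAB>signature`),
names unique, a single root, `@` back mutations cancelling root-path
variants. The expected variant set of a clade is the accumulated signature
along its root path. The bundled tree covers haplogroup H with the named
clades of the study inventory; its root signature is the universal set
{263G, 315.1C, 750G, 1438G, 4769G, 8860G, 15326G, 16519C} (the rCRS itself
belongs to H2a2a1, so an H representative shows these differences), and
signature motifs are real where printed (H1 = 3010A, H3 = 6776C,
H7 = 4793G, H23 = 10211T) and synthetic placeholders elsewhere — the file
is labelled accordingly and any user-supplied tree loads through the same
interface.

Assignment is transparent weighted parsimony: cost(clade) = Σ weights over
the symmetric difference between the comparable variant set and the
clade's expected set, where a PHP counts as carrying a signature when its
components include the signature base, a PHP compatible with the reference
costs nothing when unexpected, and length variation is ignored. Weights
default to 1.0 with classic hotspots (16519, 152, 146, 195) down-weighted
to 0.5; both the weight map and the tie tolerance are caller-configurable.
Missing and private variants are weighted symmetrically. This is a
deliberately simple, auditable engine: database-calibrated engines that
weight each SNP by its observed fluctuation rate per clade may disagree at
rare positions.

Ties within the tolerance resolve as follows: if all tied candidates lie
on a single root path (e.g. a PHP at a signature np making parent and
child equally cheap), the deepest candidate wins — the PHP counts as
carrying the signature; otherwise the call falls back to the candidates'
MRCA and is flagged (`mrca_applied`). The default tie tolerance is 0.0
(exact ties only), since no quantitative definition of "similar costs"
is established.

The rapid panel types only nps 3010/6776/4793 (derived alleles A/C/G →
H1/H3/H7, otherwise `other`); a PHP containing the derived allele counts
as derived, more than one derived marker raises a conflict flag, and a
missing-coverage np is an error. First-level summaries aggregate terminal
calls to their depth-1 ancestor, with calls to the root reported as the
paragroup (`H*`).

## Heteroplasmy and spectrum summaries

PHP records are extracted from ambiguity-coded substitutions
(transition/transversion labelled from the component pair); heteroplasmic
indels are length heteroplasmy and counted separately. Minor fractions are
optional metadata; values below the 10% detection threshold used in the
underlying sequencing protocol trigger a warning, never a re-call.
Platform stratification groups on the free-text platform column.

The variant spectrum counts every difference at its reference np,
excluding the universal differences at nps {263, 750, 4769, 8860, 15326,
16519} (note: 1438 is *not* excluded, matching the published convention),
poly-C stretch insertions at the anchor set and length heteroplasmy. PHPs
count as full differences; a multi-base block insertion is one event at
its anchor np; deletions count at their reference np. The spectrum table
labels nps with at least `min_count` (default 5) occurrences, ready for
circular plotting.

## Synthetic populations

The generator emulates the statistical shape of a CR-identical
haplogroup-H population: every sample carries the MCH motif plus the
universal substitutions; a first-level clade is drawn from the study's
inventory proportions (a terminal clade uniformly within that subtree);
private codR substitutions are Poisson-many (default mean 2.0, chosen so
that synthetic discrimination capacities land in the regime the study
reports; recorded here as a package default, not an empirical estimate) at
uniform non-signature positions; PHPs hit a configurable fraction of
individuals (default 21.8%, a second PHP in 3/47 of carriers) with minor
fractions uniform on [0.11, 0.50] by default (a right-skewed truncated
Beta option exists; the study's empirical level distribution is
unpublished, and neither law claims to be it); poly-C length variation
(an extra `309.1C`) affects a configurable fraction (default 0.3, a
typical order for MPS datasets; not a published value). In screening mode
each control region is the MCH with probability 5.6% (the published
population frequency used for extrapolation) and decoys add one common CR
polymorphism from {16311C, 16093C, 152C, 146C}.

Everything is driven by one integer seed through `numpy`'s Generator;
identical configurations produce byte-identical outputs. What passing
recovery tests show: the pipeline's decisions invert the generator's
assumptions exactly (100% haplogroup and screening accuracy without
noise, unbiased frequency recovery under screening). What they do not
show: robustness to alignment/nomenclature discordance, platform-specific
artefacts, mixtures beyond two-state PHPs, or phylogenetic structure
beyond clade signatures — none of which the generator emulates.

## Numerical and degenerate-input conventions

- Haplotype diversity requires N ≥ 2; empty datasets and empty trees are
  errors, empty variant sets are valid haplotypes (the rCRS itself).
- Matching across unequal sequenced ranges is an error rather than a
  silent range intersection.
- Group construction is deterministic given input order; JSON/TSV outputs
  sort keys and members for byte-stable reports.
- Percentages are rounded half-away-from-zero at presentation only.

## Known limitations

- No sequence-to-variant alignment: inputs are variant strings, not raw
  FASTA/FASTQ; forensic alignment harmonisation is out of scope.
- The bundled tree is a study-scope fixture, not a full phylogeny;
  assignments outside haplogroup H require a user tree.
- The parsimony engine is not calibrated on a haplotype database; calls
  can differ from fluctuation-rate-weighted engines at rare positions.
- Mixtures, more-than-two-state heteroplasmy and heteroplasmy phasing are
  not modelled.
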