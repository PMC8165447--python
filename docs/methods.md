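# Methods

This note documents the models and procedures famscan implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish
about real data.

## Domain scanning and membership

Membership is decided by exact local alignment rather than a heuristic
database search: at gene-family scale (tens to a few hundred proteins) the
quadratic DP is cheap, and exactness gives a contract that can be tested
against an independent aligner. The scan aligns a single domain reference
(shipped as editable FASTA config; the default is a synthetic 59-aa
Class II-style basic-helix-loop-helix sequence) against every protein with
BLOSUM62, gap open 11, gap extend 1, the opening penalty charged together
with the first gap residue. Traceback tie-breaks prefer diagonal, then up,
then left, so alignments are deterministic.

Significance uses the Karlin–Altschul form `E = κ·m·n·exp(−λ·s)` with
`m` the domain length and `n` the total residues scanned. λ = 0.267 and
κ = 0.041 are the classic ungapped BLOSUM62 constants, shipped as
configuration: the workflow this package systematizes fixes only the
threshold E ≤ 0.001, and on planted domains the score gap between members
(E ≲ 1e-30) and background (E ≫ 1) is many orders of magnitude, so the
precise constants are not load-bearing. Accepted hits must additionally
span a domain-sized region on the protein: 55–60 aa is the expected domain
size and the window is widened ±20% to tolerate alignment fraying.
A profile/HMM search would be more sensitive on remote homologs; similarity
to one reference is a deliberate simplification, adequate here because
membership truth on the fixtures is planted, not inferred.

## Subfamily classification

The Class I / Class II distinction rests on the four-residue deletion in
the basic region of Class I (PCF) domains. The hit region is globally
aligned to both class references; PCF is called when that alignment opens a
gap of 3–5 residues (4 ± fraying) in the hit row within the first quarter
of the Class II reference, or when the Class I reference outscores the
Class II reference. The "first quarter" boundary for the basic region is
this package's convention — the literature does not fix an exact boundary.
Within Class II, the CYC subfamily is recognized by its hydrophilic
R domain: a sliding 20-aa window C-terminal of the domain hit with polar
residue (S,T,N,Q,K,R,H,D,E) fraction ≥ 0.6. Both window length and
threshold are configurable; 0.6 separates a designed R domain (fraction
≈ 1.0) from typical globular sequence (≈ 0.45).

## Physicochemical profile

Molecular weight sums average residue masses plus one water, reported in
kDa. GRAVY is the mean Kyte–Doolittle hydropathy. The isoelectric point is
the root of the net-charge curve
`Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))`
(termini included), located by bisection. Q is strictly decreasing in pH,
so the root is unique; bisection runs to a 1e-6 pH interval, which puts
|Q| at the returned point far below the 1e-4 target even where the curve
is nearly flat (ampholytes with distant pKa values). The pKa set
(N-term 9.6, C-term 2.34, K 10.53, R 12.48, H 6.0, D 3.65, E 4.25, C 8.33,
Y 10.07), masses and hydropathies ship as editable tables; published
ExPASy-style values depend on the exact table used, so numeric equality
with any particular web service is not claimed.

## Alignment and phylogeny

The progressive aligner is intentionally simple: UPGMA guide tree on 3-mer
count distances (1 − shared/min), then profile–profile Needleman–Wunsch
with sum-of-pairs column scores (gap symbols score zero against
everything) and the same affine penalties as the scan. Two sequences
reduce exactly to plain pairwise global alignment. This is not a
replacement for a production MSA tool on divergent data; it is
deterministic, dependency-free, and sufficient for the within-family
identity levels the downstream stages consume.

Distances use pairwise deletion: columns where either row is gapped are
skipped for that pair. p-distance is the default model, matching the
common NJ default for amino-acid data; the Poisson correction
`d = −ln(1−p)` is available (`model="poisson"`). The published workflows
this replaces typically say only "Neighbor-Joining with default
parameters", so the model is surfaced as configuration rather than claimed
as fact.

Neighbor-Joining is the Saitou–Nei algorithm: join the pair minimizing
`Q_ij = (r−2)·d_ij − Σ_k d_ik − Σ_k d_jk`, branch lengths
`l_i = d_ij/2 + (Σd_i − Σd_j)/(2(r−2))`, negative computed lengths clamped
to zero, ties broken toward the smallest index pair, final three nodes
joined at an unrooted trifurcation. On additive inputs NJ is consistent:
the test suite and acceptance script verify exact topology and path-length
recovery on random additive matrices, and cross-check topology against an
independent NJ implementation. Bootstrap support is out of scope in this
version.

## NG86 Ka/Ks

Site counting, difference counting, Jukes–Cantor correction and the
selection call follow Nei–Gojobori (1986). Decisions the original leaves
to the implementer:

- stop-creating single-nucleotide changes count as nonsynonymous in site
  counting;
- substitution pathways passing through a stop codon are excluded from the
  pathway average when at least one clean pathway exists; if every pathway
  is blocked, all pathways are used with stop-passing steps counted as
  nonsynonymous (so `sd + nd` always equals the codons' Hamming distance);
- `S` is the mean of the two sequences' per-codon site sums over
  comparable (gap-free in both rows) codons;
- an undefined ratio (Ks = 0, or pS/pN ≥ 3/4 where the correction
  diverges) is a first-class sentinel (`None`), never coerced to 0 or
  infinity — sliding-window plots should show gaps, not fake zeros;
- the neutral/positive/purifying boundary at 1 uses a 1e-9 numeric
  tolerance.

Codon alignments are built by back-translating a protein alignment: each
residue column becomes its source codon, each protein gap a whole aligned
triplet; a trailing stop codon on the CDS is trimmed. Sliding windows are
150 nt stepping 9 nt by default (both multiples of 3), starting at column
1 while they fit; window counts follow `⌊(L−w)/s⌋ + 1`.

## Duplication typing

Candidates are sister-leaf pairs of the family tree — the strictest
reading of "two genes in the same branch". Pairs are retained when
global-alignment identity (identical columns over all alignment columns)
exceeds 80%; "similarity" in such rules is ambiguous between identity and
substitution-class similarity, and identity is the stricter, more
reproducible choice. Typing is positional: same chromosome with
start-to-start separation ≤ 200 kb → tandem; different chromosomes →
segmental (fragment) duplication; same chromosome beyond the bound →
unclassified rather than forced into segmental; either gene on an unplaced
scaffold → flagged unplaced. The tandem rule is stated in some papers as
"at least 200 kb", the opposite of the universal convention; this package
implements the conventional "within 200 kb" reading and records the
discrepancy here rather than resolving it silently. Genes are considered
placed when their sequence region is a `chr*` token; anything else is
treated as an unplaced scaffold.

## Promoters and cis-elements

Promoters are the `length_bp` bases immediately 5' of the translation
start — the first CDS base, not the transcription start — returned 5'→3'
on the coding orientation (minus-strand windows are reverse-complemented).
The documented range is 1,500–2,000 bp; the default is 1,500, the lower
bound, which is available more often near contig edges. Windows clipped at
a chromosome edge are flagged.

Element scanning is exact IUPAC-consensus matching with all overlapping
occurrences reported. The default strand policy scans only the promoter
strand, because curated element tables list palindrome partners (CGTCA
vs TGACG) as separate entries and both-strand scanning would double-count
them; `both` is available and maps reverse-strand hits back to promoter
coordinates. The shipped motif table is a PlantCARE-style editable config
(element, IUPAC consensus, one of three functional categories: growth and
development, stress, hormone); the upstream database's exact patterns are
unpublished, so all correctness statements are self-consistent against the
shipped table, and per-element counts from any particular web service are
not reproduction targets.

## Expression (2^–ΔΔCT)

Replicates are paired by index when forming ΔCt (target − reference), so a
plate-wide Ct shift in a sample cancels exactly; an unpaired mean-vs-mean
variant would differ only in the dispersion estimate. Dispersion is
propagated on the ΔCt scale and exponentiated (fold_range =
2^−(ΔΔCt ± sd)), the standard Livak convention. For hormone time courses,
"responds at time t" is operationalized as a two-sided Welch test on
replicate ΔCt (t vs 0 h) with p < 0.05 **and** a ≥ 2-fold change in either
direction — source workflows state "increased significantly" without a
test, so the rule is documented here as this package's choice. Degenerate
zero-variance comparisons yield a NaN p-value and are treated as not
significant. The tissue heatmap preparation is the elementwise
log2(value + 1) transform only; rendering is out of scope.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed); identical inputs give
byte-identical outputs.

**Codon evolution** is acceptance-rejection, not a Markov codon model:
each round proposes one uniform single-nucleotide change; stop-creating
proposals are rejected (NG86's implicit assumption), synonymous proposals
are accepted with probability 1 and nonsynonymous with min(ω, 1) (for
ω > 1, synonymous acceptance drops to 1/ω). Because NG86's site
normalization matches the uniform proposal distribution, the realized
event ratio tracks ω directly. Defaults for recovery experiments are
500-codon ancestors and 300 proposal rounds (≈ 8% realized divergence at
ω = 0.2) — enough divergence for stable estimates, little enough that
multiple-hit saturation stays in the Jukes–Cantor regime. Residual biases
(stop-adjacent proposal rejection, back-mutations) are at the few-percent
level, visible as mean recovered ratios of ≈ 0.19 at ω = 0.2 and ≈ 0.95 at
ω = 1.

**Family genomes** default to the shape of a mid-size Rosaceae family —
34 members (14 PCF / 12 CIN / 8 CYC) when run at full scale; tests and the
acceptance script use smaller member counts with the same structure to
keep runtimes short. Members carry the domain reference with the
class-defining features planted (4-residue basic-region deletion for PCF,
an appended polar R domain for CYC); duplicate pairs are one member CDS
plus a copy evolved at ω = 0.2 for 60 rounds (≈ 95% amino-acid identity);
decoy pairs are planted at 70% identity to exercise the retention rule;
background genes are random CDS without the domain. Chromosomes are
400 kb with genes placed ≥ 2.5 kb apart so every promoter window fits.
Tandem separations are exact start-to-start distances.

Three scrubbing passes make truth exact rather than merely likely, since
random background would otherwise confound it: (1) C-terminal tails of
non-CYC members are re-drawn until no 20-aa window reaches the R-domain
polar threshold (a uniform random window crosses 0.6 with probability
≈ 0.13); (2) decoy-pair substitutions after the domain draw only nonpolar
residues; (3) promoter backgrounds are re-drawn until a scan finds exactly
the planted motif occurrences and nothing else (at 34 × 1,500 bp a 7-mer
consensus would otherwise match by chance ≈ 3 times). Consequently,
passing fixtures demonstrates correctness of the measurement machinery on
unambiguous inputs — not scan sensitivity on diverged real domains, MSA
quality on gappy families, or motif discovery against genomic base
composition, none of which the fixtures model. There is no indel
evolution (alignment inference is not the contribution being tested) and
no empirical codon-frequency bias.

**Ct tables** are `baseline − log2(fold) + N(0, σ)` per replicate with the
reference gene fixed at fold 1; with σ = 0 the ΔΔCt estimator inverts the
generator to machine precision, and with σ = 0.2 (a typical qPCR replicate
SD) the mean estimate over many seeds stays within a few percent of truth
(2^−ΔΔCt is lognormal, so a small convexity bias of
exp((ln2)²σ²_ΔΔCt/2) ≈ 0.7% is expected and observed).

## Pipeline

One YAML config, one command; stages abort with the stage name and
offending record on error. The manifest records a hash of the
analysis-relevant config (output location excluded), the seed, library
versions and per-stage row counts. Reruns of the same config are
byte-identical except the manifest timestamp. Problem sizes used by the
test suite and acceptance script (families of 9–34 members, 3–5
chromosomes, 20-seed replication, 50-seed ω recovery, 200-seed ΔΔCt
recovery) were chosen to make sampling noise small relative to the bands
being checked while keeping a full run in the order of a minute.

## Known limitations

- Similarity-to-one-reference scanning, not HMM profiles; remote homologs
  below ~40% domain identity may be missed on real proteomes.
- The progressive MSA has no iterative refinement; deeply diverged or
  indel-rich families deserve a dedicated aligner.
- NG86 with Jukes–Cantor saturates near p = 3/4; no maximum-likelihood
  dN/dS (GY94-style) is provided.
- Duplication typing uses coordinates and tree sisterhood only; no
  synteny-block inference.
- No amplification-efficiency (Pfaffl) correction for qPCR; no RNA-seq
  read processing (the expression stage consumes tables).
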