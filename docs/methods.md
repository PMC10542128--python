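# Methods

This note documents the models and procedures implemented in
`coconut_census`, the defaults and why they are what they are, and the
limits of what the synthetic benchmarks demonstrate.

## Data model and coordinates

Genomes are ordered, stranded protein-coding gene lists per contig
(GFF3 + protein FASTA in; the pipeline never translates nucleotide
sequence — it is annotation-driven). Coordinates are 1-based inclusive.
The intergenic gap between genes is `start2 − end1 − 1`: abutting genes
have gap 0, overlapping reading frames are negative. "Adjacent" means
consecutive in start-sorted order on the same contig; orientation is
tested separately. With this convention the operonic-adjacency rule
"within 90 nucleotides" is an inclusive `gap ≤ 90` test, and overlaps
(the tightest operonic association, common in CoCoNuT operons) always
qualify.

## Profile search

`build_profile` turns a seed alignment into per-column probability
vectors with Laplace-style pseudocounts,
`p = (count + pc·bg) / (n + pc)` with `pc = 1` and a uniform background,
after dropping columns with > 50% gaps. Duplicate alignment rows are
collapsed before counting — a minimal form of sequence weighting that
makes profiles invariant to replicated sequences. Log-odds are
`log2(p/bg)`.

Scanning is ungapped best-window scoring (all windows, summed
per-column log-odds; ties to the smallest start; repeated domains are
recovered by greedy non-overlapping re-scanning, up to 4 hits per
protein). Gapped local alignment is deliberately out of scope: the
bundled seed families are ungapped by construction, and externally
produced hit tables can be imported for real data where gapped search
matters.

Significance is empirical: for each profile, a Gumbel distribution is
fitted to the best-window scores of random background sequences
(default 200 shuffles of length 300), mirroring the extreme-value
behavior of local alignment scores without BLAST's K/λ machinery.
`E = database_size × P(S ≥ s | null)`, with the database size equal to
the number of scanned proteins. E-values are floored at 1e−280 so a
threshold of exactly 0 admits nothing. Discovery searches use E ≤ 10;
domain annotation uses E ≤ 0.001; both are config fields. The
iterative search is round-based (search → cluster → rebuild profiles →
search; default 2 rounds).

The PD-(D/E)xK profile carries a catalytic-column annotation taken from
its seed alignment (the P-D ... D/E-x-K residues). A hit whose catalytic
columns are substituted is relabeled `iPD-DxK` (inactivated nuclease),
which the Type II / III typing rules rely on.

## Neighborhood filtering

An island is an anchor hit plus ≤ 10 genes per side (truncated at
contig edges, flagged, never discarded). Tiers are applied in order and
are mutually exclusive:

1. **primary** — any island gene has a direct McrB-GTPase (COG1401-
   equivalent) hit, or ≥ 1 McrB-alias and ≥ 1 McrC-alias hit (one gene
   may supply both).
2. **rescue-single** — exactly one alias side present, and some alias
   gene has an adjacent same-strand gene at gap ≤ 90 nt whose protein
   exceeds the missing role's size gate (> 200 aa McrB, > 150 aa McrC;
   strict inequalities as published).
3. **rescue-none** — no alias hits at all, but the discovery anchor has
   such an operonic partner; the size gate is chosen by the role the
   anchor's profile testifies to (a B-side anchor needs a C-sized
   partner and vice versa; unknown roles get the stricter B gate).

Tier assignment is deterministic and order-independent; islands with
identical gene spans are deduplicated.

## Pairing

Role lists come from domain evidence (GTPase/McrB aliases → B;
DUF2357/McrC aliases → C; genes with both take the lower-E-value role).
Pairing is a one-to-one minimum-cost assignment on |intergenic gap|
(scipy's Hungarian solver), with tiny tie-break penalties preferring
canonical (B transcribed before C) layouts and earlier gene order.
Layout records `canonical` / `reversed` / `intervening:k`; systems with
k > 3 intervening genes are flagged low-confidence. Orphans are
reported for manual triage, never auto-promoted.

Because the same operon is reached from several anchors and overlapping
islands can propose conflicting pairings, the pipeline resolves
globally: systems are ranked by |gap| (then layout, then id) and each
gene participates in at most one system. Operonic proximity is the
pairing signal, so the tightest pairing wins.

## Motif classification

Walker A is the leftmost `[AG]x(4)GK[ST]`; Walker B is the leftmost
run of four hydrophobics (ILVMFA) followed by two acidics, downstream
of Walker A — deliberately loose, as no stricter pattern is warranted.
The signature motif search enumerates every (N position, spacing)
candidate `N-x{1,2,3}-D` in a 120-aa window past Walker B and takes the
fewest intervening residues (nearest to Walker B among equals): the
NxD state is a conserved deletion of NxxD, so the shortest spacing is
the defining state. A greedy regex is wrong here — `N.{1,3}D` on
`NVDE·D` matches NxxxD and hides the NxD at the same asparagine — hence
the explicit enumeration. Multiple candidates set an `ambiguous` flag.

HEPN motifs are `R-x(4)-H` and `R-x-H` within a domain span, with a
nested RxH inside an RxxxxH reported once as RxxxxH; CPxC zinc-binding
motifs are counted non-overlapping.

The Type I-A helical insert is detected on alignments: a member carries
the insert when ≥ 30 residues (inclusive) between its Walker B and
signature columns fall in columns where the cluster consensus is
gapped. The pipeline path aligns each GTPase region against an
insert-free canonical reference and applies the same column test. The
30-aa threshold is a design choice; the insert is qualitatively
described but not quantified in the literature.

## Coiled-coil prediction

A COILS-style predictor: 28-residue windows × 7 heptad registers,
scored as the geometric mean of a bundled position-specific propensity
table (branched hydrophobics favored at a/d, charged residues at e/g,
proline near-prohibitive). A residue's score is the best over covering
windows; scores convert to probabilities by a two-Gaussian likelihood
ratio whose parameters — coil (1.75, 0.15), background (1.05, 0.06),
prior 0.30 — were calibrated once against the measured score
distributions of ideal heptads and random sequences and are bundled
constants; scores below the background mean clamp to probability 0 so
the wider coil Gaussian cannot capture the left tail. Segments are
maximal runs with p ≥ 0.5 of length ≥ 21 (three heptads — long enough
to mean "coiled-coil" rather than a helical hairpin). Consensus tiers
over multiple predictors: strong = ≥ 2 sources with max p ≥ 0.9;
moderate = one source ≥ 0.9 or ≥ 2 sources ≥ 0.5; weak = a single
sub-0.9 source. Two calls support the same segment when they overlap
≥ 50% of the shorter.

## Subtype typing

The rule cascade runs most-specific-first — III-B, III-C, III-A, II,
I-A, I-B, pseudo-I-B, I-C — because Type II's features are a subset of
III-A's. Prerequisite: the paired McrB gene's signature class is NxD
(NxxD/NxxxD systems are valid McrBC, called `non-coconut`).

* **III-B**: an SF1-helicase gene with N-terminal Sul7s-like wHTH and a
  fused Vsr-like nuclease, plus a separate Hsp70-NBD/SBD gene (CnuD).
* **III-C**: an effector with wHTH + two PLD nuclease domains, plus CnuD.
* **III-A**: CnuE with two HEPN domains (RxxxxH and C-terminal RxH) and
  CnuC fused to Hsp70-NBD/SBD + HEAT repeats.
* **II**: CnuE with a single RxxxxH HEPN and CnuH with SPB + RTL +
  OB-stalk ahead of the helicase.
* **I-A**: the helical insert in the CnuB GTPase.
* **I-B**: a separate CnuA with PYD + coiled-coil + REC.
* **pseudo-I-B**: I-B-like CnuB (CSD, no fused coiled-coil), no CnuA.
* **I-C**: CnuB with CSD (+YTH) and a fused coiled-coil.

Missing optional domains (YTH in the Type I family) demote confidence
to `partial` without changing the call; pseudo-I-B calls lacking YTH
note I-C as a candidate in the evidence trail. Typing contexts are
extracted fresh around each system's McrB gene so a truncated discovery
island cannot leak a neighboring locus's genes into the cascade.

TerY-P (VWA + PP2C + STK genes on one strand within the island) is
reported but never required — it is an accessory module. Superoperons
are found by walking upstream from the CoCoNuT along its strand while
gaps stay ≤ 200 nt (a design default for "close spacing"); reaching a
CARF/RtcR gene emits a record with the intervening systems (Type I RM =
Hsd clusters, Type III RM = Mod/Res, ShdA, Druantia) in 5'→3' order,
`rm_first`, and `coconut_last` (only Druantia may follow in-chain).

## Clustering and trees

Identity is exact matches over global-alignment length (BLOSUM62,
linear gap −4). Greedy centroid clustering processes sequences by
descending length and joins the first centroid at ≥ threshold (0.5 for
clustering, 0.9 for representatives). Clusters are star-aligned around
their centroid. Profile–profile comparison is a global column-to-column
alignment with match score `log2(Σa p_c[a]·q_d[a]/bg[a])` and linear
gap −1; the merge criterion is `max(score/self_p, score/self_q) > 0.1`
(the permissive, symmetric reading of "pairwise score to self-score
ratio"), merged by connected components within an iteration so the
result is order-independent, for 3 iterations (10 in final-pass mode).
GTPase domains are excised as Walker A through the signature motif plus
a 30-column margin. Trees are neighbor-joining on 1 − identity
(scikit-bio's NJ), with taxa sorted by label first so topology is
input-order invariant; clade–motif concordance is the fraction of motif
classes whose leaf set is one side of some edge bipartition of the
unrooted tree (leaf edges included). A flagging screen compares cluster
profiles against positive seeds versus negative-control profiles;
flagged clusters are reported, not deleted.

## The synthetic generator

The generator is the package's study condition, not a tuning knob. Each
domain label has a fixed core template (deterministic per label);
proteins are cores + linkers + padding, with literal motifs at known
offsets (Walker A `GPSGSGKS`, Walker B `ILVIDE`, signatures
`NVDE`/`NVVDE`/`NVVVDE`, HEPN `RADDAH`/`RSH`, catalytic `PDGLDIK` and
its inactivated `PAGLSIV`, CPxC repeats, 6×`IAALEQK` heptads).
Unconstrained positions draw from a 15-letter alphabet omitting
K, N, R, C and H, so no reserved motif can arise by chance and planted
truth is unambiguous. The GTPase core carries fixed per-signature-class
substitutions (~15%) plus a conserved post-signature tail, giving the
classes genuine clade-level signal for the trees while remaining well
within profile detection range. Seed alignments are 8 copies of each
core at 10% divergence.

Operon layouts follow the canonical subtype architectures (e.g. I-C =
cnuB[CSD,YTH,CC,GTPase-NxD] + cnuC[IG,DUF2357,PD-DxK,ZnR]; II and
III-A also plant TerY-P). Intra-operon gaps draw 30% overlaps
(−20..−1 nt) and otherwise 0–60 nt; McrB-role proteins are 260–400 aa
and McrC-role 210–340 aa so the strict size gates pass by construction.
Decoys are single genes with an McrB-alias domain and no partner.
Background genes are 90–180 aa with gaps of 120–400 nt, and planted
cassettes are separated by 11 background genes: a 10-gene island around
any in-cassette anchor therefore contains exactly one cassette, and no
background gene can satisfy a rescue filter by chance. Mutation noise
is i.i.d. substitution with motif positions protected by default.
The superoperon fixture chains CARF → HsdR/M/S → Mod/Res → ShdA → five
Druantia genes → a Type II cassette on one strand (~38 kb).

**What passing these benchmarks shows — and does not.** The cohorts
verify the *logic* of the census: filters, pairing, motif calls, the
rule cascade and the report plumbing behave exactly as specified on
loci whose ground truth is known. They do not emulate real sequence
evolution (no indels, no codon structure, no compositional bias, no
paralogy beyond the planted multi-copy islands), so recall/precision on
real genomes — where homologs diverge far beyond 15% and domain
boundaries blur — is not predicted by the 100% figures here; for real
data the external-hit import path exists precisely because gapped,
database-scale search is out of scope.

## Problem sizes and numerics

Default benchmark sizes: 20 genomes × (9 systems + 5 decoys) ≈ 4,100
genes for the recovery cohort; 200 fuzzed islands for the pairing
oracle; 1,000 random strings × 4 patterns for the regex oracle; 100
shuffles for coil discrimination; 16 leaves for the concordance check.
All randomness flows from explicit integer seeds (numpy Generator);
derived seeds stay below 2³¹. Reports are TSV with fixed column order
and a JSON manifest with sorted keys, so identical config + seed gives
byte-identical bundles. Degenerate inputs: empty alignments, ragged
alignments, uncalibrated profiles and zero-variance nulls raise;
sequences shorter than a profile or the coil window return empty
results rather than erroring.

## Known limitations

* Ungapped window scoring cannot bridge insertions inside a domain; a
  domain split by a long insertion would be found as (at most) two hits.
* The per-protein E-value uses a fixed-length null (300 aa); very long
  proteins are slightly anti-conservative.
* Star alignment around a centroid is not a true MSA; for the bundled
  families (ungapped cores) it is exact, for real data it is a rough
  stand-in.
* NJ trees carry no support values; the full-scale phylogenetics this
  mirrors would use approximate-ML with bootstrap.
* Bipartition-based concordance treats a class scattered as
  singleton-plus-rest as non-monophyletic only if neither side is a
  split; paraphyly versus polyphyly is not distinguished.
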