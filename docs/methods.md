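# Methods

This note documents the models, rules and numerical choices behind
`cyp75`, what the synthetic data generator does and does not emulate, and
the known limitations.

## Sequence model and coordinates

All coordinates are 1-based and closed on both ends: nucleotide `p` of a
CDS lies in codon `ceil(p/3)`, codon `i` spans nucleotides `3i−2..3i`.
Only the four unambiguous DNA bases are accepted; ambiguity codes are
rejected rather than silently resolved. Translation uses the standard
genetic code, stops at (and excludes) the first stop codon, ignores a
trailing partial codon, and flags `terminated_early` when the stop
precedes the final complete codon.

## Pairwise alignment and variant calling

Global alignment uses Biopython's `PairwiseAligner` with affine gaps.
Nucleotide scoring is match +2, mismatch −3, gap open −8, extend −1
(first gapped position costs the open penalty). These values make one
contiguous 14-nt deletion (−21) cheaper than any scattered placement of
the same gaps, which keeps mid-sized deletions intact. Protein alignment
uses BLOSUM62 with open −11 / extend −1, the BLAST defaults.

After alignment, a normalization pass shifts every gap run as far left
as possible whenever the swap is score-neutral (equal flanking letters
in the other row). Variant extraction then left-normalizes each indel
against the reference context, in the usual VCF sense: a deletion slides
left while the base before it equals its last deleted base, an insertion
rotates likewise. Left-normalization is mandatory — it is what makes
indel coordinates reproducible across implementations and what lets the
generator's planted coordinates be compared exactly.

SNP consequences (synonymous / missense / nonsense) are evaluated in the
reference reading frame. Everything downstream of an indel is judged by
*literal translation* of the edited sequence, never by per-variant
arithmetic, so compound events and frame-restoring double indels are
handled for free. For a frameshift, the divergence start is the first
residue at or after the first frameshifting indel's codon that differs
from the reference protein; the altered run is `premature_stop −
divergence_start` residues; the truncation is `reference length − mutant
length`.

Domain losses combine two mechanisms: essential domains whose start lies
beyond the premature stop (absent), and essential domains overlapped by
an in-frame deletion (internal deletion). Domains merely overlapped by a
frameshift's divergent run, or straddling the stop, are reported as
*altered*, not lost — a deliberate distinction, since the study system's
own usage separates "altered the ERR-triad" from "deleted the
heme-binding domain". Functional classification is then: any essential
domain lost → `null_truncation`; else any missense change at a critical
residue (defaults: G114 in SRS1, V210 in SRS2, H245 in SRS3, N302 in
SRS4, R428 by the PERF motif, Ala/Ser at SRS6 position 8) →
`impaired_substitution`; else `functional`. The classes are predictions
about the *enzyme*, not about flower colour, which also depends on other
pathway genes.

## Domain projection and the protein screen

Domains project from the annotated reference onto a query through the
protein alignment. States: `present` (every reference position maps),
`truncated` (the query ends inside the domain), `internal-deletion`
(unmapped positions flanked by aligned residues), `absent` (nothing
maps), `unalignable` (N-terminal identity below 30% over the first 200
columns — a non-homolog). Two thresholds matter:

* **N-terminal identity ≥ 0.30** — below this the query is not treated
  as a homolog at all.
* **Domain consensus identity ≥ 0.30** — a fully mapped domain whose
  residues share less than 30% identity with the domain consensus is
  demoted to `absent`. This guards against an artefact of global
  alignment: the junk tail translated after a frameshift can be smeared
  across the C-terminal domain intervals, which would otherwise make a
  truncated protein appear to carry SRS6.

The screen cascade applies, in order: fuzzy heme-motif search
(substitutions only, default ≤2 mismatches — a gapped heme motif would
fail the completeness check anyway), domain completeness over the
essential set (all SRSs, I-helix, K-helix, ERR-triad, heme-binding; the
transmembrane anchor is mapped but never essential), then SRS6
classification: Ala/Ser → F3′5′H, Thr → F3′H, anything else or a gap →
unknown. Every protein gets a record; nothing is dropped silently. The
discriminating SRS6 position defaults to 8 but is configurable to 9 —
published descriptions use both indexings — and the synthetic reference
carries Ala at position 8 and Ser at position 9 so either convention
classifies it as F3′5′H.

Logo information per column is `log2 20 − H`, with `H` the Shannon
entropy of the residue frequencies; gaps carry no frequency mass but
their fraction is reported. The small-sample correction
`e_n = (19/2n)/ln 2` is off by default.

## Median network

Characters are binary by construction: each substitution (per derived
allele, so multi-allelic sites split) and each distinct indel event is
one character, regardless of indel length. Columns with identical
presence/absence patterns condense into one column with summed weight —
the standard condensation without which observed haplotypes separated by
several private mutations would not be adjacent to anything. The median
closure iterates coordinatewise majority over all triples to a fixed
point; being defined on sets, it is order-independent, and it is guarded
above 25 characters because the closure can grow exponentially. The
network joins vectors at condensed-Hamming distance 1; closure
guarantees connectivity, so a disconnected graph is treated as an
internal error, not a data condition.

## Recombination scan

For a child and an ordered pair of parents, the informative sites are
the characters where the parents differ; for binary characters the child
matches exactly one parent at each. The minimal breakpoint count is the
number of switches in that match sequence along the gene (a left-to-right
scan is provably optimal here; an exhaustive enumeration over all
2^n switch assignments backs it in the tests). Sites where a child
matches neither parent can only occur for multistate inputs and are
excluded with a warning.

Scoring a parent pair uses **total parsimony cost = breakpoints +
triplet-private sites**, where a triplet-private site is one segregating
within the triplet at which the parents agree and the child differs —
a mutation that descent from those parents cannot supply. Ranking by
breakpoints alone is wrong in both directions: it would let a pair
"explain" a true recombinant with zero breakpoints by silently invoking
a private repeat mutation, and it would prefer a spurious one-crossover
story over plain descent-plus-one-new-mutation. Ties prefer fewer
private sites, then more informative sites, then lexicographic ids. The
5′ parent is whichever parent the child matches at the first informative
site, and the breakpoint interval is bounded by the informative sites
flanking the first switch (exclusive of both).

A child is *called* recombinant when its best explanation (i) needs at
least one crossover, (ii) explains every triplet-segregating site, and
(iii) the child is not a candidate ancestor — its derived-allele set is
not a subset of another haplotype's. Condition (iii) matters because
when both an ancestor and its descendant are sampled, the ancestor is
always trivially "explainable" as a one-crossover mix of the root and
the descendant; treating subset haplotypes as intermediates of plain
descent removes exactly these false positives while leaving genuine
chimeras (which combine alleles of two lineages and are nobody's subset)
flagged. Crossover support uses a permutation test — shuffle the order
of the informative sites, recount breakpoints, `p = (1 + #{≤ observed})
/ (n_permutations + 1)` — chosen over any parametric form because
informative-site counts are tiny.

## The synthetic data generator

The generator defines the study conditions; it is deliberately not
configurable in its paper-panel part. The reference is a stylized
510-residue F3′5′H (CDS 1,533 nt including the stop) carrying the full
domain map: transmembrane 5–25, SRS1 110–125 (G114), SRS2 208–214
(V210), SRS3 244–250 (H245), SRS4 295–315 containing the I-helix
301–308 (N302), K-helix 392–402 (ExxR at 399–402), SRS5 404–414,
ERR-triad 424–433 (PERF at 424–427, R428 as codon AGG), heme-binding
460–470 = `PFGAGRRICAG`, SRS6 487–496 (A at 494, S at 495). The protein
length 510 is the unique value making the G19833 arithmetic internally
consistent (divergence at 358 for 28 residues → mutant length 385;
385 + 125 truncated = 510).

The nucleotide sequence is found by backtracking over codons under joint
constraints: no stop in frame 0 before codon 511; the *first* stop in
the +1-shifted frame read by the G19833 C-insertion falls at mutant
codon 386; the first shifted stop after the Mex235/M0056 14-nt deletion
falls at mutant codon 430; after the UI 111 single-T deletion at
nt 1,323 (codon 441) at mutant codon 457; and after the MDRK 4-nt
insertion at mutant codon 446. Each frameshift's first mutant residue is
constrained to differ from the reference residue (so divergence starts
where stated), and indel flanks are constrained so left-normalized
coordinates equal the planted ones. Every invariant is re-verified by
literal translation each time the panel is built; violations raise
immediately.

Fixture choices where the source material is silent: the V0491/M0056
shared synonymous SNP sits at nt 501 (a third-codon position — no
second-position change can be synonymous under the standard code); the
G5686 private SNP sits at nt 300, 5′ of the recombinant's breakpoint
region, which keeps MDRK (not its descendant G5686) the uniquely most
informative 5′ donor of M0056; the M0056 crossover is planted at nt 900
(anywhere in 502–1,244 would be indistinguishable — only interval
containment is ever asserted); the G2858 15-nt in-frame deletion removes
residues 461–465 inside the heme motif; Mex235 and M0056 share identical
deletion coordinates, as the recombination narrative implies.

Random panels plant edits with per-site SNP rate 0.002 and indel rate
0.0005 (a few SNPs and at most about one indel per 1.5-kb haplotype,
matching the sparseness of natural CDS haplotypes of this gene), indel
lengths drawn from {1–6, 9, 14, 15}. Edits keep ≥ 12 nt apart (no two in
one codon), avoid creating stop codons in the reference frame, avoid the
termini, and have unambiguous left-normalized coordinates by
construction. Truth labels come from the generator's own coordinate
arithmetic plus literal translation — no alignment — so the round-trip
tests genuinely exercise the alignment-based engine. What the generator
does **not** emulate: sequencing error, alignment-ambiguous tandem
repeats, splice variation, promoter/regulatory alleles, diploid
genotypes, and deep divergence between haplotypes; passing tests
therefore demonstrate the inference chain on clean haplotype panels, not
robustness to noisy assemblies.

## Problem sizes used in the test suite

The suite verifies translation against an independently written codon
table on 1,000 random 300-nt sequences; alignment optimality against a
memoized independent recursion up to combined length 16, itself
validated by pure exhaustive enumeration on shorter inputs; median
closure against a bitmask closure oracle over 50 random matrices of up
to 12 characters; and breakpoint minimality against full switch
enumeration up to 12 informative sites. Statistical properties use two
200-haplotype random panels (planted-edit and class recovery ≥ 99%),
100 planted chimeras with ≥ 8 informative sites per flank (parent-pair
recovery ≥ 95%), and 1,000 null simulations for the permutation test
(empirical type-I ≤ 0.07 at nominal 0.05). These sizes are the package's
chosen verification scale; all are re-run by `python -m pytest`.

## Known limitations

* Variant calling assumes haplotypes are alleles of the same gene
  (identity ≥ 50% is enforced); it is not a general-purpose caller.
* Median closure is exponential in the worst case and refuses > 25
  condensed characters rather than approximating (no epsilon-style
  network reduction is implemented).
* The triplet scan models a single crossover class well; gene
  conversion tracts and multi-method consensus (RDP-style) are out of
  scope.
* The recombinant call is undirected evidence: when a panel contains a
  conflict, parsimony alone cannot always orient which haplotype is the
  chimera; the candidate-ancestor rule resolves the orientation in
  panels like the built-in one but is a heuristic.
* Domain projection trusts a single global alignment; for deeply
  diverged proteins an HMM-based annotation would be more appropriate.
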