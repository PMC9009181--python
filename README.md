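# cyp75

Haplotype-to-function analysis for flavonoid 3′5′-hydroxylase (F3′5′H,
CYP75A) coding sequences — the class of cytochrome-P450 flower-colour
genes exemplified by the common-bean *V* gene.

## The problem

Loss of F3′5′H activity shifts flavonoid production from delphinidin-type
(purple) to cyanidin-type or colourless products. Natural CDS haplotypes
of such a gene typically differ from the functional reference by a
handful of SNPs and small indels, and the biological question is always
the same chain of inference:

1. Which nucleotide variants does each haplotype carry?
2. What do they do to the protein — silent change, critical-residue
   substitution, frameshift with a premature stop?
3. Which of the conserved P450 features survive: the six substrate
   recognition sites (SRS1–6), the I-helix, the K-helix (ExxR), the
   ERR-triad/PERF region, and the heme-binding motif `PFGAGRRICAG`?
4. How are the haplotypes related — a median network of observed
   sequences plus inferred intermediates, with edges labelled by
   mutations?
5. Are any haplotypes intragenic recombinants, carrying the 5′ end of one
   lineage and the 3′ end of another?
6. Across a set of candidate proteins, which are complete F3′5′H enzymes
   at all — heme motif present, no essential domain deleted, and
   Ala/Ser (versus Thr for F3′H) at the discriminating SRS6 position?

`cyp75` implements each step as a small, tested library module plus a
command-line pipeline, and ships a fully synthetic nine-haplotype panel
(one functional reference, one critical-residue substitution allele, and
seven domain-loss alleles, including one intragenic recombinant) whose
protein-level arithmetic is engineered exactly and re-verified at
generation time.

## Methods in brief

* **Variant calling** — optimal global alignment (match +2, mismatch −3,
  gap open −8, extend −1) with mandatory left-normalization of indels, so
  coordinates in repeats are reproducible. Adjacent gap columns merge
  into single indel events.
* **Consequences** — literal translation of the edited CDS (standard
  genetic code). A frameshift's divergent run is `stop − divergence`
  residues; truncation is `reference length − mutant length`. Essential
  domains wholly downstream of a premature stop, or overlapped by an
  in-frame deletion, are lost; a haplotype losing any essential domain is
  a predicted null, one with a critical-residue missense change is
  impaired, anything else functional.
* **Median network** — every substitution and indel event is one binary
  character; identical presence/absence patterns condense into weighted
  columns; the node set is closed under coordinatewise majority of
  triples (median closure); edges join vectors one condensed character
  apart.
* **Recombination** — triplet scan: along the gene, the minimal number of
  parent switches explaining a child at the sites where two candidate
  parents differ, ranked by total parsimony cost; permutation of site
  order provides a significance level.
* **Protein screen** — heme-motif fuzzy search (≤2 substitutions),
  domain projection through a BLOSUM62 global alignment with
  completeness states (present / truncated / internal-deletion / absent),
  SRS6-residue classification, and per-domain sequence-logo information
  content (bits).

See `docs/methods.md` for the full model description and design choices.

## Worked example

Run the whole pipeline on the built-in synthetic panel:

```sh
cyp75 -v all --out results/panel
```

which writes `variants.tsv`, `variants.vcf`, `consequences.{tsv,json}`,
`network.gml` (+ node/edge tables), `recombination.tsv`, `screen.tsv`
and `summary.json`, and prints:

```json
{
 "functional_classes": {
  "functional": 1,
  "impaired_substitution": 1,
  "null_truncation": 7
 },
 "hub_haplotype": "V_5-593",
 "n_haplotypes": 9,
 "n_non_functional": 8,
 "n_observed_nodes": 9,
 "n_passing_screen": 2,
 "n_recombinants": 1,
 "recombinant_children": [
  "v_M0056"
 ],
 "reference": "V_5-593"
}
```

Reading this: of the nine haplotypes, only the reference `V_5-593`
predicts a fully functional enzyme; `vlae_V0491` carries the R428M
substitution beside the PERF motif (impaired); the remaining seven lose
the heme-binding domain and/or SRS6 outright. The median network has the
functional reference as its hub, and the triplet scan identifies exactly
one intragenic recombinant, `v_M0056`, which joins the 5′ end of
`vlae_MDRK` to the 3′ end of `v_Mex235` (single crossover between
nt 501 and nt 1,245). Only the two full-length proteins pass the
F3′5′H completeness screen.

The same stages are available individually (`cyp75 simulate`,
`variants`, `consequences`, `network`, `recomb`, `screen`) on your own
FASTA files and domain-map TSVs.

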