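# Methods

## Scope and data model

The package operates on four evidence layers about a curated *seed* set of
neurodegeneration-associated genes:

1. **Seed sets.**  A seed set carries enumerable members (gene symbols,
   optionally UniProt-style accessions) and a *declared population size* K.
   The two are deliberately decoupled: curations often state a population
   count ("the 48 most common genes") without enumerating every member, and
   all hypergeometric statistics must use the claimed K, not the enumerable
   subset.  The packaged seed set enumerates 38 members with K = 48.
2. **Interaction networks.**  Undirected simple graphs keyed by gene symbol.
   Self-interactions are excluded at network construction (they inflate
   degree without adding partners), reversed and duplicate pairs collapse to
   one unweighted edge, and multi-evidence labels are kept as edge metadata
   only.  Degree = number of distinct partners; a hub is a maximal-degree
   node (ties: all co-maximal nodes are reported, since single-hub summaries
   presume a unique maximum that real tables do not guarantee).
3. **Detection matrices.**  Boolean protein × dataset tables from shotgun
   mass spectrometry, with named dataset groups (e.g. two independent
   B-lymphocyte surveys forming the `B_cell` group).  Because MS is
   insensitive, detection is read as abundant expression; a protein counts
   as detected in a group if any dataset of the group detected it (union
   rule).  Proteins absent from a matrix are tri-state *unknown*, not
   false — curated tables only contain the rows that were reported —
   while summaries conservatively count unknown as not detected.
   Percentages over K truncate toward zero, matching how such summary
   percentages are conventionally printed (34/48 → 70%).
4. **Immunopeptidome assays.**  Ligand-elution records filtered in three
   steps to endogenous MHC class II ligands of unmanipulated human B-lineage
   cells: class II restriction; mass-spectrometry elution assays from
   B-lineage sources (EBV-transformed lymphoblastoid lines included — they
   are the dominant source material) without immunization or stimulation;
   and accession normalization through an explicit idmap so obsolete IDs do
   not split parents.  Every dropped record is charged to the first failing
   criterion in a fixed order, so drop counts plus kept count always equal
   the input count.

## Statistics

* **Enrichment factor.**  EF = (k/n)/r0.  For interactome hub scans r0 is
  the fixed constant 0.002 — the seed population (48) over the count of
  protein-coding genes with retrievable interactors (23 098) — kept as a
  constant rather than recomputed from K/N (48/23098 ≈ 0.00208) because the
  screening convention fixes it; it is configurable.  For genome-background
  parent lists the reference is K/N with N = 20 000 coding genes.  EF is
  returned unrounded (the identity EF·r0·n = k holds to machine precision);
  display layers round half-up to 2 decimals.
* **Exact test.**  One-sided enrichment p-values are the hypergeometric
  upper tail P(X ≥ k), computed via `scipy.stats.hypergeom.sf` (log-gamma
  based, stable at N ≈ 2·10⁴); k = 0 returns exactly 1.  This equals the
  one-sided Fisher exact test on the corresponding 2×2 table.  A two-sided
  option (minimum-likelihood convention) exists but is not the default:
  the analyses test enrichment only.
* **Correction.**  Bonferroni (default) and Benjamini-Hochberg, both
  accepting an explicit family size m ≥ list length.  They are implemented
  directly (statsmodels' `multipletests` does not expose m) and
  cross-checked against statsmodels in the test suite at m = list length.
* **Hub screen.**  Candidates need *strictly more than* 10 seed partners
  (configurable).  The correction family defaults to the candidates passing
  the screen — the natural family; an explicit m can be supplied when the
  intended family is wider.  Results sort by adjusted p, then EF descending,
  then symbol.
* **Allele exclusivity.**  Restriction labels are kept verbatim: serotype
  labels ("HLA-DR15"), allele pairs ("HLA-DRB1*15:01") and generic class
  labels ("HLA class II") make different claims, and silently conflating
  them would fabricate exclusivity.  A parent is exclusive to an allele
  group iff its whole (non-empty) restriction set lies inside the group; the
  default DR15 group {HLA-DR15/DR51, HLA-DRB1*15:01 (HLA-DR15), HLA-DR15}
  reflects the DRB1*15:01/DRB5 co-expression of the DR15 haplotype and is
  configurable.

## Synthetic data

The generators are pure functions of a configuration plus one integer seed;
sub-streams are derived by SHA-256 hashing of (seed, component name), so
adding a generator never shifts another's output.

* **Interactome.**  Planted hubs are wired *exactly*: a hub configured as
  (n = 500, k = 20) gets exactly 500 partners of which exactly 20 are seed
  genes, so hub-scan counts are deterministic ground truth and the EF
  estimate equals (20/500)/0.002 = 20 exactly.  The remaining non-hub nodes
  (seed and background genes alike) form an Erdős–Rényi G(n, p) background;
  including the seed genes in that pool gives non-hub nodes null-level
  seed-connectivity, which is what the recovery property is tested against.
  Defaults: 48 seed genes, 2 000 background genes, edge probability 0.002,
  one planted hub (500, 20).
* **Detection.**  Per-group Bernoulli detection with defaults equal to the
  observed seed detection rates (B cell 34/48, DC 20/48); a designated
  subset can be forced B-cell-only to plant an exact group difference.
* **Assays.**  A parent list of n_parents = 3 523 by default, each parent a
  seed gene with probability ρ·K/N (ρ = 2.6 by default, the unrounded
  enrichment of the curated parent list; 22/3523 over 48/20000 gives 2.60,
  while 0.62/0.24 on pre-rounded percentages gives 2.58 — the unrounded
  convention is used throughout).  Parents receive 1–4 verbatim restriction
  labels; a configurable fraction of records (default 0.3) is flagged as
  immunization experiments so the endogenous-ligand filter has realistic
  work to do.

What the generators do *not* emulate: scale-free degree distributions,
abundance-dependent detection, peptide-sequence realism beyond alphabet
validity, or correlated restriction assignments.  Passing recovery tests
therefore demonstrates correctness of the counting and testing machinery
under the stated null, not robustness to real-interactome topology.

## Numerical and procedural choices

* Degree ties: all co-maximal hubs reported, lexicographic order.
* Displayed EFs round half-up (floor(x·100 + 0.5)/100), avoiding banker's
  rounding surprises on .005 boundaries.
* Accession-map resolution follows chains up to depth 5, then raises —
  a cheap cycle guard for hand-built maps.
* Empty inputs: empty interaction tables yield empty networks; empty parent
  lists, queries and annotation maps are errors (their statistics are
  undefined).
* Reports serialize with sorted keys and sorted collections, so re-export is
  byte-identical.

## Problem sizes in the test suite

The suite verifies the hypergeometric tail against an exhaustive
enumeration oracle for every parameter combination with N ≤ 12 (tolerance
1e-12).  Planted-hub recovery runs 100 generator seeds with an 800-gene
background at edge probability 0.005; the assay-generator calibration
(mean EF within 10% of a planted ρ = 3) uses 60 seeds at n_parents = 1 500,
where the binomial standard error of the mean EF is about 4%.  These sizes
make the full suite run in well under a minute while keeping the sampling
error far inside the asserted bands.

## Known limitations

* Network analyses are symbol-keyed; paralogs sharing a symbol collapse.
* The union detection rule cannot distinguish "detected in one lab" from
  "detected everywhere"; no abundance modeling is attempted.
* Restriction labels are not ontology-normalized; exclusivity answers are
  relative to the supplied allele group and the verbatim label vocabulary.
* Historical interaction-database snapshots cannot be reconstructed, so
  node-for-node reproduction of previously published network figures is out
  of scope; the machinery is instead validated on packaged count tables and
  planted-truth synthetic data.
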