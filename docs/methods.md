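# Methods

## Annotation model

The unit of annotation is a *category path*: a Cat1 label, optionally refined
by a Cat2 and then a Cat3 label.  Each gene carries exactly one path; the full
path tuple, not the leaf name, is the category identity, so "Detoxification"
under STRESS RESPONSE and under some other Cat1 would be two distinct
categories (and is flagged by the validator as a nesting violation, since the
curated lists are expected to nest each leaf under a single parent).  Paths
may stop at any depth — a gene labeled only to Cat1 is counted at level 1 and
contributes to "not in category" cells at levels 2 and 3.  This keeps the
universe size identical for every category within a level, which is what
makes per-level p-values comparable.

Genes with no functional information are not dropped: they sit in an explicit
UNASSIGNED category.  This is the load-bearing design choice of the whole
approach — excluding them would shrink the background universe and shift every
other category's p-value (the `derive_background`/subset machinery lets a user
quantify exactly that effect).

The loader accepts the published CSV shape
(`Wormbase ID,Sequence ID,Category 1,Category 2,Category 3`) with a
column-mapping dialect for other headers.  A child cell repeating its parent's
label is normalized to absent.  When no explicit coding flag is present,
protein-coding status is derived from a configurable set of non-coding Cat1
labels (default: NON-CODING RNA, PSEUDOGENE); the ORF-only background keeps
coding records only.  Gene-ID resolution is exact and case-sensitive for
primary IDs (WBGene-style grammar is case-fixed) and case-insensitive for
sequence names, which appear in mixed case in the wild.

## Enrichment statistics

* **Test.** One-sided Fisher's exact test, upper tail: with universe size
  $N$, category size $K$, mapped RGS size $n$ and overlap $a$, the p-value is
  the survival function of the hypergeometric distribution at $a-1$, computed
  with `scipy.stats.hypergeom.sf`.  The test suite verifies agreement with an
  exact big-integer enumeration oracle to better than 1e-9 relative error over
  every table with $N \le 60$ (measured: ~9e-16).  Depletion is out of scope.
* **Families.** FDR correction (Benjamini–Hochberg step-up by default,
  Bonferroni behind a switch) is applied separately within each category
  level, across *all* categories present in the universe at that level.
  Categories with zero RGS genes score exactly p = 1 and stay in the family
  and the CSVs, so the BH family — and hence every adjusted p — is stable
  across gene sets run against the same universe.
* **Cat2/Cat3 background.** Deeper categories are tested against the full
  universe, not their parent, so a Cat3 row answers "is this leaf
  over-represented relative to the genome".
* **Significance.** `p_adjusted < 0.05` (configurable) AND at least
  `min_count` (default 1) RGS genes.  Plots additionally color by the
  conventional adjusted-p bins 0.05/0.01/0.001.
* **Determinism.** Rows are sorted by ascending p, ties broken by descending
  RGS count then label; CSV floats are written with a fixed `%.6g` format, so
  identical inputs produce byte-identical outputs.
* **Mapping bookkeeping.** Inputs resolve by primary ID then sequence name;
  post-resolution duplicates are collapsed and counted, unmapped identifiers
  reported verbatim and excluded from every contingency cell.  An RGS that
  maps nowhere is a hard error.

## Reannotation rules

The rule cascade over (TM consensus 0–6, transporter-domain flag,
signal-peptide flag) is total and ordered; the first match wins:
transporter before generic TM, and the signal-peptide rule only at consensus
0 ("signal sequence but no TM domain").  Consensus values 3–5 are grouped
with 1–2 into the low-confidence membrane-spanning branch: the source rules
name only 1–2 explicitly and are silent on 3–5, and grouping all
sub-unanimous predictions as lower-confidence matches the intent of
separating high- from low-confidence TM calls.  The engine touches only genes
present in the prediction table and is idempotent; gene count is conserved,
only paths change.  Ortholog calls use strict inequalities
(bitscore > 40, e-value < 0.01), both thresholds configurable.

## Coverage reports

Attribute tables (GO presence, human-ortholog and lineage-specificity flags,
optional BLAST scores) are frozen per-gene snapshots; the module never
queries live services.  Genes missing from the table count with all flags
false and are listed, so absence of evidence is visible rather than silently
dropped.  Tallies default to protein-coding genes (the convention for
GO/ortholog coverage figures), switchable.  Percentages are reported to one
decimal, rounding half-up.  Overlap counts enumerate all $2^k$ predicate
regions, which partition the category exactly.

## Visualization

SVG text is emitted directly with fixed viewBox, font metrics and 6-decimal
float formatting, making byte-determinism a property of the writer rather
than of a rendering library.  Bubble area is `scale × rgs_count` (or the
category percentage, behind a switch); the radius is therefore
`sqrt(area/π)`, checkable from the emitted attributes.  Sunburst spans: a
Cat1 arc covers its proportional share of the mapped genes carrying a Cat1
label; a child arc covers `parent_span × child_count / parent_count`.  Genes
whose path stops early leave an explicit neutral filler arc, propagated to
outer rings, so child arcs always nest inside their parent *and* every ring
closes to 360° — with independent per-ring normalization those two contracts
are mutually inconsistent.  Non-significant rows are omitted from plots but
never from CSVs.

## Synthetic data

The generator emulates the structure of a whole-genome list: 2,000 genes in
20 Cat1 groups by default, Dirichlet-weighted (α = 5) uneven category sizes,
three Cat2 per Cat1 and two Cat3 per Cat2, 10% non-coding genes, and a
10%/20%/70% mix of paths stopping at Cat1/Cat2/Cat3.  These sizes keep
hundreds of full-pipeline replicates inside seconds while leaving ~100-gene
categories for stable statistics.  A planted signal fixes one Cat1 at an
exact size and biases the RGS draw by weighted sampling without replacement
(weight = fold for category members, 1 otherwise); at fold 1 the draw is
plain uniform sampling, verified indistinguishable from uniform by
chi-square.  The standard recovery condition — fold 5, RGS 50, category
100/2,000 — recovers the planted category as the top level-1 hit in ≥95% of
200 seeded replicates.

What the generator does **not** emulate: the real *C. elegans* category-size
distribution (a 31k-gene list with a handful of huge and many tiny
categories), correlated gene families, or identifier aliasing beyond a single
synthetic sequence name per gene.  Passing tests therefore demonstrate the
statistical machinery and its calibration, not curation quality of any real
annotation list.  Synthetic IDs use the reserved `SYNG` prefix so they can
never collide with real `WBGene` identifiers.

## Numerical notes and limitations

* All randomness flows through one `numpy.random.Generator` per entry point,
  seeded explicitly; every stochastic artifact records its seed.
* p-values are never clipped; a = 0 yields exactly 1 by construction.
* The BH implementation is ~10 lines of numpy (stable argsort + reverse
  cumulative minimum) and is cross-checked against statsmodels in the tests.
* Degenerate inputs: empty universes, unmappable gene sets, categories absent
  from a universe, out-of-range consensus values and malformed CSV rows all
  raise with the offending items named; validation of annotation structure
  reports rather than raises.
* The acceptance script scales its simulations to 3,000 null
  category-replicates and 200 recovery replicates on 2,000-gene universes —
  sizes chosen to give three-decimal stability of the reported rates while
  keeping a full run in seconds.
* Real published annotation lists and their companion prediction/attribute
  snapshots are consumed from files supplied by the user; the package bundles
  none, and structural claims about any particular release (category totals,
  reassignment tallies) should be recomputed from that release's files with
  `wormcat validate`, `diff`, and the coverage tools.
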