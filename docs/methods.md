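# Methods

## Cleavage model

Every protease is reduced to single-position specificity: a set of P1
residues whose flanking peptide bond is hydrolysed, the recognized flank
(cleavage C-terminal or N-terminal to P1), and an optional set of
opposite-flank residues that suppress cleavage (the classical Xaa–Pro
resistance). Bonds are indexed 1-based, bond *i* joining residues *i* and
*i* + 1, so a chain of *N* residues has *D* = *N* − 1 bonds and no terminal
pseudo-bonds. This deliberately ignores extended-subsite preferences
(P2…P2′ and beyond): for several of the shipped enzymes (papain, calpain 2,
the cysteine proteases generally) the true specificity is dominated by P2,
and a P1/P1′ reduction over- or under-cuts accordingly. The rule fixture is
versioned (`proteases-v1`) and every rule carries a provenance note; two
entries (the pH 1.3 acid protease and pancreatic elastase) follow published
site lists verbatim, the rest are field-standard approximations. Because
DH and release counts are completely determined by the rule set, fixture
fidelity is the dominant source of drift against any external digestion
tool, which is why `bond_audit` exposes a per-bond, per-enzyme table to
attribute discrepancies to individual rule entries.

Digestion is exhaustive and time-free: every recognized bond is cut, and a
multi-enzyme digest cuts the union of the member cut sites. For P1/P1′
rules this "simultaneous" semantics coincides with sequentially digesting
fragments enzyme by enzyme (the recognition context of a bond never spans a
previous cut), a coincidence the test suite asserts on random cases rather
than assumes. Partial digestion, missed-cleavage enumeration and
pH/temperature kinetics are out of scope.

## Scoring statistics

* *DH* = 100 · *d*/*D*, with *d* the number of cut bonds — the theoretical
  degree of hydrolysis, on the 0–100 scale, per chain. Ranges across chains
  are reported as (min, max).
* *A*<sub>umami</sub> = *a*<sub>umami</sub>/*N*, with *a*<sub>umami</sub>
  the number of released fragments (counted with multiplicity) whose full
  residue string appears in the known-umami catalog. Matching is exact
  full-sequence identity, not substring occurrence in the parent chain:
  the statistic counts *released* umami peptides. Both conventions exist in
  the literature; the substring variant would count motifs never liberated
  by the enzyme set.

Release profiles default to the 2–4-residue window (short peptides
dominate reported umami actives) and deduplicate by residue string within
a chain, keeping multiplicity and positions so occurrence counts remain
available. The novelty screen is exact-match against the catalog; the
shipped catalog (`catalog-v1`, TSV) holds ten named knowns with
biopep/literature provenance tags and is deliberately extensible — its
version is stamped into every report because known-peptide coverage
directly shifts novelty counts.

## Pairwise identity

Chain homology is assessed by optimal global (end-to-end) alignment with
affine gaps via Biopython's `PairwiseAligner`; identity is identical
columns over all aligned columns, gap columns included, recorded together
with the scoring parameters. Defaults are match 1 / mismatch 0 /
gap-open −5 / gap-extend −1. Among co-optimal alignments the aligner's
first deterministic traceback is used; for the near-identical chain pairs
this workflow targets (a handful of substitutions over ~1400 residues) the
identity value is insensitive to both the tie-break and the scoring
scheme, which a test asserts across parameter settings.

## Charge, pI, mass, hydrophobicity

Net charge at pH is the Henderson–Hasselbalch sum over ionizable groups:
basic contributions 1/(1 + 10^(pH − pKa)) from the N-terminal amine and
H/K/R side chains, acidic contributions −1/(1 + 10^(pKa − pH)) from the
C-terminal carboxyl and D/E side chains, plus C/Y when
`cys_tyr_ionizable` is on (the default). The function is strictly
decreasing in pH, so the isoelectric point is the unique root, found by
bisection on [0.1, 13.9] to 10⁻⁴ pH units. Both the raw charge and its
nearest integer are reported, since "zero net charge" claims for short
peptides usually mean the rounded value.

Terminal pKa values are residue-specific: the pKa of the α-amino group
depends on the N-terminal residue, the α-carboxyl on the C-terminal
residue. This is what short-peptide pI calculators effectively do, and it
is required to explain why same-composition dipeptides show different pI.
The shipped table (`constants-v1`) was calibrated on a nine-dipeptide
reference panel — the anchor residues I/S/V/H (N-terminal) and S/T/L/M/N/Y
(C-terminal) are solved from the panel's two-group closed form
pI = (pKa_N + pKa_C)/2, other residues carry generic peptide-terminal
values (7.90 / 3.10) — and reproduces the panel within ±0.05 pH units.
The table is config-replaceable and every report names the constants
version, so an EMBOSS-style table can be swapped in for sensitivity
analysis.

Monoisotopic mass is the sum of standard residue monoisotopic masses plus
one water (18.010565 Da), reported to 4 decimals and cross-checked in the
tests against pyteomics as an independent oracle.

Hydrophobicity is an additive per-residue transfer-free-energy sum in
kcal/mol. The scale is calibrated on the same nine-dipeptide panel (the
dipeptide sums form a linear system with one free anchor, fixed at
h(S) = 4.00 kcal/mol); residues outside the panel carry interpolated
values on the same scale and no accuracy claim. Additivity itself is the
modelling assumption — conformational effects are ignored — so
hydrophobicity is treated as a descriptive column, not a screening
criterion.

The umami-residue proportion is 100 × (residues in {D, E, G, Y, A, F, H,
T, V, S}) / length, to 2 decimals.

## Screening semantics

All thresholds are strict (>) by default: non-toxic, non-allergenic,
umami proportion > 0%, log S > 0, −CE and −CIE > 40 kcal/mol, sensory
score > 5/10. Stage flags are composed monotonically (sensory-pass ⊆
docking-pass ⊆ docked ⊆ physchem-pass) and a missing annotation fails the
corresponding criterion while flagging the row, because every annotation
originates outside the package. The report is deterministically ordered
(descending −CIE, then −CE, then peptide) and `summarize_stages` exposes
per-criterion exclusion lists rather than a single pass count, so any
disagreement with an external tally can be localized to a criterion.

The shipped `published_screen_annotations.tsv` is a real published 82-peptide
predictor table (toxicity/allergenicity/log S). The companion
`docking_sensory_synthetic.tsv` is synthetic: docking energies and most
sensory scores cannot be recomputed without a docking engine and a taste
panel, so the fixture mirrors only the reported pass/fail *pattern*
(44 docking-annotated peptides, 9 dock failures, 9 dual-energy passers,
6 sensory winners, with the five printed sensory scores kept). Stage
counts derived from it validate the filter logic, not the docking.

## Synthetic data

`generate_collagen_like` emits telopeptide + (G·X·Y)ⁿ + telopeptide with
per-position residue distributions; defaults are 450 triplets and
16-residue telopeptides (~1382 residues, matching type I collagen α-chain
lengths) with X/Y compositions proline- and alanine-rich so overall
composition is rich in G, A, L, T as real α-chains are. Hydroxyproline is
written as proline since rules act on the canonical alphabet — this is the
main infidelity to real collagen chemistry, alongside the absence of real
telopeptide sequence and of any positional correlation between triplets.
Consequently, passing digestion tests on synthetic chains demonstrates
correctness of the cleavage/statistics machinery, not numerical agreement
with digests of real collagen. `mutate_chain` produces near-identical
homolog pairs (glycine backbone preserved) for identity checks.

`generate_annotations` draws every annotation field from configured
distributions (defaults: toxin rate 0, allergen rate 0.2, log S
N(1.4, 1.0), −CE N(39, 4), −CIE N(37, 4), docking failure rate 0.2,
sensory N(5, 1.2) clipped to [0, 10] — rates in the neighbourhood of the
shipped real table) and returns the true per-criterion labels computed
directly from the drawn values, enabling exact label-for-label validation
of the filter. A single seeded NumPy generator threads through all draws;
every output records its seed.

## Numerical and engineering choices

* Bisection tolerance 10⁻⁴ pH; masses rounded to 4 decimals; umami
  fractions to 2 (matching how such tables are printed).
* Degenerate inputs are errors, not silent values: empty rule lists,
  single-residue chains (D = 0), inverted length windows, duplicate
  catalog or annotation peptides, non-normalized composition tables.
* Ambiguity codes are rejected by default; a permissive mode maps them to
  a sentinel that never matches a rule and never counts as an alignment
  match.
* Pipeline outputs are plain TSV plus one JSON summary and a provenance
  record (fixture/catalog/constants versions, criteria, seed); identical
  configs byte-reproduce all tables.
* Test and acceptance problem sizes — 30-mer oracle scans, 200–300-row
  annotation tables, 450-triplet chains, 1000-case conservation sweeps —
  were chosen as the smallest sizes that exercise every code path with
  comfortable statistical margins.

## Known limitations

P1/P1′ rule expressiveness (no subsite matrices, no kinetics); exact-match
novelty (no fuzzy or substring matching); additive hydrophobicity;
calibrated rather than first-principles pKa values outside the anchored
residues; docking, toxicity, allergenicity, solubility, absorption and
sensory values are never computed, only ingested.
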