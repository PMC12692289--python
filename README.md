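# umamipep

In-silico discovery of umami taste peptides from collagen-like proteins.

Savory ("umami") taste arises when short peptides — typically 2–4 residues —
bind the T1R1/T1R3 taste receptor. Bone collagen is an attractive, cheap
precursor: its α-chains are long Gly-X-Y repeat polymers rich in residues
(G, A, E, D, S, T, V…) associated with umami taste. `umamipep` implements
the computational leg of that discovery workflow for food scientists and
peptide researchers:

1. **Simulated proteolysis.** Each protease is encoded as a P1/P1′ cleavage
   rule (the residue whose flanking bond is hydrolysed, the flank
   recognized, and optional proline-type blocking). Digestion is exhaustive
   and multi-enzyme digestion takes the union of cut sites. A shipped,
   versioned fixture encodes 20 industrial proteases.
2. **Enzyme scoring.** For a chain of *N* residues and *D* = *N* − 1 bonds
   cut at *d* of them, the theoretical degree of hydrolysis is
   *DH* = *d*/*D* × 100%, and the umami-fragment frequency is
   *A*<sub>umami</sub> = *a*<sub>umami</sub>/*N*, where *a*<sub>umami</sub>
   counts released fragments that match a catalog of known umami peptides.
   Single enzymes and 2–3-enzyme combinations are ranked by these
   statistics.
3. **Release profiling and novelty.** Released 2–4-residue fragments are
   deduplicated, located, and split into catalog-known vs novel.
4. **Physicochemical characterization.** Monoisotopic mass, isoelectric
   point (bisection on a strictly decreasing Henderson–Hasselbalch charge
   model), net charge at pH 7, a transfer-free-energy hydrophobicity sum,
   and the proportion of the ten umami residues (D, E, G, Y, A, F, H, T,
   V, S).
5. **Multi-criteria screening.** Candidates must be non-toxic,
   non-allergenic, contain umami residues, be water-soluble (log S > 0),
   dock with −CDOCKER energies −CE and −CIE > 40 kcal/mol, and score > 5
   on a 0–10 umami sensory scale. Toxicity, allergenicity, solubility,
   docking and sensory values are *ingested* annotation tables — the
   package never predicts them — and missing annotations fail closed.

A synthetic-data module generates collagen-like Gly-X-Y chains and
annotation tables with known ground-truth pass labels, so the entire
pipeline is testable without any downloads.

## Worked example

```sh
$ umamipep physchem IS VY HN
peptide  mass      pI    net_charge  net_charge_raw  hydrophobicity  umami_fraction
IS       218.1267  5.46  0           -0.1313         7.24            50.0
VY       280.1423  5.45  0           -0.0995         6.73            100.0
HN       269.1124  7.69  0            0.0943         11.08           50.0
```

Mass is the monoisotopic peptide mass in Da, `pI` the pH of zero net
charge, `net_charge` the nearest-integer charge at pH 7 (all three
dipeptides are effectively neutral in the mouth), and `umami_fraction` the
percentage of residues from the ten-residue umami set — 100% for VY (both
V and Y are umami residues), 50% for IS and HN.

Digesting a synthetic collagen chain with the acid protease + papain pair:

```sh
$ umamipep simulate --n-chains 1 --seed 1 --out chain.fa
$ umamipep digest chain.fa -e "pepsin (pH 1.3)" -e papain | head -3
chain              enzymes                   d    total_bonds  dh_percent  a_umami   peptide  multiplicity  positions
synthetic-chain-1  pepsin (pH 1.3) + papain  939  1381         67.9942     0.013025  PE       8             2-3;18-19;...
synthetic-chain-1  pepsin (pH 1.3) + papain  939  1381         67.9942     0.013025  VPT      1             7-9
```

i.e. the pair hydrolyses ~68% of the 1381 peptide bonds and releases known
umami fragments at a frequency of 0.013 per residue; the remaining columns
profile each unique released 2–4-mer. `umamipep run config.yaml` chains
every stage (digest → rank → novelty → physchem → screen) into a run
directory of TSV reports with a provenance JSON naming the rule-fixture,
catalog and constants versions used.

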