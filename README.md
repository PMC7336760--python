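# cysloopvar

Structural interpretation of missense variants in Cys-loop receptors —
pentameric ligand-gated ion channels such as the GABA<sub>A</sub>, glycine,
nicotinic acetylcholine and 5-HT<sub>3</sub> receptors. The package is aimed
at structural bioinformaticians and clinical-genetics analysts who need to
place protein-level missense variants (e.g. from ClinVar or Humsavar exports)
onto the shared architecture of this receptor family and ask: does this
residue line the pore, does an equivalent position in a paralog already carry
a pathogenic variant, and how does a substitution change the channel's
geometry?

## What it computes

Each Cys-loop subunit crosses the membrane four times (helices M1–M4); the
five M2 helices of a pentamer line the ion pathway. The package implements:

- **Cross-paralog residue mapping** (`seqmap`). Optimal pairwise alignments
  (BLOSUM62, affine gaps: open 10, extend 0.5) between subunit sequences, and
  position mapping through alignment columns, so a residue in one receptor
  gene can be expressed in the coordinates of a reference subunit
  (GABA<sub>A</sub>R α2, UniProt P47869, in the packaged data). Positions
  opposite a gap are flagged unaligned, never silently guessed.
- **M2 prime numbering** (`topology`). The family-wide index of pore
  positions (… −2′, −1′, 1′, … 9′ …), defined by arithmetic from the
  conserved 9′ activation-gate leucine (Leu291 = 9′ in GABRA2):
  `prime(p) = p − anchor_pos + anchor_prime`. The −2′ ring is the narrowest
  intracellular constriction (desensitization gate). Helix spans, flanks
  (±5 residues by default) and center-relative signed offsets (negative =
  extracellular side) come from a versioned topology config.
- **Variant tables and equivalence reports** (`variantdb`). HGVS protein
  notation parsing (`p.Pro280Leu` → (280, P, L)), coding→protein arithmetic
  (residue = ⌈c/3⌉, so c.839 → 280), ClinVar/Humsavar-style TSV dialects,
  duplicate collapsing (same change, same position, same protein = one
  variant) with removal of conflictingly interpreted records, and
  equivalence tables grouping pathogenic variants of other receptors within
  ±1 of a query position.
- **Transmembrane enrichment statistics** (`enrichment`). Per-helix variant
  counts (core-only or ±flank), a χ² goodness-of-fit against equal expected
  counts across M1–M4 (df = 3; length-proportional expectation available),
  center-relative position histograms, and zero-coverage position counts.
- **Pore geometry** (`structure3d`). PDB/mmCIF input (via gemmi), pore-axis
  detection by principal component of the transmembrane Cα cloud, HOLE-style
  maximal inscribed-sphere radius profiles in 3 Å steps with in-plane center
  refinement, chloride-passability classification (Pauling Cl⁻ radius
  1.81 Å, hydrated 3.2 Å), wild-type/mutant profile deltas, residue-level
  van der Waals and hydrogen-bond contacts, inter-residue distances, and
  Kabsch superposition RMSD.
- **Synthetic benchmarks** (`synthetic`). C5-symmetric toy channels with
  closed-form pore radii, divergent sequence families with recorded residue
  correspondences, and variant tables with controlled per-helix enrichment —
  every generator returns its ground truth.

## Worked example

Prime numbering of the GABRA2 gate residues from the packaged topology
(anchor: Leu291 = 9′):

```text
$ cysloopvar prime --pos 280
P47869  280     -2′
$ cysloopvar prime --pos 284
P47869  284     2′
$ cysloopvar prime --pos 292
P47869  292     10′
```

Pro280 sits in the −2′ desensitization-gate ring, Val284 at 2′, and Thr292 at
10′, one turn above the 9′ activation gate.

Cross-receptor equivalence report for the seven packaged GABRA2 study
variants (Met263Thr, Pro280Leu, Val284Ala, Leu291Val, Thr292Lys, Phe325Leu,
Asn335His):

```text
$ cysloopvar map --out equiv.tsv
$ head -6 equiv.tsv
# cysloopvar 0.1.0 config_hash=90640fd2b34b
query_gene  query_variant  query_pos  other_gene  family  other_variant  equivalent_ref_pos  relation
GABRA2      p.Met263Thr    263        CHRNA2      nACh    p.Ile279Asn    262                 adjacent
GABRA2      p.Met263Thr    263        GABRA1      GABA-A  p.Met263Ile    263                 exact
GABRA2      p.Met263Thr    263        GABRA1      GABA-A  p.Met263Lys    263                 exact
GABRA2      p.Met263Thr    263        GABRA1      GABA-A  p.Met263Thr    263                 exact
```

The full report has 23 rows covering six of the seven study variants
(Asn335His has no known equivalent); `relation` says whether the other
receptor's variant maps to the exact reference position or an adjacent one.

Pore profile of a synthetic three-ring channel (ring radii 5 / 3.5 / 5 Å,
carbon atoms, so the analytic radii are 3.30 / 1.80 / 3.30 Å):

```python
>>> from cysloopvar import ToyChannelSpec, gen_toy_pentamer, pore_axis, pore_profile
>>> st, analytic = gen_toy_pentamer(ToyChannelSpec())
>>> prof = pore_profile(st, pore_axis(st))
>>> prof.min_radius()
(1.7999999999999996, 0.0)
>>> prof.to_frame()[["step_A", "radius_A", "permeation_class"]]
   step_A  radius_A      permeation_class
0    -6.0  3.300000  hydrated-Cl-passable
1    -3.0  2.909772    dehydrated-Cl-only
2     0.0  1.800000               blocked
3     3.0  2.909772    dehydrated-Cl-only
4     6.0  3.300000  hydrated-Cl-passable
```

The constriction (1.80 Å) is below the Pauling Cl⁻ radius (1.81 Å), so that
station is classified as blocked for chloride.

## Input formats

- Sequences: FASTA (first header token = id; 20 standard residues + X).
- Topology: TOML, one table per protein with `M1..M4 = [start, end]`,
  `flank`, and `anchor = [residue, prime]` (see
  `src/cysloopvar/data/topology.toml`).
- Variant tables: tab-delimited. ClinVar dialect needs columns
  `gene, protein_id, hgvs_p, significance`; Humsavar dialect
  `gene, protein_id, variant, category`. A column map adapts other exports.
- Structures: PDB or mmCIF; chain→subunit-role mapping as an option.

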