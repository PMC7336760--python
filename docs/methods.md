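# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic benchmarks do and do not show.

## Residue equivalence by pairwise alignment

Every equivalence statement the package makes is a single source→reference
relation ("position p of subunit X corresponds to position q of the reference
subunit"), so residue mapping is built on optimal *pairwise* alignments to a
chosen reference rather than on a multiple sequence alignment. This keeps
each mapping independent of which other sequences happen to be in the set,
at the cost of not enforcing cross-sequence column consistency — acceptable
here because Cys-loop transmembrane regions are highly similar and each
published equivalence is itself a pairwise statement.

Alignments use BLOSUM62 with affine gap penalties, open 10 / extend 0.5
(the EMBOSS defaults; gap of length L costs 10 + (L−1)·0.5). Global mode
penalizes end gaps; local mode is used when only a conserved region (e.g.
M1–M3) is compared. Ties among equal-scoring optima are resolved by the
aligner's canonical first traceback, which is deterministic for a given
input; optimality itself is cross-checked in the test suite against an
independent three-state recursion and, at tiny sizes, against exhaustive
enumeration of all alignments. Positions whose alignment column is a gap in
the target are reported with an explicit unaligned flag plus the nearest
mapped flanking positions — downstream code must decide what to do with
them; the library never substitutes a nearest-neighbour guess.

Conservation profiles count, per reference position, the fraction of
homologs whose aligned residue is identical; a gapped column counts as
non-identical.

## Transmembrane topology and prime numbering

Helix boundaries are configuration data, not computation: TRANSMEM-style
annotations are release-dependent, so the packaged spans are a versioned
snapshot (see `data/topology.toml`) placed from published structural
landmarks of the GABA<sub>A</sub>R α2 subunit — Pro280 at the N-terminal
(−2′) end of M2, Leu291 = 9′, Met263 mid-M1, Phe325 mid-M3, Asn335 at the M3
C-terminus. Boundaries from a specific annotation release may differ by a
residue or two at either end; analyses that depend on exact span edges
(flank membership, center offsets) inherit that uncertainty.

Prime numbering is deliberately *not* derived from the M2 start. It is
anchored at the conserved 9′ gate leucine: `prime(p) = p − 291 + 9` for
GABRA2. Anchor arithmetic is exact and immune to boundary drift; the M2 span
only bounds the domain on which the numbering is defined (span ± flank).
For non-reference subunits, the position is first mapped onto the reference
by alignment and the reference's anchor arithmetic is then applied.

Helix region assignment: `core` inside the span, `flank` within ±5 residues
(configurable) of a boundary, `outside` otherwise. Where flank windows of
adjacent helices overlap, the position goes to the nearer helix; an exact
tie goes to the N-terminal-side helix — an arbitrary but deterministic rule.
The center of an even-length helix is `floor((start+end)/2)`. Center-relative
offsets are sign-flipped per helix orientation so that negative is always
toward the extracellular space.

## Variant tables, dedup, and equivalence grouping

Only missense variants are considered; records are keyed by
(protein, position, ref, alt). A variant present in both sources with the
same key is counted once (`source = both`); a key that is pathogenic-class
("pathogenic", "likely pathogenic", "pathogenic/likely pathogenic",
"disease") in one source and benign/uncertain-class in the other is treated
as a conflicting interpretation and removed from both sides. This
operationalization of "conflicting" is a design choice; a stricter or looser
class partition would change only the conflict count, not the machinery.

Equivalence reports assign each pathogenic variant of another receptor,
after expressing its position in reference coordinates, to its *nearest*
query variant within ±1 (exact at distance 0, adjacent at 1; ties to the
N-terminal query). Nearest-query assignment — rather than listing the
variant under every query within the window — keeps each other-receptor
variant in exactly one group even when two query variants are adjacent in
sequence (as Leu291Val and Thr292Lys are), which is how the packaged
23-row equivalence dataset is grouped. The ±1 window itself is an inference
from the published exact/adjacent examples.

## Enrichment statistics

The per-helix χ² goodness of fit uses equal expected counts across M1–M4
("expected by chance" under the cited test's default), df = 3, with the
exact survival function — which the tests verify against the closed form
p(x) = erfc(√(x/2)) + √(2x/π)·e^(−x/2) to 1e-10. A length-proportional
expectation is available via the `expected` argument for users who prefer a
per-residue null; the two nulls answer different questions (helix-level vs
residue-level enrichment).

For the published count vectors, the package computes: {27, 39, 16, 4} →
χ² = 31.30, p = 7.3e-7 (helix cores) and {39, 47, 31, 5} → χ² = 32.62,
p = 3.9e-7 (± 5-residue flanks). Note that some published reports pair these
two p-values with the opposite count sets; the package always reports the
value recomputed from the counts given to it.

Statistical calibration is established by simulation through the full
counting pipeline: with uniform placement (n = 86, 2,000 tables) the
rejection rate at α = 0.05 is within 0.05 ± 0.02, and with a 3× enrichment
of M2 (n = 200, 200 tables) the test rejects at α = 1e-3 in ≥ 95% of
simulations.

## Pore geometry

The pore axis is the dominant principal direction of the transmembrane Cα
cloud, through its centroid, oriented extracellular→cytoplasmic when an
extracellular reference point is supplied. The radius profile is HOLE-like:
at stations every 3 Å along the axis, the radius is the clearance
min<sub>i</sub>(‖c − x<sub>i</sub>‖ − vdW<sub>i</sub>) of the largest sphere
centered at c in the station plane, with c refined from the axis point by a
0.5 Å grid plus Nelder–Mead simplex. van der Waals radii are the Bondi set
(C 1.70, N 1.55, O 1.52, S 1.80 Å; hydrogens dropped on input).

The in-plane search disc is small by default (2 Å). A wide search lets the
inscribed sphere slip sideways out of the pore wherever the wall has gaps —
in the extreme, the wall-less synthetic channels make any off-pore position
look "wider" — so the refinement is kept local to the axis, which also
matches how pore-tracing tools track the channel center between stations.
The disc size is a parameter (`search_radius`) for strongly tilted or
kinked pores; `refine_center=False` gives a pure fixed-axis measurement.
Stations with no atoms within one step along the axis are marked undefined;
negative clearances clamp to zero and flag the station blocked.

Constriction radii are classified against chloride: below the Pauling ionic
radius (1.81 Å) the station is blocked; from 1.81 Å to below the hydrated
radius (3.2 Å) only dehydrated Cl⁻ passes; at or above 3.2 Å hydrated Cl⁻
fits. Boundary values classify upward (a radius of exactly 1.81 Å is
dehydrated-passable).

Contacts are residue-level: a van der Waals contact when two heavy atoms of
different residues are within the sum of their Bondi radii + 0.5 Å, a
hydrogen bond when an N/O pair is within 3.5 Å (the H-bond label takes
precedence for that atom pair); the reported distance is the minimum over
qualifying atom pairs, and inter-subunit flags come from the chain-role map.
These are geometric criteria in the spirit of residue-interaction-network
tools, without angular terms — adequate for flagging interaction partners,
not for H-bond energetics.

Inter-residue distances are available under two conventions, Cα–Cα and
minimum-heavy-atom, because published distance figures for these receptors
rarely state which convention they used; callers should state the convention
with any number they report. Superposition RMSD uses the Kabsch SVD solution
constrained to a proper rotation, cross-checked in the tests against Horn's
quaternion method to 1e-9.

## Synthetic benchmarks: what they do and do not show

*Toy channels* are stacks of exactly C5-symmetric single-atom rings, so the
pore radius at each ring depth is closed-form (ring radius − vdW radius) and
the profile code can be held to 0.05 Å against it, including under rigid
motion. They have no backbone, no side-chain chemistry and no walls between
rings; they validate the geometry engine, not the realism of any particular
receptor model.

*Sequence families* evolve descendants from a random ancestor with
per-column substitutions and single-residue indels (kept three columns away
from the ends so terminal alignment behaviour stays stable), recording the
true descendant→ancestor correspondence. Recovery of that truth shows the
alignment machinery is correct at the simulated divergence (alignment-based
mapping is exact without indels and ≥ 99% with 2% indels at 5–8%
substitution); real paralog families with low-complexity regions or long
indels can be harder.

*Variant tables* place variants multinomially over (helix, region)
categories with controlled weights and record each placement's truth. The
defaults mirror the scale of the real analysis (n = 86 disease variants in
the helix cores; 3× M2 enrichment for power checks). They validate counting
and test calibration, not any biological claim about where variants fall.

Analyses that require external downloads — real UniProt sequences, cryo-EM
structures from the PDB, ClinVar/Humsavar snapshots, or externally generated
mutant models — are supported through the same file interfaces (`fetch`
helper, PDB/mmCIF readers, dialect loaders) but are not exercised by the
packaged data; the published absolute counts and structure-specific radii
therefore cannot be re-derived from this repository alone.

## Degenerate inputs and tie-breaks (summary)

- Empty sequences, zero-total count vectors, sub-3-point or collinear
  coordinate sets: errors, never silent defaults.
- Alignment traceback ties: the aligner's canonical first traceback.
- Flank-overlap ties: nearer helix, then the N-terminal one.
- Multi-model structure files: first model, with a warning; altlocs: highest
  occupancy; waters and hydrogens dropped.
- All randomness flows from explicit integer seeds; same seed, same bytes.
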