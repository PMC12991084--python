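# Methods

## The comparison model

The package treats a structural comparison as a difference of *contact
frequency matrices*. For one model, the contact frequency of an unordered
residue pair (r, s) is the number of heavy-atom pairs (one atom in r, one in
s) whose Euclidean distance is ≤ 4.0 Å. The cutoff comparison is closed and
tolerance-free on double precision, which makes the contact set a
deterministic function of the coordinates; detection uses a k-d tree
(scipy.spatial.cKDTree) whose output is exactly the all-pairs scan, a fact
the test suite checks against an independent brute-force oracle on 100
random complexes. Heavy means element ≠ H/D; hydrogens are kept at parse
time and excluded at contact time, so hydrogen-aware analyses remain
possible downstream. Atom pairs within a single residue are excluded, as are
waters, ions and ligands — the three contact categories (RNA–RNA,
RNA–protein, protein–protein) name polymer classes only, and together they
partition all counted contacts.

Contact frequency is a count, not a binary indicator. This choice is forced
by the downstream arithmetic: residue Δ-scores sum gains and losses across
partners, and percent-change statements about interface packing need
magnitudes. For interface counting the atom-pair convention is the default
for consistency with the Δ-matrices, but `count_interface_contacts` also
implements unique-atom and residue-pair conventions, and the comparison
report always prints all three, since published counts rarely say which
convention they used.

## Residue correspondence

Two models are mapped chain-by-chain. Same-entity-class chains are paired
greedily by global alignment score; pairs under 30 % identity are dropped,
a threshold chosen to reject accidental pairing of non-homologous RNAs
(a 16S against a 23S scores far below it) while accepting inter-species 16S
homologues (> 70 % identical). The aligner is a deterministic
Needleman–Wunsch with match +1, mismatch −1, gap −2, and a fixed traceback
preference (diagonal, then gap-in-A, then gap-in-B). A hand-rolled pairwise
aligner was preferred over an external multiple-alignment tool because the
chain pairs this package compares are near-identical, pairwise alignment is
provably optimal under its scoring, and exact reproducibility matters more
than alignment sophistication here; the test suite verifies optimality
against exhaustive enumeration for short sequences.

Aligned non-gap columns become a residue-level partial bijection; gap
columns populate the unmapped sets and are thereby excluded from every
difference quantity. All residue addressing uses author numbering
(chain, seq_id, icode), the numbering in which mutations like A412C are
named; mmCIF label_seq_id is kept as metadata only. Modified nucleotides
are normalised to their parent base through a built-in table so that, e.g.,
a pseudouridine aligned to a uridine is not reported as a substitution.

## Δ-matrices, exclusions and scores

Δ(r, s) = countA(r, s) − countB(r, s), with B-side pairs translated into A
numbering through the residue map and missing entries counted as zero.
Model A is the variant under study, B the baseline, so losses in the
variant are negative. Exclusion happens before summing: any pair touching a
residue that is unmapped, or whose Q-score is below 0.4 in either model, is
removed and the residue recorded with its reason (`unmapped`,
`unmapped_in_reference`, `q_below_threshold`). Residues with no quality row
pass the filter — reference models often ship without per-residue Q tables
— and are simply unassessed. The alternative order (sum first, exclude
after) would let an unreliably modelled partner leak into a residue's
score; excluding pairs first was chosen as the conservative reading.

Per-residue Δ-scores assign each pair's delta to both of its residues:
gains = Σ max(Δ, 0), losses = Σ max(−Δ, 0), net = gains − losses. This
double assignment gives the conservation identity Σ_residues net =
2 × Σ_pairs Δ, which the tests verify on 1,000 random matrices. Aggregation
is per nucleotide for RNA (scores pass through) and per chain for proteins
(sums over the chain's residues). Nets are written into the PDB B-factor
column, clipped to the fixed-width field range [−99.99, 999.99], so that a
red–white–blue B-factor spectrum in any viewer maps loss→red, gain→blue;
clipping guarantees the file round-trips to two decimals.

Significance flags use the baseline model's value as the denominator for
the relative Q-score change (|qA − qB| / max(|qB|, 1e−9) > 0.10) and an
absolute criterion for local resolution (|ΔLR| > 0.5 Å). The
baseline-relative denominator is the standard reading of "percent change";
a symmetric variant would differ only at extreme changes.

Mutation neighborhoods are all residues with any heavy atom within 10 Å of
any heavy atom of the site residue. Where a quality table provides local
resolution, neighbors with a value above 3.0 Å are dropped. Note the
direction: local resolution is in Å and larger is worse, so "resolved at
3.0 Å or better" means a numeric value ≤ 3.0; the filter implements that
reading.

## Geometry

Superposition is Kabsch: SVD of the cross-covariance of centered point
sets, with the determinant-corrected middle matrix so the rotation is
always proper (no reflections). The tests compare it against an independent
quaternion (Horn) implementation to 1e−8 Å RMSD on 1,000 random instances.
RMSD selections: `P` (default; phosphates for RNA, CA for proteins — the
standard choice for rRNA, robust to base flips), `C1'`, or `heavy`
(name-matched heavy atoms). Per-residue displacement is the post-fit
distance between representative atoms (P for RNA, CA for protein, falling
back to the residue center of mass), flagged above 1.0 Å; representative
atoms rather than all-atom RMSD keep the magnitude stable under side-chain
or base rearrangement. Centers of mass are mass-weighted over heavy atoms
using standard atomic weights (gemmi's element table); an unweighted
centroid variant exists for sensitivity checks.

## Thresholds

All numeric thresholds live in `AnalysisConfig`:

| parameter | default | unit | role |
|---|---|---|---|
| contact_cutoff | 4.0 | Å | heavy-atom contact distance |
| interface_cutoff | 4.0 | Å | interface counting distance |
| q_exclude | 0.4 | – | Q-score below which a residue is excluded |
| q_change_frac | 0.10 | – | relative Q change flagging a site |
| locres_change | 0.5 | Å | local-resolution change flagging a site |
| neighborhood_radius | 10.0 | Å | mutation neighborhood radius |
| min_local_resolution | 3.0 | Å | worst local resolution kept in neighborhoods |
| shift_threshold | 1.0 | Å | displacement flag threshold |

## The synthetic generator

`generate_toy_complex` builds an RNA single helix (radius 9 Å, rise 2.8 Å,
0.6 rad twist) with P/O3′/C1′ backbone and 2–4 inward base atoms per
nucleotide (purines get four, pyrimidines three), and a protein trace whose
residues face RNA phosphates with their innermost side-chain atom placed
3.5 Å away — so RNA–RNA backbone contacts, a 4 Å RNA–protein interface, and
protein–protein trace contacts all exist by construction. Real element
symbols and masses are used so COM and polar-proximity code paths behave as
on real structures. Everything is seeded and deterministic to the byte.

What it does **not** emulate: base pairing and helical grooves, sugar
pucker, realistic protein secondary structure, crystallographic disorder,
alternate conformers, or chemically plausible stereochemistry. Passing
tests therefore demonstrate the *bookkeeping* of the pipeline — mapping,
counting, differencing, filtering, flagging — exactly, not the scientific
interpretation of any particular real structure.

`perturb` applies substitutions (base atoms re-placed along the backbone's
inward axis), whole-residue displacements, and contact edits that translate
a residue along the pair axis in bounded steps until the recomputed pair
delta reaches the requested sign and magnitude (erroring if unsatisfiable).
Ground truth stores the *recomputed* per-pair deltas of the finished
noiseless construction rather than the requested magnitudes: construction
is iterative and moving one residue perturbs its other pairs too, so tests
must compare against what exists, not what was asked. The optional global
rigid transform and Gaussian jitter are applied after ground truth is
recorded, as pure observation noise. Quality tables draw Q around a base
value (sd 0.05, clipped to [−1, 1]), plant designated residues uniformly
in [0.10, 0.39], and assign local resolution on a 2.0–4.0 Å
center-to-periphery gradient, mimicking the peripheral resolution falloff
of single-particle reconstructions.

## Problem sizes and determinism

The default test suite and the acceptance script run entirely on synthetic
complexes of 10–60 residues: 100 seeds for the contact oracle, 1,000 draws
for the conservation identity and the superposition cross-check, 20
noise-free and 100 jittered replicates for planted recovery. These sizes
make every run complete in seconds while still exercising each code path;
all randomness flows from explicit seeds, and generated files are
byte-stable (no timestamps; fixed PNG metadata).

## Known limitations

- Polar-proximity detection is distance-only (N/O/S pairs ≤ 3.5 Å); without
  donor–H–acceptor angles it over-counts true hydrogen bonds and is labelled
  a proxy throughout.
- The aligner is pairwise-global only; it is not suitable for distantly
  related chains with large rearrangements, where structure-based
  correspondence would be needed.
- Q-scores and local resolution are consumed as input tables, never computed
  from density maps.
- Subunit rotation angles (head/body tilts) are out of scope: no standard
  reference frame is defined here, and any choice would be arbitrary.
- The PDB writer emits single-character chain ids; models with multi-
  character mmCIF chain ids round-trip through mmCIF-consuming tools, not
  through the legacy PDB writer.
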