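# Methods

## Model and pipeline

`ptmhotspots` treats a protein family's modification landscape as a set of
**hotspots**: alignment columns of a family MSA that received at least one
experimentally observed PTM from any member. Working at the column level
pools sparse per-protein observations into family-level evidence and, by
construction, integrates each position independently rather than over a
sequence window — closely spaced modified positions simply appear as
neighboring peaks. Hotspots may contain multiple modification types
(e.g. phosphorylation and ubiquitination at the same column), which the
multi-type composition report summarizes.

The pipeline has three stages:

1. **Catalog + hotspot analysis.** PTM records are read from TSV (a
   column-name dialect map absorbs source-database naming differences),
   normalized to a controlled modification vocabulary, filtered to
   experimental observations, and deduplicated on
   (protein, residue, modification type) — the same site reported by
   several databases counts once, with `known_function` OR-merged and
   citations concatenated. Records whose residue letter disagrees with the
   alignment sequence are excluded rather than trusted: a mismatch almost
   always means an isoform or off-by-one numbering error, and silently
   keeping either interpretation would corrupt the column assignment.
2. **Structural projection.** One member with an available structure is
   the projection target. The chain sequence is located inside the member
   sequence (exact substring, pairwise-alignment fallback; pairings below
   90% identity are rejected as wrong-chain errors), giving a
   column → author-residue map. Per-residue SASA is computed on the
   isolated chain; interfaces come from inter-chain contacts; disordered
   unresolved residues are rescued (below).
3. **Scoring + evaluation.** Each mappable hotspot gets an FP score and a
   rank; known-vs-unknown separation statistics evaluate ranking factors.

## The FP combination

The score is multiplicative over four monotone criteria — observation
frequency, solvent accessibility, interface residence, conservation:

    IS   = PS · (1 + w_if)   if at an interface, else PS
    FP   = IS · relSASA · (cs_scale · CS) · (prc_scale · PRC)
    FP_b = IS · θ_b · (cs_scale · CS) · (prc_scale · PRC)

A multiplicative form was chosen over a weighted sum because the criteria
are gates rather than substitutes: a perfectly conserved site that can no
longer present a modifiable residue (PRC = 0), or a site buried beyond
reach, should not be rescued by a high observation count. The two branches
agree exactly at `relSASA = θ_b` (the default buried penalty *is* the
threshold), so the score is continuous in accessibility. Absolute FP
magnitudes are arbitrary — multiplying `cs_scale`/`prc_scale` by a common
constant rescales every score — and only rank order and fold-over-median
are interpreted.

Parameters (`FPWeights`):

| parameter | default | meaning |
|---|---|---|
| `interface_boost` (w_if) | 1.0 | interface residence doubles the PTM score |
| `burial_threshold` (θ_b) | 0.05 | relative-SASA cutoff for the buried branch |
| `buried_penalty` | θ_b | accessibility factor used on the buried branch |
| `prc_scale` | 100 | expresses PRC as a percent |
| `cs_scale` | 1 | conservation scale |

`ptm_score` defaults to the raw count; a log-damped variant
(`1 + ln count`) is selectable for corpora where a few heavily
re-observed sites would dominate.

**Conservation.** CS is the modal-residue frequency among non-gap rows of
the column (gaps count in neither numerator nor denominator; an all-gap
column scores 0). A residue-class hook (`residue_classes=["ST", "KR"]`
style) lets chemically conservative substitutions count as conserved; it
is off by default because any class weighting is a modeling choice the
data cannot arbitrate. PRC is the fraction of non-gap rows whose residue
is modifiable by the hotspot's modification types, using a fixed
chemistry table (phosphorylation S/T/Y; ubiquitination/acetylation K;
methylation K/R; palmitoylation, prenylation, S-nitrosylation C;
myristoylation G); `other:<label>` types fall back to the residues
actually observed modified at that column.

## Solvent accessibility and interfaces

SASA uses the Shrake–Rupley method: each heavy atom's van-der-Waals
sphere (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å; default 1.70) is
expanded by a 1.4 Å water probe and sampled with a deterministic
golden-section spiral lattice (960 points by default); a point is
accessible when outside every neighboring expanded sphere. The lattice is
fixed, so identical inputs give identical values — there is no RNG
anywhere in the structural code path. At 960 points an isolated atom
reproduces the analytic sphere area to well under 1%, and 20-atom random
clusters agree with a 10,000-point reference within 2% (both are test
oracles). Chains are always processed in isolation so that binding
partners and crystal packing cannot deflate accessibility.

Relative SASA divides by the residue type's theoretical maximum
(Tien et al. 2013 theoretical column, e.g. ALA 129, GLY 104, SER 155,
LYS 236 Å²), clamped to 1. The table is a module constant
(`structure.MAX_SASA`) and can be swapped.

Interface residues are pairs of heavy atoms on *different* chains within
5.0 Å. Same-chain contacts never count, which excludes artificial
same-chain interactions by construction. Neighbor search uses a k-d tree;
its contract — identical results to the all-pairs computation — is
enforced by a brute-force oracle test.

**Disorder rescue.** Residues absent from the structure but annotated as
intrinsically disordered (TSV of residue ranges from any disorder
predictor, or the `--assume-terminal-disorder` heuristic: unresolved
terminal runs of ≤ 30 residues) are assigned their residue type's maximum
SASA (relative SASA 1.0). Flexible tails are exactly where crystallography
goes blind and where many regulatory modifications live; scoring them as
missing or buried would systematically erase that signal. Unresolved
residues with no disorder evidence are excluded from scoring with a
warning — absence of coordinates alone is not evidence of exposure.

## Ranking and evaluation

Hotspots are ranked by descending FP within a grouping unit — per family,
or pooled across families when comparing subunits of one complex — with
deterministic tie-breaks (higher count first, then lower column). Each
result carries its group median FP and fold-over-median.

Separation between known- and unknown-function hotspots is summarized by
the ratio of class means (equivalently the known-class mean after
normalizing the unknown class to 1) and tested with a two-sided
Mann–Whitney U: exact by full enumeration of label splits when both
classes have ≤ 8 members (ties handled by mid-ranks, no special casing),
tie-corrected normal approximation otherwise; the two agree within 0.02
at the crossover. An ordinal-rank mode (`rank_mode=True`) averages ranks
instead of raw values as a sensitivity analysis; raw values are the
default because mean-normalization is directly interpretable for them.
Tests are reported per factor without multiple-testing correction, as the
factors are compared individually, not screened.

## Synthetic families

The fixture generator emulates the statistical structure the method
assumes: an ancestor sequence evolves into `n_members` rows by i.i.d.
per-site substitution (rate 0.4) and i.i.d. gaps (rate 0.02); hotspot
columns substitute at `1 − conservation` instead, and their ancestor
residue is modifiable by the assigned modification type. Known-function
hotspots (10 per family by default) are planted with higher observation
counts (mean 5 vs 1.5, drawn as 1 + Poisson so single-observation known
sites occur), higher conservation (0.95 vs 0.6), and 30% of them in a
12-residue N-terminal tail that the generated structure (an ideal α-helix
with backbone + Cβ on coaxial tracks, 3.8 Å Cα–Cα) omits and the disorder
TSV annotates. The first member is an anchor that always retains the
ancestor residue at hotspot columns, guaranteeing every planted hotspot is
plantable and mappable onto the anchor's structure. A fixed seed
reproduces every emitted byte.

Because the signal is parametric, the evaluation is parameter recovery,
not tautology: **null mode** gives the known class the unknown class's
count, conservation, *and* placement distributions (labels kept), and the
method must then find no significant separation. What the fixtures do not
emulate: realistic folds (the helix only modulates SASA smoothly),
realistic substitution models, correlated indels, interface geometry
(single-chain targets have no interfaces), or multi-type hotspots.
Passing on fixtures therefore demonstrates correct mechanics and
sensible statistical behavior, not performance on real proteomes.

## Numerical and degenerate-input choices

- All residue indices and alignment columns are 1-based; maps are built
  once per alignment and never recomputed ad hoc.
- Multi-model structure files use model 1 only; altlocs resolve to
  highest occupancy, ties alphabetically; hydrogens and non-standard
  residues (HETATM ligands, waters) are ignored with a log message.
- Duplicate records with conflicting residue letters are a hard error;
  unparseable table rows are skipped with their line number logged.
- An all-gap column has CS = PRC = 0; a zero family median leaves
  fold-over-median undefined (null in output).
- Fold-difference of a factor with zero unknown-class mean is reported as
  infinity rather than an error.
- The exact Mann–Whitney p is the fraction of label splits whose
  |U − nm/2| is at least the observed one, which handles ties without a
  continuity correction.

## Scope and limitations

Family membership, the MSA (pre-aligned input, or an external aligner via
a shell-out), and disorder annotations are inputs, not predictions made
here. mmCIF must be converted to PDB upstream. NMR ensembles are not
averaged and conformational variability between alternative structures of
a family is not exploited — scores from a single target structure inherit
that structure's idiosyncrasies, so running several targets and comparing
is advisable on real data. The evaluation sizes used by the reproduction
script (20 families of 30 members and 50 hotspots, plus 20 null controls)
were chosen so the full suite completes in about a minute while keeping
binomial noise on the reported fractions small.
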