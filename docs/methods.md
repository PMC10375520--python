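# Methods

## The procedure

For a queried ¹H or ¹³C site of a molecule with an assigned experimental
shift, the pipeline is:

1. **Descriptor.**  The covalent environment descriptor is the graph of all
   atoms within *w* bonds of the site — nodes labelled by element, edges by
   covalent bonds, nothing else (no bond orders, charges, geometry, or
   intermolecular contacts).  Because it is purely two-dimensional, the
   database can be searched from the molecular structure alone.  A database
   entry matches when an element-preserving graph isomorphism maps the query
   descriptor onto the entry's with center onto center.
2. **Adaptive depth.**  *w* starts at 6 and is reduced until the number of
   database matches exceeds 3000, trading specificity for sampling depth.
   Match counts are monotonically non-increasing in *w*, so the first depth
   that satisfies the threshold while descending is the deepest one that does.
3. **Selection.**  From the matches, 1000 environments are selected twice:
   uniformly at random (IIM), and shift-targeted (SIM).  Shift targeting
   repeats n times: draw x ~ N(δ_exp, σ) with σ the shift-prediction
   uncertainty (0.5 ppm ¹H, 5 ppm ¹³C) and take the not-yet-selected entry
   whose predicted shift is nearest x.  For bonded ¹³C–¹H pairs the draw is
   from the axis-aligned 2D Gaussian and "nearest" is the σ-normalized
   Euclidean distance d = √(((Δδ_C)/σ_C)² + ((Δδ_H)/σ_H)²).
4. **Geometry.**  Each selected entry's local atomic environment — every
   periodic image atom within 7 Å of the site — is extracted and rigidly
   superposed onto a chosen reference conformation by minimizing the RMSD of
   3–4 anchor atoms (Kabsch, proper rotations only).  When local symmetry
   (methyl rotors, equivalent ring positions) yields several witness
   isomorphisms, all are tried and the lowest-RMSD anchor pairing wins.
5. **Density.**  Per element, the map is the average over environments of
   unit-amplitude Gaussians exp(−|r − r_a|²/(2σ²)), σ = 0.5 Å, evaluated on
   a 31×31×31 grid with 12 Å sides centered at the queried site (0.4 Å
   sampling).  The averaging makes values interpretable as occupation
   fractions: 1 where an atom sits in every environment.
6. **Scoring.**  A candidate crystal's environment around the same site
   (single environment, same kernel and grid) is scored by the plain
   voxelwise product sum against the SIM − IIM difference, after zeroing
   difference voxels with magnitude < 0.01.  Global score = mean over
   unambiguous sites; normalized score = global minus the candidate-set mean.

### Assumptions

- Database structures are ordered (no disorder/partial occupancy); disordered
  CIFs are rejected rather than silently averaged.
- Bonds are perceived by the covalent-radius heuristic: distance ≤ 1.15 ×
  (r_cov(i) + r_cov(j)), minimum over periodic images.  The scale and radius
  table are configurable; the default table ships as package data.
- Descriptor graphs are intramolecular: bonds never cross between molecules,
  and each connected component of the perceived bond graph is one molecule.
- The anchor atoms' internal geometry is conformation-independent (they are
  mutually within two bonds, or belong to a rigid motif such as a phenyl
  ring or carboxylic acid group — flag `rigid_anchors`).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `w_start` | 6 | bonds | initial descriptor depth |
| `min_matches` | 3000 | – | matches required before selection |
| `n_select` | 1000 | – | environments per map |
| σ(¹H), σ(¹³C) | 0.5, 5 | ppm | selection widths = prediction uncertainty |
| `radius` | 7 | Å | environment extraction sphere |
| `grid_points`, `grid_side` | 31, 12 | –, Å | map grid (0.4 Å sampling) |
| `sigma_space` | 0.5 | Å | density kernel standard deviation |
| `noise_floor` | 0.01 | – | difference-map threshold |
| `bond_scale` | 1.15 | – | covalent-radius sum multiplier |

Selection is **without replacement** (n distinct environments); duplicates
would double-count atoms in the averaged density.  Nearest-shift ties break
by ascending entry id, making every selection reproducible from a seed.

## Numerical choices

- **Supercell bound.**  Sphere extraction replicates the cell by
  ±(⌈radius / w_axis⌉ + 1) along each axis, where w_axis is the perpendicular
  width of the cell along that axis — provably sufficient for skewed cells;
  verified against brute-force enumeration on randomized triclinic cells.
- **Kernel width.**  "Width σ = 0.5 Å" is read as the Gaussian standard
  deviation in exp(−d²/2σ²); the map normalization (divide by n_envs) is
  fixed by requiring value 1 for an always-present atom.
- **2D shift distance.**  The deviations are divided by the per-nucleus
  widths before the Euclidean combination, so a 5 ppm ¹³C mismatch counts as
  much as a 0.5 ppm ¹H mismatch — consistent with the stated per-axis widths.
- **Canonical keys.**  Weisfeiler–Lehman hashes over element labels (center
  marked) are used only as a prefilter; every candidate match is confirmed by
  explicit VF2 isomorphism, so hash collisions cannot create false matches.
- **Proper rotations only.**  The Kabsch sign correction forbids reflections;
  a chiral anchor set is never superposed onto its mirror image.
- **Overlap scores** carry no voxel-volume factor or candidate-mass
  normalization; any common scale cancels in the mean-subtraction across the
  candidate set.  Scores sum over all element channels; a per-element
  breakdown is available by scoring channels separately.
- **Degenerate inputs.**  Near-zero cell volume, collinear anchors, all-
  ambiguous assignments, and selections larger than the match list raise
  typed errors; an element absent from all environments yields an all-zero
  map (not an error).
- **Multiple matching candidate sites.**  When several sites of one candidate
  match a query descriptor (symmetry-equivalent molecules), the candidate's
  per-site score is their mean — deterministic and independent of site order.

## The synthetic database

The generator emulates the structural backbone of the real resource — a
large set of ordered small-molecule organic crystals whose predicted shifts
correlate with hydrogen bonding — at desk scale:

- Rigid planar formic acid molecules (standard bond lengths within 0.05 Å)
  packed as inversion dimers (double O–H···O=C, H···O = 1.75 Å), catemer
  chains (each OH donating to the next carbonyl along one axis), or isolated
  molecules in padded orthorhombic cells (12–15 Å); formaldehyde is available
  as a non-protic decoy species.  Default motif mix 40/20/40
  dimer/chain/isolated — hydrogen-bonded environments in the majority, as for
  real carboxylic acids, with enough free molecules to separate SIM from IIM.
- Pseudo-shifts: class base value (6 ppm acid OH, 8 ppm CH, 165 ppm C) plus
  Δ = 4 ppm when an intermolecular acceptor oxygen lies within 2.0 Å of the
  proton, plus N(0, 0.2 ppm) noise.  Uncertainties are fixed at the selection
  widths.  Δ/noise = 20 gives a cleanly separable shift signature, the regime
  the method is designed for.

What the fixtures do **not** emulate: conformational flexibility, descriptor
diversity (one dominant species keeps match counts high in ~100-structure
databases), database bias between functional groups, continuous shift–
structure relationships, and prediction errors correlated with geometry.
Passing tests therefore demonstrate the pipeline's correctness and its
ability to recover a designed shift–structure coupling, not the empirical
accuracy of shift-based ranking on real compounds.

Test and example runs scale the constants to the toy databases
(60 structures ≈ 288 site entries, `n_select=30`, `min_matches=10`); the
full-scale defaults stay in place for real databases.

## Design choices that were genuinely open

- Replacement in selection is not specified by the protocol's description;
  without replacement was chosen (see above) and is configurable in effect
  through the database size.
- Bonded-pair (2D) queries center the descriptor, environment and grid on
  the carbon; the witness isomorphism identifies the partner proton in each
  database entry.  One pair yields one map and one score.
- The database container is JSON (optionally gzipped) with a schema version;
  the descriptor-key index is rebuilt on load and verified to reproduce.
- Candidates missing a descriptor match for some site have that site excluded
  and reported rather than failing the whole candidate — CSP sets may contain
  tautomeric variants.

## Known limitations

- Maps cannot distinguish intra- from intermolecular density, and identify
  acceptor *positions*, not chemical groups.
- Ambiguous sites (CH₂ protons, symmetry-equivalent aromatic positions with
  distinct shifts) are excluded from global scores; their information is lost.
- Ranking power is bounded by database bias: environments over-represented in
  the database are promoted regardless of the true structure.
- Bond perception is heuristic; unusual coordination (hydrogen bridges near
  the covalent cutoff) may need a custom scale or radius table.
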