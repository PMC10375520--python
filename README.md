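# shiftmaps

Chemical shift-dependent interaction maps for NMR crystallography.

Solid-state NMR chemical shifts are exquisitely sensitive probes of the local
packing around a nucleus, but turning a set of assigned experimental shifts
into *structural* information normally requires DFT-level shift computations
for every candidate crystal structure.  `shiftmaps` takes a different route:
given a database of crystal structures with per-site predicted shifts, it
selects local atomic environments whose covalent surroundings match a queried
site and whose predicted shifts match the experimental value, superposes
them, and accumulates per-element 3D atomic density maps.  The difference
between the shift-targeted map (**SIM**) and a map built from randomly
selected matching environments (**IIM**) highlights non-covalent interactions
— hydrogen bonds, close aromatic contacts — that the experimental shift
promotes or suppresses, directly from the 2D molecular structure and the
assigned shifts, with no knowledge of the crystal packing.

The same maps give a quantitative score for candidate crystal structures from
crystal structure prediction (CSP): each candidate's local environment around
site *i* is rendered as a density map G_i^cand and scored by the overlap

    s_i = Σ_elements Σ_grid  G_i^cand(r) · [ G_i^SIM(r) − G_i^IIM(r) ]

(voxels of the difference with magnitude < 0.01 are zeroed to suppress
noise).  A candidate's global score is the mean of s_i over unambiguously
assigned sites, and scores are normalized across the candidate set by
subtracting the set mean, so positive values mark candidates whose packing is
more compatible with the experimental shifts than the set average.

## What is implemented

* **Covalent environment descriptors** — the labelled graph of all atoms
  within *w* bonds of a site; database matching by element-preserving graph
  isomorphism (Weisfeiler–Lehman key prefilter + VF2 confirmation), with the
  depth adapted from w = 6 downward until > 3000 matches exist.
* **Environment selection** — 1000 environments per map by default; randomly
  for the IIM, or by drawing from a Gaussian centered on the experimental
  shift (σ = 0.5 ppm for ¹H, 5 ppm for ¹³C; an axis-aligned 2D Gaussian with
  the σ-normalized distance for bonded ¹³C–¹H pairs) and taking the
  nearest-shift unselected entry per draw for the SIM.
* **Geometry** — 7 Å spherical environments extracted with full periodic
  image coverage; anchor-atom Kabsch superposition (proper rotations only)
  onto a reference conformation; per-element density maps as averages of
  unit-amplitude 3D Gaussians (σ = 0.5 Å) on a 31×31×31 grid with 12 Å
  sides (0.4 Å sampling), so an atom present at a position in every selected
  environment gives a map value of 1.
* **Scoring** — per-site overlap scores, ambiguity flagging (CH₂ protons,
  symmetry-equivalent positions), global and normalized candidate scores.
* **I/O** — CIF structures (symmetry-expanded to P1 via gemmi), CSV shift
  tables and assignments, Gaussian cube and CCP4/MRC volumetric export for
  contour display in standard viewers.
* **Synthetic databases** — at production scale this method runs against
  hundreds of thousands of CSD structures with machine-learned shift
  predictions; neither resource is redistributable, so `shiftmaps.synthetic`
  generates toy crystal databases of rigid formic
  acid molecules packed as hydrogen-bonded dimers, catemer chains or isolated
  molecules, with pseudo-shifts coupled to hydrogen bonding through a step
  model (base + Δ·[acceptor within cutoff] + noise).  Every stage of the
  pipeline is tested against these ground-truth labels.

## Worked example

Build a 60-crystal synthetic database (Δ = 4 ppm, noise 0.2 ppm), construct
the SIM and IIM around the carboxylic acid proton at its hydrogen-bonded
experimental shift (10 ppm), and rank 10 CSP-style candidates:

```python
import numpy as np
from shiftmaps import (FixtureSpec, MapConfig, acid_proton_query, build_site_maps,
                       difference_map, make_candidate_set, make_fixture_database,
                       rank_candidates)
from shiftmaps.synthetic import ACCEPTOR_OFFSET, _build_motif

spec = FixtureSpec(n_structures=60, seed=202)          # Δ = 4 ppm, noise 0.2 ppm
db, motifs = make_fixture_database(spec)
print(f"database: {len(db)} site entries from {len(db.structures)} crystals")

reference = _build_motif("isolated", (13.0, 13.0, 13.0), np.eye(3), "reference")
query = acid_proton_query(spec, hbonded=True)          # δ_exp = 10.0 ppm
config = MapConfig(n_select=30, min_matches=10)        # scaled to the toy db

rng = np.random.default_rng(7)
sim = build_site_maps(db, reference, query, "sim", config=config, rng=rng)
iim = build_site_maps(db, reference, query, "iim", config=config, rng=rng)
diff = difference_map(sim["O"], iim["O"])

locus = reference.cart_coords()[query.site_index] + ACCEPTOR_OFFSET
idx = tuple(int(np.argmin(abs(a - x))) for a, x in zip(diff.grid.axes(), locus))
print(f"O density at the acceptor locus: SIM {sim['O'].values[idx]:.3f}, "
      f"IIM {iim['O'].values[idx]:.3f}, SIM-IIM {diff.values[idx]:.3f}")

candidates, truth = make_candidate_set(spec, n_decoys=9)
reports = rank_candidates(db, reference, [query], candidates, config=config, seed=7)
print(f"true H-bonded candidate: {truth}")
for r in reports[:3]:
    print(f"  rank {r.rank}: {r.candidate_id}  global {r.global_score:+.3f}  "
          f"normalized {r.normalized_score:+.3f}")
```

Output:

```
database: 288 site entries from 60 crystals
O density at the acceptor locus: SIM 0.931, IIM 0.497, SIM-IIM 0.435
true H-bonded candidate: cand03
  rank 1: cand03  global +20.073  normalized +18.062
  rank 2: cand00  global +0.004  normalized -2.007
  rank 3: cand01  global +0.004  normalized -2.007
```

Reading this: among database environments matching the acid proton's covalent
descriptor, those selected near 10 ppm nearly all place an acceptor oxygen
1.75 Å from the proton (SIM ≈ 0.93), while a random selection does so only
about half the time (IIM ≈ 0.50).  The SIM−IIM difference of +0.44 at that
locus is what rewards the hydrogen-bonded candidate: only `cand03` has an
oxygen there, so its overlap score dwarfs the decoys' and it ranks first.

The same pipeline is available from the shell
(`shiftmaps fixtures | build-db | query | map | score`); maps exported with
`shiftmaps map --out PREFIX --format cube` can be contoured over the
structure in any volumetric viewer.

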