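# capsid-lattice

Analysis of fullerene capsid lattices — the pentamer/hexamer shells built
by retroelement and retrovirus capsid (CA) proteins — from 3-D capsomer
coordinates and particle density maps.

The package is aimed at structural biologists working with subtomogram
lattice maps and low-resolution particle reconstructions: given the 3-D
centers of capsomers on a particle surface it recovers the neighbor graph,
classifies each capsomer's symmetry environment, checks fullerene closure,
and determines local and global Caspar–Klug triangulation numbers by
walking the hexagonal lattice. A synthetic-data module generates ideal,
prolate, noisy and incomplete particles (and voxelised density maps with
immature- or mature-like interiors) so every analysis can be validated
against known ground truth.

## The geometry in brief

A quasi-equivalent icosahedral capsid is indexed by two non-negative
integers *(h, k)*: the shortest route between neighboring pentamers runs
*h* steps along one lattice direction, turns 60°, and continues *k* steps.
The triangulation number

&nbsp;&nbsp;&nbsp;&nbsp;*T* = *h*² + *hk* + *k*²

counts quasi-equivalent subunits per icosahedral asymmetric unit. A
*T*-capsid contains 60*T* subunits arranged as 10*T* + 2 capsomers: 12
pentamers (always exactly 12 on a closed shell — Euler's formula applied
to a 5/6-coordinated surface, equivalently a discrete Gauss–Bonnet
disclination sum of 12) and 10(*T* − 1) hexamers. Hexamers split into
**pseudothreefold** positions (adjacent to a pentamer) and true
**threefold** positions (surrounded by hexamers). Irregular "mixed-T"
particles carry pentamer pairs at several different *(h, k)*, which the
lattice walk resolves pair by pair even when no global T exists.

## Worked example

```python
from capsid import (generate_icosahedral, build_graph, classify_capsomers,
                    closure_report, particle_t, asu_decomposition,
                    packaging_stats)

cs = generate_icosahedral(3, 0, 24.0)          # ideal (3,0) shell, r = 24 nm
lg = classify_capsomers(build_graph(cs))
rep = closure_report(lg)
print(len(cs), rep.n_pentamers, rep.complete)
t = particle_t(lg)
print(t.verdict, t.T, len(t.pairs))
print(lg.class_counts)
print(asu_decomposition(lg))
p = packaging_stats(5.2, 2, T=9, interior_volume_nm3=5e4)
print(f"{p.bases_per_gag:.1f} bases/Gag, {p.nm3_per_base:.1f} nm^3/base")
```

prints

```
92 12 True
icosahedral 9 30
{'fivefold': 12, 'pseudothreefold': 60, 'threefold': 20, 'edge': 0}
{'fivefold': 1, 'pseudothreefold': 6, 'threefold': 2}
19.3 bases/Gag, 4.8 nm^3/base
```

Reading: the ideal (3,0) lattice holds 92 capsomers, of which 12 are
pentamers, so the shell is a complete closed fullerene. All 30 neighboring
pentamer pairs walk to canonical (3,0), hence an icosahedral *T* = 9
verdict — 540 CA subunits, with one fivefold, six pseudothreefold and two
threefold quasi-equivalent copies per asymmetric unit. A two-copy 5.2-kb
genome in such a shell with a 5 × 10⁴ nm³ interior packs about 19 bases
per Gag at roughly 5 nm³ of interior volume per base (~20 and ~5 at one
significant figure).

The same pipeline is scriptable from a shell:

```sh
capsid generate --h 3 --k 0 --radius 24 --noise 0.5 --drop 0.1 --seed 0 --out particle.csv
capsid analyze particle.csv --report report.json --markers lattice.cmm
capsid packaging --genome-kb 5.2 --copies 2 --t 9 --volume 5e4
```

`analyze` emits the closure report, per-class capsomer counts and the
T-number report as JSON; `lattice.cmm` is a Chimera-readable marker file
with the conventional color code (pentamers blue, threefold hexamers
yellow, pseudothreefold hexamers green). Density-map tools (`capsid
profile`, `capsid fsc`) compute radial profiles, particle centers, and
Fourier shell correlation curves for MRC volumes.

## Layout

- `capsid.synth` — lattice generators (icosahedral, prolate), perturbation,
  density rendering
- `capsid.graph` — neighbor graph, capsomer classification, closure checks
- `capsid.tnumber` — lattice walks, T verdicts, censuses, ASU decomposition
- `capsid.profile` — radial profiles, morphology typing, symmetry spectra,
  align/average, FSC, shrinkage correction
- `capsid.packaging` — genome-packaging statistics
- `capsid.io` / `capsid.cli` — tables, MRC, marker files, run configs, CLI
- `docs/methods.md` — models, parameter choices and limitations
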