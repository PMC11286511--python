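# Methods

This note documents the models, conventions and numerical choices behind
helifil, in the spirit of a package reference manual. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and symmetry conventions

Coordinates are ångström in a right-handed frame; the filament axis
convention is +z. Residue indices are 1-based. Hydrogens are optional and
every metric is defined on heavy atoms only — design-stage models are
typically hydrogen-free, so hydrogen-bond-like criteria use donor/acceptor
heavy atoms.

A filament is `subunit + generating rigid transform + copy count`; copy k is
the transform applied k times, with chain ids A…Z then two-character ids
(mmCIF only; the PDB writer refuses multi-character ids, >99,999 atoms and
coordinates beyond the fixed %8.3f field, pointing at mmCIF instead).

**Screw decomposition.** Any proper rigid transform is a rotation about an
axis plus a translation along it (Chasles). The rotation is converted to
axis–angle via `scipy`'s rotation vector; the axis direction is chosen so the
rise (translation component along the axis) is non-negative, flipping the
twist sign together with it, and the twist is wrapped to (−180°, 180°]. With
this convention the `DpHF19` preset (8.4 Å, −148.9°) is a left-handed
per-step rotation about +z. A pure translation decomposes as twist 0 with
the axis along the translation; the identity has no axis and raises. The
axis point is the least-squares solution of `(I − R) p = t⊥` projected onto
the plane perpendicular to the axis.

**Helical fitting.** All consecutive subunit pairs are superposed jointly:
one Kabsch problem over the concatenated (copy k → copy k+1) coordinates,
which is the least-squares "average" of the per-pair transforms, followed by
screw decomposition. Noise-free generated filaments reproduce the generator
to ~1e−12; with i.i.d. coordinate noise the fit is plain least squares with
no outlier rejection.

**Ring count.** The smallest n in 2…24 for which n·twist lies within a
tolerance of a multiple of 360°. The default tolerance of 30° is chosen so
that the five-subunit ring of the −148.9° twist qualifies (residual 24.5°)
while n = 2 (residual 62.2°) does not.

**Strand step and antiparallel detection.** The strand step is the smallest
index offset at which subunits share a heavy-atom contact (4.5 Å default),
evaluated from a central subunit to avoid end effects; offset k > 1 means k
parallel strands. Orientation signs come from each chain's principal axis
(leading eigenvector of the CA covariance, direction disambiguated
N-terminus → C-terminus) dotted with the filament axis; an arrangement is
antiparallel when both signs occur. A chain whose two leading eigenvalues
are within 10 % of each other has no usable axis and raises a degeneracy
error — the margin is deliberately coarse because sampled near-spherical
clouds have eigen-gaps of a few percent.

**Dock sampling.** Grid docks place the subunit at a radial offset along +x
with an azimuthal spin, then propagate five copies under the (rise, twist)
screw about +z. Clash (< 2.4 Å) and contact (< 4.5 Å) bookkeeping runs over
all copy pairs; both cutoffs are standard heavy-atom defaults and
configurable. Scoring beyond clash/contact counts belongs to the interface
metrics module.

## Loop closure

Fragments store per-residue backbone N/CA/C/O coordinates. A candidate is
accepted when its two terminal residues, superposed jointly onto the
junction (upstream C-terminal residue + downstream N-terminal residue; 4+4
atoms by default, configurable to 2–3 residues per side), land within the
RMSD tolerance (default 0.35 Å). One residue per side is the minimal reading
of "terminal residues"; ranking is pure RMSD with lexical tie-breaks — no
force-field rescoring, no sequence design, and rigid placement instead of
torsion-space relaxation (no force field is in scope). Stitching keeps the
anchor residues, inserts the fragment interior, renumbers consecutively, and
enforces junction peptide C–N distances in [1.2, 1.5] Å.

## Interface metrics

**SASA.** Shrake–Rupley with a deterministic golden-spiral quadrature
(960 points/sphere default), probe 1.4 Å, Bondi radii C 1.70 / N 1.55 /
O 1.52 / S 1.80 Å. The point set has a fixed lab-frame orientation, so
totals carry a small quadrature jitter (< 0.5 %) under rigid motion; a
molecule-intrinsic frame was rejected because principal-axis frames are
unstable for near-degenerate shapes. The analytic isolated-sphere and fused
two-sphere cap areas, and an independent implementation (biotite), anchor
the quadrature in the tests.

**Interface area** is the both-sides total `sasa(i) + sasa(j) − sasa(i∪j)`,
the common reporting convention for the 700 Å² design threshold, computed in
canonical pair order so it is exactly symmetric; `per_side=True` halves it.

**Shape complementarity** follows Lawrence–Colman: dot surfaces on each
side's exposed van der Waals surface (10 dots/Å²), buried patch = dots where
a solvent probe no longer fits between the surfaces (gap < 2·probe),
peripheral band of 1.5 Å trimmed, score `exp(−w·d²)(n̂_a · −n̂_b)` with
w = 0.5 Å⁻² against the nearest partner dot, statistic = mean of the two
directional medians. Perfectly mated planes score 1; planes at gap g score
exp(−w g²).

**Buried unsatisfied polars** are counted at residue level: an interface
residue (any heavy atom within 4.5 Å of the partner) counts when it has a
polar heavy atom that is buried (per-atom SASA in the complex < 5 Å²) with
no polar heavy atom of another residue within 3.5 Å. Donor-hydrogen
geometry is waived. A consequence worth knowing: along a continuous
backbone, O(i) and N(i+1) are ~2.25 Å apart, so backbone polars of an intact
chain always count as satisfied — the criterion is sensitive to side-chain
and chain-break polars, which is what the design filter targets.

**Energy surrogate.** The bound-vs-unbound gap uses a documented contact
pseudo-energy: −1 per heavy-atom pair within 4.5 Å, capped at −3 per residue
pair, +10 per clash pair under 2.4 Å; the rigid monomer's unbound energy is
zero, so the gap is the summed inter-subunit contact energy. Its absolute
scale is *not* claimed to match any force-field unit — the −15.0 filter
threshold is configuration, and the pipeline tests run on crafted record
tables rather than the surrogate's absolute values.

**Filters.** Survivors satisfy energy_gap ≤ −15.0, buried_area > 700 Å²,
sc > 0.62, unsat_count < 5 (strict on the last three, matching the
"exceeding / surpassing / below" reading). The attrition report counts each
criterion's independent removals; top-per-dock selection takes the minimal
energy gap per dock with lexical tie-breaks.

## Protonation linkage

Each subunit carries n protonatable buried histidine-like sites (solution
pKa default 6.5, within the tunable range of the parent trimers) that cannot
protonate in the assembled state. Two-state, all-or-none linkage then gives

    f_assembled(pH) = 1 / (1 + 10^(log10_K + n (pKa − pH)))

with `log10_K` the per-subunit disassembly constant at the deprotonated
limit (≤ 0 for fibres stable at high pH). Midpoint: `pKa + log10_K/n`;
10–90 % width: `log10(81)/n`, independent of the other parameters. This is a
model, not a fit: no thermodynamic constants are measured for the real
designs, and `log10_K = −21` is a calibration anchor that places the 6-site
midpoint at pH 3.0, consistent with the observed ordering of disassembly pH
across 6- and 9-site designs (a 9-site subunit at the same `log10_K` has
midpoint 4.17). Useful identity: width × slope-at-midpoint = ln(81)/4 for
any n. Fibre-level cooperativity beyond per-subunit linkage
(nucleation–elongation over hundreds of subunits) is available only as an
optional sharpening exponent, off by default, because no quantitative law is
established for it.

## Disassembly kinetics

The fibre is a contiguous run of subunits at 0.84 nm axial rise each. Active
ends shed subunits as Poisson processes at `k_end` subunits/min/end;
junctions break at `k_frag`/min; both rates are multiplied by a pH coupling,
by default the linkage model's disassembled-state weight
`10^x/(1+10^x), x = n(pKa_eff − pH)` — saturating at 1 far below the
transition, ≈ 0 above it (a bare exponential law is available). The two
physical ends of the initial fibre carry configurable factors (set one to 0
to emulate surface pinning); fragmentation-created ends are fully active.

Simulation is exact event-driven sampling: events are proposed at the
coupling's supremum over the schedule (well-defined because the default
coupling is bounded by 1 and pH schedules are monotone after the switch) and
accepted by Ogata thinning at the instantaneous coupling, so arbitrary
schedules incur no discretisation error. The recording grid is independent
of the event process; identical seeds give bit-identical traces.

Trace conventions mirror single-fibre microscopy analyses: "fibre length" is
the longest remaining fragment (total length is also recorded); each
physical end's recession is measured toward the centre of the initial fibre
(half the initial length) and saturates there. Rate estimates are OLS slopes
with residual-based standard errors, sign-flipped so shrinkage is positive;
ensemble summaries exclude fully-disassembled fibres by default, matching
declining object counts in imaging ensembles (a flag zero-counts them
instead). Sub-second disassembly deep below the transition is treated as a
regime statement (coupling ≈ 1), not a fitted rate. Problem sizes in the
tests — 200-seed ensembles of ~1 µm fibres over a few minutes of simulated
time — were chosen to give standard errors well below the effects being
checked while each suite runs in seconds.

## Synthetic inputs

The fixtures module generates every input the test surface needs and is
itself first-class, tested code. Backbones are chained from ideal internal
coordinates (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å; trans ω), which
guarantees proper peptide bonds everywhere — that is what lets loop-closure
junction checks be strict. The helical (φ, ψ) = (−63.559°, −41.433°) and
N–CA–C angle 109.746° were solved numerically, once, so the helix realises
the textbook 1.5 Å rise / 100° per residue exactly (with the tabulated bond
geometry and the textbook N–CA–C of 111.2° that point is unreachable by
(φ, ψ) alone; the angle is well within the observed protein range). Bundles
are poly-alanine (CB present so burial and contact metrics are meaningful),
helices alternating up/down on a circle, per-helix azimuthal spins drawn
from the seed, with a built-in inter-helix clash check. Design-record
metrics are drawn uniformly from ranges straddling every filter threshold
(energy gap U(−30, 0), area U(300, 1200) Å², Sc U(0.3, 0.9), unsat integer
U(0, 10)) so the filters partition non-trivially. Fragment databases are 3–8
residue backbones with helical caps and randomised loop torsions.

What the synthetic data does *not* emulate: real side chains and rotamers,
sequence-dependent energetics, cryo-EM map noise, surface-attachment physics
beyond the pinned-end toggle, and fibre growth/elongation. Passing tests
therefore demonstrate the correctness of the geometry, metrics, models and
estimators on controlled inputs — not that any particular real design would
pass the filters or reproduce a measured disassembly rate.

## Known limitations

* The contact pseudo-energy is transparent but crude; it orders docks and
  exercises the filter pipeline, it does not rank sequence designs.
* The unsatisfied-polar criterion's heavy-atom proximity rule accepts
  chemically impossible "partners" (e.g. adjacent carbonyls); it is a
  designed-in simplification for hydrogen-free models.
* `log10_K` and `pKa_eff` are free calibration parameters; midpoints are
  meaningful as orderings and sensitivities, not absolute predictions.
* The simulator has no elongation mode and no spatial resolution; per-end
  analysis follows the centre-split measurement convention rather than
  tracking material identity through fragmentation cascades.
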