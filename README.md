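# helifil

A desk-scale Python toolkit for the computational machinery behind de novo
**pH-responsive helical protein filaments**: filaments assembled from designed
subunits carrying buried histidine hydrogen-bond networks, which fall apart
sharply and reversibly when the solution pH drops by a few tenths of a unit.

The toolkit is aimed at protein designers and structural bioinformaticians who
want transparent, dependency-light implementations of the steps in that design
and analysis workflow:

* **Screw geometry** (`helifil.helical_geometry`) — a helical filament is
  generated by repeated application of one rigid transform, parameterised by
  the axial *rise* (Å) and per-subunit *twist* (degrees). The module
  propagates subunits, fits (rise, twist) back from bare coordinates via a
  joint Kabsch superposition over consecutive subunit pairs followed by a
  Chasles screw decomposition, counts cross-section ring closure, detects
  multi-strand lattices and antiparallel (dihedral, D1-like) arrangements,
  and enumerates candidate helical docks on a parameter grid.
* **Fragment-based loop closure** (`helifil.loop_closure`) — connect
  protomers into one chain by superposing fragment termini onto the junction
  (default acceptance 0.35 Å RMSD over backbone N/CA/C/O) and stitching the
  best candidate.
* **Interface metrics and the design filter** (`helifil.interface_metrics`) —
  Shrake–Rupley buried surface area, Lawrence–Colman shape complementarity
  (Sc), buried-unsatisfied-polar counting, a transparent contact
  pseudo-energy for the bound-vs-unbound gap, and the four-filter pipeline
  (energy gap ≤ −15, buried area > 700 Å², Sc > 0.62, unsatisfied polars < 5)
  with per-criterion attrition and top-per-dock selection.
* **Protonation linkage** (`helifil.ph_response`) — an all-or-none Wyman
  linkage model for n buried sites per subunit:
  `f(pH) = 1 / (1 + 10^(log10_K + n (pKa − pH)))`, midpoint
  `pKa + log10_K/n`, 10–90 % width `log10(81)/n`. Six linked sites give a
  0.3 pH-unit transition; more sites make it sharper.
* **Disassembly kinetics** (`helifil.disassembly_kinetics`) — exact
  event-driven simulation of per-end depolymerisation and fragmentation under
  a time-varying pH schedule, plus the single-fibre trace estimators used in
  TIRFM/AFM analyses (linear-fit rates on the longest remaining fragment,
  per-end recession toward the fibre centre, ensemble mean ± s.d.).
* **Synthetic inputs** (`helifil.fixtures`) — deterministic generators for
  ideal helical-bundle subunits, the `DpHF19` preset screw (8.4 Å rise,
  −148.9° twist), fragment mini-databases and design-record tables.

File I/O (PDB v3.3 / mmCIF) is handled through `helifil.model_io` on top of
gemmi. A thin CLI (`helifil …`) wraps the library.

## Worked example

```python
from helifil import fixtures as fx, helical_geometry as hg, ph_response as ph
from helifil import disassembly_kinetics as dk
import numpy as np

# build a filament from a synthetic 3-helix subunit and recover its symmetry
sub = fx.make_bundle_subunit(fx.BundleSpec(3, 20, 7.0, seed=1))
fil = hg.propagate(sub, fx.get_preset("DpHF19").transform, 40)
p = hg.fit_helical_params(fil)
print(f"rise  = {p.rise:.6f} A")      # rise  = 8.400000 A
print(f"twist = {p.twist:.6f} deg")   # twist = -148.900000 deg
print(f"ring  = {hg.ring_count(p)}")  # ring  = 5

# cooperative pH switch: 6 buried sites, calibrated disassembly constant
m = ph.ProtonationModel(n_sites=6, pKa=6.5, log10_K=-21.0)
print(ph.midpoint(m), ph.transition_width(6))  # 3.0  0.318...

# stochastic disassembly at a fast-regime end rate
params = dk.KineticParams(k_end=64.3,
                          ph_coupling=dk.PhCoupling(pKa_eff=5.0, n_sites=6))
traces = dk.simulate_ensemble(1000.0, params, dk.PhSchedule.constant(3.0),
                              2.0, 0.25, seeds=range(50))
rates = [dk.estimate_rate(t).rate for t in traces]
print(f"{np.mean(rates):.1f} +/- {np.std(rates, ddof=1):.1f} nm/min")
# 108.2 +/- 6.9 nm/min
```

The fitted 8.4 Å / −148.9° are the generating screw parameters recovered from
coordinates alone; ring = 5 means five subunits close a cross-section ring
within the 30° tolerance. The 0.32 pH-unit width is the closed-form 10–90 %
span for six linked sites. The simulated ensemble rate is total shortening of
both fibre ends, 2 × k_end × 0.84 nm/subunit ≈ 108 nm/min.

A CLI session covering the same ground:

```bash
helifil fixtures bundle sub.pdb --seed 1
helifil propagate sub.pdb fil.pdb --preset DpHF19 -n 40
helifil fitsym fil.pdb          # {"rise": 8.4, "twist": -148.9, "ring_count": 5, ...}
helifil phcurve --n-sites 6 --log10k -21
```

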