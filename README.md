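# foursphere

Analytical four-sphere volume-conductor model for EEG forward computation.

EEG signals are generated by current dipoles set up by neuronal transmembrane
currents. A *forward model* maps such a dipole — position **r**_z, moment
**p** (A·m) — to the electric potential it produces at scalp electrodes. This
package implements the classical four-sphere head model: four concentric
homogeneous shells representing brain, cerebrospinal fluid (CSF), skull, and
scalp, with the quasi-static Poisson equation ∇·σ∇Φ = −C solved per shell and
matched at the interfaces. It is intended for EEG methods work: generating
benchmark potentials, validating numerical solvers (FEM/BEM), and building
lead fields for inverse-method testing.

## The model

In each shell *s* (radius r_s, conductivity σ_s) the potential of a *radial*
dipole of magnitude p at radius r_z is an axisymmetric Legendre series

```
Φ_s(r, θ) = p / (4π σ_1 r_z²) · Σ_{n≥1} [ A_n^s (r/r_s)^n + B_n^s (r_s/r)^{n+1} ] n P_n(cos θ),
```

with the brain-shell exterior term replaced by the source term (r_z/r)^{n+1}.
A *tangential* dipole has the same coefficients with P_n¹(cos θ) and a sin φ
azimuthal factor (and no extra factor n); an arbitrary dipole is the
superposition of the two after rotating into the canonical frame (dipole on
+z, tangential moment along +y). The coefficients A_n^s, B_n^s follow from

* continuity of potential, Φ_{s+1}(r_s) = Φ_s(r_s),
* continuity of radial current, σ_{s+1} ∂Φ_{s+1}/∂r = σ_s ∂Φ_s/∂r, at r_1, r_2, r_3,
* no current leaving the scalp, ∂Φ_4/∂r (r_4) = 0,

which give a closed-form chain through auxiliaries V_n, Y_n, Z_n. Alongside
the closed form, the package ships an *independent oracle* that solves the
same boundary conditions as a per-harmonic 7×7 linear system in extended
precision — every potential can be recomputed through a route that never
touches the closed-form algebra.

Standard parameters (`default_head_model`): radii 7.9 / 8.0 / 8.5 / 9.0 cm;
σ_brain = σ_scalp = 0.33 S/m, σ_CSF = 5 σ_brain, σ_skull = σ_brain/K with
K ∈ {20, 40, 80} (default 20).

## Worked example

A radial 10⁻⁷ A·m dipole 1 mm below the brain–CSF boundary (r_z = 7.8 cm),
four electrodes:

```sh
$ cat electrodes.csv
label,x,y,z
Cz,0,0,9.0
C3,0,6.3,6.3
C4,0,-6.3,6.3
Oz,0,-8.7,-2.3
$ foursphere compute -c config.yaml -e electrodes.csv -o out.csv --units uV
INFO foursphere: model: radii ['0.079', '0.08', '0.085', '0.09'] m, ...
INFO foursphere: wrote 4 potentials to out.csv (peak |Phi| = 96.59 uV, 0.006 s)
$ cat out.csv
label,x,y,z,potential_uV
Cz,0.0,0.0,0.09,96.58880284595433
C3,0.0,0.063,0.063,1.5588901482099844
C4,0.0,-0.063,0.063,1.5588901482099844
Oz,0.0,-0.087,-0.023,-3.0783211114330116
```

The vertex electrode directly above the radial dipole sees ~97 µV — the
tens-of-microvolts magnitude typical of recorded EEG; lateral electrodes at
90° from the dipole axis see ~1.6 µV each (equal, by the axial symmetry of a
radial source), and the occipital electrode on the far side is negative. The
same computation through the library:

```python
import foursphere as fs

model = fs.default_head_model(skull_divisor=20.0)
dipole = fs.Dipole(position=(0, 0, 0.078), moment=(0, 0, 1e-7))
phi = fs.potential_dipole(model, dipole, [[0.0, 0.0, 0.09]])
print(phi * 1e6)   # [96.58880285] microvolts
```

`foursphere map` writes a (θ, φ) scalp-potential grid in long CSV format, and
`foursphere validate` runs the physical-control suite:

```
$ foursphere validate
boundary_conditions  residual 4.193e-14  tol 1e-08  [PASS]
homogeneous_limit    residual 1.824e-12  tol 1e-06  [PASS]
infinite_limit       residual 6.672e-11  tol 1e-02  [PASS]
oracle_equivalence   residual 1.842e-16  tol 1e-09  [PASS]
```

## Documentation

See `docs/methods.md` for the mathematical background, numerical-stability
strategy, conventions (units, azimuth sign, Legendre normalization),
truncation policy, and known limitations.
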