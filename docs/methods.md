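# Methods

## Physical model and assumptions

The head is idealized as four concentric spherical shells — brain (1), CSF
(2), skull (3), scalp (4) — with outer radii r_1 < r_2 < r_3 < r_4 and
scalar conductivities σ_1..σ_4 that are homogeneous within each shell,
isotropic, and frequency independent (the quasi-static approximation:
capacitive, inductive and propagation effects are negligible at
physiological frequencies). The source is an ideal current dipole at radius
r_z strictly inside the brain shell. Under these assumptions the potential
obeys ∇·σ∇Φ = −C with

* Φ continuous at r_1, r_2, r_3;
* σ ∂Φ/∂r continuous at r_1, r_2, r_3;
* ∂Φ/∂r = 0 at r_4 (no current leaves the head).

Separation of variables gives, per spherical harmonic degree n ≥ 1 (there is
no n = 0 term: a dipole injects zero net current, so the scalp surface mean
vanishes), shell solutions A_n^s (r/r_s)^n + B_n^s (r_s/r)^{n+1}. The
exterior-basis coefficient of shell 1 is fixed by the source itself to
(r_z/r)^{n+1}; the remaining seven coefficients (A_n^1, A_n^2, B_n^2, A_n^3,
B_n^3, A_n^4, B_n^4) follow from the seven boundary equations. The closed
form proceeds through auxiliaries computed outside-in —

* V_n (skull/scalp), so that B_n^3 = V_n A_n^3,
* Y_n (CSF/skull), so that B_n^2 = Y_n A_n^2,
* Z_n (brain/CSF), entering A_n^1 directly,

with B_n^4 = n/(n+1) · A_n^4 expressing the scalp Neumann condition exactly,
term by term. The radial-dipole potential carries an extra factor n and
P_n(cos θ); the tangential solution uses the same coefficients with
P_n¹(cos θ) sin φ. An arbitrary dipole is decomposed in the canonical frame
(position on +z, tangential moment along +y; the rotation is orthogonal with
determinant +1 and p_rad² + p_tan² = |p|²) and evaluated by superposition.

## Conventions

* **Units.** SI internally (m, S/m, A·m, V). Configuration files may declare
  `cm` (or `mm`); conversion happens once at the boundary. CLI output is in
  volts by default, with a `--units uV` convenience flag matching EEG
  practice.
* **Azimuth/Legendre sign.** Associated Legendre functions are generated by
  upward recurrence in the Condon–Shortley-free normalization,
  P_1¹(cos θ) = sin θ ≥ 0, and the tangential solution uses a **+sin φ**
  prefactor for a moment along canonical +y. Textbook presentations that
  include the Condon–Shortley phase write the same solution as −sin φ with
  their P_n¹; the two are algebraically identical. The combination here is
  pinned unambiguously by a physical limit: in an equal-conductivity model
  with very large radii, a +y dipole must reproduce the unbounded-medium
  potential p·(x − x₀)/(4πσ|x − x₀|³), positive on the +y side (asserted in
  the tests to 1e-6 relative).
* **Interface radii** are assigned to the inner shell. Continuity makes the
  choice immaterial to series tolerance; the tests evaluate both shell
  expansions on each interface and check agreement explicitly.
* **Validity region.** Points with r ≤ r_z are rejected: the expansions are
  stated for r > r_z only and the interior expansion is deliberately not
  implemented (EEG electrodes never sit below the source radius; silent
  extrapolation would be wrong). A dipole exactly at the center is likewise
  rejected — the 1/r_z² prefactor and the undefined radial direction make it
  numerically and geometrically indeterminate; offset it by a small amount
  instead. Electrodes below the scalp surface are permitted anywhere in
  (r_z, r_4]; the containing shell is selected automatically.

## Numerical strategy

**Stable closed form.** Naively evaluated, the auxiliaries mix decaying
terms like r_34^n with growing ones like r_43^{n+1} (≈1.059^n for the
standard radii), and in near-homogeneous configurations V_n, Y_n, Z_n
themselves grow like ratio^{2n+1} — overflowing doubles near n ≈ 2700 even
though the A/B coefficients stay tame. Every rational expression is
therefore divided through by its dominant exponential, and V, Y, Z are
carried as bounded (numerator, denominator) pairs until the A/B chain is
assembled; only ratios of adjacent radii raised to reduced powers
(always < 1) appear. Coefficients additionally factor out the common source
amplitude (r_z/r_1)^{n+1}. For field evaluation the exterior-basis
coefficient is stored pre-scaled to the shell's inner boundary,
B_n^s (r_s/r_{s-1})^{n+1}, so that the per-point factor (r_{s-1}/r)^{n+1}
never exceeds 1 — avoiding inf·0 when B_n^s itself underflows at high n.

**The linear-system oracle.** An independent route assembles, per harmonic,
the 7×7 system of the seven boundary equations with column-scaled unknowns
(each exterior coefficient replaced by its inner-boundary value, keeping all
matrix entries O(n·σ)) and solves it by Gaussian elimination with partial
pivoting in extended precision (`numpy.longdouble`; LAPACK bindings are
double-only, and a 7×7 elimination is trivial to write and verify). The
auxiliaries are recovered from their boundary-value meaning (Y = B_2/A_2,
V = B_3/A_3, Z from the shell-1 matching condition), never from the
closed-form chain. Closed form and oracle agree to ~1e-12 per coefficient
over the standard model and randomly drawn valid models for n up to 1000,
and summed potentials agree to ~1e-15 — this replaces a finite-element
cross-check at the same logical role (independent solution of the same
boundary-value problem) with a far tighter bound and desk-scale cost.

**Truncation.** Sums run to `n_max` = 5000 by default with adaptive
stopping: after `consecutive_small` = 10 successive terms below
`rel_tol` = 1e-12 of the running sum (max over the evaluated batch). Scalp
evaluations for r_z = 7.8 cm converge in ~200 terms (ratio r_z/r_4 ≈ 0.87);
evaluations on the brain–CSF boundary, where the ratio is r_z/r_1 ≈ 0.987,
need ~2000. Legendre values come from upward recurrences (stable for
|x| ≤ 1), powers from incremental multiplication. Coefficient tables are
cached per (model, r_z, method) and shared across electrodes, since the
coefficients do not depend on the evaluation point.

**Degenerate inputs.** Near-equal adjacent radii (gaps down to 1 µm) only
push the reduced ratios toward 1 and remain stable (stress-tested against
the oracle). Coefficients that decay below the normal-double range underflow
to zero harmlessly — their field contribution is far below round-off. A
genuine overflow (possible only outside the adaptive-truncation regime, e.g.
forcing huge n in near-homogeneous models) raises a series-range error
naming the failing harmonic rather than returning non-finite values.

## Validation suite

Four packaged checks, each returning a report with the residual, sample
count, tolerance and its provenance (the pass flag is forced consistent with
residual ≤ tolerance):

1. **Boundary conditions** — worst normalized continuity residual over 100
   (θ, φ) samples per interface, both dipole kinds; observed ~1e-14 against
   a 1e-8 budget. Scalp Neumann residual normalized by the mid-scalp
   derivative scale; observed ~1e-16 against 1e-10 (the cancellation is
   per-term and exact up to round-off).
2. **Homogeneous limit** — equal-σ four-sphere series vs the single-sphere
   closed form Φ(r_4, θ) = p/(4πσr_4²)·[2(cos θ − f)/d³ + (1/d − 1)/f],
   d² = 1 + f² − 2f cos θ, f = r_z/r_4; observed ~1e-12 against 1e-6.
3. **Infinite-medium limit** — equal-σ model, radii scaled ×10/×100/×1000 at
   fixed dipole–electrode geometry; the deviation from the unbounded-medium
   formula must fall monotonically and be ≤ 1% at ×1000 (observed ~1e-10;
   the finite-size correction scales like 1/scale²).
4. **Oracle equivalence** — closed-form vs linear-solve pipelines at shared
   truncation over scalp point sets; tolerance 1e-9, observed ~1e-15.

Property tests draw random valid models (radii increasing in [5, 12] cm with
≥ 1 mm gaps, conductivities log-uniform in [0.004, 2] S/m, dipole radius in
0.3–0.95 r_1) with fixed seeds.

## Design choices

* The skull-conductivity divisor K defaults to 20, with 40 and 80 as
  documented presets — the three values commonly exercised for this model.
* The infinite-medium check fixes the electrode–dipole geometry and scales
  only the radii, asserting monotone decrease over ×10/×100/×1000; a
  concrete protocol is needed because the limit itself is asymptotic.
* Truncation defaults are this package's choice (no canonical values exist):
  they are sized so that the boundary-surface checks, the slowest-converging
  use case, resolve 1e-12 tails.
* Scalp maps are written as long-format CSV (`theta_rad,phi_rad,potential_V`)
  rather than a binary grid: trivially diffable and plottable everywhere.
* The CLI is bit-reproducible for a fixed configuration — there is no hidden
  randomness in any compute path.

## Limitations

* No anisotropic, frequency-dependent, or non-concentric geometry — by
  construction of the model.
* No magnetic fields (MEG), no interior potentials (r < r_z), no multi-dipole
  lead-field assembly beyond looping over dipoles.
* The closed-form single-sphere control covers radial dipoles only (the
  series machinery handles tangential cases).
* Electrode positions are treated as exact points on or inside the scalp
  sphere; there is no electrode model (size, impedance) and no standard
  montage database.
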