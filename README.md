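# nsphere

Analytical EEG forward solutions for concentric-sphere head models with an
arbitrary number of shells.

The package evaluates the electric potential of a **radial current dipole**
inside a volume conductor built from `n` concentric, homogeneous, isotropic
spherical shells (brain / CSF / skull / scalp and beyond), and assembles
lead-field matrices for scalp electrode arrays. The per-degree constants of
the Legendre series are obtained from a single inward/outward recursion that
works for any shell count; the historical four-shell explicit constants, the
spatial-filter formulation, the homogeneous-sphere closed form, and a
brute-force boundary-condition linear solver are included as independent
cross-checks, and all paths agree to double-precision rounding.

Everything is SI: meters, S/m, A·m, volts.

## Library quick start

```python
import numpy as np
import nsphere as ns

model = ns.canonical_model("three-shell-classic")   # 1/3, 1/240, 1/3 S/m
constants = ns.harmonic_constants(model, L=100)      # cached per (model, L)
dipole = ns.RadialDipole(position=(0, 0, 0.05), moment=1e-8)  # A*m

# potential on the scalp at polar angles from the dipole axis
profile = ns.surface_potential_profile(
    model, constants, dipole, thetas=np.linspace(0, np.pi, 50)
)

# or at an arbitrary Cartesian point
res = ns.potential(model, constants, dipole, ns.FieldPoint((0.03, 0, 0.09)))
print(res.value, res.shell, res.degree_used)
```

Key entry points:

- `model_core` — `SphereModel`, `RadialDipole`, `validate_model`,
  `canonical_model`, `random_model`, `split_shell`, JSON model I/O.
- `harmonic_filters` — the per-degree propagation constants `X` and
  expansion coefficients `A_tilde` / `B_tilde` (`harmonic_constants`).
- `potential_series` — `legendre_sequence`, `locate_shell`, `potential`,
  `surface_potential_profile`.
- `reference_oracles` — four-shell explicit constants, spatial-filter
  weights, homogeneous closed form, boundary-condition linear solve.
- `leadfield_cli` — `ElectrodeArray`, `radial_leadfield`, table I/O and the
  command-line program.

Only radial dipole moments are supported; tangential components and MEG are
out of scope. Evaluation points must satisfy `r0 <= r <= R_n`.

## Command line

```sh
nsphere-leadfield \
  --model model.json \
  --dipoles dipoles.csv \
  --electrodes electrodes.csv \
  --degree 100 --reference infinity \
  --out leadfield.tsv --log run.log
```

`model.json` holds `radii_m` (ascending) and `conductivities_S_per_m`.
Dipole tables are CSV/TSV with columns `x_m,y_m,z_m,moment_Am`; electrode
tables have `x_m,y_m,z_m` and an optional `label` column and may sit up to
1% off the outer surface (they are projected radially). The output TSV has
one row per dipole, one column per channel, units V per A·m, with a `#`
header block recording degree, reference and a model digest.

## Numerical notes

- The inward recursion for `X` is evaluated with only bounded radius-ratio
  powers, so it neither overflows at high degree nor cancels at
  zero-contrast (fictitious) boundaries.
- Stored coefficients are safe in double precision for truncation degrees
  up to 300 on models whose adjacent radius ratios are at least 0.5; the
  default truncation is L = 100.
- Potentials are referenced to infinity by default; average reference is a
  post-hoc linear map (`--reference average`).
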