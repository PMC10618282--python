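# tmsbem

Charge-based boundary element solver for the electric field that
transcranial magnetic stimulation (TMS) induces in a multi-compartment
surface head model.

A TMS coil drives a rapidly changing current (`dI/dt ~ 1e8 A/s`); in the
quasistatic regime the induced field inside the head is the coil's primary
field plus the Coulomb field of charges that appear on every tissue
conductivity interface.  With the scaled surface charge density
`c = rho/eps0` as unknown, current continuity across each interface gives a
well-conditioned second-kind Fredholm equation

    c/2 - K n . (1/4pi) pv-int_S c(r') (r-r')/|r-r'|^3 dS' = K n . E_p,
    K = (sigma_in - sigma_out) / (sigma_in + sigma_out),

discretized with piecewise-constant charges on triangulated interfaces
(closed-form triangle integrals in the near field).  Two solution paths:

* **iterative** — matrix-free GMRES (the operator is applied with a
  near/far split: analytic near integrals, point-charge far sums via exact
  compiled kernels or a Barnes–Hut treecode), ~35 iterations for a
  relative residual of 1e-6;
* **direct** — factorize the system matrix once per head model (dense LU
  or a precision-tunable block-low-rank LU), then solve for arbitrarily
  many right-hand sides: one per coil position, orientation, or coil
  deformation, which is the regime of motor-mapping scans and
  neuronavigation.

Validation is self-contained: a synthetic generator builds nested
multilayer icosphere head models and parametric figure-8 coils, and the
analytic total field inside any spherically symmetric conductor (zero
radial component, conductivity-profile independent) serves as ground
truth.  Audience: researchers modeling TMS-induced fields, and anyone who
needs a compact, tested charge-based BEM with an analytic sphere oracle.

## Worked example

Build a four-layer sphere head model (radii 92/86/80/78 mm, SimNIBS-style
conductivities, 80 facets per interface at level 1) and a figure-8 coil,
then solve:

```
$ tmsbem make-spheres --level 1 --out-dir spheres
wrote 4 STL files and head.toml to spheres
$ tmsbem make-coil --out coil.csv
wrote 128 elements to coil.csv
$ tmsbem solve --manifest spheres/head.toml --coil coil.csv \
               --observation "sphere:0.05,1" --out-prefix run1
N=320 solver=iterative max|E|=25.1549 V/m mean|E|=10.4184 V/m
iterations=23 residual=5.298e-07
```

The solver reports the facet count, the GMRES iteration count and final
relative residual, and the maximum and mean total-field magnitude over the
42 observation points on the interior r = 5 cm sphere: at
`dI/dt = 9.4e7 A/s` the peak interior field under the coil is ~25 V/m, a
typical cortical field strength for suprathreshold TMS.  `run1_field.csv`
holds one `x,y,z,Ex,Ey,Ez,|E|` row per observation point and
`run1_charge.csv` the per-facet charge solution.

The same workflow from Python:

```python
import tmsbem as tb

head = tb.four_layer_sphere_model(3)              # 5120 facets
coil = tb.place_coil(tb.build_figure8_coil(0.035),
                     target=(0, 0, 0.092), axis_dir=(0, 0, -1),
                     handle_dir=(1, 0, 0), standoff=0.01)
op = tb.BemOperator(head, precision=1e-4)
rep = tb.solve_iterative(op, tb.build_rhs(head, coil), tol=1e-6)
sol = tb.ChargeSolution(rep.solution, head, coil)
fields = tb.total_field(sol, tb.icosphere(0.05, 2).vertices)
```

Other commands: `tmsbem validate-sphere` (solve at several refinements and
compare against the analytic solution), `tmsbem scan` (many coil
placements reusing one cached factorization).

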