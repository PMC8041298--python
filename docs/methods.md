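# Methods

## The fitting problem

A classical force field writes the torsional energy of a molecule as a
truncated cosine series per dihedral angle,

    E_tors = sum_i sum_{j=1..J} k_{t(i)}^j * (1 + cos(j * phi_i)),

where `i` runs over the dihedral *instances* of the molecule, `t(i)` is the
dihedral *type* of instance `i` (the equivalence class of its atom-type
quadruple), and `J` is 3 or 4. All instances of one type share one
coefficient row, so a molecule with 15 dihedrals in 6 types needs
6 × 4 = 24 parameters for a 4-term fit.

The fitting evidence is a set of conformers from constrained torsion scans.
For each conformer `k` the target is the torsional energy isolated as the
difference between a quantum-chemical total energy and the
molecular-mechanics energy evaluated with all torsion coefficients zeroed
(`E_target = E_tot(QM) − E_zero-tors(MM)`, kJ/mol). Crucially, each
conformer's record carries the values of *all* dihedrals, not only the
scanned one: in a relaxed scan every off-scan dihedral responds to the
driven one, so the per-dihedral profiles are coupled and all coefficients
must be fitted simultaneously.

Because the basis functions `1 + cos(j*phi)` are known numbers once the
geometry is known, the model is linear in the coefficients. Stacking one
row per conformer and one column per (type, term) pair — each column the
sum of its type's instance basis values — gives a design matrix `B` and the
convex objective `F(K) = ||B K − y||²`. Its stationarity conditions form
the normal equations `W K = C` with `W = BᵀB`, `C = Bᵀy`, solved exactly:
this is the "global" fit, and no iterative optimizer can beat it.

### Offset column

The QM and MM energy zeros differ by an arbitrary constant, so by default a
trailing all-ones column is appended to `B` and a free scalar offset is
fitted with the coefficients. The offset is a property of the dataset, not
of the force field: it is reported, excluded from exported parameters, and
written into topology fragments only as a comment. Disable with
`include_offset=False` (CLI `--no-offset`) when targets are already
referenced consistently.

### Singular and under-determined systems

If `W` is singular (see "identifiability" below) the minimum-norm
least-squares solution is returned and `diagnostics["singular"]` is set
rather than failing; `diagnostics["cond_W"]` reports the condition number.
Systems with fewer conformers than parameters warn.

## Bounded ("local") variant

Very large torsion coefficients are physically suspect and destabilize MD
integration, so a variant minimizes the same objective subject to the box
`−T ≤ k ≤ T` on every torsion coefficient (the offset stays free). The
default bound is T = 20 kJ/mol; unconstrained fits whose largest |k|
exceeds 20 kJ/mol emit a warning pointing to the bounded fit. The problem
is a convex box-constrained least-squares program solved with BVLS
(`scipy.optimize.lsq_linear`); tests cross-check the optimum against an
independent projected quasi-Newton solver. When no bound is active the
bounded and global solutions coincide.

## Monte Carlo baseline

A Metropolis random walk over coefficient vectors is included as the
stochastic baseline the exact method is compared against. One coefficient
is perturbed per step by a centered Gaussian (`proposal_sigma`, default
1 kJ/mol); a proposal is accepted with probability 1 when the objective
does not increase and `exp(−dF/T)` otherwise, with the temperature factor
annealed geometrically from `T_start` to `T_end` (defaults 100 → 0.01 in
objective units) over `n_iter` steps (default 50 000). The proposal
distribution and cooling law are this package's own choices; the
best-so-far vector is returned, runs are bit-reproducible under a fixed
seed, and an optional box clips proposals so runs are comparable with the
bounded fit. Since the objective is convex with an exactly computable
minimum, the walk can at best match the algebraic solution — which is the
point of the comparison: on every dataset,

    F(global) ≤ F(local, T) ≤ F(MC in the same box).

## Fourier ↔ Ryckaert-Bellemans conversion

MD engines commonly store torsions as the Ryckaert-Bellemans polynomial
`sum_n C_n cos^n(psi)` with `psi = phi − 180°`. Using
`cos(phi) = −cos(psi)` and the Chebyshev expansions of `cos(j*phi)`, the
fitted basis maps linearly and exactly onto RB coefficients:

    C0 = k1 + k3 + 2 k4      C1 = −k1 + 3 k3     C2 = 2 k2 − 8 k4
    C3 = −4 k3               C4 = 8 k4           C5 = 0

Three-term fits are zero-padded (`k4 = 0`). The constant term is preserved
— the two representations agree at every angle to machine precision, not
merely up to a shift — because an exactly checkable identity is worth more
than matching conversion tables that drop constants; constants never affect
forces. The identity is enforced in tests at ≤ 1e-10 kJ/mol over a 0.5°
grid for 1 000 random coefficient sets.

## Profile evaluation

A fit is scored per scanned dihedral: conformers are grouped by the
dihedral that was driven, the model torsional energy is evaluated for each
conformer, and the root-mean-square deviation against the recorded targets
is taken per scan, plus an unweighted average over scans. Profiles are
minimum-aligned by default (each shifted so its minimum is zero) because
absolute offsets between the QM and MM scales carry no information; pass
`align=False` to compare raw values. The average is unweighted across
scans even though scans span different energy ranges — a deliberate,
simple convention.

## Synthetic scan generator

Real scan targets require quantum-chemistry and MD single-point runs, so
the package generates datasets with the same structure from known
coefficients: for every dihedral instance, one conformer per grid angle on
the half-open grid `[−180°, 180°)` (36 points at the default 10° step —
+180° is the same conformer as −180°, so it is not duplicated), target
energies evaluated exactly from the ground-truth coefficients plus optional
Gaussian noise.

Off-scan angles follow a coupling mode:

- `smooth` (default): each instance gets a fixed baseline plus a sinusoid
  of the scan angle with per-instance amplitude (15–40°) and phase,
  imitating the relaxation response of a real scan in which all profiles
  are conjugated;
- `fixed`: off-scan angles frozen at baselines;
- `random`: off-scan angles drawn uniformly per conformer.

Amplitudes, baselines and noise are drawn from a single seeded generator,
so identical seeds give byte-identical datasets. Default ground-truth
coefficients are uniform in ±5 kJ/mol, the magnitude typical of
organophosphate torsion sets.

What the generator does *not* emulate: correlated (non-Gaussian) errors
from basis-set or functional choice, geometries that fail to converge,
non-bonded strain leaking into the target, or anharmonic coupling between
torsions and bond/angle terms. Passing recovery tests therefore
demonstrates the estimator and its implementation, not the quality of any
particular quantum reference.

### Identifiability

After generation the rank of `BᵀB` is checked and a warning is emitted if
the coefficients are not identifiable. With every instance scanned over a
full 36-point grid the design is full-rank even when all off-scan angles
are frozen; genuine rank deficiency arises from aliased grids — e.g. a 90°
step makes `cos(4*phi)` identically 1, collapsing every 4th-term column
onto a constant — and is exercised in the tests through exactly that case.

## Numerical choices and defaults

| quantity | default | unit | rationale |
|---|---|---|---|
| terms per type `J` | 4 | — | standard 4-term torsion series; 3 supported |
| bound `T` | 20 | kJ/mol | conventional safe coefficient range |
| grid step | 10 | degrees | 36-point scans per dihedral |
| noise (tests) | 0.5 | kJ/mol | typical QM/MM target scatter |
| MC iterations | 50 000 | — | ample for ≤ 25-parameter systems |
| MC cooling | geometric, 100 → 0.01 | F-units | simple, monotone schedule |

Angles are degrees in files and API, radians only inside trigonometry; the
angle domain is half-open `[−180°, 180°)` with +180° normalized to −180°.
Energies are kJ/mol throughout (GROMACS convention); there is no kcal
mode. Design columns are ordered type-major, term-minor, and the `.itp`
writer emits fixed-width 6-decimal fields so exports are byte-stable.
The function-type-5 export records the fitted `1 + cos(j*phi)` coefficients
as-is (stated in the file header); the function-type-3 Ryckaert-Bellemans
export is the exact-energy route and the recommended one.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run entirely on synthetic data:
the canonical 15-dihedral / 6-type / 540-conformer problem for recovery and
ranking checks (20 noise replicates for the RMSD average, 3 for the
per-method comparison), 50 random small systems for the solver-oracle
cross-checks, 1 000 coefficient sets for the conversion identity, and
10 000 Bernoulli trials for the acceptance law.

## Limitations

- The package consumes targets `E_tot(QM) − E_zero-tors(MM)`; it does not
  compute either term (no QM driver, no MM engine integration) and does not
  extract dihedral values from Cartesian geometries.
- No regularized (ridge/lasso) or Boltzmann-weighted fitting.
- Improper dihedrals and CHARMM CMAP corrections are out of scope.
- The exact RB conversion is one-way as implemented; the inverse exists
  only for RB sets in the image of the forward map (C5 = 0 and the C's
  consistent), which is why the CLI converts Fourier → RB only.
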