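# Methods

## Problem and model

`eit3d` simulates and inverts three-dimensional electrical impedance
tomography (EIT) on a cylindrical tank carrying three rings of 16 lateral
electrodes (48 in total). The motivating application is absolute imaging of
biological specimens such as intact maize ears, whose interior conductivity
reflects the spatial moisture distribution; the same machinery covers saline
tanks with near-insulating (acrylic) inclusions.

The forward model is the complete electrode model (CEM) discretized with
first-order tetrahedral finite elements. The domain Ω is the cylinder
(default radius 5 cm, height 8 cm), the unknown is the per-element
conductivity vector σ ∈ R^N (S/m internally; configuration surfaces accept
µS/cm with 1 µS/cm = 1e-4 S/m), and a forward solve maps (σ, drive currents)
to nodal and electrode potentials. Electrode potentials are grounded to zero
mean via a Lagrange multiplier, so differential measurements are
convention-independent.

### Contact layer

The electrode contact is modelled as a thin resistive layer *of the measured
medium itself*: the surface conductance density under electrode *l* is
σ_face / ζ_l, where σ_face is the conductivity of the element owning the
boundary face and ζ_l (Ω·m) is a geometric constant. `CEMParams.
contact_impedance` (default 1e-4 Ω·m²) states the effective contact
impedance at the reference background of 350 µS/cm, i.e. ζ_l =
contact_impedance × σ_ref. The payoff is structural: the assembled operator
is exactly homogeneous of degree one in σ, A(σ) = Σ_n σ_n K_n, so

* the measurement scaling law v(cσ) = v(σ)/c holds to solver precision,
* the Euler identity J·σ = −v is exact and validates the Jacobian, and
* reciprocity holds by symmetry of A.

A fixed, σ-independent contact impedance (the other common CEM convention)
breaks the first two identities at the 0.1–1% level; for electrolyte-wetted
contacts the conductivity-proportional layer is at least as defensible
physically, and it gives the solver sharp internal consistency checks.

### Meshing

The structured mesher subdivides the cylinder into layered wedges: azimuthal
node lines are placed on every electrode edge (three angular strips per
22.5° sector for the default 10°-wide pads) and horizontal node planes on
every electrode top/bottom edge (0.5 cm pads centred at z = 2, 4, 6 cm).
Electrode patches are therefore exact unions of lateral boundary faces,
pairwise disjoint, and the mesh is invariant under rotation by one electrode
spacing. Hexahedral cells are split into six tetrahedra around the main
diagonal with one fixed local pattern — conforming across all neighbours and
16-fold symmetric; the innermost wedge prisms use the compatible 3-tet
split. `refinement` controls the radial ring count and axial density:
refinement 1 ≈ 1,000 elements, 2 ≈ 3,000 (the package default), 3 ≈ 8,000.
The polygonal cross-section under-estimates the circular area by ~0.3% at
48 azimuthal strips. Electrode dimensions, ring heights, contact impedance
and the 1 mA drive amplitude are configurable defaults; none of them is
dictated by the underlying study conditions, which leave them open.

Radial resolution matters for phantoms: at refinement 1 every tetrahedron
touches the axis and element centroids sit at radii ≳ 2.5 cm, so small
interior inclusions are invisible; inclusion work uses refinement ≥ 2.

### Protocol

Adjacent drive, adjacent measurement: excitation k of each ring drives the
ring-adjacent pair (k+1, k); for each of the 48 excitations, 45 adjacent
pairs are read (13 in the drive's own ring — skipping the drive pair and its
two electrode-sharing neighbours, starting two positions past the drive —
and 16 in each other ring, starting at the drive's lower local electrode),
ring blocks in A, B, C order. A frame is the excitation-major vector of
48 × 45 = 2,160 differential voltages v = φ(out1) − φ(out2). The feature
reconfiguration reshapes the frame into the 48 × 45 excitation-by-
measurement matrix and transposes it to the 45 × 48 single-channel map the
network consumes; the map is exactly invertible back to the frame.

### Jacobian

Because A(σ) is linear in σ, the sensitivity of measurement l (drive pair d,
measurement pair p) is J[l,n] = (1/I) w_pᵀ K_n w_d with w the forward
solutions of the two pairs at the drive amplitude I. The adjacent protocol's
measurement pairs coincide with the drive-pair set, so one factorization and
48 solves yield the full 2,160 × N matrix; per-element volume terms are
batched with einsum and the (few) electrode-face surface terms added
explicitly. Validation: full-matrix central differences on a 240-element
mesh agree to ~4e-9 of the matrix scale, and J·σ = −v to ~1e-13.

## Phantoms

*Acrylic*: piecewise-constant fields, background 350 µS/cm, inclusions
0.0001 µS/cm; spheres, z-axis cylinders, axis-aligned cubes; membership by
element centroid (deterministic and exactly testable; no partial-volume
weighting). *Maize gradient*: σ = σ_max · Es with
Es = exp(−D_xy·s(z)/bs₁ − D_xy·s(z)/bs₂ − D_z/bs₃) and
s(z) = 1 + a·sin(bz + c), evaluated at element centroids. D_xy appears in
both of the first two exponent terms as the source model prints it (the two
terms merge into a single in-plane rate 1/bs₁ + 1/bs₂; a possible typo, kept
verbatim rather than corrected). σ_max defaults to 350 µS/cm — the gradient
model's absolute scale is not dictated anywhere, so the saline background
value is reused. The seeded sampler draws centres uniformly from the central
60% of the cylinder radially and the 20–80% band axially, sinusoid
amplitudes a ∈ [0, 0.2], and decay rates bs ∈ [2, 6] cm: inclusions remain
well inside the electrode array and fields stay numerically benign.

## Noise and detection limit

SNR is defined frame-wise on RMS amplitude: noise std =
RMS(frame)·10^(−SNR/20), i.i.d. zero-mean Gaussian, added to raw frames
before reconfiguration (the reshape is linear, so order only affects
metadata). A measurement is detectable when |v| exceeds the noise mean plus
three noise standard deviations (mean 0 here). The detection proportion is
non-decreasing in SNR; the exact proportions depend on mesh and phantom, so
only the monotone trend and the count/proportion identity are asserted.

## Learned reconstruction

The regression network is a bottleneck residual CNN: 7×7/stride-2/pad-3 stem
(1 → 64 channels; 45×48 input → 64×23×24), 3×3/stride-2/pad-1 max pool, four
stages of bottleneck blocks with depths (3, 4, 6, 3), widths (64, 128, 256,
512) and expansion 4 (projection shortcut at each stage entry, identity
elsewhere), global average pooling to a 2,048-vector, and one fully
connected layer to the N-element conductivity vector. The stage layout is
pinned by the 2,048-length pooled vector together with the stated stem;
the max-pool parameters are the conventional choice that reproduces that
length. The stack is implemented directly on numpy (im2col convolutions,
batch normalization, manual backpropagation, Adam) and is bit-deterministic
under fixed seeds; backprop is verified by finite differences.

Training minimises α·MSE with α = 100 by default: raw conductivity
residuals are small and the amplification keeps reported losses in a
readable range (Adam's per-parameter scaling makes the optimum itself
α-independent); α = 1 is plain MSE. Normalization matters more than any
other choice here. The 2,160 measurement positions span decades of
amplitude, so inputs are standardised per feature-map position (z-score per
position with training-split statistics) — with a single global scale the
network never learns at all, because the informative variations at
low-amplitude positions are numerically invisible. Targets are standardised
per element with a shrunk standard deviation (std + 5% of the largest
element std), balancing the loss across elements without exploding
near-constant ones, and the head bias starts at zero so the initial
prediction is the training-mean field. All statistics come from the
training split only, travel with the checkpoint, and are inverted at
prediction time. Defaults: 50 epochs, batch 32, Adam at 1e-4,
reduce-on-plateau (×0.5, patience 5) on validation loss — the minimal
documented dynamic-rate policy.

Desk-scale experiments (single CPU) use `NetworkSpec.reduced`: stem 16,
depths (2, 2, 2, 2), widths (16, 32, 64, 128), pooled length 512, trained
at 3e-3 (with ~750 optimizer steps the full-scale default rate of 1e-4 never leaves
the mean-field solution). The scaled-down recovery experiment — 3,024-
element mesh, 1,250 samples split 8:2 into 1,000 training / 250 validation,
single-inclusion acrylic phantoms at 40 dB, 30 epochs, all seeds fixed —
measures held-out mean CC and RMSE against the best constant-field
predictor. Under these conditions the network reaches held-out CC ≈ 0.5
with RMSE ~26% below the constant predictor; for calibration, a closed-form
ridge regression on the same data (the best linear readout, free of any
optimization budget) also tops out at CC ≈ 0.5, and the noiseless
Gauss-Newton solver with the exact forward model reaches CC ≈ 0.7. Larger
values require more data and training than the desk-scale budget provides.
A passing run shows the pipeline learns the voltage → field mapping under
the stated conditions; it does not certify performance on measured data
(electrode-contact drift, non-Gaussian noise and anatomical geometry are
outside the generator).

## Gauss-Newton comparator

Absolute imaging by damped, Tikhonov-regularized Gauss-Newton on the linear
conductivity parametrization: homogeneous initialization from an exact
scalar least-squares fit (v is 1/σ for homogeneous fields), Jacobian
recomputed each iteration, normal-equation step with identity (default) or
element-adjacency-Laplacian prior, backtracking halving until the objective
decreases, conductivity clipped at 1e-10 S/m, stop on 10 iterations or
relative objective change < 1e-6. The regularization weight is specified
relative to mean diag(JᵀJ) (default 1e-3), making it mesh- and
scale-independent. Wall-clock inverse-problem solving time (IPST) is
recorded, never asserted. With the near-insulating inclusions the problem is
strongly nonlinear; the damped linear-parametrization iteration typically
stalls after 3–5 accepted steps at CC ≈ 0.65–0.75 on ~1,000–3,000-element
meshes — adequate for a classical baseline the learned method is compared
against.

## Numerical choices and degenerate inputs

* Forward solves: sparse LU with one iterative-refinement step; relative
  residual checked against 1e-10, failure raises.
* SSIM constants c₁ = (0.01·L)², c₂ = (0.03·L)² with L the reference
  dynamic range, floored at 1e-24 so equal constant fields score 1.
* MMD uses the unbiased estimator (Gaussian kernel, median-heuristic
  bandwidth over pooled samples); negative estimates are clipped at 0 before
  the square root. KDE bandwidths by Silverman's rule with a 1e-12 floor and
  a warning for zero-variance samples; the ISE integral is trapezoidal on a
  512-point grid spanning both samples ±3 bandwidths. LMMD windows are
  contiguous index windows (remainder dropped). KNNDC averages each X
  point's mean distance to its k = 5 nearest neighbours in Y.
* All-zero frames cannot be noise-scaled (undefined RMS) and raise; the
  detection report treats them as zero passes.
* The conductivity container rejects non-positive values; predictions are
  clipped at 1e-10 S/m before being wrapped as fields.

## Known limitations

* The cylinder stands in for anatomical maize-ear geometry; no husk/kernel/
  cob surfaces are meshed.
* Real-valued conductivity at a nominal frequency; no complex admittivity
  or frequency sweep.
* The Gaussian, frame-RMS-scaled noise model omits drift, spikes, and
  contact-impedance fluctuation of physical acquisition systems.
* Full-scale replication (≈95,000-element meshes, 10,000–20,000-sample
  training) is out of scope; all experiments are scaled-down equivalents and
  headline numbers from full-scale studies are not reproduced here.
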