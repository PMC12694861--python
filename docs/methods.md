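# Methods

## The model

`quanvnet` implements a hybrid quantum-classical image classifier built
around a *quanvolutional* feature extractor. A grayscale image
`I ∈ [0,1]^{H×W}` (H, W even) is tiled into non-overlapping 2×2 patches.
Each patch's four intensities φ = (φ0, φ1, φ2, φ3) are loaded onto a
4-qubit register initialized in |0000⟩ by the encoding unitary

    U_enc(φ) = ⊗_i H_i · RY(π φ_i)_i ,

i.e. per qubit an RY rotation by π·φ_i followed by a Hadamard. The encoded
state is transformed by L ∈ {1..5} variational layers

    U_layer,l = U_entangler,l · ⊗_i RZ(θ_{l,i,2}) RY(θ_{l,i,1}) RX(θ_{l,i,0}) ,

with products applied right-to-left (RX first). The entangler applies
CNOT (model variant v1) or CZ (variant v2) on a fixed pair schedule:
(0,1),(1,2),(2,3),(3,0) for layers 1 and 4; (0,2),(1,3),(2,0),(3,1) for
layers 2 and 5; (0,1),(2,3),(1,2),(3,0) for layer 3. In each ordered pair
the first index is the CNOT control. The readout is the four Pauli-Z
expectations ⟨Z_i⟩ of the final state; over all patches these assemble an
(H/2, W/2, 4) feature map that feeds a small classical CNN
(conv/ReLU/max-pool → flatten → dense/ReLU → softmax). Quantum angles and
classical weights are optimized jointly on the categorical cross-entropy.

Everything is exact statevector simulation: expectations carry no shot
noise, and no noise channels are simulated. The register is fixed at 4
qubits (16 amplitudes); qubit 0 is the leftmost tensor factor (most
significant bit of the basis index).

A useful closed form anchors many tests: after the encoding alone,
⟨Z_i⟩ = sin(π φ_i). Because CZ is diagonal, a CZ-entangled circuit with
all θ = 0 leaves every ⟨Z⟩ expectation at exactly this value for any
layer count ("zero-angle CZ transparency"). Note also that the printed
layer-2/5 pair schedule makes the CZ entangler cancel itself ((0,2) then
(2,0), (1,3) then (3,1); CZ is symmetric and self-inverse), so those
layers act as pure rotations in the CZ variant. The schedule is
implemented literally as specified rather than "repaired".

## Gradients

Quantum-parameter gradients use the parameter-shift rule,
∂f/∂θ = [f(θ+π/2) − f(θ−π/2)]/2, which is exact for Pauli-rotation
generators. This makes the gradient contract implementation-independent:
the test suite checks it against central finite differences (h = 1e-5,
agreement within 1e-5) on random circuit configurations. Classical
gradients are ordinary backpropagation written against numpy. Optimizers
(adam, sgd, rmsprop, adamax) follow the standard published update rules;
beyond the learning rate (default 0.001) the hyperparameters are the
usual defaults (β1 = 0.9, β2 = 0.999, ε = 1e-8; ρ = 0.9 for rmsprop;
momentum 0 for sgd). Training defaults to 40 epochs, batch size 16.

Joint optimization is the default reading of "simultaneously optimizes
the quantum and classical parameters"; a `frozen_quantum` mode is
provided for the common quanvolution shortcut of treating the quantum
extractor as a fixed random filter bank.

## Hardware analysis

The CNOT-vs-CZ comparison rests on two computed artifacts:

1. **Native-gate accounting.** The published synthesis sequences on
   cross-resonance hardware are carried verbatim:
   CNOT = (I⊗(SX·RZ(−π/2)))·ECR·((RZ(π/2)·SX)⊗I) — five native gates
   (1 ECR, 2 SX, 2 RZ) — and CZ = (I⊗RZ(π))·ECR·(RZ(−π/2)⊗I) — three
   (1 ECR, 2 RZ), a 40% reduction per entangling operation. Whether each
   sequence is *unitarily equivalent* to its logical gate is checked by
   dense multiplication under this package's documented conventions
   (ECR = (X⊗I − Y⊗X)/√2 on (control, target); RZ with symmetric phases
   diag(e^{−iλ/2}, e^{iλ/2})) and reported as a global-phase fidelity
   |tr(U†V)|/4 with a pass flag at 1 − 1e-9. Under these conventions the
   fidelity is 0 for both sequences — for the CZ formula structurally so,
   since its composition keeps X/Y support on the control slot while CZ
   is diagonal, making the trace overlap exactly zero. An exhaustive
   numeric search over all ECR candidates of the form (P⊗Q ± R⊗S)/√2
   with Pauli factors, both operand orders, and the diag(1, e^{iλ}) RZ
   convention found no convention under which the printed formulas become
   exact, so the sequences are best read as gate-count accounting (their
   counts match what hardware transpilers emit) rather than as complete
   circuit identities; the report states this empirically instead of
   assuming either way. The module also reports the depth of its own
   sequences (5 and 3, longest per-qubit path); transpilers may insert
   additional gates, so device-reported depths can differ.

2. **Dephasing propagation.** Dephasing is modeled by Pauli-Z errors.
   For a Clifford gate G the conjugation E = G·P·G† maps Paulis to
   Paulis; the module computes it densely and matches the result against
   all 64 candidates (16 labels × phases {±1, ±i}, tolerance 1e-10). The
   table exhibits the key asymmetry: CZ commutes with I⊗Z and Z⊗I (Z
   errors stay weight-1, "error locality"), while CNOT maps I⊗Z to the
   correlated weight-2 error Z⊗Z. The coherence model is
   P_err = 1 − e^{−t/T1} (amplitude damping) or 1 − e^{−t/T2}
   (dephasing), with t the gate duration.

## Synthetic data

No public accession exists for the three-class fruit-grading task the
model targets, so the package generates its own: each image is a bright
disc (intensity 0.85) on a dark background (0.15) with mild center/radius
jitter (±3%), overlaid with dark circular blemishes and Gaussian pixel
noise (σ = 0.05), clipped to [0, 1]. The class signal is the blemish
density: 0.0 (fresh), 0.15 (mild), 0.4 (rotten), with the per-image spot
count Poisson-distributed with mean density × (disc area / spot area), so
density reads as expected fraction of fruit surface covered. Defaults:
3 classes × 50 images (150 total, matching a small curated-dataset
regime), 16×16 pixels. The small image size keeps a full 5-fold
cross-validation of both entangler variants under a few minutes on one
CPU core; 100×100 generation is supported when parity with
camera-derived preprocessing (resize → grayscale → normalize) is wanted.

Spot geometry (radius 1.0 px at 16×16, jitter ±20%) was fixed by a
pre-test pilot so that a trivial mean-intensity threshold classifier
reaches ≥ 0.8 holdout accuracy on the default configuration — i.e. the
task is decidedly learnable but not saturated. What the generator does
*not* emulate: real spoilage texture, specular highlights, lighting and
pose variation, class-dependent shape changes, and label noise. Passing
tests therefore demonstrate that the pipeline learns a controlled,
monotone class signal — not field performance on photographs.

Augmentation (rotation 15°, shift 0.1, shear 0.1, zoom 0.1, horizontal
flip) exists only for classical-baseline harnesses; the quantum pipeline
trains on unaugmented images.

## Evaluation protocol

5-fold cross-validation with stratified, seeded splits (global
round-robin assignment, so total fold sizes differ by at most one while
classes stay balanced). Each fold trains a fresh model; the report
aggregates fold accuracies into mean ± margin with the confidence
interval printed literally as (mean − margin, mean + margin). The margin
estimator is configurable — sample standard deviation across folds
(default), standard error, or t-based 95% half-width — because published
"±" conventions vary; the estimator used is stamped into every report.
Precision/recall/F1 are reported per class and support-weighted (weighted
recall equals accuracy, an identity the tests assert); macro averages are
also emitted. Zero-denominator precision/recall are defined as 0.

Entangler comparisons are paired: identical fold splits and identical
classical initialization seeds, so accuracy and dispersion differences
are attributable to the entangling gate alone. A stability probe
(`entangler_stability`) additionally reports the spread of final
validation accuracy across seeded re-runs per entangler, without
asserting which gate is steadier.

## Numerical choices

- Tolerances: 1e-10 for algebraic identities on printed matrices, 1e-9
  for composed circuits — comfortably above double-precision
  accumulation at 16 amplitudes.
- Unitary comparisons are always up to global phase.
- Pixel inputs outside [0, 1] are rejected (tolerance 1e-9), never
  silently clamped; the CLI performs explicit normalization instead.
- Argmax ties in prediction resolve to the lowest class index.
- Fold counts, seeds, and shuffles all derive from explicit integer
  seeds; identical configurations give bit-identical histories and
  reports. The CLI fans a single `--seed` into per-stage sub-seeds via
  `numpy.random.SeedSequence` spawn keys.
- The batched quanvolution path builds the dense 16×16 circuit unitary
  once per parameter setting and applies it to all patch states at once;
  it is tested to agree with the sequential per-patch path to machine
  precision, and the sequential path in turn against an independently
  coded dense-embedding oracle.

## Known limitations

- 4 qubits, 2×2 kernels, stride 2, grayscale only; no density-matrix or
  shot-noise simulation — noise enters only through the analytical
  hardware-analysis module.
- The classical head is a deliberately small CNN; it is not a tuned
  architecture and the package makes no claim about state-of-the-art
  accuracy on real datasets.
- Reported cross-validation numbers are properties of the synthetic
  generator's conditions (150 images, 16×16, densities 0.0/0.15/0.4),
  not reproductions of published benchmark accuracies on external
  datasets.
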