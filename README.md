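# quanvnet

Hybrid quantum-classical image classification with a 4-qubit
*quanvolutional* feature extractor, for researchers studying how the
choice of two-qubit entangling gate (CNOT vs CZ) affects trainability,
stability, and hardware cost of small quantum machine-learning models —
exercised here on a synthetic fruit-quality grading task (fresh / mild /
rotten grayscale images).

## The model

A grayscale image `I ∈ [0,1]^{H×W}` (even dimensions) is tiled into
non-overlapping 2×2 patches. Each patch φ = (φ0..φ3) is angle-encoded on
4 qubits,

    |ψ_enc⟩ = ⊗_i H_i RY(π φ_i)_i |0000⟩ ,

then transformed by L ∈ {1..5} variational layers, each a per-qubit
rotation block RZ(θ_{l,i,2})·RY(θ_{l,i,1})·RX(θ_{l,i,0}) followed by
CNOT (variant v1) or CZ (variant v2) entanglers on a fixed pair
schedule. The readout ⟨Z_i⟩ of each qubit yields a 4-channel
(H/2 × W/2 × 4) feature map, which a small classical CNN (conv → ReLU →
max-pool → dense → softmax) classifies. Quantum angles and classical
weights are trained jointly: parameter-shift gradients
([f(θ+π/2) − f(θ−π/2)]/2, exact for Pauli rotations) for the quantum
side, backpropagation for the classical side, with adam / sgd / rmsprop
/ adamax optimizers. Everything is exact statevector simulation.

A companion hardware-analysis module quantifies why CZ is the
lighter-weight entangler on cross-resonance superconducting hardware:
its native synthesis needs 3 gates (1 ECR, 2 RZ) versus CNOT's 5
(1 ECR, 2 SX, 2 RZ) — a 40% reduction — and Z (dephasing) errors commute
through CZ but are spread by CNOT into correlated Z⊗Z errors, which the
module shows by computing the full 16-entry Pauli conjugation table.

## Worked example

Paired 5-fold cross-validation of both entangler variants on the default
synthetic dataset (150 images, 16×16, 3 classes; identical folds and
seeds for both gates, ~3 minutes on one CPU core):

```python
from quanvnet import (SyntheticImageSpec, generate_dataset, ClassifierConfig,
                      compare_entanglers)
from quanvnet.evaluation import report_to_table_row

images, labels = generate_dataset(SyntheticImageSpec(seed=0))
config = ClassifierConfig(optimizer="adam", epochs=40, seed=0)
reports = compare_entanglers(images, labels, config, n_layers=1, k=5, seed=0)
for name, report in reports.items():
    print(report_to_table_row(report))
```

prints

```
{'Model': 'NNQE_v1 (CNOT)', 'Train Acc.': 0.9767, 'Test Acc.': 0.82, 'Precision': 0.8208, 'Recall': 0.82, 'F1 Score': 0.8193, 'Mean CV Acc.': '0.8200 ± 0.0837', 'Confidence Interval (CI)': '(0.7363, 0.9037)'}
{'Model': 'NNQE_v2 (CZ)', 'Train Acc.': 0.9983, 'Test Acc.': 0.9, 'Precision': 0.8994, 'Recall': 0.9, 'F1 Score': 0.8993, 'Mean CV Acc.': '0.9000 ± 0.0333', 'Confidence Interval (CI)': '(0.8667, 0.9333)'}
```

Reading the rows: both variants learn the task far above the 1/3 chance
level; under this seed the CZ variant reaches higher held-out accuracy
(0.90 vs 0.82 mean cross-validation accuracy) with a smaller fold-to-fold
margin (±0.033 vs ±0.084, sample standard deviation across the five
folds), the confidence interval being literally mean ∓ margin. These
numbers characterize the synthetic generator's conditions, not any
external benchmark.

The same pipeline is available from the shell:

```bash
quanvnet generate-data --out data/ --seed 7
quanvnet compare-entanglers --data data/dataset.npz --out results/ --layers 1 --seed 7
quanvnet analyze-gates --out gate_report.json
```

`analyze-gates` emits the native-gate accounting (5 vs 3 gates, 40%
reduction), the empirical equivalence fidelity of each published
synthesis formula under the package's documented ECR convention, and the
full Pauli error-propagation table. See `docs/methods.md` for model
details, conventions, and known limitations.

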