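"""Exact dense statevector simulation of a 4-qubit register.

All circuit arithmetic in the package flows through this module: gate
matrices, a normalized 16-amplitude state, sparse (tensor-contraction)
application of 1- and 2-qubit gates, Pauli-Z expectations, and a dense
16x16 circuit-unitary builder used as a brute-force oracle.

Conventions (fixed project-wide):

* Qubit 0 is the leftmost tensor factor, i.e. the most significant bit of
  the basis-state index: ``index = b0*8 + b1*4 + b2*2 + b3``.
* ``RZ`` uses the symmetric-phase convention ``diag(exp(-i l/2), exp(i l/2))``.
* ``ECR`` (echoed cross-resonance, the native entangler of cross-resonance
  superconducting processors) is ``(X (x) I - Y (x) X)/sqrt(2)`` on
  (control, target).
* Unitary comparisons are made up to global phase via
  ``|trace(U^dagger V)| / dim``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ATOL_ALGEBRAIC",
    "ATOL_CIRCUIT",
    "N_QUBITS",
    "DIM",
    "GateMatrix",
    "QuantumState",
    "make_gate",
    "ground_state",
    "apply_1q",
    "apply_2q",
    "expect_z",
    "full_unitary",
    "phase_fidelity",
]

#: tolerance for algebraic identities on printed gate matrices
ATOL_ALGEBRAIC = 1e-10
#: tolerance for composed circuits (accumulation over many gates)
ATOL_CIRCUIT = 1e-9

N_QUBITS = 4
DIM = 2**N_QUBITS

_I2 = np.eye(2, dtype=complex)
_X = np.array([[0, 1], [1, 0]], dtype=complex)
_Y = np.array([[0, -1j], [1j, 0]], dtype=complex)
_Z = np.array([[1, 0], [0, -1]], dtype=complex)
_H = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
_SX = 0.5 * np.array([[1 + 1j, 1 - 1j], [1 - 1j, 1 + 1j]])
_CNOT = np.array(
    [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]], dtype=complex
)
_CZ = np.diag([1, 1, 1, -1]).astype(complex)
# echoed cross-resonance on (control, target)
_ECR = (np.kron(_X, _I2) - np.kron(_Y, _X)) / np.sqrt(2)

_FIXED_GATES = {
    "H": _H,
    "CNOT": _CNOT,
    "CZ": _CZ,
    "Z": _Z,
    "SX": _SX,
    "ECR": _ECR,
}
_ROTATION_GATES = ("RY", "RX", "RZ")


def _is_unitary(m: np.ndarray, atol: float = ATOL_ALGEBRAIC) -> bool:
    return bool(np.allclose(m.conj().T @ m, np.eye(m.shape[0]), atol=atol))


@dataclass(frozen=True)
class GateMatrix:
    """A labelled unitary matrix, 2x2 (single-qubit) or 4x4 (two-qubit)."""

    label: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.shape not in ((2, 2), (4, 4), (DIM, DIM)):
            raise ValueError(
                f"gate matrix must be 2x2, 4x4 or {DIM}x{DIM}, got {m.shape}"
            )
        atol = ATOL_ALGEBRAIC if m.shape[0] < DIM else ATOL_CIRCUIT
        if not _is_unitary(m, atol=atol):
            raise ValueError(f"gate {self.label!r} is not unitary")
        object.__setattr__(self, "matrix", m)
        self.matrix.setflags(write=False)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_qubits(self) -> int:
        return int(np.log2(self.dim))

    def to_dict(self) -> dict:
        """Plain-text/JSON-serializable dump (real and imaginary parts)."""
        return {
            "label": self.label,
            "dim": self.dim,
            "real": self.matrix.real.tolist(),
            "imag": self.matrix.imag.tolist(),
        }


def make_gate(name: str, angle: float | None = None) -> GateMatrix:
    """Build a named gate matrix.

    ``RY``/``RX``/``RZ`` require an ``angle`` in radians; the fixed gates
    (``H``, ``CNOT``, ``CZ``, ``Z``, ``SX``, ``ECR``) reject one.
    """
    if name in _ROTATION_GATES:
        if angle is None:
            raise ValueError(f"{name} requires an angle")
        if not np.isfinite(angle):
            raise ValueError(f"non-finite angle for {name}: {angle!r}")
        half = angle / 2.0
        c, s = np.cos(half), np.sin(half)
        if name == "RY":
            m = np.array([[c, -s], [s, c]], dtype=complex)
        elif name == "RX":
            m = np.array([[c, -1j * s], [-1j * s, c]])
        else:  # RZ, symmetric phases
            m = np.diag([np.exp(-1j * half), np.exp(1j * half)])
        return GateMatrix(f"{name}({angle:g})", m)
    if name in _FIXED_GATES:
        if angle is not None:
            raise ValueError(f"{name} is a fixed gate and takes no angle")
        return GateMatrix(name, _FIXED_GATES[name])
    raise ValueError(f"unknown gate name: {name!r}")


@dataclass(frozen=True)
class QuantumState:
    """Pure state of the 4-qubit register: 16 complex amplitudes.

    Index ``b0*8 + b1*4 + b2*2 + b3`` with qubit 0 the leftmost tensor
    factor. Normalization is enforced at construction.
    """

    amplitudes: np.ndarray = field()

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=complex).reshape(-1)
        if a.shape != (DIM,):
            raise ValueError(f"expected {DIM} amplitudes, got {a.shape}")
        nrm = np.linalg.norm(a)
        if abs(nrm - 1.0) > ATOL_CIRCUIT:
            raise ValueError(f"state is not normalized: |psi| = {nrm}")
        object.__setattr__(self, "amplitudes", a)
        self.amplitudes.setflags(write=False)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


def ground_state() -> QuantumState:
    """The 4-qubit ground state |0000>."""
    a = np.zeros(DIM, dtype=complex)
    a[0] = 1.0
    return QuantumState(a)


def _check_qubit(qubit: int) -> None:
    if not 0 <= qubit < N_QUBITS:
        raise ValueError(f"qubit index out of range: {qubit}")


def apply_1q(state: QuantumState, gate: GateMatrix, qubit: int) -> QuantumState:
    """Apply a single-qubit gate: (I x ... x U x ... x I) |psi>."""
    if gate.dim != 2:
        raise ValueError(f"apply_1q needs a 2x2 gate, got dim {gate.dim}")
    _check_qubit(qubit)
    psi = state.amplitudes.reshape((2,) * N_QUBITS)
    out = np.tensordot(gate.matrix, psi, axes=([1], [qubit]))
    out = np.moveaxis(out, 0, qubit)
    return QuantumState(out.reshape(DIM))


def apply_2q(
    state: QuantumState, gate: GateMatrix, qubit_a: int, qubit_b: int
) -> QuantumState:
    """Apply a two-qubit gate to the ordered pair (qubit_a, qubit_b).

    For CNOT, ``qubit_a`` is the control and ``qubit_b`` the target.
    """
    if gate.dim != 4:
        raise ValueError(f"apply_2q needs a 4x4 gate, got dim {gate.dim}")
    _check_qubit(qubit_a)
    _check_qubit(qubit_b)
    if qubit_a == qubit_b:
        raise ValueError("qubit_a and qubit_b must differ")
    psi = state.amplitudes.reshape((2,) * N_QUBITS)
    g = gate.matrix.reshape(2, 2, 2, 2)  # (out_a, out_b, in_a, in_b)
    out = np.tensordot(g, psi, axes=([2, 3], [qubit_a, qubit_b]))
    out = np.moveaxis(out, [0, 1], [qubit_a, qubit_b])
    return QuantumState(out.reshape(DIM))


def z_signs(qubit: int) -> np.ndarray:
    """The +/-1 diagonal of Z on `qubit` over all 16 basis states."""
    _check_qubit(qubit)
    idx = np.arange(DIM)
    bits = (idx >> (N_QUBITS - 1 - qubit)) & 1
    return 1.0 - 2.0 * bits


def expect_z(state: QuantumState, qubit: int) -> float:
    """<psi| Z_qubit |psi>, a real number in [-1, 1]."""
    p = np.abs(state.amplitudes) ** 2
    return float(np.dot(z_signs(qubit), p))


def _embed(gate: GateMatrix, qubits: tuple[int, ...]) -> np.ndarray:
    # Dense embedding by direct bit bookkeeping (deliberately independent of
    # the tensordot path used by apply_1q/apply_2q, so full_unitary can act
    # as a brute-force oracle for sequential application).
    nq = len(qubits)
    if gate.n_qubits != nq:
        raise ValueError(
            f"gate {gate.label!r} acts on {gate.n_qubits} qubits, got {nq} indices"
        )
    for q in qubits:
        _check_qubit(q)
    if nq == 2 and qubits[0] == qubits[1]:
        raise ValueError("qubit indices must differ")
    g = gate.matrix
    U = np.zeros((DIM, DIM), dtype=complex)
    for col in range(DIM):
        bits = [(col >> (N_QUBITS - 1 - q)) & 1 for q in range(N_QUBITS)]
        sub_in = 0
        for j, q in enumerate(qubits):
            sub_in = (sub_in << 1) | bits[q]
        for sub_out in range(g.shape[0]):
            amp = g[sub_out, sub_in]
            if amp == 0:
                continue
            new_bits = list(bits)
            for j, q in enumerate(qubits):
                new_bits[q] = (sub_out >> (nq - 1 - j)) & 1
            row = 0
            for b in new_bits:
                row = (row << 1) | b
            U[row, col] += amp
    return U


def full_unitary(
    ops: Sequence[tuple[GateMatrix, int | tuple[int, int]]]
) -> GateMatrix:
    """Dense 16x16 unitary of a gate sequence (first listed gate acts first).

    ``ops`` is a list of ``(gate, qubit)`` for single-qubit gates or
    ``(gate, (a, b))`` for two-qubit gates. The result is the matrix
    product with the first gate rightmost, so applying it to a state is
    equivalent to sequential application.
    """
    if len(ops) == 0:
        raise ValueError("empty gate sequence")
    U = np.eye(DIM, dtype=complex)
    labels = []
    for gate, q in ops:
        qubits = (q,) if isinstance(q, (int, np.integer)) else tuple(q)
        U = _embed(gate, qubits) @ U
        labels.append(gate.label)
    return GateMatrix("*".join(labels) or "circuit", U)


def phase_fidelity(u: np.ndarray, v: np.ndarray) -> float:
    """|trace(U^dagger V)| / dim: 1 iff U = V up to a global phase."""
    u = np.asarray(u, dtype=complex)
    v = np.asarray(v, dtype=complex)
    if u.shape != v.shape or u.ndim != 2 or u.shape[0] != u.shape[1]:
        raise ValueError("phase_fidelity needs two square matrices of equal shape")
    return float(abs(np.trace(u.conj().T @ v)) / u.shape[0])
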