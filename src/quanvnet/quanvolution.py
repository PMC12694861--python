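"""Quanvolutional feature extraction.

A grayscale image with even height and width is tiled into non-overlapping
2x2 patches. Each patch's four normalized intensities phi_i in [0, 1] are
angle-encoded on a 4-qubit register (RY(pi*phi_i) then Hadamard per qubit),
transformed by 1-5 variational entangling layers, and read out as the four
Pauli-Z expectations, which become the four channels of an (H/2, W/2, 4)
feature map. One set of trainable angles theta[l][i][k] is shared across
every patch of an image (convolution-style weight sharing).

Each layer l applies, per qubit i, RX(theta[l][i][0]) then RY(theta[l][i][1])
then RZ(theta[l][i][2]), followed by the layer's entangling gates (CNOT or
CZ) on a fixed pair schedule:

* layers 1 and 4: (0,1), (1,2), (2,3), (3,0)
* layers 2 and 5: (0,2), (1,3), (2,0), (3,1)
* layer 3:        (0,1), (2,3), (1,2), (3,0)

In each ordered pair the first index is the CNOT control. Note that for the
CZ entangler the layer-2/5 schedule collapses to the identity (CZ is
symmetric and self-inverse, so (0,2) cancels (2,0) and (1,3) cancels
(3,1)); the schedule is implemented literally as specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .quantum_core import (
    ATOL_CIRCUIT,
    DIM,
    N_QUBITS,
    GateMatrix,
    QuantumState,
    apply_1q,
    apply_2q,
    expect_z,
    full_unitary,
    ground_state,
    make_gate,
    z_signs,
)

__all__ = [
    "PatchVector",
    "VariationalParams",
    "FeatureMap",
    "MAX_LAYERS",
    "extract_patches",
    "encode",
    "entangler_pairs",
    "apply_layer",
    "quanvolve_patch",
    "quanvolve_phis",
    "quanvolve_image",
    "circuit_ops",
    "circuit_unitary",
    "save_feature_map",
    "load_feature_map",
]

MAX_LAYERS = 5

_PAIR_SCHEDULE = {
    1: ((0, 1), (1, 2), (2, 3), (3, 0)),
    2: ((0, 2), (1, 3), (2, 0), (3, 1)),
    3: ((0, 1), (2, 3), (1, 2), (3, 0)),
    4: ((0, 1), (1, 2), (2, 3), (3, 0)),
    5: ((0, 2), (1, 3), (2, 0), (3, 1)),
}

_PIXEL_ATOL = 1e-9


@dataclass(frozen=True)
class PatchVector:
    """One flattened 2x2 patch: phi = (I[j,k], I[j,k+1], I[j+1,k], I[j+1,k+1])."""

    phi: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float).reshape(-1)
        if phi.shape != (4,):
            raise ValueError(f"patch needs 4 intensities, got {phi.shape}")
        if np.any(phi < -_PIXEL_ATOL) or np.any(phi > 1 + _PIXEL_ATOL):
            raise ValueError(f"patch intensities outside [0, 1]: {phi}")
        j, k = self.origin
        if j < 0 or k < 0 or j % 2 or k % 2:
            raise ValueError(f"patch origin must be even and non-negative: {self.origin}")
        object.__setattr__(self, "phi", np.clip(phi, 0.0, 1.0))
        self.phi.setflags(write=False)


@dataclass(frozen=True)
class VariationalParams:
    """Trainable angles theta[l][i][k] (layer, qubit, axis X/Y/Z) + entangler kind."""

    theta: np.ndarray
    entangler: str = "CZ"

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.ndim != 3 or th.shape[1:] != (N_QUBITS, 3):
            raise ValueError(
                f"theta must have shape (L, {N_QUBITS}, 3), got {th.shape}"
            )
        if not 1 <= th.shape[0] <= MAX_LAYERS:
            raise ValueError(
                f"layer count must be 1..{MAX_LAYERS}, got {th.shape[0]}"
            )
        if not np.all(np.isfinite(th)):
            raise ValueError("non-finite angle in theta")
        if self.entangler not in ("CNOT", "CZ"):
            raise ValueError(f"entangler must be 'CNOT' or 'CZ', got {self.entangler!r}")
        object.__setattr__(self, "theta", th)
        self.theta.setflags(write=False)

    @property
    def n_layers(self) -> int:
        return int(self.theta.shape[0])

    def with_theta(self, theta: np.ndarray) -> "VariationalParams":
        return VariationalParams(theta, self.entangler)


@dataclass(frozen=True)
class FeatureMap:
    """(H/2, W/2, 4) array of per-qubit <Z> expectations, entries in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != N_QUBITS:
            raise ValueError(f"feature map must be (H/2, W/2, 4), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature value")
        if np.any(np.abs(v) > 1 + ATOL_CIRCUIT):
            raise ValueError("feature value outside [-1, 1]")
        object.__setattr__(self, "values", v)
        self.values.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got ndim={img.ndim}")
    h, w = img.shape
    if h % 2 or w % 2 or h == 0 or w == 0:
        raise ValueError(f"image height and width must be even and positive, got {img.shape}")
    if np.any(img < -_PIXEL_ATOL) or np.any(img > 1 + _PIXEL_ATOL):
        bad = img[(img < -_PIXEL_ATOL) | (img > 1 + _PIXEL_ATOL)]
        raise ValueError(
            f"pixel values outside [0, 1] (e.g. {bad.flat[0]}); "
            "normalize explicitly before extraction"
        )
    return np.clip(img, 0.0, 1.0)


def image_to_phis(image: np.ndarray) -> np.ndarray:
    """All 2x2 patches of an image as an ((H/2)*(W/2), 4) array, row-major."""
    img = _check_image(image)
    h, w = img.shape
    tiles = img.reshape(h // 2, 2, w // 2, 2).transpose(0, 2, 1, 3)
    return tiles.reshape(-1, 4)


def extract_patches(image: np.ndarray) -> list[PatchVector]:
    """Tile an image into non-overlapping 2x2 patches in row-major order."""
    img = _check_image(image)
    h, w = img.shape
    phis = image_to_phis(img)
    out = []
    idx = 0
    for j in range(0, h, 2):
        for k in range(0, w, 2):
            out.append(PatchVector(phis[idx], (j, k)))
            idx += 1
    return out


def encode(patch: PatchVector) -> QuantumState:
    """Angle-encode a patch: per qubit i, RY(pi*phi_i) then H, from |0000>."""
    state = ground_state()
    h = make_gate("H")
    for i in range(N_QUBITS):
        state = apply_1q(state, make_gate("RY", np.pi * patch.phi[i]), i)
        state = apply_1q(state, h, i)
    return state


def entangler_pairs(l: int) -> list[tuple[int, int]]:
    """The ordered entangling-pair schedule for layer ``l`` (1-based)."""
    if l not in _PAIR_SCHEDULE:
        raise ValueError(f"layer index must be 1..{MAX_LAYERS}, got {l}")
    return list(_PAIR_SCHEDULE[l])


def apply_layer(state: QuantumState, params: VariationalParams, l: int) -> QuantumState:
    """One variational layer: RX, RY, RZ per qubit, then the entangler pairs."""
    if not 1 <= l <= params.n_layers:
        raise ValueError(f"layer index {l} beyond configured depth {params.n_layers}")
    th = params.theta[l - 1]
    for i in range(N_QUBITS):
        state = apply_1q(state, make_gate("RX", th[i, 0]), i)
        state = apply_1q(state, make_gate("RY", th[i, 1]), i)
        state = apply_1q(state, make_gate("RZ", th[i, 2]), i)
    ent = params.entangler
    gate = make_gate(ent)
    for a, b in entangler_pairs(l):
        state = apply_2q(state, gate, a, b)
    return state


def circuit_ops(params: VariationalParams) -> list[tuple[GateMatrix, object]]:
    """The full variational circuit as an ordered (gate, qubits) op list."""
    ops: list[tuple[GateMatrix, object]] = []
    for l in range(1, params.n_layers + 1):
        th = params.theta[l - 1]
        for i in range(N_QUBITS):
            ops.append((make_gate("RX", th[i, 0]), i))
            ops.append((make_gate("RY", th[i, 1]), i))
            ops.append((make_gate("RZ", th[i, 2]), i))
        gate = make_gate(params.entangler)
        for pair in entangler_pairs(l):
            ops.append((gate, pair))
    return ops


def circuit_unitary(params: VariationalParams) -> np.ndarray:
    """Dense 16x16 unitary of all variational layers (encoding excluded)."""
    return full_unitary(circuit_ops(params)).matrix


def quanvolve_patch(patch: PatchVector, params: VariationalParams) -> np.ndarray:
    """Feature vector (<Z_0>, <Z_1>, <Z_2>, <Z_3>) for one patch."""
    state = encode(patch)
    for l in range(1, params.n_layers + 1):
        state = apply_layer(state, params, l)
    return np.array([expect_z(state, i) for i in range(N_QUBITS)])


def _encoded_batch(phis: np.ndarray) -> np.ndarray:
    # |psi_enc> is a product state; build all N amplitude vectors at once.
    # Per qubit: H * RY(pi*x) |0> = ((c+s)/sqrt2, (c-s)/sqrt2), c=cos(pi x/2).
    half = 0.5 * np.pi * phis  # (N, 4)
    c, s = np.cos(half), np.sin(half)
    v = np.stack([(c + s), (c - s)], axis=-1) / np.sqrt(2.0)  # (N, 4, 2)
    out = np.einsum("na,nb,nc,nd->nabcd", v[:, 0], v[:, 1], v[:, 2], v[:, 3])
    return out.reshape(-1, DIM).astype(complex)


def quanvolve_phis(phis: np.ndarray, params: VariationalParams) -> np.ndarray:
    """Vectorized quanvolution of an (N, 4) batch of patch vectors -> (N, 4)."""
    phis = np.asarray(phis, dtype=float)
    if phis.ndim != 2 or phis.shape[1] != 4:
        raise ValueError(f"phis must be (N, 4), got {phis.shape}")
    if np.any(phis < -_PIXEL_ATOL) or np.any(phis > 1 + _PIXEL_ATOL):
        raise ValueError("patch intensities outside [0, 1]")
    states = _encoded_batch(np.clip(phis, 0.0, 1.0))
    final = states @ circuit_unitary(params).T
    probs = np.abs(final) ** 2
    signs = np.stack([z_signs(i) for i in range(N_QUBITS)], axis=1)  # (16, 4)
    return probs @ signs


def quanvolve_image(image: np.ndarray, params: VariationalParams) -> FeatureMap:
    """Quanvolve every 2x2 patch of an image into an (H/2, W/2, 4) feature map."""
    img = _check_image(image)
    h, w = img.shape
    feats = quanvolve_phis(image_to_phis(img), params)
    return FeatureMap(feats.reshape(h // 2, w // 2, N_QUBITS))


def save_feature_map(path: str | Path, fmap: FeatureMap, params: VariationalParams) -> None:
    """Write a feature map plus the generating parameters to NPZ."""
    np.savez(
        path,
        features=fmap.values,
        entangler=np.array(params.entangler),
        n_layers=np.array(params.n_layers),
        theta=params.theta,
    )


def load_feature_map(path: str | Path) -> tuple[FeatureMap, VariationalParams]:
    with np.load(path, allow_pickle=False) as data:
        fmap = FeatureMap(data["features"])
        params = VariationalParams(data["theta"], str(data["entangler"]))
    return fmap, params
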