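"""Pairwise attention coefficients and their two consuming branches.

A graph-attention layer assigns every evaluated residue pair ``(i, j)`` a
single raw coefficient ``e_ij`` which is shared by two branches:

* the *unsupervised* branch passes ``e_ij`` through LeakyReLU and a softmax
  over the closed neighbourhood ``N_i ∪ {i}``, yielding the aggregation
  weights ``α_ij`` (standard GAT);
* the *supervised* branch maps the same ``e_ij`` through a logistic sigmoid
  to a score ``φ_ij ∈ (0, 1)`` that is trained, with binary cross-entropy
  against edge existence, to predict whether residues i and j are in
  contact.

Four strategies generate ``e_ij`` from the node features:

========  =======================================================
AD        additive: ``aᵀ [W h_i ‖ W h_j]``
DP        dot-product: ``(W_s h_i)ᵀ (W_s h_j)``
SD        scaled dot-product: ``e_DP / F``
MX        mixed: ``e_AD · σ(e_DP)`` (the DP term gates the AD term)
========  =======================================================

``W`` is the rectangular aggregation weight (F^l × F^{l+1}) also used in
message passing; the dot-product strategies use their own square weight
``W_s`` (F^l × F^l), an independent learnable parameter. AD is asymmetric
in (i, j) because of the concatenation order, so an undirected contact is
evaluated in both orders by the supervised branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_io import ConfigurationError, ShapeMismatchError

STRATEGIES = ("AD", "DP", "SD", "MX")

#: LeakyReLU negative slope in the unsupervised branch (GAT-standard).
LEAKY_RELU_SLOPE = 0.01


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic sigmoid."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def leaky_relu(x: np.ndarray, slope: float = LEAKY_RELU_SLOPE) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float = LEAKY_RELU_SLOPE) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


@dataclass
class LayerParams:
    """Learnable parameters of one graph-attention layer.

    ``W`` (in_dim × out_dim) is shared between message aggregation and the
    AD coefficient; ``a`` (length 2·out_dim) is the shared attention
    operation; ``Ws`` (in_dim × in_dim) is the square weight of the
    dot-product strategies (required for DP/SD/MX, ignored for AD).
    """

    W: np.ndarray
    a: np.ndarray
    strategy: str = "MX"
    Ws: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        self.W = np.asarray(self.W, dtype=np.float64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if self.W.ndim != 2:
            raise ShapeMismatchError("W must be 2-D")
        if self.a.shape != (2 * self.W.shape[1],):
            raise ShapeMismatchError(
                f"a must have length {2 * self.W.shape[1]}, got {self.a.shape}"
            )
        if self.strategy in ("DP", "SD", "MX"):
            if self.Ws is None:
                raise ConfigurationError(
                    f"strategy {self.strategy} requires the square weight Ws"
                )
            self.Ws = np.asarray(self.Ws, dtype=np.float64)
            if self.Ws.shape != (self.W.shape[0], self.W.shape[0]):
                raise ShapeMismatchError(
                    f"Ws must be square {self.W.shape[0]}×{self.W.shape[0]}, "
                    f"got {self.Ws.shape}"
                )

    @property
    def in_dim(self) -> int:
        return self.W.shape[0]

    @property
    def out_dim(self) -> int:
        return self.W.shape[1]


@dataclass
class AttentionState:
    """Per-layer attention quantities kept for the loss and for inspection.

    ``coefficients`` is the dense ``(Np, Np)`` matrix of raw e_ij for every
    ordered pair; ``unsupervised_weights`` holds α_ij on the closed
    neighbourhood mask (zero elsewhere, each row summing to 1 over the
    mask); ``supervised_scores`` is σ(e) elementwise.
    """

    coefficients: np.ndarray
    unsupervised_weights: np.ndarray
    neighborhood_mask: np.ndarray

    @property
    def supervised_scores(self) -> np.ndarray:
        return sigmoid(self.coefficients)

    def scores_at(self, pairs: np.ndarray) -> np.ndarray:
        """φ_ij for an (n, 2) array of ordered index pairs."""
        pairs = np.asarray(pairs, dtype=np.intp)
        return sigmoid(self.coefficients[pairs[:, 0], pairs[:, 1]])


# ---------------------------------------------------------------------------
# Pairwise coefficients, single-pair form (reference semantics)
# ---------------------------------------------------------------------------


def _check_pair(h_i: np.ndarray, h_j: np.ndarray, params: LayerParams) -> tuple[np.ndarray, np.ndarray]:
    h_i = np.asarray(h_i, dtype=np.float64).ravel()
    h_j = np.asarray(h_j, dtype=np.float64).ravel()
    if h_i.shape != (params.in_dim,) or h_j.shape != (params.in_dim,):
        raise ShapeMismatchError(
            f"node features must have {params.in_dim} entries, "
            f"got {h_i.shape} and {h_j.shape}"
        )
    return h_i, h_j


def coeff_AD(h_i: np.ndarray, h_j: np.ndarray, params: LayerParams) -> float:
    """Additive coefficient ``aᵀ [W h_i ‖ W h_j]`` (no activation)."""
    h_i, h_j = _check_pair(h_i, h_j, params)
    z = np.concatenate([params.W.T @ h_i, params.W.T @ h_j])
    return float(params.a @ z)


def coeff_DP(h_i: np.ndarray, h_j: np.ndarray, params: LayerParams) -> float:
    """Dot-product coefficient ``(W_s h_i)ᵀ (W_s h_j)``.

    Row-vector convention throughout the package: the projection is
    ``h W_s`` (equivalently ``W_sᵀ h`` on column vectors), matching how
    the aggregation weight is applied.
    """
    h_i, h_j = _check_pair(h_i, h_j, params)
    if params.Ws is None:
        raise ConfigurationError("DP coefficient requires the square weight Ws")
    return float((params.Ws.T @ h_i) @ (params.Ws.T @ h_j))


def coeff_SD(h_i: np.ndarray, h_j: np.ndarray, params: LayerParams, F: int | None = None) -> float:
    """Scaled dot-product ``e_DP / F``; F defaults to the projection dim."""
    if F is None:
        F = params.in_dim
    if F <= 0:
        raise ConfigurationError(f"scaling dimension F must be positive, got {F}")
    return coeff_DP(h_i, h_j, params) / F


def coeff_MX(h_i: np.ndarray, h_j: np.ndarray, params: LayerParams) -> float:
    """Mixed coefficient ``e_AD · σ(e_DP)``: DP soft-gates the AD score."""
    if params.Ws is None:
        raise ConfigurationError("MX coefficient requires both AD and DP parameter sets")
    return coeff_AD(h_i, h_j, params) * float(sigmoid(coeff_DP(h_i, h_j, params)))


def pair_coefficient(h_i: np.ndarray, h_j: np.ndarray, params: LayerParams) -> float:
    """Dispatch on ``params.strategy``."""
    if params.strategy == "AD":
        return coeff_AD(h_i, h_j, params)
    if params.strategy == "DP":
        return coeff_DP(h_i, h_j, params)
    if params.strategy == "SD":
        return coeff_SD(h_i, h_j, params)
    return coeff_MX(h_i, h_j, params)


# ---------------------------------------------------------------------------
# Dense whole-graph coefficient computation (used by the model)
# ---------------------------------------------------------------------------


def coefficient_matrix(X: np.ndarray, params: LayerParams) -> tuple[np.ndarray, dict]:
    """All-pairs coefficient matrix ``E[i, j] = e_ij`` plus backprop cache.

    Vectorised over ordered pairs: for AD, ``e_ij = u_i + v_j`` with
    ``u = Z a₁``, ``v = Z a₂`` and ``Z = X W``; for DP, ``E = Z_s Z_sᵀ``
    with ``Z_s = X W_s``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != params.in_dim:
        raise ShapeMismatchError(f"features have {X.shape[1]} columns, expected {params.in_dim}")
    cache: dict = {"X": X}
    Z = X @ params.W
    cache["Z"] = Z
    strategy = params.strategy
    if strategy in ("AD", "MX"):
        a1, a2 = params.a[: params.out_dim], params.a[params.out_dim :]
        u, v = Z @ a1, Z @ a2
        E_AD = u[:, None] + v[None, :]
        cache.update(u=u, v=v, E_AD=E_AD)
    if strategy in ("DP", "SD", "MX"):
        Zs = X @ params.Ws
        S = Zs @ Zs.T
        cache.update(Zs=Zs, S=S)
    if strategy == "AD":
        E = E_AD
    elif strategy == "DP":
        E = S
    elif strategy == "SD":
        E = S / params.in_dim
    else:  # MX
        gate = sigmoid(S)
        E = E_AD * gate
        cache["gate"] = gate
    cache["E"] = E
    return E, cache


def coefficient_matrix_backward(dE: np.ndarray, params: LayerParams, cache: dict) -> dict:
    """Backprop through :func:`coefficient_matrix`.

    Returns gradients ``{"X", "W", "a", "Ws"}`` (Ws only when used).
    """
    X, Z = cache["X"], cache["Z"]
    strategy = params.strategy
    dX = np.zeros_like(X)
    dW = np.zeros_like(params.W)
    da = np.zeros_like(params.a)
    grads: dict = {}

    dE_AD = None
    dS = None
    if strategy == "AD":
        dE_AD = dE
    elif strategy == "DP":
        dS = dE
    elif strategy == "SD":
        dS = dE / params.in_dim
    else:  # MX: E = E_AD * sigmoid(S)
        gate = cache["gate"]
        dE_AD = dE * gate
        dS = dE * cache["E_AD"] * gate * (1.0 - gate)

    if dE_AD is not None:
        a1, a2 = params.a[: params.out_dim], params.a[params.out_dim :]
        du = dE_AD.sum(axis=1)
        dv = dE_AD.sum(axis=0)
        da[: params.out_dim] = Z.T @ du
        da[params.out_dim :] = Z.T @ dv
        dZ = np.outer(du, a1) + np.outer(dv, a2)
        dW += X.T @ dZ
        dX += dZ @ params.W.T
    if dS is not None:
        Zs = cache["Zs"]
        dZs = (dS + dS.T) @ Zs
        grads["Ws"] = X.T @ dZs
        dX += dZs @ params.Ws.T
    grads.update(X=dX, W=dW, a=da)
    return grads


# ---------------------------------------------------------------------------
# The two branches
# ---------------------------------------------------------------------------


def unsupervised_weights(e: np.ndarray, slope: float = LEAKY_RELU_SLOPE) -> np.ndarray:
    """Softmax over LeakyReLU-activated coefficients of one closed neighbourhood.

    ``e`` holds the coefficients e_ik for k ranging over ``N_i ∪ {i}`` (the
    node itself is always a member, so the neighbourhood is never empty).
    """
    e = np.asarray(e, dtype=np.float64)
    act = leaky_relu(e, slope)
    act = act - act.max()
    w = np.exp(act)
    return w / w.sum()


def masked_attention_weights(
    E: np.ndarray, mask: np.ndarray, slope: float = LEAKY_RELU_SLOPE
) -> np.ndarray:
    """Row-wise masked softmax of LeakyReLU(E) over closed neighbourhoods.

    ``mask`` is the boolean (Np, Np) closed-neighbourhood indicator
    (adjacency plus the diagonal). Entries outside the mask are zero; every
    row sums to 1 over its mask.
    """
    act = leaky_relu(E, slope)
    act = np.where(mask, act, -np.inf)
    act = act - act.max(axis=1, keepdims=True)
    w = np.exp(act)
    return w / w.sum(axis=1, keepdims=True)


def supervised_scores(e: np.ndarray) -> np.ndarray:
    """σ(e) elementwise: the edge-existence probability of each pair."""
    return sigmoid(np.asarray(e, dtype=np.float64))
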