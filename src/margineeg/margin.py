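"""Margin-optimized (SVM-enhanced) attention.

Standard scaled dot-product attention scores key positions purely by
similarity to a query.  The layer implemented here instead scores positions
with a linear decision function score_j = A . phi(x_j) + b whose parameters
(A, b) are trained under a soft-margin SVM objective, written as the
differentiable hinge surrogate

    L_SVM = 1/2 ||A||^2 + C * sum_i max(0, 1 - y_i (A . phi(x_i) + b)),

so the attention weights are pushed to emphasize feature directions that
separate the two classes (labels y in {-1, +1}) with a maximal margin.  The
surrogate is exactly the primal soft-margin SVM objective with the slack
variables xi_i eliminated (xi_i = max(0, 1 - margin_i) at the optimum), so
minimizing it by gradient descent inside the network replaces an external
quadratic-programming solve.

Labels enter only through this auxiliary loss, evaluated on the
attention-pooled feature of each trial; the forward scoring path is
label-free and therefore usable at test time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import nn

__all__ = [
    "AttentionInputs", "MarginAttentionParams", "HingeInstance", "HingeLossResult",
    "softmax_attention", "hinge_objective", "hinge_gradient", "fit_hinge",
    "margin_scores", "margin_attention_forward", "total_loss",
    "MarginAttentionLayer",
]


# --------------------------------------------------------------------- types

@dataclass
class AttentionInputs:
    Q: np.ndarray  # (n_q, d_k)
    K: np.ndarray  # (n, d_k)
    V: np.ndarray  # (n, d_v)

    def __post_init__(self):
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.K = np.atleast_2d(np.asarray(self.K, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if self.Q.shape[1] != self.K.shape[1]:
            raise ValueError("queries and keys must share the key dimension")
        if self.K.shape[0] != self.V.shape[0]:
            raise ValueError("keys and values must have equal first dimension")
        if self.d_k == 0:
            raise ValueError("key dimension must be positive")

    @property
    def d_k(self) -> int:
        return self.K.shape[1]


@dataclass
class MarginAttentionParams:
    """Attention weight vector A, bias b, and the SVM trade-off constants."""

    A: np.ndarray
    b: float = 0.0
    C: float = 1.0
    lambda_aux: float = 0.1

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float).reshape(-1)
        if self.C <= 0:
            raise ValueError("regularization C must be positive")
        if self.lambda_aux < 0:
            raise ValueError("lambda_aux must be non-negative")


@dataclass
class HingeInstance:
    phi: np.ndarray  # (n, d_phi) feature representations
    y: np.ndarray    # (n,) labels in {-1, +1}

    def __post_init__(self):
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.y = np.asarray(self.y).reshape(-1)
        if len(self.y) != self.phi.shape[0]:
            raise ValueError("labels and features must have equal length")
        if len(self.y) < 1:
            raise ValueError("need at least one sample")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be -1 or +1")
        self.y = self.y.astype(float)


@dataclass
class HingeLossResult:
    loss: float
    margins: np.ndarray       # y_i (A . phi_i + b)
    hinge_terms: np.ndarray   # max(0, 1 - margin_i) = slack surrogates xi_i


# ----------------------------------------------------------- functional ops

def softmax_attention(inp: AttentionInputs) -> tuple[np.ndarray, np.ndarray]:
    """Attention(Q,K,V) = softmax(Q K^T / sqrt(d_k)) V."""
    logits = inp.Q @ inp.K.T / np.sqrt(inp.d_k)
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    weights = e / e.sum(axis=-1, keepdims=True)
    return weights, weights @ inp.V


def hinge_objective(params: MarginAttentionParams, inst: HingeInstance) -> HingeLossResult:
    """Exact evaluation of L_SVM = 1/2||A||^2 + C sum_i max(0, 1 - margin_i)."""
    if params.A.shape[0] != inst.phi.shape[1]:
        raise ValueError("A and phi dimensions do not match")
    margins = inst.y * (inst.phi @ params.A + params.b)
    hinge = np.maximum(0.0, 1.0 - margins)
    loss = 0.5 * float(params.A @ params.A) + params.C * float(hinge.sum())
    return HingeLossResult(loss=loss, margins=margins, hinge_terms=hinge)


def hinge_gradient(params: MarginAttentionParams,
                   inst: HingeInstance) -> tuple[np.ndarray, float]:
    """Analytic (sub)gradient of the hinge surrogate w.r.t. (A, b).

    At the kink (margin exactly 1) the subgradient 0 is chosen, matching the
    autodiff convention for max(0, .).
    """
    res = hinge_objective(params, inst)
    active = res.margins < 1.0  # strict: zero subgradient at the kink
    gA = params.A - params.C * (inst.y[active] @ inst.phi[active])
    gb = -params.C * float(inst.y[active].sum())
    return gA, gb


def fit_hinge(inst: HingeInstance, C: float = 1.0,
              init: tuple[np.ndarray, float] | None = None,
              max_iter: int = 2000) -> tuple[MarginAttentionParams, HingeLossResult]:
    """Minimize the hinge surrogate over (A, b) with analytic gradients.

    The objective is convex and piecewise quadratic; L-BFGS-B on the analytic
    subgradient reliably reaches the optimum for the low-dimensional feature
    spaces the attention layer uses.
    """
    d = inst.phi.shape[1]
    if init is None:
        x = np.zeros(d + 1)
    else:
        x = np.concatenate([np.asarray(init[0], dtype=float).reshape(-1),
                            [float(init[1])]])

    def make_fun(eps: float):
        # quadratically smoothed hinge: C^1, coincides with the hinge outside
        # an eps-neighbourhood of the kink; error of the minimum is O(C n eps)
        def fun(z):
            A, b = z[:d], z[d]
            m = inst.y * (inst.phi @ A + b)
            u = 1.0 - m
            h = np.where(u <= 0, 0.0,
                         np.where(u >= eps, u - eps / 2.0, u ** 2 / (2 * eps)))
            dh = np.where(u <= 0, 0.0, np.where(u >= eps, 1.0, u / eps))
            loss = 0.5 * A @ A + C * h.sum()
            coeff = C * dh * inst.y
            gA = A - coeff @ inst.phi
            gb = -coeff.sum()
            return loss, np.concatenate([gA, [gb]])
        return fun

    def solve(x0):
        z = x0
        for eps in (1e-1, 1e-2, 1e-3, 1e-4, 1e-6, 1e-8, 1e-10):
            sol = optimize.minimize(make_fun(eps), z, jac=True,
                                    method="L-BFGS-B",
                                    options={"maxiter": max_iter,
                                             "maxcor": 30,
                                             "ftol": 1e-16, "gtol": 1e-14})
            z = sol.x
        return z

    # smoothing continuation with warm starts; a couple of perturbed restarts
    # guard against premature L-BFGS termination near the kinks
    rng = np.random.default_rng(0)
    candidates = [solve(x)]
    for _ in range(2):
        candidates.append(solve(candidates[0] + rng.normal(0, 0.05, size=d + 1)))
    vals = [hinge_objective(
        MarginAttentionParams(A=z[:d], b=float(z[d]), C=C), inst).loss
        for z in candidates]
    x = candidates[int(np.argmin(vals))]
    params = MarginAttentionParams(A=x[:d], b=float(x[d]), C=C)
    return params, hinge_objective(params, inst)


def margin_scores(params: MarginAttentionParams, phi: np.ndarray) -> np.ndarray:
    """Label-free scores A . phi_j + b over key positions."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if params.A.shape[0] != phi.shape[1]:
        raise ValueError("A and phi dimensions do not match")
    return phi @ params.A + params.b


def _normalize_scores(scores: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "softmax":
        e = np.exp(scores - scores.max())
        return e / e.sum()
    if normalization == "clip":
        clipped = np.maximum(scores, 0.0)
        total = clipped.sum()
        if total <= 0:  # all scores non-positive: fall back to uniform
            return np.full_like(scores, 1.0 / len(scores))
        return clipped / total
    raise ValueError("normalization must be 'softmax' or 'clip'")


def margin_attention_forward(inp: AttentionInputs, params: MarginAttentionParams,
                             label: int | None = None,
                             normalization: str = "softmax"
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Margin-scored attention over one trial's key positions.

    phi is taken to be the key representations.  Returns (weights over the n
    key positions, pooled context = weights . V, auxiliary hinge loss).  In
    inference mode (label None) the auxiliary loss is exactly 0; in training
    mode the trial label is broadcast to the attention-pooled feature and the
    hinge surrogate is evaluated there.
    """
    scores = margin_scores(params, inp.K)
    weights = _normalize_scores(scores, normalization)
    context = weights @ inp.V
    if label is None:
        return weights, context, 0.0
    if label not in (-1, 1):
        raise ValueError("label must be -1 or +1")
    pooled_phi = weights @ inp.K
    res = hinge_objective(params, HingeInstance(phi=pooled_phi[None, :],
                                                y=np.array([label])))
    return weights, context, res.loss


def total_loss(ce_loss: float, aux_loss: float, lambda_aux: float) -> float:
    """Combined objective: cross-entropy + lambda * margin surrogate."""
    if lambda_aux < 0:
        raise ValueError("lambda_aux must be non-negative")
    return ce_loss + lambda_aux * aux_loss


# ------------------------------------------------------------ network layer

class MarginAttentionLayer(nn.Module):
    """Drop-in attention pooling over a hidden-state sequence (batch, T, d).

    phi_j = W_phi h_j is the feature representation of key position j;
    score_j = A . phi_j + b; weights = softmax over positions (per head);
    the pooled context is the weight-averaged value sequence (values are the
    hidden states themselves).  In 'svm_margin' mode with labels supplied,
    the layer also returns the hinge surrogate evaluated on the pooled
    features, averaged over trials (and heads) so the auxiliary loss is
    batch-size stable.  In 'softmax' mode the same architecture runs with the
    auxiliary loss fixed at zero - a standard learned-score attention.
    """

    def __init__(self, d_model: int, d_phi: int, rng: np.random.Generator,
                 C: float = 1.0, n_heads: int = 1, mode: str = "svm_margin",
                 share_heads: bool = False):
        super().__init__()
        if mode not in ("svm_margin", "softmax"):
            raise ValueError("mode must be 'svm_margin' or 'softmax'")
        self.mode = mode
        self.C = C
        self.n_heads = n_heads
        self.share_heads = share_heads
        n_A = 1 if share_heads else n_heads
        self.w_phi = nn.Linear(d_model, d_phi, rng)
        self.A = nn.Tensor(rng.normal(0.0, 0.1, size=(d_phi, n_A)),
                           requires_grad=True)
        self.b = nn.Tensor(np.zeros(n_A), requires_grad=True)

    def __call__(self, hs: nn.Tensor, labels: np.ndarray | None = None):
        B, T, d = hs.shape
        phi = self.w_phi(hs)                      # (B, T, d_phi)
        scores = phi @ self.A + self.b            # (B, T, nH)
        w = scores.softmax(axis=1)                # weights over key positions
        wt = w.transpose(0, 2, 1)                 # (B, nH, T)
        ctx = (wt @ hs).mean(axis=1)              # head-averaged (B, d)
        weights = nn.Tensor(w.data.mean(axis=-1)) # (B, T) for inspection
        if self.mode == "svm_margin" and labels is not None:
            labels = np.asarray(labels, dtype=float).reshape(-1)
            if len(labels) != B:
                raise ValueError("labels length must match the batch size")
            if not np.all(np.isin(labels, (-1.0, 1.0))):
                raise ValueError("labels must be -1 or +1")
            pooled_phi = wt @ phi                 # (B, nH, d_phi)
            a_t = self.A.transpose(1, 0)          # (nH|1, d_phi)
            m = (pooled_phi * a_t).sum(axis=-1) + self.b   # (B, nH)
            y = nn.Tensor(labels[:, None])
            hinge = (1.0 - y * m).relu()
            aux = 0.5 * (self.A * self.A).sum() + self.C * hinge.mean()
        else:
            aux = nn.Tensor(0.0)
        return ctx, weights, aux
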