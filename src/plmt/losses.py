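"""Loss terms for the three-stage semi-supervised pipeline.

Stage A (mean teacher) optimizes

    L_total^A = L_sup^A + lambda_A * lambda_d(t) * L_con^A

and Stage C (pseudo-label mean teacher) optimizes

    L_total^C = L_sup^C + lambda_C * lambda_d(t) * (alpha*K*L_con^C + beta*L_pse^C)

where L_sup is pixel cross-entropy on labeled slices, L_con is the
mean-squared error between student and teacher probability maps on the
unlabeled stream, L_pse is cross-entropy against the fixed Stage-B pseudo
labels, lambda_d(t) = exp(-5 (1 - t/t_max)^2) is the Gaussian warm-up, and
(alpha, beta) are trainable convex weights derived from a single
unconstrained scalar z via the logistic function, so alpha + beta = 1
holds exactly for every finite z. The temperature K rescales the
consistency term to the magnitude of the pseudo-label term so the adaptive
weights do not collapse onto the smaller loss.

All functions accept either plain NumPy arrays or autodiff ``Tensor``s;
training passes Tensors so gradients flow, tests may pass arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor
from .backbone import ConfigurationError, InputError

CE_EPS = 1e-8  # clamp inside the logarithm; one-hot targets stay finite


def _scalar(x) -> float:
    return float(x.item()) if isinstance(x, Tensor) else float(x)


@dataclass
class LossWeights:
    """Trade-off weights of the semi-supervised losses.

    ``z`` is the single unconstrained trainable scalar behind the adaptive
    pair (alpha, beta); it is optimized jointly with the network weights
    on the Stage-C total and excluded from weight decay.
    """

    lambda_a: float = 0.1
    lambda_c: float = 0.1
    K: float = 1000.0
    z: Tensor = field(default_factory=lambda: Tensor(0.0, requires_grad=True))

    def __post_init__(self):
        if self.lambda_a < 0 or self.lambda_c < 0 or self.K < 0:
            raise ConfigurationError("lambda_a, lambda_c and K must be non-negative")
        if not isinstance(self.z, Tensor):
            self.z = Tensor(float(self.z), requires_grad=True)


@dataclass
class LossBreakdown:
    """One logged snapshot of the loss composition at an iteration."""

    sup: float
    con: float | None
    pse: float | None
    ramp: float
    alpha: float | None
    beta: float | None
    total: object  # Tensor during training, float in summaries

    @property
    def total_value(self) -> float:
        return _scalar(self.total)

    LOG_FIELDS = ("iteration", "sup", "con", "pse", "ramp", "alpha", "beta", "total")

    def log_line(self, iteration: int) -> str:
        vals = [iteration, self.sup, self.con, self.pse, self.ramp,
                self.alpha, self.beta, self.total_value]
        return "\t".join("" if v is None else
                         (str(v) if isinstance(v, int) else f"{v:.8g}")
                         for v in vals)

    @staticmethod
    def log_header() -> str:
        return "\t".join(LossBreakdown.LOG_FIELDS)


def cross_entropy(probs, target) -> Tensor:
    """Mean pixel cross-entropy of predicted probabilities vs. an integer mask."""
    probs = as_tensor(probs)
    target = np.asarray(target)
    if not np.issubdtype(target.dtype, np.integer):
        raise InputError("target mask must be integer-valued")
    if probs.ndim != 4 or target.shape != (probs.shape[0],) + probs.shape[2:]:
        raise InputError(
            f"probs {probs.shape} and target {target.shape} are incompatible")
    c = probs.shape[1]
    if target.min() < 0 or target.max() >= c:
        raise InputError(f"target classes must lie in [0, {c})")
    picked = probs.gather_channel(target)
    return -((picked + CE_EPS).log().mean())


def mse_loss(p_student, p_teacher) -> Tensor:
    """Mean squared difference over batch, class and pixel axes jointly."""
    a, b = as_tensor(p_student), as_tensor(p_teacher)
    if a.shape != b.shape:
        raise InputError(f"shape mismatch {a.shape} vs {b.shape}")
    return ((a - b) ** 2).mean()


def supervised_loss(model_out, labels) -> Tensor:
    """Cross-entropy over the labeled sub-batch."""
    model_out = as_tensor(model_out)
    if model_out.shape[0] == 0:
        raise InputError("labeled sub-batch is empty")
    return cross_entropy(model_out, labels)


def consistency_loss(student_out, teacher_out) -> Tensor:
    """Student/teacher output MSE; the teacher side is detached, so only
    student parameters receive gradient from this term."""
    teacher_out = as_tensor(teacher_out)
    if teacher_out.requires_grad:
        teacher_out = teacher_out.detach()
    return mse_loss(student_out, teacher_out)


def pseudo_loss(student_out, pseudo) -> Tensor:
    """Cross-entropy of student outputs against fixed Stage-B pseudo labels."""
    return cross_entropy(student_out, pseudo)


def adaptive_weights(z):
    """Convex pair (alpha, beta) = (logistic(z), 1 - logistic(z))."""
    if isinstance(z, Tensor):
        if not np.all(np.isfinite(z.data)):
            raise InputError("z must be finite")
        alpha = z.sigmoid()
        return alpha, 1.0 - alpha
    if not math.isfinite(z):
        raise InputError("z must be finite")
    alpha = 1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1.0 + math.exp(z))
    return alpha, 1.0 - alpha


def warmup_weight(t: int, t_max: int) -> float:
    """Gaussian warm-up lambda_d(t) = exp(-5 (1 - min(t, t_max)/t_max)^2)."""
    if t_max <= 0:
        raise ConfigurationError(f"t_max must be positive, got {t_max}")
    if t < 0:
        raise ConfigurationError(f"t must be non-negative, got {t}")
    frac = min(t, t_max) / t_max
    return math.exp(-5.0 * (1.0 - frac) ** 2)


def stage_a_total(sup, con, w: LossWeights, ramp: float) -> LossBreakdown:
    """L_total^A = L_sup + lambda_A * lambda_d(t) * L_con."""
    total = sup + (w.lambda_a * ramp) * con
    return LossBreakdown(sup=_scalar(sup), con=_scalar(con), pse=None,
                         ramp=float(ramp), alpha=None, beta=None, total=total)


def stage_c_total(sup, con, pse, w: LossWeights, ramp: float) -> LossBreakdown:
    """L_total^C = L_sup + lambda_C * lambda_d(t) * (alpha*K*L_con + beta*L_pse)."""
    alpha, beta = adaptive_weights(w.z)
    total = sup + (w.lambda_c * ramp) * (alpha * float(w.K) * con + beta * pse)
    return LossBreakdown(sup=_scalar(sup), con=_scalar(con), pse=_scalar(pse),
                         ramp=float(ramp), alpha=_scalar(alpha), beta=_scalar(beta),
                         total=total)
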