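"""Bounding-box regression losses with a training-driven dynamic shape factor.

Three losses are provided, all defined on the absolute regression error
``x = |prediction - target|`` in normalized box-delta space:

* :func:`smooth_l1` — the classic Huber-style piecewise loss with a fixed
  branch point ``beta``.
* :func:`ds_l1` — dynamic Smooth L1: identical in form, but the branch point
  ``alpha_now`` shrinks during training as regression errors shrink, so that
  low-error ("high-quality") samples keep contributing gradient.
* :func:`dbs_l1` — dynamic *balanced* Smooth L1: the quadratic inlier branch
  is replaced by a logarithmic one,

      L(x) = (a/b) (b x + 1) ln(b x + 1) - a x      for x < a,
      L(x) = x + C                                  otherwise,

  with ``a = alpha_now``. The constants ``b`` and ``C`` are not free: they
  are pinned by requiring the loss to be continuous and once-differentiable
  at the branch point ``x = a`` with outer slope 1, which gives the closed
  forms ``b = (e^{1/a} - 1) / a`` and ``C = 1/b - a^2``. Compared with the
  quadratic branch, the log branch puts a steeper gradient on small errors,
  and the effect strengthens as ``alpha_now`` decreases.

``alpha_now`` itself is updated from training statistics: at every training
iteration the K_alpha-th smallest absolute regression error of the positive
samples is recorded, and once per update cadence ``alpha_now`` is set to the
median of the recorded statistics (clamped), after which ``b`` and ``C`` are
re-solved. See :class:`DynamicLossState` and :func:`update_alpha`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from dyndet.exceptions import InvalidParameterError, InvalidStateError

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicLossState",
    "smooth_l1",
    "ds_l1",
    "solve_bc",
    "dbs_l1",
    "dbs_l1_gradient",
    "update_alpha",
]

#: tolerance used to decide whether a state's (b, C) match its alpha_now
_STALE_TOL = 1e-8

#: set once the short-sample fallback has been reported at WARNING level
_FALLBACK_WARNED: set = set()


def smooth_l1(x, beta: float):
    """Smooth L1 loss of the absolute regression error ``x``.

    Quadratic ``0.5 x^2 / beta`` for ``x < beta``, linear ``x - 0.5 beta``
    beyond; continuous and once-differentiable at ``x = beta``.

    Parameters
    ----------
    x : float or array-like
        Regression error(s); the absolute value is taken.
    beta : float
        Branch point, must be positive.
    """
    if not (isinstance(beta, (int, float)) and math.isfinite(beta) and beta > 0):
        raise InvalidParameterError(f"beta must be a positive finite real, got {beta!r}")
    x = np.abs(np.asarray(x, dtype=float))
    out = np.where(x < beta, 0.5 * x * x / beta, x - 0.5 * beta)
    return float(out) if out.ndim == 0 else out


def ds_l1(x, alpha_now: float):
    """Dynamic Smooth L1: Smooth L1 whose branch point is the dynamic factor.

    Exactly ``smooth_l1(x, beta=alpha_now)``; kept as its own entry point
    because the two play different roles (fixed hyperparameter vs. a factor
    re-estimated from training statistics).
    """
    if not (isinstance(alpha_now, (int, float)) and math.isfinite(alpha_now) and alpha_now > 0):
        raise InvalidParameterError(
            f"alpha_now must be a positive finite real, got {alpha_now!r}"
        )
    return smooth_l1(x, beta=alpha_now)


def solve_bc(alpha_now: float) -> tuple[float, float]:
    """Constants ``(b, C)`` making DBS L1 C0- and C1-continuous at ``x = alpha``.

    Gradient continuity with outer slope 1 requires
    ``alpha * ln(b * alpha + 1) = 1``, i.e. ``b = (e^{1/alpha} - 1) / alpha``;
    value continuity then gives ``C = 1/b - alpha^2``.

    Raises
    ------
    InvalidParameterError
        If ``alpha_now`` is not a positive finite real, or is so small that
        ``e^{1/alpha}`` overflows (alpha below ~1/700).
    """
    if not (isinstance(alpha_now, (int, float)) and math.isfinite(alpha_now) and alpha_now > 0):
        raise InvalidParameterError(
            f"alpha_now must be a positive finite real, got {alpha_now!r}"
        )
    try:
        b = (math.exp(1.0 / alpha_now) - 1.0) / alpha_now
    except OverflowError as exc:
        raise InvalidParameterError(
            f"alpha_now={alpha_now} too small: exp(1/alpha) overflows"
        ) from exc
    c = 1.0 / b - alpha_now * alpha_now
    return b, c


@dataclass
class DynamicLossState:
    """State of the dynamic balanced loss: shape factor plus its statistics.

    Attributes
    ----------
    alpha_now : float
        Current branch point / shape factor of the loss.
    b, C : float
        Continuity constants, always solved for the current ``alpha_now``.
    error_buffer : list of float
        Per-iteration recorded order statistics (the K_alpha-th smallest
        absolute regression error), cleared at every cadence update.
    K_alpha : int
        Which order statistic of the per-iteration error sample to record.
    clamp : (float, float)
        Inclusive bounds for ``alpha_now`` after each update.
    cadence : int
        Number of recorded iterations between consecutive alpha updates.
        The first window doubles as warm-up: alpha is untouched until
        ``cadence`` statistics have accumulated.
    """

    alpha_now: float = 1.0
    b: float = math.e - 1.0
    C: float = 1.0 / (math.e - 1.0) - 1.0
    error_buffer: list = field(default_factory=list)
    K_alpha: int = 10
    clamp: tuple = (0.05, 1.0)
    cadence: int = 100

    @classmethod
    def create(
        cls,
        alpha_init: float = 1.0,
        k_alpha: int = 10,
        cadence: int = 100,
        clamp: tuple = (0.05, 1.0),
    ) -> "DynamicLossState":
        if k_alpha < 1:
            raise InvalidParameterError(f"K_alpha must be >= 1, got {k_alpha}")
        if cadence < 1:
            raise InvalidParameterError(f"cadence must be >= 1, got {cadence}")
        if not (0 < clamp[0] <= clamp[1]):
            raise InvalidParameterError(f"invalid alpha clamp {clamp}")
        alpha = float(min(max(alpha_init, clamp[0]), clamp[1]))
        b, c = solve_bc(alpha)
        return cls(alpha_now=alpha, b=b, C=c, K_alpha=int(k_alpha),
                   clamp=(float(clamp[0]), float(clamp[1])), cadence=int(cadence))

    def check_consistent(self) -> None:
        """Raise if (b, C) are stale with respect to alpha_now."""
        b, c = solve_bc(self.alpha_now)
        if abs(b - self.b) > _STALE_TOL * max(1.0, abs(b)) or abs(c - self.C) > _STALE_TOL:
            raise InvalidStateError(
                f"(b={self.b}, C={self.C}) stale for alpha_now={self.alpha_now}; "
                f"expected (b={b}, C={c})"
            )


def _as_state(state) -> DynamicLossState:
    if isinstance(state, DynamicLossState):
        state.check_consistent()
        return state
    # allow a bare alpha for convenience
    alpha = float(state)
    b, c = solve_bc(alpha)
    return DynamicLossState(alpha_now=alpha, b=b, C=c)


def dbs_l1(x, state):
    """Dynamic balanced Smooth L1 loss of the absolute regression error.

    ``(a/b)(bx+1)ln(bx+1) - a x`` for ``x < a``, ``x + C`` otherwise, with
    ``a = state.alpha_now`` and ``(b, C)`` its continuity constants.

    ``state`` may be a consistent :class:`DynamicLossState` or a bare positive
    alpha (constants solved on the fly).
    """
    st = _as_state(state)
    a, b, c = st.alpha_now, st.b, st.C
    x = np.abs(np.asarray(x, dtype=float))
    bx1 = b * x + 1.0
    inner = (a / b) * bx1 * np.log(bx1) - a * x
    out = np.where(x < a, inner, x + c)
    return float(out) if out.ndim == 0 else out


def dbs_l1_gradient(x, state):
    """Analytic derivative of :func:`dbs_l1` with respect to ``x >= 0``.

    ``a * ln(b x + 1)`` on the inner branch, 1 on the linear branch; the
    continuity constraint makes the two agree at ``x = a``.
    """
    st = _as_state(state)
    a, b = st.alpha_now, st.b
    x = np.abs(np.asarray(x, dtype=float))
    out = np.where(x < a, a * np.log(b * x + 1.0), 1.0)
    return float(out) if out.ndim == 0 else out


def update_alpha(state: DynamicLossState, errors_E) -> DynamicLossState:
    """Record an error statistic and, at cadence, refresh ``alpha_now``.

    Appends the ``K_alpha``-th smallest value of ``errors_E`` to the buffer.
    When the buffer reaches ``state.cadence`` entries, ``alpha_now`` is set to
    ``min(alpha_now, median(buffer))`` — the factor only ever tightens, so a
    noisy window cannot undo earlier progress — clamped to ``state.clamp``;
    the continuity constants are re-solved and the buffer cleared.

    If fewer than ``K_alpha`` errors are supplied, the largest available
    order statistic is used instead (with a logged warning).

    The state is updated in place and returned.
    """
    errs = np.abs(np.asarray(errors_E, dtype=float)).ravel()
    if errs.size == 0:
        raise InvalidParameterError("errors_E must be non-empty")
    k = state.K_alpha
    if k > errs.size:
        # routine early in training when few positives exist; warn once
        level = logging.DEBUG if _FALLBACK_WARNED else logging.WARNING
        logger.log(level,
                   "K_alpha=%d exceeds sample size %d; using the largest order "
                   "statistic", k, errs.size)
        _FALLBACK_WARNED.add("k_alpha")
        k = errs.size
    stat = float(np.partition(errs, k - 1)[k - 1])
    state.error_buffer.append(stat)
    if len(state.error_buffer) >= state.cadence:
        alpha = min(state.alpha_now, float(np.median(state.error_buffer)))
        alpha = min(max(alpha, state.clamp[0]), state.clamp[1])
        state.alpha_now = alpha
        state.b, state.C = solve_bc(alpha)
        state.error_buffer.clear()
    return state
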