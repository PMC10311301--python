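"""Maximum-likelihood estimation of a single overdispersion parameter Q.

Given per-gene allelic counts (m_l, p_l) and fixed per-gene allelic-imbalance
estimates AI_l, the likelihood of a shared variance-inflation factor Q is

    L(Q) = prod_l pmf_eBB(m_l | n_l = m_l + p_l, AI_l, Q)

with a per-gene urn increment d_l = (Q - 1) / (n_l - Q).  The maximiser is
found by projected gradient ascent on log Q with a backtracking line
search.  Everything here is deterministic; stochasticity lives in the
simulation module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import EBBInvalidParameters

__all__ = ["GeneObservation", "QFitConfig", "QFitResult", "loglik_q", "fit_q", "ObservationSet"]


@dataclass(frozen=True)
class GeneObservation:
    """One gene's counts in one library plus its fixed AI estimate."""

    m: int
    p: int
    ai_hat: float

    @property
    def n(self) -> int:
        return self.m + self.p


@dataclass(frozen=True)
class QFitConfig:
    """Optimizer settings for the one-dimensional Q fit.

    The fit runs on x = log q with backtracking line search.  ``q_max`` is
    capped at 0.99 * min_l n_l because d(q) has a pole at q = n_l.
    """

    q_min: float = 0.05
    q_max_frac: float = 0.99
    x_tol: float = 1e-6       # convergence on |delta log q|
    grad_tol: float = 1e-8    # convergence on |d loglik / d log q|
    max_iter: int = 500


@dataclass
class QFitResult:
    q: float
    loglik: float
    iterations: int
    converged: bool
    boundary_hit: bool
    n_genes: int
    n_excluded_degenerate: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def iqcc(self) -> float:
        return float(np.sqrt(self.q))


class ObservationSet:
    """Vectorised evaluation of the Q log-likelihood and its gradient.

    Flattens the paired-log1p sums of all genes into index arrays once so
    that each (log)likelihood evaluation is a handful of numpy operations
    over ~sum(n_l) elements.  Genes with ai_hat exactly 0 or 1 carry no
    information about Q (their eBB degenerates) and are excluded, with the
    count reported.
    """

    def __init__(self, observations: list[GeneObservation] | tuple):
        obs = [o for o in observations if o.n > 0]
        self.n_excluded_degenerate = sum(
            1 for o in obs if o.ai_hat <= 0.0 or o.ai_hat >= 1.0
        )
        obs = [o for o in obs if 0.0 < o.ai_hat < 1.0]
        if not obs:
            raise ValueError("no usable observations (all empty or degenerate AI)")
        self.m = np.array([o.m for o in obs], dtype=np.int64)
        self.p = np.array([o.p for o in obs], dtype=np.int64)
        self.n = self.m + self.p
        self.ai = np.array([o.ai_hat for o in obs], dtype=float)
        self.n_genes = len(obs)
        self.min_n = int(self.n.min())

        g = np.arange(self.n_genes)
        # i-sum: i = 0..m_l-1 for each gene
        self._gi = np.repeat(g, self.m)
        self._i = _concat_aranges(self.m)
        # j-sum: j = 0..p_l-1
        self._gj = np.repeat(g, self.p)
        self._j = _concat_aranges(self.p)
        # k-sum for the gradient: k = 0..n_l-1
        self._gk = np.repeat(g, self.n)
        self._k = _concat_aranges(self.n)

    def _d(self, q: float) -> np.ndarray:
        return (q - 1.0) / (self.n - q)

    def loglik(self, q: float) -> float:
        """Sum of paired-log1p eBB log-pmfs; -inf if any gene is impossible."""
        if not 0 < q < self.min_n:
            raise ValueError(f"q={q} outside (0, min n={self.min_n})")
        d = self._d(q)
        a, b = self.ai, 1.0 - self.ai
        x_i = -b[self._gi] / (1.0 + self._i * d[self._gi])
        mj, aj, bj, dj, j = (
            self.m[self._gj], a[self._gj], b[self._gj], d[self._gj], self._j,
        )
        x_j = (mj * bj - mj * dj - (j + 1.0) * aj) / (
            (j + 1.0) * (1.0 + (mj + j) * dj)
        )
        if np.any(x_i <= -1.0) or np.any(x_j <= -1.0):
            return -np.inf
        return float(np.sum(np.log1p(x_i)) + np.sum(np.log1p(x_j)))

    def grad(self, q: float) -> float:
        """Analytic d loglik / dq (sum of per-gene d log pmf / dq)."""
        d = self._d(q)
        a, b = self.ai, 1.0 - self.ai
        fa = a[self._gi] + self._i * d[self._gi]
        fb = b[self._gj] + self._j * d[self._gj]
        fk = 1.0 + self._k * d[self._gk]
        if np.any(fa <= 0) or np.any(fb <= 0) or np.any(fk <= 0):
            raise EBBInvalidParameters(f"gradient undefined at q={q}")
        s = (
            np.bincount(self._gi, self._i / fa, minlength=self.n_genes)
            + np.bincount(self._gj, self._j / fb, minlength=self.n_genes)
            - np.bincount(self._gk, self._k / fk, minlength=self.n_genes)
        )
        dd_dq = (self.n - 1.0) / (self.n - q) ** 2
        return float(np.sum(s * dd_dq))


def _concat_aranges(lengths: np.ndarray) -> np.ndarray:
    """[arange(l) for l in lengths], concatenated, without a python loop."""
    total = int(lengths.sum())
    starts = np.repeat(np.cumsum(np.concatenate(([0], lengths[:-1]))), lengths)
    return np.arange(total) - starts


def loglik_q(observations: list[GeneObservation], q: float) -> float:
    """Log-likelihood of a shared Q over a set of gene observations."""
    if not observations:
        raise ValueError("empty observation list")
    return ObservationSet(observations).loglik(q)


def fit_q(
    observations: list[GeneObservation] | ObservationSet,
    config: QFitConfig | None = None,
) -> QFitResult:
    """Maximise the Q likelihood by gradient ascent on log q.

    Starts at q = 1 (the binomial point, always feasible for AI in (0,1));
    backtracks the step until the Armijo condition holds; converges on
    |delta log q| < x_tol or |gradient| < grad_tol.  Non-convergence after
    ``max_iter`` steps is flagged, not raised.
    """
    config = config or QFitConfig()
    obs = observations if isinstance(observations, ObservationSet) else ObservationSet(observations)
    lo = np.log(config.q_min)
    hi = np.log(config.q_max_frac * obs.min_n)

    x = np.clip(0.0, lo, hi)  # log q = 0 -> q = 1
    f = obs.loglik(float(np.exp(x)))
    step = 0.1
    it = 0
    converged = False
    for it in range(1, config.max_iter + 1):
        q = float(np.exp(x))
        g = obs.grad(q) * q  # chain rule onto x = log q
        if abs(g) < config.grad_tol:
            converged = True
            break
        moved = False
        while step > 1e-14:
            x_new = float(np.clip(x + step * np.sign(g), lo, hi))
            f_new = obs.loglik(float(np.exp(x_new)))
            if np.isfinite(f_new) and f_new > f:
                moved = True
                break
            step *= 0.5
        if not moved:
            converged = True  # no uphill move representable: at optimum
            break
        if abs(x_new - x) < config.x_tol:
            x, f = x_new, f_new
            converged = True
            break
        x, f = x_new, f_new
        step = min(step * 2.0, 5.0)

    q = float(np.exp(x))
    boundary = bool(np.isclose(x, lo) or np.isclose(x, hi))
    return QFitResult(
        q=q,
        loglik=f,
        iterations=it,
        converged=converged,
        boundary_hit=boundary,
        n_genes=obs.n_genes,
        n_excluded_degenerate=obs.n_excluded_degenerate,
    )
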