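"""Batch-wide per-library overdispersion (iQCC) estimation.

The model: every library j in a batch shares the same underlying RNA (a
spike-in aliquot, or a technical replicate), so every gene has one true
allelic imbalance across the batch while each library carries its own
technical overdispersion Q_j = iQCC_j^2.  Estimation alternates between

  * AI step — per-gene AI from the whole batch with inverse-Q weighting,
      AI = (sum_i m_i / Q_i) / (sum_i (m_i + p_i) / Q_i),
    leaving library j out when estimating the AI used for j's own fit
    (spike-in mode), and
  * Q step — one-dimensional maximum likelihood for each Q_j given the
    fixed AI vector (see :mod:`ebbase.qfit`),

starting from Q_i = 1 (where the AI step reduces to the pooled fraction)
and iterating to convergence.  Leaving j out makes Q_j an overestimate
when the rest-of-batch coverage N is comparable to j's coverage n;
including j makes it an underestimate.  In technical-replicate mode
(small batches, similar overdispersion assumed) both one-sided fits are
run and iQCC_j is their geometric mean, which cancels the two biases in
log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountsTable
from .qfit import GeneObservation, ObservationSet, QFitConfig, QFitResult, fit_q

__all__ = [
    "BatchConfig",
    "OverdispersionModel",
    "OverdispersionResults",
    "estimate_ai",
    "filter_table",
    "fit_iqcc_spikein",
    "fit_iqcc_replicates",
    "LowCoverageWarning",
]

logger = logging.getLogger(__name__)

# below ~tens of thousands of allelic reads per library the estimates lose fidelity
LOW_COVERAGE_TOTAL = 50_000


class LowCoverageWarning(UserWarning):
    pass


@dataclass(frozen=True)
class BatchConfig:
    """Settings for the batch fit.

    min_gene_coverage: per-library fitting threshold on n = m + p (genes
        below it are dropped from that library's likelihood only).
    autosomes_only: restrict the fit to autosomal genes when chromosome
        labels are available (sex chromosomes carry real allelic skew).
    outer_tol: convergence tolerance on max |delta iQCC| between outer
        iterations.
    single_pass_spread: if all first-round Q estimates lie within this
        relative spread of each other the first pass is accepted without
        iteration (homogeneous batches need no refinement).
    """

    min_gene_coverage: int = 30
    autosomes_only: bool = True
    outer_tol: float = 1e-3
    max_outer_iterations: int = 50
    single_pass_spread: float = 0.2
    qfit: QFitConfig = field(default_factory=QFitConfig)


def filter_table(
    table: CountsTable, config: BatchConfig, sample: str
) -> np.ndarray:
    """Boolean mask of genes usable for fitting ``sample``'s Q.

    A gene is retained iff its coverage in the target library is at least
    ``min_gene_coverage`` (boundary inclusive) and, when enabled and
    chromosome labels exist, it is autosomal.
    """
    n = (table.m[sample] + table.p[sample]).to_numpy()
    mask = n >= config.min_gene_coverage
    if config.autosomes_only:
        mask &= table.autosomal_mask()
    if not mask.any():
        raise ValueError(
            f"no gene passes the coverage/autosome filter for sample {sample!r}"
        )
    return mask


def estimate_ai(
    table: CountsTable,
    q: np.ndarray | pd.Series,
    gene: int | None = None,
    exclude: str | None = None,
) -> np.ndarray | float:
    """Batch AI estimate per gene with inverse-Q (effective-count) weighting.

        AI = (sum_i m_i / Q_i) / (sum_i (m_i + p_i) / Q_i)

    over the included libraries; ``exclude`` drops one library
    (leave-one-out).  With all Q_i = 1 this is the pooled allelic
    fraction.  Genes with zero included coverage return NaN.

    Returns the full per-gene vector, or a scalar when ``gene`` (a
    positional index) is given.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("all Q values must be positive")
    samples = table.samples
    if len(q) != len(samples):
        raise ValueError("one Q per library required")
    w = 1.0 / q
    if exclude is not None:
        w = w.copy()
        w[samples.index(exclude)] = 0.0
    num = table.m.to_numpy() @ w
    den = (table.m.to_numpy() + table.p.to_numpy()) @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(ai[gene]) if gene is not None else ai


@dataclass
class OverdispersionResults:
    """Fitted per-library overdispersion for one batch."""

    sample_ids: list[str]
    q: np.ndarray
    mode: str
    iterations: int
    converged: bool
    per_sample_genes_used: np.ndarray
    q_over: np.ndarray | None = None
    q_under: np.ndarray | None = None
    fit_details: list[QFitResult] | None = None
    model: "OverdispersionModel | None" = None

    @property
    def iqcc(self) -> np.ndarray:
        return np.sqrt(self.q)

    @property
    def iqcc_over(self) -> np.ndarray | None:
        return None if self.q_over is None else np.sqrt(self.q_over)

    @property
    def iqcc_under(self) -> np.ndarray | None:
        return None if self.q_under is None else np.sqrt(self.q_under)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "q": self.q,
                "iqcc": self.iqcc,
                "genes_used": self.per_sample_genes_used,
                "converged": self.converged,
                "q_over": self.q_over if self.q_over is not None else np.nan,
                "q_under": self.q_under if self.q_under is not None else np.nan,
            }
        )
        return df

    def summary(self) -> str:
        lines = [
            "Overdispersion (iQCC) estimation results",
            "=" * 46,
            f"mode:             {self.mode}",
            f"libraries:        {len(self.sample_ids)}",
            f"outer iterations: {self.iterations}",
            f"converged:        {self.converged}",
            "-" * 46,
            f"{'sample':<14}{'iQCC':>8}{'Q':>9}{'genes':>8}",
        ]
        for i, s in enumerate(self.sample_ids):
            lines.append(
                f"{s:<14}{self.iqcc[i]:>8.3f}{self.q[i]:>9.3f}"
                f"{self.per_sample_genes_used[i]:>8d}"
            )
        return "\n".join(lines)

    def plot_iqcc(self, ax=None):
        """Bar plot of per-library iQCC (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.5 * len(self.sample_ids), 3))
        ax.bar(self.sample_ids, self.iqcc, color="#4878a8")
        ax.axhline(1.0, ls="--", c="gray", lw=1)
        ax.set_ylabel("iQCC")
        ax.tick_params(axis="x", rotation=45)
        return ax


class OverdispersionModel:
    """Per-library overdispersion model for a batch sharing one RNA source.

    Parameters
    ----------
    table : CountsTable
        genes x libraries maternal/paternal counts.
    mode : {"spikein", "replicates"}
        "spikein" uses leave-one-out AI estimates (good when the batch is
        large); "replicates" additionally fits the include-self
        underestimate and reports the geometric mean (good for 2-3
        technical replicates with similar overdispersion).
    config : BatchConfig, optional
    """

    def __init__(
        self,
        table: CountsTable,
        mode: str = "spikein",
        config: BatchConfig | None = None,
    ):
        if mode not in ("spikein", "replicates"):
            raise ValueError(f"unknown mode {mode!r}")
        min_samples = 2
        if table.n_samples < min_samples:
            raise ValueError(
                f"at least {min_samples} libraries are required (got {table.n_samples})"
            )
        if mode == "spikein" and table.n_samples < 3:
            warnings.warn(
                "spike-in mode with fewer than 3 libraries: leave-one-out AI "
                "estimates will be noisy and Q overestimated; consider "
                "mode='replicates'",
                LowCoverageWarning,
                stacklevel=2,
            )
        self.table = table
        self.mode = mode
        self.config = config or BatchConfig()
        self._warn_low_coverage()
        # per-sample fitting masks are fixed across iterations
        self._masks = {
            s: filter_table(table, self.config, s) for s in table.samples
        }

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, mode: str = "spikein", config: BatchConfig | None = None
    ) -> "OverdispersionModel":
        """Build from a wide frame with <sample>_mat / <sample>_pat columns."""
        from .io import counts_from_dataframe

        return cls(counts_from_dataframe(df), mode=mode, config=config)

    def _warn_low_coverage(self) -> None:
        totals = self.table.total_counts_per_sample()
        low = totals[totals < LOW_COVERAGE_TOTAL]
        if len(low):
            warnings.warn(
                "libraries with < {:,} total allelic counts (reduced iQCC "
                "fidelity): {}".format(LOW_COVERAGE_TOTAL, list(low.index)),
                LowCoverageWarning,
                stacklevel=3,
            )

    # -- fitting ---------------------------------------------------------

    def _fit_one_sided(self, leave_one_out: bool):
        """Alternate AI and Q fitting until the iQCC vector stabilises."""
        table, cfg = self.table, self.config
        samples = table.samples
        S = len(samples)
        m_arr = table.m.to_numpy()
        p_arr = table.p.to_numpy()
        q = np.ones(S)
        genes_used = np.zeros(S, dtype=int)
        details: list[QFitResult] = [None] * S
        converged = False
        outer = 0
        for outer in range(1, cfg.max_outer_iterations + 1):
            iqcc_prev = np.sqrt(q)
            q_new = np.empty(S)
            for j, s in enumerate(samples):
                ai = estimate_ai(table, q, exclude=s if leave_one_out else None)
                mask = self._masks[s] & np.isfinite(ai)
                obs = ObservationSet(
                    [
                        GeneObservation(int(m), int(p), float(a))
                        for m, p, a in zip(m_arr[mask, j], p_arr[mask, j], ai[mask])
                    ]
                )
                res = fit_q(obs, cfg.qfit)
                q_new[j] = res.q
                genes_used[j] = obs.n_genes
                details[j] = res
            delta = np.max(np.abs(np.sqrt(q_new) - iqcc_prev))
            q = q_new
            if outer == 1:
                spread = q.max() / q.min() - 1.0
                if spread <= cfg.single_pass_spread:
                    converged = True
                    break
            if delta < cfg.outer_tol:
                converged = True
                break
        return q, genes_used, details, outer, converged

    def fit(self) -> OverdispersionResults:
        """Run the alternating estimation and return the fitted results."""
        if self.mode == "spikein":
            q, genes, details, iters, conv = self._fit_one_sided(leave_one_out=True)
            return OverdispersionResults(
                sample_ids=self.table.samples,
                q=q,
                mode=self.mode,
                iterations=iters,
                converged=conv,
                per_sample_genes_used=genes,
                fit_details=details,
                model=self,
            )
        # replicates: geometric mean of the leave-one-out overestimate and
        # the include-self underestimate
        q_over, genes, det_over, it1, conv1 = self._fit_one_sided(leave_one_out=True)
        q_under, _, det_under, it2, conv2 = self._fit_one_sided(leave_one_out=False)
        q_geo = np.sqrt(q_over * q_under)
        return OverdispersionResults(
            sample_ids=self.table.samples,
            q=q_geo,
            mode=self.mode,
            iterations=max(it1, it2),
            converged=conv1 and conv2,
            per_sample_genes_used=genes,
            q_over=q_over,
            q_under=q_under,
            fit_details=det_over,
            model=self,
        )


def fit_iqcc_spikein(
    table: CountsTable, config: BatchConfig | None = None
) -> OverdispersionResults:
    """Spike-in mode batch iQCC estimation (leave-one-out AI)."""
    return OverdispersionModel(table, mode="spikein", config=config).fit()


def fit_iqcc_replicates(
    table: CountsTable, config: BatchConfig | None = None
) -> OverdispersionResults:
    """Technical-replicate mode: geometric mean of over/under estimates."""
    return OverdispersionModel(table, mode="replicates", config=config).fit()
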