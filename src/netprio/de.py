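"""Two-group differential expression with empirical-Bayes moderated t-statistics.

Per gene g a two-sample comparison yields a log2 ratio (treatment mean minus
control mean) and a residual variance s_g^2 on d_g = n - 2 degrees of
freedom.  Assuming the gene-level variances are drawn from a scaled inverse
chi-square prior with d0 degrees of freedom and scale s0^2, the posterior
variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

shrinks each gene's variance toward the global value, and the moderated
statistic t~_g = log2_ratio / (s~_g * sqrt(1/n_t + 1/n_c)) follows a t
distribution with d0 + d_g degrees of freedom under the null.  The
hyperparameters (d0, s0^2) are estimated by the method of moments on
log s_g^2 (Smyth 2004 closed forms, via digamma/trigamma inversion).  When
the moment equation has no positive solution, d0 is set to +inf and s0^2 to
the pooled (df-weighted mean) variance, so moderation degenerates to full
shrinkage onto the pooled value.

P-values are corrected by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from .io import CONTROL, TREATMENT, ExpressionMatrix

logger = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values.

    adj_(i) = min(1, min_{j >= i} p_(j) * n / j), mapped back to input order.
    Raises on entries outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of P-values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("P-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty_like(p)
    adj[order] = adj_sorted
    return adj


@dataclass(frozen=True)
class ModerationParams:
    """Prior degrees of freedom and prior variance of the variance model."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (possibly +inf)")
        if not (self.s0_sq >= 0):
            raise ValueError("s0_sq must be >= 0")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Method-of-moments fit of the inverse-chi-square variance prior.

    Works on z_g = log s_g^2: with e_g = z_g - digamma(d/2) + log(d/2),
    E[e_g] = log s0^2 + digamma(d0/2) - log(d0/2) and
    Var[e_g] = trigamma(d/2) + trigamma(d0/2), which the trigamma inverse
    turns into the closed-form estimators.  Zero variances are excluded from
    the fit; if the moment equation has no positive solution the prior is
    d0 = +inf with s0^2 = pooled variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    pooled = float(np.mean(s2))
    if pos.size < 2:
        return ModerationParams(d0=np.inf, s0_sq=pooled)
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        return ModerationParams(d0=d0, s0_sq=s0_sq)
    return ModerationParams(d0=np.inf, s0_sq=pooled)


def _two_sided_t_p(t: np.ndarray, df: float | np.ndarray) -> np.ndarray:
    if np.isinf(np.asarray(df)).all():
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-sample t-test, one test per gene.

    Parameters
    ----------
    d0 : float, optional
        Prior degrees of freedom.  ``None`` (default) estimates it from the
        data; ``0`` disables moderation (ordinary t); ``inf`` forces full
        shrinkage to the prior variance.
    s0_sq : float, optional
        Prior variance.  ``None`` estimates it (or, when only ``d0`` is
        overridden, uses the pooled variance).

    Attributes (after :meth:`fit`)
    ------------------------------
    genes_, log2_ratio_, t_stat_, p_value_, adj_p_ : per-gene results
    d0_, s0_sq_ : hyperparameters actually used
    df_residual_, df_total_ : residual and total degrees of freedom
    """

    def __init__(self, d0: float | None = None, s0_sq: float | None = None):
        self.d0 = d0
        self.s0_sq = s0_sq

    def fit(self, X, y=None) -> "ModeratedTTest":
        """Fit on an :class:`ExpressionMatrix`, or on an (n_samples,
        n_genes) array with ``y`` giving 'control'/'treatment' labels."""
        if isinstance(X, ExpressionMatrix):
            values = X.values.to_numpy(dtype=float)  # genes x samples
            labels = X.groups.to_numpy()
            self.genes_ = np.asarray(X.genes, dtype=object)
        else:
            values = np.asarray(X, dtype=float).T  # -> genes x samples
            labels = np.asarray(y)
            self.genes_ = np.asarray([f"g{i}" for i in range(values.shape[0])],
                                     dtype=object)
        ctrl = values[:, labels == CONTROL]
        trt = values[:, labels == TREATMENT]
        n_c, n_t = ctrl.shape[1], trt.shape[1]
        if n_c < 2 or n_t < 2:
            raise ValueError("each group needs at least two samples")
        n_genes = values.shape[0]

        lfc = trt.mean(axis=1) - ctrl.mean(axis=1)
        df_res = float(n_c + n_t - 2)
        ss = ctrl.var(axis=1, ddof=1) * (n_c - 1) + trt.var(axis=1, ddof=1) * (n_t - 1)
        s2 = ss / df_res
        if np.all(s2 == 0):
            raise ValueError("degenerate matrix: zero variance in all genes")

        if n_genes == 1:
            warnings.warn("single gene: moderation skipped, ordinary t used")
            params = ModerationParams(d0=0.0, s0_sq=0.0)
        elif self.d0 is not None:
            s0 = self.s0_sq
            if s0 is None:
                s0 = float(np.mean(s2)) if self.d0 > 0 else 0.0
            params = ModerationParams(d0=float(self.d0), s0_sq=s0)
        else:
            params = estimate_moderation(s2, df_res)
        self.d0_, self.s0_sq_ = params.d0, params.s0_sq

        if np.isinf(params.d0):
            s2_post = np.full_like(s2, params.s0_sq)
            df_total = np.inf
        else:
            s2_post = (params.d0 * params.s0_sq + df_res * s2) / (params.d0 + df_res)
            # total df is capped at the pooled residual df, as in limma
            df_total = min(params.d0 + df_res, df_res * n_genes)
        se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_c))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lfc / se
        t = np.where(se > 0, t, np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
        p = _two_sided_t_p(t, df_total)

        self.log2_ratio_ = lfc
        self.t_stat_ = t
        self.p_value_ = p
        self.adj_p_ = bh_adjust(p)
        self.df_residual_ = df_res
        self.df_total_ = df_total
        return self

    def signature(self) -> pd.DataFrame:
        """Return the fitted results as a signature DataFrame."""
        return pd.DataFrame({
            "gene": self.genes_,
            "log2_ratio": self.log2_ratio_,
            "t_stat": self.t_stat_,
            "p_value": self.p_value_,
            "adj_p": self.adj_p_,
        })


def moderated_t(matrix: ExpressionMatrix, d0: float | None = None,
                s0_sq: float | None = None) -> pd.DataFrame:
    """Compute a moderated-t differential-expression signature.

    Thin functional wrapper over :class:`ModeratedTTest`; returns a
    DataFrame with columns gene, log2_ratio, t_stat, p_value, adj_p.
    """
    return ModeratedTTest(d0=d0, s0_sq=s0_sq).fit(matrix).signature()
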