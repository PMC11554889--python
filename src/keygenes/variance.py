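"""Inverse-gamma variance filtering of expression data.

The filter assumes the population variance sigma^2 of a gene's (log-scale)
expression follows an inverse-gamma law across genes. For gene i with
unbiased sample variance s_i^2 the filter assigns

    p_i = Pr[sigma^2 >= s_i^2],

the upper tail of the fitted inverse-gamma — so p_i = 1 when s_i^2 = 0 and
p_i decreases monotonically toward 0 as s_i^2 grows. Genes with p below a
cutoff (default 0.05) are kept as high-variance candidates: since the
variance of a differentially expressed pattern exceeds that of an equally
expressed one, large s_i^2 is evidence of differential expression.

Shape/scale are estimated by method of moments (alpha = m^2/v + 2,
beta = m (alpha - 1), with m and v the mean and variance of the positive
s_i^2), optionally refined by maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset


def gene_variances(data: ExpressionDataset) -> np.ndarray:
    """Unbiased per-gene sample variance across all samples."""
    if data.n_samples < 2:
        raise ValueError("variance needs at least 2 samples")
    return data.values.var(axis=1, ddof=1)


def fit_inverse_gamma(variances: np.ndarray, method: str = "mom") -> tuple[float, float]:
    """Fit (alpha, beta) of an inverse-gamma to the positive variances.

    Zero variances are excluded from the fit (they are assigned p = 1
    downstream). ``method='mle'`` refines the moment estimate by maximum
    likelihood with the location fixed at 0.
    """
    v = np.asarray(variances, dtype=float)
    if (v < 0).any():
        raise ValueError("variances must be nonnegative")
    pos = v[v > 0]
    if pos.size < 10:
        raise ValueError("need at least 10 positive variances to fit")
    m = pos.mean()
    var = pos.var(ddof=1)
    if var == 0:
        raise ValueError("degenerate fit: all variances equal")
    alpha = m * m / var + 2.0
    beta = m * (alpha - 1.0)
    if method == "mle":
        alpha, _, beta = stats.invgamma.fit(pos, alpha, floc=0, scale=beta)
    elif method != "mom":
        raise ValueError(f"unknown fit method {method!r}")
    return float(alpha), float(beta)


def variance_pvalues(variances: np.ndarray, fit: tuple[float, float]) -> np.ndarray:
    """Upper-tail p_i = Pr[sigma^2 >= s_i^2] under the fitted inverse-gamma.

    p_i = 1 exactly at s_i^2 = 0 and decreases monotonically in s_i^2.
    """
    alpha, beta = fit
    v = np.asarray(variances, dtype=float)
    p = stats.invgamma.sf(v, alpha, scale=beta)
    p = np.where(v <= 0, 1.0, p)
    return p


def filter_genes(data: ExpressionDataset, p_cutoff: float = 0.05,
                 method: str = "mom") -> list[str]:
    """Genes whose variance p-value falls strictly below the cutoff,
    in the dataset's original gene order."""
    res = VarianceFilter(data, p_cutoff=p_cutoff, method=method).fit()
    return res.selected_genes()


class VarianceFilter:
    """Inverse-gamma variance model of an expression dataset.

    Parameters
    ----------
    data : ExpressionDataset
    p_cutoff : float
        Strict upper bound on the Eq.-style upper-tail p-value for a gene
        to be selected (default 0.05).
    method : str
        'mom' (method of moments, default) or 'mle'.
    """

    def __init__(self, data: ExpressionDataset, p_cutoff: float = 0.05,
                 method: str = "mom"):
        self.data = data
        self.p_cutoff = p_cutoff
        self.method = method

    def fit(self) -> "VarianceFilterResults":
        s2 = gene_variances(self.data)
        if not (s2 > 0).any():
            # an all-constant matrix needs no fit: every gene gets p = 1
            return VarianceFilterResults(
                self, s2, float("nan"), float("nan"), np.ones_like(s2)
            )
        alpha, beta = fit_inverse_gamma(s2, method=self.method)
        p = variance_pvalues(s2, (alpha, beta))
        return VarianceFilterResults(self, s2, alpha, beta, p)


@dataclass
class VarianceFilterResults:
    model: VarianceFilter
    variances: np.ndarray
    alpha: float
    beta: float
    pvalues: np.ndarray

    @property
    def selected(self) -> np.ndarray:
        return self.pvalues < self.model.p_cutoff

    def selected_genes(self) -> list[str]:
        return [g for g, keep in zip(self.model.data.gene_ids, self.selected) if keep]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.model.data.gene_ids,
                "s2": self.variances,
                "p_value": self.pvalues,
                "selected": self.selected.astype(int),
            }
        )

    def summary(self) -> str:
        n_sel = int(self.selected.sum())
        return "\n".join(
            [
                "Inverse-gamma variance filter",
                f"  genes: {len(self.variances)}   samples: {self.model.data.n_samples}",
                f"  fit ({self.model.method}): alpha = {self.alpha:.4f}, beta = {self.beta:.4f}",
                f"  p < {self.model.p_cutoff:g}: {n_sel} genes selected "
                f"({100 * n_sel / len(self.variances):.1f}%)",
            ]
        )
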