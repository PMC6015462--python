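"""Two-group differential expression with empirical-Bayes moderated t.

Per gene: logFC = mean(case) - mean(control) on the (assumed log-scale)
input; the pooled residual variance ``s_g^2`` (d = n - 2 df) is shrunk
toward a prior ``s0^2`` with prior df ``d0`` estimated by method of
moments on ``log s_g^2`` (closed form via trigamma inversion); the
moderated statistic ``t = logFC / (s_tilde * sqrt(1/n1 + 1/n2))`` is
referred to a t distribution on ``d0 + d`` degrees of freedom, and
p-values are Benjamini-Hochberg adjusted across genes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import CASE, CONTROL, DifferentialResult, validate_expression, validate_phenotype

log = logging.getLogger(__name__)

__all__ = ["moderated_t_test", "bh_adjust", "de_gene_set", "fit_variance_prior", "trigamma_inverse"]


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on a convex scale)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from gene-wise variances.

    Works on ``e_g = log s_g^2 - digamma(d/2) + log(d/2)`` whose mean and
    variance identify the prior; a non-positive excess variance means the
    variances are essentially exchangeable and the prior df is infinite
    (fully pooled variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        log.info("variance moments imply infinite prior df; pooling variances")
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_test(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    study_id: str = "study",
    d0_override: float | None = None,
) -> DifferentialResult:
    """Empirical-Bayes moderated two-group t test per gene.

    ``d0_override`` forces the prior df (0 disables moderation entirely,
    reproducing the ordinary pooled-variance t test); by default the prior
    is estimated from the data.
    """
    validate_expression(expr)
    validate_phenotype(phenotype, expr)
    case_ids = phenotype.index[phenotype == CASE]
    ctrl_ids = phenotype.index[phenotype == CONTROL]
    n1, n2 = len(case_ids), len(ctrl_ids)
    if min(n1, n2) < 2:
        raise ValueError("both groups need at least 2 samples")
    xc = expr[case_ids].to_numpy()
    xk = expr[ctrl_ids].to_numpy()
    logfc = xc.mean(axis=1) - xk.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xk - xk.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if d0_override is None:
        d0, s0_2 = fit_variance_prior(s2, d)
    else:
        d0 = float(d0_override)
        s0_2 = fit_variance_prior(s2, d)[1] if d0 != 0 else 0.0

    if d0 == 0:
        s2_tilde = s2.copy()
        df_total = float(d)
    elif np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    df_eff = min(df_total, 1e12)  # scipy handles huge df as the normal limit
    p = 2.0 * stats.t.sf(np.abs(t), df_eff)

    dead = s2 == 0
    if d0 == 0 and dead.any():
        log.warning("%d genes with zero residual variance: p forced to 1", int(dead.sum()))
        t = np.where(dead, 0.0, t)
        p = np.where(dead, 1.0, p)
    elif dead.any():
        # moderation lends these genes a positive variance, but a gene flat
        # in both groups still carries no evidence: follow the same rule
        flat = dead & (logfc == 0)
        if flat.any():
            t = np.where(flat, 0.0, t)
            p = np.where(flat, 1.0, p)

    table = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "p_adj": bh_adjust(p)},
        index=expr.index.copy(),
    )
    return DifferentialResult(table=table, study_id=study_id)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def de_gene_set(result: DifferentialResult, alpha: float = 0.05) -> set[str]:
    """Genes called differentially expressed at BH-adjusted p < alpha."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return set(result.table.index[result.table["p_adj"] < alpha])
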