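"""Statistical primitives used across the pipeline.

Implements the empirical-Bayes moderated t-test (variance shrinkage across
genes), exact tests for contingency tables (2x2 and the Freeman-Halton r x c
extension), Wilson score intervals for binomial proportions, and Welch's
t-test.  Standard pieces (the 2x2 exact test, the Wilson interval, Welch)
delegate to scipy/statsmodels; the moderated t and the r x c enumeration are
implemented here.

Moderated t model
-----------------
For gene g a linear model with residual variance ``s2_g`` on ``d_g`` degrees
of freedom is combined with a scaled inverse-chi-square prior
``1/sigma2_g ~ chi2_{d0} / (d0 * s0^2)``.  The posterior variance is

    s2_tilde_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t is the ordinary t with ``s2_tilde_g`` in place of
``s2_g``, referred to a t distribution on ``d0 + d_g`` degrees of freedom.
The hyperparameters ``(d0, s0^2)`` are fitted by the method of moments on the
log sample variances (matching marginal mean and variance of ``log s2_g``
under the scaled-F marginal, with the trigamma equation solved by Newton
iteration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.proportion import proportion_confint

from .cohort_io import ExpressionMatrix

__all__ = [
    "EnumerationLimitError",
    "ModeratedTResult",
    "moderated_t",
    "fit_variance_prior",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "wilson_ci",
    "welch_t_test",
]


class EnumerationLimitError(RuntimeError):
    """Exact r x c enumeration would exceed the configured table budget."""


@dataclass(frozen=True)
class ModeratedTResult:
    """Per-gene moderated-t output plus the fitted global variance prior."""

    gene_ids: list[str]
    effect: np.ndarray        # slope estimate per gene
    s2: np.ndarray            # residual variance per gene
    df_residual: np.ndarray   # residual df per gene
    s2_post: np.ndarray       # posterior (shrunken) variance per gene
    t: np.ndarray             # moderated t statistic
    p: np.ndarray             # two-sided p-value
    df_prior: float           # d0 (may be inf)
    s2_prior: float           # s0^2

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"effect": self.effect, "s2": self.s2, "t": self.t, "p": self.p},
            index=pd.Index(self.gene_ids, name="gene"),
        )


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for trigamma inverse
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / np.maximum(y, 1e-12) < 1e-10):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit (d0, s0^2) by moments of log sample variances.

    Returns ``(inf, exp(mean adjusted log-variance))`` when the empirical
    spread of log variances is no larger than expected from sampling alone
    (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(np.mean(e))
    # excess variance of e beyond the sampling contribution trigamma(d/2)
    n = e.size
    excess = float(np.mean((e - ebar) ** 2 * n / (n - 1) -
                           special.polygamma(1, d / 2.0)))
    if excess <= 0:
        return math.inf, float(np.exp(ebar))
    d0 = 2.0 * float(_trigamma_inverse(np.array([excess]))[0])
    s0_2 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(
    expr: ExpressionMatrix,
    response,
    *,
    gene_as_predictor: bool = False,
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated t for every gene against one response.

    By default each gene's expression is regressed on the response
    (design: intercept + response); with ``gene_as_predictor=True`` the
    roles are swapped and the common response is regressed on each gene's
    expression (the construction used for cancer-gene selection, where the
    response is a vector of baseline-model residuals).

    ``prior_df`` overrides the fitted prior df: 0 reproduces the ordinary
    per-gene t-test, ``inf`` forces complete shrinkage to the pooled
    variance.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    if n != len(expr.sample_ids):
        raise ValueError("response length does not match sample count")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(y) == 0 and not gene_as_predictor:
        raise ValueError("response is constant")

    X = expr.values  # genes x samples
    G = X.shape[0]
    dfres = np.full(G, float(n - 2))

    if gene_as_predictor:
        # per gene: response ~ 1 + gene
        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sxx = np.einsum("gs,gs->g", xc, xc)
        degenerate = sxx <= 0
        sxx_safe = np.where(degenerate, 1.0, sxx)
        beta = (xc @ yc) / sxx_safe
        rss = np.maximum(yc @ yc - beta**2 * sxx_safe, 0.0)
        s2 = rss / (n - 2)
        v = 1.0 / sxx_safe  # unscaled variance of the slope
    else:
        # per gene: gene ~ 1 + response
        yc = y - y.mean()
        syy = float(yc @ yc)
        if syy <= 0:
            raise ValueError("response is constant")
        xc = X - X.mean(axis=1, keepdims=True)
        beta = (xc @ yc) / syy
        rss = np.maximum(np.einsum("gs,gs->g", xc, xc) - beta**2 * syy, 0.0)
        s2 = rss / (n - 2)
        v = np.full(G, 1.0 / syy)
        degenerate = np.zeros(G, dtype=bool)

    if prior_df is None:
        d0, s0_2 = fit_variance_prior(s2, dfres)
    else:
        d0 = float(prior_df)
        if math.isinf(d0):
            _, s0_2 = fit_variance_prior(s2, dfres)
        elif d0 == 0:
            s0_2 = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
        else:
            _, s0_2 = fit_variance_prior(s2, dfres)

    if math.isinf(d0):
        s2_post = np.full(G, s0_2)
        df_total = np.full(G, math.inf)
    else:
        s2_post = (d0 * s0_2 + dfres * s2) / (d0 + dfres)
        df_total = d0 + dfres

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / np.sqrt(s2_post * v)
    tstat[degenerate] = 0.0
    if math.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return ModeratedTResult(
        gene_ids=expr.gene_ids, effect=beta, s2=s2, df_residual=dfres,
        s2_post=s2_post, t=tstat, p=p, df_prior=d0, s2_prior=s0_2)


# ---------------------------------------------------------------------------
# exact tests for contingency tables
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("contingency table entries must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Two-sidedness by probability-mass ordering: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def fisher_exact_rxc(
    table,
    *,
    max_tables: int = 5_000_000,
    monte_carlo: bool = False,
    n_sim: int = 100_000,
    seed: int | None = None,
) -> float:
    """Freeman-Halton exact test for an r x c table.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table
    (relative tolerance 1e-7, matching common implementations).  All-zero
    rows/columns are dropped first.  If the enumeration would visit more
    than ``max_tables`` tables, raises :class:`EnumerationLimitError`
    unless ``monte_carlo=True``, in which case the p-value is estimated by
    sampling tables with fixed margins via random label permutation.
    """
    t = _as_table(table)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0:
        raise ValueError("table has no positive entries")
    if 1 in t.shape:
        return 1.0  # a single row or column is fully determined by margins
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())

    lf = special.gammaln(np.arange(n + 1) + 1.0)  # log factorials

    def log_prob(tab_flat: np.ndarray) -> float:
        return float(lf[row].sum() + lf[col].sum() - lf[n]
                     - lf[tab_flat].sum())

    lp_obs = log_prob(t.ravel())
    tol = 1e-7

    if monte_carlo:
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(len(col)), col)
        rows_rep = np.repeat(np.arange(len(row)), row)
        hits = 0
        for _ in range(n_sim):
            perm = rng.permutation(labels)
            sim = np.zeros_like(t)
            np.add.at(sim, (rows_rep, perm), 1)
            if log_prob(sim.ravel()) <= lp_obs + tol:
                hits += 1
        return float((hits + 1) / (n_sim + 1))

    r, c = t.shape
    total = 0.0
    count = 0
    colsum = col.astype(np.int64)

    def recurse(ri: int, remaining_col: np.ndarray, lp_partial: float):
        nonlocal total, count
        if ri == r - 1:
            # last row fully determined
            count += 1
            if count > max_tables:
                raise EnumerationLimitError(
                    f"more than {max_tables} tables with these margins; "
                    "use monte_carlo=True with a seed")
            lp = lp_partial - float(lf[remaining_col].sum())
            if lp <= lp_obs + tol:
                total += math.exp(lp)
            return
        # enumerate row ri cell by cell
        def fill(ci: int, left_in_row: int, rem_col: np.ndarray,
                 lp_cells: float):
            if ci == c - 1:
                x = left_in_row
                if x > rem_col[ci]:
                    return
                rem2 = rem_col.copy()
                rem2[ci] -= x
                # feasibility: remaining rows can absorb remaining columns
                recurse(ri + 1, rem2, lp_cells - float(lf[x]))
                return
            hi = min(left_in_row, rem_col[ci])
            for x in range(hi + 1):
                rem2 = rem_col.copy()
                rem2[ci] -= x
                fill(ci + 1, left_in_row - x, rem2, lp_cells - float(lf[x]))

        fill(0, int(row[ri]), remaining_col, lp_partial)

    base = float(lf[row].sum() + lf[col].sum() - lf[n])
    recurse(0, colsum, base)
    return float(min(total, 1.0))


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def welch_t_test(x, y) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
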