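"""Per-probe two-group differential expression with moderated t statistics.

The model is the standard small-sample workhorse for expression panels: an
independent two-group linear model per probe on the log2 scale (robust Huber
IRLS by default), empirical-Bayes shrinkage of the per-probe residual
variances toward an ensemble prior, and Benjamini–Hochberg control of the
false discovery rate.

Variance moderation follows the scaled inverse-chi-square hierarchy: with
per-probe residual variances ``s_g^2`` on ``df`` degrees of freedom and a
prior ``s0^2`` on ``d0`` degrees of freedom, the posterior variance is

    s_tilde^2 = (d0*s0^2 + df*s^2) / (d0 + df)

and the moderated t = coef / (s_tilde * stdev_unscaled) is referred to a t
distribution on ``d0 + df`` degrees of freedom. The hyperparameters (d0,
s0^2) are estimated by moment matching on the log residual variances via
digamma/trigamma inversion; when the trigamma equation has no positive
solution the variances are fully pooled (d0 = infinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "DEFit",
    "DEResults",
    "TwoGroupDE",
    "fit_two_group",
    "ebayes_moderate",
    "benjamini_hochberg",
    "volcano_table",
]


class DEError(ValueError):
    pass


@dataclass
class DEFit:
    """Per-probe two-group fit: coefficient (log2 fold change alt - ref),
    its standard error, the residual df and residual sd."""

    probes: pd.Index
    coef: np.ndarray
    se: np.ndarray
    df: float
    sigma: np.ndarray
    stdev_unscaled: np.ndarray
    contrast: tuple[str, str]
    robust: bool
    notes: list = field(default_factory=list)


def _as_frame(expr) -> pd.DataFrame:
    if hasattr(expr, "values") and isinstance(getattr(expr, "values"), pd.DataFrame):
        return expr.values  # ExpressionMatrix
    if isinstance(expr, pd.DataFrame):
        return expr
    raise DEError("expr must be a DataFrame or ExpressionMatrix")


def fit_two_group(expr, labels, robust: bool = True, contrast=None) -> DEFit:
    """Fit an independent two-group model to every probe.

    ``labels`` aligns with the sample columns and must take exactly two
    values, each on >= 2 samples. The coefficient is the (alt - ref) group
    difference on the log2 scale; ``contrast=(ref, alt)`` fixes the
    orientation (default: sorted label order).

    With ``robust`` the per-probe fit is iteratively reweighted least squares
    with Huber weights (tuning constant 1.345, <=50 iterations, tol 1e-8);
    probes where the robust scale degenerates fall back to the ordinary fit
    with a logged note.
    """
    frame = _as_frame(expr)
    labels = np.asarray(labels)
    if labels.shape[0] != frame.shape[1]:
        raise DEError("labels must align with expression columns")
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise DEError(f"exactly two label levels required, got {levels}")
    if contrast is None:
        ref, alt = levels
    else:
        ref, alt = contrast
        if set((ref, alt)) != set(levels):
            raise DEError(f"contrast {contrast} does not match labels {levels}")
    m_ref, m_alt = labels == ref, labels == alt
    n1, n2 = int(m_ref.sum()), int(m_alt.sum())
    if n1 < 2 or n2 < 2:
        raise DEError(f"each group needs >=2 samples (got {ref}:{n1}, {alt}:{n2})")
    Y = frame.to_numpy(dtype=float)
    df_resid = float(n1 + n2 - 2)
    su = float(np.sqrt(1.0 / n1 + 1.0 / n2))
    notes: list = []

    # ordinary (pooled two-sample) fit, fully vectorised
    mu1 = Y[:, m_ref].mean(axis=1)
    mu2 = Y[:, m_alt].mean(axis=1)
    ss = ((Y[:, m_ref] - mu1[:, None]) ** 2).sum(axis=1) + (
        (Y[:, m_alt] - mu2[:, None]) ** 2
    ).sum(axis=1)
    sigma = np.sqrt(ss / df_resid)
    coef = mu2 - mu1
    se = sigma * su

    if robust:
        import statsmodels.api as sm

        X = np.column_stack([np.ones(n1 + n2), m_alt.astype(float)])
        for i in range(Y.shape[0]):
            y = Y[i]
            if np.ptp(y) == 0:  # constant probe: robust fit is degenerate
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
                        maxiter=50, tol=1e-8
                    )
                scale = float(res.scale)
                if not np.isfinite(scale) or scale <= 0:
                    raise ValueError("degenerate robust scale")
                coef[i] = res.params[1]
                se[i] = res.bse[1]
                sigma[i] = scale
            except Exception as exc:  # pragma: no cover - rare numerical failures
                notes.append(f"probe {frame.index[i]}: robust fit failed ({exc}); ordinary fit used")

    with np.errstate(divide="ignore", invalid="ignore"):
        stdev_unscaled = np.where(sigma > 0, se / np.where(sigma > 0, sigma, 1.0), su)
    return DEFit(
        probes=frame.index,
        coef=coef,
        se=se,
        df=df_resid,
        sigma=sigma,
        stdev_unscaled=stdev_unscaled,
        contrast=(ref, alt),
        robust=robust,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# empirical Bayes


def trigamma_inverse(y: float, tol: float = 1e-10, maxiter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(maxiter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < tol:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log residual variances.

    Returns ``(inf, s0^2)`` when the excess variance of the log variances is
    non-positive (fully pooled case).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise DEError("all residual variances are zero; use ordinary t statistics")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
    return d0, s0_2


def ebayes_moderate(fit: DEFit, prior_df: float | None = None, prior_var: float | None = None):
    """Moderated t and p per probe. ``prior_df``/``prior_var`` override the
    moment-matched hyperparameters (``prior_df=0`` gives the ordinary t;
    ``prior_df=inf`` fully pools the variances)."""
    s2 = fit.sigma**2
    df = fit.df
    if df < 1:
        raise DEError("residual df must be >= 1")
    if prior_df is None:
        if len(fit.probes) < 10:
            raise DEError("hyperparameter estimation needs >= 10 probes; pass prior_df")
        d0, s0_2 = estimate_variance_prior(s2, df)
        if prior_var is not None:
            s0_2 = prior_var
    else:
        d0 = float(prior_df)
        s0_2 = prior_var if prior_var is not None else (
            estimate_variance_prior(s2, df)[1] if d0 > 0 else 0.0
        )
    if d0 == 0:
        post_s2 = s2
        total_df = df
    elif np.isinf(d0):
        post_s2 = np.full_like(s2, s0_2)
        total_df = np.inf
    else:
        post_s2 = (d0 * s0_2 + df * s2) / (d0 + df)
        total_df = d0 + df
    denom = np.sqrt(post_s2) * fit.stdev_unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, fit.coef / np.where(denom > 0, denom, 1.0), 0.0)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return pd.DataFrame(
        {
            "logFC": fit.coef,
            "se": fit.se,
            "t": t,
            "p": p,
            "posterior_sd": np.sqrt(post_s2),
        },
        index=fit.probes,
    ), d0, s0_2


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(pvalues, fdr: float = 0.01):
    """BH step-up q-values and rejection flags.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; flag = (q <= fdr).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DEError("pvalues must be a vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DEError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    flags = q <= fdr
    return q, flags


def volcano_table(result: pd.DataFrame, fdr_flags=None) -> pd.DataFrame:
    """Plot-ready (logFC, -log10 p, flag) table; the FDR cut is attached as
    ``.attrs['p_cutoff']`` — the largest p among rejected hypotheses."""
    tab = pd.DataFrame(
        {
            "logFC": result["logFC"],
            "neg_log10_p": -np.log10(result["p"].clip(lower=np.finfo(float).tiny)),
            "flag": result["flag"] if fdr_flags is None else np.asarray(fdr_flags),
        },
        index=result.index,
    )
    tab.loc[result["p"] >= 1.0, "neg_log10_p"] = 0.0
    flagged = result.loc[tab["flag"], "p"]
    tab.attrs["p_cutoff"] = float(flagged.max()) if len(flagged) else float("nan")
    return tab


# ---------------------------------------------------------------------------
# model / results objects


class TwoGroupDE:
    """Two-group moderated differential expression model.

    Parameters
    ----------
    expr : ExpressionMatrix or DataFrame
        Probe x sample log2 expression.
    labels : sequence
        Group label per sample column (exactly two levels).
    contrast : (ref, alt), optional
        Orientation of the reported log fold change (alt minus ref).
    robust : bool
        Huber IRLS per probe (default) vs ordinary least squares.
    """

    def __init__(self, expr, labels, contrast=None, robust: bool = True):
        self.expr = _as_frame(expr)
        self.labels = np.asarray(labels)
        self.contrast = contrast
        self.robust = robust

    @classmethod
    def from_dataframe(cls, expr: pd.DataFrame, metadata: pd.DataFrame, contrast, **kw):
        """Build from an expression frame plus a metadata table with
        ``sample_id`` and ``group`` columns, subsetting to the two contrast
        groups."""
        ref, alt = contrast
        meta = metadata.set_index("sample_id")["group"]
        keep = [s for s in expr.columns if meta.get(s) in (ref, alt)]
        if not keep:
            raise DEError(f"no samples match contrast {contrast}")
        return cls(expr[keep], meta.loc[keep].to_numpy(), contrast=contrast, **kw)

    def fit(self, moderate: bool = True, fdr: float = 0.01, prior_df: float | None = None):
        defit = fit_two_group(self.expr, self.labels, robust=self.robust, contrast=self.contrast)
        if not moderate:
            prior_df = 0.0
        if prior_df is None and len(defit.probes) < 10:
            warnings.warn(
                "fewer than 10 probes: variance moderation skipped (ordinary t)",
                stacklevel=2,
            )
            prior_df = 0.0
        tab, d0, s0_2 = ebayes_moderate(defit, prior_df=prior_df)
        q, flags = benjamini_hochberg(tab["p"].to_numpy(), fdr=fdr)
        tab["q"] = q
        tab["flag"] = flags
        return DEResults(tab, defit, fdr=fdr, prior_df=d0, prior_var=s0_2)


class DEResults:
    """Fitted two-group DE results: per-probe logFC, moderated t, p, BH q."""

    def __init__(self, table: pd.DataFrame, fit: DEFit, fdr: float, prior_df: float, prior_var: float):
        self.table = table
        self.fit = fit
        self.fdr = fdr
        self.prior_df = prior_df
        self.prior_var = prior_var

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["flag"]]

    def volcano_table(self) -> pd.DataFrame:
        return volcano_table(self.table)

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        tab = self.volcano_table()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(tab["logFC"], tab["neg_log10_p"], s=10, c="0.6", label="not significant")
        sig = tab[tab["flag"]]
        if len(sig):
            ax.scatter(sig["logFC"], sig["neg_log10_p"], s=14, c="crimson", label="significant")
        cutoff = tab.attrs.get("p_cutoff")
        if cutoff and np.isfinite(cutoff):
            ax.axhline(-np.log10(cutoff), ls="--", c="k", lw=0.8)
        ax.set_xlabel(f"log2 fold change ({self.fit.contrast[1]} - {self.fit.contrast[0]})")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self, top: int = 10) -> str:
        ref, alt = self.fit.contrast
        n_sig = int(self.table["flag"].sum())
        lines = [
            "Two-group moderated differential expression",
            f"  contrast: {alt} - {ref}   robust: {self.fit.robust}",
            f"  probes: {len(self.table)}   residual df: {self.fit.df:g}   "
            f"prior df: {self.prior_df:g}   prior var: {self.prior_var:.4g}",
            f"  significant at BH FDR {self.fdr:g}: {n_sig}",
            "",
            self.table.sort_values("p").head(top).to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)
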