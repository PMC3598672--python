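"""Cell-specific expression deconvolution for whole-blood profiles.

Whole blood is a mixture: the measured expression of a probe is the
fraction-weighted sum of its expression in the constituent leukocyte
populations. Within each subject group g the model is a multiple regression
of expression onto the relative cell-type frequencies *through the origin*
(zero cells contribute zero signal):

    y_g = beta_1g * x_1g + ... + beta_Kg * x_Kg + eps_g

so beta_kg is the mean expression attributable to cell type k in group g.
Two groups are compared per cell type with a Wald-like statistic whose
standard error pools the per-group coefficient SEs with sample-size weights:

    t_k21 = (beta_k2 - beta_k1) / se_k21,
    se_k21 = sqrt((n1*se_k1^2 + n2*se_k2^2) / (n1 + n2))

and significance is assessed against an empirical null built by reshuffling
the group labels (each sample's expression/fraction pair travels intact),
with the two-sided (b+1)/(B+1) p-value convention.

Fractions are carried on the 0-1 scale. The per-percent coefficient the
field usually quotes is the 0-1-scale coefficient times 0.01; the scale
choice cancels exactly in t_k21.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellFractions",
    "CellRegressionFit",
    "GRANULOCYTE_PBMC",
    "group_cell_fractions",
    "fit_cell_regression",
    "cssam_statistic",
    "permutation_test",
    "deconvolve_contrast",
    "CellDeconvolution",
    "DeconvResults",
]


class DeconvolutionError(ValueError):
    pass


GRANULOCYTE_PBMC: dict[str, tuple[str, ...]] = {
    "granulocytes": ("neutrophils", "eosinophils", "basophils"),
    "pbmc": ("lymphocytes", "monocytes"),
}

IDENTITY_SCHEME: dict[str, tuple[str, ...]] = {
    c: (c,) for c in ("neutrophils", "lymphocytes", "monocytes", "eosinophils", "basophils")
}


@dataclass
class CellFractions:
    """Sample x cell-type proportions; rows renormalized to sum to 1."""

    frame: pd.DataFrame
    source: str = "raw"

    def __post_init__(self) -> None:
        vals = self.frame.to_numpy(dtype=float)
        if (vals < 0).any():
            bad = self.frame.index[(vals < 0).any(axis=1)][0]
            raise DeconvolutionError(f"negative fraction in sample {bad!r}")
        totals = vals.sum(axis=1)
        if (totals <= 0).any():
            bad = self.frame.index[totals <= 0][0]
            raise DeconvolutionError(f"sample {bad!r} has zero total fraction")
        self.frame = self.frame.div(totals, axis=0)

    @property
    def celltypes(self) -> list[str]:
        return list(self.frame.columns)

    def to_numpy(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "sample_id"
        out.to_csv(path)

    @staticmethod
    def from_csv(path, source: str = "file") -> "CellFractions":
        return CellFractions(pd.read_csv(path, index_col=0), source=source)


def group_cell_fractions(differentials: pd.DataFrame, scheme=None) -> CellFractions:
    """Collapse leukocyte differential percentages into grouped fractions.

    The default scheme sums neutrophils+eosinophils+basophils into
    granulocytes and lymphocytes+monocytes into PBMC; rows are renormalized
    to sum to 1 (printed differentials need not close to 100%).
    """
    scheme = GRANULOCYTE_PBMC if scheme is None else scheme
    numeric = differentials.apply(pd.to_numeric, errors="coerce")
    if (numeric < 0).any().any():
        bad = numeric.columns[(numeric < 0).any()][0]
        raise DeconvolutionError(f"negative percentage in column {bad!r}")
    cols = {c.lower(): c for c in differentials.columns}
    out = {}
    for gname, members in scheme.items():
        missing = [m for m in members if m.lower() not in cols]
        if missing:
            raise DeconvolutionError(f"missing leukocyte class column(s): {missing}")
        out[gname] = sum(
            pd.to_numeric(differentials[cols[m.lower()]]) for m in members
        )
    frame = pd.DataFrame(out, index=differentials.index)
    return CellFractions(frame, source="grouped")


@dataclass
class CellRegressionFit:
    """Zero-intercept regression of one probe's expression on cell fractions
    within one group."""

    group: str
    beta: pd.Series
    se: pd.Series
    n: int
    df: int
    sigma: float
    resid: np.ndarray


def _design(fractions) -> tuple[np.ndarray, list[str], pd.Index]:
    if isinstance(fractions, CellFractions):
        return fractions.to_numpy(), fractions.celltypes, fractions.frame.index
    if isinstance(fractions, pd.DataFrame):
        return fractions.to_numpy(dtype=float), list(fractions.columns), fractions.index
    arr = np.asarray(fractions, dtype=float)
    return arr, [f"cell{k + 1}" for k in range(arr.shape[1])], pd.RangeIndex(arr.shape[0])


def fit_cell_regression(y, fractions, group: str = "") -> CellRegressionFit:
    """Least squares through the origin: beta = (X'X)^-1 X'y with SEs from
    the residual variance on n - K degrees of freedom."""
    X, names, _ = _design(fractions)
    y = np.asarray(y, dtype=float).ravel()
    n, K = X.shape
    if y.shape[0] != n:
        raise DeconvolutionError("expression vector must align with fraction rows")
    if n < K + 1:
        warnings.warn(
            f"n={n} samples for K={K} cell types leaves {n - K} residual df",
            stacklevel=2,
        )
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < K:
        raise DeconvolutionError(
            "fraction matrix is rank deficient; consider merging cell types"
        )
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - K
    if df > 0:
        sigma2 = float(resid @ resid) / df
    else:
        sigma2 = np.nan
    se = np.sqrt(np.maximum(sigma2, 0.0) * np.diag(xtx_inv))
    return CellRegressionFit(
        group=group,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        n=n,
        df=df,
        sigma=float(np.sqrt(sigma2)) if df > 0 else float("nan"),
        resid=resid,
    )


def cssam_statistic(fit1: CellRegressionFit, fit2: CellRegressionFit, k=None):
    """Between-group statistic per cell type:
    t = (beta_k2 - beta_k1) / sqrt((n1*se1^2 + n2*se2^2)/(n1+n2)).

    With ``k`` a single cell-type name returns scalars ``(t, pooled_se)``;
    otherwise Series over the shared cell types. A zero pooled SE yields
    t = 0 for equal coefficients and signed infinity (with a warning)
    otherwise.
    """
    common = [c for c in fit1.beta.index if c in fit2.beta.index]
    if not common:
        raise DeconvolutionError("fits share no cell types")
    b1, b2 = fit1.beta[common], fit2.beta[common]
    se1, se2 = fit1.se[common], fit2.se[common]
    n1, n2 = fit1.n, fit2.n
    pooled = np.sqrt((n1 * se1**2 + n2 * se2**2) / (n1 + n2))
    diff = b2 - b1
    t = pd.Series(0.0, index=pd.Index(common))
    nz = pooled > 0
    t[nz] = diff[nz] / pooled[nz]
    degenerate = (~nz) & (diff != 0)
    if degenerate.any():
        warnings.warn("zero pooled SE with unequal coefficients -> infinite statistic",
                      stacklevel=2)
        t[degenerate] = np.sign(diff[degenerate]) * np.inf
    if k is not None:
        return float(t[k]), float(pooled[k])
    return t, pooled


# ---------------------------------------------------------------------------
# batched zero-intercept fits over permutations


def _batched_group_stats(y, X, masks):
    """Per-permutation zero-intercept fits within a boolean sample mask.

    ``masks``: (B, n) booleans selecting the group's samples in each
    permutation. Returns (beta (B,K), se2 (B,K), ok (B,)) where ok flags
    permutations with an invertible within-group design.
    """
    M = masks.astype(float)
    B, n = M.shape
    K = X.shape[1]
    A = np.einsum("bi,ik,il->bkl", M, X, X)
    c = np.einsum("bi,ik,i->bk", M, X, y)
    det = np.linalg.det(A)
    ok = np.abs(det) > 1e-12 * (np.trace(A, axis1=1, axis2=2) / K + 1e-300) ** K
    beta = np.zeros((B, K))
    se2 = np.zeros((B, K))
    if ok.any():
        Aok = A[ok]
        Ainv = np.linalg.inv(Aok)
        beta_ok = np.einsum("bkl,bl->bk", Ainv, c[ok])
        pred = beta_ok @ X.T  # (Bok, n)
        rss = np.einsum("bi,bi->b", M[ok], (y[None, :] - pred) ** 2)
        ng = M[ok].sum(axis=1)
        df = ng - K
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = np.where(df > 0, rss / np.maximum(df, 1), np.nan)
        diag = np.einsum("bkk->bk", Ainv)
        beta[ok] = beta_ok
        se2[ok] = sigma2[:, None] * diag
    return beta, se2, ok


def _perm_t(y, X, mask1, n1, n2):
    """csSAM t per cell type for each permutation given group-1 masks."""
    b1, s1, ok1 = _batched_group_stats(y, X, mask1)
    b2, s2, ok2 = _batched_group_stats(y, X, ~mask1)
    pooled2 = (n1 * s1 + n2 * s2) / (n1 + n2)
    # a pooled SE at floating-point noise level means an exact within-group
    # fit (e.g. constant expression): the statistic is defined as zero there
    tol = (1e-9 * (np.abs(y).max() + 1.0)) ** 2
    defined = pooled2 > tol
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(defined, (b2 - b1) / np.sqrt(np.where(defined, pooled2, 1.0)), 0.0)
    return t, ok1 & ok2


def permutation_test(
    y,
    fractions,
    labels,
    B: int = 1000,
    seed=0,
    contrast=None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Empirical two-sided p per cell type from B label reshuffles.

    Each sample's (expression, fractions) pair stays intact; only the group
    labels move — the statistic is exchangeable under the null of no
    between-group difference in cell-specific expression. p = (1 + #{|t_b| >=
    |t_obs|}) / (B + 1), so the smallest attainable p is 1/(B+1).
    Permutations whose within-group design is singular are resampled (with a
    logged warning).
    """
    if B < 1:
        raise DeconvolutionError("B must be >= 1")
    X, names, _ = _design(fractions)
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise DeconvolutionError(f"exactly two label levels required, got {levels}")
    g1, g2 = (levels if contrast is None else contrast)
    if set((g1, g2)) != set(levels):
        raise DeconvolutionError(f"contrast {contrast} does not match labels {levels}")
    obs_mask1 = labels == g1
    n1, n2 = int(obs_mask1.sum()), int((~obs_mask1).sum())
    n = n1 + n2
    K = X.shape[1]

    t_obs, ok = _perm_t(y, X, obs_mask1[None, :], n1, n2)
    if not ok[0]:
        raise DeconvolutionError("observed within-group design is singular")
    t_obs = t_obs[0]

    rng = np.random.default_rng(seed) if rng is None else rng
    t_perm = np.empty((0, K))
    needed = B
    attempts = 0
    while needed > 0:
        draw = max(needed, 1)
        perm = np.tile(np.arange(n), (draw, 1))
        perm = rng.permuted(perm, axis=1)
        mask1 = np.zeros((draw, n), dtype=bool)
        np.put_along_axis(mask1, perm[:, :n1], True, axis=1)
        t_b, ok_b = _perm_t(y, X, mask1, n1, n2)
        if not ok_b.all():
            warnings.warn(
                f"{int((~ok_b).sum())} singular permutation(s) resampled", stacklevel=2
            )
        t_perm = np.vstack([t_perm, t_b[ok_b]])
        needed = B - t_perm.shape[0]
        attempts += 1
        if attempts > 50:
            raise DeconvolutionError("could not draw enough non-singular permutations")
    t_perm = t_perm[:B]

    exceed = (np.abs(t_perm) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (B + 1.0)

    fit1 = fit_cell_regression(y[obs_mask1], X[obs_mask1], group=str(g1))
    fit2 = fit_cell_regression(y[~obs_mask1], X[~obs_mask1], group=str(g2))
    fit1.beta.index = fit1.se.index = pd.Index(names)
    fit2.beta.index = fit2.se.index = pd.Index(names)
    _, pooled = cssam_statistic(fit1, fit2)
    return pd.DataFrame(
        {
            "cell_type": names,
            "beta_g1": fit1.beta.to_numpy(),
            "se_g1": fit1.se.to_numpy(),
            "beta_g2": fit2.beta.to_numpy(),
            "se_g2": fit2.se.to_numpy(),
            "t": t_obs,
            "pooled_se": pooled.to_numpy(),
            "p_perm": p,
            "B": B,
            "group1": str(g1),
            "group2": str(g2),
        }
    )


def deconvolve_contrast(
    expr, fractions, labels, probes=None, B: int = 1000, seed=0, contrast=None
) -> pd.DataFrame:
    """Run the per-cell-type comparison for each requested probe.

    ``expr`` is a probe x sample frame (or ExpressionMatrix); ``fractions``
    aligns with its sample columns. Returns one row per probe x cell type.
    """
    frame = expr.values if hasattr(expr, "provenance") else expr
    if probes is None:
        probes = list(frame.index)
    missing = [p for p in probes if p not in frame.index]
    if missing:
        raise DeconvolutionError(f"probe(s) not in expression matrix: {missing}")
    ss = np.random.SeedSequence(seed)
    out = []
    for probe, child in zip(probes, ss.spawn(len(probes))):
        tab = permutation_test(
            frame.loc[probe].to_numpy(),
            fractions,
            labels,
            B=B,
            contrast=contrast,
            rng=np.random.default_rng(child),
        )
        tab.insert(0, "probe", probe)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# model / results objects


class CellDeconvolution:
    """Cell-specific expression contrast model.

    Parameters
    ----------
    expr : probe x sample DataFrame (log2 expression) or ExpressionMatrix
    fractions : CellFractions or DataFrame aligned with the samples
    labels : group label per sample (or a metadata frame with sample_id/group)
    """

    def __init__(self, expr, fractions, labels):
        self.expr = expr.values if hasattr(expr, "provenance") else expr
        if isinstance(labels, pd.DataFrame):
            labels = labels.set_index("sample_id").loc[list(self.expr.columns), "group"].to_numpy()
        self.labels = np.asarray(labels)
        if not isinstance(fractions, CellFractions):
            fractions = CellFractions(pd.DataFrame(fractions))
        if isinstance(fractions.frame.index, pd.Index) and set(self.expr.columns) <= set(
            fractions.frame.index
        ):
            fractions = CellFractions(
                fractions.frame.loc[list(self.expr.columns)], source=fractions.source
            )
        self.fractions = fractions

    def fit(self, contrast, probes=None, B: int = 1000, seed=0) -> "DeconvResults":
        mask = np.isin(self.labels, list(contrast))
        expr = self.expr.loc[:, mask]
        frac = CellFractions(self.fractions.frame.loc[expr.columns], source=self.fractions.source)
        table = deconvolve_contrast(
            expr, frac, self.labels[mask], probes=probes, B=B, seed=seed, contrast=contrast
        )
        return DeconvResults(table, contrast=contrast, B=B, seed=seed)


class DeconvResults:
    """Per-probe, per-cell-type group comparison results."""

    def __init__(self, table: pd.DataFrame, contrast, B: int, seed):
        self.table = table
        self.contrast = tuple(contrast)
        self.B = B
        self.seed = seed

    def summary(self) -> str:
        g1, g2 = self.contrast
        lines = [
            "Cell-specific expression contrast (zero-intercept group regressions,",
            f"  pooled-SE Wald-like statistic, {self.B}-permutation empirical p)",
            f"  contrast: {g2} vs {g1}   seed: {self.seed}",
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def plot_bars(self, probe=None, ax=None):
        """Grouped bar chart of per-cell-type coefficients with SE whiskers."""
        import matplotlib.pyplot as plt

        tab = self.table
        if probe is not None:
            tab = tab[tab["probe"] == probe]
        if ax is None:
            _, ax = plt.subplots()
        idx = np.arange(len(tab))
        w = 0.38
        ax.bar(idx - w / 2, tab["beta_g1"], w, yerr=tab["se_g1"], capsize=3,
               color="0.6", label=str(self.contrast[0]))
        ax.bar(idx + w / 2, tab["beta_g2"], w, yerr=tab["se_g2"], capsize=3,
               color="white", edgecolor="k", label=str(self.contrast[1]))
        ax.set_xticks(idx, tab["cell_type"])
        ax.set_ylabel("cell-specific expression (log2 units / unit fraction)")
        ax.legend(frameon=False, fontsize=8)
        return ax
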