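"""Simulation benchmarks: oracle equivalence, calibration and power.

These harnesses exercise the package end to end against independent oracles
(closed-form normal equations, brute-force step-up, analytic hand values)
and against its own synthetic ground truth. They are used by the test suite
and by the reproduction script; problem sizes are chosen so each harness
runs in seconds to minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import demo_subjects, summarize_cohort
from .de import TwoGroupDE, benjamini_hochberg, ebayes_moderate, fit_two_group
from .deconvolution import (
    CellRegressionFit,
    cssam_statistic,
    fit_cell_regression,
    permutation_test,
)
from .preprocess import (
    content_normalize,
    filter_min_count,
    negative_background_threshold,
    positive_control_normalize,
    run_preprocess,
)
from .simulate import DEFAULT_DIRICHLET_ALPHA, SimulationConfig, simulate_cohort


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# printed-table worked example


def table1_quantities() -> dict:
    """Derived demographics of the bundled example cohort."""
    s = summarize_cohort(demo_subjects())
    return {
        "pc20_pre_geomean": s.pc20_pre_geomean,
        "pc20_post_geomean": s.pc20_post_geomean,
        "shift_mean": s.shift_mean_se[0],
        "shift_se": s.shift_mean_se[1],
        "asthmatic_age_mean": s.age_mean_se["asthmatic"][0],
        "asthmatic_age_se": s.age_mean_se["asthmatic"][1],
        "n_asthmatic": 7,
        "n_shifts": int(s.shifts.notna().sum()),
        "shifts": [float(v) for v in s.shifts.dropna()],
    }


# ---------------------------------------------------------------------------
# deconvolution oracles


def deconv_oracle_max_error(n_instances: int = 200, seed=0) -> float:
    """Max |difference| between fit_cell_regression and explicit normal
    equations over random instances (K in {2,3}, n in 6..20)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        K = int(rng.integers(2, 4))
        n = int(rng.integers(6, 21))
        X = rng.dirichlet(np.ones(K) * 2.0, size=n)
        y = X @ rng.normal(5.0, 2.0, K) + rng.normal(0.0, 0.5, n)
        fit = fit_cell_regression(y, X)
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        se = np.sqrt((y - X @ beta) @ (y - X @ beta) / (n - K) * np.diag(xtx_inv))
        worst = max(
            worst,
            float(np.max(np.abs(fit.beta.to_numpy() - beta))),
            float(np.max(np.abs(fit.se.to_numpy() - se))),
        )
    return worst


def cssam_hand_case() -> dict:
    """Hand-evaluated pooled-SE statistic: beta=(1,2), se=(0.5,0.5), n=(4,7)
    gives pooled se = 0.5 and t = 2.0; group swap negates t exactly."""
    mk = lambda b, n: CellRegressionFit(
        "g", pd.Series({"k": b}), pd.Series({"k": 0.5}), n, n - 1, 1.0, np.zeros(n)
    )
    f1, f2 = mk(1.0, 4), mk(2.0, 7)
    t, se = cssam_statistic(f1, f2, "k")
    t_swap, _ = cssam_statistic(f2, f1, "k")
    return {"t": t, "pooled_se": se, "antisymmetry_error": abs(t + t_swap)}


def _linear_mixture(rng, n1, n2, alpha1, alpha2, effect, sigma=1.0, base=8.0):
    """Expression from the zero-intercept mixture model with a PBMC-only
    coefficient shift of ``effect`` residual sds in group 2."""
    f1 = rng.dirichlet(alpha1, n1)
    f2 = rng.dirichlet(alpha2, n2)
    X = np.vstack([f1, f2])
    y = np.concatenate(
        [f1 @ np.array([base, base]), f2 @ np.array([base, base + effect * sigma])]
    )
    y = y + rng.normal(0.0, sigma, n1 + n2)
    labels = np.array(["g1"] * n1 + ["g2"] * n2)
    return y, X, labels


def permutation_calibration(
    reps: int = 200,
    B: int = 1000,
    n1: int = 7,
    n2: int = 7,
    alpha=DEFAULT_DIRICHLET_ALPHA["pre"],
    seed=0,
) -> dict:
    """Null rejection rate of the permutation test at p <= 0.05."""
    ss = np.random.SeedSequence([seed, 101])
    rej = 0
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        y, X, labels = _linear_mixture(rng, n1, n2, alpha, alpha, effect=0.0)
        tab = permutation_test(
            y, X, labels, B=B, rng=np.random.default_rng(child.spawn(1)[0])
        )
        rej += int(tab["p_perm"].iloc[1] <= 0.05)
    half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
    return {
        "rejection_rate": rej / reps,
        "n_replicates": reps,
        "interval_low": 0.05 - half,
        "interval_high": 0.05 + half,
    }


def pbmc_power_harness(
    reps: int = 50,
    B: int = 1000,
    n1: int = 4,
    n2: int = 7,
    effect: float = 4.0,
    alpha1=DEFAULT_DIRICHLET_ALPHA["HC"],
    alpha2=DEFAULT_DIRICHLET_ALPHA["pre"],
    seed=0,
) -> dict:
    """PBMC-only group effect of ``effect`` residual sds: fraction of
    replicates with PBMC perm p <= 0.05, granulocyte p > 0.05, and both."""
    ss = np.random.SeedSequence([seed, 202])
    pbmc_hit = gran_null = joint = 0
    for child in ss.spawn(reps):
        rng = np.random.default_rng(child)
        y, X, labels = _linear_mixture(rng, n1, n2, alpha1, alpha2, effect=effect)
        tab = permutation_test(
            y, X, labels, B=B, rng=np.random.default_rng(child.spawn(1)[0])
        )
        p_gran, p_pbmc = tab["p_perm"].iloc[0], tab["p_perm"].iloc[1]
        pbmc_hit += int(p_pbmc <= 0.05)
        gran_null += int(p_gran > 0.05)
        joint += int(p_pbmc <= 0.05 and p_gran > 0.05)
    return {
        "pbmc_power": pbmc_hit / reps,
        "granulocyte_specificity": gran_null / reps,
        "joint_success": joint / reps,
        "n_replicates": reps,
        "effect_residual_sds": effect,
    }


# ---------------------------------------------------------------------------
# preprocessing invariants


def preprocess_invariants(seed=0) -> dict:
    """Invariant deviations measured on a simulated cohort plus toy checks:
    equalized positive-control sums and detected-set totals, detection vs a
    brute-force scan, and boundary behaviour of the min-count filter."""
    from .preprocess import CountMatrix

    cfg = SimulationConfig(n_hc=4, n_asthma=7, n_probes=300, seed=_seed_int(
        np.random.SeedSequence([seed, 303])))
    cohort = simulate_cohort(cfg)

    posn = positive_control_normalize(cohort.counts)
    pos_sums = posn.of_class("pos").sum(axis=0)
    pos_dev = float((pos_sums.max() - pos_sums.min()) / pos_sums.mean())

    thresholded, detected = negative_background_threshold(posn)
    contentn = content_normalize(thresholded, detected)
    totals = contentn.values.loc[detected].sum(axis=0)
    content_dev = float((totals.max() - totals.min()) / totals.mean())

    # brute-force detection scan on the pos-normalized counts
    neg = posn.of_class("neg")
    T = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    endo = posn.of_class("endogenous")
    brute = set(endo.index[((endo - T) >= 0).all(axis=1)])
    mismatch = len(brute.symmetric_difference(set(detected)))

    # a probe sitting exactly at the threshold is retained
    values = pd.DataFrame({"s1": [100.0, 99.0], "s2": [100.0, 500.0]},
                          index=["at", "below"])
    cm = CountMatrix(values, pd.Series("endogenous", index=values.index))
    kept = list(filter_min_count(cm, threshold=100.0).values.index)

    return {
        "pos_sum_rel_deviation": pos_dev,
        "content_total_rel_deviation": content_dev,
        "detection_mismatch_count": mismatch,
        "n_detected": len(detected),
        "boundary_probe_retained": int(kept == ["at"]),
    }


def preprocess_attrition(seed=0, n_probes: int = 734) -> dict:
    """Probe attrition of the full ladder on a paper-scale simulated cohort."""
    cfg = SimulationConfig(n_probes=n_probes, seed=_seed_int(
        np.random.SeedSequence([seed, 304])))
    cohort = simulate_cohort(cfg)
    _, qc = run_preprocess(cohort.counts)
    return {
        "n_input": qc.retained("input"),
        "n_detected": qc.retained("negative_background_threshold"),
        "n_retained": qc.retained("filter_min_count"),
    }


# ---------------------------------------------------------------------------
# differential expression


def de_null_calibration(
    runs: int = 50, n_probes: int = 1000, n1: int = 4, n2: int = 7, seed=0
) -> dict:
    """Mean fraction of probes flagged at BH FDR 1% under a pure null."""
    ss = np.random.SeedSequence([seed, 404])
    rates = []
    for child in ss.spawn(runs):
        rng = np.random.default_rng(child)
        expr = pd.DataFrame(
            rng.normal(size=(n_probes, n1 + n2)),
            columns=[f"s{i}" for i in range(n1 + n2)],
        )
        res = TwoGroupDE(expr, ["HC"] * n1 + ["pre"] * n2, robust=False).fit(fdr=0.01)
        rates.append(float(res.table["flag"].mean()))
    rates = np.asarray(rates)
    mc_se = float(rates.std(ddof=1) / np.sqrt(runs))
    return {
        "mean_flag_rate": float(rates.mean()),
        "mc_se": mc_se,
        "bound": 0.01 + 3 * mc_se,
        "n_runs": runs,
        "n_probes": n_probes,
    }


def bh_brute_force_max_diff(n_vectors: int = 30, seed=0) -> float:
    """Max |q difference| between the step-up implementation and a literal
    brute-force evaluation of the BH definition on random p-vectors."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(0, 1, size=int(rng.integers(3, 60)))
        q, _ = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        for i in range(m):
            cand = [m * p[order[j]] / (j + 1) for j in range(m)
                    if p[order[j]] >= p[i] - 1e-15]
            worst = max(worst, abs(q[i] - min(1.0, min(cand))))
    return worst


def moderated_t_d0_limit_max_diff(seed=0) -> float:
    """Max |moderated t - ordinary t| in the d0 -> 0 limit."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    expr = pd.DataFrame(rng.normal(size=(200, 11)),
                        columns=[f"s{i}" for i in range(11)])
    fit = fit_two_group(expr, ["a"] * 4 + ["b"] * 7, robust=False)
    tab, *_ = ebayes_moderate(fit, prior_df=0.0)
    ordinary = fit.coef / fit.se
    return float(np.max(np.abs(tab["t"].to_numpy() - ordinary)))


# ---------------------------------------------------------------------------
# qPCR


def qpcr_hand_values() -> dict:
    """Hand-arithmetic delta-Ct checks and the censoring rule."""
    from .qpcr import collapse_replicates, delta_ct

    rows = []
    for rep, ct in enumerate((30.0, 30.0), 1):
        rows.append({"sample_id": "s1", "assay": "miR-X", "assay_class": "target",
                     "replicate": rep, "ct": ct})
    for name, ct in (("RNU44", 25.0), ("RNU6B", 27.0)):
        for rep in (1, 2):
            rows.append({"sample_id": "s1", "assay": name, "assay_class": "reference",
                         "replicate": rep, "ct": ct})
    for rep, ct in enumerate((36.0, 37.0), 1):
        rows.append({"sample_id": "s1", "assay": "miR-low", "assay_class": "target",
                     "replicate": rep, "ct": ct})
    collapsed = collapse_replicates(pd.DataFrame(rows))
    out = delta_ct(collapsed).set_index("assay")
    return {
        "delta_ct": float(out.loc["miR-X", "delta_ct"]),
        "rel_expr": float(out.loc["miR-X", "rel_expr"]),
        "censored_mean_ct": float(out.loc["miR-low", "ct_mean"]),
        "censored_flag": int(out.loc["miR-low", "censored"]),
    }
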