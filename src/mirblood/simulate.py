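"""Synthetic NanoString-like cohorts with known cell-specific ground truth.

The generator emulates a three-group allergen-challenge design (healthy
controls, pre-challenge and paired post-challenge asthmatics) profiled on a
digital counting panel:

* leukocyte fractions per sample drawn from per-group Dirichlet distributions
  whose concentrations are moment-matched to published granulocyte/PBMC
  differentials for this kind of cohort,
* endogenous counts as negative-binomial draws around a cell-fraction-weighted
  mixture ``libsize_s * eff_s * sum_k f_sk * cell_means[p, k, g(s)]``,
* a six-point positive spike-in ladder (0.125-128 fM, geometric spacing),
  eight negative-control background probes and five housekeeping mRNAs,
* optional RT-qPCR Ct tables for a chosen target with duplicate wells and
  two small-RNA reference assays.

Every draw flows from a single integer seed so emitted CSVs are reproducible
byte for byte. All distributional choices are synthetic stand-ins (recorded
as such in the cohort manifest): the real assay's noise process is not
publicly characterised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import CountMatrix

GROUPS = ("HC", "pre", "post")

#: Dirichlet concentrations moment-matched to observed granulocyte/PBMC
#: differential means and spreads in allergen-challenge cohorts
#: (alpha0 = m(1-m)/s^2 - 1 with m the mean granulocyte fraction and s its sd).
DEFAULT_DIRICHLET_ALPHA: dict[str, tuple[float, ...]] = {
    "HC": (3.3, 1.7),
    "pre": (9.4, 5.5),
    "post": (28.4, 12.9),
}

POS_LADDER = (0.125, 0.5, 2.0, 8.0, 32.0, 128.0)
HOUSEKEEPING = ("ACTB", "B2M", "GAPDH", "RPL19", "RPLP0")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror the profiled study design: 4 healthy controls, 7 paired
    pre/post asthmatics, a 734-probe endogenous panel over K=2 grouped cell
    types (granulocytes, PBMC).
    """

    n_hc: int = 4
    n_asthma: int = 7
    n_probes: int = 734
    n_celltypes: int = 2
    celltype_names: tuple[str, ...] = ("granulocytes", "pbmc")
    dirichlet_alpha: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_DIRICHLET_ALPHA)
    )
    cell_means: np.ndarray | None = None  # (n_probes, K, len(GROUPS))
    dispersion: float = 0.1
    libsize_sigma: float = 0.1
    libsize_factors: np.ndarray | None = None
    assay_eff_sigma: float = 0.1
    pos_control_ladder: tuple[float, ...] = POS_LADDER
    pos_counts_per_fm: float = 25.0
    neg_control_mean: float = 8.0
    neg_control_sd: float = 3.0
    hk_mean: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_asthma < 0:
            raise SimulationError("group sizes must be non-negative")
        if self.n_hc < 1 and self.n_asthma < 1:
            raise SimulationError("need at least one HC or one asthmatic subject")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if len(self.celltype_names) != self.n_celltypes:
            raise SimulationError("celltype_names length must equal n_celltypes")
        ladder = tuple(self.pos_control_ladder)
        if len(ladder) != 6 or any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise SimulationError("pos_control_ladder must be 6 strictly increasing values")
        for g, alpha in self.dirichlet_alpha.items():
            for j, a in enumerate(alpha):
                if a <= 0:
                    raise SimulationError(
                        f"dirichlet_alpha[{g!r}][{j}] = {a} must be strictly positive"
                    )


@dataclass
class SimulatedCohort:
    counts: CountMatrix
    fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    metadata: pd.DataFrame  # sample_id, subject_id, group
    truth: np.ndarray  # cell_means actually used
    config: SimulationConfig
    seed: int


# ---------------------------------------------------------------------------


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_cell_fractions(n_samples: int, alpha: Sequence[float], seed=0) -> np.ndarray:
    """Dirichlet cell-type fractions; each row is non-negative and sums to 1."""
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 2:
        raise SimulationError("alpha must be a vector of length >= 2")
    for j, a in enumerate(alpha):
        if a <= 0:
            raise SimulationError(f"alpha[{j}] = {a} must be strictly positive")
    rng = _rng(seed)
    frac = rng.dirichlet(alpha, size=n_samples)
    return frac


def default_cell_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-probe baseline abundances (log-normal, heavy right tail so that a
    realistic minority of probes clears background and the count filter),
    modulated per cell type; identical across groups unless spiked."""
    base = rng.lognormal(mean=np.log(25.0), sigma=1.6, size=config.n_probes)
    cell_mod = rng.lognormal(mean=0.0, sigma=0.5, size=(config.n_probes, config.n_celltypes))
    means = base[:, None] * cell_mod  # (P, K)
    return np.repeat(means[:, :, None], len(GROUPS), axis=2)


def spike_effect(
    cell_means: np.ndarray,
    probe_index: int,
    factor: float,
    groups: Sequence[str],
    celltypes: Sequence[int] | None = None,
) -> np.ndarray:
    """Multiply one probe's mean by ``factor`` in the given groups (and
    optionally only in the given cell-type columns). Returns a copy."""
    out = cell_means.copy()
    gidx = [GROUPS.index(g) for g in groups]
    kidx = list(range(out.shape[1])) if celltypes is None else list(celltypes)
    for g in gidx:
        for k in kidx:
            out[probe_index, k, g] *= factor
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion*mu^2
    (gamma-Poisson mixture); exact Poisson when dispersion == 0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig,
    fractions: np.ndarray,
    group_labels: Sequence[str],
    sample_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    cell_means: np.ndarray | None = None,
) -> CountMatrix:
    """Draw a full count matrix (endogenous + pos/neg/hk controls)."""
    rng = _rng(config.seed) if rng is None else rng
    fractions = np.asarray(fractions, dtype=float)
    n_samples = fractions.shape[0]
    if len(group_labels) != n_samples:
        raise SimulationError("fractions rows must align with group_labels")
    if fractions.shape[1] != config.n_celltypes:
        raise SimulationError("fractions columns must equal n_celltypes")
    if config.dispersion < 0:
        raise SimulationError("dispersion must be >= 0")
    means = cell_means if cell_means is not None else config.cell_means
    if means is None:
        means = default_cell_means(config, rng)
    means = np.asarray(means, dtype=float)
    if means.shape != (config.n_probes, config.n_celltypes, len(GROUPS)):
        raise SimulationError(
            f"cell_means must have shape (n_probes, K, {len(GROUPS)}); got {means.shape}"
        )
    for g in group_labels:
        if g not in GROUPS:
            raise SimulationError(f"unknown group label {g!r}")

    lib = config.libsize_factors
    if lib is None:
        lib = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_samples)
    lib = np.asarray(lib, dtype=float)
    if np.any(lib <= 0):
        raise SimulationError("libsize factors must be > 0")
    eff = rng.lognormal(mean=0.0, sigma=config.assay_eff_sigma, size=n_samples)

    gidx = np.array([GROUPS.index(g) for g in group_labels])
    # expected endogenous count: lib_s * eff_s * sum_k f_sk * mean[p, k, g(s)]
    mixture = np.einsum("sk,pks->ps", fractions, means[:, :, gidx])
    mu_endo = mixture * (lib * eff)[None, :]
    endo = _nb_draw(rng, mu_endo, config.dispersion).astype(float)

    ladder = np.asarray(config.pos_control_ladder, dtype=float)
    mu_pos = config.pos_counts_per_fm * ladder[:, None] * eff[None, :]
    pos = rng.poisson(mu_pos).astype(float)

    neg = rng.normal(config.neg_control_mean, config.neg_control_sd, size=(8, n_samples))
    neg = np.clip(np.round(neg), 0, None)

    mu_hk = config.hk_mean * (lib * eff)[None, :] * np.ones((len(HOUSEKEEPING), 1))
    hk = _nb_draw(rng, mu_hk, config.dispersion).astype(float)

    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    endo_ids = [f"hsa-miR-SIM{i + 1:04d}" for i in range(config.n_probes)]
    pos_ids = [f"POS_{c}({v:g})" for c, v in zip("ABCDEF", ladder)]
    neg_ids = [f"NEG_{i + 1:02d}" for i in range(8)]
    probe_ids = endo_ids + pos_ids + neg_ids + list(HOUSEKEEPING)
    values = pd.DataFrame(
        np.vstack([endo, pos, neg, hk]), index=probe_ids, columns=list(sample_ids)
    )
    probe_class = pd.Series(
        ["endogenous"] * len(endo_ids)
        + ["pos"] * 6
        + ["neg"] * 8
        + ["hk"] * len(HOUSEKEEPING),
        index=probe_ids,
    )
    return CountMatrix(values, probe_class)


def simulate_cohort(config: SimulationConfig, cell_means: np.ndarray | None = None) -> SimulatedCohort:
    """Simulate a full cohort: HC samples plus paired pre/post asthmatics."""
    rng = _rng(config.seed)
    meta_rows = []
    for i in range(config.n_hc):
        meta_rows.append({"sample_id": f"HC{i + 1:02d}", "subject_id": f"HC{i + 1:02d}", "group": "HC"})
    for i in range(config.n_asthma):
        sid = f"A{i + 1:02d}"
        meta_rows.append({"sample_id": f"{sid}_pre", "subject_id": sid, "group": "pre"})
        meta_rows.append({"sample_id": f"{sid}_post", "subject_id": sid, "group": "post"})
    metadata = pd.DataFrame(meta_rows)

    groups = metadata["group"].tolist()
    frac_rows = []
    for g in groups:
        alpha = np.asarray(config.dirichlet_alpha[g], dtype=float)
        frac_rows.append(rng.dirichlet(alpha))
    fractions = pd.DataFrame(
        np.asarray(frac_rows),
        index=metadata["sample_id"].tolist(),
        columns=list(config.celltype_names),
    )

    means = cell_means if cell_means is not None else config.cell_means
    if means is None:
        means = default_cell_means(config, rng)
    counts = simulate_counts(
        config,
        fractions.to_numpy(),
        groups,
        sample_ids=metadata["sample_id"].tolist(),
        rng=rng,
        cell_means=means,
    )
    return SimulatedCohort(counts, fractions, metadata, means, config, config.seed)


def simulate_ct_table(
    abundance: pd.Series,
    assay: str = "hsa-miR-SIM0001",
    references: Sequence[str] = ("RNU44", "RNU6B"),
    ref_abundance: float = 16.0,
    ct_at_unit: float = 30.0,
    duplicate_sd: float = 0.15,
    n_replicates: int = 2,
    seed=0,
) -> pd.DataFrame:
    """qPCR Ct table for one target assay plus reference assays.

    Ct follows ``ct_at_unit - log2(abundance)`` so a doubling of abundance
    lowers Ct by exactly one cycle; duplicate wells get independent Gaussian
    noise. Low abundances naturally emit Ct > 35 (censorable downstream).
    """
    rng = _rng(seed)
    rows = []
    for sample, ab in abundance.items():
        if ab <= 0:
            raise SimulationError(f"abundance for sample {sample!r} must be > 0")
        assays = [(assay, "target", ct_at_unit - np.log2(ab))] + [
            (ref, "reference", ct_at_unit - np.log2(ref_abundance)) for ref in references
        ]
        for name, cls, true_ct in assays:
            for rep in range(1, n_replicates + 1):
                ct = true_ct + (rng.normal(0.0, duplicate_sd) if duplicate_sd > 0 else 0.0)
                rows.append(
                    {
                        "sample_id": sample,
                        "assay": name,
                        "assay_class": cls,
                        "replicate": rep,
                        "ct": float(ct),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: SimulatedCohort, outdir, ct_table: pd.DataFrame | None = None) -> dict:
    """Write counts/fractions/metadata (+ optional Ct table) CSVs and a YAML
    manifest recording the generating configuration and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.counts.to_csv(outdir / "counts.csv")
    fr = cohort.fractions.copy()
    fr.index.name = "sample_id"
    fr.to_csv(outdir / "fractions.csv")
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    paths = {
        "counts": "counts.csv",
        "fractions": "fractions.csv",
        "metadata": "metadata.csv",
    }
    if ct_table is not None:
        ct_table.to_csv(outdir / "ct.csv", index=False)
        paths["ct"] = "ct.csv"

    cfg = asdict(cohort.config)
    cfg.pop("cell_means", None)
    cfg.pop("libsize_factors", None)
    cfg["dirichlet_alpha"] = {g: list(map(float, a)) for g, a in cfg["dirichlet_alpha"].items()}
    cfg["pos_control_ladder"] = list(map(float, cfg["pos_control_ladder"]))
    cfg["celltype_names"] = list(cfg["celltype_names"])
    manifest = {
        "generator": "mirblood.simulate",
        "note": (
            "all count, fraction and Ct distributions are synthetic stand-ins; "
            "the profiled assay's noise process is not publicly characterised"
        ),
        "seed": int(cohort.seed),
        "config": cfg,
        "files": paths,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
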