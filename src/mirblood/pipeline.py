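"""End-to-end run orchestration: simulate (or load) -> preprocess -> DE per
contrast -> cross-contrast intersection -> deconvolve -> qPCR -> cohort
summary, with a provenance manifest so a config + seed fully determines every
output byte."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import read_subjects, summarize_cohort
from .de import TwoGroupDE
from .deconvolution import CellDeconvolution, CellFractions
from .preprocess import read_count_table, run_preprocess
from .qpcr import collapse_replicates, delta_ct, read_ct_table
from .simulate import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: str
    seed: int
    simulate: dict | None = None  # SimulationConfig kwargs; None -> load inputs
    counts: str | None = None
    fractions: str | None = None
    metadata: str | None = None
    ct: str | None = None
    subjects: str | None = None
    corrections: dict = field(default_factory=dict)
    contrasts: list = field(default_factory=lambda: [["HC", "pre"], ["pre", "post"]])
    fdr: float = 0.01
    min_count: float = 100.0
    B: int = 1000
    robust: bool = True
    deconvolve_probes: str | list = "intersection"

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise PipelineError("config must set a seed (stochastic stages depend on it)")
        return RunConfig(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns a dict of result tables and
    writes CSVs + QC + manifest under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ----- inputs -------------------------------------------------------
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        cohort = _stage("simulate")(simulate_cohort)(sim_cfg)
        write_cohort(cohort, outdir / "simulated")
        counts = cohort.counts
        fractions = CellFractions(cohort.fractions, source="simulated")
        metadata = cohort.metadata
    else:
        if not (config.counts and config.metadata):
            raise PipelineError("either a simulate block or counts+metadata paths are required")
        counts = _stage("load_counts")(read_count_table)(config.counts)
        metadata = pd.read_csv(config.metadata)
        fractions = (
            CellFractions.from_csv(config.fractions) if config.fractions else None
        )

    # ----- preprocessing ------------------------------------------------
    expr, qc = _stage("preprocess")(run_preprocess)(
        counts, corrections=config.corrections or None, min_count=config.min_count
    )
    qc.to_json(outdir / "qc.json")
    (outdir / "qc.txt").write_text(qc.to_text() + "\n")
    expr.to_csv(outdir / "expression.csv")
    results["expression"] = expr
    results["qc"] = qc

    # ----- differential expression per contrast -------------------------
    labels = metadata.set_index("sample_id")["group"]
    de_results = {}
    for ref, alt in config.contrasts:
        model = TwoGroupDE.from_dataframe(expr.values, metadata, (ref, alt), robust=config.robust)
        res = model.fit(fdr=config.fdr)
        tag = f"{ref}_vs_{alt}"
        out = res.table.copy()
        out.index.name = "probe"
        out.to_csv(outdir / f"de_{tag}.csv")
        de_results[tag] = res
        logger.info("DE %s: %d significant at FDR %g", tag, len(res.significant), config.fdr)
    results["de"] = de_results

    # ----- cross-contrast intersection ----------------------------------
    sig_sets = [set(res.significant) for res in de_results.values()]
    common = sorted(set.intersection(*sig_sets)) if sig_sets else []
    inter = pd.DataFrame({"probe": common})
    for tag, res in de_results.items():
        if common:
            inter[f"logFC_{tag}"] = res.table.loc[common, "logFC"].to_numpy()
            inter[f"q_{tag}"] = res.table.loc[common, "q"].to_numpy()
    inter.to_csv(outdir / "intersection.csv", index=False)
    results["intersection"] = inter

    # ----- cell-specific deconvolution ----------------------------------
    if fractions is not None:
        if config.deconvolve_probes == "intersection":
            probes = common
        elif isinstance(config.deconvolve_probes, str):
            probes = [config.deconvolve_probes]
        else:
            probes = list(config.deconvolve_probes)
        probes = [p for p in probes if p in expr.values.index]
        deconv_tabs = {}
        if probes:
            model = CellDeconvolution(expr, fractions, metadata)
            for i, (ref, alt) in enumerate(config.contrasts):
                tag = f"{ref}_vs_{alt}"
                res = model.fit((ref, alt), probes=probes, B=config.B,
                                seed=np.random.SeedSequence([config.seed, 7, i]).generate_state(1)[0] % (2**31))
                res.table.to_csv(outdir / f"deconv_{tag}.csv", index=False)
                deconv_tabs[tag] = res
        results["deconvolution"] = deconv_tabs

    # ----- qPCR ---------------------------------------------------------
    if config.ct:
        ct = _stage("qpcr")(read_ct_table)(config.ct)
        collapsed = collapse_replicates(ct)
        dct = delta_ct(collapsed)
        dct.to_csv(outdir / "qpcr_delta_ct.csv", index=False)
        results["qpcr"] = dct

    # ----- cohort summary -----------------------------------------------
    if config.subjects:
        subjects = _stage("cohort")(read_subjects)(config.subjects)
        summary = summarize_cohort(subjects)
        summary.to_frame().to_csv(outdir / "cohort_summary.csv", index=False)
        results["cohort"] = summary

    # ----- manifest -----------------------------------------------------
    manifest = {
        "package": "mirblood",
        "version": __version__,
        "seed": int(config.seed),
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "n_significant": {tag: int(len(res.significant)) for tag, res in de_results.items()},
        "intersection": common,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    results["manifest"] = manifest
    return results
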