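"""Count preprocessing for digital miRNA expression panels.

Raw nCounter-style code counts are carried through a fixed ladder of steps:

1. probe-specific background subtraction (user-supplied correction table),
2. scaling to the sum of the six positive spike-in controls,
3. per-sample background thresholding from the eight negative controls
   (mean + 2 sd) with an all-samples detection rule,
4. content normalisation to the sum of the detected probes,
5. a minimum-count filter, and
6. log2 transformation (floored at one count).

Each step is a pure function on :class:`CountMatrix`; :func:`run_preprocess`
composes them and fills a :class:`QCReport` with probe attrition and the
per-sample scale factors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "pos", "neg", "hk")

_RCC_CLASS_MAP = {
    "endogenous": "endogenous",
    "positive": "pos",
    "negative": "neg",
    "housekeeping": "hk",
    "pos": "pos",
    "neg": "neg",
    "hk": "hk",
}


class PreprocessError(ValueError):
    """Raised when an input violates a preprocessing contract."""


@dataclass
class CountMatrix:
    """Probe x sample count table with a per-probe class annotation.

    ``values`` holds one row per probe and one column per sample. Raw counts
    are non-negative integers; intermediate stages may hold real values
    (scaled or background-subtracted counts).
    """

    values: pd.DataFrame
    probe_class: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.probe_class = self.probe_class.reindex(self.values.index)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise PreprocessError(f"duplicate probe ids: {dups}")
        if self.values.isna().any().any():
            raise PreprocessError("count matrix contains missing cells")
        bad = set(self.probe_class.dropna().unique()) - set(PROBE_CLASSES)
        if bad or self.probe_class.isna().any():
            missing = self.probe_class.index[self.probe_class.isna()].tolist()
            raise PreprocessError(
                f"unknown probe class(es) {sorted(bad)}; probes without class: {missing}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def class_ids(self, cls: str) -> pd.Index:
        return self.values.index[self.probe_class == cls]

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.values.loc[self.class_ids(cls)]

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.values.copy(), self.probe_class.copy())

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.probe_class == c).sum()) for c in PROBE_CLASSES}

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "probe_class", self.probe_class)
        out.index.name = "probe_id"
        out.to_csv(path)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression for the probes surviving all filters."""

    values: pd.DataFrame
    provenance: list = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "probe_id"
        out.to_csv(path)

    @staticmethod
    def from_csv(path) -> "ExpressionMatrix":
        df = pd.read_csv(path, index_col=0)
        return ExpressionMatrix(df.astype(float), provenance=[{"step": "from_csv"}])


@dataclass
class QCReport:
    """Per-step probe attrition and per-sample scale factors."""

    steps: list = field(default_factory=list)
    pos_scale_factors: dict = field(default_factory=dict)
    content_scale_factors: dict = field(default_factory=dict)
    detection_thresholds: dict = field(default_factory=dict)

    def record(self, step: str, endogenous_retained: int, **params) -> None:
        if self.steps and endogenous_retained > self.steps[-1]["endogenous_retained"]:
            raise PreprocessError("probe retention must be non-increasing across steps")
        self.steps.append(
            {"step": step, "endogenous_retained": int(endogenous_retained), "params": params}
        )

    def retained(self, step: str) -> int:
        for rec in self.steps:
            if rec["step"] == step:
                return rec["endogenous_retained"]
        raise KeyError(step)

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "pos_scale_factors": self.pos_scale_factors,
            "content_scale_factors": self.content_scale_factors,
            "detection_thresholds": self.detection_thresholds,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = ["QC report", "========="]
        for rec in self.steps:
            lines.append(f"{rec['step']:32s} endogenous retained: {rec['endogenous_retained']}")
        if self.detection_thresholds:
            lines.append("detection thresholds (mean + 2 sd of negatives):")
            for s, t in self.detection_thresholds.items():
                lines.append(f"  {s}: {t:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# reading


def read_count_table(path, dialect: str = "csv") -> CountMatrix:
    """Read a probe x sample count table.

    ``dialect='csv'`` expects columns ``probe_id, probe_class, <sample...>``.
    ``dialect='rcc-like'`` reads a simple sectioned text format with a
    ``<Code_Summary>`` section whose CSV lines are
    ``CodeClass,Name,<sample...>``.
    """
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
        if "probe_class" not in df.columns:
            raise PreprocessError("csv dialect requires a 'probe_class' column")
        probe_class = df["probe_class"].astype(str)
        values = df.drop(columns=["probe_class"])
    elif dialect == "rcc-like":
        values, probe_class = _read_rcc_like(path)
    else:
        raise PreprocessError(f"unknown dialect {dialect!r}; use 'csv' or 'rcc-like'")

    probe_class = probe_class.map(lambda c: _RCC_CLASS_MAP.get(str(c).lower(), str(c)))
    values = values.apply(pd.to_numeric)
    neg_cells = values < 0
    if neg_cells.any().any():
        probe = values.index[neg_cells.any(axis=1)][0]
        raise PreprocessError(f"negative raw count in row for probe {probe!r}")
    if not np.allclose(values.to_numpy(), np.round(values.to_numpy())):
        raise PreprocessError("raw counts must be integers")
    return CountMatrix(values, probe_class)


def _read_rcc_like(path) -> tuple[pd.DataFrame, pd.Series]:
    rows, header, in_section = [], None, False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("<"):
                in_section = line.lower().startswith("<code_summary>")
                continue
            if not in_section:
                continue
            parts = [p.strip() for p in line.split(",")]
            if header is None:
                if parts[0].lower() != "codeclass":
                    raise PreprocessError("rcc-like Code_Summary must start with CodeClass,Name,...")
                header = parts
                continue
            rows.append(parts)
    if header is None:
        raise PreprocessError("no <Code_Summary> section found")
    samples = header[2:]
    names = [r[1] for r in rows]
    classes = pd.Series([r[0] for r in rows], index=names)
    values = pd.DataFrame(
        [[float(x) for x in r[2:]] for r in rows], index=names, columns=samples
    )
    return values, classes


# ---------------------------------------------------------------------------
# pipeline steps


def probe_background_correct(
    counts: CountMatrix, corrections: Mapping[str, float] | None
) -> CountMatrix:
    """Subtract probe-specific background; negatives are set to 1.

    ``corrections`` maps probe id -> non-negative count to subtract from that
    probe in every sample. Probes not listed pass through unchanged.
    """
    out = counts.copy()
    if not corrections:
        return out
    unknown = [p for p in corrections if p not in out.values.index]
    if unknown:
        raise PreprocessError(f"correction listed for unknown probe(s): {unknown}")
    for probe, corr in corrections.items():
        if corr < 0:
            raise PreprocessError(f"negative correction for probe {probe!r}")
        row = out.values.loc[probe] - float(corr)
        out.values.loc[probe] = row.where(row >= 0, 1.0)
    return out


def positive_control_normalize(
    counts: CountMatrix, qc: QCReport | None = None
) -> CountMatrix:
    """Scale each sample so positive-control sums match their cross-sample mean."""
    pos = counts.of_class("pos")
    if pos.shape[0] < 1:
        raise PreprocessError("no positive-control probes present")
    sums = pos.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise PreprocessError(f"zero positive-control sum in sample(s): {list(zero)}")
    factors = sums.mean() / sums
    out = counts.copy()
    out.values = out.values * factors
    if qc is not None:
        qc.pos_scale_factors = {s: float(f) for s, f in factors.items()}
    return out


def negative_background_threshold(
    counts: CountMatrix, subtract: bool = True, qc: QCReport | None = None
) -> tuple[CountMatrix, pd.Index]:
    """Per-sample background threshold from the negative controls.

    For each sample ``s`` the threshold is ``mean(neg_s) + 2*sd(neg_s)``
    (sample sd, n-1 denominator). Endogenous counts are replaced by
    ``count - T_s`` (when ``subtract``); the detected set holds the probes
    whose subtracted value is non-negative in *every* sample, and probes
    outside it are removed.
    """
    neg = counts.of_class("neg")
    if neg.shape[0] < 2:
        raise PreprocessError("need >=2 negative-control probes to estimate a sd")
    thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    endo_ids = counts.class_ids("endogenous")
    subtracted = counts.values.loc[endo_ids] - thresholds
    detected = subtracted.index[(subtracted >= 0).all(axis=1)]
    out = counts.copy()
    if subtract:
        out.values.loc[endo_ids] = subtracted
    keep = out.values.index.difference(endo_ids.difference(detected), sort=False)
    out = CountMatrix(out.values.loc[keep], out.probe_class.loc[keep])
    if qc is not None:
        qc.detection_thresholds = {s: float(t) for s, t in thresholds.items()}
    return out, detected


def content_normalize(
    counts: CountMatrix, detected_set: Iterable[str], qc: QCReport | None = None
) -> CountMatrix:
    """Scale each sample so its detected-set total equals the cross-sample mean."""
    detected = pd.Index(detected_set)
    if len(detected) == 0:
        raise PreprocessError("empty detected set")
    totals = counts.values.loc[detected].sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise PreprocessError(f"zero detected-set total in sample(s): {list(zero)}")
    factors = totals.mean() / totals
    out = counts.copy()
    out.values = out.values * factors
    if qc is not None:
        qc.content_scale_factors = {s: float(f) for s, f in factors.items()}
    return out


def filter_min_count(
    counts: CountMatrix, threshold: float = 100.0, rule: str = "min"
) -> CountMatrix:
    """Keep endogenous probes whose normalized counts clear ``threshold``.

    ``rule='min'`` (default) requires the minimum across samples to be
    >= threshold; ``rule='mean'`` requires the cross-sample mean to be.
    Control probes are dropped here — they have served their purpose and the
    downstream expression matrix holds endogenous probes only.
    """
    if threshold <= 0:
        raise PreprocessError("threshold must be > 0")
    endo = counts.of_class("endogenous")
    if rule == "min":
        keep = endo.index[endo.min(axis=1) >= threshold]
    elif rule == "mean":
        keep = endo.index[endo.mean(axis=1) >= threshold]
    else:
        raise PreprocessError(f"unknown rule {rule!r}")
    if len(keep) == 0:
        warnings.warn("no probes pass the minimum-count filter", stacklevel=2)
    return CountMatrix(counts.values.loc[keep], counts.probe_class.loc[keep])


def log2_transform(counts: CountMatrix, provenance: list | None = None) -> ExpressionMatrix:
    """log2 of counts floored at one count (so zero maps to zero)."""
    vals = np.log2(counts.values.clip(lower=1.0))
    prov = list(provenance or [])
    prov.append({"step": "log2_transform", "floor": 1.0})
    return ExpressionMatrix(vals, prov)


def run_preprocess(
    raw: CountMatrix,
    corrections: Mapping[str, float] | None = None,
    min_count: float = 100.0,
    min_count_rule: str = "min",
    subtract_background: bool = True,
) -> tuple[ExpressionMatrix, QCReport]:
    """Full ladder: correct -> pos-normalize -> background/detect -> content-normalize
    -> min-count filter -> log2. Returns the expression matrix and the QC report."""
    qc = QCReport()
    n_endo = len(raw.class_ids("endogenous"))
    qc.record("input", n_endo, classes=raw.class_counts())

    corrected = probe_background_correct(raw, corrections)
    qc.record("probe_background_correct", n_endo, n_corrections=len(corrections or {}))

    posn = positive_control_normalize(corrected, qc=qc)
    qc.record("positive_control_normalize", n_endo)

    thresholded, detected = negative_background_threshold(
        posn, subtract=subtract_background, qc=qc
    )
    qc.record("negative_background_threshold", len(detected), subtract=subtract_background)

    contentn = content_normalize(thresholded, detected, qc=qc)
    qc.record("content_normalize", len(detected))

    filtered = filter_min_count(contentn, threshold=min_count, rule=min_count_rule)
    qc.record(
        "filter_min_count",
        len(filtered.probe_ids),
        threshold=min_count,
        rule=min_count_rule,
    )

    provenance = [dict(rec) for rec in qc.steps]
    expr = log2_transform(filtered, provenance=provenance)
    qc.record("log2_transform", len(filtered.probe_ids))
    return expr, qc
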