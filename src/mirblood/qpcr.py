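"""RT-qPCR relative quantification via the delta-Ct method.

Duplicate wells are averaged per (sample, assay); a collapsed mean Ct above
35 cycles is treated as below the assay's detection level and censored.
Target Cts are normalized against the per-sample mean Ct of the small-RNA
reference assays (RNU44 and RNU6B by default):

    dCt = Ct_target - mean(Ct_references),   relative expression = 2^-dCt

Samples with a censored reference are excluded from normalization (with a
logged reason). The relative expression feeds the same zero-intercept
cell-fraction regression used for the panel data.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import deconvolution

logger = logging.getLogger(__name__)

CT_DETECTION_LIMIT = 35.0
DEFAULT_REFERENCES = ("RNU44", "RNU6B")


class QpcrError(ValueError):
    pass


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct CSV: sample_id, assay, assay_class, replicate, ct."""
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "assay_class", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise QpcrError(f"Ct table missing column(s): {sorted(missing)}")
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    if (df["ct"] <= 0).any():
        bad = df.loc[df["ct"] <= 0].iloc[0]
        raise QpcrError(f"non-positive Ct for sample {bad['sample_id']!r}, assay {bad['assay']!r}")
    dup = df.duplicated(subset=["sample_id", "assay", "replicate"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise QpcrError(
            f"duplicate replicate index {bad['replicate']} for "
            f"({bad['sample_id']!r}, {bad['assay']!r})"
        )
    return df


def collapse_replicates(
    ct_table: pd.DataFrame, censor_threshold: float = CT_DETECTION_LIMIT
) -> pd.DataFrame:
    """Average replicate wells; censor measurements whose mean Ct exceeds the
    detection limit. A missing duplicate passes through with a warning."""
    validate_ct_table(ct_table)
    grouped = ct_table.groupby(["sample_id", "assay"], sort=True)
    out = grouped.agg(
        assay_class=("assay_class", "first"),
        ct_mean=("ct", "mean"),
        n_replicates=("ct", "size"),
    ).reset_index()
    singles = out[out["n_replicates"] < 2]
    if len(singles):
        warnings.warn(
            f"{len(singles)} (sample, assay) pair(s) have a single replicate", stacklevel=2
        )
    out["censored"] = out["ct_mean"] > censor_threshold
    return out


def delta_ct(
    collapsed: pd.DataFrame, references: Sequence[str] = DEFAULT_REFERENCES
) -> pd.DataFrame:
    """Per (sample, target): dCt against the mean of the reference assays and
    the derived relative expression 2^-dCt. Censored targets carry no dCt;
    samples with any censored reference are excluded entirely."""
    references = list(references)
    rows = []
    for sample, sub in collapsed.groupby("sample_id", sort=True):
        refs = sub[sub["assay"].isin(references)]
        if len(refs) < len(references):
            missing = sorted(set(references) - set(refs["assay"]))
            raise QpcrError(f"sample {sample!r} lacks reference assay(s) {missing}")
        if refs["censored"].any():
            logger.warning(
                "sample %r excluded: censored reference assay(s) %s",
                sample,
                sorted(refs.loc[refs["censored"], "assay"]),
            )
            continue
        ref_mean = float(refs["ct_mean"].mean())
        targets = sub[~sub["assay"].isin(references)]
        for _, row in targets.iterrows():
            censored = bool(row["censored"])
            d = float(row["ct_mean"]) - ref_mean if not censored else np.nan
            rows.append(
                {
                    "sample_id": sample,
                    "assay": row["assay"],
                    "ct_mean": float(row["ct_mean"]),
                    "ref_ct_mean": ref_mean,
                    "censored": censored,
                    "delta_ct": d,
                    "rel_expr": 2.0 ** (-d) if not censored else np.nan,
                }
            )
    return pd.DataFrame(rows)


def qpcr_cell_regression(
    delta_ct_results: pd.DataFrame,
    fractions,
    labels,
    assay: str | None = None,
    value: str = "rel_expr",
    B: int = 1000,
    seed=0,
    contrast=None,
) -> pd.DataFrame:
    """Regress the qPCR readout onto cell fractions per group and compare.

    ``value`` chooses the regressed quantity: ``rel_expr`` (default) or
    ``delta_ct``. Delegates to the deconvolution machinery; ``labels`` may be
    a metadata frame (sample_id/group) or a per-sample vector aligned with
    the delta-Ct rows.
    """
    if value not in ("rel_expr", "delta_ct"):
        raise QpcrError("value must be 'rel_expr' or 'delta_ct'")
    tab = delta_ct_results
    if assay is not None:
        tab = tab[tab["assay"] == assay]
    elif tab["assay"].nunique() > 1:
        raise QpcrError("multiple assays present; pass assay=")
    tab = tab[~tab["censored"]]
    samples = tab["sample_id"].tolist()
    y = tab[value].to_numpy(dtype=float)

    if isinstance(fractions, deconvolution.CellFractions):
        frame = fractions.frame
    else:
        frame = pd.DataFrame(fractions)
    frac = deconvolution.CellFractions(frame.loc[samples], source="qpcr")

    if isinstance(labels, pd.DataFrame):
        labels = labels.set_index("sample_id").loc[samples, "group"].to_numpy()
    labels = np.asarray(labels)
    if contrast is not None:
        keep = np.isin(labels, list(contrast))
        y, labels = y[keep], labels[keep]
        frac = deconvolution.CellFractions(frac.frame.loc[np.array(samples)[keep]], source="qpcr")
    return deconvolution.permutation_test(y, frac, labels, B=B, seed=seed, contrast=contrast)
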