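"""Stress-response summarization of FPKM matrices and 2^-ddCt qPCR
relative expression.

FPKM matrices are genes x samples, with sample labels of the form
``<condition>_<timepoint>h``; every condition must include a 0 h
control.  Heatmap-ready scalings: log2(FPKM + 1), or per-gene z-scores
of the log2 values.  A gene is called responsive when
|log2((FPKM_t + 1) / (FPKM_0 + 1))| >= 1 at any stressed timepoint
(the pseudocount keeps zero-FPKM genes finite; the cutoff is
configurable).

The 2^-ddCt method: technical replicates are averaged first;
dCt = mean Ct(target) - mean Ct(reference) per sample;
ddCt = dCt(treated) - dCt(control at 0 h); fold = 2^-ddCt, so the
control fold is 1 by construction.  The replicate SD is propagated in
Ct space (SDs of target and reference added in quadrature) and then
exponentiated to a fold-scale factor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from genefamscan.io_formats import get_logger

logger = get_logger(__name__)

_SAMPLE_RE = re.compile(r"^(?P<condition>.+)_(?P<time>[0-9.]+)h$")


def parse_sample_label(label: str) -> tuple[str, float]:
    m = _SAMPLE_RE.match(label)
    if not m:
        raise ValueError(f"sample label {label!r} not of the form <condition>_<t>h")
    return m.group("condition"), float(m.group("time"))


def scale_matrix(
    matrix: pd.DataFrame,
    mode: str = "log2",
    response_cutoff: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale an FPKM matrix for display and call responsive genes.

    Returns (scaled matrix, per-gene boolean response call).
    """
    if mode not in {"log2", "zscore"}:
        raise ValueError(f"unknown mode {mode!r}")
    if (matrix < 0).any().any():
        raise ValueError("negative FPKM values")
    labels = {c: parse_sample_label(c) for c in matrix.columns}
    conditions = {cond for cond, _ in labels.values()}
    for cond in conditions:
        if (cond, 0.0) not in labels.values():
            raise ValueError(f"condition {cond!r} lacks a 0 h control sample")
    log2m = np.log2(matrix + 1.0)
    if mode == "log2":
        scaled = log2m
    else:
        std = log2m.std(axis=1, ddof=0)
        centered = log2m.sub(log2m.mean(axis=1), axis=0)
        scaled = centered.div(std.replace(0.0, 1.0), axis=0)
    responsive = pd.Series(False, index=matrix.index)
    for col, (cond, t) in labels.items():
        if t == 0.0:
            continue
        control_col = next(
            c for c, (c2, t2) in labels.items() if c2 == cond and t2 == 0.0
        )
        lfc = log2m[col] - log2m[control_col]
        responsive |= lfc.abs() >= response_cutoff
    return scaled, responsive


@dataclass
class RelativeExpression:
    """2^-ddCt folds per (gene, tissue, condition, timepoint)."""

    folds: pd.DataFrame  # columns: gene, tissue, condition, timepoint, fold, sd_factor


REQUIRED_CT_COLUMNS = [
    "gene", "tissue", "condition", "timepoint", "replicate", "ct",
]


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_timepoint: float = 0.0,
) -> RelativeExpression:
    """Relative expression by the 2^-ddCt method.

    ``ct_table`` columns: gene, tissue, condition, timepoint, replicate,
    ct.  The reference gene must be present in every sample and every
    (gene, tissue, condition) must include the control timepoint.
    """
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    stats = (
        ct_table.groupby(["gene", "tissue", "condition", "timepoint"])["ct"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "ct_mean", "std": "ct_sd"})
        .reset_index()
    )
    stats["ct_sd"] = stats["ct_sd"].fillna(0.0)
    ref = stats[stats["gene"] == reference_gene].set_index(
        ["tissue", "condition", "timepoint"]
    )
    targets = stats[stats["gene"] != reference_gene]
    rows = []
    for (gene, tissue, condition), grp in targets.groupby(
        ["gene", "tissue", "condition"]
    ):
        grp = grp.set_index("timepoint").sort_index()
        if control_timepoint not in grp.index:
            raise ValueError(
                f"{gene}/{tissue}/{condition}: missing control timepoint "
                f"{control_timepoint}"
            )
        dct = {}
        sd = {}
        for t, row in grp.iterrows():
            key = (tissue, condition, t)
            if key not in ref.index:
                raise ValueError(
                    f"reference gene {reference_gene!r} missing for sample "
                    f"{tissue}/{condition}/{t}"
                )
            rrow = ref.loc[key]
            dct[t] = row["ct_mean"] - rrow["ct_mean"]
            sd[t] = float(np.hypot(row["ct_sd"], rrow["ct_sd"]))
        for t in grp.index:
            ddct = dct[t] - dct[control_timepoint]
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    "condition": condition,
                    "timepoint": t,
                    "fold": float(2.0 ** (-ddct)),
                    "sd_factor": float(2.0 ** sd[t]),
                }
            )
    folds = pd.DataFrame(
        rows,
        columns=["gene", "tissue", "condition", "timepoint", "fold", "sd_factor"],
    )
    logger.info("delta_delta_ct: %d (gene, sample) folds", len(folds))
    return RelativeExpression(folds)
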