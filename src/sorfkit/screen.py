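"""CRISPR proliferation-screen scoring and hit classification.

Counts are normalized per column to reads per million and log2
transformed with a +1 pseudocount; each sgRNA's log2 fold change (LFC)
is the mean of its final-timepoint normalized values minus the mean of
its initial ones. The per-ORF phenotype score is the mean LFC of the
sgRNAs targeting the ORF body; sgRNAs targeting the 1-kb region upstream
of the ORF act as host-RNA knockout controls.

Hit classes (body = body score, up = upstream score):
  |body| > 1 and |up| < 1  -> pro_proliferative (body <= -1) or
                              anti_proliferative (body >= 1)
  |body| > 1 and |up| >= 1 -> host_rna_effect
  otherwise                -> non_hit
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REGIONS = ("body", "upstream", "scramble", "essential")

BODY_THRESHOLD = 1.0
UPSTREAM_THRESHOLD = 1.0


def normalize_log2(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million then log2(x+1), column-wise.

    ``counts`` is sgRNA x sample with non-negative integer reads.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero column sum in sample(s): {list(zero.index)}")
    rpm = counts / sums * 1e6
    return np.log2(rpm + 1.0)


def guide_lfc(
    norm: pd.DataFrame,
    initial_cols: Sequence[str],
    final_cols: Sequence[str],
) -> pd.Series:
    """Per-sgRNA log2 fold change: mean(final) - mean(initial)."""
    if not len(initial_cols) or not len(final_cols):
        raise ValueError("need at least one initial and one final column")
    missing = [c for c in [*initial_cols, *final_cols] if c not in norm.columns]
    if missing:
        raise ValueError(f"columns not in matrix: {missing}")
    lfc = norm[list(final_cols)].mean(axis=1) - norm[list(initial_cols)].mean(axis=1)
    lfc.name = "lfc"
    return lfc


def classify_hit(body: float, upstream: float | None) -> str:
    """Apply the dual body/upstream thresholds to one ORF's scores."""
    if abs(body) <= BODY_THRESHOLD:
        return "non_hit"
    if upstream is None or np.isnan(upstream):
        return "non_hit"
    if abs(upstream) < UPSTREAM_THRESHOLD:
        return "pro_proliferative" if body <= -BODY_THRESHOLD else "anti_proliferative"
    return "host_rna_effect"


def phenotype_scores(lfc: pd.Series, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-ORF phenotype scores and hit classes from guide LFCs.

    ``manifest`` needs columns sgrna_id, target_id, region. ORFs with no
    body guides in the LFC table are excluded with a warning; ORFs with
    no upstream guides get an undefined upstream score and class
    ``non_hit`` with flag ``no_upstream_guides``.
    """
    for col in ("sgrna_id", "target_id", "region"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    targeted = manifest[manifest["region"].isin(["body", "upstream"])]
    if (targeted["target_id"].isna() | (targeted["target_id"] == "")).any():
        raise ValueError("body/upstream sgRNAs must carry a valid orf_id")
    merged = targeted.merge(
        lfc.rename("lfc"), left_on="sgrna_id", right_index=True, how="left"
    )
    rows = []
    for orf_id, sub in merged.groupby("target_id", sort=True):
        body = sub.loc[(sub["region"] == "body") & sub["lfc"].notna(), "lfc"]
        upstream = sub.loc[(sub["region"] == "upstream") & sub["lfc"].notna(), "lfc"]
        if body.empty:
            logger.warning("%s: no body sgRNAs with counts; excluded", orf_id)
            continue
        body_score = float(body.mean())
        up_score = float(upstream.mean()) if len(upstream) else float("nan")
        flags = () if len(upstream) else ("no_upstream_guides",)
        rows.append(
            {
                "orf_id": orf_id,
                "body_score": body_score,
                "upstream_score": up_score,
                "n_body": int(len(body)),
                "n_upstream": int(len(upstream)),
                "hit_class": classify_hit(body_score,
                                          up_score if len(upstream) else None),
                "flags": flags,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["orf_id", "body_score", "upstream_score", "n_body",
                 "n_upstream", "hit_class", "flags"],
    )


def control_separation(lfc: pd.Series, manifest: pd.DataFrame) -> dict:
    """Screen QC: essential-gene guides must drop out far more than scrambles.

    Reports per-region |LFC| summaries and a one-sided rank-sum test that
    |LFC| of essential controls exceeds that of scrambles. Missing control
    classes skip the QC with a warning rather than failing the run.
    """
    merged = manifest.merge(
        lfc.rename("lfc"), left_on="sgrna_id", right_index=True, how="inner"
    )
    per_region = {
        region: sub["lfc"].abs().describe().to_dict()
        for region, sub in merged.groupby("region")
    }
    out: dict = {"per_region_abs_lfc": per_region, "qc_performed": False}
    ess = merged.loc[merged["region"] == "essential", "lfc"].abs()
    scr = merged.loc[merged["region"] == "scramble", "lfc"].abs()
    if ess.empty or scr.empty:
        missing = [r for r, s in (("essential", ess), ("scramble", scr)) if s.empty]
        warnings.warn(
            f"control class(es) missing from manifest: {missing}; QC skipped",
            stacklevel=2,
        )
        return out
    stat, p = stats.mannwhitneyu(ess, scr, alternative="greater")
    out.update(
        {
            "qc_performed": True,
            "rank_sum_statistic": float(stat),
            "p_value": float(p),
            "essential_median_abs_lfc": float(ess.median()),
            "scramble_median_abs_lfc": float(scr.median()),
            "qc_pass": bool(p < 0.01 and ess.median() > scr.median()),
        }
    )
    return out


def score_screen(
    counts: pd.DataFrame,
    manifest: pd.DataFrame,
    initial_cols: Sequence[str],
    final_cols: Sequence[str],
) -> tuple[pd.DataFrame, dict]:
    """Normalize, compute guide LFCs, score ORFs and run control QC."""
    norm = normalize_log2(counts)
    lfc = guide_lfc(norm, initial_cols, final_cols)
    phenotypes = phenotype_scores(lfc, manifest)
    qc = control_separation(lfc, manifest)
    return phenotypes, qc
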