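"""Post-search filtering of peptide-spectrum matches.

Implements the fixed filter cascade applied to search-engine output:

1. discard spectra matched to two or more *distinct* peptide sequences
   (a spectrum matching one sequence shared by several ORFs is kept);
2. peptide-level target-decoy FDR control (default 1%);
3. removal of peptides supported only by ``annotated`` ORFs, and of
   intORF-only peptides whose sequence is an exact substring of a
   canonical protein;
4. redundant-ORF resolution: within genomic-overlap groups, a longer ORF
   with unique-region PSM support evicts the shorter overlapping ORF.

The FDR estimator is the plain decoy/target count ratio swept over score
thresholds, converted to monotone q-values (no +1 correction, no pi0).
Peptides tied at the threshold score are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import chain
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSM_COLUMNS = ("spectrum_id", "sample_id", "peptide", "orf_ids", "score", "is_decoy")

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


@dataclass
class FilterReport:
    """Audit trail of record counts through the filter cascade."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, unit: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {stage!r}: count increased {n_in}->{n_out}")
        prev = next(
            (s for s in reversed(self.stages) if s["unit"] == unit), None
        )
        if prev is not None and n_in > prev["n_out"]:
            raise ValueError(
                f"stage {stage!r}: input {n_in} exceeds previous output "
                f"{prev['n_out']} for unit {unit!r}"
            )
        self.stages.append(
            {"stage": stage, "unit": unit, "n_in": n_in, "n_out": n_out}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "unit", "n_in", "n_out"])

    def count(self, stage: str) -> int:
        for s in self.stages:
            if s["stage"] == stage:
                return s["n_out"]
        raise KeyError(stage)


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"row {row}: cannot interpret is_decoy value {value!r}")


def load_psm_table(path: str | Path) -> pd.DataFrame:
    """Load a PSM TSV into a typed table.

    Required columns: spectrum_id, sample_id, peptide, orf_ids
    (semicolon-separated), score, is_decoy. Duplicate (spectrum_id,
    peptide) rows collapse to the best-scoring one.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in PSM_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.index[scores.isna() & df["score"].notna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric score at row {bad[0] + 2} "
            f"(value {df['score'].iloc[bad[0]]!r})"
        )
    if scores.isna().any() or not np.isfinite(scores).all():
        raise ValueError(f"{path}: score column contains missing/non-finite values")
    df = df.assign(
        score=scores,
        is_decoy=[_parse_bool(v, i + 2) for i, v in enumerate(df["is_decoy"])],
        orf_ids=[
            tuple(sorted(filter(None, str(v).split(";")))) if pd.notna(v) else ()
            for v in df["orf_ids"]
        ],
    )
    # collapse duplicate (spectrum, peptide) rows keeping the best score
    df = (
        df.sort_values("score", ascending=False, kind="mergesort")
        .drop_duplicates(subset=["spectrum_id", "peptide"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    decoy_with_targets = df["is_decoy"] & df["orf_ids"].map(bool)
    if decoy_with_targets.any():
        raise ValueError(f"{path}: decoy records must not carry target orf_ids")
    return df[list(PSM_COLUMNS)]


def discard_ambiguous_spectra(psms: pd.DataFrame) -> pd.DataFrame:
    """Drop every record of any spectrum matched to >=2 distinct peptides."""
    n_seqs = psms.groupby("spectrum_id")["peptide"].transform("nunique")
    return psms[n_seqs == 1].reset_index(drop=True)


def peptide_level_fdr(
    psms: pd.DataFrame, alpha: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-level target-decoy FDR filtering.

    Aggregates PSMs to the best score per peptide sequence (targets and
    decoys separately), sweeps score thresholds computing
    ``FDR(t) = #decoy peptides >= t / #target peptides >= t``, converts to
    monotone q-values, and retains target peptides with ``q <= alpha``.

    Returns ``(retained, all_peptides)`` where ``all_peptides`` carries
    every target/decoy peptide with its q-value for auditing.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if psms.empty:
        raise ValueError("no PSM records to filter")
    agg = (
        psms.groupby(["peptide", "is_decoy"], sort=False)
        .agg(
            best_score=("score", "max"),
            psm_count=("score", "size"),
            samples=("sample_id", lambda s: tuple(sorted(set(s)))),
            orf_ids=("orf_ids", lambda col: tuple(sorted(set(chain.from_iterable(col))))),
        )
        .reset_index()
    )
    if not agg["is_decoy"].any():
        raise ValueError(
            "no decoy peptides present: run the search against the decoy "
            "library so the FDR can be estimated"
        )
    agg = agg.sort_values(
        ["best_score", "is_decoy", "peptide"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    cum_decoy = agg["is_decoy"].cumsum()
    cum_target = (~agg["is_decoy"]).cumsum()
    fdr_row = cum_decoy / cum_target.clip(lower=1)
    # threshold = score: counts taken at the last row of each tied score
    fdr_at_score = (
        pd.Series(fdr_row.values, index=agg.index)
        .groupby(agg["best_score"], sort=False)
        .transform("last")
    )
    q = fdr_at_score[::-1].cummin()[::-1]
    agg["q_value"] = q.clip(upper=1.0).values
    retained = agg[(~agg["is_decoy"]) & (agg["q_value"] <= alpha)].copy()
    retained = retained.drop(columns=["is_decoy"]).reset_index(drop=True)
    return retained, agg


def remove_annotated_and_embedded(
    pepids: pd.DataFrame,
    catalogue: pd.DataFrame,
    canonical: Mapping[str, str],
    il_equivalent: bool = False,
) -> pd.DataFrame:
    """Remove annotated-only peptides and canonical-embedded intORF peptides.

    A peptide is removed when every supporting ORF has category
    ``annotated``, or when every supporting ORF is an ``intORF`` *and* its
    sequence is an exact substring of some canonical protein. Setting
    ``il_equivalent`` collapses I/L before the substring test.
    """
    cat = catalogue.set_index("orf_id")["category"]
    haystack = "|".join(canonical.values())
    if il_equivalent:
        haystack = haystack.replace("I", "L")

    def keep(row) -> bool:
        cats = {cat[o] for o in row.orf_ids}
        if cats == {"annotated"}:
            return False
        if cats == {"intORF"}:
            needle = row.peptide.replace("I", "L") if il_equivalent else row.peptide
            if needle in haystack:
                return False
        return True

    mask = [keep(row) for row in pepids.itertuples()]
    return pepids[mask].reset_index(drop=True)


def _overlap_groups(orf_rows: pd.DataFrame) -> list[list[str]]:
    """Connected components of genomic overlap on one chromosome+strand."""
    groups: list[list[str]] = []
    for _, sub in orf_rows.groupby(["chrom", "strand"], sort=True):
        sub = sub.sort_values(["g_min", "g_max", "orf_id"], kind="mergesort")
        current: list[str] = []
        reach = -1
        for row in sub.itertuples():
            if current and row.g_min <= reach:
                current.append(row.orf_id)
            else:
                if len(current) > 1:
                    groups.append(current)
                current = [row.orf_id]
            reach = max(reach, row.g_max)
        if len(current) > 1:
            groups.append(current)
    return groups


def resolve_redundant_orfs(
    pepids: pd.DataFrame, catalogue: pd.DataFrame
) -> pd.DataFrame:
    """Resolve redundant overlapping ORFs across the identified set.

    ORFs supporting retained peptides are grouped by genomic overlap on
    the same strand. Within each group, processed in descending length, a
    longer ORF supported by at least one peptide that is *not* a substring
    of a shorter overlapping ORF's full peptide evicts that shorter ORF.
    Groups where the condition never fires are retained intact and their
    peptides flagged ``unresolved_redundant``. Peptides losing all
    supporting ORFs are removed.
    """
    if pepids.empty:
        out = pepids.copy()
        out["flags"] = pd.Series(dtype=object)
        return out
    cat = catalogue.set_index("orf_id")
    support: dict[str, set[str]] = {}
    for row in pepids.itertuples():
        for o in row.orf_ids:
            support.setdefault(o, set()).add(row.peptide)
    orf_rows = cat.loc[sorted(support)].reset_index()
    discarded: set[str] = set()
    unresolved: set[str] = set()
    for group in _overlap_groups(orf_rows):
        info = cat.loc[group]
        order = info.sort_values(
            ["length_nt", "orf_id"], ascending=[False, True], kind="mergesort"
        )
        removed_here: set[str] = set()
        had_pair = False
        for long_id in order.index:
            if long_id in removed_here:
                continue
            L = info.loc[long_id]
            for short_id in order.index:
                if short_id == long_id or short_id in removed_here:
                    continue
                S = info.loc[short_id]
                if S.length_nt >= L.length_nt:
                    continue
                if S.g_min > L.g_max or L.g_min > S.g_max:
                    continue
                had_pair = True
                if any(p not in S.peptide for p in support[long_id]):
                    removed_here.add(short_id)
        discarded |= removed_here
        if had_pair and not removed_here:
            unresolved |= set(group)
    new_rows = []
    for row in pepids.itertuples(index=False):
        kept = tuple(o for o in row.orf_ids if o not in discarded)
        if not kept:
            continue
        d = row._asdict()
        d["orf_ids"] = kept
        flags = set(d.get("flags") or ())
        if any(o in unresolved for o in kept):
            flags.add("unresolved_redundant")
        d["flags"] = tuple(sorted(flags))
        new_rows.append(d)
    return pd.DataFrame(new_rows, columns=list(pepids.columns) + (
        [] if "flags" in pepids.columns else ["flags"]
    ))


def summarize_support(pepids: pd.DataFrame) -> dict:
    """PSM-support and cross-sample detection summary for the final catalogue."""
    n = len(pepids)
    if n == 0:
        return {
            "n_peptides": 0, "single_psm_fraction": float("nan"),
            "multi_psm_fraction": float("nan"),
            "multi_sample_fraction": float("nan"),
        }
    single = int((pepids["psm_count"] == 1).sum())
    multi_sample = int((pepids["samples"].map(len) >= 2).sum())
    return {
        "n_peptides": n,
        "single_psm_fraction": single / n,
        "multi_psm_fraction": (n - single) / n,
        "multi_sample_fraction": multi_sample / n,
    }


def run_psm_pipeline(
    psms: pd.DataFrame,
    catalogue: pd.DataFrame,
    canonical: Mapping[str, str],
    alpha: float = 0.01,
    il_equivalent: bool = False,
) -> tuple[pd.DataFrame, FilterReport]:
    """Run the full fixed-order filter cascade, returning catalogue + report."""
    report = FilterReport()
    n0 = len(psms)
    unambiguous = discard_ambiguous_spectra(psms)
    report.add("ambiguity_filter", "psm", n0, len(unambiguous))
    retained, all_peps = peptide_level_fdr(unambiguous, alpha=alpha)
    n_target_peps = int((~all_peps["is_decoy"]).sum())
    report.add("peptide_fdr", "peptide", n_target_peps, len(retained))
    deannotated = remove_annotated_and_embedded(
        retained, catalogue, canonical, il_equivalent=il_equivalent
    )
    report.add("annotated_embedded_removal", "peptide", len(retained),
               len(deannotated))
    resolved = resolve_redundant_orfs(deannotated, catalogue)
    report.add("redundancy_resolution", "peptide", len(deannotated),
               len(resolved))
    # attach resolved categories for downstream naming/summaries
    cat = catalogue.set_index("orf_id")["category"]
    resolved = resolved.assign(
        categories=[tuple(sorted({cat[o] for o in r})) for r in resolved["orf_ids"]]
    )
    return resolved, report
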