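"""Expression quantification and the sex-biased screen.

Expression is quantified as FPKM (fragments per kilobase of feature per
million mapped fragments) with the zero-substitution convention: any FPKM
of exactly 0 is replaced by 0.001 so fold changes against silent features
stay finite.  Sex-biased transcripts are called per developmental stage from
the pooled one-sample-per-sex design: the effect size is the log2 ratio of
substituted FPKM values, the p-value comes from a pluggable two-sample count
test (default: two-proportion normal test of the feature count against the
library total), and multiplicity is controlled per stage with
Benjamini–Hochberg FDR.  A feature is sex-specific when the other sex's raw
count is zero at every stage.  The candidate screen keeps fragments with
male-shifted expression (log2FC ≥ 1) at one or more stages of the
sex-determination window (before 40 days after hatch).
"""

from __future__ import annotations

import math
from collections.abc import Callable
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError, ValidationError
from .subtraction_pipeline import Fragment

FPKM_FLOOR = 0.001


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    total_mapped: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM table: count × 10⁹ / (length × library total), zeros → 0.001.

    ``lengths`` is per feature (bp); ``total_mapped`` per sample (defaults
    to the column sums of ``counts``).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValidationError("every feature needs a length")
    if (lengths <= 0).any():
        raise ValidationError("feature lengths must be positive")
    if total_mapped is None:
        total_mapped = counts.sum(axis=0)
    total_mapped = total_mapped.reindex(counts.columns)
    if (total_mapped <= 0).any():
        raise ValidationError("total_mapped must be positive for every sample")
    out = counts.astype(float).mul(1e9).div(lengths, axis=0).div(total_mapped, axis=1)
    return out.mask(out == 0.0, FPKM_FLOOR)


def benjamini_hochberg(pvalues: Iterable[float]) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone in the raw p-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided normal test of equal proportions x1/n1 vs x2/n2.

    The default per-feature count test for the pooled (replicate-free)
    design; returns 1.0 when both counts are zero.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library totals must be positive")
    if x1 == 0 and x2 == 0:
        return 1.0
    p_pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (x1 / n1 - x2 / n2) / se
    return 2.0 * float(stats.norm.sf(abs(z)))


def sex_specific_features(counts: pd.DataFrame) -> pd.DataFrame:
    """Sex-specificity over all stages from raw counts.

    ``male_specific``: zero raw count in every female sample and nonzero in
    at least one male sample (and mirrored for ``female_specific``).
    Columns are named ``{M,F}{stage}``.
    """
    m_cols = [c for c in counts.columns if c.startswith("M")]
    f_cols = [c for c in counts.columns if c.startswith("F")]
    if not m_cols or not f_cols:
        raise UsageError("count table must contain both M* and F* samples")
    male_any = counts[m_cols].sum(axis=1) > 0
    female_any = counts[f_cols].sum(axis=1) > 0
    return pd.DataFrame(
        {
            "male_specific": male_any & ~female_any,
            "female_specific": female_any & ~male_any,
        },
        index=counts.index,
    )


def sex_biased_calls(
    fpkm_table: pd.DataFrame,
    counts: pd.DataFrame,
    stage: int,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    test: Callable[[int, int, int, int], float] = two_proportion_test,
) -> pd.DataFrame:
    """Per-stage differential calls between the pooled male and female sample.

    Returns a frame with log2fc (male over female, substituted FPKM),
    pvalue, fdr and flag ∈ {male_biased, female_biased, none}.  Flags
    require |log2fc| ≥ lfc_threshold and fdr ≤ fdr_threshold.
    """
    m_col, f_col = f"M{stage}", f"F{stage}"
    for col in (m_col, f_col):
        if col not in counts.columns or col not in fpkm_table.columns:
            raise UsageError(f"missing sample column {col}")
    lfc = np.log2(fpkm_table[m_col] / fpkm_table[f_col])
    n_m = int(counts[m_col].sum())
    n_f = int(counts[f_col].sum())
    pvals = np.array(
        [test(int(xm), n_m, int(xf), n_f) for xm, xf in zip(counts[m_col], counts[f_col])]
    )
    fdr = benjamini_hochberg(pvals)
    flag = np.where(
        (lfc >= lfc_threshold) & (fdr <= fdr_threshold),
        "male_biased",
        np.where((lfc <= -lfc_threshold) & (fdr <= fdr_threshold), "female_biased", "none"),
    )
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": pvals, "fdr": fdr, "flag": flag}, index=counts.index
    )


def expression_flags(
    counts: pd.DataFrame,
    lengths: pd.Series,
    stages: Iterable[int],
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    test: Callable[[int, int, int, int], float] = two_proportion_test,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All stages at once: (fpkm, per-stage log2fc matrix, flags).

    Flags is a feature × stage frame of {male_biased, female_biased, none},
    with two extra boolean columns for all-stage sex specificity.
    """
    table = fpkm(counts, lengths)
    lfc = {}
    flags = {}
    for stage in stages:
        calls = sex_biased_calls(table, counts, stage, lfc_threshold, fdr_threshold, test)
        lfc[stage] = calls["log2fc"]
        flags[stage] = calls["flag"]
    lfc_df = pd.DataFrame(lfc)
    flags_df = pd.DataFrame(flags)
    spec = sex_specific_features(counts)
    flags_df["male_specific"] = spec["male_specific"]
    flags_df["female_specific"] = spec["female_specific"]
    return table, lfc_df, flags_df


def male_candidate_screen(
    fragments: list[Fragment],
    lfc_by_stage: pd.DataFrame,
    fragment_feature: dict[str, str] | None = None,
    stages_before: Iterable[int] = (18, 22, 26, 30, 35),
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Keep fragments male-shifted before gonadal differentiation.

    Each fragment is quantified through its source transcript (or an
    explicit fragment → feature map).  A fragment survives when its log2
    fold change reaches ``lfc_min`` at ≥ 1 stage of ``stages_before``; the
    result is ranked by the maximum such fold change and carries the full
    per-stage pass/fail matrix.
    """
    stages = [s for s in stages_before if s in lfc_by_stage.columns]
    if not stages:
        raise UsageError("none of the requested stages are quantified")
    rows = []
    for f in fragments:
        feature = (fragment_feature or {}).get(f.fragment_id, f.source_transcript_id)
        if feature not in lfc_by_stage.index:
            continue
        lfc = lfc_by_stage.loc[feature, stages]
        passes = lfc >= lfc_min
        rows.append(
            {
                "fragment_id": f.fragment_id,
                "feature_id": feature,
                "max_log2fc": float(lfc.max()),
                "n_stages_passing": int(passes.sum()),
                **{f"pass_{s}": bool(passes[s]) for s in stages},
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = df[df["n_stages_passing"] >= 1]
    return df.sort_values(
        ["max_log2fc", "fragment_id"], ascending=[False, True]
    ).reset_index(drop=True)
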