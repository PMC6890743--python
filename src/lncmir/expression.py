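"""Expression-layer statistics.

Fold changes, the differential-expression filter (|log2FC|, p, BH q),
lncRNA-target Pearson correlation over per-stage log2 fold-change vectors,
correlation binning, and the comparative-Ct (2^-ddCt) qPCR utility.

p-values: the published workflow used Cuffdiff, which models replicated
count data and is out of scope here.  For replicate-free FPKM fixtures this
module provides a stand-in test (a conditional-binomial comparison of
FPKM-scaled pseudo-counts between two samples, i.e. the classical
two-sample Poisson rate test) that is NOT equivalent to Cuffdiff; real
analyses should pass externally computed p-values through instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log2_fold_change",
    "standin_pvalues",
    "differential_filter",
    "pearson_correlation",
    "correlate_pairs",
    "bin_correlations",
    "relative_expression_ddct",
]


def _check_stages(df: pd.DataFrame, *stages):
    for s in stages:
        if s not in df.columns:
            raise KeyError(f"stage {s!r} not in expression matrix")


def log2_fold_change(
    df: pd.DataFrame, stage_a: str, stage_b: str, pseudocount: float = 1.0
) -> pd.Series:
    """Per-transcript log2((FPKM_b + c) / (FPKM_a + c)).

    ``stage_a`` is the reference.  ``pseudocount`` may be 0 only when every
    involved value is positive.
    """
    _check_stages(df, stage_a, stage_b)
    a = df[stage_a].to_numpy(float) + pseudocount
    b = df[stage_b].to_numpy(float) + pseudocount
    if pseudocount <= 0 and ((a <= 0).any() or (b <= 0).any()):
        raise ValueError("pseudocount 0 requires strictly positive FPKM")
    return pd.Series(np.log2(b / a), index=df.index, name=f"{stage_b}_vs_{stage_a}")


def standin_pvalues(
    df: pd.DataFrame, stage_a: str, stage_b: str, scale: float = 20.0
) -> pd.Series:
    """Replicate-free stand-in p-values (two-sample Poisson rate test).

    FPKM values are scaled to pseudo-counts and the two samples are
    compared with the conditional binomial test.  Labeled non-equivalent
    to a replicated DE model; use only on simulated fixtures.
    """
    _check_stages(df, stage_a, stage_b)
    ka = np.rint(df[stage_a].to_numpy(float) * scale).astype(int)
    kb = np.rint(df[stage_b].to_numpy(float) * scale).astype(int)
    pvals = np.ones(len(df))
    for i, (a, b) in enumerate(zip(ka, kb)):
        n = a + b
        if n > 0:
            pvals[i] = stats.binomtest(b, n, 0.5).pvalue
    return pd.Series(pvals, index=df.index, name="p")


def differential_filter(
    de: pd.DataFrame,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.005,
    q_thresh: float = 0.01,
    fc_scale: str = "log2",
) -> pd.DataFrame:
    """DE filter: |log2FC| >= threshold AND p < 0.005 AND BH q < 0.01.

    ``de`` needs columns ``log2fc`` and ``p`` (one contrast).  BH
    adjustment is applied within the contrast.  ``fc_scale='log2'``
    interprets ``fc_thresh`` in log2 units (default 1, i.e. 2-fold);
    ``fc_scale='literal'`` demands |log2FC| >= 2 for the stricter reading
    of a "fold change beyond +/-2" gate.
    """
    if de.empty:
        raise ValueError("empty contrast")
    out = de.copy()
    gate = fc_thresh if fc_scale == "log2" else 2.0
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["pass"] = (
        (out["log2fc"].abs() >= gate)
        & (out["p"] < p_thresh)
        & (out["q"] < q_thresh)
    )
    return out


def pearson_correlation(vec_a, vec_b) -> float:
    """Product-moment correlation; raises on zero variance or length < 3."""
    a = np.asarray(vec_a, float)
    b = np.asarray(vec_b, float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("vectors must share a length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def correlate_pairs(
    df: pd.DataFrame,
    pairs: list,
    reference_stage: str,
    stages: list,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pearson r between per-stage log2FC vectors of interacting pairs.

    Each pair is correlated over ``stages`` (log2 fold change of each
    stage against ``reference_stage``).  Zero-variance pairs are kept with
    ``r = NaN`` and ``defined = False`` so they can be excluded from
    binning without being silently dropped.
    """
    fc = pd.DataFrame(
        {s: log2_fold_change(df, reference_stage, s, pseudocount) for s in stages}
    )
    rows = []
    for a, b in pairs:
        try:
            r = pearson_correlation(fc.loc[a].to_numpy(), fc.loc[b].to_numpy())
            rows.append({"lncrna_id": a, "target_id": b, "r": r, "n": len(stages),
                         "defined": True})
        except ValueError:
            rows.append({"lncrna_id": a, "target_id": b, "r": np.nan,
                         "n": len(stages), "defined": False})
    return pd.DataFrame(rows)


def bin_correlations(records: pd.DataFrame) -> dict:
    """Correlation-range summary of defined pairs.

    Fractions with |r| >= 0.8, 0.6 and 0.5, plus the positive/negative
    split, mirroring the standard reporting bins.
    """
    defined = records[records["defined"]] if "defined" in records else records
    r = defined["r"].to_numpy(float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise ValueError("no defined correlations to bin")
    return {
        "n": int(r.size),
        "frac_abs_ge_0.8": float((np.abs(r) >= 0.8).mean()),
        "frac_abs_ge_0.6": float((np.abs(r) >= 0.6).mean()),
        "frac_abs_ge_0.5": float((np.abs(r) >= 0.5).mean()),
        "frac_positive": float((r > 0).mean()),
        "frac_negative": float((r < 0).mean()),
        "mean_r": float(r.mean()),
    }


def relative_expression_ddct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Comparative-Ct relative expression: 2^(-ddCt).

    ddCt = (Ct_target - Ct_reference) - (Ct_target_cal - Ct_reference_cal).
    """
    ddct = (ct_target - ct_reference) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return float(2.0 ** (-ddct))
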