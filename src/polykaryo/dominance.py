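"""Homoeolog expression dominance across tissues.

For each homoeolog triplet (one gene per subgenome) and tissue, a
randomized-complete-block ANOVA — subgenome as the fixed 3-level factor,
replicate as the block (the "replicate kept as random" layout, which for
a balanced design yields the same F statistic as the one-way mixed
model) — tests for differential expression among subgenomes.  When the
omnibus test rejects, the top subgenome is contrasted against each of
the other two using the pooled error term; it is called dominant iff
both contrasts are individually significant.  Per-tissue dominant counts
are then tested against the neutral 1:1:1 expectation with a chi-square
test (df = 2), and pairwise count ratios are reported.

Analysis is on log2(TPM + 0.01) by default, which makes calls invariant
to global rescaling of the TPM unit; a raw-scale option exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TripletExpression

SG_LABELS = ("SG1", "SG2", "SG3")
NONE_LABEL = "NONE"

LOG_OFFSET = 0.01


def filter_triplets(
    expr: TripletExpression, tissue: str, min_tpm: float = 0.01
) -> TripletExpression:
    """Drop triplets with an unexpressed homoeolog in ``tissue``.

    A homoeolog fails the floor when every replicate is below ``min_tpm``;
    the triplet needs all three homoeologs, so one failing homoeolog
    drops the whole triplet for that tissue.
    """
    ids, arr = expr.tissue_array(tissue)  # (T, 3, R)
    expressed = (arr >= min_tpm).any(axis=2).all(axis=1)
    keep = [t for t, ok in zip(ids, expressed) if ok]
    sub = expr.data[
        (expr.data["tissue"] == tissue) & expr.data["triplet_id"].isin(set(keep))
    ]
    return TripletExpression(sub.reset_index(drop=True))


def _rcb_anova(y: np.ndarray):
    """Vectorized randomized-complete-block ANOVA per triplet.

    ``y``: (T, 3, R) response.  Returns (F, p, mse, df_error) with the
    subgenome factor on 2 df and error on 2(R-1) df.
    """
    t, a, r = y.shape
    assert a == 3
    grand = y.mean(axis=(1, 2), keepdims=True)
    treat = y.mean(axis=2, keepdims=True)
    block = y.mean(axis=1, keepdims=True)
    ss_total = ((y - grand) ** 2).sum(axis=(1, 2))
    ss_treat = (r * (treat - grand) ** 2).sum(axis=(1, 2))
    ss_block = (a * (block - grand) ** 2).sum(axis=(1, 2))
    ss_error = np.maximum(ss_total - ss_treat - ss_block, 0.0)
    df_error = a * r - a - r + 1  # (a-1)(r-1)
    ms_treat = ss_treat / (a - 1)
    mse = ss_error / df_error
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_treat / mse
    p = stats.f.sf(f, a - 1, df_error)
    # zero error variance: unequal means -> decide by means with p = 0
    zero_var = mse <= 1e-300
    p = np.where(zero_var & (ss_treat > 0), 0.0, p)
    p = np.where(zero_var & (ss_treat <= 0), 1.0, p)
    return f, p, mse, df_error


def call_dominance(
    expr: TripletExpression,
    tissue: str,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-triplet dominance calls for one tissue.

    Returns a frame with the dominant subgenome (or NONE), the omnibus
    p-value, the two top-vs-other contrast p-values, and subgenome means
    (on the analysis scale).
    """
    ids, arr = expr.tissue_array(tissue)
    y = np.log2(arr + LOG_OFFSET) if log_scale else arr.astype(float)
    t, _, r = y.shape
    f, p_omni, mse, df_err = _rcb_anova(y)
    means = y.mean(axis=2)  # (T, 3)
    top = means.argmax(axis=1)
    order = np.argsort(means, axis=1)
    se = np.sqrt(2.0 * mse / r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (means[np.arange(t), top] - means[np.arange(t), order[:, 1]]) / se
        t2 = (means[np.arange(t), top] - means[np.arange(t), order[:, 0]]) / se
    p1 = 2.0 * stats.t.sf(np.abs(t1), df_err)
    p2 = 2.0 * stats.t.sf(np.abs(t2), df_err)
    zero_var = mse <= 1e-300
    strict_top = (means[np.arange(t), top] > means[np.arange(t), order[:, 1]])
    p1 = np.where(zero_var & strict_top, 0.0, np.where(zero_var, 1.0, p1))
    p2 = np.where(zero_var & (means[np.arange(t), top] >
                              means[np.arange(t), order[:, 0]]),
                  0.0, np.where(zero_var, 1.0, p2))
    dominant = np.full(t, NONE_LABEL, dtype=object)
    sig = (p_omni < alpha) & (p1 < alpha) & (p2 < alpha) & strict_top
    dominant[sig] = np.asarray(SG_LABELS, dtype=object)[top[sig]]
    return pd.DataFrame(
        {
            "triplet_id": ids,
            "tissue": tissue,
            "dominant": dominant,
            "p_omnibus": p_omni,
            "p_top_vs_mid": p1,
            "p_top_vs_low": p2,
            "mean_sg1": means[:, 0],
            "mean_sg2": means[:, 1],
            "mean_sg3": means[:, 2],
            "zero_variance": zero_var,
        }
    )


@dataclass
class DominanceSummary:
    tissue: str
    n_tested: int
    counts: Dict[str, int]  # dominant triplets per subgenome
    chi2: Optional[float]  # vs 1:1:1, df = 2; None if no dominant calls
    p_value: Optional[float]
    ratios: Dict[str, float]  # SG3/SG1, SG3/SG2, SG2/SG1 dominant-count ratios


def summarize_dominance(calls: pd.DataFrame, n_tested: int) -> DominanceSummary:
    """Count dominant triplets per subgenome and test against 1:1:1."""
    tissues = calls["tissue"].unique()
    if len(tissues) != 1:
        raise ValueError("summarize one tissue at a time")
    counts = {sg: int((calls["dominant"] == sg).sum()) for sg in SG_LABELS}
    total = sum(counts.values())
    if total > 0:
        observed = np.array([counts[sg] for sg in SG_LABELS], dtype=float)
        chi2, p = stats.chisquare(observed)
        chi2, p = float(chi2), float(p)
    else:
        chi2 = p = None

    def _ratio(a: str, b: str) -> float:
        return counts[a] / counts[b] if counts[b] > 0 else float("inf")

    return DominanceSummary(
        tissue=str(tissues[0]),
        n_tested=n_tested,
        counts=counts,
        chi2=chi2,
        p_value=p,
        ratios={
            "SG3/SG1": _ratio("SG3", "SG1"),
            "SG3/SG2": _ratio("SG3", "SG2"),
            "SG2/SG1": _ratio("SG2", "SG1"),
        },
    )


def dominance_analysis(
    expr: TripletExpression,
    tissues: Optional[List[str]] = None,
    alpha: float = 0.05,
    min_tpm: float = 0.01,
    log_scale: bool = True,
) -> tuple[pd.DataFrame, List[DominanceSummary]]:
    """Filter, call and summarize dominance for each requested tissue."""
    tissues = tissues if tissues is not None else expr.tissues
    all_calls = []
    summaries = []
    for tissue in tissues:
        kept = filter_triplets(expr, tissue, min_tpm=min_tpm)
        if kept.data.empty:
            continue
        calls = call_dominance(kept, tissue, alpha=alpha, log_scale=log_scale)
        all_calls.append(calls)
        summaries.append(summarize_dominance(calls, n_tested=len(calls)))
    calls_frame = (
        pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame()
    )
    return calls_frame, summaries
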