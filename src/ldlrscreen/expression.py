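"""Cholesterol-modulation calls from the two-condition expression experiment.

Genes are tested per contrast (statin vs control, nLDL vs control) with an
unpaired two-sided pooled-variance Student t-test on linear-scale expression
(df = n1 + n2 - 2; duplicates per condition give df = 2), and effect sizes
are reported as signed fold-changes: the ratio r of group means when r >= 1,
otherwise -1/r, so down-regulation is a negative number of magnitude >= 1
and no value falls in (-1, 1). A gene is cholesterol-modulated when its
expression rises under sterol depletion (statin: FC >= +1.1, P <= 0.05)
and/or falls under sterol loading (nLDL: FC <= -1.1, P <= 0.05). No
multiple-testing correction is applied by default (raw P <= 0.05); a
Benjamini-Hochberg option exists, as does a log2-scale test variant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

CONTRASTS = {"statin_vs_control": "statin", "nldl_vs_control": "nldl"}

MOD_UP = "up"
MOD_DOWN = "down"
MOD_NONE = "none"


def signed_fold_change(mean_treat: float, mean_ctrl: float) -> float:
    """Signed fold-change of two positive group means.

    Returns r = mean_treat/mean_ctrl when r >= 1 and -1/r otherwise;
    antisymmetric under swapping the groups, equal to 1.0 when they agree.
    """
    if mean_treat <= 0 or mean_ctrl <= 0:
        raise ValueError("group means must be strictly positive")
    r = mean_treat / mean_ctrl
    return r if r >= 1.0 else -1.0 / r


def _pooled_t(treat: np.ndarray, ctrl: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided pooled-variance t-test; returns (t, p, degenerate_variance).

    Degenerate case: both groups have zero within-group variance. Equal
    means then give p = 1, unequal means p = 0 with the degenerate flag set.
    """
    n1, n2 = len(treat), len(ctrl)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per group")
    v1 = float(np.var(treat, ddof=1))
    v2 = float(np.var(ctrl, ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        if float(np.mean(treat)) == float(np.mean(ctrl)):
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    t, p = sps.ttest_ind(treat, ctrl, equal_var=True)
    return float(t), float(p), False


def de_test(
    expr: pd.DataFrame,
    contrast: str,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Differential-expression test for one contrast, all genes.

    ``expr`` is a long table (gene, condition, replicate, expression) on the
    linear scale. Returns one row per gene with ``signed_fc``, ``p_value``
    and a ``degenerate_variance`` flag. With ``log_scale`` the t-test runs on
    log2 values (the fold-change is then the ratio of geometric means);
    otherwise the test is on the linear scale as measured.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    treat_cond = CONTRASTS[contrast]
    sub = expr[expr["condition"].isin(("control", treat_cond))]
    rows = []
    for gene, grp in sub.groupby("gene", sort=False):
        treat = grp.loc[grp["condition"] == treat_cond, "expression"].to_numpy(float)
        ctrl = grp.loc[grp["condition"] == "control", "expression"].to_numpy(float)
        if len(treat) == 0 or len(ctrl) == 0:
            raise ValueError(f"gene {gene!r} lacks data for contrast {contrast}")
        if log_scale:
            t, p, degen = _pooled_t(np.log2(treat), np.log2(ctrl))
            fc = signed_fold_change(
                float(np.exp2(np.mean(np.log2(treat)))),
                float(np.exp2(np.mean(np.log2(ctrl)))),
            )
        else:
            t, p, degen = _pooled_t(treat, ctrl)
            fc = signed_fold_change(float(np.mean(treat)), float(np.mean(ctrl)))
        rows.append(
            {
                "gene": gene,
                "contrast": contrast,
                "signed_fc": fc,
                "p_value": p,
                "t_statistic": t,
                "degenerate_variance": degen,
            }
        )
    return pd.DataFrame(rows).sort_values("gene", kind="mergesort",
                                          ignore_index=True)


def _direction(fc: float, p: float, alpha: float, fc_threshold: float) -> str:
    if p > alpha:
        return MOD_NONE
    if fc >= fc_threshold:
        return MOD_UP
    if fc <= -fc_threshold:
        return MOD_DOWN
    return MOD_NONE


def de_all(
    expr: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.1,
    log_scale: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Both contrasts for every gene, with per-contrast modulation direction.

    With ``fdr`` the p-values are Benjamini-Hochberg adjusted within each
    contrast before thresholding (off by default: the classification uses
    raw P <= alpha).
    """
    frames = []
    for contrast in CONTRASTS:
        df = de_test(expr, contrast, log_scale=log_scale)
        if fdr:
            df["p_value"] = sps.false_discovery_control(df["p_value"], method="bh")
        df["modulated_direction"] = [
            _direction(fc, p, alpha, fc_threshold)
            for fc, p in zip(df["signed_fc"], df["p_value"])
        ]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def classify_modulated(
    de_results: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.1,
) -> pd.DataFrame:
    """Per-gene cholesterol-modulation call from both contrasts.

    Modulated iff the statin contrast is significantly up
    (signed_fc >= +fc_threshold, p <= alpha) or the nLDL contrast
    significantly down (signed_fc <= -fc_threshold, p <= alpha). Both
    contrasts must be present for every gene.
    """
    pivot: dict[str, dict[str, tuple[float, float]]] = {}
    for _, row in de_results.iterrows():
        pivot.setdefault(row["gene"], {})[row["contrast"]] = (
            row["signed_fc"], row["p_value"]
        )
    rows = []
    for gene in sorted(pivot):
        both = pivot[gene]
        missing = set(CONTRASTS) - set(both)
        if missing:
            raise ValueError(
                f"gene {gene!r} missing contrast(s): {', '.join(sorted(missing))}"
            )
        s_fc, s_p = both["statin_vs_control"]
        n_fc, n_p = both["nldl_vs_control"]
        statin_up = s_fc >= fc_threshold and s_p <= alpha
        nldl_down = n_fc <= -fc_threshold and n_p <= alpha
        rows.append(
            {"gene": gene, "cholesterol_modulated": bool(statin_up or nldl_down)}
        )
    return pd.DataFrame(rows, columns=["gene", "cholesterol_modulated"])
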