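"""Candidate integration and the screening funnel report.

A primary hit graduates to a cherry-picked candidate when its expression is
cholesterol-modulated and/or it carries a lipid-GWAS association flag
(inclusive OR by default; stricter "and" and "expression_only" policies are
available for sensitivity analysis). The funnel report tallies the staged
attrition — genes screened, scorable, primary hits (up/down), candidates,
rescreened, validated — and the deconvolution validation rate as a
percentage of rescreened candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


class IntegrationError(ValueError):
    """Inconsistent inputs to integration or the funnel report."""


def integrate(
    summaries: pd.DataFrame,
    modulated: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    policy: str = "or",
) -> pd.DataFrame:
    """Combine hit calls with expression modulation and annotation flags.

    Outer-joins on gene over the hit-summary universe: genes absent from the
    expression or flag table are kept and treated as not-modulated /
    unflagged (counts logged), so the hit universe is preserved. Duplicate
    gene rows in any input are an error. The ``candidate`` flag is:

    - ``or``              hit and (modulated or flagged)
    - ``and``             hit and modulated and flagged
    - ``expression_only`` hit and modulated
    """
    if policy not in ("or", "and", "expression_only"):
        raise IntegrationError(f"unknown integration policy {policy!r}")
    for name, df in (("hit summary", summaries), ("modulation", modulated),
                     ("annotation flags", flags)):
        if df is None:
            continue
        dup = df["gene"].duplicated()
        if dup.any():
            raise IntegrationError(
                f"duplicate gene row(s) in {name} table: "
                f"{', '.join(sorted(set(df.loc[dup, 'gene'])))}"
            )

    out = summaries[["gene", "hit_call"]].merge(
        modulated[["gene", "cholesterol_modulated"]], on="gene", how="left"
    )
    n_unmeasured = int(out["cholesterol_modulated"].isna().sum())
    if n_unmeasured:
        logger.info(
            "%d gene(s) absent from the expression table treated as "
            "not-modulated", n_unmeasured,
        )
    out["cholesterol_modulated"] = out["cholesterol_modulated"].eq(True)
    if flags is not None:
        out = out.merge(flags[["gene", "lipid_gwas_flag"]], on="gene", how="left")
        out["lipid_gwas_flag"] = out["lipid_gwas_flag"].eq(True)
    else:
        out["lipid_gwas_flag"] = False

    is_hit = out["hit_call"].isin(("up", "down"))
    if policy == "or":
        evidence = out["cholesterol_modulated"] | out["lipid_gwas_flag"]
    elif policy == "and":
        evidence = out["cholesterol_modulated"] & out["lipid_gwas_flag"]
    else:
        evidence = out["cholesterol_modulated"]
    out["candidate"] = is_hit & evidence
    return out.sort_values("gene", kind="mergesort", ignore_index=True)


@dataclass(frozen=True)
class FunnelReport:
    """Stage counts of the screening funnel and the validation rate."""

    n_genes_screened: int
    n_scorable: int
    n_primary_hits: int
    n_hits_up: int
    n_hits_down: int
    n_candidates: int
    n_rescreened: int
    n_validated: int
    validation_rate_percent: float | None  # None when nothing was rescreened

    def __post_init__(self) -> None:
        chain = (
            ("n_validated", self.n_validated, "n_rescreened", self.n_rescreened),
            ("n_rescreened", self.n_rescreened, "n_candidates", self.n_candidates),
            ("n_candidates", self.n_candidates, "n_primary_hits", self.n_primary_hits),
            ("n_primary_hits", self.n_primary_hits, "n_scorable", self.n_scorable),
            ("n_scorable", self.n_scorable, "n_genes_screened", self.n_genes_screened),
        )
        for lo_name, lo, hi_name, hi in chain:
            if lo > hi:
                raise IntegrationError(
                    f"funnel monotonicity violated: {lo_name}={lo} > "
                    f"{hi_name}={hi}"
                )
        if self.n_hits_up + self.n_hits_down != self.n_primary_hits:
            raise IntegrationError("up/down split must sum to n_primary_hits")
        if self.validation_rate_percent is not None and not (
            0.0 <= self.validation_rate_percent <= 100.0
        ):
            raise IntegrationError("validation rate must lie in [0, 100]")

    def to_text(self) -> str:
        rate = (
            "n/a (no genes rescreened)"
            if self.validation_rate_percent is None
            else f"{self.validation_rate_percent:.1f}%"
        )
        return (
            "Screening funnel\n"
            "----------------\n"
            f"genes screened      {self.n_genes_screened}\n"
            f"scorable            {self.n_scorable}\n"
            f"primary hits        {self.n_primary_hits} "
            f"(up {self.n_hits_up}, down {self.n_hits_down})\n"
            f"candidates          {self.n_candidates}\n"
            f"rescreened          {self.n_rescreened}\n"
            f"validated           {self.n_validated}\n"
            f"validation rate     {rate}\n"
        )

    def to_dict(self) -> dict:
        return {
            "n_genes_screened": self.n_genes_screened,
            "n_scorable": self.n_scorable,
            "n_primary_hits": self.n_primary_hits,
            "n_hits_up": self.n_hits_up,
            "n_hits_down": self.n_hits_down,
            "n_candidates": self.n_candidates,
            "n_rescreened": self.n_rescreened,
            "n_validated": self.n_validated,
            "validation_rate_percent": self.validation_rate_percent,
        }


def funnel_report(
    summaries: pd.DataFrame,
    candidates: pd.DataFrame,
    deconv_records: pd.DataFrame | None = None,
) -> FunnelReport:
    """Tally the funnel from the per-stage tables.

    ``validation_rate_percent`` = 100 x validated / rescreened, stored at
    full precision (rounding is presentation-only); None when no gene was
    rescreened. Stage-count monotonicity is asserted at construction.
    """
    n_screened = int(summaries["gene"].nunique())
    n_scorable = int(summaries["scorable"].sum())
    n_up = int((summaries["hit_call"] == "up").sum())
    n_down = int((summaries["hit_call"] == "down").sum())
    n_candidates = int(candidates["candidate"].sum())
    if deconv_records is None or len(deconv_records) == 0:
        n_rescreened = n_validated = 0
        rate = None
    else:
        n_rescreened = int(deconv_records["gene"].nunique())
        n_validated = int(deconv_records["validated"].sum())
        rate = 100.0 * n_validated / n_rescreened
    return FunnelReport(
        n_genes_screened=n_screened,
        n_scorable=n_scorable,
        n_primary_hits=n_up + n_down,
        n_hits_up=n_up,
        n_hits_down=n_down,
        n_candidates=n_candidates,
        n_rescreened=n_rescreened,
        n_validated=n_validated,
        validation_rate_percent=rate,
    )
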