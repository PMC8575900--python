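"""Gene-level hit calling from per-well robust z-scores.

A gene's phenotype is summarized by its replicate z-vector (one z per
replicate whose well passed QC). A primary hit requires at least
``primary_min_replicates`` (default 2) replicates beyond the inclusive
threshold |z| >= 2.0 on the same side; genes whose replicates exceed the
threshold in contradictory directions are not hits. Candidates are ranked by
the mean replicate z. Deconvolution validation re-tests each candidate with
the individual siRNAs of its pool and requires at least ``deconv_min_sirnas``
(default 1) siRNAs beyond |z| >= 1.6 on the primary direction's side.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HIT_UP = "up"
HIT_DOWN = "down"
HIT_NONE = "none"


def summarize_genes(
    wellz: pd.DataFrame,
    design: pd.DataFrame | None = None,
    min_replicates_usable: int = 2,
) -> pd.DataFrame:
    """Per-gene replicate z vectors from a normalized well table.

    Only sample-role wells with ``qc_flag == 'ok'`` contribute; replicates
    whose well was excluded are dropped from the vector. Genes with fewer
    than ``min_replicates_usable`` usable replicates are flagged unscorable
    (they stay in the table but are never called). If ``design`` is given,
    designed genes missing from the z table entirely are appended as
    unscorable rows and logged as a completeness report.
    """
    ok = wellz[(wellz["role"] == "sample") & (wellz["qc_flag"] == "ok")]
    per_rep = (
        ok.groupby(["gene", "replicate"], sort=False)["z"].mean().reset_index()
    )
    rows = []
    for gene, grp in per_rep.groupby("gene", sort=False):
        zs = grp.sort_values("replicate")["z"].to_numpy(float)
        rows.append(
            {
                "gene": gene,
                "replicate_z": zs.tolist(),
                "n_replicates_used": len(zs),
                "mean_z": float(np.mean(zs)),
                "scorable": len(zs) >= min_replicates_usable,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["gene", "replicate_z", "n_replicates_used", "mean_z", "scorable"],
    )
    if design is not None:
        designed = set(design.loc[design["role"] == "sample", "gene"])
        missing = sorted(designed - set(out["gene"]))
        if missing:
            logger.warning(
                "completeness: %d designed gene(s) absent from z table "
                "(all replicates excluded): %s%s",
                len(missing), ", ".join(missing[:10]),
                "..." if len(missing) > 10 else "",
            )
            out = pd.concat(
                [
                    out,
                    pd.DataFrame(
                        {
                            "gene": missing,
                            "replicate_z": [[] for _ in missing],
                            "n_replicates_used": 0,
                            "mean_z": np.nan,
                            "scorable": False,
                        }
                    ),
                ],
                ignore_index=True,
            )
    return out.sort_values("gene", kind="mergesort", ignore_index=True)


def call_primary_hits(
    summaries: pd.DataFrame, t: float = 2.0, k: int = 2
) -> pd.DataFrame:
    """Apply the replicate hit rule; thresholds are inclusive.

    hit_call = up iff >= ``k`` replicates have z >= +t; down iff >= ``k``
    have z <= -t; a gene satisfying both (possible only when k <= n/2) is
    called none — contradictory replicates are not a coherent phenotype.
    Unscorable genes are never called.
    """
    if t <= 0:
        raise ValueError("z threshold t must be > 0")
    if k < 1:
        raise ValueError("min replicates k must be >= 1")
    out = summaries.copy()
    n_up, n_down, calls = [], [], []
    for zs, scorable in zip(out["replicate_z"], out["scorable"]):
        z = np.asarray(zs, float)
        up = int(np.sum(z >= t))
        down = int(np.sum(z <= -t))
        if not scorable:
            call = HIT_NONE
        elif up >= k and down >= k:
            call = HIT_NONE  # mixed direction
        elif up >= k:
            call = HIT_UP
        elif down >= k:
            call = HIT_DOWN
        else:
            call = HIT_NONE
        n_up.append(up)
        n_down.append(down)
        calls.append(call)
    out["n_beyond_up"] = n_up
    out["n_beyond_down"] = n_down
    out["hit_call"] = calls
    return out


def rank_hits(summaries: pd.DataFrame) -> pd.DataFrame:
    """Order called hits for follow-up: up-hits by descending mean z, then
    down-hits by ascending mean z; ties broken by gene identifier."""
    up = summaries[summaries["hit_call"] == HIT_UP].sort_values(
        ["mean_z", "gene"], ascending=[False, True], kind="mergesort"
    )
    down = summaries[summaries["hit_call"] == HIT_DOWN].sort_values(
        ["mean_z", "gene"], ascending=[True, True], kind="mergesort"
    )
    return pd.concat([up, down], ignore_index=True)


def summarize_deconvolution(
    deconv_wellz: pd.DataFrame, primary_calls: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate deconvolution wells into per-gene siRNA z vectors.

    Each individual siRNA's z is the mean over its replicate wells
    (mirroring the primary screen's replicate aggregation); vectors are
    ordered by siRNA index. ``primary_calls`` supplies each gene's
    primary_direction (its hit_call); genes without a directional primary
    call cannot be validated and raise.
    """
    direction = primary_calls.set_index("gene")["hit_call"]
    ok = deconv_wellz[
        (deconv_wellz["role"] == "sample") & (deconv_wellz["qc_flag"] == "ok")
    ]
    per_sirna = (
        ok.groupby(["gene", "sirna"], sort=False)["z"].mean().reset_index()
    )
    rows = []
    for gene, grp in per_sirna.groupby("gene", sort=False):
        if gene not in direction.index or direction[gene] not in (HIT_UP, HIT_DOWN):
            raise ValueError(
                f"deconvolution record for {gene!r} has no directional "
                "primary call; validation is direction-conditional"
            )
        zs = grp.sort_values("sirna")["z"].to_numpy(float)
        rows.append(
            {
                "gene": gene,
                "primary_direction": direction[gene],
                "sirna_z": zs.tolist(),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "primary_direction", "sirna_z"])


def validate_deconvolution(
    records: pd.DataFrame, t: float = 1.6, m: int = 1
) -> pd.DataFrame:
    """Mark records validated when >= ``m`` individual siRNAs reproduce the
    primary phenotype: z >= +t for up-hits, z <= -t for down-hits
    (inclusive)."""
    if t <= 0:
        raise ValueError("z threshold t must be > 0")
    if m < 1:
        raise ValueError("min siRNAs m must be >= 1")
    out = records.copy()
    validated = []
    for direction, zs in zip(out["primary_direction"], out["sirna_z"]):
        z = np.asarray(zs, float)
        if direction == HIT_UP:
            n = int(np.sum(z >= t))
        elif direction == HIT_DOWN:
            n = int(np.sum(z <= -t))
        else:
            raise ValueError(
                "record without a directional primary_direction cannot be "
                f"validated: {direction!r}"
            )
        validated.append(n >= m)
    out["validated"] = validated
    return out
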