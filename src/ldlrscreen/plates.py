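"""Per-plate robust normalization of well intensities.

Wells failing the viability filter (fewer segmented nuclei than
``min_valid_objects``, default 500) are excluded before any statistic is
computed. Each remaining well's mean intensity is standardized against its
own plate: z = (x - median) / (MAD * c), where the median and MAD are taken
over all QC-passing, non-empty wells of that plate (samples and the randomly
distributed controls alike). With the default consistency constant c = 1 the
z unit is literally one plate MAD, so the published +/-2-MAD hit rule reads
z >= 2; c = 1.4826 gives the Gaussian-consistent scale. A switch restricts
the centre/scale to non-silencing control wells only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PipelineConfig

QC_OK = "ok"
QC_LOW_COUNT = "excluded_low_cell_count"
QC_DEGENERATE = "excluded_degenerate_scale"


class PlateError(ValueError):
    """A plate cannot be normalized (too few wells, missing stats)."""


def qc_filter(
    wells: pd.DataFrame, min_valid_objects: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition wells into (passing, excluded) by the viability filter.

    A well is excluded iff ``valid_object_count < min_valid_objects``; the
    boundary count equal to the threshold passes. Empty wells are excluded
    from statistics regardless (flagged with the low-count code, as they
    contain no cells). Excluded rows carry a ``qc_flag`` column.
    """
    if min_valid_objects < 0:
        raise ValueError("min_valid_objects must be >= 0")
    low = wells["valid_object_count"] < min_valid_objects
    bad = low | (wells["role"] == "empty")
    passing = wells.loc[~bad].copy()
    excluded = wells.loc[bad].copy()
    excluded["qc_flag"] = QC_LOW_COUNT
    return passing, excluded


def compute_plate_stats(
    passing: pd.DataFrame,
    c: float = 1.0,
    min_plate_wells: int = 8,
    scale_reference: str = "plate",
) -> pd.DataFrame:
    """Per-plate robust centre and scale from QC-passing wells.

    Returns a table with columns ``plate, center, scale, c, n_qc_pass,
    degenerate``; ``scale`` is MAD x c. With ``scale_reference='ns_controls'``
    only non-silencing wells define centre and scale. Even-sized medians are
    the mean of the two central order statistics. Plates with fewer passing
    wells than ``min_plate_wells`` are unusable and raise :class:`PlateError`
    naming them; a zero MAD flags the plate degenerate.
    """
    if c <= 0:
        raise ValueError("consistency constant c must be > 0")
    if len(passing) == 0:
        raise PlateError("no QC-passing wells: nothing to normalize")
    ref = passing
    if scale_reference == "ns_controls":
        ref = passing.loc[passing["role"] == "ns_control"]
    elif scale_reference != "plate":
        raise ValueError("scale_reference must be 'plate' or 'ns_controls'")

    all_plates = pd.unique(passing["plate"])
    sizes = ref.groupby("plate", sort=False)["mean_intensity"].size()
    short = sorted(
        set(all_plates) - set(sizes.index[sizes >= min_plate_wells])
    )
    if short:
        raise PlateError(
            f"plate(s) unusable, fewer than {min_plate_wells} QC-passing "
            f"reference wells: {', '.join(map(str, short))}"
        )

    rows = []
    for plate, grp in ref.groupby("plate", sort=False):
        x = grp["mean_intensity"].to_numpy(float)
        m = float(np.median(x))
        s = float(np.median(np.abs(x - m))) * c
        rows.append(
            {
                "plate": plate,
                "center": m,
                "scale": s,
                "c": c,
                "n_qc_pass": int((passing["plate"] == plate).sum()),
                "degenerate": s == 0.0,
            }
        )
    return pd.DataFrame(rows)


def robust_z(wells: pd.DataFrame, stats: pd.DataFrame) -> pd.DataFrame:
    """Robust z per QC-passing well: z = (x - center) / scale.

    Wells on degenerate (zero-MAD) plates get ``qc_flag`` =
    ``excluded_degenerate_scale`` and no z. A well on a plate absent from
    ``stats`` raises :class:`PlateError` naming the plate.
    """
    missing = sorted(set(wells["plate"]) - set(stats["plate"]))
    if missing:
        raise PlateError(
            f"no plate statistics for plate(s): {', '.join(map(str, missing))}"
        )
    st = stats.set_index("plate")
    out = wells.copy()
    center = st["center"].reindex(out["plate"]).to_numpy(float)
    scale = st["scale"].reindex(out["plate"]).to_numpy(float)
    degenerate = st["degenerate"].reindex(out["plate"]).to_numpy(bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (out["mean_intensity"].to_numpy(float) - center) / scale
    z[degenerate] = np.nan
    out["z"] = z
    out["qc_flag"] = np.where(degenerate, QC_DEGENERATE, QC_OK)
    return out


def normalize_screen(
    wells: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Viability filter, plate statistics and robust z in one pass.

    Returns ``(wellz, stats, excluded)`` where ``wellz`` holds z-scores for
    QC-passing wells and ``excluded`` the viability-filtered wells.
    """
    passing, excluded = qc_filter(wells, config.min_valid_objects)
    stats = compute_plate_stats(
        passing,
        c=config.mad_consistency_constant,
        min_plate_wells=config.min_plate_wells,
        scale_reference=config.scale_reference,
    )
    return robust_z(passing, stats), stats, excluded
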