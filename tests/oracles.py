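"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths (and numpy's
median/statistics helpers where the package relies on them): medians come
from explicit sorting, the df=2 t-distribution tail from its closed form,
and the screen decision rules from plain loops over the raw tables.
"""

from __future__ import annotations

import math


def bf_median(values) -> float:
    """Sort-based median; even length -> mean of the two central values."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("empty")
    mid = n // 2
    if n % 2:
        return xs[mid]
    return 0.5 * (xs[mid - 1] + xs[mid])


def bf_mad(values, c: float = 1.0) -> float:
    m = bf_median(values)
    return bf_median([abs(v - m) for v in values]) * c


def bf_robust_z(values, c: float = 1.0) -> list[float]:
    m = bf_median(values)
    s = bf_mad(values, c)
    return [(v - m) / s for v in values]


def t2_two_sided_p(t: float) -> float:
    """Two-sided tail of Student's t with 2 degrees of freedom, closed form:
    p = 1 - |t| / sqrt(2 + t^2)."""
    a = abs(t)
    return 1.0 - a / math.sqrt(2.0 + a * a)


def pooled_t(treat, ctrl) -> float:
    """Pooled-variance two-sample t statistic from first principles."""
    n1, n2 = len(treat), len(ctrl)
    m1 = sum(treat) / n1
    m2 = sum(ctrl) / n2
    v1 = sum((x - m1) ** 2 for x in treat) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in ctrl) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def bf_screen_calls(wells_rows, min_cells: int = 500, c: float = 1.0,
                    t: float = 2.0, k: int = 2) -> dict[str, str]:
    """Apply the printed screen rules directly to raw well rows.

    ``wells_rows`` is an iterable of dicts with keys plate, gene, role,
    replicate, valid_object_count, mean_intensity. Returns
    gene -> 'up'/'down'/'none' for every scorable sample gene (>= 2 usable
    replicates); mixed-direction genes are 'none'.
    """
    # viability filter, then per-plate robust z
    by_plate: dict[str, list[dict]] = {}
    for r in wells_rows:
        if r["role"] == "empty" or r["valid_object_count"] < min_cells:
            continue
        by_plate.setdefault(r["plate"], []).append(r)

    gene_rep_z: dict[str, dict[int, list[float]]] = {}
    for rows in by_plate.values():
        xs = [r["mean_intensity"] for r in rows]
        m = bf_median(xs)
        s = bf_mad(xs, c)
        if s == 0:
            continue
        for r in rows:
            if r["role"] != "sample":
                continue
            z = (r["mean_intensity"] - m) / s
            gene_rep_z.setdefault(r["gene"], {}).setdefault(
                int(r["replicate"]), []
            ).append(z)

    calls: dict[str, str] = {}
    for gene, reps in gene_rep_z.items():
        zs = [sum(v) / len(v) for _, v in sorted(reps.items())]
        if len(zs) < 2:
            continue
        up = sum(1 for z in zs if z >= t)
        down = sum(1 for z in zs if z <= -t)
        if up >= k and down >= k:
            calls[gene] = "none"
        elif up >= k:
            calls[gene] = "up"
        elif down >= k:
            calls[gene] = "down"
        else:
            calls[gene] = "none"
    return calls


def bf_recovery(calls: dict[str, str], truth_effect: dict[str, float]):
    """Direction-aware TP/FP/FN and precision/recall from plain loops."""
    tp = fp = fn = 0
    for gene, call in calls.items():
        eff = truth_effect[gene]
        sign = 1 if eff > 0 else (-1 if eff < 0 else 0)
        csign = {"up": 1, "down": -1, "none": 0}[call]
        correct = csign != 0 and csign == sign
        if correct:
            tp += 1
        elif csign != 0:
            fp += 1
        if sign != 0 and not correct:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return tp, fp, fn, precision, recall
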