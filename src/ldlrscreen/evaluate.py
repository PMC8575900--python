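"""Scoring against simulator ground truth and null calibration.

Recovery metrics are direction-aware: a gene called "up" whose true effect
is negative counts as a false positive, not a true positive. The null
calibration compares the empirical fraction of genes called in a zero-effect
screen with the analytic expectation of the replicate rule,
``P = sum_{j>=k} C(r,j) u^j (1-u)^{r-j} + sum_{j>=k} C(r,j) d^j (1-d)^{r-j}``,
where u and d are the per-replicate single-well exceedance probabilities
P(z >= +t) and P(z <= -t) under the generator's noise model, estimated by an
independent Monte-Carlo oracle (default >= 10^6 simulated wells on finite
plates). The two one-sided terms are summed because a directional call
requires k concordant replicates; with k > r/2 both directions cannot be
satisfied at once, so the sum is exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PipelineConfig
from .simulate import SimulationConfig, _well_noise_sigma

STAGES = ("primary_hits", "candidates", "validated")


@dataclass(frozen=True)
class RecoveryMetrics:
    stage: str
    true_positive: int
    false_positive: int
    false_negative: int
    precision: float | None  # None when no calls were made
    recall: float | None     # None when no true regulators exist

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_calls(
    stage: str,
    summaries: pd.DataFrame | None = None,
    candidates: pd.DataFrame | None = None,
    deconv_records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalize a stage's output into (gene, direction, selected).

    - primary_hits: scorable genes; selected iff hit_call is directional.
    - candidates:   integration output joined to hit directions.
    - validated:    deconvolution records; selected iff validated.
    The returned gene set is the stage's decision universe (unscorable genes
    are excluded rather than counted as negatives).
    """
    if stage == "primary_hits":
        if summaries is None:
            raise ValueError("primary_hits stage needs the hit summary table")
        sub = summaries[summaries["scorable"]]
        return pd.DataFrame(
            {
                "gene": sub["gene"],
                "direction": sub["hit_call"],
                "selected": sub["hit_call"].isin(("up", "down")),
            }
        )
    if stage == "candidates":
        if candidates is None:
            raise ValueError("candidates stage needs the integration table")
        return pd.DataFrame(
            {
                "gene": candidates["gene"],
                "direction": candidates["hit_call"],
                "selected": candidates["candidate"].astype(bool),
            }
        )
    if stage == "validated":
        if deconv_records is None:
            raise ValueError("validated stage needs deconvolution records")
        return pd.DataFrame(
            {
                "gene": deconv_records["gene"],
                "direction": deconv_records["primary_direction"],
                "selected": deconv_records["validated"].astype(bool),
            }
        )
    raise ValueError(f"unknown stage {stage!r}")


def recovery_metrics(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    stage: str = "primary_hits",
    min_effect: float = 0.0,
) -> RecoveryMetrics:
    """Direction-aware precision/recall of one stage against ground truth.

    A true regulator is a gene with nonzero ``true_screen_effect``; with a
    positive ``min_effect`` gray zone, genes with 0 < |effect| < min_effect
    are excluded from both TP and FN accounting (a call on them still counts
    as neither FP nor TP — they leave the evaluation universe).
    """
    if len(truth) == 0:
        raise ValueError("empty ground truth")
    merged = calls.merge(
        truth[["gene", "true_screen_effect"]], on="gene", how="inner"
    )
    eff = merged["true_screen_effect"].to_numpy(float)
    gray = (eff != 0.0) & (np.abs(eff) < min_effect)
    merged = merged.loc[~gray]
    eff = merged["true_screen_effect"].to_numpy(float)
    selected = merged["selected"].to_numpy(bool)
    direction = merged["direction"].to_numpy(object)
    call_sign = np.where(direction == "up", 1, np.where(direction == "down", -1, 0))
    true_sign = np.sign(eff).astype(int)

    correct = selected & (true_sign != 0) & (call_sign == true_sign)
    tp = int(correct.sum())
    fp = int((selected & ~correct).sum())
    fn = int(((true_sign != 0) & ~correct).sum())
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    return RecoveryMetrics(stage, tp, fp, fn, precision, recall)


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullCalibration:
    empirical_fraction: float
    n_genes: int
    analytic_expectation: float
    p_up: float
    p_down: float
    p_two_sided: float
    empirical_se: float

    def within(self, n_se: float = 3.0) -> bool:
        return abs(self.empirical_fraction - self.analytic_expectation) <= (
            n_se * self.empirical_se
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def single_well_exceedance(
    sim: SimulationConfig,
    t: float,
    c: float = 1.0,
    n_draws: int = 1_000_000,
    seed: int = 12345,
) -> tuple[float, float]:
    """Monte-Carlo oracle for the per-replicate null exceedance (u, d).

    Simulates finite plates mirroring the screen's composition — null
    sample/NS wells plus the positive and negative control wells at their
    fixed effects — computes each plate's median/MAD robust z, and returns
    the fractions of *null* wells with z >= +t and z <= -t. At least
    ``n_draws`` null wells are simulated.
    """
    n_null = (
        sim.wells_per_plate
        - sim.n_pos_per_plate
        - sim.n_neg_per_plate
        - sim.n_cytotox_per_plate
    )
    n_plates = int(np.ceil(n_draws / n_null))
    sigma = _well_noise_sigma(sim.well_noise_cv)
    rng = np.random.default_rng(seed)
    up = down = total = 0
    batch = max(1, int(2e6) // sim.wells_per_plate)
    for start in range(0, n_plates, batch):
        b = min(batch, n_plates - start)
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, (b, sim.wells_per_plate)))
        x = noise.copy()
        x[:, n_null:n_null + sim.n_pos_per_plate] *= 1.0 + sim.pos_control_effect
        x[:, n_null + sim.n_pos_per_plate:] *= 1.0 + sim.neg_control_effect
        med = np.median(x, axis=1, keepdims=True)
        mad = np.median(np.abs(x - med), axis=1, keepdims=True) * c
        z = (x[:, :n_null] - med) / mad
        up += int(np.sum(z >= t))
        down += int(np.sum(z <= -t))
        total += b * n_null
    return up / total, down / total


def analytic_null_expectation(u: float, d: float, r: int, k: int) -> float:
    """P(gene called) under the null: k-of-r concordant exceedances, either
    direction; exact for k > r/2."""
    return float(sps.binom.sf(k - 1, r, u) + sps.binom.sf(k - 1, r, d))


def null_calibration(
    sim: SimulationConfig,
    cfg: PipelineConfig | None = None,
    n_oracle_draws: int = 1_000_000,
) -> NullCalibration:
    """Run a zero-effect screen through the pipeline and compare the called
    fraction with the analytic expectation of the replicate rule."""
    from .hits import call_primary_hits, summarize_genes
    from .plates import normalize_screen
    from .simulate import simulate_screen

    if sim.frac_true_up != 0 or sim.frac_true_down != 0:
        raise ValueError("null calibration requires a zero-effect config")
    cfg = cfg or PipelineConfig()

    _, wells, _ = simulate_screen(sim)
    wellz, _, _ = normalize_screen(wells, cfg)
    summaries = summarize_genes(wellz)
    called = call_primary_hits(
        summaries, t=cfg.primary_z_threshold, k=cfg.primary_min_replicates
    )
    scorable = called[called["scorable"]]
    n = len(scorable)
    frac = float(scorable["hit_call"].isin(("up", "down")).mean())

    u, d = single_well_exceedance(
        sim,
        t=cfg.primary_z_threshold,
        c=cfg.mad_consistency_constant,
        n_draws=n_oracle_draws,
        seed=sim.seed + 977,
    )
    expect = analytic_null_expectation(
        u, d, sim.n_replicates, cfg.primary_min_replicates
    )
    se = float(np.sqrt(expect * (1.0 - expect) / n)) if n else float("nan")
    return NullCalibration(
        empirical_fraction=frac,
        n_genes=n,
        analytic_expectation=expect,
        p_up=u,
        p_down=d,
        p_two_sided=u + d,
        empirical_se=se,
    )


def recall_curve(
    base: SimulationConfig,
    effect_sizes: list[float],
    cfg: PipelineConfig | None = None,
) -> list[float]:
    """Recall of the primary stage across fixed spike effect sizes.

    Every run reuses the base config's seed, coupling the noise draws across
    effect sizes so the curve isolates the effect of spike magnitude.
    """
    from .hits import call_primary_hits, summarize_genes
    from .plates import normalize_screen
    from .simulate import simulate_screen

    cfg = cfg or PipelineConfig()
    out = []
    for e in effect_sizes:
        sim = dataclasses.replace(base, effect_size_range=(e, e))
        _, wells, truth = simulate_screen(sim)
        wellz, _, _ = normalize_screen(wells, cfg)
        summaries = summarize_genes(wellz)
        called = call_primary_hits(
            summaries, t=cfg.primary_z_threshold, k=cfg.primary_min_replicates
        )
        m = recovery_metrics(stage_calls("primary_hits", summaries=called), truth)
        out.append(m.recall if m.recall is not None else 0.0)
    return out
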