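"""Synthetic genome-wide RNAi screen with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
fluorescence LDL-uptake readout per well (mean DiI intensity over imaged
fields), multiplicative lognormal plate effects and well noise, randomly
placed control wells on every plate (non-silencing, NPC1 positive, LDLR
negative, KIF11 cytotoxicity controls), cytotoxic knockdowns with collapsed
cell counts, and a matched two-condition (statin / nLDL vs vehicle control)
duplicate expression experiment in which a subset of genes is truly
sterol-modulated.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ConfigError, plate_layout

#: gene-column labels carried by control wells (the role column is authoritative)
CONTROL_LABELS = {
    "ns_control": "NS",
    "pos_control_npc1": "siNPC1",
    "neg_control_ldlr": "siLDLR",
    "cytotox_control_kif11": "siKIF11",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screen and expression experiment.

    Screen effects are fractional changes in mean well intensity: the NPC1
    positive control raises DiI-LDL uptake by 30%; the LDLR negative control
    default (-70%) is a free parameter, as the knockdown's published effect
    size is qualitative only. Well intensity is
    ``plate_factor * baseline * (1 + effect) * lognormal noise`` with the
    plate factor lognormal(0, plate_effect_sd) and well noise scaled to unit
    mean at the configured coefficient of variation. Cell counts are Poisson;
    cytotoxic knockdowns and the KIF11 control are centred low so they fall
    under the 500-cell viability filter.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    wells_per_plate: int = 384
    n_ns_per_plate: int = 16
    n_pos_per_plate: int = 4
    n_neg_per_plate: int = 4
    n_cytotox_per_plate: int = 4
    baseline_intensity: float = 1000.0
    well_noise_cv: float = 0.15
    plate_effect_sd: float = 0.15
    frac_true_up: float = 0.02
    frac_true_down: float = 0.02
    effect_size_range: tuple[float, float] = (0.3, 0.8)
    pos_control_effect: float = 0.30
    neg_control_effect: float = -0.70
    cytotox_fraction: float = 0.02
    cell_count_mean: float = 1500.0
    cytotox_cell_count_mean: float = 200.0
    sirna_efficacy_range: tuple[float, float] = (0.3, 1.0)
    n_sirnas_per_pool: int = 3
    gwas_flag_rate: float = 0.05
    expr_n_replicates: int = 2
    expr_noise_sd: float = 0.1
    frac_modulated: float = 0.35
    modulated_log2fc_range: tuple[float, float] = (0.2, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_true_up", "frac_true_down", "cytotox_fraction",
                     "gwas_flag_rate", "frac_modulated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_true_up + self.frac_true_down > 1.0:
            raise ConfigError("frac_true_up + frac_true_down must be <= 1")
        for name in ("baseline_intensity", "well_noise_cv", "cell_count_mean",
                     "cytotox_cell_count_mean"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.plate_effect_sd < 0:
            raise ConfigError("plate_effect_sd must be >= 0")
        if self.n_controls_per_plate >= self.wells_per_plate:
            raise ConfigError(
                f"{self.n_controls_per_plate} control wells exceed plate "
                f"capacity {self.wells_per_plate}"
            )
        lo, hi = self.sirna_efficacy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("sirna_efficacy_range must satisfy 0 <= lo <= hi <= 1")

    @property
    def n_controls_per_plate(self) -> int:
        return (self.n_ns_per_plate + self.n_pos_per_plate
                + self.n_neg_per_plate + self.n_cytotox_per_plate)

    @property
    def sample_capacity(self) -> int:
        return self.wells_per_plate - self.n_controls_per_plate

    def n_plates(self, n_units: int | None = None) -> int:
        """Plates needed per replicate for ``n_units`` sample wells."""
        n = self.n_genes if n_units is None else n_units
        return max(1, math.ceil(n / self.sample_capacity))


def _well_noise_sigma(cv: float) -> float:
    # lognormal sigma such that the multiplier has the requested CV
    return math.sqrt(math.log1p(cv * cv))


def simulate_truth(config: SimulationConfig,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene ground truth (screen effects, cytotoxicity, expression
    modulation, GWAS flags) for ``config.n_genes`` genes named g000001..."""
    n = config.n_genes
    genes = [f"g{i + 1:06d}" for i in range(n)]
    lo, hi = config.effect_size_range
    n_up = int(round(config.frac_true_up * n))
    n_down = int(round(config.frac_true_down * n))
    order = rng.permutation(n)
    effect = np.zeros(n)
    effect[order[:n_up]] = rng.uniform(lo, hi, n_up)
    effect[order[n_up:n_up + n_down]] = -rng.uniform(lo, hi, n_down)

    cytotoxic = rng.random(n) < config.cytotox_fraction
    gwas = rng.random(n) < config.gwas_flag_rate

    n_mod = int(round(config.frac_modulated * n))
    mod_idx = rng.permutation(n)[:n_mod]
    mlo, mhi = config.modulated_log2fc_range
    statin = np.zeros(n)
    nldl = np.zeros(n)
    # sterol-responsive genes rise on cholesterol depletion (statin) and
    # fall on enrichment (nLDL), the SREBP2-target pattern
    statin[mod_idx] = rng.uniform(mlo, mhi, n_mod)
    nldl[mod_idx] = -rng.uniform(mlo, mhi, n_mod)

    return pd.DataFrame(
        {
            "gene": genes,
            "true_screen_effect": effect,
            "cytotoxic": cytotoxic,
            "true_statin_log2fc": statin,
            "true_nldl_log2fc": nldl,
            "lipid_gwas_flag": gwas,
        }
    )


def _layout_plates(
    config: SimulationConfig,
    rng: np.random.Generator,
    units: pd.DataFrame,
    plate_prefix: str,
) -> pd.DataFrame:
    """Place sample units (gene [, sirna]) and controls onto plates.

    Each unit occupies one well per replicate; control wells are drawn at
    fresh random positions on every plate of every replicate. Returns the
    design table (replicate, plate, well, gene, role [, sirna]).
    """
    n_units = len(units)
    n_plates = config.n_plates(n_units)
    names = plate_layout(config.wells_per_plate)
    control_roles = (
        ["ns_control"] * config.n_ns_per_plate
        + ["pos_control_npc1"] * config.n_pos_per_plate
        + ["neg_control_ldlr"] * config.n_neg_per_plate
        + ["cytotox_control_kif11"] * config.n_cytotox_per_plate
    )
    n_ctrl = len(control_roles)
    has_sirna = "sirna" in units.columns

    rows: list[dict] = []
    for rep in range(1, config.n_replicates + 1):
        for p in range(n_plates):
            plate_id = f"{plate_prefix}r{rep}-p{p + 1:03d}"
            perm = rng.permutation(config.wells_per_plate)
            ctrl_pos = set(perm[:n_ctrl].tolist())
            ctrl_iter = iter(zip(sorted(ctrl_pos), control_roles))
            # note: roles are assigned to sorted positions so the *set* of
            # control positions is random, matching randomized placement
            ctrl_map = {pos: role for pos, role in ctrl_iter}
            start = p * config.sample_capacity
            unit_iter = iter(range(start, min(start + config.sample_capacity,
                                              n_units)))
            for w in range(config.wells_per_plate):
                if w in ctrl_map:
                    role = ctrl_map[w]
                    row = {
                        "plate": plate_id,
                        "well": names[w],
                        "replicate": rep,
                        "gene": CONTROL_LABELS[role],
                        "role": role,
                    }
                    if has_sirna:
                        row["sirna"] = 0
                else:
                    i = next(unit_iter, None)
                    if i is None:
                        row = {
                            "plate": plate_id,
                            "well": names[w],
                            "replicate": rep,
                            "gene": "",
                            "role": "empty",
                        }
                        if has_sirna:
                            row["sirna"] = 0
                    else:
                        row = {
                            "plate": plate_id,
                            "well": names[w],
                            "replicate": rep,
                            "gene": units["gene"].iat[i],
                            "role": "sample",
                        }
                        if has_sirna:
                            row["sirna"] = int(units["sirna"].iat[i])
                rows.append(row)
    return pd.DataFrame(rows)


def _measure(
    config: SimulationConfig,
    rng: np.random.Generator,
    design: pd.DataFrame,
    effect_of_unit: dict,
    cytotoxic_genes: set[str],
) -> pd.DataFrame:
    """Draw intensities and cell counts for a laid-out design."""
    n = len(design)
    role = design["role"].to_numpy()
    plate_key = (design["plate"].astype(str)).to_numpy()

    plates = pd.unique(plate_key)
    factors = dict(zip(plates, np.exp(
        rng.normal(0.0, config.plate_effect_sd, len(plates)))))
    plate_factor = np.array([factors[p] for p in plate_key])

    if "sirna" in design.columns:
        keys = list(zip(design["gene"], design["sirna"]))
    else:
        keys = list(design["gene"])
    effect = np.zeros(n)
    for i, (r, k) in enumerate(zip(role, keys)):
        if r == "sample":
            effect[i] = effect_of_unit.get(k, 0.0)
        elif r == "pos_control_npc1":
            effect[i] = config.pos_control_effect
        elif r == "neg_control_ldlr":
            effect[i] = config.neg_control_effect

    sigma = _well_noise_sigma(config.well_noise_cv)
    noise = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, n))  # unit mean
    intensity = config.baseline_intensity * plate_factor * (1.0 + effect) * noise

    gene = design["gene"].to_numpy()
    low_count = (role == "cytotox_control_kif11") | np.array(
        [r == "sample" and g in cytotoxic_genes for r, g in zip(role, gene)]
    )
    count_mean = np.where(low_count, config.cytotox_cell_count_mean,
                          config.cell_count_mean)
    counts = rng.poisson(count_mean)

    empty = role == "empty"
    intensity[empty] = 0.0
    counts[empty] = 0

    out = design.copy()
    out["valid_object_count"] = counts.astype(int)
    out["mean_intensity"] = intensity
    return out


def simulate_screen(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the primary screen.

    Returns ``(design, wells, truth)``: the plate design (replicate, plate,
    well, gene, role), the measured well table, and the per-gene ground
    truth. Identical config and seed reproduce identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    design = _layout_plates(config, rng, truth[["gene"]], plate_prefix="")
    effects = dict(zip(truth["gene"], truth["true_screen_effect"]))
    cytotoxic = set(truth.loc[truth["cytotoxic"], "gene"])
    wells = _measure(config, rng, design, effects, cytotoxic)
    return design, wells, truth


def simulate_deconvolution(
    config: SimulationConfig,
    truth: pd.DataFrame,
    candidate_genes: list[str],
) -> pd.DataFrame:
    """Generate the deconvolution screen for ``candidate_genes``.

    Each candidate's pool is split into ``n_sirnas_per_pool`` individual
    siRNAs; siRNA *j* of a gene inherits the gene's true screen effect
    attenuated by an independent efficacy factor drawn uniformly from
    ``sirna_efficacy_range``. The plate/noise model matches the primary
    screen. Empty candidate list yields an empty table.
    """
    known = set(truth["gene"])
    unknown = [g for g in candidate_genes if g not in known]
    if unknown:
        raise ValueError(f"candidate gene(s) not in simulated truth: "
                         f"{', '.join(unknown[:5])}")
    cols = ["plate", "well", "replicate", "gene", "role", "sirna",
            "valid_object_count", "mean_intensity"]
    if not candidate_genes:
        return pd.DataFrame(columns=cols)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    k = config.n_sirnas_per_pool
    units = pd.DataFrame(
        {
            "gene": np.repeat(list(candidate_genes), k),
            "sirna": np.tile(np.arange(1, k + 1), len(candidate_genes)),
        }
    )
    lo, hi = config.sirna_efficacy_range
    efficacy = rng.uniform(lo, hi, len(units))
    gene_effect = dict(zip(truth["gene"], truth["true_screen_effect"]))
    effect_of_unit = {
        (g, int(s)): gene_effect[g] * e
        for g, s, e in zip(units["gene"], units["sirna"], efficacy)
    }
    design = _layout_plates(config, rng, units, plate_prefix="d")
    cytotoxic = set(truth.loc[truth["cytotoxic"], "gene"])
    wells = _measure(config, rng, design, effect_of_unit, cytotoxic)
    return wells[cols]


def simulate_expression(
    config: SimulationConfig, truth: pd.DataFrame
) -> pd.DataFrame:
    """Generate the two-condition duplicate expression experiment.

    log2 expression = per-gene baseline + condition shift + N(0, expr_noise_sd);
    the statin shift is ``true_statin_log2fc``, the nLDL shift
    ``true_nldl_log2fc``, control zero. Values are emitted on the linear scale.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = truth["gene"].to_numpy()
    n = len(genes)
    base = rng.normal(8.0, 2.0, n)  # log2 abundance baseline
    shifts = {
        "control": np.zeros(n),
        "nldl": truth["true_nldl_log2fc"].to_numpy(),
        "statin": truth["true_statin_log2fc"].to_numpy(),
    }
    frames = []
    for cond in ("control", "nldl", "statin"):
        for rep in range(1, config.expr_n_replicates + 1):
            noise = rng.normal(0.0, config.expr_noise_sd, n)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "condition": cond,
                        "replicate": rep,
                        "expression": np.exp2(base + shifts[cond] + noise),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
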