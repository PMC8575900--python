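"""Readers, writers and configuration for screen tables.

All tables are delimited text (comma by default, tab accepted), UTF-8, with a
required header row. In-memory, tables are pandas DataFrames with validated
schemas; row-level invariant violations are reported with 1-based file line
numbers (the header is line 1).

Table schemas
-------------
well table        : plate, well, replicate, gene, role, valid_object_count,
                    mean_intensity  (optional extra column: sirna, used by
                    deconvolution tables)
expression table  : gene, condition, replicate, expression
flag table        : gene, lipid_gwas_flag
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Roles a well can play on a screening plate. The role column is
#: authoritative; control wells additionally carry the control label
#: (NS, siLDLR, siNPC1, siKIF11) in the gene column.
ROLES = (
    "sample",
    "ns_control",
    "pos_control_npc1",
    "neg_control_ldlr",
    "cytotox_control_kif11",
    "empty",
)

#: Treatment conditions of the expression experiment (case-folded on read).
CONDITIONS = ("control", "nldl", "statin")

WELL_COLUMNS = (
    "plate",
    "well",
    "replicate",
    "gene",
    "role",
    "valid_object_count",
    "mean_intensity",
)
EXPRESSION_COLUMNS = ("gene", "condition", "replicate", "expression")
FLAG_COLUMNS = ("gene", "lipid_gwas_flag")


class FormatError(ValueError):
    """Structural problem with a file: missing column, unknown label."""


class ValidationError(ValueError):
    """A row violates a data invariant (negative count, nonpositive value)."""


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and switches of the analysis pipeline.

    Defaults encode the published decision rules: wells with fewer than 500
    segmented nuclei are discarded; a gene is a primary hit when at least two
    replicate wells reach a robust z of magnitude 2.0 (inclusive) in the same
    direction; a candidate validates in the deconvolution screen when at
    least one of its three individual siRNAs reaches |z| >= 1.6 on the
    primary direction; expression modulation requires a two-sided pooled
    t-test P <= 0.05 and signed fold-change of magnitude >= 1.1.
    """

    min_valid_objects: int = 500
    mad_consistency_constant: float = 1.0  # 1.4826 for Gaussian-consistent MAD
    primary_z_threshold: float = 2.0
    primary_min_replicates: int = 2
    deconv_z_threshold: float = 1.6
    deconv_min_sirnas: int = 1
    de_alpha: float = 0.05
    de_fc_threshold: float = 1.1
    random_seed: int = 0
    # secondary switches (documented ambiguities / common alternatives)
    scale_reference: str = "plate"  # or "ns_controls"
    min_plate_wells: int = 8
    de_log_scale: bool = False
    de_fdr: bool = False
    integration_policy: str = "or"  # "or" | "and" | "expression_only"

    def __post_init__(self) -> None:
        if self.min_valid_objects < 0:
            raise ConfigError("min_valid_objects must be >= 0")
        for name in (
            "mad_consistency_constant",
            "primary_z_threshold",
            "deconv_z_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.primary_min_replicates < 1:
            raise ConfigError("primary_min_replicates must be >= 1")
        if self.deconv_min_sirnas < 1:
            raise ConfigError("deconv_min_sirnas must be >= 1")
        if not 0.0 < self.de_alpha < 1.0:
            raise ConfigError("de_alpha must lie in (0, 1)")
        if self.de_fc_threshold <= 1.0:
            raise ConfigError("de_fc_threshold must be > 1")
        if self.scale_reference not in ("plate", "ns_controls"):
            raise ConfigError("scale_reference must be 'plate' or 'ns_controls'")
        if self.integration_policy not in ("or", "and", "expression_only"):
            raise ConfigError(
                "integration_policy must be 'or', 'and' or 'expression_only'"
            )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat key/value YAML config; unspecified keys take defaults.

    Unknown keys raise :class:`ConfigError` (fail-fast, no silent typo
    absorption). The fully resolved config is echoed at INFO level.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    cfg = PipelineConfig(**data)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# well naming helpers (384-well convention: rows A..P, columns 1..24)
# ---------------------------------------------------------------------------

def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> microtiter well name like ``A01``."""
    if row < 0 or col < 0:
        raise ValueError("row/col must be nonnegative")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def plate_layout(wells_per_plate: int) -> list[str]:
    """All well names of a plate in row-major order (e.g. A01..P24 for 384)."""
    n_cols = {96: 12, 384: 24, 1536: 48}.get(wells_per_plate)
    if n_cols is None:
        # fall back to a 2:3 aspect if a nonstandard size is requested
        n_cols = int(round((wells_per_plate * 3 / 2) ** 0.5))
        while wells_per_plate % n_cols:
            n_cols += 1
    n_rows = wells_per_plate // n_cols
    return [well_name(r, c) for r in range(n_rows) for c in range(n_cols)]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _to_number(df: pd.DataFrame, column: str, path, kind=float) -> pd.Series:
    try:
        return df[column].astype(kind)
    except (ValueError, TypeError):
        for i, v in enumerate(df[column]):
            try:
                kind(v)
            except (ValueError, TypeError):
                raise FormatError(
                    f"{path}, line {i + 2}: cannot parse {column}={v!r}"
                ) from None
        raise  # pragma: no cover


def read_well_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read and validate a per-well screen measurement table.

    Returns a DataFrame with columns ``plate, well, replicate, gene, role,
    valid_object_count, mean_intensity`` (plus ``sirna`` if present, for
    deconvolution tables). Every row is parsed or rejected with a
    line-numbered message.
    """
    df = _read_delimited(path, sep)
    _require_columns(df, WELL_COLUMNS, path)
    out = pd.DataFrame(
        {
            "plate": df["plate"],
            "well": df["well"],
            "replicate": _to_number(df, "replicate", path, int),
            "gene": df["gene"],
            "role": df["role"].str.lower(),
            "valid_object_count": _to_number(df, "valid_object_count", path, int),
            "mean_intensity": _to_number(df, "mean_intensity", path, float),
        }
    )
    if "sirna" in df.columns:
        out["sirna"] = _to_number(df, "sirna", path, int)

    bad_role = ~out["role"].isin(ROLES)
    if bad_role.any():
        i = int(bad_role.idxmax())
        raise FormatError(
            f"{path}, line {i + 2}: unknown role {out['role'].iloc[i]!r} "
            f"(expected one of {', '.join(ROLES)})"
        )
    for col, ok in (
        ("replicate", out["replicate"] >= 1),
        ("valid_object_count", out["valid_object_count"] >= 0),
        ("mean_intensity", (out["mean_intensity"] >= 0) & out["mean_intensity"].notna()),
    ):
        bad = ~ok
        if bad.any():
            i = int(bad.idxmax())
            raise ValidationError(
                f"{path}, line {i + 2}: invalid {col}={out[col].iloc[i]!r}"
            )
    return out


def write_well_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a well table with deterministic row order (plate, well, replicate)."""
    cols = [c for c in (*WELL_COLUMNS, "sirna") if c in df.columns]
    out = df[cols].sort_values(["plate", "well", "replicate"], kind="mergesort")
    out.to_csv(path, sep=sep, index=False)


def read_expression_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene x condition x replicate expression table (linear scale)."""
    df = _read_delimited(path, sep)
    _require_columns(df, EXPRESSION_COLUMNS, path)
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "condition": df["condition"].str.lower(),  # declared dialect rule
            "replicate": _to_number(df, "replicate", path, int),
            "expression": _to_number(df, "expression", path, float),
        }
    )
    bad = ~out["condition"].isin(CONDITIONS)
    if bad.any():
        i = int(bad.idxmax())
        raise FormatError(
            f"{path}, line {i + 2}: unknown condition {df['condition'].iloc[i]!r} "
            f"(expected one of {', '.join(CONDITIONS)})"
        )
    nonpos = ~(out["expression"] > 0) | ~out["expression"].apply(
        lambda x: x == x and abs(x) != float("inf")
    )
    if nonpos.any():
        i = int(nonpos.idxmax())
        raise ValidationError(
            f"{path}, line {i + 2}: expression must be a positive finite "
            f"linear-scale value, got {df['expression'].iloc[i]!r}"
        )
    return out


def write_expression_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    out = df[list(EXPRESSION_COLUMNS)].sort_values(
        ["gene", "condition", "replicate"], kind="mergesort"
    )
    out.to_csv(path, sep=sep, index=False)


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def read_flag_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene-level annotation-flag table (lipid-GWAS association)."""
    df = _read_delimited(path, sep)
    _require_columns(df, FLAG_COLUMNS, path)
    flags = df["lipid_gwas_flag"].str.lower().map(_BOOL)
    if flags.isna().any():
        i = int(flags.isna().idxmax())
        raise FormatError(
            f"{path}, line {i + 2}: cannot parse boolean "
            f"lipid_gwas_flag={df['lipid_gwas_flag'].iloc[i]!r}"
        )
    dup = df["gene"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene row(s): "
            f"{', '.join(sorted(set(df['gene'][dup])))}"
        )
    return pd.DataFrame({"gene": df["gene"], "lipid_gwas_flag": flags.astype(bool)})


def write_flag_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    out = df[list(FLAG_COLUMNS)].sort_values("gene", kind="mergesort")
    out.to_csv(path, sep=sep, index=False)


def read_truth_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a simulator ground-truth table written by :func:`write_truth_table`."""
    df = _read_delimited(path, sep)
    required = (
        "gene",
        "true_screen_effect",
        "cytotoxic",
        "true_statin_log2fc",
        "true_nldl_log2fc",
        "lipid_gwas_flag",
    )
    _require_columns(df, required, path)
    return pd.DataFrame(
        {
            "gene": df["gene"],
            "true_screen_effect": _to_number(df, "true_screen_effect", path),
            "cytotoxic": df["cytotoxic"].str.lower().map(_BOOL).astype(bool),
            "true_statin_log2fc": _to_number(df, "true_statin_log2fc", path),
            "true_nldl_log2fc": _to_number(df, "true_nldl_log2fc", path),
            "lipid_gwas_flag": df["lipid_gwas_flag"].str.lower().map(_BOOL).astype(bool),
        }
    )


def write_truth_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.sort_values("gene", kind="mergesort").to_csv(path, sep=sep, index=False)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write any result table as delimited text with a header."""
    df.to_csv(path, sep=sep, index=False)
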