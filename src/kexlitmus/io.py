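"""File formats, unit handling and provenance.

Canonical on-disk dialect: CSV (TSV accepted) with unit-bearing headers.
Concentration columns must declare their unit in the header (``L0_M``,
``L0_mM``, ``L0_uM``); rates are s^-1 throughout.  All values are converted
to molar and s^-1 on load — internal code never sees mixed units — and
ambiguous headers are rejected rather than guessed.

Two dispersion schemas are accepted:

* rate schema:      residue, field_MHz, L0_<unit>, nu_hz, r2eff, sigma
* intensity schema: residue, field_MHz, L0_<unit>, nu_hz, intensity
  (reference rows carry an empty nu_hz cell)

k_ex tables carry: residue, L0_<unit>, kex, sigma_kex.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .dispersion import DispersionCurve, IntensityRecord
from .litmus import KexProfile

__all__ = [
    "RunConfig",
    "read_dispersion_table",
    "read_kex_table",
    "write_dispersion_table",
    "write_kex_table",
    "write_provenance",
]

_CONC_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6}


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Internal units are molar and s^-1 (conversions happen at the I/O
    boundary); every run writes a provenance record (config + hash + tool
    version + seed) next to its outputs, from which the outputs are
    regenerable bit-identically with the same tool version.
    """

    command: str
    inputs: dict = field(default_factory=dict)
    mechanisms: tuple[str, ...] = ("TS", "CS", "IF")
    conf_exchange_total: float = 20_000.0
    kd_default: float = 3.7e-4
    seed: int | None = None

    def write(self, path: str | Path) -> dict:
        return write_provenance(
            {
                "command": self.command,
                "inputs": self.inputs,
                "mechanisms": list(self.mechanisms),
                "conf_exchange_total_s-1": self.conf_exchange_total,
                "kd_default_M": self.kd_default,
                "seed": self.seed,
            },
            path,
        )


def _find_conc_column(columns, stem: str) -> tuple[str, float]:
    hits = []
    for col in columns:
        if col == stem or col.startswith(stem + "_"):
            unit = col[len(stem) + 1:] if col != stem else ""
            hits.append((col, unit))
    if not hits:
        raise ValueError(f"no {stem} column found in {list(columns)}")
    if len(hits) > 1:
        raise ValueError(f"multiple {stem} columns: {[h[0] for h in hits]}")
    col, unit = hits[0]
    if unit not in _CONC_FACTORS:
        raise ValueError(
            f"concentration column {col!r} must declare a unit suffix "
            f"({stem}_M, {stem}_mM or {stem}_uM); refusing to guess"
        )
    return col, _CONC_FACTORS[unit]


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: table is empty")
    return df


def _check_duplicates(df: pd.DataFrame, keys: list[str], path) -> None:
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate {tuple(keys)} keys on lines {lines}")


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]
            raise ValueError(f"{path}: non-numeric {col!r} values on lines {lines}")
        df[col] = coerced


def read_dispersion_table(
    path: str | Path, T_relax: float | None = None
) -> list[DispersionCurve] | list[IntensityRecord]:
    """Load a dispersion table in either accepted schema.

    Rate-schema files return validated :class:`DispersionCurve` objects
    (grouped by residue, field and L0, sorted by CPMG frequency).
    Intensity-schema files return :class:`IntensityRecord` objects and
    require the constant-time delay ``T_relax`` (s).
    """
    df = _read_csv(path)
    cols = set(df.columns)
    L0_col, factor = _find_conc_column(df.columns, "L0")
    if {"r2eff", "sigma"} <= cols:
        _require_numeric(df, ["field_MHz", L0_col, "nu_hz", "r2eff", "sigma"], path)
        _check_duplicates(df, ["residue", "field_MHz", L0_col, "nu_hz"], path)
        curves = []
        for (rid, f_MHz, L0), grp in df.groupby(["residue", "field_MHz", L0_col], sort=True):
            grp = grp.sort_values("nu_hz")
            curves.append(
                DispersionCurve(
                    residue_id=str(rid), field_MHz=float(f_MHz), L0=float(L0) * factor,
                    nu_cpmg=tuple(grp["nu_hz"]), R2eff=tuple(grp["r2eff"]),
                    sigma=tuple(grp["sigma"]),
                )
            )
        return curves
    if "intensity" in cols:
        if T_relax is None:
            raise ValueError("intensity schema requires T_relax")
        _require_numeric(df, ["field_MHz", L0_col, "intensity"], path)
        _check_duplicates(df, ["residue", "field_MHz", L0_col, "nu_hz"], path)
        records = []
        for row in df.itertuples(index=False):
            nu = getattr(row, "nu_hz")
            nu = None if pd.isna(nu) else float(nu)
            records.append(
                IntensityRecord(
                    residue_id=str(row.residue), nu_cpmg=nu,
                    intensity=float(row.intensity), T_relax=T_relax,
                )
            )
        return records
    raise ValueError(
        f"{path}: header matches neither the rate schema (r2eff, sigma) nor "
        f"the intensity schema (intensity); got {sorted(cols)}"
    )


def read_kex_table(path: str | Path, P0: float) -> list[KexProfile]:
    """Load per-residue k_ex profiles (residue, L0_<unit>, kex, sigma_kex).

    ``P0`` is the total observed-protein concentration (M).  Rows are
    sorted by L0 per residue (with a warning if the file was unsorted).
    """
    df = _read_csv(path)
    L0_col, factor = _find_conc_column(df.columns, "L0")
    missing = {"residue", "kex", "sigma_kex"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    _require_numeric(df, [L0_col, "kex", "sigma_kex"], path)
    _check_duplicates(df, ["residue", L0_col], path)
    profiles = []
    for rid, grp in df.groupby("residue", sort=True):
        if not grp[L0_col].is_monotonic_increasing:
            warnings.warn(f"{path}: L0 unsorted for residue {rid}; sorting", stacklevel=2)
        grp = grp.sort_values(L0_col)
        profiles.append(
            KexProfile(
                residue_id=str(rid), P0=P0,
                points=tuple(
                    (float(l) * factor, float(k), float(s))
                    for l, k, s in zip(grp[L0_col], grp["kex"], grp["sigma_kex"])
                ),
            )
        )
    return profiles


def write_dispersion_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a rate-schema dispersion table (canonical CSV dialect)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_kex_table(profiles: list[KexProfile], path: str | Path) -> None:
    rows = [
        {"residue": p.residue_id, "L0_M": l, "kex": k, "sigma_kex": s}
        for p in profiles
        for l, k, s in p.points
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)


def _tool_version() -> str:
    try:
        return version("kexlitmus")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_provenance(config: dict, path: str | Path) -> dict:
    """Write a provenance record (config + hash + tool version) as JSON.

    Outputs are regenerable bit-identically from this record with the same
    tool version: it captures every parameter and the seed.
    """
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "tool": "kexlitmus",
        "version": _tool_version(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return record
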