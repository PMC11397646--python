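"""Table readers, run configuration, and validated ingestion.

All inputs are plain CSV (UTF-8, comma-separated, "." decimal, header
mandatory, case-insensitive column names).  Readers validate every row
against the domain-type invariants and collect rejects in an error
report — bad rows are never silently dropped.  If more than half the
rows of a file are invalid the read fails outright.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .energetics import HBondGeometry, NBOInteraction, TorsionProfile
from .mutarotation import MutarotationSeries
from .nmr import ClassifierWindows, NMRObservables
from .thermo import AnomerEquilibrium

__all__ = [
    "RunConfig",
    "RowError",
    "TableReadError",
    "read_equilibria",
    "read_mutarotation",
    "read_nmr_observables",
    "read_torsion_profile",
    "read_hbond_geometries",
    "read_nbo_interactions",
]

#: Hours per labelled time unit.
TIME_UNIT_HOURS = {"min": 1.0 / 60.0, "h": 1.0, "d": 24.0}


class TableReadError(RuntimeError):
    """Unreadable file, missing mandatory column, or >50% invalid rows."""


@dataclass(frozen=True)
class RowError:
    row_index: int
    reason: str


@dataclass(frozen=True)
class RunConfig:
    """Serializable settings that fully determine a pipeline run."""

    rt_mode: str = "paper_rounded"
    a_value: float = 1.25               # kcal/mol; 1.93 for the THP variant
    a_value_ring: str = "cyclohexane"
    reference_percent_beta: float = 47.1   # reference tetrahydropyranol, DMSO
    reference_solvent: str = "DMSO-d6"
    temperature: float = 298.0
    flat_tol: float = 3.5               # mutarotation flatness gate, % points
    classifier_windows: dict = field(default_factory=dict)
    output_dir: str = "."
    log_level: str = "INFO"

    def windows(self) -> ClassifierWindows:
        return ClassifierWindows(**self.classifier_windows)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text))
        return cls(**(data or {}))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _load_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TableReadError(f"cannot read {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise TableReadError(f"{path}: missing mandatory columns {sorted(missing)}")
    return df


def _check_error_fraction(path, errors, n_rows) -> None:
    if n_rows and len(errors) > 0.5 * n_rows:
        raise TableReadError(
            f"{path}: {len(errors)}/{n_rows} rows invalid (>50%); "
            f"first: {errors[0].reason}"
        )


def read_equilibria(
    path: str | Path,
) -> tuple[list[AnomerEquilibrium], list[RowError]]:
    """Read anomer-equilibrium rows; auto-fills percent_alpha if absent."""
    df = _load_csv(path, {"compound_id", "percent_beta"})
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            alpha = row.get("percent_alpha")
            out.append(AnomerEquilibrium(
                compound_id=str(row["compound_id"]),
                solvent=str(row.get("solvent", "") or ""),
                temperature=float(row.get("temperature_k", 298.0) or 298.0),
                percent_beta=float(row["percent_beta"]),
                percent_alpha=None if pd.isna(alpha) or alpha is None
                else float(alpha),
            ))
        except Exception as exc:
            errors.append(RowError(int(i), str(exc)))
    _check_error_fraction(path, errors, len(df))
    return out, errors


def read_mutarotation(
    path: str | Path, default_final_time_h: float = 7 * 24.0
) -> tuple[list[MutarotationSeries], list[RowError]]:
    """Read mutarotation time courses, converting time units to hours.

    Columns: compound_id, solvent, time_value, time_unit {min,h,d},
    percent_beta.  A blank time_value on the last row of a compound marks
    an untimed final reading; it is ingested at ``default_final_time_h``
    (7 d by convention) and the row error report flags the convention.
    """
    df = _load_csv(path, {"compound_id", "time_value", "time_unit", "percent_beta"})
    errors: list[RowError] = []
    series: list[MutarotationSeries] = []
    for cid, grp in df.groupby("compound_id", sort=False):
        pts = []
        solvent = str(grp.iloc[0].get("solvent", "") or "")
        for i, row in grp.iterrows():
            try:
                unit = str(row["time_unit"]).strip().lower()
                if pd.isna(row["time_value"]):
                    t_h = default_final_time_h
                    errors.append(RowError(
                        int(i),
                        f"{cid}: untimed final point ingested at "
                        f"{default_final_time_h} h by convention",
                    ))
                else:
                    if unit not in TIME_UNIT_HOURS:
                        raise ValueError(f"unknown time unit {unit!r}")
                    t_h = float(row["time_value"]) * TIME_UNIT_HOURS[unit]
                pts.append((t_h, float(row["percent_beta"])))
            except Exception as exc:
                errors.append(RowError(int(i), f"{cid}: {exc}"))
        try:
            series.append(MutarotationSeries(str(cid), solvent, tuple(pts)))
        except Exception as exc:
            errors.append(RowError(-1, f"{cid}: {exc}"))
    return series, errors


def read_nmr_observables(
    path: str | Path,
) -> tuple[list[NMRObservables], list[RowError]]:
    """Read per-species NMR observables; blank cells become ``None``."""
    df = _load_csv(path, {"species_id"})

    def opt(row, col):
        v = row.get(col)
        return None if v is None or pd.isna(v) else float(v)

    def shifts(row, col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        if isinstance(v, str):
            v = v.strip()
            if not v:
                return None
            return tuple(float(x) for x in v.split(";"))
        return (float(v),)

    out, errors = [], []
    for i, row in df.iterrows():
        try:
            out.append(NMRObservables(
                species_id=str(row["species_id"]),
                j_h1_h2=opt(row, "j_h1_h2"),
                one_bond_j_c1_h1=opt(row, "one_bond_j_c1_h1"),
                delta_c1=opt(row, "delta_c1"),
                j_ch_eq_ch=opt(row, "j_ch_eq_ch"),
                j_ch_chn=opt(row, "j_ch_chn"),
                optical_rotation_d=opt(row, "optical_rotation_d"),
                rotation_solvent=str(row.get("rotation_solvent", "") or ""),
                acetylated=bool(row.get("acetylated", False)),
                extra_h_shifts=shifts(row, "extra_h_shifts"),
                extra_c_shifts=shifts(row, "extra_c_shifts"),
            ))
        except Exception as exc:
            errors.append(RowError(int(i), str(exc)))
    _check_error_fraction(path, errors, len(df))
    return out, errors


def read_torsion_profile(path: str | Path) -> TorsionProfile:
    """Read one dihedral scan (angle_deg, energy_kcal)."""
    df = _load_csv(path, {"angle_deg", "energy_kcal"})
    return TorsionProfile(
        tuple(df["angle_deg"].astype(float)),
        tuple(df["energy_kcal"].astype(float)),
    )


def read_hbond_geometries(
    path: str | Path,
) -> tuple[list[HBondGeometry], list[RowError]]:
    """Read donor/acceptor distance rows (donor, acceptor, d_angstrom)."""
    df = _load_csv(path, {"donor", "acceptor", "d_angstrom"})
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            out.append(HBondGeometry(
                str(row["donor"]), str(row["acceptor"]),
                float(row["d_angstrom"]),
            ))
        except Exception as exc:
            errors.append(RowError(int(i), str(exc)))
    _check_error_fraction(path, errors, len(df))
    return out, errors


def read_nbo_interactions(
    path: str | Path,
) -> tuple[list[NBOInteraction], list[RowError]]:
    """Read NBO rows (donor, acceptor, q, f_au, eps_i_au, eps_j_au)."""
    df = _load_csv(path, {"donor", "acceptor", "q", "f_au", "eps_i_au", "eps_j_au"})
    out, errors = [], []
    for i, row in df.iterrows():
        try:
            out.append(NBOInteraction(
                str(row["donor"]), str(row["acceptor"]),
                float(row["q"]), float(row["f_au"]),
                float(row["eps_i_au"]), float(row["eps_j_au"]),
            ))
        except Exception as exc:
            errors.append(RowError(int(i), str(exc)))
    _check_error_fraction(path, errors, len(df))
    return out, errors
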