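"""CSV readers and writers for the pipeline's tabular interfaces.

All tables are UTF-8 CSV with a header row and `.` decimals. The measurement
table carries either ready per-gram amounts (``amount_ugN_per_g``) or raw
analyser columns (``conc_mgN_L`` for slurry filtrates, ``n2o_ppm`` for
headspace samples) plus bottle geometry, converted on load. Reading is
all-or-nothing per file: every violating row is collected and reported with
its line number before anything is returned.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .genes import GENES
from .kinetics import (
    DEFAULT_TEMPERATURE_K,
    IncubationSeries,
    RateEstimate,
    convert_headspace_n2o,
    convert_slurry_concentration,
)
from .errors import GuildfluxError

ID_COLS = ["site_id", "replicate_id", "assay", "treatment"]


def read_measurements(path: str | Path) -> list[IncubationSeries]:
    """Parse a measurement CSV into validated incubation series.

    Rows are grouped by (site, replicate, assay, treatment); within each
    bottle, times must start at 0 and strictly increase. Raw-column files are
    converted to μg N per g dry soil on load.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ID_COLS + ["time_h"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    has_amount = "amount_ugN_per_g" in df.columns
    has_conc = "conc_mgN_L" in df.columns
    has_ppm = "n2o_ppm" in df.columns
    if not (has_amount or has_conc or has_ppm):
        raise SchemaError(
            f"{path.name}: need amount_ugN_per_g, or raw conc_mgN_L / n2o_ppm columns"
        )

    errors: list[str] = []
    # +2: header line plus 1-based numbering, matching what an editor shows.
    df = df.assign(_line=df.index + 2)

    def amount_of(row) -> float:
        if has_amount and pd.notna(row.get("amount_ugN_per_g")):
            return float(row["amount_ugN_per_g"])
        if has_conc and pd.notna(row.get("conc_mgN_L")):
            return convert_slurry_concentration(
                float(row["conc_mgN_L"]),
                float(row.get("slurry_volume_ml", 80.0)),
                float(row.get("dry_soil_mass_g", 10.0)),
            )
        if has_ppm and pd.notna(row.get("n2o_ppm")):
            return convert_headspace_n2o(
                float(row["n2o_ppm"]),
                float(row.get("headspace_volume_ml", 170.0)),
                float(row.get("temperature_K", DEFAULT_TEMPERATURE_K)),
                float(row.get("pressure_atm", 1.0)),
                float(row.get("dry_soil_mass_g", 10.0)),
            )
        raise GuildfluxError("no measurement value in row")

    series: list[IncubationSeries] = []
    # Row order within a bottle is preserved: out-of-order times are a schema
    # violation (likely a mislabelled row), not something to silently repair.
    for key, grp in df.groupby(ID_COLS, sort=True):
        first_line = int(grp["_line"].iloc[0])
        try:
            amounts = [amount_of(row) for _, row in grp.iterrows()]
            series.append(
                IncubationSeries(
                    site_id=str(key[0]),
                    replicate_id=str(key[1]),
                    assay=str(key[2]),
                    treatment=str(key[3]),
                    times=tuple(float(t) for t in grp["time_h"]),
                    amounts=tuple(amounts),
                )
            )
        except GuildfluxError as exc:
            errors.append(f"row {first_line} ({'/'.join(map(str, key))}): {exc}")
    if errors:
        raise SchemaError(f"{path.name}: {len(errors)} invalid series:\n" + "\n".join(errors))
    return series


def write_measurements(series: Sequence[IncubationSeries], path: str | Path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "replicate_id": s.replicate_id,
            "assay": s.assay,
            "treatment": s.treatment,
            "time_h": t,
            "amount_ugN_per_g": a,
        }
        for s in series
        for t, a in zip(s.times, s.amounts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def rates_frame(
    series: Sequence[IncubationSeries],
    estimates: Sequence[RateEstimate],
    qc: Sequence[bool],
) -> pd.DataFrame:
    """One row per bottle: ids, slope, diagnostics, linearity flag."""
    rows = []
    for s, e, ok in zip(series, estimates, qc):
        rows.append(
            {
                "site_id": s.site_id,
                "replicate_id": s.replicate_id,
                "assay": s.assay,
                "treatment": s.treatment,
                "k": e.k,
                "se_k": e.se_k,
                "intercept": e.intercept,
                "r2": e.r_squared if e.r_squared is not None else float("nan"),
                "n_points": e.n_points,
                "qc_pass": ok,
            }
        )
    return pd.DataFrame(rows)


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("site_id", "replicate_id", "gene", "copies") if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing columns {missing}")
    unknown = sorted(set(df["gene"]) - set(GENES))
    if unknown:
        raise SchemaError(f"{Path(path).name}: unknown genes {unknown}")
    if (df["copies"] < 0).any():
        bad = df.index[df["copies"] < 0][0] + 2
        raise SchemaError(f"{Path(path).name}: negative copies at row {bad}")
    return df


def read_environment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site_id" not in df.columns:
        raise SchemaError(f"{Path(path).name}: missing site_id column")
    return df
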