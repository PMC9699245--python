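"""CSV readers/writers and report assembly.

One CSV dialect everywhere: comma separator, point decimal, UTF-8,
mandatory header.  Columns are keyed by name (order is free); a
decimal-comma or otherwise non-numeric cell is a schema error naming
the offending row.  Row numbers count the header as row 1, matching
what a user sees in a spreadsheet.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregation import ThTTrace
from .dpph import DPPHSeries
from .enzyme import ProgressCurve
from .errors import InputError, SchemaError
from .quenching import QuenchTitration

__all__ = [
    "SCHEMAS",
    "read_assay_csv",
    "traces_from_frame",
    "curves_from_frame",
    "titrations_from_frame",
    "dpph_from_frame",
    "write_frame_csv",
    "traces_to_frame",
    "curves_to_frame",
    "RunReport",
    "build_report",
    "KINETIC_ROW_LABELS",
]

# schema id -> (numeric columns, string columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "tht": (("time_s", "signal", "replicate"), ("condition",)),
    "ellman": (
        ("time_s", "absorbance", "substrate_mM", "inhibitor_uM", "replicate"),
        ("condition",),
    ),
    "quench": (("quencher_uM", "intensity"), ("condition",)),
    "dpph": (("flavonoid_uM", "absorbance_517", "control_absorbance"), ()),
}

# Monotone-time schemas: (group-by columns, time column)
_TIME_ORDERED = {
    "tht": (["condition", "replicate"], "time_s"),
    "ellman": (["condition", "inhibitor_uM", "substrate_mM", "replicate"], "time_s"),
    "quench": (["condition"], "quencher_uM"),
    "dpph": ([], "flavonoid_uM"),
}


def read_assay_csv(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate an assay CSV against a named schema.

    Returns a typed DataFrame whose index preserves the original file
    row numbers.  Raises :class:`SchemaError` for a missing column, a
    non-numeric cell (including decimal commas) or nonincreasing time
    within a series, naming the first offending row.
    """
    if schema not in SCHEMAS:
        raise InputError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    numeric_cols, string_cols = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed CSV structure
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in (*numeric_cols, *string_cols) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df.index = df.index + 2  # header is row 1
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if df[col].isna().any():
            bad = bad.union(df.index[df[col].isna()])
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value {df[col].get(bad[0])!r} in column "
                f"{col!r}", row=int(bad[0]),
            )
        df[col] = converted
    for col in string_cols:
        df[col] = df[col].fillna("").astype(str)
    group_cols, time_col = _TIME_ORDERED[schema]
    groups = df.groupby(group_cols, sort=False) if group_cols else [(None, df)]
    for _, g in groups:
        t = g[time_col].to_numpy()
        if len(t) > 1:
            nonmono = np.nonzero(np.diff(t) <= 0)[0]
            if len(nonmono):
                raise SchemaError(
                    f"{path}: {time_col} not strictly increasing",
                    row=int(g.index[nonmono[0] + 1]),
                )
    return df


def traces_from_frame(df: pd.DataFrame, monomer_concentration: float) -> list[ThTTrace]:
    """Split a validated 'tht' frame into per-(condition, replicate) traces."""
    out = []
    for (cond, rep), g in df.groupby(["condition", "replicate"], sort=True):
        out.append(
            ThTTrace(
                time=g["time_s"].to_numpy(),
                signal=g["signal"].to_numpy(),
                condition=str(cond),
                replicate=int(rep),
                monomer_concentration=monomer_concentration,
            )
        )
    return out


def curves_from_frame(df: pd.DataFrame) -> list[ProgressCurve]:
    """Split a validated 'ellman' frame into progress curves."""
    keys = ["condition", "inhibitor_uM", "substrate_mM", "replicate"]
    out = []
    for (cond, inh, sub, rep), g in df.groupby(keys, sort=True):
        out.append(
            ProgressCurve(
                time=g["time_s"].to_numpy(),
                absorbance=g["absorbance"].to_numpy(),
                substrate_mM=float(sub),
                inhibitor_uM=float(inh),
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return out


def titrations_from_frame(df: pd.DataFrame) -> list[QuenchTitration]:
    out = []
    for cond, g in df.groupby("condition", sort=True):
        out.append(
            QuenchTitration(
                quencher_uM=g["quencher_uM"].to_numpy(),
                intensity=g["intensity"].to_numpy(),
                condition=str(cond),
            )
        )
    return out


def dpph_from_frame(df: pd.DataFrame) -> DPPHSeries:
    control = df["control_absorbance"].to_numpy()
    if not np.allclose(control, control[0]):
        raise SchemaError("control_absorbance must be constant within a series")
    return DPPHSeries(
        concentration_uM=df["flavonoid_uM"].to_numpy(),
        absorbance_517=df["absorbance_517"].to_numpy(),
        control_absorbance=float(control[0]),
    )


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.12g}"
    return str(x)


def write_frame_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame with deterministic 12-significant-digit floats."""
    buf = _io.StringIO()
    buf.write(",".join(df.columns) + "\n")
    for row in df.itertuples(index=False):
        buf.write(",".join(_fmt(v) for v in row) + "\n")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(buf.getvalue(), encoding="utf-8")


def traces_to_frame(traces: list[ThTTrace]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.time,
                "signal": tr.signal,
                "condition": tr.condition,
                "replicate": tr.replicate,
            }
        )
        for tr in traces
    ]
    return pd.concat(frames, ignore_index=True)[
        ["time_s", "signal", "condition", "replicate"]
    ]


def curves_to_frame(curves: list[ProgressCurve]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "time_s": c.time,
                "absorbance": c.absorbance,
                "substrate_mM": c.substrate_mM,
                "inhibitor_uM": c.inhibitor_uM,
                "condition": c.condition,
                "replicate": c.replicate,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)


KINETIC_ROW_LABELS = [
    "k_n (1e-5 s^-1)",
    "k_e (M^-1 s^-1)",
    "t_0 (s)",
    "t_1/2 (s)",
    "t_1 (s)",
    "Inhibition (%)",
]


@dataclass(frozen=True)
class RunReport:
    """Assembled analysis report: per-stage tables plus provenance.

    Tables carry printed-units conventions (k_n scaled to 1e-5 s^-1);
    ``to_json`` serialises everything at full precision with sorted
    keys so identical inputs give identical bytes.
    """

    kinetic_table: pd.DataFrame | None = None
    enzyme_table: pd.DataFrame | None = None
    binding_table: pd.DataFrame | None = None
    rsc_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload: dict = {"provenance": self.provenance}
        for name in ("kinetic_table", "enzyme_table", "binding_table", "rsc_table"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = {
                    "index": [str(i) for i in df.index],
                    "columns": [str(c) for c in df.columns],
                    "data": [
                        [None if (isinstance(v, float) and np.isnan(v)) else v
                         for v in row]
                        for row in df.itertuples(index=False, name=None)
                    ],
                }
        return json.dumps(payload, sort_keys=True, indent=2)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(self.to_json(), encoding="utf-8")
        for name in ("kinetic_table", "enzyme_table", "binding_table", "rsc_table"):
            df = getattr(self, name)
            if df is not None:
                write_frame_csv(
                    df.reset_index(names="parameter"), directory / f"{name}.csv"
                )


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def build_report(
    aggregation: dict[str, dict] | None = None,
    enzyme: dict[str, dict] | None = None,
    binding: dict[str, dict] | None = None,
    rsc: list[tuple[float, float]] | None = None,
    provenance: dict | None = None,
) -> RunReport:
    """Assemble stage outputs into a :class:`RunReport`.

    aggregation maps condition -> {k_n, k_e, t0, t_half, t1,
    inhibition_pct} in SI units (s^-1, M^-1 s^-1, s); the kinetic table
    scales k_n to the customary 1e-5 s^-1 convention.  At least one
    stage must be supplied.
    """
    if not any([aggregation, enzyme, binding, rsc]):
        raise InputError("report needs at least one stage output")
    kinetic = None
    if aggregation:
        cols = {}
        for cond, p in aggregation.items():
            cols[cond] = [
                p["k_n"] * 1e5,
                p["k_e"],
                p["t0"],
                p["t_half"],
                p["t1"],
                p.get("inhibition_pct", np.nan),
            ]
        kinetic = pd.DataFrame(cols, index=KINETIC_ROW_LABELS)
    enzyme_df = pd.DataFrame(enzyme).T if enzyme else None
    binding_df = pd.DataFrame(binding).T if binding else None
    rsc_df = (
        pd.DataFrame(rsc, columns=["concentration_uM", "rsc_pct"]) if rsc else None
    )
    return RunReport(
        kinetic_table=kinetic,
        enzyme_table=enzyme_df,
        binding_table=binding_df,
        rsc_table=rsc_df,
        provenance=provenance or {},
    )
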