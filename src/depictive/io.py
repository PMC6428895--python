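"""Event-table I/O, gating, and the mitochondria-density channel.

Event tables are cells-as-rows frames with flow channels (FSC, SSC,
MitoTracker, AnnexinV) plus a dose column; CSV/TSV is the canonical
interchange format.  Gating follows the experimental recipe: sequential
threshold / interval / rectangle gates, with the fraction alive computed as
the Annexin-V-negative count over the MitoTracker-positive count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

__all__ = [
    "CHANNEL_COLUMNS",
    "Gate",
    "GateSpec",
    "load_events",
    "apply_gates",
    "fraction_alive_by_dose",
    "compute_density_channel",
]

CHANNEL_COLUMNS = ("FSC", "SSC", "MitoTracker", "AnnexinV")


def load_events(path, format: str = "csv", required=("dose",),
                channel_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load an event table from CSV/TSV with schema validation.

    ``channel_map`` renames file columns to canonical channel names.
    FCS ingestion is not supported in this build; request CSV/TSV exports.
    """
    if format == "fcs":
        raise InvalidInputError(
            "FCS ingestion is not available in this build; export the "
            "events to CSV/TSV instead"
        )
    if format not in ("csv", "tsv"):
        raise InvalidInputError(f"unknown format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    sep = "\t" if format == "tsv" or path.suffix == ".tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise SchemaError(f"malformed event table {path}: {exc}") from exc
    if channel_map:
        df = df.rename(columns=channel_map)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"event table {path} is missing columns {missing}")
    numeric = [c for c in df.columns if c in CHANNEL_COLUMNS + ("dose", "log_rho")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"column {col!r}: non-numeric value at line "
                f"{int(bad[0]) + 2} of {path}"  # +2: header plus 1-basing
            )
        df[col] = coerced
    for col in CHANNEL_COLUMNS:
        if col in df.columns and (df[col] < 0).any():
            row = int(df.index[df[col] < 0][0]) + 2
            raise SchemaError(f"negative {col} value at line {row} of {path}")
    if df["dose"].isna().any():
        row = int(df.index[df["dose"].isna()][0]) + 2
        raise SchemaError(f"missing dose at line {row} of {path}")
    return df


@dataclass(frozen=True)
class Gate:
    """One gating step.

    kind "threshold": keep rows with channel >= bounds (scalar) when
    ``keep_inside``; "interval": bounds = (lo, hi) on one channel;
    "rect": two channels with bounds = ((lo1, hi1), (lo2, hi2)).
    """

    name: str
    channels: tuple[str, ...]
    kind: str
    bounds: tuple
    keep_inside: bool = True

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        for ch in self.channels:
            if ch not in table.columns:
                raise SchemaError(f"gate {self.name!r}: no channel {ch!r}")
        if self.kind == "threshold":
            inside = table[self.channels[0]].to_numpy() >= float(self.bounds)
        elif self.kind == "interval":
            lo, hi = self.bounds
            x = table[self.channels[0]].to_numpy()
            inside = (x >= lo) & (x <= hi)
        elif self.kind == "rect":
            (lo1, hi1), (lo2, hi2) = self.bounds
            x = table[self.channels[0]].to_numpy()
            y = table[self.channels[1]].to_numpy()
            inside = (x >= lo1) & (x <= hi1) & (y >= lo2) & (y <= hi2)
        else:
            raise InvalidInputError(f"unknown gate kind {self.kind!r}")
        return inside if self.keep_inside else ~inside

    @classmethod
    def from_dict(cls, d: dict) -> "Gate":
        ch = d.get("channels", d.get("channel"))
        channels = (ch,) if isinstance(ch, str) else tuple(ch)
        bounds = d["bounds"]
        if isinstance(bounds, list):
            bounds = tuple(tuple(b) if isinstance(b, list) else b for b in bounds)
        return cls(name=d["name"], channels=channels, kind=d["kind"],
                   bounds=bounds, keep_inside=bool(d.get("keep_inside", True)))


GateSpec = list  # ordered list of Gate


def apply_gates(table: pd.DataFrame, gates: list[Gate]):
    """Sequentially filter a table; returns (gated table, retention counts)."""
    counts = [{"gate": "(input)", "retained": len(table)}]
    out = table
    for gate in gates:
        out = out[gate.mask(out)]
        counts.append({"gate": gate.name, "retained": len(out)})
    return out.copy(), pd.DataFrame(counts)


def fraction_alive_by_dose(table: pd.DataFrame, gates: list[Gate],
                           denominator_gate: str,
                           by: str = "dose") -> pd.DataFrame:
    """Per-dose fraction alive from a gate chain.

    The denominator is the cell count after ``denominator_gate`` (the
    MitoTracker-positive gate in the experimental recipe); the numerator is
    the count surviving the full chain (Annexin-V negative).
    """
    names = [g.name for g in gates]
    if denominator_gate not in names:
        raise InvalidInputError(f"no gate named {denominator_gate!r}")
    upto = names.index(denominator_gate) + 1
    denom_table, _ = apply_gates(table, gates[:upto])
    final_table, _ = apply_gates(denom_table, gates[upto:])
    denom = denom_table.groupby(by).size()
    num = final_table.groupby(by).size().reindex(denom.index, fill_value=0)
    return pd.DataFrame({
        by: denom.index.to_numpy(),
        "total": denom.to_numpy(int),
        "alive": num.to_numpy(int),
        "fraction_alive": (num / denom).to_numpy(float),
    })


def compute_density_channel(table: pd.DataFrame) -> pd.DataFrame:
    """Add log_rho = log(MitoTracker) - log(FSC), the mitochondria density.

    Rows with a non-positive MitoTracker or FSC value are excluded; the
    number removed is recorded in ``table.attrs["n_excluded_nonpositive"]``.
    """
    for col in ("MitoTracker", "FSC"):
        if col not in table.columns:
            raise SchemaError(f"density channel needs column {col!r}")
    ok = (table["MitoTracker"] > 0) & (table["FSC"] > 0)
    out = table[ok].copy()
    out["log_rho"] = np.log(out["MitoTracker"].to_numpy()) \
        - np.log(out["FSC"].to_numpy())
    out.attrs["n_excluded_nonpositive"] = int((~ok).sum())
    return out
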