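"""CSV signal-table and results I/O plus run configuration.

At the file boundary units live in the column names: ``b_s_per_mm2``,
``big_delta_ms``, ``small_delta_ms``, and reported lengths in
micrometres.  Internally everything is seconds and millimetres.  Every
results directory gets a JSON run manifest recording the seed, software
version, a hash of the configuration and the per-region diagnostic
flags, so a run is reproducible from config plus input files alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fitting import FitConfig, FitResult, SignalTable, results_to_frame

__all__ = [
    "RunConfig",
    "read_signal_table",
    "write_signal_table",
    "read_reference_lengths",
    "write_results",
]

_CSV_REQUIRED = ["subject", "session", "region", "b_s_per_mm2",
                 "big_delta_ms", "small_delta_ms", "direction", "signal"]


@dataclass
class RunConfig:
    """Serialisable description of one analysis run."""

    fit: FitConfig = field(default_factory=FitConfig)
    protocol: str = "paper-default"
    seed: int = 0
    snr: float | None = 50.0
    model: str = "va"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fit = FitConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in raw.pop("fit", {}).items()})
        return cls(fit=fit, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_signal_table(path) -> SignalTable:
    """Read a signal CSV (ms / s-per-mm^2 headers) into internal units.

    Raises a validation error naming missing columns or the
    (subject, session, region, Delta) groups lacking a b = 0 record.
    Unknown columns are preserved.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = df.rename(columns={"b_s_per_mm2": "b"}).copy()
    out["Delta"] = out.pop("big_delta_ms").astype(float) * 1e-3
    out["delta"] = out.pop("small_delta_ms").astype(float) * 1e-3
    for col in ("b", "signal"):
        out[col] = out[col].astype(float)
    return SignalTable(out)


def write_signal_table(table: SignalTable, path) -> None:
    """Write a signal table with unit-bearing headers; round-trip lossless."""
    df = table.data.copy()
    df["big_delta_ms"] = df.pop("Delta") * 1e3
    df["small_delta_ms"] = df.pop("delta") * 1e3
    df = df.rename(columns={"b": "b_s_per_mm2"})
    cols = _CSV_REQUIRED + [c for c in df.columns if c not in _CSV_REQUIRED]
    # %.17g keeps doubles round-trip exact
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_reference_lengths(path) -> dict:
    """Two-column CSV (region, median segment length in um) -> dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (region, length_um)")
    region_col, len_col = df.columns[:2]
    return dict(zip(df[region_col], df[len_col].astype(float)))


def _lengths_to_um(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in list(out.columns):
        if col.startswith("l_"):
            out[col.replace("l_", "l_um_", 1)] = out.pop(col) * 1e3
    return out


def write_results(obj, outdir, config: RunConfig | None = None,
                  name: str = "results") -> Path:
    """Write a results object as CSV plus a JSON run manifest.

    ``obj`` may be a list of FitResult, a DataFrame, or any dataclass
    with scalar fields (repeatability / validation results).  Fit-result
    lengths are converted to micrometres in the CSV.  Returns the CSV
    path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    flags = {}
    if isinstance(obj, list) and obj and isinstance(obj[0], FitResult):
        df = _lengths_to_um(results_to_frame(obj))
        flags = {f"{r.subject}/{r.session}/{r.region}": r.flags for r in obj}
    elif isinstance(obj, pd.DataFrame):
        df = obj
    elif hasattr(obj, "__dataclass_fields__"):
        d = {k: v for k, v in asdict(obj).items()
             if not hasattr(v, "__len__") or isinstance(v, str)}
        d["flags"] = ";".join(getattr(obj, "flags", []))
        df = pd.DataFrame([d])
    else:
        raise TypeError(f"cannot serialise {type(obj)!r}")
    csv_path = outdir / f"{name}.csv"
    df.to_csv(csv_path, index=False)
    manifest = {
        "software": "ivimva",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "outputs": [csv_path.name],
        "diagnostics": flags,
    }
    with open(outdir / f"{name}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return csv_path
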