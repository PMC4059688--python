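"""Readers/writers and run configuration.

Conventions: time is rows, series are columns; delimited text carries a
header row of series labels; scale indices in written reports are 1-based
(C1 = fastest IMF), matching the usual IMF numbering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .memd import IMFDecomposition, MultichannelSeries
from .na_memd import TrialTensor
from .significance import SignificanceReport

__all__ = ["RunConfig", "read_series", "write_series", "write_report",
           "read_report", "write_decomposition", "read_decomposition"]


@dataclass
class RunConfig:
    """All pipeline tunables plus a provenance block; JSON round-trippable.
    Unknown keys are rejected on load to catch config typos."""

    K: int = 64
    stop_thresholds: tuple[float, float, float] = (0.075, 0.75, 0.075)
    max_sift_iters: int = 15
    max_imfs: int | None = None
    m: int = 15
    variance_fraction: float = 0.06
    window_len: int | None = None
    window_step: int | None = None
    alpha: float = 0.05
    seed: int | None = None
    version: str = ""
    timestamp: str = ""
    input_sha256: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stop_thresholds" in d:
            d["stop_thresholds"] = tuple(d["stop_thresholds"])
        return cls(**d)

    def stamp(self, input_path: str | Path | None = None) -> "RunConfig":
        from . import __version__
        self.version = __version__
        self.timestamp = datetime.now(timezone.utc).isoformat()
        if input_path is not None:
            self.input_sha256 = hashlib.sha256(
                Path(input_path).read_bytes()).hexdigest()
        return self


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_series(path: str | Path, fs: float) -> MultichannelSeries | TrialTensor:
    """Load a signal: TSV/CSV with a label header → MultichannelSeries;
    an HDF5 file with a 3-axis ``values`` dataset → TrialTensor."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            values = np.asarray(f["values"])
        if values.ndim != 3:
            raise ValueError("HDF5 input must have axes time × channels × trials")
        return TrialTensor(values, fs)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        raise ValueError(f"non-numeric column(s) in {path.name}: {list(bad)}")
    nan_rows, nan_cols = np.nonzero(df.isna().to_numpy())
    if len(nan_rows):
        raise ValueError(
            f"NaN at row {nan_rows[0] + 2} (1-based, incl. header), "
            f"column {df.columns[nan_cols[0]]!r} in {path.name}")
    return MultichannelSeries(df.to_numpy(dtype=float), fs,
                              labels=list(map(str, df.columns)))


def write_series(s: MultichannelSeries, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(s.values, columns=s.labels).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.17g")


def write_decomposition(dec: IMFDecomposition, path: str | Path) -> None:
    """Store a decomposition as HDF5 with axes (scale, time, series)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("imfs", data=dec.imfs)
        f.create_dataset("residue", data=dec.residue)
        f.create_dataset("norm_sds", data=dec.norm_sds)
        f.attrs["sample_rate_hz"] = dec.sample_rate_hz
        f.attrs["roles"] = dec.roles
        f.attrs["labels"] = dec.labels


def read_decomposition(path: str | Path) -> IMFDecomposition:
    with h5py.File(path, "r") as f:
        return IMFDecomposition(
            imfs=np.asarray(f["imfs"]),
            residue=np.asarray(f["residue"]),
            norm_sds=np.asarray(f["norm_sds"]),
            sample_rate_hz=float(f.attrs["sample_rate_hz"]),
            roles=[str(r) for r in f.attrs["roles"]],
            labels=[str(l) for l in f.attrs["labels"]],
        )


def report_frame(report: SignificanceReport) -> pd.DataFrame:
    rows = []
    for s in range(report.n_scales):
        for c, lab in enumerate(report.data_labels):
            rows.append({
                "scale": s + 1, "series": lab,
                "distance": report.distances[s, c],
                "ci_low": report.ci_low[s], "ci_high": report.ci_high[s],
                "significant": bool(report.significant[s, c]),
            })
    return pd.DataFrame(rows)


def write_report(report: SignificanceReport, path: str | Path,
                 config: RunConfig | None = None) -> None:
    """Write a significance report as TSV plus a JSON mirror with metadata."""
    path = Path(path)
    report_frame(report).to_csv(path, sep="\t", index=False, float_format="%.6g")
    payload = {
        "config": dataclasses.asdict(config) if config else None,
        "meta": report.meta,
        "alpha": report.alpha,
        "data_labels": report.data_labels,
        "distances": report.distances.tolist(),
        "ci_low": report.ci_low.tolist(),
        "ci_high": report.ci_high.tolist(),
        "significant": report.significant.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(payload, indent=2))


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
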