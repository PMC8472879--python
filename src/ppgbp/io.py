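"""On-disk formats: HDF5 record/window stores with CSV manifests.

A record store is one HDF5 file with one group per subject holding the
``ppg`` (and optional ``abp``) arrays with an ``fs`` attribute, plus a
sibling CSV manifest (``<store>.manifest.csv``) listing subject id,
duration and sampling rate.  Window stores keep model inputs, labels and
provenance in aligned datasets keyed by (subject_id, source_offset).
Signals round-trip losslessly at 64-bit.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd
import yaml

from ppgbp.datasets import WindowSet
from ppgbp.preprocess import WaveformRecord

logger = logging.getLogger(__name__)

__all__ = [
    "write_record_store", "read_record_store", "iter_record_store",
    "write_window_store", "read_window_store", "manifest_path",
    "wfdb_adapter", "RecordStoreError", "RunConfig",
]


@dataclass
class RunConfig:
    """Validated configuration of one full pipeline run.

    Defaults mirror the standard protocol: 7-beat windows, −7 dB SNR gate,
    2000-window subject cap, Adam α = 0.001 with patience 10, 10 mmHg
    evaluation bins.  The resolved config is archived next to every
    output so any artifact can be reproduced from (config, seed).
    """

    seed: int = 0
    n_subjects: int = 10
    strategy: str = "const_beats"
    length_parameter: int = 7
    snr_threshold_db: float = -7.0
    derivatives: bool = False
    split_mode: str = "non_mixed"
    per_subject_cap: int = 2000
    architecture: str = "cnn_small"
    learning_rate: float = 1e-3
    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 128
    bin_width_mmhg: float = 10.0
    sbp_range: tuple[float, float] = (75.0, 165.0)
    dbp_range: tuple[float, float] = (40.0, 80.0)
    hr_range: tuple[float, float] = (50.0, 140.0)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from ppgbp.models import ARCHITECTURES
        if self.strategy not in ("const_time", "const_beats"):
            raise ValueError(f"invalid strategy {self.strategy!r}")
        if self.split_mode not in ("non_mixed", "mixed"):
            raise ValueError(f"invalid split_mode {self.split_mode!r}")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"invalid architecture {self.architecture!r}")
        if self.learning_rate <= 0 or self.max_epochs <= 0:
            raise ValueError("learning_rate and max_epochs must be positive")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be below max_epochs")
        if self.per_subject_cap <= 0 or self.bin_width_mmhg <= 0:
            raise ValueError("cap and bin width must be positive")
        for name in ("sbp_range", "dbp_range", "hr_range"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} low must be below high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("run config must be a YAML mapping")
        for name in ("sbp_range", "dbp_range", "hr_range"):
            if name in raw:
                raw[name] = tuple(raw[name])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def archive(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_config.yaml"
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path


class RecordStoreError(RuntimeError):
    """Structural problem in a record store (manifest/group mismatch)."""


def manifest_path(store_path: str | Path) -> Path:
    store_path = Path(store_path)
    return store_path.with_suffix(store_path.suffix + ".manifest.csv")


def write_record_store(records: list[WaveformRecord], path: str | Path,
                       profiles: list | None = None) -> Path:
    """Write records (and optional generator profiles) to an HDF5 store."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    with h5py.File(path, "w") as h5:
        for i, record in enumerate(records):
            grp = h5.create_group(record.subject_id)
            grp.create_dataset("ppg", data=record.ppg, dtype="f8")
            if record.abp is not None:
                grp.create_dataset("abp", data=record.abp, dtype="f8")
            grp.attrs["fs"] = record.fs
            grp.attrs["subject_id"] = record.subject_id
            row = {"subject_id": record.subject_id,
                   "duration_s": record.duration_s, "fs": record.fs}
            if profiles is not None:
                p = profiles[i]
                row.update(base_hr=p.base_hr, base_sbp=p.base_sbp,
                           base_dbp=p.base_dbp, noise_sd=p.noise_sd,
                           bp_drift_amplitude=p.bp_drift_amplitude,
                           seed=p.seed)
            rows.append(row)
    pd.DataFrame(rows).to_csv(manifest_path(path), index=False)
    return path


def iter_record_store(path: str | Path) -> Iterator[WaveformRecord]:
    """Stream records one subject at a time (stores may exceed memory)."""
    path = Path(path)
    manifest = pd.read_csv(manifest_path(path))
    with h5py.File(path, "r") as h5:
        for sid in manifest["subject_id"].astype(str):
            if sid not in h5:
                raise RecordStoreError(
                    f"manifest lists subject {sid!r} but the store has no "
                    "such group")
            grp = h5[sid]
            if "fs" not in grp.attrs:
                raise RecordStoreError(f"group {sid!r} lacks an fs attribute")
            yield WaveformRecord(
                subject_id=sid, ppg=grp["ppg"][...],
                abp=grp["abp"][...] if "abp" in grp else None,
                fs=float(grp.attrs["fs"]))


def read_record_store(path: str | Path) -> list[WaveformRecord]:
    return list(iter_record_store(path))


def write_window_store(windows: WindowSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("X", data=windows.X, dtype="f8")
        h5.create_dataset("y", data=windows.y, dtype="f8")
        h5.create_dataset("subject",
                          data=np.array(windows.subject, dtype="S"))
        h5.create_dataset("offset", data=windows.offset)
        h5.create_dataset("hr", data=windows.hr)
        h5.create_dataset("snr", data=windows.snr)
    return path


def read_window_store(path: str | Path) -> WindowSet:
    with h5py.File(path, "r") as h5:
        return WindowSet(
            X=h5["X"][...], y=h5["y"][...],
            subject=h5["subject"][...].astype(str),
            offset=h5["offset"][...], hr=h5["hr"][...], snr=h5["snr"][...])


def wfdb_adapter(path: str | Path) -> list[WaveformRecord]:
    """Ingest PhysioNet waveform records with PLETH and ABP channels.

    Optional: requires the ``wfdb`` package.  Records lacking either
    channel are skipped with a warning; the record name becomes the
    subject id.
    """
    try:
        import wfdb  # noqa: PLC0415
    except ImportError as exc:
        raise RuntimeError(
            "the wfdb package is required for PhysioNet ingestion; "
            "install it with `pip install wfdb`") from exc
    path = Path(path)
    headers = sorted(path.glob("*.hea")) if path.is_dir() else [path]
    out = []
    for header in headers:
        rec = wfdb.rdrecord(str(header.with_suffix("")))
        names = [n.upper() for n in rec.sig_name]
        if "PLETH" not in names or "ABP" not in names:
            logger.warning("record %s lacks PLETH/ABP; skipped", header.stem)
            continue
        sig = rec.p_signal
        out.append(WaveformRecord(
            subject_id=rec.record_name,
            ppg=sig[:, names.index("PLETH")],
            abp=sig[:, names.index("ABP")], fs=float(rec.fs)))
    return out
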