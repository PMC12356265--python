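"""MZmine-style export IO: MGF spectra, quant-table CSV, normalization.

The MGF dialect handled here is the minimal one emitted by MZmine /
GNPS exporters: BEGIN IONS blocks with PEPMASS, optional CHARGE,
RTINSECONDS and FEATURE_ID/SCANS headers followed by ``mz intensity``
peak lines.  Retention time is minutes internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "FeatureTable",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "read_quant_csv",
    "write_quant_csv",
    "normalize_range",
]


class MgfError(ValueError):
    """Malformed MGF input (message carries the 1-based line number)."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS spectrum with precursor metadata; peaks sorted by m/z."""

    feature_id: str
    precursor_mz: float
    charge: int = 1
    rt: float = 0.0  # minutes
    peaks: tuple[Peak, ...] = field(default_factory=tuple)
    polarity: str = "+"
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz))
        )

    @property
    def is_empty(self) -> bool:
        return not self.peaks

    def peaks_in_range(self, mz_min: float, mz_max: float) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if mz_min <= p.mz <= mz_max)


@dataclass
class FeatureTable:
    """MS1 feature rows: id, m/z, retention time, per-sample areas."""

    frame: pd.DataFrame  # columns: feature_id (str), mz, rt, + area columns

    def __post_init__(self) -> None:
        dupes = self.frame["feature_id"][self.frame["feature_id"].duplicated()]
        if len(dupes):
            raise ValueError(
                "duplicate feature ids in table: " + ", ".join(sorted(set(dupes)))
            )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame["feature_id"])

    def row(self, feature_id: str) -> pd.Series:
        hit = self.frame[self.frame["feature_id"] == str(feature_id)]
        if hit.empty:
            raise KeyError(feature_id)
        return hit.iloc[0]

    @property
    def area_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("feature_id", "mz", "rt")]


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into spectra; peaks are sorted on read.

    Missing CHARGE defaults to +1 (positive mode); FEATURE_ID falls back
    to SCANS.  A block without peaks is retained and logged.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    headers: dict[str, str] = {}
    peaks: list[Peak] = []
    in_block = False
    block_line = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper() == "BEGIN IONS":
                if in_block:
                    raise MgfError(f"{path}:{lineno}: nested BEGIN IONS")
                in_block, headers, peaks, block_line = True, {}, [], lineno
                continue
            if line.upper() == "END IONS":
                if not in_block:
                    raise MgfError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                spectra.append(_finish_block(headers, peaks, path, block_line))
                in_block = False
                continue
            if not in_block:
                continue  # tolerate stray global headers (e.g. COM=)
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                headers[key.strip().upper()] = value.strip()
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise MgfError(f"{path}:{lineno}: bad peak line {line!r}")
                try:
                    peaks.append(Peak(float(fields[0]), float(fields[1])))
                except ValueError as exc:
                    raise MgfError(f"{path}:{lineno}: bad peak line {line!r}") from exc
    if in_block:
        raise MgfError(f"{path}:{block_line}: BEGIN IONS never closed")
    return spectra


def _finish_block(
    headers: dict[str, str], peaks: list[Peak], path: Path, lineno: int
) -> Spectrum:
    if "PEPMASS" not in headers:
        raise MgfError(f"{path}:{lineno}: block missing PEPMASS")
    pepmass = float(headers["PEPMASS"].split()[0])
    feature_id = headers.get("FEATURE_ID") or headers.get("SCANS")
    if feature_id is None:
        raise MgfError(f"{path}:{lineno}: block has neither FEATURE_ID nor SCANS")
    charge_text = headers.get("CHARGE", "1+")
    polarity = "-" if charge_text.endswith("-") else "+"
    charge = int(charge_text.rstrip("+-") or 1)
    rt = float(headers.get("RTINSECONDS", 0.0)) / 60.0
    if not peaks:
        logger.warning("spectrum %s has an empty peak list", feature_id)
    return Spectrum(
        feature_id=str(feature_id),
        precursor_mz=pepmass,
        charge=charge,
        rt=rt,
        peaks=tuple(peaks),
        polarity=polarity,
    )


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (m/z to 1e-5, intensity to 1e-4)."""
    path = Path(path)
    with path.open("w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"FEATURE_ID={s.feature_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={abs(s.charge)}{'-' if s.polarity == '-' else '+'}\n")
            fh.write(f"RTINSECONDS={s.rt * 60.0:.3f}\n")
            for note in s.annotations:
                fh.write(f"#{note}\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.4f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# Quant CSV
# ---------------------------------------------------------------------------

_ID_NAMES = {"row id", "id", "feature_id"}
_MZ_NAMES = {"row m/z", "m/z", "mz", "row mz"}
_RT_NAMES = {"row retention time", "retention time", "rt"}


def read_quant_csv(path: str | Path) -> FeatureTable:
    """Read an MZmine-style quant table.

    Recognizes ``row ID`` / ``row m/z`` / ``row retention time`` header
    names case-insensitively; remaining numeric columns are treated as
    per-sample peak areas, anything else is ignored (logged).
    """
    raw = pd.read_csv(path)
    rename: dict[str, str] = {}
    for col in raw.columns:
        low = col.strip().lower()
        if low in _ID_NAMES:
            rename[col] = "feature_id"
        elif low in _MZ_NAMES:
            rename[col] = "mz"
        elif low in _RT_NAMES:
            rename[col] = "rt"
    frame = raw.rename(columns=rename)
    missing = {"feature_id", "mz", "rt"} - set(frame.columns)
    if missing:
        raise ValueError(f"quant CSV {path} missing columns: {sorted(missing)}")
    keep = ["feature_id", "mz", "rt"]
    for col in frame.columns:
        if col in keep:
            continue
        if pd.api.types.is_numeric_dtype(frame[col]):
            keep.append(col)
        else:
            logger.info("ignoring non-numeric quant column %r", col)
    frame = frame[keep].copy()
    frame["feature_id"] = frame["feature_id"].astype(str)
    return FeatureTable(frame)


def write_quant_csv(table: FeatureTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_range(s: Spectrum, mz_min: float, mz_max: float) -> Spectrum:
    """Max-min normalize intensities of peaks inside [mz_min, mz_max].

    I_norm = (I - Imin) / (Imax - Imin) over in-range peaks only; peaks
    outside the range keep ``normalized=None``.  When all in-range
    intensities are equal every in-range peak maps to 1.0 (keeps a lone
    diagnostic peak visible).
    """
    if mz_min >= mz_max:
        raise ValueError(f"invalid range: [{mz_min}, {mz_max}]")
    in_range = [p for p in s.peaks if mz_min <= p.mz <= mz_max]
    if not in_range:
        logger.warning(
            "spectrum %s: no peaks in normalization range [%g, %g]",
            s.feature_id, mz_min, mz_max,
        )
        return s
    lo = min(p.intensity for p in in_range)
    hi = max(p.intensity for p in in_range)
    span = hi - lo
    new_peaks = []
    for p in s.peaks:
        if mz_min <= p.mz <= mz_max:
            norm = 1.0 if span == 0 else (p.intensity - lo) / span
            new_peaks.append(replace(p, normalized=norm))
        else:
            new_peaks.append(replace(p, normalized=None))
    return replace(s, peaks=tuple(new_peaks))
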