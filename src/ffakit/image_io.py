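"""Decoding heterogeneous FFA image files into a uniform frame model.

Fundus fluorescein angiography (FFA) series arrive as loose collections of
TIFF/PNG/JPEG/BMP/DICOM files from different cameras. This module decodes
each file to a float image on [0, 1], recovers the acquisition time in
seconds post-injection (embedded metadata, filename pattern, sidecar CSV,
or burned-in ``mm:ss`` timestamp), and groups frames into time-sorted
per-(subject, eye, session) series.
"""
from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from . import glyphs
from .errors import (
    AmbiguousOcrError,
    DecodeError,
    DuplicateFrameError,
    EmptyStudyError,
    FormatError,
    MissingTimeError,
)

SUPPORTED_EXTENSIONS = {".tif", ".tiff", ".png", ".jpg", ".jpeg", ".bmp", ".dcm"}

#: hardware dialects whose sensors image fluorescein emission (~520 nm);
#: for these the green channel of an RGB export carries the signal.
FUNDUS_DIALECTS = {"spectralis", "topcon", "fundus"}

EYES = ("OS", "OD")
SESSIONS = ("AM", "PM")
SPECIES = ("mouse", "nhp", "human")

DEFAULT_FILENAME_PATTERN = (
    r"(?P<subject>[A-Za-z0-9-]+)_(?P<eye>OS|OD)_(?P<session>AM|PM)_t(?P<t>\d+(?:\.\d+)?)"
)


@dataclass
class Frame:
    """One grayscale FFA frame.

    pixels are float64 in [0, 1]; ``t_acq`` is seconds post-injection
    (None until recovered); ``dialect`` tags the acquisition hardware.
    """

    pixels: np.ndarray
    t_acq: float | None = None
    source_path: str = ""
    dialect: str = "generic"
    pixel_scale_um: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("Frame pixels must be 2-D")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"Frame must be at least 64x64, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Frame pixels must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("Frame pixels must lie in [0, 1]")
        if self.t_acq is not None and self.t_acq < 0:
            raise ValueError("t_acq must be non-negative")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, **updates) -> "Frame":
        return replace(self, pixels=pixels, **updates)


@dataclass(frozen=True)
class SeriesKey:
    """Identity of one imaging session: subject, eye, AM/PM, species."""

    subject_id: str
    eye: str
    session: str
    species: str

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")

    def label(self) -> str:
        return f"{self.subject_id}_{self.eye}_{self.session}"


@dataclass
class ImageSeries:
    """Time-ordered frames of one (subject, eye, session)."""

    key: SeriesKey
    frames: list[Frame]

    def finalize(self) -> "ImageSeries":
        """Sort by acquisition time and enforce the series invariants."""
        if any(f.t_acq is None for f in self.frames):
            raise MissingTimeError(
                f"series {self.key.label()} has frames without acquisition time"
            )
        self.frames.sort(key=lambda f: f.t_acq)
        if len(self.frames) < 2:
            raise ValueError(f"series {self.key.label()} needs >= 2 timed frames")
        times = [f.t_acq for f in self.frames]
        for a, b, fa, fb in zip(times, times[1:], self.frames, self.frames[1:]):
            if a == b:
                raise DuplicateFrameError(
                    f"duplicate t_acq={a} in {self.key.label()}: "
                    f"{fa.source_path} and {fb.source_path}"
                )
        return self

    @property
    def times(self) -> list[float]:
        return [f.t_acq for f in self.frames]


# ---------------------------------------------------------------------------
# decoding

def _normalize_bitdepth(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if arr.dtype == np.int16:  # DICOM often stores signed
        arr = arr.astype(float)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def _to_luminance(arr: np.ndarray, dialect: str) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        if dialect in FUNDUS_DIALECTS:
            return rgb[..., 1]
        return rgb.mean(axis=2)
    raise DecodeError(f"unsupported channel layout {arr.shape}")


def read_frame(path: str | Path, dialect: str = "generic") -> Frame:
    """Decode one image file into a :class:`Frame`.

    Pixels are normalized to [0, 1] by container bit depth; RGB inputs
    are reduced to the green channel for fundus dialects, otherwise to
    the channel mean. Embedded acquisition-time metadata (TIFF
    ImageDescription JSON, PNG text chunk, DICOM AcquisitionTime) is
    captured into ``frame.metadata`` but not interpreted here; see
    :func:`recover_time`.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise FormatError(f"unsupported extension {ext!r}: {path}")
    if not path.exists():
        raise DecodeError(f"no such file: {path}")
    meta: dict = {}
    try:
        if ext == ".dcm":
            import pydicom

            ds = pydicom.dcmread(str(path))
            raw = ds.pixel_array
            if "AcquisitionTime" in ds:
                meta["dicom_acquisition_time"] = str(ds.AcquisitionTime)
        elif ext in (".tif", ".tiff"):
            with tifffile.TiffFile(str(path)) as tf:
                raw = tf.asarray()
                desc = tf.pages[0].description
            if desc:
                try:
                    meta.update(json.loads(desc))
                except (json.JSONDecodeError, TypeError):
                    pass
        else:
            raw = iio.imread(path)
            try:
                props = iio.immeta(path)
            except Exception:
                props = {}
            if "acquisition_seconds" in props:
                meta["acquisition_seconds"] = props["acquisition_seconds"]
    except (FormatError, DecodeError):
        raise
    except Exception as exc:  # corrupt container
        raise DecodeError(f"could not decode {path}: {exc}") from exc
    gray = _to_luminance(_normalize_bitdepth(np.asarray(raw)), dialect)
    return Frame(pixels=gray, source_path=str(path), dialect=dialect, metadata=meta)


def write_frame_tiff(frame: Frame, path: str | Path) -> None:
    """Write a frame as 16-bit grayscale TIFF with its time in the description."""
    px = np.round(np.clip(frame.pixels, 0, 1) * 65535).astype(np.uint16)
    desc = {}
    if frame.t_acq is not None:
        desc["acquisition_seconds"] = frame.t_acq
    tifffile.imwrite(str(path), px, description=json.dumps(desc))


# ---------------------------------------------------------------------------
# acquisition-time recovery

def _parse_dicom_time(value: str) -> float:
    """DICOM TM 'HHMMSS.frac' -> seconds since midnight."""
    value = value.strip()
    h, m = int(value[0:2]), int(value[2:4])
    s = float(value[4:]) if len(value) > 4 else 0.0
    return h * 3600 + m * 60 + s


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def decode_timestamp_overlay(
    frame: Frame,
    roi: tuple[int, int, int, int],
    glyph_atlas: Mapping[str, np.ndarray] | None = None,
    min_correlation: float = 0.7,
    ambiguity_margin: float = 0.02,
) -> float:
    """Decode a burned-in ``mm:ss`` timestamp by template matching.

    roi = (row0, col0, row1, col1) bounds the overlay. Each character
    cell is matched by normalized cross-correlation against the packaged
    glyph atlas; the best match must exceed ``min_correlation`` and beat
    the runner-up by ``ambiguity_margin``.
    """
    if glyph_atlas is None:
        glyph_atlas = glyphs.atlas()
    r0, c0, r1, c1 = roi
    patch = frame.pixels[r0:r1, c0:c1]
    ys, xs = np.nonzero(patch > 0.5 * patch.max()) if patch.max() > 0 else ((), ())
    if len(ys) == 0:
        raise MissingTimeError(f"no overlay pixels in ROI of {frame.source_path}")
    patch = patch[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    scale = max(1, round(patch.shape[0] / glyphs.GLYPH_H))
    # block-average back to atlas resolution
    h = glyphs.GLYPH_H * scale
    n_chars = round((patch.shape[1] / scale + 1) / glyphs.GLYPH_PITCH)
    w = (n_chars * glyphs.GLYPH_PITCH - 1) * scale
    padded = np.zeros((h, w))
    padded[:min(h, patch.shape[0]), :min(w, patch.shape[1])] = \
        patch[:h, :w]
    small = padded.reshape(glyphs.GLYPH_H, scale, -1, scale).mean(axis=(1, 3))
    text = []
    for i in range(n_chars):
        cell = small[:, i * glyphs.GLYPH_PITCH:i * glyphs.GLYPH_PITCH + glyphs.GLYPH_W]
        if cell.shape[1] < glyphs.GLYPH_W:
            cell = np.pad(cell, ((0, 0), (0, glyphs.GLYPH_W - cell.shape[1])))
        scores = {ch: _ncc(cell, tmpl) for ch, tmpl in glyph_atlas.items()}
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        (best_ch, best), (_, second) = ranked[0], ranked[1]
        if best < min_correlation:
            raise MissingTimeError(
                f"overlay glyph {i} unmatched (best corr {best:.3f}) in {frame.source_path}"
            )
        if best - second < ambiguity_margin:
            raise AmbiguousOcrError(
                f"overlay glyph {i} ambiguous (corr gap {best - second:.4f}) "
                f"in {frame.source_path}"
            )
        text.append(best_ch)
    m = re.fullmatch(r"(\d+):(\d{2})", "".join(text))
    if not m:
        raise MissingTimeError(
            f"overlay {''.join(text)!r} is not mm:ss in {frame.source_path}"
        )
    return int(m.group(1)) * 60.0 + int(m.group(2))


@dataclass
class TimeRecoveryConfig:
    """Ordered sources for acquisition-time recovery.

    ``sources`` is tried in order; default metadata -> filename ->
    sidecar -> overlay-ocr.
    """

    sources: Sequence[str] = ("metadata", "filename", "sidecar", "overlay-ocr")
    filename_pattern: str = r"t(?P<t>\d+(?:\.\d+)?)"
    sidecar: Mapping[str, float] | None = None
    injection_time_s: float | None = None  # seconds since midnight (DICOM)
    ocr_roi: tuple[int, int, int, int] | None = None


def load_sidecar(path: str | Path) -> dict[str, float]:
    """Read a ``filename,seconds`` CSV sidecar timing table."""
    table: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["filename"]] = float(row["seconds"])
    return table


def recover_time(frame: Frame, config: TimeRecoveryConfig) -> float:
    """Return the first acquisition time recovered from the configured sources."""
    if not config.sources:
        raise MissingTimeError("no time sources configured")
    for source in config.sources:
        t = _try_source(frame, source, config)
        if t is not None:
            return float(t)
    raise MissingTimeError(f"no time source yielded a time for {frame.source_path}")


def _try_source(frame: Frame, source: str, config: TimeRecoveryConfig) -> float | None:
    if source == "metadata":
        if "acquisition_seconds" in frame.metadata:
            return float(frame.metadata["acquisition_seconds"])
        if "dicom_acquisition_time" in frame.metadata:
            if config.injection_time_s is None:
                return None  # cannot anchor to injection; fall through
            t = _parse_dicom_time(frame.metadata["dicom_acquisition_time"])
            dt = t - config.injection_time_s
            return dt if dt >= 0 else None
        return None
    if source == "filename":
        m = re.search(config.filename_pattern, Path(frame.source_path).name)
        return float(m.group("t")) if m else None
    if source == "sidecar":
        if config.sidecar is None:
            return None
        return config.sidecar.get(Path(frame.source_path).name)
    if source == "overlay-ocr":
        if config.ocr_roi is None:
            return None
        try:
            return decode_timestamp_overlay(frame, config.ocr_roi)
        except MissingTimeError:
            return None
    raise ValueError(f"unknown time source {source!r}")


# ---------------------------------------------------------------------------
# study ingestion

def _discover_files(root: Path) -> list[Path]:
    files = [p for p in sorted(root.rglob("*"))
             if p.is_file() and p.suffix.lower() in SUPPORTED_EXTENSIONS]
    return files


def _key_for(path: Path, species: str, pattern: str) -> SeriesKey | None:
    m = re.search(pattern, path.name)
    if not m:
        return None
    return SeriesKey(
        subject_id=m.group("subject"),
        eye=m.group("eye"),
        session=m.group("session"),
        species=species,
    )


def ingest_study(
    root: str | Path,
    species: str,
    dialect: str = "generic",
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
    time_config: TimeRecoveryConfig | None = None,
    manifest_path: str | Path | None = None,
) -> list[ImageSeries]:
    """Scan *root* for FFA frames and assemble per-session series.

    Frames are keyed by a named-group filename pattern (subject, eye,
    session). Sidecar timing tables named ``timing.csv`` are picked up
    per directory. Series with fewer than two timed frames are reported
    in the manifest and dropped. A JSON ingest manifest recording every
    file's disposition is written next to *root* (or to
    ``manifest_path``).
    """
    root = Path(root)
    files = _discover_files(root)
    if not files:
        raise EmptyStudyError(f"no ingestible images under {root}")
    if time_config is None:
        time_config = TimeRecoveryConfig()

    sidecars: dict[Path, Mapping[str, float]] = {}
    groups: dict[SeriesKey, list[Frame]] = {}
    dispositions: list[dict] = []
    for path in files:
        entry = {"path": str(path), "status": "ingested", "reason": ""}
        key = _key_for(path, species, filename_pattern)
        if key is None:
            entry.update(status="skipped", reason="filename does not match pattern")
            dispositions.append(entry)
            continue
        try:
            frame = read_frame(path, dialect=dialect)
        except (DecodeError, FormatError) as exc:
            entry.update(status="skipped", reason=str(exc))
            dispositions.append(entry)
            continue
        cfg = time_config
        sidecar_file = path.parent / "timing.csv"
        if cfg.sidecar is None and sidecar_file.exists():
            if path.parent not in sidecars:
                sidecars[path.parent] = load_sidecar(sidecar_file)
            cfg = replace(cfg, sidecar=sidecars[path.parent])
        try:
            frame.t_acq = recover_time(frame, cfg)
        except MissingTimeError as exc:
            entry.update(status="skipped", reason=f"no acquisition time: {exc}")
            dispositions.append(entry)
            continue
        groups.setdefault(key, []).append(frame)
        dispositions.append(entry)

    series_list: list[ImageSeries] = []
    dropped: list[dict] = []
    for key in sorted(groups, key=lambda k: (k.subject_id, k.eye, k.session)):
        frames = groups[key]
        if len(frames) < 2:
            dropped.append({"series": key.label(), "n_frames": len(frames),
                            "reason": "fewer than 2 timed frames"})
            continue
        series_list.append(ImageSeries(key=key, frames=frames).finalize())

    n_skipped = sum(1 for d in dispositions if d["status"] == "skipped")
    manifest = {
        "root": str(root),
        "species": species,
        "n_discovered": len(files),
        "n_ingested": len(files) - n_skipped,
        "n_skipped": n_skipped,
        "files": dispositions,
        "dropped_series": dropped,
        "series": [
            {"key": s.key.label(), "n_frames": len(s.frames), "times": s.times}
            for s in series_list
        ],
    }
    if manifest_path is None:
        manifest_path = root / "ingest_manifest.json"
    Path(manifest_path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return series_list
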