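"""TPS landmark file I/O, image scaling, and photo/landmark quality filtering.

The TPS dialect handled here is the tpsDig/tpsUtil flavour: each record is
an ``LM=<n>`` line followed by ``n`` whitespace-separated ``x y`` coordinate
rows and optional ``IMAGE=``, ``ID=`` and ``SCALE=`` metadata lines.  Keys
are case-insensitive and blank lines are ignored.  Coordinates are stored in
image convention (y increasing downward) and converted to mathematical
convention (y up) on load; generalized Procrustes analysis is invariant to
this choice, but the convention is fixed so distances and templates agree.

Quality ranks follow the field protocol for photographic landmarking: each
landmark and each photo carries a rank in {1, 2, 3}, 1 = poor, 2 = average,
3 = excellent; the filter retains specimens whose photo rank and all
landmark ranks meet a threshold (default 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: number of landmarks the downstream analysis requires per specimen
N_LANDMARKS = 21

VALID_RANKS = (1, 2, 3)


class TPSParseError(ValueError):
    """Raised for malformed TPS records; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks plus acquisition metadata.

    ``coords`` is an ``(n, 2)`` float array in image units until
    :func:`apply_scale` converts it to mm (``scale`` mm per image unit).
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    image: str | None = None
    landmark_quality: tuple[int, ...] | None = None
    photo_quality: int | None = None
    year: int | None = None
    scale_applied: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if self.scale is not None and not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if self.landmark_quality is not None:
            self.landmark_quality = tuple(int(r) for r in self.landmark_quality)
            bad = [r for r in self.landmark_quality if r not in VALID_RANKS]
            if bad:
                raise ValueError(f"landmark ranks must be in {VALID_RANKS}, got {bad}")
            if len(self.landmark_quality) != len(self.coords):
                raise ValueError("one quality rank per landmark required")
        if self.photo_quality is not None and self.photo_quality not in VALID_RANKS:
            raise ValueError(f"photo rank must be in {VALID_RANKS}")

    @property
    def n_landmarks(self) -> int:
        return len(self.coords)

    @property
    def is_valid(self) -> bool:
        """True when the configuration has the full landmark set."""
        return self.n_landmarks == N_LANDMARKS


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS file into landmark configurations, preserving record order.

    Records whose landmark count differs from 21 are loaded but flagged
    invalid (``config.is_valid``); genuinely malformed input (bad coordinate
    rows, LM count disagreeing with the rows present) raises
    :class:`TPSParseError` with a line number.

    Loaded y coordinates are negated (image convention, y down, to math
    convention, y up).
    """
    path = Path(path)
    records: list[LandmarkConfiguration] = []
    lm_expected: int | None = None
    coords: list[tuple[float, float]] = []
    meta: dict[str, str] = {}
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal lm_expected, coords, meta
        if lm_expected is None:
            return
        if len(coords) != lm_expected:
            raise TPSParseError(
                f"record declares LM={lm_expected} but has {len(coords)} "
                "coordinate rows",
                start_line,
            )
        arr = np.asarray(coords, dtype=float)
        arr[:, 1] *= -1.0  # image y-down -> math y-up
        scale = float(meta["SCALE"]) if "SCALE" in meta else None
        records.append(
            LandmarkConfiguration(
                specimen_id=meta.get("ID", f"record_{len(records)}"),
                coords=arr,
                scale=scale,
                image=meta.get("IMAGE"),
            )
        )
        lm_expected, coords, meta = None, [], {}

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            if sep and key.strip().upper() in {"LM", "IMAGE", "ID", "SCALE"}:
                key = key.strip().upper()
                value = value.strip()
                if key == "LM":
                    flush(line_no)
                    try:
                        lm_expected = int(value)
                    except ValueError:
                        raise TPSParseError(f"bad LM count {value!r}", line_no) from None
                    start_line = line_no
                elif lm_expected is None:
                    raise TPSParseError(f"{key}= before any LM= record", line_no)
                else:
                    meta[key] = value
                continue
            if lm_expected is None:
                raise TPSParseError("coordinate row outside any record", line_no)
            parts = line.split()
            if len(parts) != 2:
                raise TPSParseError(f"malformed coordinate row {line!r}", line_no)
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise TPSParseError(f"malformed coordinate row {line!r}", line_no) from None
    flush(line_no=-1)
    n_invalid = sum(not c.is_valid for c in records)
    logger.info("read %d TPS records from %s (%d flagged invalid)", len(records), path, n_invalid)
    return records


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations in the TPS dialect read by :func:`read_tps`.

    Coordinates are written back in image convention (y negated) at full
    ``repr`` precision so a read/write round trip is lossless.
    """
    path = Path(path)
    lines: list[str] = []
    for cfg in configs:
        lines.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            lines.append(f"{float(x)!r} {float(-y)!r}")
        if cfg.image is not None:
            lines.append(f"IMAGE={cfg.image}")
        lines.append(f"ID={cfg.specimen_id}")
        if cfg.scale is not None:
            lines.append(f"SCALE={cfg.scale!r}")
    path.write_text("\n".join(lines) + "\n")


class ScaleError(ValueError):
    pass


def apply_scale(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Convert a configuration from image units to mm using its photo scale.

    Multiplies coordinates by ``scale`` (mm per image unit) and consumes the
    scale (set to 1).  Applying twice is a state error, not a silent no-op.
    """
    if config.scale_applied:
        raise ScaleError(f"{config.specimen_id}: scale already applied")
    if config.scale is None:
        raise ScaleError(f"{config.specimen_id}: no SCALE present; cannot convert to mm")
    return replace(
        config,
        coords=config.coords * config.scale,
        scale=1.0,
        scale_applied=True,
    )


@dataclass
class Exclusion:
    specimen_id: str
    reason: str


def quality_filter(
    configs: Sequence[LandmarkConfiguration],
    min_photo_rank: int = 2,
    min_landmark_rank: int = 2,
) -> tuple[list[LandmarkConfiguration], list[Exclusion]]:
    """Partition specimens by photo/landmark quality ranks.

    A specimen is retained when its photo rank >= ``min_photo_rank`` and all
    its landmark ranks >= ``min_landmark_rank``.  Specimens without ranks
    pass with a warning (deposited datasets may not carry ranks).  The
    returned exclusion log names the failing criterion per specimen, and
    retained + excluded always partition the input.
    """
    retained: list[LandmarkConfiguration] = []
    excluded: list[Exclusion] = []
    n_unranked = 0
    for cfg in configs:
        if cfg.photo_quality is None and cfg.landmark_quality is None:
            n_unranked += 1
            retained.append(cfg)
            continue
        if cfg.photo_quality is not None and cfg.photo_quality < min_photo_rank:
            excluded.append(
                Exclusion(cfg.specimen_id, f"photo rank {cfg.photo_quality} < {min_photo_rank}")
            )
            continue
        if cfg.landmark_quality is not None:
            low = [
                (i, r) for i, r in enumerate(cfg.landmark_quality) if r < min_landmark_rank
            ]
            if low:
                i, r = low[0]
                excluded.append(
                    Exclusion(
                        cfg.specimen_id,
                        f"landmark {i} rank {r} < {min_landmark_rank}"
                        + (f" (+{len(low) - 1} more)" if len(low) > 1 else ""),
                    )
                )
                continue
        retained.append(cfg)
    if n_unranked:
        logger.warning(
            "quality filter: %d specimen(s) without ranks retained unfiltered",
            n_unranked,
        )
    logger.info(
        "quality filter: %d retained, %d excluded of %d",
        len(retained), len(excluded), len(configs),
    )
    return retained, excluded
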