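"""Cell trajectories, moving-direction annotation, and motility statistics.

A migrating cell is annotated, at an anchor frame, with one of four
quadrant labels (upper right / upper left / lower left / lower right)
describing the displacement vector at the first later time its *net*
displacement exceeds one cell diameter (18 µm for NIH/3T3 fibroblasts).
Coordinates follow the image convention: x grows rightward, y grows
downward, so a negative Δy means the cell moved *up* in the displayed
image.  The crossing search runs on a fixed evaluation grid (15-min
spacing by default) regardless of the acquisition interval.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_DIAMETER_UM = 18.0
DEFAULT_EVAL_INTERVAL_MIN = 15.0


class MissingFrameError(KeyError):
    """A requested frame index is not present in the trajectory."""


class InvalidIntervalError(ValueError):
    """Evaluation interval is not a multiple of the acquisition interval."""


class UndefinedMotilityError(ValueError):
    """Speed/directionality requested for a cell that never crossed."""


class DirectionLabel(enum.IntEnum):
    """Quadrant of the displacement vector in image coordinates.

    ``Δy <= 0`` (y-down) means the cell moved toward the *upper* half of
    the image.  The four predicates partition every non-zero (Δx, Δy).
    """

    UPPER_RIGHT = 0
    UPPER_LEFT = 1
    LOWER_LEFT = 2
    LOWER_RIGHT = 3


def classify_displacement(dx_um: float, dy_um: float) -> DirectionLabel:
    """Map a displacement vector to its quadrant label.

    Boundary conventions: Δx ≥ 0 counts as "right", Δy ≤ 0 counts as
    "upper"; (0, 0) therefore maps to upper right, but callers only
    reach this function with displacements longer than one diameter.
    """
    if dy_um <= 0:
        return DirectionLabel.UPPER_RIGHT if dx_um >= 0 else DirectionLabel.UPPER_LEFT
    return DirectionLabel.LOWER_RIGHT if dx_um >= 0 else DirectionLabel.LOWER_LEFT


@dataclass(frozen=True)
class TrackPoint:
    frame_index: int
    time_min: float
    x_um: float
    y_um: float


@dataclass
class Trajectory:
    """Time-ordered positions of one tracked cell, in micrometers."""

    cell_id: int
    frames: np.ndarray        # (T,) int, strictly increasing
    x_um: np.ndarray          # (T,) float
    y_um: np.ndarray          # (T,) float
    frame_interval_min: float
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x_um = np.asarray(self.x_um, dtype=np.float64)
        self.y_um = np.asarray(self.y_um, dtype=np.float64)
        if self.frames.size < 1:
            raise ValueError("trajectory needs at least one point")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if not (self.frames.size == self.x_um.size == self.y_um.size):
            raise ValueError("frames/x/y length mismatch")

    def __len__(self) -> int:
        return int(self.frames.size)

    def __iter__(self) -> Iterator[TrackPoint]:
        for f, x, y in zip(self.frames, self.x_um, self.y_um):
            yield TrackPoint(int(f), float(f) * self.frame_interval_min, float(x), float(y))

    def index_of(self, frame: int) -> int:
        idx = np.searchsorted(self.frames, frame)
        if idx >= self.frames.size or self.frames[idx] != frame:
            raise MissingFrameError(f"frame {frame} not in trajectory of cell {self.cell_id}")
        return int(idx)

    def position(self, frame: int) -> tuple[float, float]:
        i = self.index_of(frame)
        return float(self.x_um[i]), float(self.y_um[i])


@dataclass(frozen=True)
class AnnotatedSample:
    """One (cell, anchor frame) with its direction label.

    ``delta_t_min`` is the time from the anchor to the first evaluation
    point whose net displacement exceeds the diameter threshold, and
    ``(dx_um, dy_um)`` is the displacement vector at that crossing.
    """

    cell_id: int
    frame_index: int
    label: DirectionLabel
    delta_t_min: float
    dx_um: float
    dy_um: float

    @property
    def net_displacement_um(self) -> float:
        return float(np.hypot(self.dx_um, self.dy_um))


def net_displacement(traj: Trajectory, t0: int, t: int) -> float:
    """Euclidean distance (µm) between the positions at frames t0 and t."""
    if t0 > t:
        raise ValueError("t0 must not exceed t")
    x0, y0 = traj.position(t0)
    x1, y1 = traj.position(t)
    return float(np.hypot(x1 - x0, y1 - y0))


def resample_interval(
    traj: Trajectory, eval_interval_min: float = DEFAULT_EVAL_INTERVAL_MIN
) -> Trajectory:
    """Subsample a trajectory onto the evaluation grid.

    Keeps every (eval/acquisition)-th point starting from the first; a
    5-min acquisition evaluated on a 15-min grid keeps every 3rd point.
    """
    ratio = eval_interval_min / traj.frame_interval_min
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-9:
        raise InvalidIntervalError(
            f"evaluation interval {eval_interval_min} min is not an integer "
            f"multiple of the acquisition interval {traj.frame_interval_min} min"
        )
    if step == 1:
        return traj
    return Trajectory(
        cell_id=traj.cell_id,
        frames=traj.frames[::step],
        x_um=traj.x_um[::step],
        y_um=traj.y_um[::step],
        frame_interval_min=eval_interval_min,
        pixel_size_um=traj.pixel_size_um,
    )


def annotate_direction(
    traj: Trajectory, t0: int, diameter_um: float = DEFAULT_DIAMETER_UM
) -> AnnotatedSample | None:
    """Annotate the moving direction at anchor frame ``t0``.

    Scans frames after ``t0`` in order and stops at the first whose net
    displacement from the anchor strictly exceeds ``diameter_um``; the
    quadrant of the displacement vector at that crossing is the label.
    ``traj`` must already be on the evaluation grid (see
    :func:`resample_interval`).  Returns ``None`` when the track ends
    before any crossing (the cell is excluded from the dataset).
    """
    i0 = traj.index_of(t0)
    x0, y0 = traj.x_um[i0], traj.y_um[i0]
    dx = traj.x_um[i0 + 1 :] - x0
    dy = traj.y_um[i0 + 1 :] - y0
    net = np.hypot(dx, dy)
    crossed = np.nonzero(net > diameter_um)[0]
    if crossed.size == 0:
        return None
    j = int(crossed[0])
    frame_at_cross = int(traj.frames[i0 + 1 + j])
    delta_t = (frame_at_cross - t0) * traj.frame_interval_min
    return AnnotatedSample(
        cell_id=traj.cell_id,
        frame_index=int(t0),
        label=classify_displacement(float(dx[j]), float(dy[j])),
        delta_t_min=float(delta_t),
        dx_um=float(dx[j]),
        dy_um=float(dy[j]),
    )


def annotate_all(
    traj: Trajectory,
    diameter_um: float = DEFAULT_DIAMETER_UM,
    eval_interval_min: float = DEFAULT_EVAL_INTERVAL_MIN,
) -> list[AnnotatedSample]:
    """Annotate every anchor frame of one cell on the evaluation grid.

    Every frame up to the last that still crosses becomes an annotation
    target; anchors whose remaining track never exceeds the threshold
    are skipped.
    """
    rtraj = resample_interval(traj, eval_interval_min)
    out = []
    for f in rtraj.frames[:-1]:
        s = annotate_direction(rtraj, int(f), diameter_um)
        if s is not None:
            out.append(s)
    return out


def _steps_to_crossing(traj: Trajectory, t0: int, diameter_um: float) -> np.ndarray:
    """Consecutive step lengths (µm) from the anchor to the crossing frame."""
    sample = annotate_direction(traj, t0, diameter_um)
    if sample is None:
        raise UndefinedMotilityError(
            f"cell {traj.cell_id} never exceeds {diameter_um} µm after frame {t0}"
        )
    i0 = traj.index_of(t0)
    i1 = traj.index_of(t0 + int(round(sample.delta_t_min / traj.frame_interval_min)))
    dx = np.diff(traj.x_um[i0 : i1 + 1])
    dy = np.diff(traj.y_um[i0 : i1 + 1])
    return np.hypot(dx, dy)


def average_speed(
    traj: Trajectory, t0: int, diameter_um: float = DEFAULT_DIAMETER_UM
) -> float:
    """Average speed v = ΣΔd / Δt (µm/min) from anchor to crossing."""
    steps = _steps_to_crossing(traj, t0, diameter_um)
    sample = annotate_direction(traj, t0, diameter_um)
    assert sample is not None
    return float(steps.sum() / sample.delta_t_min)


def directionality(
    traj: Trajectory, t0: int, diameter_um: float = DEFAULT_DIAMETER_UM
) -> float:
    """Directionality k = Δr / ΣΔd, in (0, 1]; 1 for straight paths."""
    steps = _steps_to_crossing(traj, t0, diameter_um)
    sample = annotate_direction(traj, t0, diameter_um)
    assert sample is not None
    total = float(steps.sum())
    if total <= 0:
        raise UndefinedMotilityError("total path length is zero")
    return sample.net_displacement_um / total


# ---------------------------------------------------------------------------
# CSV / JSON interchange

TRACKS_COLUMNS = ["cell_id", "frame", "x_px", "y_px"]
ANNOTATION_COLUMNS = ["cell_id", "frame", "label", "delta_t_min", "dx_um", "dy_um"]


def trajectories_to_frame(trajs: Sequence[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into the tracks CSV dialect (pixel units)."""
    rows = []
    for tr in trajs:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": tr.frames,
                    "x_px": tr.x_um / tr.pixel_size_um,
                    "y_px": tr.y_um / tr.pixel_size_um,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TRACKS_COLUMNS)


def write_tracks(
    trajs: Sequence[Trajectory],
    csv_path: str | Path,
    meta_path: str | Path | None = None,
) -> None:
    trajectories_to_frame(trajs).to_csv(csv_path, index=False)
    if meta_path is not None and trajs:
        meta = {
            "pixel_size_um": trajs[0].pixel_size_um,
            "frame_interval_min": trajs[0].frame_interval_min,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_tracks(
    csv_path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
    meta_path: str | Path | None = None,
) -> list[Trajectory]:
    """Load tracks from CSV (`cell_id,frame,x_px,y_px`) plus metadata."""
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
        pixel_size_um = meta["pixel_size_um"]
        frame_interval_min = meta["frame_interval_min"]
    if pixel_size_um is None or frame_interval_min is None:
        raise ValueError("pixel_size_um and frame_interval_min (or meta_path) are required")
    df = pd.read_csv(csv_path)
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                cell_id=int(cid),
                frames=grp["frame"].to_numpy(),
                x_um=grp["x_px"].to_numpy() * pixel_size_um,
                y_um=grp["y_px"].to_numpy() * pixel_size_um,
                frame_interval_min=frame_interval_min,
                pixel_size_um=pixel_size_um,
            )
        )
    return out


def annotations_to_frame(samples: Sequence[AnnotatedSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": s.cell_id,
                "frame": s.frame_index,
                "label": int(s.label),
                "delta_t_min": s.delta_t_min,
                "dx_um": s.dx_um,
                "dy_um": s.dy_um,
            }
            for s in samples
        ],
        columns=ANNOTATION_COLUMNS,
    )


def write_annotations(samples: Sequence[AnnotatedSample], csv_path: str | Path) -> None:
    annotations_to_frame(samples).to_csv(csv_path, index=False)


def read_annotations(csv_path: str | Path) -> list[AnnotatedSample]:
    df = pd.read_csv(csv_path)
    return [
        AnnotatedSample(
            cell_id=int(r.cell_id),
            frame_index=int(r.frame),
            label=DirectionLabel(int(r.label)),
            delta_t_min=float(r.delta_t_min),
            dx_um=float(r.dx_um),
            dy_um=float(r.dy_um),
        )
        for r in df.itertuples()
    ]
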