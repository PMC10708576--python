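"""MOTChallenge CSV and movement-CSV readers/writers.

MOT files are comma-separated with columns
``frame, id, bb_left, bb_top, bb_width, bb_height, conf, x, y, z``
(9 or 10 columns accepted; the trailing world-coordinate columns are -1
placeholders).  File frame indices are 1-based by format convention;
in-memory frames are 0-based — the conversion happens here and nowhere
else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .geometry import BBox, Detection
from .movement import MovementSeries
from .tracker import Track

__all__ = ["MotRecord", "read_mot", "write_mot", "tracks_to_records",
           "records_to_detections", "write_movement_csv"]


@dataclass(frozen=True)
class MotRecord:
    """One MOT CSV line, frame index already converted to 0-based."""

    frame: int  # 0-based in memory
    id: int  # -1 for raw detections
    box: BBox
    conf: float


def read_mot(path: str | Path) -> dict[int, list[MotRecord]]:
    """Parse a det.txt/gt.txt file into per-frame record lists.

    Malformed lines raise with their 1-based line number.
    """
    out: dict[int, list[MotRecord]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) not in (7, 9, 10):
                raise ValueError(
                    f"{path}:{lineno}: expected 7, 9 or 10 columns, got {len(row)}"
                )
            try:
                frame = int(float(row[0]))
                tid = int(float(row[1]))
                x, y, w, h = (float(v) for v in row[2:6])
                conf = float(row[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if frame < 1:
                raise ValueError(f"{path}:{lineno}: frame index must be >= 1")
            rec = MotRecord(frame=frame - 1, id=tid, box=BBox(x, y, w, h), conf=conf)
            out.setdefault(rec.frame, []).append(rec)
    return out


def write_mot(records: list[MotRecord], path: str | Path) -> None:
    """Write records sorted by (frame, id); frame converted to 1-based."""
    recs = sorted(records, key=lambda r: (r.frame, r.id))
    with open(path, "w", newline="") as fh:
        for r in recs:
            b = r.box
            fh.write(
                f"{r.frame + 1},{r.id},{b.x:.3f},{b.y:.3f},{b.w:.3f},{b.h:.3f},"
                f"{r.conf:.4f},-1,-1,-1\n"
            )


def tracks_to_records(tracks: list[Track]) -> list[MotRecord]:
    return [
        MotRecord(frame=f, id=t.track_id, box=b, conf=1.0)
        for t in tracks
        for f, b in sorted(t.boxes.items())
    ]


def records_to_detections(per_frame: dict[int, list[MotRecord]]) -> dict[int, list[Detection]]:
    return {
        f: [Detection(box=r.box, score=r.conf, frame=f) for r in recs]
        for f, recs in per_frame.items()
    }


def write_movement_csv(series: MovementSeries, path: str | Path) -> None:
    """Movement CSV: track_id, frame, method, movement_px, cumulative_px."""
    with open(path, "w", newline="") as fh:
        fh.write("track_id,frame,method,movement_px,cumulative_px\n")
        for tid in series.track_ids():
            for rec, cum in zip(series.records[tid], series.cumulative[tid]):
                fh.write(f"{tid},{rec.frame},{rec.method},{rec.value:.4f},{cum:.4f}\n")
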