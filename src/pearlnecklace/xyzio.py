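"""Extended-XYZ trajectory reader/writer.

Frame layout::

    <N>
    time=<tau> seed=<int or none>
    <tag> <x> <y> <z> <charge>
    ...

with tag C/N/P for neutral/negative/positive beads and coordinates printed
at fixed 6-decimal precision, so write -> read -> write round-trips
bit-exactly on the text representation.
"""

from __future__ import annotations

import numpy as np

from .simulator import Conformation, Trajectory

__all__ = ["write_xyz", "read_xyz", "XYZParseError"]

_TAGS = {0: "C", -1: "N", 1: "P"}


class XYZParseError(ValueError):
    """Malformed extended-XYZ input; message names the offending line."""


def _tag(z: int) -> str:
    if z > 0:
        return "P"
    if z < 0:
        return "N"
    return "C"


def write_xyz(traj: Trajectory, path) -> None:
    """Write all frames of a trajectory to extended XYZ."""
    seed = traj.metadata.get("seed")
    with open(path, "w") as fh:
        for i in range(len(traj)):
            _write_frame(fh, traj.positions[i], traj.charges, traj.times[i], seed)


def write_xyz_frame(conf: Conformation, path, mode: str = "w", seed=None) -> None:
    with open(path, mode) as fh:
        _write_frame(fh, conf.positions, conf.charges, conf.time, seed)


def _write_frame(fh, positions, charges, time, seed) -> None:
    fh.write(f"{positions.shape[0]}\n")
    fh.write(f"time={time:.6f} seed={'none' if seed is None else int(seed)}\n")
    for (x, y, z), q in zip(positions, charges):
        fh.write(f"{_tag(int(q))} {x:.6f} {y:.6f} {z:.6f} {int(q)}\n")


def read_xyz(path, metadata: dict | None = None) -> Trajectory:
    """Read an extended-XYZ trajectory; parse errors name file line numbers."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames_pos = []
    frames_t = []
    charges = None
    seed = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if lines[i].strip() == "":
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise XYZParseError(
                f"line {i + 1}: expected bead count for frame {frame_no}, "
                f"got {lines[i]!r}"
            ) from err
        if i + 1 >= len(lines):
            raise XYZParseError(f"line {i + 2}: missing comment line of frame {frame_no}")
        comment = lines[i + 1]
        t = None
        for token in comment.split():
            if token.startswith("time="):
                t = float(token[5:])
            elif token.startswith("seed="):
                v = token[5:]
                seed = None if v == "none" else int(v)
        if t is None:
            raise XYZParseError(f"line {i + 2}: frame {frame_no} comment lacks time=")
        if i + 2 + n > len(lines):
            raise XYZParseError(
                f"line {len(lines)}: truncated frame {frame_no} "
                f"(expected {n} atom lines)"
            )
        pos = np.empty((n, 3))
        z = np.empty(n, dtype=np.int64)
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) != 5:
                raise XYZParseError(
                    f"line {i + 3 + k}: expected '<tag> x y z charge', "
                    f"got {lines[i + 2 + k]!r}"
                )
            try:
                pos[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
                z[k] = int(parts[4])
            except ValueError as err:
                raise XYZParseError(f"line {i + 3 + k}: bad numeric field") from err
        if charges is None:
            charges = z
        elif not np.array_equal(charges, z) or n != frames_pos[0].shape[0]:
            raise XYZParseError(
                f"line {i + 1}: frame {frame_no} bead count/charges differ "
                f"from frame 1"
            )
        frames_pos.append(pos)
        frames_t.append(t)
        i += 2 + n
    if not frames_pos:
        raise XYZParseError("no frames found")
    md = dict(metadata or {})
    if seed is not None:
        md.setdefault("seed", seed)
    return Trajectory(
        positions=np.stack(frames_pos), times=np.array(frames_t),
        charges=charges, metadata=md,
    )
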