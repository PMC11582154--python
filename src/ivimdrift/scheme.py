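"""Acquisition schemes for drift-robust IVIM protocols.

An IVIM examination consists of one or more scans, each an ordered list of
acquisitions with a diffusion weighting b (s/mm²), an encoding direction
(unit 3-vector, or None for b = 0), a flow-encoding factor c (s/mm; 0 for
flow-compensated waveforms and for b = 0), and an acquisition time t
(seconds from scan start).

The drift-robust ("mixed") looping distributes every b-value and encoding
direction over the scan time by incrementing the b index and the direction
index simultaneously; the drift-sensitive ("ordered") looping sorts by
ascending b with directions in direct succession.  Schemes round-trip to
FSL-style bval/bvec text files with an optional cval sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Acquisition",
    "AcquisitionScheme",
    "CANONICAL_DIRECTIONS",
    "build_mixed_scheme",
    "low_high_order",
    "ordered_scheme",
    "ordering_permutation",
    "protocol_preset",
    "ballistic_flow_encoding",
    "read_scheme",
    "write_scheme",
    "validate_scheme",
]

#: Canonical encoding-direction succession: x, y, z, -x, -y, -z.
CANONICAL_DIRECTIONS: tuple[tuple[float, float, float], ...] = (
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (-1.0, 0.0, 0.0),
    (0.0, -1.0, 0.0),
    (0.0, 0.0, -1.0),
)

#: sIVIM b-value sequence implementing 2/3/1 repetitions of 0/200/800 s/mm².
SIVIM_B_SEQUENCE: tuple[float, ...] = (0.0, 200.0, 800.0, 200.0, 0.0, 200.0)
DIFFUSIVE_B_VALUES: tuple[float, ...] = (0, 5, 10, 20, 30, 50, 100, 200, 500, 800)
BALLISTIC_B_VALUES: tuple[float, ...] = (0, 5, 10, 20, 30, 100, 200)

#: Seconds per volume reproducing the preset scan durations (4.5/7.5/10.5 min).
DEFAULT_VOLUME_INTERVAL = 7.5

_DIR_TOL = 1e-6


@dataclass(frozen=True)
class Acquisition:
    """One volume of a dMRI scan."""

    n: int
    b: float
    direction: tuple[float, float, float] | None
    c: float
    t: float
    scan_id: str

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"negative b-value {self.b}")
        if self.c < 0:
            raise ValueError(f"negative flow-encoding factor {self.c}")
        if self.b > 0:
            if self.direction is None:
                raise ValueError("b > 0 acquisition requires a direction")
            norm = math.sqrt(sum(d * d for d in self.direction))
            if abs(norm - 1.0) > _DIR_TOL:
                raise ValueError(f"direction {self.direction} is not unit norm")


@dataclass
class AcquisitionScheme:
    """Ordered list of acquisitions with a fixed per-volume interval."""

    acquisitions: list[Acquisition]
    volume_interval: float = DEFAULT_VOLUME_INTERVAL

    def __len__(self) -> int:
        return len(self.acquisitions)

    @property
    def duration(self) -> float:
        return self.volume_interval * len(self.acquisitions)

    @property
    def b(self) -> np.ndarray:
        return np.array([a.b for a in self.acquisitions], dtype=float)

    @property
    def c(self) -> np.ndarray:
        return np.array([a.c for a in self.acquisitions], dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.array([a.t for a in self.acquisitions], dtype=float)

    @property
    def directions(self) -> np.ndarray:
        """(N, 3) array; rows are NaN for b = 0 acquisitions."""
        out = np.full((len(self), 3), np.nan)
        for i, a in enumerate(self.acquisitions):
            if a.direction is not None:
                out[i] = a.direction
        return out

    @property
    def scan_ids(self) -> list[str]:
        return [a.scan_id for a in self.acquisitions]

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b == 0)


def validate_scheme(scheme: AcquisitionScheme) -> None:
    """Raise ValueError if the scheme violates its invariants."""
    acqs = scheme.acquisitions
    if [a.n for a in acqs] != list(range(len(acqs))):
        raise ValueError("acquisition indices must be consecutive from 0")
    for scan in set(a.scan_id for a in acqs):
        ts = [a.t for a in acqs if a.scan_id == scan]
        if any(t2 < t1 for t1, t2 in zip(ts, ts[1:])):
            raise ValueError(f"times not nondecreasing within scan {scan!r}")
    if len(scheme.b0_indices) < 2:
        raise ValueError("scheme needs at least two b = 0 acquisitions")


def _as_direction(vec: Sequence[float]) -> tuple[float, float, float]:
    v = tuple(float(x) for x in vec)
    if len(v) != 3:
        raise ValueError("directions must be 3-vectors")
    norm = math.sqrt(sum(x * x for x in v))
    if abs(norm - 1.0) > _DIR_TOL:
        raise ValueError(f"direction {v} is not unit norm")
    return v


def build_mixed_scheme(
    b_sequence: Sequence[float],
    directions: Sequence[Sequence[float]] | None = None,
    n_cycles: int = 1,
    volume_interval: float = DEFAULT_VOLUME_INTERVAL,
    scan_id: str = "scan",
    c_for_b: Mapping[float, float] | Callable[[float], float] | None = None,
) -> AcquisitionScheme:
    """Loop through (b, direction) combinations with simultaneous increments.

    At global step t the b index is ``t mod len(b_sequence)`` and the
    direction index ``(t + t // lcm(len(b_sequence), len(directions)))
    mod len(directions)``; the extra unit offset per completed lcm cycle
    guarantees full (b, direction) coverage even when the two lengths share
    factors.  b = 0 entries carry no direction (repetitions) but still
    consume a direction slot.
    """
    if not len(b_sequence):
        raise ValueError("b_sequence must be nonempty")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if directions is None:
        directions = CANONICAL_DIRECTIONS
    dirs = [_as_direction(d) for d in directions]
    if not dirs:
        raise ValueError("directions must be nonempty")

    if c_for_b is None:
        c_fun = lambda b: 0.0
    elif callable(c_for_b):
        c_fun = c_for_b
    else:
        table = dict(c_for_b)
        c_fun = lambda b: table[b]

    nb, nd = len(b_sequence), len(dirs)
    cycle_lcm = math.lcm(nb, nd)
    acqs = []
    for t in range(nb * n_cycles):
        i = t % nb
        j = (t + t // cycle_lcm) % nd
        b = float(b_sequence[i])
        direction = None if b == 0 else dirs[j]
        c = 0.0 if b == 0 else float(c_fun(b))
        acqs.append(Acquisition(t, b, direction, c, t * volume_interval, scan_id))
    return AcquisitionScheme(acqs, volume_interval)


def low_high_order(b_values: Sequence[float]) -> list[float]:
    """Alternate smallest/largest remaining value: 0, 800, 5, 500, ..."""
    vals = list(b_values)
    if not vals:
        raise ValueError("b_values must be nonempty")
    if sorted(set(vals)) != vals:
        raise ValueError("b_values must be sorted ascending and unique")
    out: list[float] = []
    lo, hi = 0, len(vals) - 1
    take_low = True
    while lo <= hi:
        out.append(vals[lo] if take_low else vals[hi])
        if take_low:
            lo += 1
        else:
            hi -= 1
        take_low = not take_low
    return out


def _direction_rank(direction: tuple[float, float, float] | None):
    if direction is None:
        return (-1, (0.0, 0.0, 0.0))
    for k, cd in enumerate(CANONICAL_DIRECTIONS):
        if all(abs(a - b) <= _DIR_TOL for a, b in zip(direction, cd)):
            return (k, direction)
    return (len(CANONICAL_DIRECTIONS), direction)


def ordering_permutation(scheme: AcquisitionScheme) -> np.ndarray:
    """Permutation p with ordered[m] = original[p[m]] (ascending b, canonical
    direction succession within each b, then original repetition order)."""
    keys = [
        (a.b, _direction_rank(a.direction), a.n) for a in scheme.acquisitions
    ]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=int)


def ordered_scheme(scheme: AcquisitionScheme) -> AcquisitionScheme:
    """Re-sort a scheme by ascending b-value (the drift-sensitive looping)."""
    perm = ordering_permutation(scheme)
    acqs = []
    for m, p in enumerate(perm):
        a = scheme.acquisitions[int(p)]
        acqs.append(replace(a, n=m, t=m * scheme.volume_interval))
    return AcquisitionScheme(acqs, scheme.volume_interval)


def ballistic_flow_encoding(b: float, c_max: float = 0.3, b_max: float = 200.0) -> float:
    """Synthetic flow-encoding factor table for the non-flow-compensated scan.

    For a fixed bipolar waveform shape with varying gradient amplitude,
    b ∝ G² and c ∝ G, hence c ∝ √b; scaled to c_max s/mm at the maximum
    b-value of the ballistic protocol.
    """
    return 0.0 if b <= 0 else c_max * math.sqrt(b / b_max)


def protocol_preset(
    name: str, volume_interval: float = DEFAULT_VOLUME_INTERVAL
) -> AcquisitionScheme | tuple[AcquisitionScheme, AcquisitionScheme]:
    """Return the sIVIM, diffusive, or ballistic (FC, NC) preset scheme(s).

    sIVIM: b-sequence 0, 200, 800, 200, 0, 200 s/mm² × 6 cycles (36 volumes,
    4.5 min).  diffusive: 10 b-values in low–high order × 6 cycles (60
    volumes, 7.5 min).  ballistic: two scans (flow-compensated with c = 0,
    non-flow-compensated with c > 0 for b > 0) over 7 b-values in low–high
    order × 6 cycles (2 × 42 volumes, 10.5 min total).
    """
    name = name.lower()
    if name == "sivim":
        return build_mixed_scheme(
            SIVIM_B_SEQUENCE, n_cycles=6, volume_interval=volume_interval,
            scan_id="sIVIM",
        )
    if name == "diffusive":
        return build_mixed_scheme(
            low_high_order(sorted(DIFFUSIVE_B_VALUES)), n_cycles=6,
            volume_interval=volume_interval, scan_id="diffusive",
        )
    if name == "ballistic":
        seq = low_high_order(sorted(BALLISTIC_B_VALUES))
        fc = build_mixed_scheme(
            seq, n_cycles=6, volume_interval=volume_interval,
            scan_id="ballistic-FC",
        )
        nc = build_mixed_scheme(
            seq, n_cycles=6, volume_interval=volume_interval,
            scan_id="ballistic-NC", c_for_b=ballistic_flow_encoding,
        )
        return fc, nc
    raise ValueError(f"unknown protocol {name!r}")


def write_scheme(
    scheme: AcquisitionScheme,
    bval_path: str | Path,
    bvec_path: str | Path,
    cval_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write FSL-style bval (1 row) / bvec (3 rows) files, an optional cval
    sidecar (1 row, s/mm) and a JSON sidecar with scheme metadata.

    b = 0 acquisitions are written with the conventional (0, 0, 0) bvec.
    """
    b = scheme.b
    dirs = np.nan_to_num(scheme.directions, nan=0.0)
    Path(bval_path).write_text(" ".join(f"{x:.1f}" for x in b) + "\n")
    rows = [" ".join(f"{x:.6f}" for x in dirs[:, k]) for k in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")
    if cval_path is not None:
        Path(cval_path).write_text(
            " ".join(f"{x:.6f}" for x in scheme.c) + "\n"
        )
    if sidecar_path is not None:
        meta = {
            "volume_interval": scheme.volume_interval,
            "scan_ids": scheme.scan_ids,
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=1))


def _read_rows(path: str | Path, expected_rows: int) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != expected_rows:
        raise ValueError(f"{path}: expected {expected_rows} row(s), got {len(lines)}")
    try:
        rows = [np.array([float(tok) for tok in ln.split()]) for ln in lines]
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric token ({exc})") from None
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: ragged rows")
    return np.vstack(rows)


def read_scheme(
    bval_path: str | Path,
    bvec_path: str | Path,
    cval_path: str | Path | None = None,
    sidecar_path: str | Path | None = None,
    volume_interval: float = DEFAULT_VOLUME_INTERVAL,
    scan_id: str = "scan",
) -> AcquisitionScheme:
    """Read an acquisition scheme from bval/bvec (and optional cval) files."""
    b = _read_rows(bval_path, 1)[0]
    vec = _read_rows(bvec_path, 3)
    if vec.shape[1] != b.size:
        raise ValueError(
            f"length mismatch: {b.size} b-values vs {vec.shape[1]} bvec columns"
        )
    if cval_path is not None:
        c = _read_rows(cval_path, 1)[0]
        if c.size != b.size:
            raise ValueError("length mismatch between bval and cval")
    else:
        c = np.zeros_like(b)
    scan_ids = [scan_id] * b.size
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
        volume_interval = float(meta.get("volume_interval", volume_interval))
        scan_ids = meta.get("scan_ids", scan_ids)
    acqs = []
    for n in range(b.size):
        direction = None if b[n] == 0 else _as_direction(vec[:, n] / np.linalg.norm(vec[:, n]))
        acqs.append(
            Acquisition(n, float(b[n]), direction, float(c[n]),
                        n * volume_interval, scan_ids[n])
        )
    return AcquisitionScheme(acqs, volume_interval)
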