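"""Generate the packaged 64-channel 10-10 montage table.

Coordinates are constructed from the idealized spherical layout of the
extended international 10-10 system on a unit sphere (x: right, y: anterior,
z: superior):

* the sagittal midline arc (NZ .. CZ .. IZ) and the coronal arc through the
  ears (T9 .. CZ .. T10) are great circles subdivided at 10% (18 deg) steps;
* the circumferential circle through FPZ, T7, OZ, T8 sits at 18 deg
  elevation and is subdivided at 5% (18 deg azimuth) steps;
* every interior row (AF, F, FC, CP, P, PO) lies on the circle through its
  two circumferential anchors and its midline electrode, subdivided at equal
  arc-angle steps.

Electrode order matches the PhysioNet 64-channel recording layout, which is
the canonical node order everywhere in the package.

Run from the repository root:  python tools/generate_montage.py
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "mignet" / "resources" / "standard_1010_64.tsv"

# canonical PhysioNet channel order (names upper-cased, trailing dots removed)
CHANNEL_ORDER = [
    "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "CZ", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "FP1", "FPZ", "FP2",
    "AF7", "AF3", "AFZ", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FT8",
    "T7", "T8", "T9", "T10",
    "TP7", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POZ", "PO4", "PO8",
    "O1", "OZ", "O2",
    "IZ",
]


def _sph(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit-sphere point; azimuth measured from +y (nasion) toward +x (right)."""
    az, el = math.radians(azimuth_deg), math.radians(elevation_deg)
    return np.array([
        math.cos(el) * math.sin(az),
        math.cos(el) * math.cos(az),
        math.sin(el),
    ])


def _arc_through(a: np.ndarray, m: np.ndarray, b: np.ndarray, n_points: int) -> list[np.ndarray]:
    """n_points equally spaced on the sphere circle through a, m, b, from a to b via m."""
    normal = np.cross(b - a, m - a)
    normal /= np.linalg.norm(normal)
    d = float(normal @ a)              # plane offset; circle center is d * normal
    center = d * normal
    r = math.sqrt(max(1.0 - d * d, 0.0))
    e1 = (a - center) / np.linalg.norm(a - center)
    e2 = np.cross(normal, e1)

    def angle(p: np.ndarray) -> float:
        v = p - center
        return math.atan2(float(v @ e2), float(v @ e1))

    beta = angle(b)
    theta_m = angle(m)
    # pick the rotation direction that passes through m
    if beta < 0:
        beta += 2 * math.pi
    if theta_m < 0:
        theta_m += 2 * math.pi
    if theta_m > beta:  # m not between 0 and beta going ccw -> go clockwise
        beta -= 2 * math.pi
    ts = np.linspace(0.0, 1.0, n_points)
    return [center + r * (math.cos(t * beta) * e1 + math.sin(t * beta) * e2) for t in ts]


def build_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}

    # sagittal midline: NZ(0%) .. CZ(50%) .. IZ(100%), elevation sweeps 0->90->0
    midline = ["NZ", "FPZ", "AFZ", "FZ", "FCZ", "CZ", "CPZ", "PZ", "POZ", "OZ", "IZ"]
    for i, name in enumerate(midline):
        frac = i / 10.0
        az = 0.0 if frac <= 0.5 else 180.0
        el = 180.0 * frac if frac <= 0.5 else 180.0 * (1.0 - frac)
        pos[name] = _sph(az, el)

    # coronal ear-to-ear arc: T9 .. CZ .. T10
    coronal = ["T9", "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8", "T10"]
    for i, name in enumerate(coronal):
        frac = i / 10.0
        az = -90.0 if frac <= 0.5 else 90.0
        el = 180.0 * frac if frac <= 0.5 else 180.0 * (1.0 - frac)
        pos[name] = _sph(az, el)

    # circumferential circle at 18 deg elevation, 18 deg azimuth steps from FPZ
    circumf = {
        "FP2": 18, "AF8": 36, "F8": 54, "FT8": 72, "T8": 90,
        "TP8": 108, "P8": 126, "PO8": 144, "O2": 162,
        "FP1": -18, "AF7": -36, "F7": -54, "FT7": -72, "T7": -90,
        "TP7": -108, "P7": -126, "PO7": -144, "O1": -162,
    }
    for name, az in circumf.items():
        pos[name] = _sph(float(az), 18.0)

    # interior rows: circle through (left anchor, midline, right anchor)
    rows = {
        ("AF7", "AFZ", "AF8"): ["AF7", "AF5", "AF3", "AF1", "AFZ", "AF2", "AF4", "AF6", "AF8"],
        ("F7", "FZ", "F8"): ["F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"],
        ("FT7", "FCZ", "FT8"): ["FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"],
        ("TP7", "CPZ", "TP8"): ["TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"],
        ("P7", "PZ", "P8"): ["P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"],
        ("PO7", "POZ", "PO8"): ["PO7", "PO5", "PO3", "PO1", "POZ", "PO2", "PO4", "PO6", "PO8"],
    }
    for (la, mid, ra), names in rows.items():
        pts = _arc_through(pos[la], pos[mid], pos[ra], len(names))
        for name, p in zip(names, pts):
            pos.setdefault(name, p)

    return pos


def main() -> None:
    pos = build_positions()
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as fh:
        fh.write("name\tx\ty\tz\n")
        for name in CHANNEL_ORDER:
            x, y, z = pos[name]
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")
    print(f"wrote {OUT} ({len(CHANNEL_ORDER)} electrodes)")


if __name__ == "__main__":
    main()
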