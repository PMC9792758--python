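"""59-channel EEG montage: names, integer codes, spherical scalp positions.

The montage is the anterior-to-posterior ordered 59-electrode subset of the
10-10 system used throughout the pipeline.  Channel codes are 1-based and fixed
by four anchors: code 1 = Fpz, 43 = Pz, 50 = POz, 57 = Oz, 59 = O2.  Codes
43-59 form the parieto-occipital "V1" region; everything else is "other".

Head coordinates are meters, origin at the head center: +x right, +y anterior,
+z superior.  Positions are computed from standard 10-10 arc fractions on a
sphere (default radius 0.092 m): midline electrodes lie on the sagittal
nasion-inion great circle, the outermost lateral electrodes on the horizontal
circle through the ears, and intermediate electrodes on great-circle arcs
between the two, at even fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import MontageError, ParseError

Region = Literal["posterior_v1", "other"]

POSTERIOR_V1_CODES = tuple(range(43, 60))  #: codes of the V1 region (Pz..O2)

#: Canonical channel order.  Rows run anterior to posterior; within a row the
#: midline electrode comes first, then pairs left/right, outermost last.
CHANNEL_NAMES: tuple[str, ...] = (
    # frontal pole / anterior frontal
    "Fpz", "Fp1", "Fp2",
    "AFz", "AF3", "AF4", "AF7", "AF8",
    # frontal
    "Fz", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8",
    # fronto-central
    "FCz", "FC1", "FC2", "FC3", "FC4", "FC5", "FC6", "FT7", "FT8",
    # central
    "Cz", "C1", "C2", "C3", "C4", "C5", "C6", "T7", "T8",
    # centro-parietal
    "CPz", "CP1", "CP2", "CP3", "CP4", "CP5", "CP6",
    # parietal (code 43 = Pz)
    "Pz", "P1", "P2", "P3", "P4", "P5", "P6",
    # parieto-occipital (code 50 = POz)
    "POz", "PO3", "PO4", "PO5", "PO6", "PO7", "PO8",
    # occipital (code 57 = Oz)
    "Oz", "O1", "O2",
)

# (midline arc fraction, lateral step count, lateral endpoint fraction) per row.
# The midline fraction f places the row's midline electrode at angle f*pi along
# the nasion->Cz->inion great circle; the endpoint fraction g places the row's
# outermost electrode at angle g*pi around the horizontal circle (from nasion).
_ROW_GEOMETRY: dict[str, tuple[float, float]] = {
    "Fp": (0.10, 0.10),
    "AF": (0.20, 0.20),
    "F": (0.30, 0.30),
    "FC": (0.40, 0.40),
    "C": (0.50, 0.50),
    "CP": (0.60, 0.60),
    "P": (0.70, 0.70),
    "PO": (0.80, 0.80),
    "O": (0.90, 0.90),
}


@dataclass(frozen=True)
class ChannelSpec:
    """One electrode: 10-10 name, 1-based code, scalp position, region label."""

    name: str
    code: int
    position: np.ndarray  # (3,), meters
    region: Region

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if pos.shape != (3,):
            raise MontageError(f"position of {self.name} must be a 3-vector")


@dataclass(frozen=True)
class Montage:
    """Ordered 59-channel montage on a spherical scalp."""

    channels: tuple[ChannelSpec, ...]
    sphere_radius: float = 0.092

    def __post_init__(self) -> None:
        _validate(self)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def positions(self) -> np.ndarray:
        """(59, 3) array in canonical code order."""
        return np.stack([c.position for c in self.channels])

    def channel(self, code: int) -> ChannelSpec:
        if not 1 <= code <= len(self.channels):
            raise ValueError(f"channel code {code} out of range")
        return self.channels[code - 1]

    def code_of(self, name: str) -> int:
        for c in self.channels:
            if c.name == name:
                return c.code
        raise ValueError(f"no channel named {name!r}")


def _validate(montage: Montage) -> None:
    ch = montage.channels
    if len(ch) != 59:
        raise MontageError(f"montage must have 59 channels, got {len(ch)}")
    if [c.code for c in ch] != list(range(1, 60)):
        raise MontageError("channel codes must be 1..59 in order")
    anchors = {1: "Fpz", 43: "Pz", 50: "POz", 57: "Oz", 59: "O2"}
    for code, name in anchors.items():
        if ch[code - 1].name != name:
            raise MontageError(
                f"code {code} must be {name}, got {ch[code - 1].name}"
            )
    for c in ch:
        r = float(np.linalg.norm(c.position))
        if not 0.07 <= r <= 0.11:
            raise MontageError(
                f"{c.name}: scalp radius {r:.4f} m outside [0.07, 0.11]"
            )
        want: Region = "posterior_v1" if c.code in POSTERIOR_V1_CODES else "other"
        if c.region != want:
            raise MontageError(f"{c.name}: region must be {want}")
    for name in ("Pz", "POz", "Oz"):
        x = ch[[c.name for c in ch].index(name)].position[0]
        if abs(x) >= 1e-3:
            raise MontageError(f"{name} must sit on the sagittal midline")


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between unit vectors ``a`` and ``b``."""
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        return a
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _midline_unit(f: float) -> np.ndarray:
    """Unit vector at fraction f of the nasion->vertex->inion arc."""
    ang = np.pi * f
    return np.array([0.0, np.cos(ang), np.sin(ang)])


def _horizontal_unit(g: float, side: int) -> np.ndarray:
    """Unit vector at fraction g around the horizontal circle; side=+1 right."""
    ang = np.pi * g
    return np.array([side * np.sin(ang), np.cos(ang), 0.0])


def _unit_position(name: str) -> np.ndarray:
    """Unit-sphere position for a 10-10 label in the canonical subset."""
    row = name.rstrip("0123456789z")
    suffix = name[len(row):]
    if row in ("T", "FT", "TP"):  # temporal labels live on their row's circle
        row = {"T": "C", "FT": "FC", "TP": "CP"}[row]
        suffix = {"7": "7", "8": "8"}[suffix]
    f, g = _ROW_GEOMETRY[row if row != "Fp" else "Fp"]
    if suffix == "z":
        return _midline_unit(f)
    num = int(suffix)
    side = 1 if num % 2 == 0 else -1  # odd = left, even = right
    endpoint = _horizontal_unit(g, side)
    if row in ("Fp", "O"):
        # Fp1/2 and O1/2 sit on the horizontal circle themselves
        return endpoint
    midline = _midline_unit(f)
    # lateral index 1..4 -> arc fraction; the 7/8 pair is the endpoint
    steps = {"1": 0.25, "2": 0.25, "3": 0.5, "4": 0.5,
             "5": 0.75, "6": 0.75, "7": 1.0, "8": 1.0}
    if row == "PO":  # three pairs only: PO3/4, PO5/6, PO7/8
        steps = {"3": 1 / 3, "4": 1 / 3, "5": 2 / 3, "6": 2 / 3,
                 "7": 1.0, "8": 1.0}
    if row == "AF":  # AF3/4 midway, AF7/8 at the endpoint
        steps = {"3": 0.5, "4": 0.5, "7": 1.0, "8": 1.0}
    return _slerp(midline, endpoint, steps[suffix])


def build_standard_montage(sphere_radius: float = 0.092) -> Montage:
    """Canonical 59-channel montage on a sphere of ``sphere_radius`` meters."""
    channels = []
    for i, name in enumerate(CHANNEL_NAMES):
        code = i + 1
        pos = _unit_position(name) * sphere_radius
        region: Region = "posterior_v1" if code in POSTERIOR_V1_CODES else "other"
        channels.append(ChannelSpec(name=name, code=code, position=pos,
                                    region=region))
    return Montage(channels=tuple(channels), sphere_radius=sphere_radius)


def region_codes(montage: Montage, region: Region) -> list[int]:
    """Ordered channel codes of one region; the two regions partition 1..59."""
    if region not in ("posterior_v1", "other"):
        raise ValueError(f"unknown region {region!r}")
    return [c.code for c in montage.channels if c.region == region]


def save_positions(montage: Montage, path: str | Path) -> None:
    """Write ``name<TAB>x<TAB>y<TAB>z`` per line (meters), one header line."""
    lines = ["# units: m"]
    for c in montage.channels:
        x, y, z = c.position
        lines.append(f"{c.name}\t{x:.6f}\t{y:.6f}\t{z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_positions(path: str | Path, sphere_radius: float = 0.092) -> Montage:
    """Read an electrode-position file; codes are assigned by file order."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParseError(f"line {lineno}: expected 'name x y z'")
        name = parts[0]
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric coordinate") from exc
        rows.append((name, np.array(xyz)))
    if len(rows) != 59:
        raise MontageError(f"expected 59 channels, file has {len(rows)}")
    channels = []
    for i, (name, pos) in enumerate(rows):
        code = i + 1
        region: Region = "posterior_v1" if code in POSTERIOR_V1_CODES else "other"
        channels.append(ChannelSpec(name=name, code=code, position=pos,
                                    region=region))
    return Montage(channels=tuple(channels), sphere_radius=sphere_radius)
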