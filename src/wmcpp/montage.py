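"""Schematic 10-10 electrode montage with 2-D scalp coordinates.

Coordinates are a flat schematic layout on the unit disc (nose up, +x right,
+y anterior), *not* a projected head model: they exist so that the simulator
can place a smooth centro-parietal topography and so that topography exports
carry sensible positions.  Mastoids M1/M2 sit just outside the disc below the
ears.
"""

from __future__ import annotations

import re

import numpy as np

from .errors import ConfigError

# anterior-posterior coordinate per 10-10 row
_ROW_Y = {
    "Fp": 0.85,
    "AF": 0.68,
    "F": 0.50,
    "FT": 0.25,
    "FC": 0.25,
    "T": 0.00,
    "C": 0.00,
    "TP": -0.25,
    "CP": -0.25,
    "P": -0.50,
    "PO": -0.68,
    "O": -0.85,
}

# lateral magnitude per 10-10 column digit (odd = left, even = right)
_COL_X = {1: 0.20, 2: 0.20, 3: 0.45, 4: 0.45, 5: 0.70, 6: 0.70, 7: 0.95, 8: 0.95}

_SPECIAL = {"M1": (-1.10, -0.35), "M2": (1.10, -0.35)}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|[1-8])$")

#: Default simulation/analysis montage: 29 scalp sites spanning the head,
#: including the centro-parietal analysis cluster, plus both mastoids.
DEFAULT_MONTAGE = [
    "Fp1", "Fp2",
    "F3", "Fz", "F4",
    "FC1", "FCz", "FC2",
    "C3", "C1", "Cz", "C2", "C4",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P3", "P1", "Pz", "P2", "P4",
    "PO3", "POz", "PO4",
    "O1", "Oz", "O2",
    "M1", "M2",
]

#: Full 61-electrode 10-10 montage (plus mastoids) as used at acquisition.
FULL_MONTAGE = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "M1", "M2",
]


def channel_position(label: str) -> tuple[float, float]:
    """Schematic (x, y) coordinate of a 10-10 channel label."""
    if label in _SPECIAL:
        return _SPECIAL[label]
    m = _LABEL_RE.match(label)
    if m is None or m.group(1) not in _ROW_Y:
        raise ConfigError(f"unknown channel label: {label!r}")
    row, col = m.group(1), m.group(2)
    y = _ROW_Y[row]
    if col == "z":
        return (0.0, y)
    d = int(col)
    x = _COL_X[d] * (-1.0 if d % 2 else 1.0)
    return (x, y)


def montage_positions(labels: list[str]) -> np.ndarray:
    """(n_channels, 2) array of schematic coordinates for ``labels``."""
    return np.array([channel_position(lb) for lb in labels], dtype=float)


def spatial_weights(
    positions: np.ndarray, center: tuple[float, float], width: float
) -> np.ndarray:
    """Isotropic Gaussian spatial profile over 2-D channel positions."""
    d2 = np.sum((positions - np.asarray(center, float)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))
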