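"""Electrode montages on the unit sphere.

Two 64-channel layouts are provided, mirroring the two cap systems under
comparison: an equidistant layout (dry multipin cap) and an extended
10-20 layout (conventional gel cap). Positions use an RAS-like frame:
+x right, +y anterior (nose), +z superior, all points normalized to the
unit sphere. Spherical-spline interpolation and the posterior weighting
of the synthetic generator only require this normalized geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

EQUIDISTANT64 = "equidistant64"
TENTWENTY64 = "tentwenty64"

# 64 labels of the extended international 10-20 (10-10) system used for
# the gel cap, including the mastoids that carry ground/reference leads.
_TENTWENTY_LABELS = [
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "M1", "M2",
]
assert len(_TENTWENTY_LABELS) == 64


@dataclass
class Montage:
    """Electrode labels with unit-sphere positions."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit norm
    layout_kind: str = "custom"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (len(self.labels), 3):
            raise ValidationError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("montage labels must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("montage positions must lie on the unit sphere")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, labels: list[str]) -> np.ndarray:
        """Row indices of ``labels`` in this montage (error if any missing)."""
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in lookup]
        if missing:
            raise ValidationError(f"labels missing from montage: {missing}")
        return np.array([lookup[lab] for lab in labels], dtype=int)


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    return x / np.linalg.norm(x, axis=1, keepdims=True)


def equidistant_64() -> Montage:
    """Equidistant 64-electrode layout of the dry multipin cap.

    Built as a golden-angle (Fibonacci) spiral over the head surface from
    just below the equator (mastoid level) to the vertex, which gives a
    near-uniform inter-electrode spacing like the fabric cap's layout.
    Labels are E01..E64 ordered from frontal to occipital rows.
    """
    n = 64
    z = np.linspace(-0.15, 0.985, n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = golden * np.arange(n)
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    # order anterior -> posterior for readable labels
    order = np.argsort(-pts[:, 1], kind="stable")
    pts = pts[order]
    labels = [f"E{i + 1:02d}" for i in range(n)]
    return Montage(labels, _normalize_rows(pts), layout_kind=EQUIDISTANT64)


def tentwenty_64() -> Montage:
    """Extended 10-20 64-electrode layout of the gel cap.

    Positions come from the standard idealized 10-05 electrode set
    (via MNE), re-centered on a least-squares sphere fit and projected to
    the unit sphere, then rotated so +y points to the nasion.
    """
    import mne  # local import: only needed for this layout

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos_map = std.get_positions()["ch_pos"]
    pts = np.array([pos_map[lab] for lab in _TENTWENTY_LABELS], dtype=np.float64)
    center = _fit_sphere_center(pts)
    pts = pts - center
    # MNE head frame is already +x right / +y nasion / +z up.
    return Montage(list(_TENTWENTY_LABELS), _normalize_rows(pts), layout_kind=TENTWENTY64)


def _fit_sphere_center(pts: np.ndarray) -> np.ndarray:
    """Least-squares sphere center: linearized |p - c|^2 = r^2 fit."""
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def save_montage(montage: Montage, path) -> None:
    """Write a montage as delimited text: label, x, y, z (tab-separated)."""
    with open(path, "w") as fh:
        fh.write("# label\tx\ty\tz\n")
        for lab, p in zip(montage.labels, montage.positions):
            fh.write(f"{lab}\t{p[0]:.12g}\t{p[1]:.12g}\t{p[2]:.12g}\n")


def load_montage(path, layout_kind: str = "custom") -> Montage:
    """Read a delimited montage file; positions are normalized on load."""
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 4:
                raise ValidationError(f"montage line needs 4 fields: {line!r}")
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    pts = np.asarray(rows)
    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms <= 0):
        raise ValidationError("montage contains a zero position")
    return Montage(labels, pts / norms[:, None], layout_kind=layout_kind)
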