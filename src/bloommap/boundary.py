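"""The CIE-space bloom boundary: two quadratics meeting near the white point.

The frontier between bloom and bloom-free water colour is represented by two
second-order polynomials in the chromaticity abscissa x, one on each side of
a split (default 1/3, the white point): y1 for x < split, y2 for x >= split.
The shipped default carries the trained coefficients

    y1 = 4.8093 x^2 - 3.0958 x + 0.8357   (x < 1/3)
    y2 = 4.9040 x^2 - 3.5759 x + 0.9862   (x >= 1/3)

:func:`fit_boundary` reproduces the training procedure: bin labelled bloom
chromaticities by x, take a low percentile of y per bin (the weakest blooms),
and least-squares fit a quadratic to the per-bin percentiles on each side.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

SPLIT_DEFAULT = 1.0 / 3.0


@dataclass(frozen=True)
class BloomBoundary:
    """Two quadratic coefficient triples (a, b, c) and the split abscissa."""

    left_coeffs: tuple[float, float, float]
    right_coeffs: tuple[float, float, float]
    split: float = SPLIT_DEFAULT
    percentile: float = 0.01
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in ("left_coeffs", "right_coeffs"):
            coeffs = tuple(float(v) for v in getattr(self, name))
            if len(coeffs) != 3 or not all(np.isfinite(coeffs)):
                raise ValueError(f"{name} must be three finite coefficients")
            object.__setattr__(self, name, coeffs)
        # The boundary must stay positive everywhere and inside (0, 1) on
        # [0.05, 0.7]; beyond x ~ 0.73 a quadratic frontier may exceed 1,
        # which is harmless since no chromaticity point has y > 1 - x there.
        xs = np.linspace(0.0, 1.0, 201)
        ys = boundary_y(xs, self)
        if not (ys > 0).all():
            raise ValueError("boundary must be positive on [0, 1]")
        core = (xs >= 0.05) & (xs <= 0.7)
        if not (ys[core] < 1).all():
            raise ValueError("boundary must stay below 1 on [0.05, 0.7]")
        gap = abs(_poly(self.left_coeffs, self.split) - _poly(self.right_coeffs, self.split))
        if gap >= 0.01:
            raise ValueError(f"boundary is discontinuous at the split (gap {gap:.4f} >= 0.01)")


@dataclass(frozen=True)
class TrainingSample:
    """A labelled bloom chromaticity used to fit the boundary."""

    x: float
    y: float
    label: str = ""


def _poly(coeffs: Sequence[float], x):
    a, b, c = coeffs
    return (a * x + b) * x + c


def boundary_y(x, boundary: "BloomBoundary"):
    """Boundary ordinate at abscissa x (left quadratic below the split,
    right quadratic at and above it).  Vectorised."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < boundary.split,
        _poly(boundary.left_coeffs, x),
        _poly(boundary.right_coeffs, x),
    )
    return out if out.ndim else float(out)


def classify_point(x: float, y: float, boundary: "BloomBoundary") -> bool:
    """True iff (x, y) lies strictly above the boundary (a bloom colour)."""
    if not (np.isfinite(x) and np.isfinite(y)):
        return False
    return bool(y > boundary_y(x, boundary))


def fit_boundary(
    samples: Iterable,
    bin_width: float = 0.01,
    percentile: float = 0.01,
    min_bin_count: int = 50,
    split: float = SPLIT_DEFAULT,
) -> BloomBoundary:
    """Fit the two boundary quadratics from labelled bloom chromaticities.

    Samples are binned by x (width ``bin_width``); in each bin with at least
    ``min_bin_count`` points the ``percentile`` quantile of y is taken (linear
    interpolation between order statistics); an unweighted ordinary
    least-squares quadratic is fitted to the (bin centre, quantile) pairs on
    each side of ``split``.  Raises ``ValueError`` naming the side if fewer
    than three usable bins remain on it.

    ``samples`` may be an iterable of :class:`TrainingSample`, of (x, y)
    pairs, or a 2-column array.
    """
    xy = _as_xy(samples)
    finite = np.isfinite(xy).all(axis=1)
    xy = xy[finite]
    if xy.size == 0:
        raise ValueError("no finite training samples")

    idx = np.floor(xy[:, 0] / bin_width).astype(np.int64)
    coeffs: dict[str, tuple[float, float, float]] = {}
    for side, mask in (("left", None), ("right", None)):
        centres, quants = [], []
        for b in np.unique(idx):
            centre = (b + 0.5) * bin_width
            on_left = centre < split
            if (side == "left") != on_left:
                continue
            ys = xy[idx == b, 1]
            if ys.size < min_bin_count:
                continue
            centres.append(centre)
            quants.append(np.quantile(ys, percentile, method="linear"))
        if len(centres) < 3:
            raise ValueError(
                f"fewer than 3 usable bins on the {side} side of the split "
                f"({len(centres)} found)"
            )
        a, b_, c = np.polyfit(np.asarray(centres), np.asarray(quants), 2)
        coeffs[side] = (float(a), float(b_), float(c))

    return BloomBoundary(
        coeffs["left"],
        coeffs["right"],
        split=split,
        percentile=percentile,
        provenance=f"fit_boundary(bin_width={bin_width}, percentile={percentile}, "
        f"min_bin_count={min_bin_count}, n={xy.shape[0]})",
    )


def _as_xy(samples: Iterable) -> np.ndarray:
    rows = []
    arr = np.asarray(samples) if not hasattr(samples, "__next__") else None
    if arr is not None and arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype != object:
        return arr.astype(float)
    for s in samples:
        if isinstance(s, TrainingSample):
            rows.append((s.x, s.y))
        elif hasattr(s, "x") and hasattr(s, "y"):
            rows.append((float(s.x), float(s.y)))
        else:
            x, y = s
            rows.append((float(x), float(y)))
    return np.asarray(rows, dtype=float).reshape(-1, 2)


# ---------------------------------------------------------------------------
# serialization

def to_json(boundary: BloomBoundary, path: str | Path | None = None) -> str:
    doc = json.dumps(asdict(boundary), indent=2)
    if path is not None:
        Path(path).write_text(doc)
    return doc


def from_json(source: str | Path) -> BloomBoundary:
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    d = json.loads(text)
    return BloomBoundary(
        tuple(d["left_coeffs"]),
        tuple(d["right_coeffs"]),
        split=d.get("split", SPLIT_DEFAULT),
        percentile=d.get("percentile", 0.01),
        provenance=d.get("provenance", ""),
    )


def load_default_boundary() -> BloomBoundary:
    """The shipped boundary with the trained quadratic coefficients."""
    text = resources.files("bloommap").joinpath("data/default_boundary.json").read_text()
    d = json.loads(text)
    return BloomBoundary(
        tuple(d["left_coeffs"]),
        tuple(d["right_coeffs"]),
        split=d.get("split", SPLIT_DEFAULT),
        percentile=d.get("percentile", 0.01),
        provenance=d.get("provenance", ""),
    )


DEFAULT_BOUNDARY = BloomBoundary(
    (4.8093, -3.0958, 0.8357),
    (4.9040, -3.5759, 0.9862),
    provenance="trained CIE-fluorescence boundary (shipped default)",
)
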