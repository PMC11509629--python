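"""The force-curve container and its plain-text file format.

A :class:`ForceCurve` is a pair of equally long arrays -- indentation depth
``h`` and force ``F`` -- in strict SI units (meters, newtons), plus a free-form
metadata mapping (geometry, material, noise, seed, ... for synthetic curves).

The native on-disk format is two-column delimited text with a commented
header, e.g.::

    # bluntfit-curve: 1
    # depth_unit: nm
    # force_unit: nN
    # tip_family: sphero_conical
    # tip_radius_m: 2e-07
    ...
    0.3  0.0021
    0.6  0.0060

Unknown header keys are preserved verbatim on a read/write roundtrip.
Proprietary AFM vendor exports are out of scope: curves are expected to be
pre-exported to text, baseline-corrected, with the contact point at the
origin.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ForceCurve", "CurveFormatError", "read_curve", "write_curve", "UNIT_SCALES"]

log = logging.getLogger(__name__)

#: multiplicative factors to SI for the unit names accepted in headers
UNIT_SCALES = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # force
    "n": 1.0, "N": 1.0, "mN": 1e-3, "uN": 1e-6, "µN": 1e-6, "nN": 1e-9, "pN": 1e-12,
}

MIN_POINTS = 5


class CurveFormatError(ValueError):
    """Raised for unparseable curve files or files with too few valid points."""


@dataclass
class ForceCurve:
    """Paired (depth, force) samples in SI units with provenance metadata."""

    h: np.ndarray
    F: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.h.ndim != 1 or self.h.shape != self.F.shape:
            raise ValueError("h and F must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return self.h.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ForceCurve)
            and np.array_equal(self.h, other.h)
            and np.array_equal(self.F, other.F)
            and self.metadata == other.metadata
        )

    @property
    def h_max(self) -> float:
        return float(self.h.max())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"indentation_m": self.h, "force_N": self.F})


_HEADER_RE = re.compile(r"^#\s*([^:]+?)\s*:\s*(.*?)\s*$")


def _parse_number(text: str):
    try:
        f = float(text)
    except ValueError:
        return text
    if f.is_integer() and "." not in text and "e" not in text.lower():
        return int(f)
    return f


def read_curve(path, units: tuple[str, str] | None = None) -> ForceCurve:
    """Read a two-column (depth, force) text file into SI units.

    Parameters
    ----------
    path : path-like
        Whitespace-, comma- or tab-delimited file with ``# key: value`` header
        lines.
    units : (str, str), optional
        ``(depth_unit, force_unit)`` override, e.g. ``("nm", "nN")``.  Required
        when the file header does not declare units.

    Notes
    -----
    Leading rows with negative depth (pre-contact) are dropped with a logged
    count; depths are sorted into strictly increasing order by a stable sort.
    """
    path = Path(path)
    meta: dict = {}
    rows: list[tuple[float, float]] = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                m = _HEADER_RE.match(line.strip())
                if m:
                    meta[m.group(1)] = _parse_number(m.group(2))
                continue
            if not line.strip():
                continue
            parts = re.split(r"[,\s]+", line.strip())
            # float() is correctly rounded, so repr-written values roundtrip
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except (ValueError, IndexError):
                n_bad += 1
    if n_bad:
        log.info("%s: skipped %d non-numeric rows", path, n_bad)
    if not rows:
        raise CurveFormatError(f"{path}: no parseable two-column numeric rows")

    if units is not None:
        depth_unit, force_unit = units
    else:
        depth_unit = meta.get("depth_unit")
        force_unit = meta.get("force_unit")
        if depth_unit is None or force_unit is None:
            raise CurveFormatError(
                f"{path}: no units in header and no override given"
            )
    try:
        scale_h = UNIT_SCALES[str(depth_unit)]
        scale_F = UNIT_SCALES[str(force_unit)]
    except KeyError as exc:
        raise CurveFormatError(f"{path}: unknown unit {exc}") from exc

    data = np.asarray(rows, dtype=float)
    h = data[:, 0] * scale_h
    F = data[:, 1] * scale_F
    n_pre = int(np.sum(h < 0))
    if n_pre:
        log.info("%s: dropped %d pre-contact rows (negative depth)", path, n_pre)
        keep = h >= 0
        h, F = h[keep], F[keep]
    order = np.argsort(h, kind="stable")
    h, F = h[order], F[order]
    if h.size < MIN_POINTS:
        raise CurveFormatError(
            f"{path}: only {h.size} valid points (need >= {MIN_POINTS})"
        )
    meta.pop("bluntfit-curve", None)
    meta["depth_unit"] = depth_unit
    meta["force_unit"] = force_unit
    return ForceCurve(h=h, F=F, metadata=meta)


def write_curve(path, curve: ForceCurve, units: tuple[str, str] | None = None) -> None:
    """Write a curve as commented-header two-column text.

    Values are stored in display units (taken from the curve metadata, falling
    back to nm/nN) at full float precision (``repr`` roundtrip), so
    ``read_curve(write_curve(c)) == c`` including metadata.
    """
    path = Path(path)
    if units is None:
        units = (
            curve.metadata.get("depth_unit", "m"),
            curve.metadata.get("force_unit", "N"),
        )
    depth_unit, force_unit = units
    scale_h = UNIT_SCALES[depth_unit]
    scale_F = UNIT_SCALES[force_unit]
    skip = {"depth_unit", "force_unit", "source"}
    with open(path, "w") as fh:
        fh.write("# bluntfit-curve: 1\n")
        fh.write(f"# depth_unit: {depth_unit}\n")
        fh.write(f"# force_unit: {force_unit}\n")
        for key, value in curve.metadata.items():
            if key not in skip and key != "bluntfit-curve":
                fh.write(f"# {key}: {value}\n")
        for h, F in zip(curve.h / scale_h, curve.F / scale_F):
            fh.write(f"{float(h)!r}\t{float(F)!r}\n")
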