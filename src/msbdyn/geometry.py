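"""Spatial characterization of spine pairs.

Head-to-head distances between spine-head centres of mass, head/base
orientation classification ("towards" when heads are nearer than bases,
"away" when further, "parallel" when equidistant within a tolerance), linear
spine density, and random selection of adjacent control pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionMismatchError, InsufficientDataError
from .records import SpineRecord

ORIENTATION_TOLERANCE_UM = 0.15  # ≈ one pixel; proxy for a visual call

__all__ = [
    "SpinePair",
    "head_distance",
    "classify_orientation",
    "spine_density",
    "select_control_pairs",
    "pairs_to_frame",
    "ORIENTATION_TOLERANCE_UM",
]


@dataclass
class SpinePair:
    """A pair of spines with its spatial measurements."""

    spine_a: SpineRecord
    spine_b: SpineRecord
    head_distance: float
    orientation: str  # towards | parallel | away
    provenance: str = "msb_candidate"  # msb_candidate | control

    def ids(self) -> tuple[int, int]:
        return (self.spine_a.id, self.spine_b.id)


def _coords(point) -> np.ndarray:
    arr = np.asarray(point, dtype=float)
    if arr.ndim != 1 or arr.size not in (2, 3):
        raise DimensionMismatchError("expected a 2- or 3-vector of coordinates")
    if np.isnan(arr).any():
        raise DimensionMismatchError("coordinate contains missing components")
    return arr


def _point_distance(p, q) -> float:
    a, b = _coords(p), _coords(q)
    if a.size != b.size:
        raise DimensionMismatchError(
            f"coordinate dimensions differ ({a.size} vs {b.size}); "
            "one spine may be missing its z coordinate")
    return float(math.sqrt(((a - b) ** 2).sum()))


def head_distance(a: SpineRecord, b: SpineRecord) -> float:
    """Euclidean distance (µm) between the head centres of mass."""
    return _point_distance(a.head_um, b.head_um)


def classify_orientation(a: SpineRecord, b: SpineRecord,
                         tolerance: float = ORIENTATION_TOLERANCE_UM) -> str:
    """Classify a spine pair's mutual orientation from head and base distances.

    With head distance ``dh`` and base distance ``db``: ``parallel`` when
    ``|dh − db| ≤ tolerance``, ``towards`` when ``dh < db − tolerance``
    (heads nearer than bases), ``away`` when ``dh > db + tolerance``.
    """
    if tolerance < 0:
        raise ConfigError(f"tolerance: must be >= 0, got {tolerance!r}")
    dh = head_distance(a, b)
    db = _point_distance(a.base_um, b.base_um)
    if abs(dh - db) <= tolerance:
        return "parallel"
    return "towards" if dh < db else "away"


def spine_density(spines, dendrite_length: float) -> float:
    """Linear spine density (spines/µm) along a dendritic segment."""
    if dendrite_length <= 0:
        raise ConfigError(f"dendrite_length: must be > 0, got {dendrite_length!r}")
    count = spines if isinstance(spines, (int, np.integer)) else len(spines)
    return count / dendrite_length


def _axis_position(spine: SpineRecord) -> float:
    # position along the dendrite: the base x coordinate
    return float(spine.base_um[0])


def select_control_pairs(spines: list[SpineRecord],
                         exclude_pairs: list[SpinePair] | None = None,
                         rng: np.random.Generator | None = None,
                         n_pairs: int | None = None) -> list[SpinePair]:
    """Randomly select adjacent spine pairs as controls.

    Spines are ordered along the dendrite (base x); candidate pairs are
    consecutive eligible spines, excluding any spine already in
    ``exclude_pairs``. Pairs are drawn in random order, greedily keeping
    non-overlapping ones, up to ``n_pairs`` (all possible when None).
    Deterministic for a fixed ``rng`` seed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    excluded_ids = set()
    for pair in exclude_pairs or []:
        excluded_ids.update(pair.ids())
    eligible = sorted((s for s in spines if s.id not in excluded_ids),
                      key=_axis_position)
    if len(eligible) < 2:
        raise InsufficientDataError(
            f"need >= 2 eligible spines for control pairing, have {len(eligible)}")
    candidates = list(range(len(eligible) - 1))
    order = rng.permutation(len(candidates))
    used: set[int] = set()
    out: list[SpinePair] = []
    for k in order:
        if n_pairs is not None and len(out) >= n_pairs:
            break
        i = candidates[k]
        if i in used or i + 1 in used:
            continue
        a, b = eligible[i], eligible[i + 1]
        out.append(SpinePair(spine_a=a, spine_b=b,
                             head_distance=head_distance(a, b),
                             orientation=classify_orientation(a, b),
                             provenance="control"))
        used.update((i, i + 1))
    out.sort(key=lambda p: p.ids())
    return out


def pairs_to_frame(pairs: list[SpinePair]) -> pd.DataFrame:
    """Tabulate pairs (ids, distance, orientation, provenance) for export."""
    return pd.DataFrame([
        {"spine_a": p.spine_a.id, "spine_b": p.spine_b.id,
         "head_distance_um": p.head_distance, "orientation": p.orientation,
         "provenance": p.provenance}
        for p in pairs])
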