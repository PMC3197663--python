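"""Ground-truthed synthetic scenes of spiny dendrites and presynaptic boutons.

The generator builds a parametric dendritic segment — a straight shaft with
spines at a set linear density, a configurable fraction of the synaptic
profiles being multisynaptic boutons (MSBs) contacting spine pairs — together
with per-frame spine-volume trajectories whose difference-index trend equals a
sampled per-pair dominance rate. Scenes can be rendered into calibrated
two-channel image stacks (channel 0: boutons; channel 1: dendrite fill) so
segmentation, profiling, geometry and dynamics can all be tested against
known truth without any external data.

Defaults mirror the quantitative regime of dissociated hippocampal cultures:
0.75 spines/µm, ~8% MSB profiles, MSB head distances ~N(0.98, 0.12²) µm vs
control ~N(2.53, 0.64²) µm, orientation class odds 14:5:3 (MSB) vs 7:9:6
(control), dominance rates ~N(0.042, 0.004²)/h (MSB pairs) vs
~N(0.002, 0.007²)/h (single-bouton pairs), hourly frames, 0.14 µm pixels and
0.37 µm z-steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .records import ImageStack

ORIENTATION_CLASSES = ("towards", "parallel", "away")
X_MARGIN = 1.0  # µm of field of view on each side of the dendrite

__all__ = [
    "SceneConfig",
    "SpineTruth",
    "BoutonTruth",
    "GroundTruthScene",
    "PairSeries",
    "generate_scene",
    "render_stack",
    "sample_spine_pairs",
    "sample_pair_dynamics",
    "write_truth_tables",
    "read_truth_tables",
]


@dataclass
class SceneConfig:
    """All knobs of the synthetic scene, in physical units.

    Lengths are µm, times hours, rates ΔDiffIndex/h. ``intensity_noise_sd``
    is the relative (fractional) Gaussian noise applied both to rendered
    voxel intensities and to tabular integrated-density measurements.
    """

    dendrite_length: float = 40.0
    spine_density: float = 0.75
    msb_pair_fraction: float = 0.08
    msb_head_distance_mean: float = 0.98
    msb_head_distance_sd: float = 0.12
    control_head_distance_mean: float = 2.53
    control_head_distance_sd: float = 0.64
    orientation_probs_msb: tuple[float, float, float] = (14 / 22, 5 / 22, 3 / 22)
    orientation_probs_control: tuple[float, float, float] = (7 / 22, 9 / 22, 6 / 22)
    dominance_rate_mean_msb: float = 0.042
    dominance_rate_sd_msb: float = 0.004
    dominance_rate_mean_ssb: float = 0.002
    dominance_rate_sd_ssb: float = 0.007
    intensity_noise_sd: float = 0.05
    n_frames: int = 16
    frame_interval: float = 1.0
    pixel_size_xy: float = 0.14
    z_step: float = 0.37
    psf_sigma_xy: float = 0.20
    psf_sigma_z: float = 0.50
    # scene-building details not tied to a reported statistic
    min_head_distance: float = 0.05
    orientation_offset: float = 0.5  # |base dist - head dist| for towards/away, µm
    spine_height_mean: float = 1.2
    spine_height_sd: float = 0.1
    base_volume: float = 20000.0  # initial spine integrated density, a.u.
    volume_floor_frac: float = 0.05
    shrinkage_mode: str = "linear_volume"  # or "abrupt"
    shaft_radius: float = 0.25
    shaft_peak: float = 300.0  # shaft amplitude, detector counts
    bouton_radius: float = 0.30
    bouton_volume: float = 12000.0
    bouton_offset: float = 0.45  # bouton centre above spine head, µm
    detector_max: int = 65535
    seed: int = 0

    def validate(self) -> None:
        positive = (
            "dendrite_length",
            "msb_head_distance_mean",
            "msb_head_distance_sd",
            "control_head_distance_mean",
            "control_head_distance_sd",
            "frame_interval",
            "pixel_size_xy",
            "z_step",
            "psf_sigma_xy",
            "psf_sigma_z",
            "min_head_distance",
            "spine_height_mean",
            "base_volume",
            "shaft_radius",
            "bouton_radius",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name}: must be > 0, got {getattr(self, name)!r}")
        for name in ("spine_density", "intensity_noise_sd", "dominance_rate_sd_msb",
                     "dominance_rate_sd_ssb", "spine_height_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be >= 0, got {getattr(self, name)!r}")
        if not 0 <= self.msb_pair_fraction < 1:
            raise ConfigError(
                f"msb_pair_fraction: must be in [0, 1), got {self.msb_pair_fraction!r}")
        for name in ("orientation_probs_msb", "orientation_probs_control"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if probs.shape != (3,) or (probs < 0).any():
                raise ConfigError(f"{name}: need 3 non-negative entries")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities must sum to 1 (got {probs.sum()})")
        if self.n_frames < 2:
            raise ConfigError(f"n_frames: must be >= 2, got {self.n_frames!r}")
        if not 0 < self.volume_floor_frac < 1:
            raise ConfigError("volume_floor_frac: must be in (0, 1)")
        if self.shrinkage_mode not in ("linear_volume", "abrupt"):
            raise ConfigError(
                f"shrinkage_mode: must be 'linear_volume' or 'abrupt', got {self.shrinkage_mode!r}")

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class SpineTruth:
    """One spine of the ground truth: static geometry plus volume trajectory."""

    id: int
    base_um: tuple[float, float, float]
    head_um: np.ndarray  # (n_frames, 3) x,y,z µm
    volume: np.ndarray  # (n_frames,) integrated density, a.u.
    pair_id: int | None = None
    role: str = "unpaired"  # dominant | nondominant | unpaired
    pair_class: str | None = None  # msb | ssb | None
    truth_rate: float | None = None
    orientation: str | None = None
    retracted_frame: int | None = None


@dataclass
class BoutonTruth:
    id: int
    center_um: tuple[float, float, float]
    radius_um: float
    spine_ids: tuple[int, ...]
    label: str  # msb | single


@dataclass
class GroundTruthScene:
    config: SceneConfig
    spines: list[SpineTruth]
    boutons: list[BoutonTruth]
    shaft_y: float
    shaft_z: float

    def pairs(self, pair_class: str | None = None) -> dict[int, tuple[SpineTruth, SpineTruth]]:
        """Truth pairs keyed by pair id, optionally filtered by class."""
        out: dict[int, list[SpineTruth]] = {}
        for sp in self.spines:
            if sp.pair_id is None:
                continue
            if pair_class is not None and sp.pair_class != pair_class:
                continue
            out.setdefault(sp.pair_id, []).append(sp)
        return {k: tuple(sorted(v, key=lambda s: s.id)) for k, v in out.items()
                if len(v) == 2}

    def truth_diff_index(self, pair_id: int) -> np.ndarray:
        """Noise-free DiffIndex series of a truth pair (dominant preselected)."""
        a, b = self.pairs()[pair_id]
        dom, non = (a, b) if a.volume.mean() >= b.volume.mean() else (b, a)
        total = dom.volume + non.volume
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, (dom.volume - non.volume) / total, np.nan)


@dataclass
class PairSeries:
    """Tabular measured dynamics of one spine pair (no rendering involved)."""

    pair_id: int
    pair_class: str
    times: np.ndarray
    intden_a: np.ndarray
    intden_b: np.ndarray
    truth_rate: float


def _rng_for(config: SceneConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per purpose
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _truncated_normal(rng, mean, sd, lower, size=None):
    """Resampling-based truncated normal; fine for mild truncation."""
    x = rng.normal(mean, sd, size=size)
    bad = x < lower
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = x < lower
    return x


def _base_distance_for(orientation: str, dh: float, offset: float) -> float:
    if orientation == "towards":
        return dh + offset
    if orientation == "parallel":
        return dh
    return max(dh - offset, 0.15)  # away; bases closer than heads


def _pair_volume_trajectories(rng, config: SceneConfig, rate: float,
                              eps_range: float) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Volume series (dominant, nondominant) with truth DiffIndex slope ``rate``.

    Total pair volume is held constant, so a linear DiffIndex is exactly a
    linear exchange of volume. The initial asymmetry is kept consistent with
    the trend sign — the spine carrying the sampled trend is the one with the
    higher window-mean volume — so that mean-density preselection recovers
    the sampled rate (sign included) and the fitted-rate distribution
    converges to the configured one. The nondominant spine floors at
    ``volume_floor_frac`` of its initial volume, after which it is retracted
    (volume 0).
    """
    v = config.base_volume * rng.normal(1.0, 0.05)
    t = config.times()
    eps = rng.uniform(0.0, eps_range)
    d0 = max(eps, 0.03 - rate * float(t.mean()))
    v_dom0, v_non0 = v * (1 + d0), v * (1 - d0)
    total = v_dom0 + v_non0
    d = d0 + rate * t
    d_floor = 1.0 - 2.0 * config.volume_floor_frac * v_non0 / total
    retracted = None
    hit = np.nonzero(d > d_floor)[0]
    if hit.size:
        retracted = int(hit[0])
        if config.shrinkage_mode == "linear_volume":
            d = np.minimum(d, d_floor)
    d = np.clip(d, -1.0, 1.0)
    v_dom = total * (1 + d) / 2
    v_non = total * (1 - d) / 2
    if retracted is not None:
        if config.shrinkage_mode == "abrupt":
            v_non = np.where(t < t[retracted], v_non0, 0.0)
            v_dom = np.where(t < t[retracted], v_dom0, total)
        else:
            v_non[retracted:] = 0.0
            v_dom[retracted:] = total
    return v_dom, v_non, retracted


def _make_pair_spines(rng, config: SceneConfig, ids: tuple[int, int], pair_id: int,
                      xc: float, shaft_y: float, shaft_z: float, kind: str,
                      pair_class: str) -> list[SpineTruth]:
    """Two spines sharing a bouton-style geometry around x-centre ``xc``."""
    if kind == "msb":
        dh = float(_truncated_normal(rng, config.msb_head_distance_mean,
                                     config.msb_head_distance_sd,
                                     config.min_head_distance))
        probs = config.orientation_probs_msb
    else:
        dh = float(_truncated_normal(rng, config.control_head_distance_mean,
                                     config.control_head_distance_sd,
                                     config.min_head_distance))
        probs = config.orientation_probs_control
    orientation = str(rng.choice(ORIENTATION_CLASSES, p=np.asarray(probs, float)))
    db = _base_distance_for(orientation, dh, config.orientation_offset)
    height = float(_truncated_normal(rng, config.spine_height_mean,
                                     config.spine_height_sd, 0.6))
    rate_mean, rate_sd = ((config.dominance_rate_mean_msb, config.dominance_rate_sd_msb)
                          if pair_class == "msb"
                          else (config.dominance_rate_mean_ssb, config.dominance_rate_sd_ssb))
    rate = float(rng.normal(rate_mean, rate_sd))
    eps_range = 0.05 if pair_class == "msb" else 0.15
    v_dom, v_non, retracted = _pair_volume_trajectories(rng, config, rate, eps_range)
    dom_first = bool(rng.integers(2))
    spines = []
    for i, (sid, sign) in enumerate(zip(ids, (-1.0, 1.0))):
        base = (xc + sign * db / 2, shaft_y, shaft_z)
        head = np.tile([xc + sign * dh / 2, shaft_y + height, shaft_z],
                       (config.n_frames, 1))
        is_dom = (i == 0) == dom_first
        spines.append(SpineTruth(
            id=sid, base_um=base, head_um=head,
            volume=(v_dom if is_dom else v_non).copy(),
            pair_id=pair_id, role="dominant" if is_dom else "nondominant",
            pair_class=pair_class, truth_rate=rate, orientation=orientation,
            retracted_frame=None if is_dom else retracted))
    return spines


def generate_scene(config: SceneConfig) -> GroundTruthScene:
    """Build a ground-truth scene from a validated configuration.

    Deterministic for a fixed ``config.seed``. Spine count is
    ``round(spine_density * dendrite_length)``; the number of MSB pairs is
    chosen so that MSB profiles make up ``msb_pair_fraction`` of synaptic
    profiles (an MSB pair shares one bouton, every other spine gets its own).
    Remaining spines are grouped into adjacent single-bouton ("SSB") truth
    pairs whose volume trajectories carry the slow SSB dominance rates.
    """
    config.validate()
    rng = _rng_for(config, 0)
    n_spines = int(round(config.spine_density * config.dendrite_length))
    shaft_y, shaft_z = 1.5, 2.2

    if n_spines == 0:
        return GroundTruthScene(config, [], [], shaft_y, shaft_z)

    n_pairs = int(round(config.msb_pair_fraction * n_spines
                        / (1.0 + config.msb_pair_fraction)))
    n_pairs = min(n_pairs, n_spines // 2)

    spacing = config.dendrite_length / n_spines
    slots = X_MARGIN + (np.arange(n_spines) + 0.5) * spacing
    slots = slots + rng.uniform(-0.1, 0.1, size=n_spines) * spacing

    # non-overlapping adjacent slot pairs become MSB pairs
    pair_starts: list[int] = []
    candidates = list(rng.permutation(n_spines - 1)) if n_spines > 1 else []
    taken = np.zeros(n_spines, dtype=bool)
    for c in candidates:
        if len(pair_starts) == n_pairs:
            break
        if not taken[c] and not taken[c + 1]:
            pair_starts.append(int(c))
            taken[c] = taken[c + 1] = True

    spines: list[SpineTruth] = []
    next_pair = 0
    for start in sorted(pair_starts):
        xc = float((slots[start] + slots[start + 1]) / 2)
        spines.extend(_make_pair_spines(
            rng, config, (start, start + 1), next_pair, xc,
            shaft_y, shaft_z, kind="msb", pair_class="msb"))
        next_pair += 1

    # leftover spines: adjacent pairs with SSB-like slow trajectories
    leftovers = [i for i in range(n_spines) if not taken[i]]
    ssb_groups = [tuple(leftovers[i:i + 2]) for i in range(0, len(leftovers) - 1, 2)]
    grouped = {s for g in ssb_groups for s in g}
    for ga, gb in ssb_groups:
        rate = float(rng.normal(config.dominance_rate_mean_ssb,
                                config.dominance_rate_sd_ssb))
        v_dom, v_non, _ = _pair_volume_trajectories(rng, config, rate, 0.15)
        dom_first = bool(rng.integers(2))
        for i, sid in enumerate((ga, gb)):
            height = float(_truncated_normal(rng, config.spine_height_mean,
                                             config.spine_height_sd, 0.6))
            bx = float(slots[sid])
            hx = bx + float(rng.uniform(-0.1, 0.1))
            is_dom = (i == 0) == dom_first
            spines.append(SpineTruth(
                id=sid, base_um=(bx, shaft_y, shaft_z),
                head_um=np.tile([hx, shaft_y + height, shaft_z], (config.n_frames, 1)),
                volume=(v_dom if is_dom else v_non).copy(),
                pair_id=next_pair, role="dominant" if is_dom else "nondominant",
                pair_class="ssb", truth_rate=rate))
        next_pair += 1
    for sid in leftovers:
        if sid in grouped:
            continue
        height = float(_truncated_normal(rng, config.spine_height_mean,
                                         config.spine_height_sd, 0.6))
        bx = float(slots[sid])
        v = config.base_volume * rng.normal(1.0, 0.05) * np.ones(config.n_frames)
        spines.append(SpineTruth(
            id=sid, base_um=(bx, shaft_y, shaft_z),
            head_um=np.tile([bx + float(rng.uniform(-0.1, 0.1)),
                             shaft_y + height, shaft_z], (config.n_frames, 1)),
            volume=v))
    spines.sort(key=lambda s: s.id)

    # boutons: one per MSB pair (shared), one per remaining spine
    boutons: list[BoutonTruth] = []
    bid = 0
    for pid, (a, b) in sorted(generate_scene_pairs(spines, "msb").items()):
        mid = (a.head_um[0] + b.head_um[0]) / 2
        boutons.append(BoutonTruth(
            id=bid, center_um=(float(mid[0]), float(mid[1] + config.bouton_offset),
                               float(mid[2])),
            radius_um=config.bouton_radius, spine_ids=(a.id, b.id), label="msb"))
        bid += 1
    msb_spine_ids = {s.id for s in spines if s.pair_class == "msb"}
    for sp in spines:
        if sp.id in msb_spine_ids:
            continue
        hx, hy, hz = sp.head_um[0]
        boutons.append(BoutonTruth(
            id=bid, center_um=(float(hx), float(hy + config.bouton_offset), float(hz)),
            radius_um=config.bouton_radius, spine_ids=(sp.id,), label="single"))
        bid += 1

    return GroundTruthScene(config, spines, boutons, shaft_y, shaft_z)


def generate_scene_pairs(spines: list[SpineTruth], pair_class: str
                         ) -> dict[int, tuple[SpineTruth, SpineTruth]]:
    out: dict[int, list[SpineTruth]] = {}
    for sp in spines:
        if sp.pair_id is not None and sp.pair_class == pair_class:
            out.setdefault(sp.pair_id, []).append(sp)
    return {k: tuple(sorted(v, key=lambda s: s.id)) for k, v in out.items()
            if len(v) == 2}


def sample_spine_pairs(config: SceneConfig, n_pairs: int, kind: str,
                       rng: np.random.Generator | None = None) -> list[dict]:
    """Sample isolated spine-pair geometries without building a whole scene.

    ``kind`` is ``"msb"`` (shared-bouton pairs: head distances from the MSB
    distribution, MSB orientation odds) or ``"control"`` (random adjacent
    pairs: control distributions). Each returned dict holds the truth draw
    (``head_distance``, ``base_distance``, ``orientation``) plus head/base
    coordinates laid out so the draws are realised exactly.
    """
    if kind not in ("msb", "control"):
        raise ConfigError(f"kind: must be 'msb' or 'control', got {kind!r}")
    config.validate()
    if rng is None:
        rng = _rng_for(config, 2 if kind == "msb" else 3)
    if kind == "msb":
        mean, sd = config.msb_head_distance_mean, config.msb_head_distance_sd
        probs = np.asarray(config.orientation_probs_msb, float)
    else:
        mean, sd = config.control_head_distance_mean, config.control_head_distance_sd
        probs = np.asarray(config.orientation_probs_control, float)
    dh = _truncated_normal(rng, mean, sd, config.min_head_distance, size=n_pairs)
    orientation = rng.choice(ORIENTATION_CLASSES, size=n_pairs, p=probs)
    heights = _truncated_normal(rng, config.spine_height_mean,
                                config.spine_height_sd, 0.6, size=n_pairs)
    out = []
    for i in range(n_pairs):
        db = _base_distance_for(str(orientation[i]), float(dh[i]),
                                config.orientation_offset)
        h = float(heights[i])
        out.append({
            "kind": kind,
            "head_distance": float(dh[i]),
            "base_distance": db,
            "orientation": str(orientation[i]),
            "head_a": (-dh[i] / 2, h, 0.0),
            "head_b": (dh[i] / 2, h, 0.0),
            "base_a": (-db / 2, 0.0, 0.0),
            "base_b": (db / 2, 0.0, 0.0),
        })
    return out


def sample_pair_dynamics(config: SceneConfig, n_pairs: int, pair_class: str,
                         rng: np.random.Generator | None = None) -> list[PairSeries]:
    """Sample measured integrated-density series for spine pairs.

    Truth volume trajectories follow the class dominance-rate distribution;
    the measured series multiply each frame by ``1 + N(0, intensity_noise_sd)``
    (independent per spine per frame), emulating measurement noise on the
    integrated density without rendering images.
    """
    if pair_class not in ("msb", "ssb"):
        raise ConfigError(f"pair_class: must be 'msb' or 'ssb', got {pair_class!r}")
    config.validate()
    if rng is None:
        rng = _rng_for(config, 4 if pair_class == "msb" else 5)
    rate_mean, rate_sd = ((config.dominance_rate_mean_msb, config.dominance_rate_sd_msb)
                          if pair_class == "msb"
                          else (config.dominance_rate_mean_ssb, config.dominance_rate_sd_ssb))
    eps_range = 0.05 if pair_class == "msb" else 0.15
    t = config.times()
    out = []
    for pid in range(n_pairs):
        rate = float(rng.normal(rate_mean, rate_sd))
        v_dom, v_non, _ = _pair_volume_trajectories(rng, config, rate, eps_range)
        noise = rng.normal(1.0, config.intensity_noise_sd, size=(2, config.n_frames))
        out.append(PairSeries(
            pair_id=pid, pair_class=pair_class, times=t.copy(),
            intden_a=np.maximum(v_dom * noise[0], 0.0),
            intden_b=np.maximum(v_non * noise[1], 0.0),
            truth_rate=rate))
    return out


# ---------------------------------------------------------------------------
# rendering

def _fov_shape(config: SceneConfig, shaft_y: float, shaft_z: float
               ) -> tuple[int, int, int]:
    y_extent = shaft_y + config.spine_height_mean + 4 * config.spine_height_sd \
        + config.bouton_offset + 3 * config.bouton_radius + 0.5
    z_extent = 2 * shaft_z
    nz = max(int(math.ceil(z_extent / config.z_step)), 1)
    ny = max(int(math.ceil(y_extent / config.pixel_size_xy)), 1)
    # dendrite runs from x = X_MARGIN with a matching margin on the right
    nx = max(int(math.ceil((config.dendrite_length + 2 * X_MARGIN)
                           / config.pixel_size_xy)), 1)
    return nz, ny, nx


def _add_blob(vol: np.ndarray, center_um, sigmas_um, total, config: SceneConfig
              ) -> None:
    """Add an anisotropic Gaussian blob with summed intensity ≈ ``total``.

    Voxel values sample the continuous density at voxel centres scaled by the
    voxel volume; at the default sigma/voxel ratios the discrete sum matches
    the analytic integral to well under 1%.
    """
    if total <= 0:
        return
    nz, ny, nx = vol.shape
    px, pz = config.pixel_size_xy, config.z_step
    cx, cy, cz = center_um
    sx, sy, sz = sigmas_um
    x0, x1 = int((cx - 4 * sx) // px), int((cx + 4 * sx) // px) + 1
    y0, y1 = int((cy - 4 * sy) // px), int((cy + 4 * sy) // px) + 1
    z0, z1 = int((cz - 4 * sz) // pz), int((cz + 4 * sz) // pz) + 1
    # warn only when a substantial (±2σ) part of the object is clipped
    if (cx - 2 * sx < 0 or cx + 2 * sx > nx * px
            or cy - 2 * sy < 0 or cy + 2 * sy > ny * px
            or cz - 2 * sz < 0 or cz + 2 * sz > nz * pz):
        warnings.warn("scene object extends outside the field of view; clipping",
                      stacklevel=3)
    x0, y0, z0 = max(x0, 0), max(y0, 0), max(z0, 0)
    x1, y1, z1 = min(x1, nx), min(y1, ny), min(z1, nz)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) + 0.5) * px
    ys = (np.arange(y0, y1) + 0.5) * px
    zs = (np.arange(z0, z1) + 0.5) * pz
    gx = np.exp(-0.5 * ((xs - cx) / sx) ** 2)
    gy = np.exp(-0.5 * ((ys - cy) / sy) ** 2)
    gz = np.exp(-0.5 * ((zs - cz) / sz) ** 2)
    norm = total * (px * px * pz) / ((2 * np.pi) ** 1.5 * sx * sy * sz)
    vol[z0:z1, y0:y1, x0:x1] += norm * gz[:, None, None] * gy[None, :, None] \
        * gx[None, None, :]


def render_stack(scene: GroundTruthScene, config: SceneConfig | None = None
                 ) -> ImageStack:
    """Render a scene into a calibrated T,Z,C,Y,X uint16 stack.

    Channel 0 renders boutons, channel 1 the dendritic shaft plus spine
    heads; each object is an anisotropic Gaussian blob whose summed
    intensity is proportional to its truth volume. Additive Gaussian noise
    with per-voxel s.d. ``intensity_noise_sd ×`` the noise-free signal is
    applied, then intensities are rounded and clipped to the detector range.
    Bit-identical for a fixed seed.
    """
    if config is None:
        config = scene.config
    config.validate()
    nz, ny, nx = _fov_shape(config, scene.shaft_y, scene.shaft_z)
    data = np.zeros((config.n_frames, nz, 2, ny, nx), dtype=np.float64)
    sig_spine = (config.psf_sigma_xy, config.psf_sigma_xy, config.psf_sigma_z)
    sig_bouton = (config.bouton_radius, config.bouton_radius,
                  max(config.bouton_radius, config.psf_sigma_z))

    # shaft: uniform along x, Gaussian cross-section (fill channel)
    ys = (np.arange(ny) + 0.5) * config.pixel_size_xy
    zs = (np.arange(nz) + 0.5) * config.z_step
    cross = config.shaft_peak * np.exp(
        -0.5 * (((ys[None, :] - scene.shaft_y) ** 2
                 + (zs[:, None] - scene.shaft_z) ** 2) / config.shaft_radius ** 2))
    xs = (np.arange(nx) + 0.5) * config.pixel_size_xy
    along = ((xs >= X_MARGIN)
             & (xs <= X_MARGIN + config.dendrite_length)).astype(float)
    shaft = cross[:, :, None] * along[None, None, :]

    spine_by_id = {sp.id: sp for sp in scene.spines}
    for t in range(config.n_frames):
        data[t, :, 1] += shaft
        for sp in scene.spines:
            _add_blob(data[t, :, 1], tuple(sp.head_um[t]), sig_spine,
                      float(sp.volume[t]), config)
        for bt in scene.boutons:
            # multisynaptic boutons are elongated to span their spine heads
            xs = [spine_by_id[i].head_um[0, 0] for i in bt.spine_ids
                  if i in spine_by_id]
            span = (max(xs) - min(xs)) if len(xs) > 1 else 0.0
            sig = (sig_bouton[0] + 0.3 * span, sig_bouton[1], sig_bouton[2])
            _add_blob(data[t, :, 0], bt.center_um, sig,
                      config.bouton_volume * (1 + span), config)

    if config.intensity_noise_sd > 0:
        rng = _rng_for(config, 1)
        data = data + rng.standard_normal(data.shape) * (config.intensity_noise_sd * data)
    data = np.clip(np.rint(data), 0, config.detector_max).astype(np.uint16)
    return ImageStack(data=data, pixel_size_xy=config.pixel_size_xy,
                      z_step=config.z_step, frame_interval=config.frame_interval)


# ---------------------------------------------------------------------------
# truth tables

def write_truth_tables(scene: GroundTruthScene, directory) -> dict[str, str]:
    """Write the scene as CSV tables plus a YAML config; returns the paths.

    ``spines.csv`` has one row per spine per frame; ``boutons.csv`` one row
    per bouton. Round-trips losslessly through :func:`read_truth_tables`.
    """
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = scene.config
    rows = []
    for sp in scene.spines:
        for t in range(cfg.n_frames):
            rows.append({
                "spine_id": sp.id, "frame": t,
                "time_h": t * cfg.frame_interval,
                "head_x": sp.head_um[t, 0], "head_y": sp.head_um[t, 1],
                "head_z": sp.head_um[t, 2],
                "base_x": sp.base_um[0], "base_y": sp.base_um[1],
                "base_z": sp.base_um[2],
                "volume": sp.volume[t],
                "pair_id": sp.pair_id, "role": sp.role,
                "pair_class": sp.pair_class, "truth_rate": sp.truth_rate,
                "orientation": sp.orientation,
                "retracted_frame": sp.retracted_frame,
            })
    spine_cols = ["spine_id", "frame", "time_h", "head_x", "head_y", "head_z",
                  "base_x", "base_y", "base_z", "volume", "pair_id", "role",
                  "pair_class", "truth_rate", "orientation", "retracted_frame"]
    spines_path = directory / "spines.csv"
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows, columns=spine_cols).to_csv(spines_path, index=False,
                                                  float_format="%.17g")
    brows = [{"bouton_id": b.id, "x": b.center_um[0], "y": b.center_um[1],
              "z": b.center_um[2], "radius": b.radius_um,
              "spine_ids": ";".join(str(s) for s in b.spine_ids),
              "label": b.label} for b in scene.boutons]
    boutons_path = directory / "boutons.csv"
    pd.DataFrame(brows, columns=["bouton_id", "x", "y", "z", "radius",
                                 "spine_ids", "label"]).to_csv(
        boutons_path, index=False, float_format="%.17g")
    config_path = directory / "scene_config.yaml"
    meta = asdict(cfg) | {"shaft_y": scene.shaft_y, "shaft_z": scene.shaft_z}
    with open(config_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return {"spines": str(spines_path), "boutons": str(boutons_path),
            "config": str(config_path)}


def read_truth_tables(directory) -> GroundTruthScene:
    """Reconstruct a :class:`GroundTruthScene` written by :func:`write_truth_tables`."""
    from pathlib import Path
    directory = Path(directory)
    with open(directory / "scene_config.yaml") as fh:
        meta = yaml.safe_load(fh)
    shaft_y = meta.pop("shaft_y")
    shaft_z = meta.pop("shaft_z")
    for key in ("orientation_probs_msb", "orientation_probs_control"):
        meta[key] = tuple(meta[key])
    config = SceneConfig(**meta)
    spines_df = pd.read_csv(directory / "spines.csv",
                            float_precision="round_trip")
    spines: list[SpineTruth] = []
    if len(spines_df):
        for sid, grp in spines_df.groupby("spine_id", sort=True):
            grp = grp.sort_values("frame")
            first = grp.iloc[0]

            def _opt(v):
                return None if pd.isna(v) else v
            pair_id = _opt(first["pair_id"])
            retr = _opt(first["retracted_frame"])
            spines.append(SpineTruth(
                id=int(sid),
                base_um=(float(first["base_x"]), float(first["base_y"]),
                         float(first["base_z"])),
                head_um=grp[["head_x", "head_y", "head_z"]].to_numpy(float),
                volume=grp["volume"].to_numpy(float),
                pair_id=None if pair_id is None else int(pair_id),
                role=str(first["role"]),
                pair_class=_opt(first["pair_class"]),
                truth_rate=_opt(first["truth_rate"]),
                orientation=_opt(first["orientation"]),
                retracted_frame=None if retr is None else int(retr)))
    boutons_df = pd.read_csv(directory / "boutons.csv",
                             float_precision="round_trip")
    boutons = []
    for _, row in boutons_df.iterrows():
        sids = tuple(int(s) for s in str(row["spine_ids"]).split(";") if s != "")
        boutons.append(BoutonTruth(
            id=int(row["bouton_id"]),
            center_um=(float(row["x"]), float(row["y"]), float(row["z"])),
            radius_um=float(row["radius"]), spine_ids=sids, label=str(row["label"])))
    return GroundTruthScene(config, spines, boutons, shaft_y, shaft_z)
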