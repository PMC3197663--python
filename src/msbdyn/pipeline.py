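"""End-to-end analysis: rendered scene → synapse census → pair dynamics.

One call runs the whole chain without manual steps: segment boutons and
spine heads on the first frame, classify synaptic profiles, apply the MSB
spine-pair criteria, pair single-bouton spines with their nearest neighbors,
measure each pair's integrated-density series over time with a fixed ball
aperture at the tracked head position, fit dominance rates, and compare the
two classes. When the input is a synthetic scene the report also scores
recovery of the ground truth.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from . import dynamics as dyn
from . import imageops as ops
from .errors import InsufficientDataError
from .geometry import SpinePair, classify_orientation, head_distance, spine_density
from .profiles import classify_profiles, identify_msb_pairs
from .records import FILL_CHANNEL, PRESYNAPTIC_CHANNEL, ImageStack, SpineRecord
from .synthetic import GroundTruthScene, SceneConfig, generate_scene, render_stack

__all__ = ["run_pipeline", "analyze_stack", "match_points"]

MATCH_TOLERANCE_UM = 0.3
MEASURE_RADIUS_UM = 0.45


def match_points(truth_xyz: np.ndarray, found_xyz: np.ndarray,
                 tolerance: float = MATCH_TOLERANCE_UM) -> dict:
    """Greedy one-to-one matching of truth to detected points.

    Candidate pairs within ``tolerance`` (µm) are matched nearest-first.
    Returns the matched index pairs and the recovered fraction of truth.
    """
    truth_xyz = np.asarray(truth_xyz, dtype=float)
    found_xyz = np.asarray(found_xyz, dtype=float)
    if len(truth_xyz) == 0 or len(found_xyz) == 0:
        return {"matches": [], "recovered_fraction": 0.0 if len(truth_xyz) else 1.0}
    tree = cKDTree(found_xyz)
    pairs = []
    for i, p in enumerate(truth_xyz):
        for j in tree.query_ball_point(p, r=tolerance):
            pairs.append((float(np.linalg.norm(p - found_xyz[j])), i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_f: set[int] = set()
    matches = []
    for d, i, j in pairs:
        if i in used_t or j in used_f:
            continue
        matches.append((i, j, d))
        used_t.add(i)
        used_f.add(j)
    return {"matches": matches,
            "recovered_fraction": len(matches) / len(truth_xyz)}


def _measure_pair_series(stack: ImageStack, spine_a: SpineRecord,
                         spine_b: SpineRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrated-density series of two heads with a fixed ball aperture."""
    shape = stack.frame(0, FILL_CHANNEL).shape
    regions = [ops.ball_region(shape, s.head_um, MEASURE_RADIUS_UM,
                               pixel_size_xy=stack.pixel_size_xy,
                               z_step=stack.z_step) for s in (spine_a, spine_b)]
    times = stack.times()
    series = np.zeros((2, stack.n_frames))
    for t in range(stack.n_frames):
        vol = ops.despeckle_outliers(stack.frame(t, FILL_CHANNEL))
        for k, region in enumerate(regions):
            series[k, t] = ops.integrated_density(vol, region)
    return times, series[0], series[1]


def analyze_stack(stack: ImageStack, *, window_h: float = dyn.DEFAULT_WINDOW_H,
                  punctum_threshold_rel: float = 0.5,
                  spine_threshold_rel: float = 0.25) -> dict:
    """Analyze a calibrated two-channel stack; returns the full report."""
    calib = dict(pixel_size_xy=stack.pixel_size_xy, z_step=stack.z_step)
    boutons = ops.segment_puncta(stack.frame(0, PRESYNAPTIC_CHANNEL),
                                 threshold_rel=punctum_threshold_rel,
                                 channel=PRESYNAPTIC_CHANNEL, **calib)
    fill0 = stack.frame(0, FILL_CHANNEL)
    shaft_mask = ops.detect_shaft_mask(fill0, pixel_size_xy=stack.pixel_size_xy)
    spines = ops.segment_spine_heads(fill0, shaft_mask,
                                     threshold_rel=spine_threshold_rel, **calib)
    profiles, opposites, summary = classify_profiles(boutons, spines)

    length = ops.shaft_length(shaft_mask, stack.pixel_size_xy)
    density = spine_density(spines, length) if length > 0 else None

    candidate_pairs = []
    for profile in profiles:
        partners = [p for p in profile.partners if isinstance(p, SpineRecord)]
        for a, b in combinations(partners, 2):
            candidate_pairs.append(SpinePair(
                spine_a=a, spine_b=b, head_distance=head_distance(a, b),
                orientation=classify_orientation(a, b)))
    msb_pairs = identify_msb_pairs(profiles, candidate_pairs)
    msb_ids = {i for p in msb_pairs for i in p.ids()}

    ssb_spines = []
    for profile in profiles:
        if profile.label != "single":
            continue
        partner = profile.partners[0]
        if isinstance(partner, SpineRecord) and partner.id not in msb_ids:
            ssb_spines.append(partner)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ssb_pairs = dyn.pair_ssb_neighbors(ssb_spines, spines)

    msb_dyn, ssb_dyn = [], []
    for pair_class, pairs in (("msb", [(p.spine_a, p.spine_b) for p in msb_pairs]),
                              ("ssb", ssb_pairs)):
        for k, (a, b) in enumerate(pairs):
            times, sa, sb = _measure_pair_series(stack, a, b)
            try:
                pd_ = dyn.pair_dynamics(k, pair_class, times, sa, sb,
                                        id_a=a.id, id_b=b.id, window_h=window_h)
            except InsufficientDataError:
                continue
            (msb_dyn if pair_class == "msb" else ssb_dyn).append(pd_)

    try:
        comparison = dyn.compare_classes(msb_dyn, ssb_dyn)
    except InsufficientDataError:
        comparison = None
    return {
        "boutons": boutons, "spines": spines,
        "profiles": profiles, "opposites": opposites, "summary": summary,
        "dendrite_length_um": length, "spine_density_per_um": density,
        "msb_pairs": msb_pairs, "ssb_pairs": ssb_pairs,
        "msb_dynamics": msb_dyn, "ssb_dynamics": ssb_dyn,
        "comparison": comparison,
    }


def run_pipeline(config: SceneConfig, scene: GroundTruthScene | None = None
                 ) -> dict:
    """Generate (or take) a scene, render it, analyze it, score recovery."""
    if scene is None:
        scene = generate_scene(config)
    stack = render_stack(scene, config)
    report = analyze_stack(stack)

    truth_heads = np.array([s.head_um[0] for s in scene.spines]).reshape(-1, 3)
    found_heads = np.array([s.head_um for s in report["spines"]]).reshape(-1, 3)
    truth_boutons = np.array([b.center_um for b in scene.boutons]).reshape(-1, 3)
    found_boutons = np.array([b.centroid_um for b in report["boutons"]]).reshape(-1, 3)
    report["scene"] = scene
    report["stack"] = stack
    report["spine_recovery"] = match_points(truth_heads, found_heads)
    report["bouton_recovery"] = match_points(truth_boutons, found_boutons)
    return report
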