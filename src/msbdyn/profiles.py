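"""Synaptic-profile classification from pre/postsynaptic contacts.

A presynaptic bouton "contacts" a postsynaptic object when their segmented
regions overlap or abut (boundary gap within one pixel by default). A bouton
with two or more postsynaptic partners fits the multisynaptic-bouton (MSB)
profile; one partner is a single profile. The converse arrangement — one
postsynaptic punctum contacted by several boutons — is the "opposite"
profile. For live imaging, candidate MSB spine pairs must additionally share
a bouton, have head centres within 1.3 µm and be angled towards each other
or parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import CalibrationError, ConfigError
from .geometry import SpinePair
from .records import PunctumRecord, SpineRecord

DEFAULT_CONTACT_GAP_UM = 0.14  # one pixel: "abutting"
DEFAULT_MAX_HEAD_DISTANCE_UM = 1.3

__all__ = [
    "SynapticProfile",
    "OppositeProfile",
    "detect_contacts",
    "classify_profiles",
    "identify_msb_pairs",
    "passes_msb_criteria",
    "DEFAULT_CONTACT_GAP_UM",
    "DEFAULT_MAX_HEAD_DISTANCE_UM",
]


@dataclass
class SynapticProfile:
    """One bouton and all postsynaptic partners it contacts."""

    bouton: PunctumRecord
    partners: list
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.partners:
            raise ConfigError("partners: a synaptic profile needs >= 1 partner")
        self.label = "msb" if len(self.partners) >= 2 else "single"


@dataclass
class OppositeProfile:
    """One postsynaptic object contacted by multiple boutons."""

    postsynaptic: object
    boutons: list

    def __post_init__(self) -> None:
        if len(self.boutons) < 2:
            raise ConfigError("boutons: an opposite profile needs >= 2 boutons")


def _calibration_of(obj) -> tuple[float, float | None]:
    return (getattr(obj, "pixel_size_xy", None), getattr(obj, "z_step", None))


def region_gap_um(region_a: np.ndarray, region_b: np.ndarray,
                  sizes: np.ndarray) -> float:
    """Minimum boundary-to-boundary distance (µm) between two voxel sets.

    Voxels are axis-aligned boxes; the gap between two boxes along one axis
    is ``max(0, |Δindex| − 1) × size`` and 0 for overlapping or 8/26-adjacent
    voxels. Computed exactly over all voxel pairs.
    """
    a = np.asarray(region_a)[:, None, :]
    b = np.asarray(region_b)[None, :, :]
    per_axis = np.maximum(np.abs(a - b) - 1, 0) * sizes
    return float(np.sqrt((per_axis ** 2).sum(axis=2)).min())


def detect_contacts(set_a: list, set_b: list,
                    contact_gap: float = DEFAULT_CONTACT_GAP_UM) -> list[tuple]:
    """Find abutting-or-overlapping pairs between two sets of segmented objects.

    ``(a, b)`` is a contact iff their voxel regions share a voxel, or the
    minimum boundary-to-boundary distance is at most ``contact_gap`` (µm).
    All objects must carry regions on the same calibrated grid. A KD-tree
    over physical voxel centres prefilters candidate pairs; the exact box
    gap is then computed per candidate.
    """
    if contact_gap < 0:
        raise ConfigError("contact_gap: must be >= 0")
    if not set_a or not set_b:
        return []
    calibs = {_calibration_of(o) for o in list(set_a) + list(set_b)}
    calibs.discard((None, None))
    if len(calibs) > 1:
        raise CalibrationError(f"objects carry mismatched calibrations: {calibs}")
    if not calibs:
        raise CalibrationError("objects carry no pixel calibration")
    pixel_size_xy, z_step = next(iter(calibs))
    regions_a = [np.asarray(a.region) for a in set_a]
    regions_b = [np.asarray(b.region) for b in set_b]
    ndims = {r.shape[1] for r in regions_a + regions_b}
    if len(ndims) != 1:
        raise CalibrationError("regions have mixed dimensionality")
    ndim = next(iter(ndims))
    sizes = np.array([z_step, pixel_size_xy, pixel_size_xy][-ndim:]
                     if ndim == 3 else [pixel_size_xy, pixel_size_xy])
    # centre distance exceeds box gap by at most one voxel diagonal
    reach = contact_gap + float(np.linalg.norm(sizes)) + 1e-9
    b_voxels = np.concatenate(regions_b) * sizes
    b_owner = np.concatenate([np.full(len(r), j) for j, r in enumerate(regions_b)])
    tree = cKDTree(b_voxels)
    contacts = []
    for i, ra in enumerate(regions_a):
        hits = tree.query_ball_point(ra * sizes, r=reach)
        candidates = sorted({int(b_owner[k]) for h in hits for k in h})
        for j in candidates:
            if region_gap_um(ra, regions_b[j], sizes) <= contact_gap:
                contacts.append((set_a[i], set_b[j]))
    return contacts


def classify_profiles(boutons: list, postsynaptic_objects: list,
                      contact_gap: float = DEFAULT_CONTACT_GAP_UM
                      ) -> tuple[list[SynapticProfile], list[OppositeProfile], dict]:
    """Classify every bouton's synaptic profile and summarize the census.

    Each bouton with at least one contacted partner yields one
    :class:`SynapticProfile` (labelled ``msb`` for ≥2 partners — partner
    multiplicity is preserved in ``partners``); each postsynaptic object
    contacted by ≥2 boutons yields an :class:`OppositeProfile`. The summary
    reports counts and percentages under both plausible denominators
    (profiles and contacts), lone puncta per channel, and the pre:post
    puncta ratio.
    """
    if not boutons or not postsynaptic_objects:
        profiles: list[SynapticProfile] = []
        opposites: list[OppositeProfile] = []
        contacts: list[tuple] = []
    else:
        contacts = detect_contacts(boutons, postsynaptic_objects, contact_gap)
        by_bouton: dict[int, list] = {}
        by_post: dict[int, list] = {}
        for a, b in contacts:
            by_bouton.setdefault(id(a), []).append(b)
            by_post.setdefault(id(b), []).append(a)
        profiles = [SynapticProfile(bouton=a, partners=by_bouton[id(a)])
                    for a in boutons if id(a) in by_bouton]
        opposites = [OppositeProfile(postsynaptic=b, boutons=by_post[id(b)])
                     for b in postsynaptic_objects
                     if len(by_post.get(id(b), [])) >= 2]
    summary = summarize_profiles(profiles, opposites, len(contacts),
                                 n_boutons=len(boutons),
                                 n_postsynaptic=len(postsynaptic_objects))
    return profiles, opposites, summary


def summarize_profiles(profiles: list[SynapticProfile],
                       opposites: list[OppositeProfile], n_contacts: int,
                       *, n_boutons: int, n_postsynaptic: int) -> dict:
    """Census summary; percentages are None when the denominator is zero."""
    n_profiles = len(profiles)
    n_msb = sum(1 for p in profiles if p.label == "msb")
    contacted_posts = {id(q) for p in profiles for q in p.partners}

    def pct(num, den):
        return 100.0 * num / den if den else None
    return {
        "n_boutons": n_boutons,
        "n_postsynaptic": n_postsynaptic,
        "n_profiles": n_profiles,
        "n_single": n_profiles - n_msb,
        "n_msb": n_msb,
        "msb_pct_of_profiles": pct(n_msb, n_profiles),
        "n_contacts": n_contacts,
        "msb_pct_of_contacts": pct(n_msb, n_contacts),
        "n_opposite": len(opposites),
        "opposite_pct_of_profiles": pct(len(opposites), n_profiles),
        "opposite_pct_of_contacts": pct(len(opposites), n_contacts),
        "lone_presynaptic": n_boutons - n_profiles,
        "lone_postsynaptic": n_postsynaptic - len(contacted_posts),
        "pre_post_ratio": (n_boutons / n_postsynaptic) if n_postsynaptic else None,
    }


def passes_msb_criteria(pair: SpinePair,
                        max_head_distance: float = DEFAULT_MAX_HEAD_DISTANCE_UM
                        ) -> bool:
    """Spatial live-imaging criteria for an MSB spine pair: head centres
    closer than ``max_head_distance`` and orientation towards or parallel."""
    return (pair.head_distance < max_head_distance
            and pair.orientation in ("towards", "parallel"))


def identify_msb_pairs(profiles: list[SynapticProfile],
                       spine_pairs: list[SpinePair],
                       max_head_distance: float = DEFAULT_MAX_HEAD_DISTANCE_UM
                       ) -> list[SpinePair]:
    """Flag spine pairs as MSB candidates for live analysis.

    A pair qualifies iff both spines contact the same bouton (appear in one
    profile's partner list) and it passes :func:`passes_msb_criteria`.
    Returned pairs carry ``provenance="msb_candidate"``.
    """
    shared: set[frozenset[int]] = set()
    for profile in profiles:
        ids = [p.id for p in profile.partners if isinstance(p, SpineRecord)]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                shared.add(frozenset((a, b)))
    out = []
    for pair in spine_pairs:
        if frozenset(pair.ids()) in shared and \
                passes_msb_criteria(pair, max_head_distance):
            pair.provenance = "msb_candidate"
            out.append(pair)
    return out
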