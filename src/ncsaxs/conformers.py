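"""Coarse-grained bead models of nucleosomal DNA.

The nucleosome core particle (NCP) wraps ~147 bp of duplex DNA in a
left-handed superhelix around the histone octamer.  Salt titration and
stopped-flow experiments probe states ranging from the fully wrapped
particle through partially released ("J"-shaped) intermediates to free
linear DNA.  This module builds rigid two-beads-per-bp models of those
states: each base pair contributes two backbone beads placed
diametrically across the duplex cross-section, so the duplex diameter
(2 x ``duplex_radius`` = 20 A) shows up directly as the short-range d1
feature in pair-distance distributions.

Partially released conformers are a wrapped central arc plus straight
arms leaving tangentially at the release points; the candidate pool for
ensemble fitting enumerates release amounts at both ends.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HelixParams",
    "Conformer",
    "PoolSpec",
    "DEFAULT_RELEASE_GRID",
    "build_duplex",
    "build_wrapped",
    "build_released",
    "build_protein_core",
    "generate_pool",
    "classify_symmetry",
    "rg_of",
    "dmax_of",
]

DNA = "DNA"
PROTEIN = "PROTEIN"


@dataclass(frozen=True)
class HelixParams:
    """Geometry of B-form duplex DNA and of the nucleosomal superhelix.

    All lengths in Angstrom, angles in degrees.  Defaults are the
    canonical nucleosome numbers -- superhelix radius 41.9 A, pitch
    25.9 A per turn -- with B-DNA rise 3.4 A/bp and twist 34.3 deg/bp.
    ``duplex_radius`` (11 A) is the backbone-bead radius, calibrated so
    the duplex-diameter signature in model pair-distance distributions
    sits at the canonical d1 ~ 20 A.

    ``wrapped_turns`` is None by default, meaning the angular extent of
    a full wrap is derived from the bp count so the superhelical arc
    length equals the B-DNA contour length (147 bp span ~1.88
    start-to-end turns at this radius; the familiar 1.65-turn figure
    refers to the crystallographic entry/exit convention).  An explicit
    value overrides the derivation and is checked for consistency.
    """

    superhelix_radius: float = 41.9
    superhelix_pitch: float = 25.9
    wrapped_turns: float | None = None
    rise_per_bp: float = 3.4
    duplex_radius: float = 11.0
    twist_per_bp: float = 34.3

    def __post_init__(self) -> None:
        for name in ("superhelix_radius", "superhelix_pitch", "rise_per_bp",
                     "duplex_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wrapped_turns is not None and self.wrapped_turns <= 0:
            raise ValueError("wrapped_turns must be > 0")

    @property
    def _per_turn_length(self) -> float:
        c = self.superhelix_pitch / (2.0 * np.pi)
        return 2.0 * np.pi * np.hypot(self.superhelix_radius, c)

    def turns_for(self, bp_wrapped: int) -> float:
        """Turn count for a full wrap of ``bp_wrapped`` base pairs.

        Derived from the contour length when ``wrapped_turns`` is None,
        so that the path-length/contour-length consistency holds by
        construction.
        """
        if self.wrapped_turns is not None:
            return self.wrapped_turns
        return (bp_wrapped - 1) * self.rise_per_bp / self._per_turn_length

    def path_mismatch(self, bp_wrapped: int) -> float:
        """Relative mismatch between the superhelix arc length and the
        contour length of ``bp_wrapped`` base pairs at ``rise_per_bp``.

        Zero by construction for derived turns; nonzero only when an
        explicit ``wrapped_turns`` is imposed.
        """
        contour = (bp_wrapped - 1) * self.rise_per_bp
        path = self.turns_for(bp_wrapped) * self._per_turn_length
        return abs(path - contour) / contour


@dataclass
class Conformer:
    """Labelled bead model of one DNA (+ optional protein-core) state.

    ``beads`` is an (N, 3) float array in Angstrom; ``labels`` tags each
    bead as DNA or PROTEIN.  DNA-only models carry exactly two beads per
    base pair.  ``released_left``/``released_right`` record how many bp
    have left the wrapped superhelix at each end.
    """

    beads: np.ndarray
    labels: np.ndarray
    bp_total: int
    released_left: int = 0
    released_right: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError("beads must be an (N, 3) array")
        if len(self.labels) != len(self.beads):
            raise ValueError("labels and beads length mismatch")
        if not np.all(np.isfinite(self.beads)):
            raise ValueError("bead coordinates must be finite")
        if self.released_left < 0 or self.released_right < 0:
            raise ValueError("release counts must be >= 0")
        if self.released_left + self.released_right > self.bp_total:
            raise ValueError("total release exceeds bp_total")
        n_dna = int(np.sum(self.labels == DNA))
        if n_dna and n_dna != 2 * self.bp_total:
            raise ValueError("DNA bead count must be 2 x bp_total")

    @property
    def total_released(self) -> int:
        return self.released_left + self.released_right

    def dna_only(self) -> "Conformer":
        keep = self.labels == DNA
        return replace(self, beads=self.beads[keep], labels=self.labels[keep])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Conformer":
        xyz = self.beads
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, beads=xyz)


# Default release grid: 32 unique (left, right) release pairs spanning
# fully wrapped -> fully released, with symmetric and asymmetric
# members including both orientations of each single-end series.
DEFAULT_RELEASE_GRID: tuple[tuple[int, int], ...] = (
    (0, 0),
    # symmetric releases
    (9, 9), (18, 18), (28, 28), (37, 37), (46, 46), (55, 55), (64, 64),
    # single-end releases, both orientations
    (18, 0), (37, 0), (55, 0), (74, 0), (92, 0), (110, 0), (128, 0), (147, 0),
    (0, 18), (0, 37), (0, 55), (0, 74), (0, 92), (0, 110), (0, 128), (0, 147),
    # unequal two-end releases, both orientations
    (37, 18), (18, 37), (55, 18), (18, 55),
    (74, 37), (37, 74), (92, 37), (37, 92),
)


@dataclass(frozen=True)
class PoolSpec:
    """Specification of the conformer candidate pool."""

    bp_total: int = 147
    release_grid: tuple[tuple[int, int], ...] = DEFAULT_RELEASE_GRID
    include_protein_core: bool = False

    def __post_init__(self) -> None:
        if self.bp_total < 2:
            raise ValueError("bp_total must be >= 2")
        pairs = [tuple(p) for p in self.release_grid]
        if len(set(pairs)) != len(pairs):
            raise ValueError("release_grid pairs must be unique")
        for left, right in pairs:
            if left < 0 or right < 0 or left + right > self.bp_total:
                raise ValueError(f"invalid release pair ({left}, {right})")


def _duplex_offsets(n_bp: int, params: HelixParams,
                    phase0: float = 0.0) -> np.ndarray:
    """Cross-section offset angles (radians) for bp 0..n_bp-1."""
    twist = np.radians(params.twist_per_bp)
    return phase0 + twist * np.arange(n_bp)


def build_duplex(bp_total: int, params: HelixParams | None = None,
                 name: str | None = None) -> Conformer:
    """Straight B-form duplex of ``bp_total`` base pairs along +z.

    Two beads per bp sit diametrically at ``duplex_radius`` about the
    helix axis, advancing ``rise_per_bp`` and rotating ``twist_per_bp``
    per step; the end-to-end axis length is (bp_total - 1) x rise.
    """
    params = params or HelixParams()
    if bp_total < 2:
        raise ValueError("bp_total must be >= 2")
    phi = _duplex_offsets(bp_total, params)
    z = params.rise_per_bp * np.arange(bp_total)
    r = params.duplex_radius
    strand1 = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    strand2 = np.column_stack([-r * np.cos(phi), -r * np.sin(phi), z])
    beads = np.concatenate([strand1, strand2])
    labels = np.full(len(beads), DNA)
    return Conformer(beads, labels, bp_total, released_left=0,
                     released_right=bp_total,
                     name=name or f"duplex_{bp_total}bp")


def _superhelix_frames(theta: np.ndarray, params: HelixParams):
    """Points, tangents, normals, binormals of the left-handed superhelix.

    Path: (R cos t, -R sin t, c t) with c = pitch / 2 pi.
    """
    R = params.superhelix_radius
    c = params.superhelix_pitch / (2.0 * np.pi)
    pts = np.column_stack([R * np.cos(theta), -R * np.sin(theta), c * theta])
    tan = np.column_stack([-R * np.sin(theta), -R * np.cos(theta),
                           np.full_like(theta, c)])
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    # outward radial direction, orthogonalised against the tangent
    nrm = np.column_stack([np.cos(theta), -np.sin(theta),
                           np.zeros_like(theta)])
    nrm -= np.sum(nrm * tan, axis=1, keepdims=True) * tan
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    binrm = np.cross(tan, nrm)
    return pts, tan, nrm, binrm


def _beads_on_frames(pts, nrm, binrm, phi, radius):
    """Two strand beads per frame at +-radius, cross-section angle phi."""
    u = (np.cos(phi)[:, None] * nrm + np.sin(phi)[:, None] * binrm)
    return np.concatenate([pts + radius * u, pts - radius * u])


def _check_overlaps(beads: np.ndarray, min_sep: float = 1.0) -> None:
    from scipy.spatial.distance import pdist

    if len(beads) >= 2 and pdist(beads).min() < min_sep:
        raise ValueError(
            f"degenerate geometry: bead separation below {min_sep} A")


def build_wrapped(bp_total: int, params: HelixParams | None = None,
                  name: str | None = None) -> Conformer:
    """Duplex wound along the left-handed nucleosomal superhelix.

    One bp per equal angular increment over ``wrapped_turns``; the local
    duplex frame is transported along the path so the two strand beads
    stay diametric about the path tangent.
    """
    params = params or HelixParams()
    if bp_total < 2:
        raise ValueError("bp_total must be >= 2")
    if params.path_mismatch(bp_total) > 0.02:
        warnings.warn(
            "superhelix arc length and bp contour length disagree by "
            f"{100 * params.path_mismatch(bp_total):.1f}% for "
            f"{bp_total} bp", stacklevel=2)
    theta = np.linspace(0.0, 2.0 * np.pi * params.turns_for(bp_total),
                        bp_total)
    pts, _, nrm, binrm = _superhelix_frames(theta, params)
    phi = _duplex_offsets(bp_total, params)
    beads = _beads_on_frames(pts, nrm, binrm, phi, params.duplex_radius)
    _check_overlaps(beads)
    labels = np.full(len(beads), DNA)
    return Conformer(beads, labels, bp_total,
                     name=name or f"wrapped_{bp_total}bp")


def build_released(bp_total: int, released_left: int, released_right: int,
                   params: HelixParams | None = None,
                   name: str | None = None) -> Conformer:
    """Partially unwrapped conformer: wrapped central arc + straight arms.

    ``released_left``/``released_right`` bp leave the superhelix at each
    end as straight tangential arms continuous with the wrapped path.
    (0, 0) reproduces :func:`build_wrapped` bead-for-bead; releasing all
    bp yields a straight duplex.
    """
    params = params or HelixParams()
    if released_left < 0 or released_right < 0:
        raise ValueError("release counts must be >= 0")
    if released_left + released_right > bp_total:
        raise ValueError("total release exceeds bp_total")
    auto = name or f"released_L{released_left}_R{released_right}"
    n_wrap = bp_total - released_left - released_right
    if n_wrap <= 1:
        # nothing (or a single bp) left on the core: straight DNA
        c = build_duplex(bp_total, params, name=auto)
        return replace(c, released_left=released_left,
                       released_right=released_right)
    if released_left == 0 and released_right == 0:
        c = build_wrapped(bp_total, params, name=auto)
        return replace(c, name=auto)

    # wrapped arc spans the proportional share of the full wrap
    dtheta = 2.0 * np.pi * params.turns_for(bp_total) / (bp_total - 1)
    theta = dtheta * np.arange(n_wrap)
    pts, tan, nrm, binrm = _superhelix_frames(theta, params)

    rise = params.rise_per_bp
    centers = [pts]
    frames_n = [nrm]
    frames_b = [binrm]
    if released_left:
        steps = np.arange(released_left, 0, -1)[:, None]
        arm = pts[0] - steps * rise * tan[0]
        centers.insert(0, arm)
        frames_n.insert(0, np.repeat(nrm[:1], released_left, axis=0))
        frames_b.insert(0, np.repeat(binrm[:1], released_left, axis=0))
    if released_right:
        steps = np.arange(1, released_right + 1)[:, None]
        arm = pts[-1] + steps * rise * tan[-1]
        centers.append(arm)
        frames_n.append(np.repeat(nrm[-1:], released_right, axis=0))
        frames_b.append(np.repeat(binrm[-1:], released_right, axis=0))
    centers = np.concatenate(centers)
    frames_n = np.concatenate(frames_n)
    frames_b = np.concatenate(frames_b)
    phi = _duplex_offsets(bp_total, params)
    beads = _beads_on_frames(centers, frames_n, frames_b, phi,
                             params.duplex_radius)
    _check_overlaps(beads)
    labels = np.full(len(beads), DNA)
    return Conformer(beads, labels, bp_total, released_left, released_right,
                     name=auto)


def build_protein_core(params: HelixParams | None = None,
                       n_beads: int = 8, ring_radius: float = 18.0,
                       half_height: float = 9.0,
                       bp_total: int = 147) -> np.ndarray:
    """Pseudo-histone core: ``n_beads`` PROTEIN beads on two staggered
    rings about the superhelix axis, centred on the wrapped DNA.

    A schematic stand-in for the octamer used in contrast
    demonstrations, not an atomic model.
    """
    params = params or HelixParams()
    ang = 2.0 * np.pi * np.arange(n_beads) / n_beads
    z0 = params.superhelix_pitch * params.turns_for(bp_total) / 2.0
    z = z0 + half_height * np.where(np.arange(n_beads) % 2 == 0, 1.0, -1.0)
    return np.column_stack([ring_radius * np.cos(ang),
                            ring_radius * np.sin(ang), z])


def with_protein_core(c: Conformer, params: HelixParams | None = None,
                      **core_kwargs) -> Conformer:
    """Return a copy of ``c`` with pseudo-histone core beads appended."""
    core = build_protein_core(params, **core_kwargs)
    beads = np.concatenate([c.beads, core])
    labels = np.concatenate([c.labels, np.full(len(core), PROTEIN)])
    return replace(c, beads=beads, labels=labels)


def generate_pool(spec: PoolSpec | None = None,
                  params: HelixParams | None = None) -> list[Conformer]:
    """Build the candidate pool: one conformer per release pair.

    The default grid yields exactly 32 members spanning fully wrapped to
    fully released, with symmetric, asymmetric and both-orientation
    single-end series.
    """
    spec = spec or PoolSpec()
    params = params or HelixParams()
    pool: list[Conformer] = []
    seen: set[str] = set()
    for left, right in spec.release_grid:
        c = build_released(spec.bp_total, left, right, params)
        if c.name in seen:
            raise ValueError(f"duplicate conformer name {c.name!r}")
        seen.add(c.name)
        if spec.include_protein_core and classify_symmetry(c) != "free":
            c = with_protein_core(c, params)
        pool.append(c)
    return pool


def classify_symmetry(c: Conformer, threshold: int = 10) -> str:
    """Classify a conformer by its recorded release counts.

    Returns ``wrapped`` if both ends released < ``threshold`` bp,
    ``free`` if nearly everything is released, otherwise ``symmetric``
    or ``asymmetric`` by whether |left - right| <= ``threshold``.
    """
    left, right = c.released_left, c.released_right
    if left < threshold and right < threshold:
        return "wrapped"
    if left + right >= c.bp_total - threshold:
        return "free"
    return "symmetric" if abs(left - right) <= threshold else "asymmetric"


def rg_of(c: Conformer, weights: np.ndarray | None = None) -> float:
    """Radius of gyration: rms bead distance from the (weighted) centroid."""
    if len(c.beads) < 2:
        raise ValueError("need at least 2 beads")
    w = np.ones(len(c.beads)) if weights is None else np.asarray(weights,
                                                                 dtype=float)
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("weights sum to zero")
    centroid = (w[:, None] * c.beads).sum(axis=0) / wsum
    d2 = np.sum((c.beads - centroid) ** 2, axis=1)
    return float(np.sqrt((w * d2).sum() / wsum))


def dmax_of(c: Conformer) -> float:
    """Maximum pairwise bead distance."""
    from scipy.spatial.distance import pdist

    if len(c.beads) < 2:
        raise ValueError("need at least 2 beads")
    return float(pdist(c.beads).max())
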