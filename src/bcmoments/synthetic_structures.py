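"""Idealized C-alpha traces: helices, sheets, mixed motifs, labeled datasets.

Geometry follows textbook secondary-structure parameters: an alpha
helix with 1.5 A rise, 2.3 A radius and 100 degrees twist per residue
(3.6 residues/turn, consecutive C-alpha ~3.8 A apart), beta strands
with 3.3 A axial spacing and a small alternating zigzag, paired strands
4.8 A apart.  Connecting loops are laid on circular arcs so that every
consecutive C-alpha distance stays in the physical 3.0-4.3 A band.
Optional Gaussian coordinate jitter emulates thermal/experimental
noise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import brentq

from .structure_io import CaTrace, ResidueId

CLASS_LABELS = ("all_alpha", "all_beta_parallel", "all_beta_antiparallel", "alpha_beta")

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0
STRAND_SPACING = 3.3  # axial C-alpha spacing along a strand
STRAND_ZIGZAG = 0.6  # out-of-line zigzag amplitude
STRAND_GAP = 4.8  # inter-strand pairing distance
LOOP_STEP = 3.5  # target consecutive distance along connecting arcs


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic domain."""

    class_label: str
    n_residues: int
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}")
        if self.n_residues < 12:
            raise ValueError("n_residues must be >= 12")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _as_trace(coords: np.ndarray) -> CaTrace:
    ids = tuple(ResidueId("A", i + 1, "") for i in range(len(coords)))
    return CaTrace(ids, np.asarray(coords, dtype=float))


def make_helix(
    n: int,
    rise: float = HELIX_RISE,
    radius: float = HELIX_RADIUS,
    twist: float = HELIX_TWIST_DEG,
) -> CaTrace:
    """Ideal alpha helix along +z; defaults give 3.6 residues/turn."""
    if n < 4:
        raise ValueError("a helix needs at least 4 residues")
    i = np.arange(n)
    theta = np.radians(twist) * i
    coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])
    return _as_trace(coords)


def _helix_coords(
    n: int,
    start: np.ndarray,
    axis: np.ndarray,
    phase: float = 0.0,
    rise: float = HELIX_RISE,
    radius: float = HELIX_RADIUS,
    twist: float = HELIX_TWIST_DEG,
) -> np.ndarray:
    """Helix of n residues with its axis along an arbitrary unit direction."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # any orthonormal frame perpendicular to the axis
    probe = np.array([1.0, 0.0, 0.0])
    if abs(axis @ probe) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    e1 = probe - (probe @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    i = np.arange(n)
    theta = np.radians(twist) * i + phase
    return (
        np.asarray(start)
        + np.outer(rise * i, axis)
        + radius * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
    )


def _strand_coords(
    n: int, start: np.ndarray, direction: np.ndarray, zigzag_dir: np.ndarray
) -> np.ndarray:
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    zig = np.asarray(zigzag_dir, dtype=float)
    zig = zig / np.linalg.norm(zig)
    i = np.arange(n)
    return (
        np.asarray(start)
        + np.outer(STRAND_SPACING * i, direction)
        + np.outer(STRAND_ZIGZAG * (-1.0) ** i, zig)
    )


def _arc_loop(
    a: np.ndarray, b: np.ndarray, n_interior: int, bulge_dir: np.ndarray, step: float = LOOP_STEP
) -> np.ndarray:
    """Interior points of a circular arc from a to b with near-equal chord steps.

    The arc lies in the plane spanned by the chord and bulge_dir and
    bulges toward bulge_dir; n_interior + 1 segments of equal chord
    length connect the endpoints.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = n_interior + 1
    c = float(np.linalg.norm(b - a))
    if c == 0.0:
        raise ValueError("arc endpoints coincide")
    s = max(step, c / m + 1e-9)  # straight-ish if the chord is already long
    if c >= m * s:
        s = c / m + 1e-9
    u = (b - a) / c
    v = np.asarray(bulge_dir, dtype=float)
    v = v - (v @ u) * u
    if np.linalg.norm(v) < 1e-9:
        raise ValueError("bulge direction parallel to the chord")
    v /= np.linalg.norm(v)

    def gap(theta: float) -> float:
        return math.sin(theta / 2.0) - (c / s) * math.sin(theta / (2.0 * m))

    theta = brentq(gap, 1e-9, 2.0 * math.pi - 1e-9)
    radius = c / (2.0 * math.sin(theta / 2.0))
    h = radius * math.cos(theta / 2.0)
    center = a + (c / 2.0) * u - h * v
    psi = -theta / 2.0 + theta * np.arange(1, m) / m
    return center + radius * (np.outer(np.sin(psi), u) + np.outer(np.cos(psi), v))


def make_sheet(
    n_per_strand: int,
    topology: str,
    strand_gap: float = STRAND_GAP,
    loop_len: int | None = None,
) -> CaTrace:
    """Two-strand beta sheet.

    Antiparallel: the second strand runs back so residue p pairs with q,
    p+1 with q-1 (a hairpin, connected by a short arc of ``loop_len``
    residues, default 3).  Parallel: both strands run the same way, p
    pairing with q, p+1 with q+1; the connector is a long spacer
    (default 3 * n_per_strand residues) routed out of the sheet plane so
    it adds no pairing signal.
    """
    if topology not in ("parallel", "antiparallel"):
        raise ValueError(f"topology must be 'parallel' or 'antiparallel', got {topology!r}")
    if n_per_strand < 4:
        raise ValueError("n_per_strand must be >= 4")
    origin = np.zeros(3)
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    strand1 = _strand_coords(n_per_strand, origin, ex, ez)
    x_end = STRAND_SPACING * (n_per_strand - 1)
    if topology == "antiparallel":
        loop = 3 if loop_len is None else loop_len
        if loop < 2:
            raise ValueError("antiparallel loop_len must be >= 2")
        strand2 = _strand_coords(n_per_strand, np.array([x_end, strand_gap, 0.0]), -ex, ez)
        connector = _arc_loop(strand1[-1], strand2[0], loop, ex)
    else:
        spacer = 3 * n_per_strand if loop_len is None else loop_len
        if spacer < 2:
            raise ValueError("parallel spacer must be >= 2")
        strand2 = _strand_coords(n_per_strand, np.array([0.0, strand_gap, 0.0]), ex, ez)
        connector = _arc_loop(strand1[-1], strand2[0], spacer, ez)
    return _as_trace(np.vstack([strand1, connector, strand2]))


def _alpha_domain(n: int) -> np.ndarray:
    """2-4 antiparallel-packed helices connected by short arcs."""
    n_helices = 2 if n < 45 else 3 if n < 75 else 4
    loop = 4
    per_helix = round((n - (n_helices - 1) * loop) / n_helices)
    pieces: list[np.ndarray] = []
    spacing = 10.0
    ez = np.array([0.0, 0.0, 1.0])
    for k in range(n_helices):
        used = sum(len(p) for p in pieces)
        up = k % 2 == 0
        helix_len = per_helix if k < n_helices - 1 else max(4, n - used - (loop if pieces else 0))
        z0 = 0.0 if up else (helix_len - 1) * HELIX_RISE
        start = np.array([k * spacing, 0.0, z0])
        helix = _helix_coords(helix_len, start, ez if up else -ez)
        if pieces:
            bulge = ez if not up else -ez  # connect at the top after an up helix
            pieces.append(_arc_loop(pieces[-1][-1], helix[0], loop, bulge))
        pieces.append(helix)
    return np.vstack(pieces)


def _beta_domain(n: int, topology: str) -> np.ndarray:
    ex = np.array([1.0, 0.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    if topology == "antiparallel":
        n_strands = 2 if n < 40 else 3 if n < 60 else 4
        loop = 3
        per = round((n - (n_strands - 1) * loop) / n_strands)
        pieces: list[np.ndarray] = []
        for k in range(n_strands):
            used = sum(len(p) for p in pieces)
            length = per if k < n_strands - 1 else max(4, n - used - (loop if pieces else 0))
            forward = k % 2 == 0
            x0 = 0.0 if forward else STRAND_SPACING * (length - 1)
            start = np.array([x0, k * STRAND_GAP, 0.0])
            strand = _strand_coords(length, start, ex if forward else -ex, ez)
            if pieces:
                pieces.append(_arc_loop(pieces[-1][-1], strand[0], loop, ex if forward else -ex))
            pieces.append(strand)
        return np.vstack(pieces)
    # parallel: same-direction strands with out-of-plane crossover connectors
    n_strands = 2 if n < 45 else 3
    per = round(n / (2 * n_strands - 1))
    connector = per
    pieces = []
    for k in range(n_strands):
        used = sum(len(p) for p in pieces)
        length = per if k < n_strands - 1 else max(4, n - used - (connector if pieces else 0))
        start = np.array([0.0, k * STRAND_GAP, 0.0])
        strand = _strand_coords(length, start, ex, ez)
        if pieces:
            pieces.append(_arc_loop(pieces[-1][-1], strand[0], connector, ez))
        pieces.append(strand)
    return np.vstack(pieces)


def _crossover_helix_len(per: int) -> int:
    # span the strand length so both junction arcs stay short
    return max(4, round((STRAND_SPACING * (per - 1) - 4.0) / HELIX_RISE) + 1)


def _alpha_beta_domain(n: int) -> np.ndarray:
    """Beta-alpha-beta repeats: parallel strands with helices as crossovers.

    Each crossover helix runs back over the sheet plane (9 A above it),
    its span matched to the strand length so the connecting arcs are
    short.
    """
    ex = np.array([1.0, 0.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    n_strands = 2 if n < 55 else 3
    junction = 2  # arc residues on each side of a crossover helix

    def planned_total(per: int) -> int:
        return n_strands * per + (n_strands - 1) * (_crossover_helix_len(per) + 2 * junction)

    per = min(range(4, n), key=lambda p: abs(planned_total(p) - n))
    helix_len = _crossover_helix_len(per)
    pieces: list[np.ndarray] = []
    for k in range(n_strands):
        if pieces:
            # crossover helix above the sheet plane, running backwards
            helix_start = np.array(
                [STRAND_SPACING * (per - 1) - 2.0, (k - 0.5) * STRAND_GAP, 9.0]
            )
            helix = _helix_coords(helix_len, helix_start, -ex)
            pieces.append(_arc_loop(pieces[-1][-1], helix[0], junction, ez))
            pieces.append(helix)
        used = sum(len(p) for p in pieces)
        length = per if k < n_strands - 1 else max(4, n - used - (junction if pieces else 0))
        start = np.array([0.0, k * STRAND_GAP, 0.0])
        strand = _strand_coords(length, start, ex, ez)
        if pieces:
            pieces.append(_arc_loop(pieces[-1][-1], strand[0], junction, ez))
        pieces.append(strand)
    return np.vstack(pieces)


_JITTER_SMOOTH_SIGMA = 2.0  # residues


def _chain_correlated_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Gaussian coordinate jitter, correlated along the chain.

    White Gaussian displacements are smoothed along the residue index
    (like the low-frequency deformations of an elastic backbone) and
    rescaled so each coordinate keeps marginal standard deviation
    ``sd``; neighbouring residues then move together, which preserves
    physical bond lengths.
    """
    from scipy.ndimage import gaussian_filter1d

    white = rng.normal(0.0, 1.0, size=(n, 3))
    smooth = gaussian_filter1d(white, _JITTER_SMOOTH_SIGMA, axis=0, mode="nearest")
    impulse = np.zeros(max(n, 17))
    impulse[len(impulse) // 2] = 1.0
    weights = gaussian_filter1d(impulse, _JITTER_SMOOTH_SIGMA, mode="nearest")
    amplitude = math.sqrt(float((weights**2).sum()))
    return sd * smooth / amplitude


def make_domain(spec: SyntheticSpec) -> CaTrace:
    """Generate one synthetic domain per the spec's class recipe.

    Raises if the construction cannot land within 10% of the requested
    residue count.
    """
    builders = {
        "all_alpha": lambda n: _alpha_domain(n),
        "all_beta_antiparallel": lambda n: _beta_domain(n, "antiparallel"),
        "all_beta_parallel": lambda n: _beta_domain(n, "parallel"),
        "alpha_beta": lambda n: _alpha_beta_domain(n),
    }
    coords = builders[spec.class_label](spec.n_residues)
    if abs(len(coords) - spec.n_residues) > 0.1 * spec.n_residues:
        raise ValueError(
            f"construction for {spec.class_label} yielded {len(coords)} residues, "
            f"more than 10% off the requested {spec.n_residues}"
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + _chain_correlated_jitter(rng, len(coords), spec.noise_sd)
    return _as_trace(coords)


def make_dataset(
    n_per_class: int, noise_sd: float, seed: int
) -> list[tuple[str, CaTrace]]:
    """Balanced labeled dataset: n_per_class domains per class, sizes in [40, 120]."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    dataset: list[tuple[str, CaTrace]] = []
    for label in CLASS_LABELS:
        for _ in range(n_per_class):
            size = int(rng.integers(40, 121))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = SyntheticSpec(label, size, noise_sd, sub_seed)
            dataset.append((label, make_domain(spec)))
    return dataset
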