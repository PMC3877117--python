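"""Distance matrix construction and Gabor decomposition into contact classes.

The pairwise C-alpha distance matrix (DM) of a domain is a grayscale
texture image: an alpha helix draws a low-value strip 3-4 residues from
and parallel to the main diagonal, a parallel beta sheet a parallel
strip further out, an anti-parallel sheet a strip perpendicular to the
diagonal, and tertiary packing contacts short horizontal/vertical
dashes.  Convolving the DM with oriented Gabor kernels turns each local
low-distance strip into a negative response; thresholding at <= 0 then
yields binary contact matrices (BCMs), one per contact class:

* t135 (carrier at 135 degrees, stripes parallel to the diagonal)
  responds to helices and parallel sheets, separated afterwards by
  distance from the diagonal into BCM_H and BCM_P;
* t45 responds to anti-parallel sheets -> BCM_A;
* t0+90 (sum of the 0- and 90-degree kernels) responds to the
  horizontal/vertical dash patterns of other near contacts -> BCM_O.

The kernels keep a small positive DC component, so a featureless
background of large distances convolves to a positive value (-> 0)
while a low-distance strip aligned with the kernel's negative lobes
drives the response below zero (-> 1).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .config import BcmConfig, GaborConfig, PipelineConfig
from .structure_io import CaTrace

logger = logging.getLogger(__name__)


class FilterSizeError(ValueError):
    """Domain shorter than the convolution kernel."""


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric N x N matrix of pairwise C-alpha distances in Angstroms."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass(frozen=True)
class GaborTemplate:
    """A sampled convolution kernel of the bank."""

    kernel: np.ndarray
    orientation_deg: str
    wavelength: float
    aspect_ratio: float
    major_axis: float

    @property
    def size(self) -> int:
        return self.kernel.shape[0]


@dataclasses.dataclass(frozen=True)
class TemplateBank:
    t135: GaborTemplate
    t45: GaborTemplate
    t0_90: GaborTemplate

    def __iter__(self):
        return iter((self.t135, self.t45, self.t0_90))


@dataclasses.dataclass(frozen=True)
class BCMSet:
    """The four binary contact matrices (helix, parallel, anti-parallel, other)."""

    H: np.ndarray
    P: np.ndarray
    A: np.ndarray
    O: np.ndarray

    def __post_init__(self) -> None:
        for name in ("H", "P", "A", "O"):
            m = np.asarray(getattr(self, name), dtype=np.int8)
            object.__setattr__(self, name, m)
            if m.shape != (self.n, self.n):
                raise ValueError("all BCMs must be square with a common size")
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"BCM_{name} is not binary")
            if not np.array_equal(m, m.T):
                raise ValueError(f"BCM_{name} is not symmetric")

    @property
    def n(self) -> int:
        return np.asarray(self.H).shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"H": self.H, "P": self.P, "A": self.A, "O": self.O}


def compute_distance_matrix(trace: CaTrace) -> DistanceMatrix:
    """Pairwise Euclidean C-alpha distances of a trace."""
    diff = trace.coords[:, None, :] - trace.coords[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(np.maximum(values, values.T))


def gabor_value(
    x: float,
    y: float,
    orientation_deg: float,
    wavelength: float,
    aspect_ratio: float,
    major_axis: float,
) -> float:
    """Real (cosine-phase) 2-D Gabor function.

    A Gaussian elliptical envelope with major axis of length
    ``major_axis`` (= 2 sigma) along the orientation, minor axis shorter
    by ``aspect_ratio``, times a cosine carrier of period ``wavelength``
    along the orientation; unit value at the origin.
    """
    if wavelength <= 0 or aspect_ratio <= 0 or major_axis <= 0:
        raise ValueError("wavelength, aspect_ratio and major_axis must be positive")
    theta = math.radians(orientation_deg)
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    sigma = major_axis / 2.0
    envelope = math.exp(-(xr**2 + (aspect_ratio * yr) ** 2) / (2.0 * sigma**2))
    return envelope * math.cos(2.0 * math.pi * xr / wavelength)


def _sample_kernel(orientation_deg: float, cfg: GaborConfig) -> np.ndarray:
    half = cfg.size // 2
    grid = np.arange(-half, half + 1)
    kernel = np.empty((cfg.size, cfg.size))
    for i, y in enumerate(grid):  # row offset
        for j, x in enumerate(grid):  # column offset
            kernel[i, j] = gabor_value(
                x, y, orientation_deg, cfg.wavelength, cfg.aspect_ratio, cfg.major_axis
            )
    return kernel


def build_template_bank(config: GaborConfig | None = None) -> TemplateBank:
    """Sample the three kernels t135, t45 and t0+90 on an integer grid.

    The kernels keep their natural (positive) DC component: the sign
    threshold downstream separates matched low-distance strips (response
    <= 0) from the large-distance background (positive response), which
    only works if a featureless background convolves to a positive
    value.  A configuration whose sampled kernel mean is not positive is
    rejected.
    """
    cfg = config or GaborConfig()

    def template(orientation: str, raw: np.ndarray) -> GaborTemplate:
        if raw.mean() <= 0:
            raise ValueError(
                f"gabor configuration gives a non-positive kernel mean for t{orientation}; "
                "the sign binarization would mark the background as contacts"
            )
        return GaborTemplate(
            kernel=raw,
            orientation_deg=orientation,
            wavelength=cfg.wavelength,
            aspect_ratio=cfg.aspect_ratio,
            major_axis=cfg.major_axis,
        )

    k135 = _sample_kernel(135.0, cfg)
    k45 = _sample_kernel(45.0, cfg)
    k0_90 = _sample_kernel(0.0, cfg) + _sample_kernel(90.0, cfg)
    return TemplateBank(
        t135=template("135", k135),
        t45=template("45", k45),
        t0_90=template("0+90", k0_90),
    )


def filter_binarize(dm: DistanceMatrix, template: GaborTemplate) -> np.ndarray:
    """Convolve the DM with one kernel and threshold the response at <= 0.

    Borders are handled by edge replication; a 1 marks positions where
    the local distance texture matches the kernel's stripe pattern
    (negative or zero response).
    """
    if dm.n < template.size:
        raise FilterSizeError(
            f"domain of size {dm.n} is shorter than the {template.size}x{template.size} "
            f"kernel; need at least {template.size} residues"
        )
    if np.ptp(dm.values) == 0.0:
        logger.warning("constant distance matrix: binarization is degenerate")
    response = ndimage.convolve(dm.values, template.kernel, mode="nearest")
    return (response <= 0.0).astype(np.int8)


def split_band(binary: np.ndarray, d0: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a binary matrix into a near-diagonal band (helix) and the rest (parallel sheet).

    H keeps ones with 1 <= |i-j| <= d0, P those with |i-j| > d0; the
    diagonal itself is dropped from both.
    """
    binary = np.asarray(binary)
    if not np.isin(binary, (0, 1)).all():
        raise ValueError("split_band expects a binary matrix")
    if d0 < 1:
        raise ValueError("d0 must be >= 1")
    n = binary.shape[0]
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    h = np.where((sep >= 1) & (sep <= d0), binary, 0).astype(np.int8)
    p = np.where(sep > d0, binary, 0).astype(np.int8)
    return h, p


def _mask_diagonal_band(binary: np.ndarray, half_width: int) -> np.ndarray:
    n = binary.shape[0]
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return np.where(sep > half_width, binary, 0).astype(np.int8)


def decompose(
    dm: DistanceMatrix,
    bank: TemplateBank | None = None,
    config: PipelineConfig | None = None,
) -> BCMSet:
    """Decompose a distance matrix into the four binary contact matrices."""
    cfg = config or PipelineConfig()
    if bank is None:
        bank = build_template_bank(cfg.gabor)
    bcm_cfg: BcmConfig = cfg.bcm
    h, p = split_band(filter_binarize(dm, bank.t135), bcm_cfg.d0)
    a = _mask_diagonal_band(filter_binarize(dm, bank.t45), bcm_cfg.mask_band)
    o = _mask_diagonal_band(filter_binarize(dm, bank.t0_90), bcm_cfg.mask_band)
    return BCMSet(H=h, P=p, A=a, O=o)


def write_bcms(bcms: BCMSet, outdir: str | Path, stem: str) -> list[Path]:
    """Write the four BCMs as 0/1 TSV files named <stem>.<H|P|A|O>.bcm.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, matrix in bcms.as_dict().items():
        path = outdir / f"{stem}.{name}.bcm.tsv"
        np.savetxt(path, matrix, fmt="%d", delimiter="\t")
        paths.append(path)
    return paths
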