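"""Composition and Legendre moments of contact matrices; 49-D descriptor assembly.

Each binary contact matrix is summarized two ways.  Its composition
moment is the density of ones in the strict upper triangle (count /
(N(N-1)/2)), i.e. the average abundance of that contact class.  Its
shape is captured by discrete Legendre moments

    lambda_pq = (2p+1)(2q+1)/N^2 * sum_ij P_p(x_i) P_q(y_j) f(i, j)

with the pixel grid mapped onto [-1, 1] by x_i = -1 + 2i/(N-1).
Because the matrices are symmetric, lambda_pq = lambda_qp, so only the
pairs with p <= q and 1 <= p+q <= 5 are kept: 11 moments per matrix.
The full descriptor is 49-dimensional: 4 composition moments, a length
feature (ln N by default), and 4 x 11 Legendre moments.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .config import PipelineConfig
from .dm_bcm import BCMSet, build_template_bank, compute_distance_matrix, decompose
from .structure_io import CaTrace

MAX_ORDER = 5

#: Default (p, q) pairs: p <= q, 1 <= p+q <= 5.
DEFAULT_MOMENT_ORDERS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (0, 2),
    (0, 3),
    (0, 4),
    (0, 5),
    (1, 1),
    (1, 2),
    (1, 3),
    (1, 4),
    (2, 2),
    (2, 3),
)

BCM_ORDER = ("H", "P", "A", "O")


@dataclasses.dataclass(frozen=True)
class CompositionMoments:
    c_H: float
    c_P: float
    c_A: float
    c_O: float
    area: int

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.c_H, self.c_P, self.c_A, self.c_O)


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """The 49-D moment descriptor with a named schema."""

    schema: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.schema),):
            raise ValueError("schema/values length mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError("features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.schema, self.values.tolist()))


def feature_schema(orders: Sequence[tuple[int, int]] = DEFAULT_MOMENT_ORDERS) -> tuple[str, ...]:
    names = [f"comp_{k}" for k in BCM_ORDER]
    names.append("length")
    for k in BCM_ORDER:
        names.extend(f"lm_{k}_{p}{q}" for p, q in orders)
    return tuple(names)


def composition_moments(bcms: BCMSet) -> CompositionMoments:
    """Upper-triangle density of each contact class."""
    n = bcms.n
    if n < 2:
        raise ValueError("composition moments need N >= 2 (upper-triangle area is zero)")
    area = n * (n - 1) // 2
    iu = np.triu_indices(n, k=1)
    dens = {name: float(m[iu].sum()) / area for name, m in bcms.as_dict().items()}
    return CompositionMoments(dens["H"], dens["P"], dens["A"], dens["O"], area)


def legendre_polynomial(n: int, x: float | np.ndarray) -> float | np.ndarray:
    """Legendre polynomial P_n via the three-term recurrence, n in 0..5."""
    if not 0 <= n <= MAX_ORDER:
        raise ValueError(f"degree must be in 0..{MAX_ORDER}, got {n}")
    x = np.asarray(x, dtype=float)
    p_prev = np.ones_like(x)
    if n == 0:
        return p_prev if p_prev.ndim else float(p_prev)
    p = x.copy()
    for k in range(1, n):
        p, p_prev = ((2 * k + 1) * x * p - k * p_prev) / (k + 1), p
    return p if p.ndim else float(p)


def _normalized_grid(n: int) -> np.ndarray:
    if n < 2:
        raise ValueError("need at least a 2x2 image")
    return -1.0 + 2.0 * np.arange(n) / (n - 1)


def legendre_moment(image: np.ndarray, p: int, q: int) -> float:
    """Discrete Legendre moment lambda_pq of a square image."""
    if p < 0 or q < 0 or p + q > MAX_ORDER:
        raise ValueError(f"moment order must satisfy p,q >= 0 and p+q <= {MAX_ORDER}")
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    grid = _normalized_grid(n)
    lp = np.asarray(legendre_polynomial(p, grid))
    lq = np.asarray(legendre_polynomial(q, grid))
    norm = (2 * p + 1) * (2 * q + 1) / n**2
    return float(norm * lp @ image @ lq)


def _legendre_moments_batch(
    image: np.ndarray, orders: Sequence[tuple[int, int]]
) -> np.ndarray:
    """All requested lambda_pq of one image, sharing the polynomial tables."""
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    grid = _normalized_grid(n)
    table = np.stack([np.asarray(legendre_polynomial(d, grid)) for d in range(MAX_ORDER + 1)])
    projected = table @ image @ table.T  # projected[p, q] = sum P_p(x_i) f P_q(y_j)
    out = np.empty(len(orders))
    for k, (p, q) in enumerate(orders):
        if p < 0 or q < 0 or p + q > MAX_ORDER:
            raise ValueError(f"invalid moment order ({p},{q})")
        out[k] = (2 * p + 1) * (2 * q + 1) / n**2 * projected[p, q]
    return out


def legendre_feature_block(
    bcms: BCMSet,
    orders: Sequence[tuple[int, int]] = DEFAULT_MOMENT_ORDERS,
    length_mode: str = "log",
) -> np.ndarray:
    """The 45 structural features: one length feature plus 11 moments per BCM."""
    n = bcms.n
    length_feature = float(np.log(n)) if length_mode == "log" else float(n)
    blocks = [np.array([length_feature])]
    for name in BCM_ORDER:
        blocks.append(_legendre_moments_batch(bcms.as_dict()[name], orders))
    return np.concatenate(blocks)


def featurize_bcms(bcms: BCMSet, config: PipelineConfig | None = None) -> FeatureVector:
    cfg = config or PipelineConfig()
    comp = composition_moments(bcms)
    block = legendre_feature_block(bcms, length_mode=cfg.moments.length_mode)
    values = np.concatenate([np.array(comp.as_tuple()), block])
    return FeatureVector(feature_schema(), values)


def featurize(trace: CaTrace, config: PipelineConfig | None = None) -> FeatureVector:
    """Full pipeline: distance matrix -> Gabor decomposition -> 49-D descriptor."""
    cfg = config or PipelineConfig()
    dm = compute_distance_matrix(trace)
    bank = build_template_bank(cfg.gabor)
    bcms = decompose(dm, bank, cfg)
    return featurize_bcms(bcms, cfg)
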