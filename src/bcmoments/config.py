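"""Pipeline configuration.

All tunable parameters of the descriptor pipeline live here, grouped the
way the stages consume them: ``gabor.*`` controls the filter bank,
``bcm.*`` the band split of the binarized responses, ``moments.*`` the
feature assembly.  Defaults are calibrated to the geometry of ideal
secondary-structure elements (a 3.6 residue/turn helix produces a
contact strip of 3-4 residue period next to the diagonal).
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any


@dataclasses.dataclass(frozen=True)
class GaborConfig:
    """Parameters of the Gabor template bank.

    wavelength : period of the cosine carrier, in residues.  The default 8
        puts the kernel's flanking negative lobes 4 residues from its
        center, matching the 3-4 residue width of secondary-structure
        contact strips.
    aspect_ratio : major/minor axis ratio of the Gaussian envelope.
    major_axis : envelope major-axis length (2 sigma), in residues.
    size : odd side length of the sampled square kernel.

    The sampled kernels must keep a positive mean: the binarization rule
    (response <= 0) relies on large background distances convolving to
    positive values so that only matched low-distance strips flip sign.
    """

    wavelength: float = 8.0
    aspect_ratio: float = 1.5
    major_axis: float = 8.0
    size: int = 9

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.aspect_ratio <= 0 or self.major_axis <= 0:
            raise ValueError("gabor parameters must be positive")
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"gabor.size must be an odd integer >= 3, got {self.size}")


@dataclasses.dataclass(frozen=True)
class BcmConfig:
    """Band bookkeeping for the binary contact matrices.

    d0 : sequence-separation cutoff splitting the helix band from the
        parallel-sheet band in the 135-degree response.
    mask_band : half-width of the diagonal band zeroed in the
        anti-parallel and other-contact matrices (adjacent residues are
        always ~3.8 A apart and carry no sheet signal).
    """

    d0: int = 5
    mask_band: int = 1

    def __post_init__(self) -> None:
        if self.d0 < 1:
            raise ValueError("bcm.d0 must be >= 1")
        if self.mask_band < 0:
            raise ValueError("bcm.mask_band must be >= 0")


@dataclasses.dataclass(frozen=True)
class MomentsConfig:
    """Feature-assembly options.

    length_mode : "log" appends ln(N) as the length feature, "raw"
        appends N itself.
    """

    length_mode: str = "log"

    def __post_init__(self) -> None:
        if self.length_mode not in ("log", "raw"):
            raise ValueError(f"moments.length_mode must be 'log' or 'raw', got {self.length_mode!r}")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    gabor: GaborConfig = dataclasses.field(default_factory=GaborConfig)
    bcm: BcmConfig = dataclasses.field(default_factory=BcmConfig)
    moments: MomentsConfig = dataclasses.field(default_factory=MomentsConfig)
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "PipelineConfig":
        """Build a config from a nested mapping, rejecting unknown keys."""
        known = {"gabor", "bcm", "moments", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections/keys: {sorted(unknown)}")
        sections = {}
        for name, typ in (("gabor", GaborConfig), ("bcm", BcmConfig), ("moments", MomentsConfig)):
            sub = data.get(name, {})
            fields = {f.name for f in dataclasses.fields(typ)}
            bad = set(sub) - fields
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            sections[name] = typ(**sub)
        return cls(seed=int(data.get("seed", 0)), **sections)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls.from_mapping(tomllib.load(fh))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
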