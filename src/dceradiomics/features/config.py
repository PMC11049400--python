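"""Extraction configuration and the feature-vector container."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ExtractionConfig:
    """Settings of the feature battery.

    The CT preset uses a fixed bin width of 25 HU, an intensity shift of
    1000 HU for the squared-intensity (energy) family, 1 mm isotropic
    resampling and LoG sigmas of 1-5 mm, giving 14 image sets (original +
    5 LoG + 8 wavelet).  The MR preset z-scores the volume (x100), uses a
    bin width of 5, a shift of 300, 2 mm resampling and LoG sigmas of
    2-5 mm, giving 13 image sets.
    """

    modality: str = "CT"
    bin_width: float = 25.0
    voxel_array_shift: float = 1000.0
    resampled_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pad_distance: int = 10
    normalize: bool = False
    normalize_scale: float = 100.0
    log_sigmas: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wavelet: bool = True
    wavelet_name: str = "coif1"
    interpolation: str = "bspline"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if any(s <= 0 for s in self.resampled_spacing):
            raise ValueError("resampled_spacing must be positive")
        if self.pad_distance < 0:
            raise ValueError("pad_distance must be >= 0")

    @property
    def n_image_sets(self) -> int:
        return 1 + len(self.log_sigmas) + (8 if self.wavelet else 0)

    @classmethod
    def ct_default(cls) -> "ExtractionConfig":
        return cls()

    @classmethod
    def mr_default(cls) -> "ExtractionConfig":
        return cls(
            modality="MR",
            bin_width=5.0,
            voxel_array_shift=300.0,
            resampled_spacing=(2.0, 2.0, 2.0),
            normalize=True,
            normalize_scale=100.0,
            log_sigmas=(2.0, 3.0, 4.0, 5.0),
        )

    @classmethod
    def preset(cls, modality: str) -> "ExtractionConfig":
        if modality.upper() == "CT":
            return cls.ct_default()
        if modality.upper() == "MR":
            return cls.mr_default()
        raise ValueError(f"unknown modality preset {modality!r}")


@dataclass
class FeatureVector:
    """Ordered feature-name -> value map with per-feature degeneracy flags.

    Flagged entries hold a defined sentinel value but should be treated as
    missing by downstream statistics.
    """

    values: dict[str, float]
    flags: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def names(self) -> list[str]:
        return list(self.values)
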