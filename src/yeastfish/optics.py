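"""Imaging geometry and the Gaussian PSF approximation.

Defaults describe a widefield setup typical for yeast smFISH: 100x / NA 1.4
oil objective, 13 um camera pixels (130 nm sample-side), 32 z-layers at
0.25 um.  Diffraction-limited spots are modelled as 3-D Gaussians with the
standard widefield approximation

    sigma_xy = 0.21 * lambda_em / NA
    sigma_z  = 0.66 * lambda_em * n_immersion / NA**2

so the PSF width grows linearly with emission wavelength, as appropriate
when each FISH channel uses a different dye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from yeastfish.exceptions import ConfigurationError

#: emission maxima (nm) of the study's dyes, keyed by channel name
DEFAULT_WAVELENGTHS = {
    "Cy3": 576.0,  # ATTO-550
    "Cy5": 664.0,  # ATTO-647N
    "YFP": 523.0,  # ATTO-488
    "SPB": 474.0,  # mTurquoise
    "DAPI": 461.0,
}


@dataclass(frozen=True)
class OpticsConfig:
    pixel_size_nm: float = 130.0
    z_step_um: float = 0.25
    n_z: int = 32
    na: float = 1.4
    n_immersion: float = 1.515
    em_wavelength_nm: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WAVELENGTHS)
    )

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise ConfigurationError("n_z must be >= 1")
        if self.z_step_um <= 0:
            raise ConfigurationError("z_step_um must be > 0")
        if not 0 < self.na <= self.n_immersion:
            raise ConfigurationError("need 0 < NA <= n_immersion")

    def wavelength(self, channel: str) -> float:
        try:
            return float(self.em_wavelength_nm[channel])
        except KeyError as exc:
            raise ConfigurationError(
                f"channel {channel!r} has no emission wavelength"
            ) from exc


def psf_sigma(optics: OpticsConfig, channel: str) -> tuple[float, float]:
    """(sigma_xy in pixels, sigma_z in z-layers) for a channel's emission."""
    lam = optics.wavelength(channel)
    sigma_xy_nm = 0.21 * lam / optics.na
    sigma_z_nm = 0.66 * lam * optics.n_immersion / optics.na**2
    return (
        sigma_xy_nm / optics.pixel_size_nm,
        sigma_z_nm / (optics.z_step_um * 1000.0),
    )
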