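"""Simulation and analysis configuration.

All lengths are in micrometers, interfocal distances in nanometers, time in
frames internally (``frame_interval`` minutes per frame; conversions to hours
happen only at reporting boundaries).

The defaults describe the study conditions the synthetic generator emulates:
*Pseudomonas putida* microcolonies seeded from a stationary-phase culture that
contains a small transfer-competent (tc) subpopulation, imaged every 30 min
for up to 100 frames, reaching stationary phase again after ~12 h of growth.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["SimConfig", "OpticsConfig", "config_to_dict", "config_from_dict"]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic time-lapse generator.

    The eCherry reporter intensities are lognormal per class; the tc and
    non-tc log-means are separated by 8 non-tc log-sds by default, so the
    upper-tail quantile classifier operates well inside its working regime.
    The tc copy-number process is a capped pure-birth process that starts
    after a single excision event during the activation window; its rate is
    calibrated so that ~19% of wild-type tc cells reach a lifetime maximum of
    >=3 foci and ~2.0% of non-tc cells do (via rare high-scoring spurious
    foci), matching the preset definitions.
    """

    # --- movie geometry / timing -------------------------------------------------
    frames: int = 100                 # number of frames in the movie
    frame_interval: float = 30.0      # minutes per frame
    initial_cells: int = 300          # founder cells seeded in frame 0
    stationary_frame: int = 24        # growth ceases here (12 h at 30-min frames)

    # --- population composition --------------------------------------------------
    tc_fraction: float = 0.045        # fraction of founders that are tc cells
    recipient_fraction: float = 0.0   # ICE-free recipient founders (transfer mixes)

    # --- eCherry reporter (log-mean, log-sd of arbitrary units) -------------------
    echerry_nontc: tuple[float, float] = (5.70, 0.25)
    echerry_tc: tuple[float, float] = (7.70, 0.35)
    echerry_recipient: tuple[float, float] = (5.00, 0.20)
    echerry_noise: float = 0.03       # per-frame multiplicative noise (CV)

    # --- growth / division / lysis -----------------------------------------------
    growth_rate: float = 1.122        # per-frame length multiplication factor
    division_length: float = 2.8      # mean division length, um
    division_jitter: float = 0.12     # relative jitter on the division length
    birth_length: tuple[float, float] = (1.0, 1.8)  # founder lengths (stationary)
    cell_width: float = 0.7           # um
    tc_division_deficit: float = 0.1  # division probability multiplier for tc cells
    tc_growth_factor: float = 0.2     # exponent on growth_rate for tc cells
    tc_lysis_prob: float = 0.02       # per-frame lysis probability of tc cells

    # --- focus processes ----------------------------------------------------------
    replication_onset_length: float = 2.2  # second chromosomal focus above this, um
    spurious_rate: float = 0.25       # per cell-frame rate of low-scoring spurious foci
    spurious_pass_rate: float = 0.0021  # per cell-frame rate of threshold-passing spurious
    dim_prob_nontc: float = 0.08      # cells whose true foci score below threshold
    dim_prob_tc: float = 0.15
    excision_prob: float = 0.9        # probability a tc cell excises during the window
    excision_window: int = 8          # frames after seeding in which excision can occur
    copy_birth_rate: float = 0.068    # per-frame birth probability of the excised copy
    copy_birth_window: int = 16       # frames after excision during which copies replicate
    copy_cap: int = 6                 # maximum excised copy number

    # --- strain capabilities (preset switches) -------------------------------------
    excisable: bool = True            # attL recombination site intact
    array_present: bool = True        # lacO array present (foci visible)
    reporter_present: bool = True     # LacI-CFP expressed (foci visible)

    # --- colabel (CFP/YFP) interfocal displacement, nm -----------------------------
    interfocal_integrated: tuple[float, float] = (199.0, 126.0)   # mean, sd
    interfocal_excised: tuple[float, float] = (385.0, 185.0)

    # --- conjugative transfer -------------------------------------------------------
    transfer_rate: float = 0.015       # per-frame per-contact rate per excised copy above 1
    integration_prob: float = 0.2     # conditional-trap capture (integration) probability
    echerry_delay: tuple[float, float] = (3.5, 10.0)  # hours, recipient reporter onset
    abort_persistence: int = 3        # frames an aborted recipient focus persists

    # --- spatial layout --------------------------------------------------------------
    colony_spacing: float = 12.0      # um between founder cells

    seed: Optional[int] = None        # default seed; an explicit seed argument wins

    def __post_init__(self) -> None:
        if not 0.0 <= self.tc_fraction <= 1.0:
            raise ValueError(f"tc_fraction must be in [0, 1], got {self.tc_fraction}")
        if not 0.0 <= self.recipient_fraction <= 1.0:
            raise ValueError("recipient_fraction must be in [0, 1]")
        if self.copy_cap > 8 or self.copy_cap < 1:
            raise ValueError(f"copy_cap must be in 1..8, got {self.copy_cap}")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        for name in (
            "growth_rate", "tc_lysis_prob", "spurious_rate", "spurious_pass_rate",
            "excision_prob", "copy_birth_rate", "transfer_rate", "integration_prob",
            "tc_division_deficit", "dim_prob_nontc", "dim_prob_tc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for prob in ("tc_lysis_prob", "excision_prob", "copy_birth_rate",
                     "integration_prob", "tc_division_deficit"):
            if getattr(self, prob) > 1:
                raise ValueError(f"{prob} must be <= 1")
        if self.echerry_delay[0] >= self.echerry_delay[1]:
            raise ValueError("echerry_delay must be an increasing (low, high) range")

    def replace(self, **overrides) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **overrides)

    @property
    def frames_per_hour(self) -> float:
        return 60.0 / self.frame_interval


@dataclass(frozen=True)
class OpticsConfig:
    """Rendering optics for synthetic image stacks.

    Defaults approximate a 100x/1.45 objective on a 6.5-um-pixel sCMOS camera
    (65 nm object-plane pixels) and a diffraction-limited spot of ~130 nm
    Gaussian sigma.
    """

    pixel_size: float = 0.065     # um per pixel
    psf_sigma: float = 0.13       # um, Gaussian approximation of the PSF
    background: float = 150.0     # camera background, counts
    noise_sd: float = 8.0         # Gaussian read-noise sd, counts
    cell_fluor: float = 60.0      # diffuse in-cell fluorescence above background
    spot_photons: float = 4000.0  # integrated counts per focus
    saturation: int = 65535       # 16-bit full well

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")


def config_to_dict(config: SimConfig) -> dict:
    """Flatten a SimConfig to a plain dict (tuples become lists)."""
    d = dataclasses.asdict(config)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def config_from_dict(d: dict) -> SimConfig:
    """Inverse of :func:`config_to_dict`; unknown keys are rejected."""
    names = {f.name: f for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    clean = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(v)
        clean[k] = v
    return SimConfig(**clean)
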