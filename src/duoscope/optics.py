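"""Optical ground-truth parameters and synthetic-scene descriptors.

:class:`OpticsParams` holds the physical quantities the calibration
pipeline estimates — the PWM→depth response of the electrowetting lens,
the Petzval field-curvature sphere, radial distortion and the red−green
chromatic offset — so synthetic data can be generated from known truth
and every downstream fit checked against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class OpticsParams:
    """Ground-truth optical model of the miniscope light path.

    Parameters
    ----------
    pixel_size_um : float
        Sensor pixel pitch in micrometres.  Object-space sampling is
        ``pixel_size_um / magnification`` (see :attr:`object_pixel_um`).
    magnification : float
        Optical magnification of the GRIN + tube-lens relay (~3.3×).
    depth_per_pwm_um : float
        Focal-plane shift per percent of EWL PWM duty cycle, in µm.
        The default 7.7 spans a 770 µm axial range over 0–100 %.
    depth_offset_um : float
        Focal depth at 0 % duty cycle, in µm.
    petzval_radius_um : float
        Radius of the spherical surface of best focus, in µm.
    petzval_center_um : tuple of float
        Sphere centre (x0, y0, z0) in object-space µm; lateral origin is
        the field-of-view centre, z increases away from the objective.
        The best-focus surface is the near cap, z(x, y) = z0 − sqrt(R² − ρ²).
    radial_distortion_k : float
        Coefficient of the single-term radial model
        r_obs = r_true (1 + k r_true²), in µm⁻².
    chroma_shift_um : tuple of float
        (Δx, Δy, Δz) red-minus-green chromatic offset in µm.  The
        default carries the measured device scale: limited lateral
        aberration and a pronounced axial offset of −123.7 µm.
    defocus_blur_gain : float
        Gaussian blur radius growth in pixels per µm of defocus.
    """

    pixel_size_um: float = 4.5
    magnification: float = 3.3
    depth_per_pwm_um: float = 7.7
    depth_offset_um: float = 0.0
    petzval_radius_um: float = 343.1
    petzval_center_um: tuple[float, float, float] = (0.0, 0.0, 443.1)
    radial_distortion_k: float = 1e-6
    chroma_shift_um: tuple[float, float, float] = (0.5, 0.5, -123.7)
    defocus_blur_gain: float = 0.25

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.petzval_radius_um <= 0:
            raise ValueError("petzval_radius_um must be positive")
        if self.defocus_blur_gain < 0:
            raise ValueError("defocus_blur_gain must be non-negative")
        if len(self.petzval_center_um) != 3 or len(self.chroma_shift_um) != 3:
            raise ValueError("petzval_center_um and chroma_shift_um are 3-vectors")

    @property
    def object_pixel_um(self) -> float:
        """Object-space micrometres per sensor pixel."""
        return self.pixel_size_um / self.magnification

    def focal_depth_um(self, pwm_percent: float) -> float:
        """Focal depth (µm) commanded by a PWM duty cycle in percent."""
        return self.depth_offset_um + self.depth_per_pwm_um * pwm_percent

    def identity(self) -> "OpticsParams":
        """Aberration-free copy: no distortion, flat field, no chroma shift."""
        return replace(
            self,
            radial_distortion_k=0.0,
            petzval_radius_um=1e12,
            petzval_center_um=(0.0, 0.0, 1e12),
            chroma_shift_um=(0.0, 0.0, 0.0),
        )


@dataclass(frozen=True)
class SceneSpec:
    """Descriptor of a synthetic two-channel calcium-imaging scene.

    Defaults emulate a densely labelled cortical field of view: a broad
    green GECI population, a smaller static red-labelled subpopulation,
    GCaMP6f-like transient kinetics and modest brain-motion jitter.
    """

    n_neurons_green: int = 100
    n_neurons_red: int = 40
    overlap_fraction: float = 0.9
    soma_radius_px: float = 5.0
    transient_rate_hz: float = 0.15
    decay_tau_s: float = 0.5
    noise_sd: float = 0.02
    jitter_sd_px: float = 1.0

    def __post_init__(self) -> None:
        if self.n_neurons_green < 0 or self.n_neurons_red < 0:
            raise ValueError("neuron counts must be non-negative")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be positive")
        if self.soma_radius_px <= 0:
            raise ValueError("soma_radius_px must be positive")
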