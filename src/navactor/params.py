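"""Bundled noise parameters for the three sources of variability.

The actor model distinguishes motor noise (signal-dependent, on executed
velocities), observation noise (state-dependent, on landmark range/bearing),
and representation noise (time-dependent decay of the remembered map). The
same parameters drive both the generative simulation and the agent's internal
uncertainties. Ablations zero a source in both places at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .env_model import MotorNoise, ObservationNoise
from .belief_filter import RepresentationNoise

__all__ = ["NoiseParams", "DEFAULT_NOISE"]


@dataclass(frozen=True)
class NoiseParams:
    motor: MotorNoise
    observation: ObservationNoise
    representation: RepresentationNoise

    @classmethod
    def zero(cls) -> "NoiseParams":
        return cls(MotorNoise(), ObservationNoise(), RepresentationNoise())

    def without(
        self,
        *,
        motor: bool = False,
        perceptual: bool = False,
        representation: bool = False,
    ) -> "NoiseParams":
        """Return a copy with the selected sources zeroed (model ablation)."""
        out = self
        if motor:
            out = replace(out, motor=MotorNoise())
        if perceptual:
            out = replace(out, observation=ObservationNoise(floor=out.observation.floor))
        if representation:
            out = replace(out, representation=RepresentationNoise())
        return out


# Default noise magnitudes. The original studies' exact values are not
# reproduced here; these were chosen once from the constraints discussed in
# docs/methods.md (human step-length/veering/turning variability, visual
# range/bearing acuity falling off with distance and eccentricity, slow
# memory decay) and are flagged non-canonical.
DEFAULT_NOISE = NoiseParams(
    motor=MotorNoise(alpha1=0.25, alpha2=0.05, alpha3=0.05, alpha4=0.25),
    observation=ObservationNoise(
        sigma_r_min=0.10, sigma_r_max=0.20, sigma_psi_min=0.10, sigma_psi_max=0.20
    ),
    representation=RepresentationNoise(delta_xy=0.01),
)
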