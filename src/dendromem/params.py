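"""Shared parameter containers for the biophysical surrogate and tuning."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BiophysParams", "SurrogateKernels"]


@dataclass(frozen=True)
class BiophysParams:
    """The five tunable cell parameters searched by the optimizer.

    v_rest          membrane resting potential, mV
    spatial_mode    spine placement scheme: "linspace" (equidistant) or
                    "uniform" (i.i.d. random)
    density_setting spine-density multiplier of the wiring-law prediction
                    (1.0 = the law's density, 0.5 = half, 2.0 = double)
    ampa_fraction   fraction of spines carrying an AMPA receptor, [0, 1]
    nmda_fraction   fraction of spines carrying an NMDA receptor, [0, 1]
    """

    v_rest: float = -80.0
    spatial_mode: str = "linspace"
    density_setting: float = 1.0
    ampa_fraction: float = 1.0
    nmda_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.spatial_mode not in ("linspace", "uniform"):
            raise ValueError(f"unknown spatial_mode {self.spatial_mode!r}")
        if self.density_setting <= 0:
            raise ValueError("density_setting must be > 0")
        for name in ("ampa_fraction", "nmda_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_tuple(self) -> tuple:
        return (
            self.v_rest,
            self.spatial_mode,
            self.density_setting,
            self.ampa_fraction,
            self.nmda_fraction,
        )


@dataclass(frozen=True)
class SurrogateKernels:
    """Constants of the built-in somatic-EPSP surrogate.

    Double-exponential synaptic kernels with passive cable attenuation and a
    sigmoidal NMDA cluster boost. Defaults are of the order used in
    compartmental models of cortical pyramidal dendrites; they parameterise
    the surrogate, they are not measured quantities.

    tau_rise_ampa / tau_decay_ampa   AMPA kinetics, ms
    tau_rise_nmda / tau_decay_nmda   NMDA kinetics, ms
    amp_ampa / amp_nmda              somatic unitary amplitudes, mV
    lambda_atten                     cable space constant for exp(-x/λ), μm
    cluster_window                   co-activation window on the branch, μm
    cluster_threshold                sigmoid midpoint, co-active NMDA spines;
                                     set near the within-window NMDA count at
                                     the wiring-law density so the sigmoid is
                                     maximally sensitive there (under-driven
                                     at half density, saturated at double)
    cluster_slope                    sigmoid slope, spines
    cluster_boost                    maximal multiplicative NMDA boost
    v_opt / v_sigma / hyper_gain     the NMDA gain is bell-shaped in the
                                     resting potential — the Mg²⁺-unblock vs
                                     driving-force trade-off — peaking at
                                     v_opt (mV) with width v_sigma (mV) and
                                     maximal boost hyper_gain: moderate
                                     hyperpolarisation raises the gain, deep
                                     hyperpolarisation lowers it again
    drive_resolution                 step (mV) in which the branch's summed
                                     AMPA and NMDA drives reach the soma;
                                     models the stereotyped, near
                                     all-or-none character of dendritic
                                     output, and gives the branch a finite
                                     somatic-waveform repertoire
    """

    tau_rise_ampa: float = 0.5
    tau_decay_ampa: float = 5.0
    tau_rise_nmda: float = 3.0
    tau_decay_nmda: float = 60.0
    amp_ampa: float = 0.6
    amp_nmda: float = 0.4
    lambda_atten: float = 150.0
    cluster_window: float = 10.0
    cluster_threshold: float = 15.0
    cluster_slope: float = 3.0
    cluster_boost: float = 1.5
    v_opt: float = -81.0
    v_sigma: float = 4.0
    hyper_gain: float = 0.8
    drive_resolution: float = 0.1
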