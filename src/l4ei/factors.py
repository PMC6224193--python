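"""Plasticity factors linking measured E-I ratio shifts to model weight changes.

Brief monocular deprivation changes synaptic strengths in layer 4 in three
measurable ways, summarized by three multiplicative factors applied to the
baseline peak conductances of the network model:

* ``delta_e`` — depression of thalamocortical synapses onto excitatory
  (pyramidal) neurons, measured directly from the drop in evoked quantal
  amplitude (about 0.9, i.e. 90% of control).
* ``delta_i`` — depression of thalamocortical synapses onto inhibitory (PV+)
  neurons.  Not measured directly; derived from the shift in the
  pyramidal/PV EPSC charge ratio between hemispheres.
* ``pi_fb`` — potentiation of recurrent (intracortical) excitatory synapses
  onto inhibitory neurons, derived from the shift in the intracortical E-I
  ratio under the assumption that PV->pyramidal inhibitory strength is
  unchanged (which was verified experimentally).

The single parameter ``rho_ei = delta_e / delta_i`` captures the change of
the thalamocortical (feedforward) E-I ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ScenarioFactors", "derive_delta_i", "derive_pi", "make_factors"]


@dataclass(frozen=True)
class ScenarioFactors:
    """Multiplicative synaptic-change factors for the deprivation scenarios.

    All factors are dimensionless fractions of the control (baseline) peak
    conductance.  ``make_factors(1, 1, 1)`` is the baseline.
    """

    delta_e: float
    delta_i: float
    pi_fb: float
    rho_ei: float = field(init=False)
    #: recorded modelling assumption behind the derivation of pi_fb
    assumption: str = field(
        default="PV->pyramidal inhibitory strength unchanged by deprivation",
        compare=False,
        repr=False,
    )

    def __post_init__(self) -> None:
        for name in ("delta_e", "delta_i", "pi_fb"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"invalid factor: {name}={v!r} must be > 0")
        object.__setattr__(self, "rho_ei", self.delta_e / self.delta_i)


def derive_delta_i(
    delta_e: float, ratio_control: float, ratio_deprived: float
) -> float:
    """Depression factor for thalamic drive onto inhibitory neurons.

    The deprived/control shift of the pyramidal/PV thalamocortical EPSC
    charge ratio equals ``delta_e / delta_i``, so

        delta_i = delta_e / (ratio_deprived / ratio_control)

    With the measured ``delta_e = 0.9`` and a shift of 1.5 this gives 0.6.
    """
    if not (delta_e > 0 and ratio_control > 0 and ratio_deprived > 0):
        raise ValueError("invalid ratio: all inputs must be > 0")
    return delta_e / (ratio_deprived / ratio_control)


def derive_pi(ic_ratio_control: float, ic_ratio_deprived: float) -> float:
    """Potentiation factor for recurrent excitation onto inhibitory neurons.

    The intracortical E-I charge ratio drops after deprivation; with
    PV->pyramidal strength unchanged, the whole shift is attributed to
    potentiation of excitatory feedback onto inhibitory cells:

        pi = ic_ratio_control / ic_ratio_deprived
    """
    if not (ic_ratio_control > 0 and ic_ratio_deprived > 0):
        raise ValueError("invalid ratio: both ratios must be > 0")
    return ic_ratio_control / ic_ratio_deprived


def make_factors(delta_e: float, delta_i: float, pi_fb: float) -> ScenarioFactors:
    """Bundle the three factors, computing ``rho_ei = delta_e / delta_i``.

    Values above 1 for the depression factors are accepted with a warning
    (they would describe potentiation, not depression).
    """
    if delta_e > 1 or delta_i > 1:
        import warnings

        warnings.warn(
            "depression factor > 1: delta_e/delta_i normally lie in (0, 1]",
            stacklevel=2,
        )
    return ScenarioFactors(delta_e=delta_e, delta_i=delta_i, pi_fb=pi_fb)
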