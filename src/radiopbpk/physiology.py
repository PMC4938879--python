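"""Reference physiology and construction of the compartment network.

The model body is divided into seven well-stirred compartments — lungs,
arterial blood, venous blood, kidney, liver, brain and a lumped rest-of-body
— connected by blood flow.  This module holds the physiological constants
(organ masses, blood-flow fractions, cardiac-output allometry) and derives
from them the per-compartment volumes [ml] and blood flows [ml/min] that the
ODE model consumes.

Conventions
-----------
* Compartments are identified by the short codes ``Lu, A, V, K, L, BR, RB``.
* Internal units are ml, min and Bq; unit conversions live at the I/O
  boundary.
* The brain compartment is restricted to its vascular space: large peptides
  do not cross the blood-brain barrier, so only the cerebral blood volume
  (3.8 % of the brain by default) is available for distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "COMPARTMENTS",
    "SYSTEMIC_ORGANS",
    "PhysiologySpec",
    "CompartmentSet",
    "default_physiology",
    "cardiac_output",
    "build_compartments",
]

#: Ordered compartment codes: lungs, arterial, venous, kidney, liver, brain,
#: rest of body.
COMPARTMENTS: tuple[str, ...] = ("Lu", "A", "V", "K", "L", "BR", "RB")

#: Organs fed in parallel from the arterial compartment; their flows must sum
#: to the cardiac output.
SYSTEMIC_ORGANS: tuple[str, ...] = ("K", "L", "BR", "RB")

_ORGAN_KEYS = (
    "lungs",
    "kidney",
    "liver",
    "brain",
    "venous_blood",
    "arterial_blood",
    "rest_of_body",
)

_ORGAN_TO_CODE = {
    "lungs": "Lu",
    "kidney": "K",
    "liver": "L",
    "brain": "BR",
    "venous_blood": "V",
    "arterial_blood": "A",
    "rest_of_body": "RB",
}

_FLOW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PhysiologySpec:
    """Physiological constants defining one (reference or patient) body.

    Parameters
    ----------
    organ_masses
        Organ mass [g] for each of the seven organs/compartments.
    flow_fractions
        Percentage of cardiac output perfusing each systemic organ
        (kidney, liver, brain, rest_of_body).  Lungs and the two blood
        compartments carry the full cardiac output in series and are not
        listed here.
    tissue_density
        Average tissue density [g/ml] used to convert masses to volumes.
    cardiac_output_coeff, cardiac_output_exponent
        Allometric cardiac output ``coeff * BW**exponent`` in L/h with body
        weight in kg.
    body_weight
        Body weight [kg].
    brain_cbv_fraction
        Fraction of the anatomical brain volume accessible to the tracer
        (the cerebral blood volume).
    """

    organ_masses: dict[str, float]
    flow_fractions: dict[str, float]
    tissue_density: float = 1.0
    cardiac_output_coeff: float = 15.0
    cardiac_output_exponent: float = 0.74
    body_weight: float = 70.0
    brain_cbv_fraction: float = 0.038

    def __post_init__(self) -> None:
        missing = set(_ORGAN_KEYS) - set(self.organ_masses)
        if missing:
            raise ValueError(f"organ_masses missing entries: {sorted(missing)}")
        for organ, mass in self.organ_masses.items():
            if not mass > 0:
                raise ValueError(f"organ mass must be > 0, got {organ}={mass}")
        systemic = {"kidney", "liver", "brain", "rest_of_body"}
        missing = systemic - set(self.flow_fractions)
        if missing:
            raise ValueError(f"flow_fractions missing entries: {sorted(missing)}")
        for organ, frac in self.flow_fractions.items():
            if not 0 < frac <= 100:
                raise ValueError(
                    f"flow fraction must be in (0, 100], got {organ}={frac}"
                )
        total = sum(self.flow_fractions[o] for o in systemic)
        if abs(total - 100.0) > _FLOW_SUM_TOL:
            raise ValueError(
                "systemic flow fractions must sum to 100%: "
                f"got {total!r} (deficit {100.0 - total!r})"
            )
        if not self.tissue_density > 0:
            raise ValueError("tissue_density must be > 0")
        if not 0 < self.brain_cbv_fraction <= 1:
            raise ValueError("brain_cbv_fraction must be in (0, 1]")
        if not self.body_weight > 0:
            raise ValueError("body_weight must be > 0")

    def with_(self, **changes) -> "PhysiologySpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class CompartmentSet:
    """Derived per-compartment volumes and flows.

    ``volumes`` and ``flows`` are keyed by compartment code.  ``flows`` for
    the lungs and the two blood compartments equal the total cardiac output
    ``q_c`` (series arrangement); systemic organ flows sum to ``q_c`` by
    construction (flow conservation).
    """

    volumes: dict[str, float]
    flows: dict[str, float]
    q_c: float
    order: tuple[str, ...] = field(default=COMPARTMENTS)

    def __post_init__(self) -> None:
        for code in self.order:
            if not self.volumes.get(code, 0.0) > 0:
                raise ValueError(f"compartment volume must be > 0: {code}")
        systemic_sum = sum(self.flows[c] for c in SYSTEMIC_ORGANS)
        if abs(systemic_sum - self.q_c) > _FLOW_SUM_TOL * max(self.q_c, 1.0):
            raise ValueError(
                "flow conservation violated: sum of systemic flows "
                f"{systemic_sum} != cardiac output {self.q_c}"
            )

    @property
    def volume_vector(self):
        import numpy as np

        return np.array([self.volumes[c] for c in self.order])


def default_physiology(**overrides) -> PhysiologySpec:
    """Reference adult physiology.

    Masses and flow fractions follow the standard human reference values
    used for this model: lungs 1000 g, kidney 299 g (22 % of cardiac
    output), liver 1910 g (17.5 %), brain 1420 g (11.4 %), venous and
    arterial blood 2350 g each, rest of body 64371 g (49.1 %).  Cardiac
    output is allometric, 15 L/(h·kg^0.74); density 1 g/ml; body weight
    70 kg; brain restricted to a 3.8 % cerebral blood volume.

    Keyword overrides are applied on top (e.g. ``body_weight=62``).
    """
    spec = PhysiologySpec(
        organ_masses={
            "lungs": 1000.0,
            "kidney": 299.0,
            "liver": 1910.0,
            "brain": 1420.0,
            "venous_blood": 2350.0,
            "arterial_blood": 2350.0,
            "rest_of_body": 64371.0,
        },
        flow_fractions={
            "kidney": 22.0,
            "liver": 17.5,
            "brain": 11.4,
            "rest_of_body": 49.1,
        },
    )
    if overrides:
        spec = spec.with_(**overrides)
    return spec


def cardiac_output(
    body_weight: float, coeff: float = 15.0, exponent: float = 0.74
) -> float:
    """Allometric total cardiac output, returned in ml/min.

    ``coeff * body_weight**exponent`` is evaluated in L/h (body weight in
    kg) and converted to ml/min.  At unit body weight the power term is 1,
    so the output is simply the coefficient: 15 L/h = 250 ml/min.
    """
    if not body_weight > 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight}")
    litres_per_hour = coeff * body_weight**exponent
    return litres_per_hour * 1000.0 / 60.0


def build_compartments(spec: PhysiologySpec) -> CompartmentSet:
    """Derive compartment volumes [ml] and blood flows [ml/min].

    Volumes are mass/density, except the brain which is restricted to its
    cerebral blood volume ``brain_cbv_fraction * mass / density``.  Flows
    are the stated fractions of the allometric cardiac output; lungs and
    the arterial/venous compartments carry the full cardiac output.
    """
    q_c = cardiac_output(
        spec.body_weight, spec.cardiac_output_coeff, spec.cardiac_output_exponent
    )
    volumes: dict[str, float] = {}
    for organ, mass in spec.organ_masses.items():
        code = _ORGAN_TO_CODE[organ]
        v = mass / spec.tissue_density
        if code == "BR":
            v *= spec.brain_cbv_fraction
        volumes[code] = v
    flows = {"Lu": q_c, "A": q_c, "V": q_c}
    for organ in ("kidney", "liver", "brain", "rest_of_body"):
        code = _ORGAN_TO_CODE[organ]
        flows[code] = spec.flow_fractions[organ] / 100.0 * q_c
    return CompartmentSet(volumes=volumes, flows=flows, q_c=q_c)
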