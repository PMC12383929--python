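"""Whole-eye compartmental sink for tear-film drug.

The tear-film Q3D network couples to an anatomically resolved compartment
model of the eye: a layered cornea (epithelium, stroma, endothelium), the
conjunctiva, aqueous humor, lens, iris-ciliary body, vitreous body, choroid,
sclera, and seven retinal layers (NFL, GCL, IPL, INL, OPL, PL, RPE) chained
linearly — sixteen compartments in all.  Species exchange is first-order and
permeability-limited:

    J_ab = PS_ab · (C_a − C_b / K_ab)      [µL/min · µg/mL]

where PS is a permeability–surface-area product and K_ab the equilibrium
partition coefficient of b relative to a.  The tear→epithelium link uses the
drug's tear–epithelium distribution coefficient K_D; the fornical sacs feed
the conjunctiva.  PS and partition values are calibration placeholders
exposed in the config — the acceptance surface of the simulator is the tear
film, and this model functions as a calibratable absorption sink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Q3DMesh
from .transport import SpeciesField

__all__ = [
    "EyeCompartment",
    "EyeLink",
    "EyeModel",
    "REQUIRED_COMPARTMENTS",
    "DEFAULT_EYE_CONFIG",
    "build_eye_model",
    "pk_step",
]

RETINA_LAYERS = ("NFL", "GCL", "IPL", "INL", "OPL", "PL", "RPE")

REQUIRED_COMPARTMENTS = (
    "cornea_epithelium",
    "cornea_stroma",
    "cornea_endothelium",
    "conjunctiva",
    "aqueous_humor",
    "lens",
    "iris_ciliary_body",
    "vitreous_body",
    "choroid",
    "sclera",
) + RETINA_LAYERS


@dataclass
class EyeCompartment:
    """Homogeneous tissue compartment.

    ``clearance`` [µL/min] removes drug irreversibly (e.g. aqueous turnover,
    choroidal blood flow); cleared mass is tallied on the model.
    """

    name: str
    volume_uL: float
    concentration: float = 0.0  # µg/mL
    clearance_uL_min: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_uL <= 0:
            raise ValueError(f"compartment {self.name!r} needs volume > 0")
        if self.clearance_uL_min < 0:
            raise ValueError("clearance must be >= 0")


@dataclass(frozen=True)
class EyeLink:
    """Symmetric exchange link a↔b with partition K = C_b/C_a at equilibrium."""

    a: str
    b: str
    PS_uL_min: float
    partition: float = 1.0

    def __post_init__(self) -> None:
        if self.PS_uL_min < 0:
            raise ValueError(f"link {self.a}->{self.b}: PS must be >= 0")
        if self.partition <= 0:
            raise ValueError(f"link {self.a}->{self.b}: partition must be > 0")


@dataclass
class EyeModel:
    """Compartment set, adjacency, and tear-film coupling."""

    compartments: dict[str, EyeCompartment]
    links: list[EyeLink]
    PS_cornea_uL_min: float = 0.3  # tear film -> corneal epithelium
    PS_conjunctiva_uL_min: float = 0.6  # fornical sacs -> conjunctiva
    cleared_ug: float = 0.0

    @property
    def total_mass_ug(self) -> float:
        return float(
            sum(c.concentration * c.volume_uL * 1e-3 for c in self.compartments.values())
            + self.cleared_ug
        )

    def concentration(self, name: str) -> float:
        return self.compartments[name].concentration


# Volumes are literature-scale placeholders [µL]; PS values are calibration
# placeholders [µL/min] to be fitted against a user's own data.
DEFAULT_EYE_CONFIG: dict = {
    "compartments": {
        "cornea_epithelium": {"volume_uL": 3.5},
        "cornea_stroma": {"volume_uL": 28.0},
        "cornea_endothelium": {"volume_uL": 1.0},
        "conjunctiva": {"volume_uL": 35.0},
        "aqueous_humor": {"volume_uL": 250.0, "clearance_uL_min": 2.5},
        "lens": {"volume_uL": 230.0},
        "iris_ciliary_body": {"volume_uL": 60.0},
        "vitreous_body": {"volume_uL": 4000.0},
        "choroid": {"volume_uL": 400.0, "clearance_uL_min": 10.0},
        "sclera": {"volume_uL": 550.0},
        "NFL": {"volume_uL": 15.0},
        "GCL": {"volume_uL": 15.0},
        "IPL": {"volume_uL": 20.0},
        "INL": {"volume_uL": 20.0},
        "OPL": {"volume_uL": 15.0},
        "PL": {"volume_uL": 25.0},
        "RPE": {"volume_uL": 10.0},
    },
    "links": [
        {"a": "cornea_epithelium", "b": "cornea_stroma", "PS_uL_min": 1.5},
        {"a": "cornea_stroma", "b": "cornea_endothelium", "PS_uL_min": 2.0},
        {"a": "cornea_endothelium", "b": "aqueous_humor", "PS_uL_min": 2.0},
        {"a": "aqueous_humor", "b": "lens", "PS_uL_min": 0.1},
        {"a": "aqueous_humor", "b": "iris_ciliary_body", "PS_uL_min": 1.0},
        {"a": "aqueous_humor", "b": "vitreous_body", "PS_uL_min": 0.3},
        {"a": "vitreous_body", "b": "NFL", "PS_uL_min": 0.2},
        {"a": "NFL", "b": "GCL", "PS_uL_min": 0.5},
        {"a": "GCL", "b": "IPL", "PS_uL_min": 0.5},
        {"a": "IPL", "b": "INL", "PS_uL_min": 0.5},
        {"a": "INL", "b": "OPL", "PS_uL_min": 0.5},
        {"a": "OPL", "b": "PL", "PS_uL_min": 0.5},
        {"a": "PL", "b": "RPE", "PS_uL_min": 0.5},
        {"a": "RPE", "b": "choroid", "PS_uL_min": 0.5},
        {"a": "choroid", "b": "sclera", "PS_uL_min": 0.8},
        {"a": "sclera", "b": "conjunctiva", "PS_uL_min": 0.8},
    ],
    "tear_coupling": {"PS_cornea_uL_min": 0.3, "PS_conjunctiva_uL_min": 0.6},
}


class EyeConfigError(ValueError):
    """Invalid eye-model configuration."""


def build_eye_model(config: dict | None = None) -> EyeModel:
    """Construct and validate the whole-eye model from a config mapping.

    The config must name every required compartment; links may only refer
    to configured compartments (a dangling link is a config error).
    """
    cfg = config if config is not None else DEFAULT_EYE_CONFIG
    comp_cfg = cfg.get("compartments", {})
    missing = [n for n in REQUIRED_COMPARTMENTS if n not in comp_cfg]
    if missing:
        raise EyeConfigError(f"missing compartments: {missing}")
    compartments = {
        name: EyeCompartment(
            name=name,
            volume_uL=c["volume_uL"],
            concentration=c.get("concentration", 0.0),
            clearance_uL_min=c.get("clearance_uL_min", 0.0),
        )
        for name, c in comp_cfg.items()
    }
    links = []
    for lk in cfg.get("links", []):
        for end in (lk["a"], lk["b"]):
            if end not in compartments:
                raise EyeConfigError(
                    f"link {lk['a']}->{lk['b']} references unknown "
                    f"compartment {end!r}"
                )
        links.append(
            EyeLink(
                a=lk["a"],
                b=lk["b"],
                PS_uL_min=lk["PS_uL_min"],
                partition=lk.get("partition", 1.0),
            )
        )
    tc = cfg.get("tear_coupling", {})
    return EyeModel(
        compartments=compartments,
        links=links,
        PS_cornea_uL_min=tc.get("PS_cornea_uL_min", 0.3),
        PS_conjunctiva_uL_min=tc.get("PS_conjunctiva_uL_min", 0.6),
    )


def pk_step(
    model: EyeModel,
    tear_field: SpeciesField,
    mesh: Q3DMesh,
    volumes_uL: np.ndarray,
    dt: float,
    K_D: float = 2.5,
) -> tuple[EyeModel, SpeciesField]:
    """Advance inter-compartment exchange one explicit step (in place).

    Tear→epithelium flux uses the tear-film region average against the
    epithelial concentration scaled by the distribution coefficient ``K_D``;
    sac fluid feeds the conjunctiva the same way.  Fluxes between linked eye
    compartments follow J = PS(C_a − C_b/K).  Net transfer out of the tear
    surface accumulates in the field's absorbed sink; clearance mass is
    tallied on the model, so tear + eye + sinks is conserved.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tear_field = tear_field.copy()
    v = np.asarray(volumes_uL, dtype=float)

    def couple(region_idx: list[int], comp_name: str, PS: float) -> None:
        if PS <= 0:
            return
        comp = model.compartments[comp_name]
        v_sel = v[region_idx]
        vtot = float(v_sel.sum())
        if vtot <= 0:
            return
        c_tear = tear_field.dissolved_ug[region_idx].sum() / (vtot * 1e-3)
        J = PS / 60.0 * 1e-3 * (c_tear - comp.concentration / K_D)  # µg/s
        transfer = J * dt
        # never withdraw more than the region holds
        transfer = min(transfer, float(tear_field.dissolved_ug[region_idx].sum()))
        w = v_sel / vtot
        tear_field.dissolved_ug[region_idx] -= transfer * w
        comp.concentration += transfer / (comp.volume_uL * 1e-3)
        tear_field.sinks["absorbed"] += transfer

    couple(mesh.region_indices("tear_film"), "cornea_epithelium",
           model.PS_cornea_uL_min)
    sac_idx = mesh.region_indices("upper_fornical_sac") + mesh.region_indices(
        "lower_fornical_sac"
    )
    couple(sac_idx, "conjunctiva", model.PS_conjunctiva_uL_min)

    dmass = {name: 0.0 for name in model.compartments}
    for lk in model.links:
        ca = model.compartments[lk.a].concentration
        cb = model.compartments[lk.b].concentration
        J = lk.PS_uL_min / 60.0 * 1e-3 * (ca - cb / lk.partition)
        dmass[lk.a] -= J * dt
        dmass[lk.b] += J * dt
    for name, comp in model.compartments.items():
        if comp.clearance_uL_min > 0:
            out = comp.clearance_uL_min / 60.0 * 1e-3 * comp.concentration * dt
            out = min(out, comp.concentration * comp.volume_uL * 1e-3 + dmass[name])
            dmass[name] -= out
            model.cleared_ug += out
        comp.concentration += dmass[name] / (comp.volume_uL * 1e-3)
    return model, tear_field
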