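"""Parameterized solid-supported bilayer models.

A supported membrane on a silicon wafer is modelled as::

    Si | SiO2 | [interstitial water] | inner heads | tails | outer heads | solvent

with the tails either a single layer (three-layer bilayer model) or split
into inner and outer sub-layers with independently adjustable SLDs
(four-layer model, used once peptide is bound and the two leaflets may
differ).  The beam enters through the silicon, so "inner" means closest to
the oxide and the incident medium of the reflectivity kernel is silicon.

Structural parameters (thicknesses, roughnesses, volume fractions) are
shared across solvent contrasts; only the solvent SLD and the labile-H
exchange of headgroups and peptide differ between D2O and H2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from . import materials as mat
from .reflect_kernel import ReflectivityCurve, ResolutionSpec, Slab, abeles_reflectivity, smear

__all__ = [
    "Parameter",
    "ParameterSet",
    "Contrast",
    "MembraneModel",
    "build_model",
]

FRACTION_TOL = 0.02

Scenario = Literal["none", "uneven", "oriented_n_in", "oriented_n_out"]


class ModelError(ValueError):
    pass


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass
class Parameter:
    """A named model parameter with bounds, a vary flag and an optional tie
    to a master parameter (tied parameters mirror the master's value)."""

    name: str
    value: float
    lower: float = -np.inf
    upper: float = np.inf
    vary: bool = False
    tie: str | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ModelError(f"{self.name}: bounds out of order")


class ParameterSet:
    """Ordered collection of :class:`Parameter` with tie resolution and a
    flat free-vector view for the optimizer."""

    def __init__(self, params: Iterable[Parameter] = ()) -> None:
        self._params: dict[str, Parameter] = {}
        for p in params:
            self.add(p)

    def add(self, p: Parameter) -> Parameter:
        self._params[p.name] = p
        return p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def names(self) -> list[str]:
        return list(self._params)

    def value(self, name: str) -> float:
        """Resolved value of a parameter (following ties to the master)."""
        seen = set()
        p = self._params[name]
        while p.tie is not None:
            if p.name in seen:
                raise ModelError(f"tie cycle at {p.name}")
            seen.add(p.name)
            p = self._params[p.tie]
        return p.value

    def free_names(self) -> list[str]:
        return [p.name for p in self if p.vary and p.tie is None]

    def free_values(self) -> np.ndarray:
        return np.array([self._params[n].value for n in self.free_names()])

    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self._params[n].lower for n in self.free_names()])
        hi = np.array([self._params[n].upper for n in self.free_names()])
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ModelError("varied parameters must have finite bounds")
        return lo, hi

    def set_free(self, values: Sequence[float]) -> None:
        names = self.free_names()
        if len(values) != len(names):
            raise ModelError("free-vector length mismatch")
        for n, v in zip(names, values):
            self._params[n].value = float(v)

    def copy(self) -> "ParameterSet":
        return ParameterSet(replace(p) for p in self)

    def report(self) -> list[dict]:
        """Flat round-trippable parameter table."""
        return [
            {
                "name": p.name,
                "value": self.value(p.name),
                "lower": p.lower,
                "upper": p.upper,
                "vary": p.vary,
                "tie": p.tie,
            }
            for p in self
        ]


# --------------------------------------------------------------------------
# Contrasts and the membrane model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Contrast:
    """A solvent contrast: name and deuterium fraction of the water."""

    name: str
    d_fraction: float


_STANDARD_CONTRASTS = {"d2o": Contrast("d2o", 1.0), "h2o": Contrast("h2o", 0.0)}


@dataclass
class MembraneModel:
    """A bilayer slab model shared across solvent contrasts.

    ``fitted_tail_slds=True`` switches the tail layers from
    composition-derived SLDs to directly fitted per-contrast layer SLDs
    (solvent included) — the parametrization used for peptide-bound data
    where the leaflet compositions are unknown.
    """

    template: Literal["three_layer", "four_layer"]
    contrasts: dict[str, Contrast]
    parameters: ParameterSet
    peptide: mat.LabeledPeptide | None = None
    scenario: Scenario = "none"
    fitted_tail_slds: bool = False
    interstitial_water: bool = False
    resolution: ResolutionSpec = field(default_factory=ResolutionSpec)
    lipid_tail_sld: Mapping[str, float] = field(default_factory=dict)
    head_sld: Mapping[str, float] = field(default_factory=dict)

    # -- per-leaflet peptide SLD under the generation/interpretation scenario
    def peptide_sld(self, contrast: str, leaflet: Literal["inner", "outer"]) -> float:
        if self.peptide is None:
            return 0.0
        f = self.contrasts[contrast].d_fraction
        if self.scenario in ("none", "uneven"):
            segment = "whole"
        elif self.scenario == "oriented_n_in":
            segment = "n_half" if leaflet == "inner" else "c_half"
        elif self.scenario == "oriented_n_out":
            segment = "c_half" if leaflet == "inner" else "n_half"
        else:
            raise ModelError(f"unknown scenario: {self.scenario}")
        return mat.peptide_sld(self.peptide, f, segment)

    def _tail_layer(self, contrast: str, leaflet: Literal["inner", "outer"],
                    thickness: float, roughness: float) -> Slab:
        p = self.parameters
        solvent = p.value(f"solvent_sld_{contrast}")
        if self.fitted_tail_slds:
            sld = p.value(f"tail_sld_{leaflet}_{contrast}")
            return Slab(thickness, sld, roughness)
        phi_lip = p.value("phi_lipid")
        phi_pep = p.value(f"phi_peptide_{leaflet}") if self.peptide is not None else 0.0
        phi_solv = 1.0 - phi_lip - phi_pep
        if phi_solv < -FRACTION_TOL:
            raise ModelError(
                f"tail fractions exceed 1 (phi_lipid={phi_lip}, phi_peptide={phi_pep})"
            )
        phi_solv = max(phi_solv, 0.0)
        sld = mat.mix_sld(
            [
                (self.lipid_tail_sld[contrast], phi_lip),
                (self.peptide_sld(contrast, leaflet), phi_pep),
                (solvent, phi_solv),
            ],
            tol=FRACTION_TOL,
        )
        return Slab(thickness, sld, roughness)

    def expand(self, contrast: str) -> list[Slab]:
        """Slab stack for one contrast: semi-infinite Si first, solvent last."""
        if contrast not in self.contrasts:
            raise ModelError(f"unknown contrast: {contrast!r}")
        p = self.parameters
        solvent = p.value(f"solvent_sld_{contrast}")
        rough_bi = p.value("roughness_bilayer")

        def hydrated(dry: float, phi_solvent: float) -> float:
            return mat.mix_sld(
                [(dry, 1.0 - phi_solvent), (solvent, phi_solvent)], tol=FRACTION_TOL
            )

        stack = [Slab(0.0, p.value("substrate_sld"))]
        stack.append(
            Slab(
                p.value("oxide_thickness"),
                hydrated(p.value("oxide_sld"), p.value("oxide_solvent")),
                p.value("roughness_oxide"),
            )
        )
        if self.interstitial_water:
            stack.append(Slab(p.value("water_thickness"), solvent, rough_bi))
        head = self.head_sld[contrast]
        phi_h = p.value("head_solvent")
        stack.append(Slab(p.value("head_thickness_inner"), hydrated(head, phi_h), rough_bi))
        if self.template == "three_layer":
            stack.append(
                self._tail_layer(contrast, "inner", p.value("tail_thickness"), rough_bi)
            )
        elif self.template == "four_layer":
            stack.append(
                self._tail_layer(contrast, "inner", p.value("tail_thickness_inner"), rough_bi)
            )
            stack.append(
                self._tail_layer(contrast, "outer", p.value("tail_thickness_outer"), rough_bi)
            )
        else:
            raise ModelError(f"unknown template: {self.template!r}")
        stack.append(Slab(p.value("head_thickness_outer"), hydrated(head, phi_h), rough_bi))
        stack.append(Slab(0.0, solvent, p.value("roughness_solvent")))
        return stack

    def model_r(self, contrast: str, q: np.ndarray,
                resolution: ResolutionSpec | None = None) -> np.ndarray:
        """Resolution-smeared model reflectivity for one contrast."""
        res = resolution or self.resolution
        return smear(lambda qq: abeles_reflectivity(self.expand(contrast), qq), q, res)

    @property
    def tail_thickness_total(self) -> float:
        p = self.parameters
        if self.template == "three_layer":
            return p.value("tail_thickness")
        return p.value("tail_thickness_inner") + p.value("tail_thickness_outer")

    def copy(self) -> "MembraneModel":
        return replace(self, parameters=self.parameters.copy())


# --------------------------------------------------------------------------
# Templates
# --------------------------------------------------------------------------

def build_model(
    template: Literal["three_layer", "four_layer"],
    contrasts: Sequence[str] = ("d2o", "h2o"),
    peptide: mat.LabeledPeptide | None = None,
    scenario: Scenario = "none",
    lipid_deuterated: bool = False,
    fitted_tail_slds: bool = False,
    interstitial_water: bool = False,
    resolution: ResolutionSpec | None = None,
) -> MembraneModel:
    """Construct a DMPC/DMPG (3:1) supported-bilayer model with default
    structural values and bounds.

    ``lipid_deuterated`` selects d54 (chain-perdeuterated) acyl tails.
    Parameters default to ``vary=False``; the caller flags what to refine.
    """
    if template not in ("three_layer", "four_layer"):
        raise ModelError(f"unknown template: {template!r}")
    cmap = {}
    for c in contrasts:
        if c not in _STANDARD_CONTRASTS:
            raise ModelError(f"unknown contrast: {c!r} (expected d2o/h2o)")
        cmap[c] = _STANDARD_CONTRASTS[c]

    tail_name = "myristoyl_tails_d54" if lipid_deuterated else "myristoyl_tails_h"
    tail_sld = {c: mat.material_sld(tail_name) for c in cmap}
    head_sld = {
        c: mat.material_sld("pcpg_head_3to1", solvent_d_fraction=cmap[c].d_fraction)
        for c in cmap
    }

    ps = ParameterSet()
    ps.add(Parameter("substrate_sld", 2.07e-6, 2.0e-6, 2.2e-6))
    ps.add(Parameter("oxide_sld", 3.47e-6, 3.0e-6, 3.8e-6))
    ps.add(Parameter("oxide_thickness", 10.0, 3.0, 30.0))
    ps.add(Parameter("oxide_solvent", 0.0, 0.0, 0.5))
    ps.add(Parameter("roughness_oxide", 3.0, 0.5, 8.0))
    ps.add(Parameter("roughness_bilayer", 3.0, 0.5, 8.0))
    ps.add(Parameter("roughness_solvent", 3.0, 0.5, 8.0))
    if interstitial_water:
        ps.add(Parameter("water_thickness", 3.0, 0.0, 15.0))
    ps.add(Parameter("head_thickness_inner", 8.0, 5.0, 14.0))
    ps.add(Parameter("head_thickness_outer", 8.0, 5.0, 14.0, tie="head_thickness_inner"))
    ps.add(Parameter("head_solvent", 0.3, 0.0, 0.8))
    if template == "three_layer":
        ps.add(Parameter("tail_thickness", 26.0, 18.0, 40.0))
    else:
        ps.add(Parameter("tail_thickness_inner", 13.0, 9.0, 20.0))
        ps.add(Parameter("tail_thickness_outer", 13.0, 9.0, 20.0))
    ps.add(Parameter("phi_lipid", 0.95, 0.5, 1.0))
    for c in cmap.values():
        ps.add(
            Parameter(
                f"solvent_sld_{c.name}",
                mat.solvent_sld(c.d_fraction),
                -0.6e-6,
                6.4e-6,
            )
        )
    if peptide is not None:
        ps.add(Parameter("phi_peptide_inner", 0.0, 0.0, 0.5))
        ps.add(Parameter("phi_peptide_outer", 0.0, 0.0, 0.5))
    if fitted_tail_slds:
        leaflets = ("inner", "outer") if template == "four_layer" else ("inner",)
        for leaflet in leaflets:
            for c in cmap:
                ps.add(
                    Parameter(f"tail_sld_{leaflet}_{c}", tail_sld[c], -1.0e-6, 8.0e-6)
                )

    return MembraneModel(
        template=template,
        contrasts=cmap,
        parameters=ps,
        peptide=peptide,
        scenario=scenario,
        fitted_tail_slds=fitted_tail_slds,
        interstitial_water=interstitial_water,
        resolution=resolution or ResolutionSpec(),
        lipid_tail_sld=tail_sld,
        head_sld=head_sld,
    )
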