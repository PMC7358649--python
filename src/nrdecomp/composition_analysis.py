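"""Interpretation of fitted bilayer structure.

Once the slab model is refined against two (or more) solvent contrasts, the
fitted layer SLDs can be decomposed into component volume fractions, because
each contrast adds an independent linear equation

    SLD_layer(c) = SLD_lipid(c) phi_lipid + SLD_peptide(c) phi_peptide
                   + SLD_solvent(c) phi_solvent,        sum(phi) = 1.

From the tail-region decomposition follow the area per lipid

    A_lipid = V_m / (tau * phi_lipid)

(V_m the lipid tail volume, tau the leaflet tail thickness), the
fluid-vs-gel phase call, and — with a peptide deuterated only in its
N-terminal half — a comparison of two structural interpretations of
leaflet-asymmetric SLDs: an uneven peptide distribution across the leaflets
(scenario A) versus a membrane-spanning peptide with a preferred orientation
(scenario B, evaluated N-terminus-in and N-terminus-out).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from . import materials as mat

__all__ = [
    "DecompositionResult",
    "ScenarioComparison",
    "area_per_lipid",
    "assign_phase",
    "peptide_volume_fraction",
    "orientation_scenarios",
    "helix_length",
    "decompose_fit_report",
]

#: molecular volume of one lipid's two myristoyl chains (A^3)
DEFAULT_TAIL_VOLUME = 756.0

#: area-per-lipid threshold (A^2) separating fluid (L_alpha) from gel
#: (L_beta) for di-C14 PC/PG bilayers near their melting transition
DEFAULT_PHASE_THRESHOLD = 47.0

#: canonical alpha-helix rise per residue (A)
ALPHA_HELIX_RISE = 1.5

#: default per-equation SLD tolerance (1/A^2) when judging scenarios without
#: a propagated uncertainty
DEFAULT_SLD_TOL = 2e-8


class AnalysisError(ValueError):
    pass


def area_per_lipid(v_m: float, tau: float, phi_lipid: float) -> float:
    """A_lipid = V_m / (tau * phi_lipid), in A^2.

    ``v_m`` is the molecular volume of the lipid component occupying the
    layer (A^3), ``tau`` the layer thickness (A), ``phi_lipid`` its volume
    fraction."""
    if tau <= 0:
        raise AnalysisError(f"tau must be > 0, got {tau}")
    if not 0.0 < phi_lipid <= 1.0:
        raise AnalysisError(f"phi_lipid must be in (0, 1], got {phi_lipid}")
    return v_m / (tau * phi_lipid)


def assign_phase(
    a_lipid: float, threshold: float = DEFAULT_PHASE_THRESHOLD
) -> Literal["liquid_crystalline", "gel"]:
    """Phase call from the area per lipid; values at the threshold are
    assigned to the fluid phase."""
    if a_lipid <= 0:
        raise AnalysisError(f"area per lipid must be > 0, got {a_lipid}")
    return "liquid_crystalline" if a_lipid >= threshold else "gel"


def helix_length(n_residues: int, rise_per_residue: float = ALPHA_HELIX_RISE) -> float:
    """End-to-end length (nm) of an ideal linear alpha-helix of
    ``n_residues`` residues."""
    if n_residues < 0:
        raise AnalysisError(f"negative residue count: {n_residues}")
    return n_residues * rise_per_residue / 10.0


# --------------------------------------------------------------------------
# Volume-fraction decomposition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeFractions:
    phi_lipid: float
    phi_peptide: float
    phi_solvent: float
    residual: float  # rms SLD misfit, 1/A^2
    condition_number: float
    clipped: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi_lipid, self.phi_peptide, self.phi_solvent)


def _solve_fractions(
    rows: list[tuple[float, float, float, float]]
) -> tuple[np.ndarray, float, float]:
    """Least-squares solve of sum_k SLD_k phi_k = m with sum(phi) = 1.

    Each row is (m, lipid, peptide, solvent).  phi_lipid is eliminated via
    the closure, leaving m - L = (P - L) phi_p + (S - L) phi_s.
    Returns (phi[3], rms residual, condition number).
    """
    a = np.array([[p - l, s - l] for _, l, p, s in rows])
    b = np.array([m - l for m, l, _, s in rows])
    cond = float(np.linalg.cond(a))
    if not np.isfinite(cond) or cond > 1e12:
        raise AnalysisError(
            "degenerate contrast set: component SLDs are not distinguishable "
            f"(condition number {cond:.3g})"
        )
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    phi_p, phi_s = x
    phi = np.array([1.0 - phi_p - phi_s, phi_p, phi_s])
    resid = a @ x - b
    rms = float(np.sqrt(np.mean(resid**2)))
    return phi, rms, cond


def peptide_volume_fraction(
    layer_slds: Mapping[str, float],
    sld_lipid: Mapping[str, float],
    sld_peptide: Mapping[str, float],
    sld_solvent: Mapping[str, float],
) -> VolumeFractions:
    """Decompose one layer's per-contrast SLDs into lipid, peptide and
    solvent volume fractions (closure sum(phi) = 1; least squares when more
    than two contrasts are available).  Fractions outside [0, 1] are clipped
    and flagged."""
    contrasts = list(layer_slds)
    if len(contrasts) < 2:
        raise AnalysisError("need at least two contrasts to decompose a layer")
    rows = [
        (layer_slds[c], sld_lipid[c], sld_peptide[c], sld_solvent[c]) for c in contrasts
    ]
    phi, rms, cond = _solve_fractions(rows)
    clipped = bool(np.any(phi < -1e-9) or np.any(phi > 1 + 1e-9))
    phi = np.clip(phi, 0.0, 1.0)
    return VolumeFractions(
        phi_lipid=float(phi[0]),
        phi_peptide=float(phi[1]),
        phi_solvent=float(phi[2]),
        residual=rms,
        condition_number=cond,
        clipped=clipped,
    )


# --------------------------------------------------------------------------
# Orientation scenarios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioComparison:
    """Comparison of leaflet-asymmetry interpretations.

    ``uneven`` holds per-leaflet fractions under an uneven peptide
    distribution; ``oriented`` holds, per orientation, the single shared
    peptide fraction of a membrane-spanning peptide with per-leaflet solvent.
    ``best`` is the preferred interpretation; ``indistinguishable`` is set
    when the orientations cannot be separated within the SLD uncertainty.
    """

    uneven: dict[str, VolumeFractions]  # keys: inner, outer
    uneven_residual: float
    oriented: dict[str, dict]  # keys: n_in, n_out
    best: str  # "uneven" | "n_in" | "n_out"
    indistinguishable: bool
    sld_tolerance: float


def _oriented_solve(
    inner: Mapping[str, float],
    outer: Mapping[str, float],
    pep_inner: Mapping[str, float],
    pep_outer: Mapping[str, float],
    lipid: Mapping[str, float],
    solvent: Mapping[str, float],
) -> dict:
    """One shared phi_peptide, per-leaflet solvent, over both leaflets and
    all contrasts (least squares)."""
    contrasts = list(inner)
    # unknowns: phi_p, phi_s_in, phi_s_out; closure per leaflet
    a, b = [], []
    for c in contrasts:
        a.append([pep_inner[c] - lipid[c], solvent[c] - lipid[c], 0.0])
        b.append(inner[c] - lipid[c])
    for c in contrasts:
        a.append([pep_outer[c] - lipid[c], 0.0, solvent[c] - lipid[c]])
        b.append(outer[c] - lipid[c])
    a, b = np.array(a), np.array(b)
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    phi_p, phi_s_in, phi_s_out = x
    resid = a @ x - b
    rms = float(np.sqrt(np.mean(resid**2)))
    clipped = bool(np.any(x < -1e-9) or phi_p + max(phi_s_in, phi_s_out) > 1 + 1e-9)
    return {
        "phi_peptide": float(np.clip(phi_p, 0.0, 1.0)),
        "phi_solvent_inner": float(np.clip(phi_s_in, 0.0, 1.0)),
        "phi_solvent_outer": float(np.clip(phi_s_out, 0.0, 1.0)),
        "phi_lipid_inner": float(np.clip(1.0 - phi_p - phi_s_in, 0.0, 1.0)),
        "phi_lipid_outer": float(np.clip(1.0 - phi_p - phi_s_out, 0.0, 1.0)),
        "residual": rms,
        "clipped": clipped,
    }


def orientation_scenarios(
    inner_leaflet_slds: Mapping[str, float],
    outer_leaflet_slds: Mapping[str, float],
    peptide: mat.LabeledPeptide,
    lipid_slds: Mapping[str, float],
    solvent_slds: Mapping[str, float],
    solvent_d_fraction: Mapping[str, float] | None = None,
    sld_uncertainty: float | None = None,
) -> ScenarioComparison:
    """Compare interpretations of a leaflet SLD asymmetry.

    Scenario A ("uneven"): the whole-peptide SLD in both leaflets with
    independent per-leaflet fractions.  Scenario B ("oriented"): a spanning
    peptide contributes its N-terminal-half SLD to one leaflet and its
    C-terminal-half SLD to the other, with a single shared peptide fraction;
    both orientations are evaluated.  The scenario with the smallest misfit
    wins, with a parsimony preference for the more constrained oriented
    scenarios when residuals agree within ``sld_uncertainty``; orientations
    whose residuals differ by less than the uncertainty are flagged
    indistinguishable.

    Requires an asymmetrically labeled peptide — with identical half SLDs
    the orientations are equal by construction.
    """
    contrasts = list(inner_leaflet_slds)
    if set(outer_leaflet_slds) != set(contrasts):
        raise AnalysisError("leaflet SLD contrast sets differ")
    dfrac = solvent_d_fraction or {c: (1.0 if c == "d2o" else 0.0) for c in contrasts}
    tol = DEFAULT_SLD_TOL if sld_uncertainty is None else float(sld_uncertainty)

    d_n = sum(peptide.deuteron_count(p) for p in peptide.segment_residues("n_half"))
    d_c = sum(peptide.deuteron_count(p) for p in peptide.segment_residues("c_half"))
    if d_n == d_c:
        raise AnalysisError(
            "peptide labeling is symmetric between the halves; orientations "
            "are indistinguishable by construction"
        )
    pep_whole = {c: mat.peptide_sld(peptide, dfrac[c], "whole") for c in contrasts}
    pep_n = {c: mat.peptide_sld(peptide, dfrac[c], "n_half") for c in contrasts}
    pep_c = {c: mat.peptide_sld(peptide, dfrac[c], "c_half") for c in contrasts}

    uneven = {
        "inner": peptide_volume_fraction(
            inner_leaflet_slds, lipid_slds, pep_whole, solvent_slds
        ),
        "outer": peptide_volume_fraction(
            outer_leaflet_slds, lipid_slds, pep_whole, solvent_slds
        ),
    }
    uneven_res = float(
        np.sqrt(0.5 * (uneven["inner"].residual ** 2 + uneven["outer"].residual ** 2))
    )
    oriented = {
        "n_in": _oriented_solve(
            inner_leaflet_slds, outer_leaflet_slds, pep_n, pep_c, lipid_slds, solvent_slds
        ),
        "n_out": _oriented_solve(
            inner_leaflet_slds, outer_leaflet_slds, pep_c, pep_n, lipid_slds, solvent_slds
        ),
    }

    res_nin = oriented["n_in"]["residual"]
    res_nout = oriented["n_out"]["residual"]
    best_oriented = "n_in" if res_nin <= res_nout else "n_out"
    # parsimony: prefer the 3-parameter oriented fit over the saturated
    # uneven fit when it explains the data within tolerance
    if oriented[best_oriented]["residual"] <= uneven_res + tol:
        best = best_oriented
    else:
        best = "uneven"
    return ScenarioComparison(
        uneven=uneven,
        uneven_residual=uneven_res,
        oriented=oriented,
        best=best,
        indistinguishable=bool(abs(res_nin - res_nout) <= tol),
        sld_tolerance=tol,
    )


# --------------------------------------------------------------------------
# Per-state decomposition report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DecompositionResult:
    """Full interpretation of one fitted sample state."""

    layers: dict[str, VolumeFractions]
    area_per_lipid: float
    phase: str
    scenarios: ScenarioComparison | None = None
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD

    def report(self) -> dict:
        out = {
            "area_per_lipid_A2": self.area_per_lipid,
            "phase": self.phase,
            "phase_threshold_A2": self.phase_threshold,
            "layers": {
                name: {
                    "phi_lipid": vf.phi_lipid,
                    "phi_peptide": vf.phi_peptide,
                    "phi_solvent": vf.phi_solvent,
                    "residual": vf.residual,
                }
                for name, vf in self.layers.items()
            },
        }
        if self.scenarios is not None:
            sc = self.scenarios
            out["scenarios"] = {
                "best": sc.best,
                "indistinguishable": sc.indistinguishable,
                "sld_tolerance": sc.sld_tolerance,
                "uneven": {
                    leaf: {
                        "phi_peptide": vf.phi_peptide,
                        "phi_solvent": vf.phi_solvent,
                        "residual": vf.residual,
                    }
                    for leaf, vf in sc.uneven.items()
                },
                "oriented": sc.oriented,
            }
        return out


# --------------------------------------------------------------------------
# Decomposition of a fit report
# --------------------------------------------------------------------------

def _param_table(report: dict) -> tuple[dict, dict, dict]:
    values = {row["name"]: row["value"] for row in report["parameters"]}
    cis = {row["name"]: row.get("ci95") for row in report["parameters"]}
    stderr = {row["name"]: row.get("stderr") for row in report["parameters"]}
    return values, cis, stderr


def decompose_fit_report(
    report: dict,
    tail_volume: float = DEFAULT_TAIL_VOLUME,
    phase_threshold: float = DEFAULT_PHASE_THRESHOLD,
    sld_uncertainty: float | None = None,
) -> DecompositionResult:
    """Interpret a fit report produced by the refinement stage.

    For a composition-parameterized model the lipid fraction and tail
    thickness give the area per lipid and phase directly.  For a four-layer
    fit with directly fitted per-contrast tail SLDs, the leaflet SLDs are
    decomposed into volume fractions and the orientation scenarios compared;
    the scenario tolerance comes from the Monte-Carlo confidence intervals
    of the tail SLDs when present, else from their linearized errors.
    """
    values, cis, stderr = _param_table(report)
    contrasts = report.get("contrasts") or ["d2o", "h2o"]
    solvent = {c: values[f"solvent_sld_{c}"] for c in contrasts}

    if report.get("fitted_tail_slds"):
        tail_mat = (
            "myristoyl_tails_d54" if report.get("lipid_deuterated") else "myristoyl_tails_h"
        )
        lipid = {c: mat.material_sld(tail_mat) for c in contrasts}
        inner = {c: values[f"tail_sld_inner_{c}"] for c in contrasts}
        outer = {c: values[f"tail_sld_outer_{c}"] for c in contrasts}
        if sld_uncertainty is None:
            sigmas = []
            for leaflet in ("inner", "outer"):
                for c in contrasts:
                    name = f"tail_sld_{leaflet}_{c}"
                    if cis.get(name):
                        lo, hi = cis[name]
                        sigmas.append((hi - lo) / (2 * 1.96))
                    elif stderr.get(name):
                        sigmas.append(stderr[name])
            sld_uncertainty = float(np.mean(sigmas)) if sigmas else None
        peptide = mat.mac1()
        scenarios = orientation_scenarios(
            inner, outer, peptide, lipid, solvent, sld_uncertainty=sld_uncertainty
        )
        if scenarios.best == "uneven":
            layers = {"tails_inner": scenarios.uneven["inner"],
                      "tails_outer": scenarios.uneven["outer"]}
            phi_lip = {leaf: scenarios.uneven[k].phi_lipid
                       for leaf, k in (("inner", "inner"), ("outer", "outer"))}
        else:
            ori = scenarios.oriented[scenarios.best]
            layers = {
                f"tails_{leaf}": VolumeFractions(
                    phi_lipid=ori[f"phi_lipid_{leaf}"],
                    phi_peptide=ori["phi_peptide"],
                    phi_solvent=ori[f"phi_solvent_{leaf}"],
                    residual=ori["residual"],
                    condition_number=float("nan"),
                )
                for leaf in ("inner", "outer")
            }
            phi_lip = {leaf: ori[f"phi_lipid_{leaf}"] for leaf in ("inner", "outer")}
        tau = {
            "inner": values["tail_thickness_inner"],
            "outer": values["tail_thickness_outer"],
        }
        areas = [area_per_lipid(tail_volume, tau[leaf], phi_lip[leaf])
                 for leaf in ("inner", "outer") if phi_lip[leaf] > 0]
        a_lipid = float(np.mean(areas))
    else:
        phi_lipid = values["phi_lipid"]
        phi_pep = values.get("phi_peptide_inner", 0.0)
        if report.get("template") == "four_layer":
            tau_leaflet = 0.5 * (
                values["tail_thickness_inner"] + values["tail_thickness_outer"]
            )
        else:
            tau_leaflet = 0.5 * values["tail_thickness"]
        a_lipid = area_per_lipid(tail_volume, tau_leaflet, phi_lipid)
        layers = {
            "tails": VolumeFractions(
                phi_lipid=phi_lipid,
                phi_peptide=phi_pep,
                phi_solvent=max(1.0 - phi_lipid - phi_pep, 0.0),
                residual=0.0,
                condition_number=float("nan"),
            )
        }
        scenarios = None

    return DecompositionResult(
        layers=layers,
        area_per_lipid=a_lipid,
        phase=assign_phase(a_lipid, phase_threshold),
        scenarios=scenarios,
        phase_threshold=phase_threshold,
    )
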