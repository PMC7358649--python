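"""Ground-truth reflectivity generator for the supported-bilayer study.

Emulates the experimental design without any measured data: DMPC/DMPG (3:1)
bilayers on silicon, chain-deuterated (d54) and hydrogenous lipids, before
and after binding of the half-deuterated peptide, at a fluid-phase and a
gel-phase temperature, each measured in D2O and H2O — 16 curves in all.
Counting noise is heteroscedastic Gaussian, sigma = max(a * R, floor), with
the noise level written into the dR column, and every curve is deterministic
for a given seed.  Each generated curve is accompanied by its ground truth
so recovery tests can compare fitted values against generating values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .membrane_model import MembraneModel, Scenario, build_model
from .reflect_kernel import ReflectivityCurve, ResolutionSpec
from . import io as nio

__all__ = ["NoiseSpec", "GroundTruth", "generate_curve", "generate_study_fixture",
           "default_q_grid", "TAIL_VOLUME_A3"]

#: molecular volume of the two myristoyl chains of one lipid (A^3)
TAIL_VOLUME_A3 = 756.0


@dataclass(frozen=True)
class NoiseSpec:
    """Relative counting noise with an absolute background floor."""

    relative: float = 0.01
    floor: float = 1e-8


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a curve: model template, scenario,
    the full generating parameter vector, noise and seed."""

    template: str
    scenario: Scenario
    lipid_deuterated: bool
    peptide_present: bool
    parameters: dict[str, float]
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    temperature_c: float = 30.0
    dq_over_q: float = 0.084

    def build(self) -> MembraneModel:
        from . import materials as mat

        model = build_model(
            self.template,
            contrasts=("d2o", "h2o"),
            peptide=mat.mac1() if self.peptide_present else None,
            scenario=self.scenario,
            lipid_deuterated=self.lipid_deuterated,
            resolution=ResolutionSpec(self.dq_over_q),
        )
        for name, value in self.parameters.items():
            model.parameters[name].value = float(value)
            model.parameters[name].tie = None
        return model

    def to_dict(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["noise"] = NoiseSpec(**d["noise"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_q_grid(n: int = 120, q_min: float = 0.01, q_max: float = 0.30) -> np.ndarray:
    """Instrument-like Q grid (1/A), geometric spacing."""
    return np.geomspace(q_min, q_max, n)


def generate_curve(
    truth: GroundTruth,
    contrast: str,
    q: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> ReflectivityCurve:
    """Simulate one contrast: smeared model reflectivity plus Gaussian
    counting noise; the dR column records the noise width used."""
    q = default_q_grid() if q is None else np.asarray(q, dtype=float)
    noise = noise if noise is not None else truth.noise
    seed = truth.seed if seed is None else seed
    model = truth.build()
    r_model = model.model_r(contrast, q)
    if noise.relative == 0 and noise.floor == 0:
        return ReflectivityCurve(q, r_model, dr=None, dq=truth.dq_over_q * q)
    sigma = np.maximum(noise.relative * r_model, noise.floor)
    rng = np.random.default_rng(seed)
    r = np.maximum(r_model + rng.normal(0.0, sigma), 0.0)
    return ReflectivityCurve(q, r, dr=sigma, dq=truth.dq_over_q * q)


# --------------------------------------------------------------------------
# Study fixture
# --------------------------------------------------------------------------

# Generating parameter values.  Fluid-phase (30 C) bilayer: thin tails, area
# per lipid ~60 A^2; gel-phase (15 C): thicker tails, ~45 A^2.  Peptide
# binding thickens the tail region and displaces lipid.
_BARE_COMMON = {
    "oxide_thickness": 10.0,
    "oxide_sld": 3.47e-6,
    "roughness_oxide": 3.0,
    "roughness_bilayer": 3.0,
    "roughness_solvent": 3.0,
    "head_thickness_inner": 8.0,
    "head_solvent": 0.30,
}

_STATE_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("bare", "30C"): {**_BARE_COMMON, "tail_thickness": 26.4, "phi_lipid": 0.95},
    ("bare", "15C"): {**_BARE_COMMON, "tail_thickness": 34.5, "phi_lipid": 0.97},
    ("mac1", "30C"): {
        **_BARE_COMMON,
        "tail_thickness_inner": 14.2,
        "tail_thickness_outer": 14.2,
        "phi_lipid": 0.72,
    },
    ("mac1", "15C"): {
        **_BARE_COMMON,
        "tail_thickness_inner": 15.4,
        "tail_thickness_outer": 15.4,
        "phi_lipid": 0.74,
    },
}

#: peptide volume fractions used in generation, per scenario
_SCENARIO_FRACTIONS: dict[Scenario, tuple[float, float]] = {
    "uneven": (0.10, 0.22),
    "oriented_n_in": (0.18, 0.18),
    "oriented_n_out": (0.18, 0.18),
}


def make_truth(
    state: str,
    temperature: str,
    lipid_deuterated: bool,
    scenario: Scenario = "oriented_n_in",
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth for one sample state of the study design."""
    params = dict(_STATE_PARAMS[(state, temperature)])
    peptide_present = state == "mac1"
    if peptide_present:
        phi_in, phi_out = _SCENARIO_FRACTIONS[scenario]
        params["phi_peptide_inner"] = phi_in
        params["phi_peptide_outer"] = phi_out
        template = "four_layer"
    else:
        scenario = "none"
        template = "three_layer"
    return GroundTruth(
        template=template,
        scenario=scenario,
        lipid_deuterated=lipid_deuterated,
        peptide_present=peptide_present,
        parameters=params,
        noise=noise or NoiseSpec(),
        seed=seed,
        temperature_c=30.0 if temperature == "30C" else 15.0,
    )


def generate_study_fixture(
    seed: int,
    outdir: str | Path | None = None,
    scenario: Scenario = "oriented_n_in",
    noise: NoiseSpec | None = None,
    q: np.ndarray | None = None,
) -> dict[str, tuple[dict[str, ReflectivityCurve], GroundTruth]]:
    """The full 16-curve study fixture.

    Keys are ``{labeling}_{state}_{temperature}`` (8 sample states), each
    mapping to (curves-per-contrast, ground truth).  Peptide-bound states
    are generated under ``scenario``.  When ``outdir`` is given, curves are
    written as 4-column ASCII and truths as YAML next to them.
    """
    seeds = np.random.SeedSequence(seed).generate_state(16, dtype=np.uint32)
    fixture: dict[str, tuple[dict[str, ReflectivityCurve], GroundTruth]] = {}
    i = 0
    for labeling, deuterated in (("d54", True), ("h", False)):
        for state in ("bare", "mac1"):
            for temperature in ("30C", "15C"):
                truth = make_truth(
                    state, temperature, deuterated, scenario=scenario, noise=noise,
                    seed=int(seeds[i] % 2**31),
                )
                curves = {}
                for j, contrast in enumerate(("d2o", "h2o")):
                    curves[contrast] = generate_curve(
                        truth, contrast, q=q, seed=int((seeds[i] + 7919 * (j + 1)) % 2**31)
                    )
                key = f"{labeling}_{state}_{temperature}"
                fixture[key] = (curves, truth)
                i += 1
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, (curves, truth) in fixture.items():
            truth.save(outdir / f"{key}.truth.yaml")
            for contrast, curve in curves.items():
                nio.write_reflectivity(outdir / f"{key}_{contrast}.dat", curve)
    return fixture
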