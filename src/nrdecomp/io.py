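"""Reflectivity file I/O and run configuration.

The canonical data file is plain ASCII with 2-4 whitespace- or
comma-separated numeric columns, ``Q  R  [dR  [dQ]]``, comment lines
starting with ``#``.  The fourth column is the resolution FWHM in Q
(converted to a Gaussian standard deviation by FWHM / (2 sqrt(2 ln 2))
inside the smearing kernel).  Files without a dR column get synthetic
fractional errors (configurable, with a warning) so weighted fitting stays
defined.

A run configuration is a YAML file naming the model template, the data file
per contrast, which parameters vary and inside which bounds, the resolution,
the random seeds and the Monte-Carlo replicate count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .reflect_kernel import ReflectivityCurve

__all__ = ["read_reflectivity", "write_reflectivity", "RunConfig", "load_config"]

DEFAULT_SYNTHETIC_DR_FRACTION = 0.02


class IOError_(ValueError):
    pass


def read_reflectivity(
    path: str | Path, synthetic_dr_fraction: float = DEFAULT_SYNTHETIC_DR_FRACTION
) -> ReflectivityCurve:
    """Read a 2-4 column ASCII reflectivity file.

    Missing dR columns are replaced by ``synthetic_dr_fraction * R`` with a
    warning so that weighted fits remain possible.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = re.split(r"[,\s]+", line)
        try:
            rows.append([float(x) for x in fields])
        except ValueError:
            raise IOError_(f"{path}:{lineno}: non-numeric field in {line!r}") from None
    if not rows:
        raise IOError_(f"{path}: no data rows")
    ncol = len(rows[0])
    if ncol < 2 or ncol > 4 or any(len(r) != ncol for r in rows):
        raise IOError_(f"{path}: expected 2-4 consistent columns, got {ncol}")
    data = np.array(rows)
    q, r = data[:, 0], data[:, 1]
    if np.any(np.diff(q) <= 0):
        raise IOError_(f"{path}: Q must be strictly increasing")
    dr = data[:, 2] if ncol >= 3 else None
    dq = data[:, 3] if ncol == 4 else None
    if dr is None:
        warnings.warn(
            f"{path}: no dR column; using synthetic fractional errors "
            f"({synthetic_dr_fraction:.3g} * R)",
            stacklevel=2,
        )
        dr = np.maximum(synthetic_dr_fraction * r, 1e-12)
    return ReflectivityCurve(q, r, dr=dr, dq=dq)


def write_reflectivity(path: str | Path, curve: ReflectivityCurve) -> None:
    """Write a curve as 4-column (or fewer) ASCII, dQ column as FWHM."""
    cols = [curve.q, curve.r]
    header = "Q(1/A) R"
    if curve.dr is not None:
        cols.append(curve.dr)
        header += " dR"
        if curve.dq is not None:
            cols.append(curve.dq)
            header += " dQ(FWHM)"
    np.savetxt(path, np.column_stack(cols), fmt="%.10e", header=header)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated fit-run configuration."""

    template: str
    contrasts: dict[str, Path]  # contrast name -> data file
    seeds: dict[str, int]
    lipid_deuterated: bool = False
    peptide_present: bool = False
    scenario: str = "none"
    fitted_tail_slds: bool = False
    vary: list[str] = field(default_factory=list)
    set_values: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    dq_over_q: float = 0.084
    mc_replicates: int = 1008
    synthetic_dr_fraction: float = DEFAULT_SYNTHETIC_DR_FRACTION
    output_dir: Path = Path("nrdecomp_out")

    def __post_init__(self) -> None:
        if "fit" not in self.seeds or "mc" not in self.seeds:
            raise IOError_("config must provide seeds: {fit: <int>, mc: <int>}")
        for name, p in self.contrasts.items():
            if not Path(p).exists():
                raise IOError_(f"data file for contrast {name!r} not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (see README for keys)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise IOError_(f"{path}: config must be a mapping")
    base = Path(path).parent
    try:
        contrasts = {k: base / v for k, v in raw["contrasts"].items()}
        cfg = RunConfig(
            template=raw["template"],
            contrasts=contrasts,
            seeds={k: int(v) for k, v in raw.get("seeds", {}).items()},
            lipid_deuterated=bool(raw.get("lipid_deuterated", False)),
            peptide_present=bool(raw.get("peptide_present", False)),
            scenario=raw.get("scenario", "none"),
            fitted_tail_slds=bool(raw.get("fitted_tail_slds", False)),
            vary=list(raw.get("vary", [])),
            set_values={k: float(v) for k, v in raw.get("set", {}).items()},
            bounds={k: (float(v[0]), float(v[1])) for k, v in raw.get("bounds", {}).items()},
            dq_over_q=float(raw.get("dq_over_q", 0.084)),
            mc_replicates=int(raw.get("mc_replicates", 1008)),
            synthetic_dr_fraction=float(
                raw.get("synthetic_dr_fraction", DEFAULT_SYNTHETIC_DR_FRACTION)
            ),
            output_dir=base / raw.get("output_dir", "nrdecomp_out"),
        )
    except KeyError as exc:
        raise IOError_(f"{path}: missing required config key {exc}") from None
    return cfg
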