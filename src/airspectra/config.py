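"""Run-wide configuration: units, physical constants, solver knobs.

Unit conventions used throughout the package:

* geometry (radius, length, coordinates) in **mm**
* resistance in **cmH2O s l^-1**
* pressure in **cmH2O**, volume in **l**, time in **s**

A branch resistance computed from Poiseuille's law,
``r = prefactor * mu * l / a**4`` with ``mu`` in Pa s and ``l``, ``a`` in mm,
comes out in Pa s mm^-3 and is converted to cmH2O s l^-1 by
``MM3_PER_L / PA_PER_CMH2O``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import yaml

#: Pa per cmH2O (conventional water column at 4 deg C, g = 9.80665 m/s^2).
PA_PER_CMH2O = 98.0665
#: mm^3 per litre.
MM3_PER_L = 1.0e6
#: conversion factor Pa s mm^-3 -> cmH2O s l^-1
PA_S_MM3_TO_CMH2O_S_L = MM3_PER_L / PA_PER_CMH2O


@dataclass
class RunConfig:
    """Central record of physical constants and solver settings.

    The defaults reproduce the package's standard study conditions; every
    field is serialized losslessly through :meth:`to_yaml`/:meth:`from_yaml`
    so that a run is reproducible from its metadata file alone.
    """

    # physical constants
    air_viscosity_pa_s: float = 1.93e-5
    poiseuille_prefactor: float = 8.0 / math.pi
    # generator defaults
    trachea_radius_mm: float = 9.0
    length_to_diameter: float = 3.0
    gaussian_resample_floor: float = 0.05  # resample draws below this fraction of mean
    constriction_mode: str = "reduce_by"  # or "multiply_by"
    # solver knobs
    dense_laplacian_eig_cap: int = 5000  # full L_int spectrum only below this size
    dense_maury_cap: int = 4096  # dense |T| x |T| assembly only below this
    linear_residual_rtol: float = 1e-10
    eig_residual_rtol: float = 1e-8
    periodicity_rtol: float = 1e-4
    # misc
    seed: int = 0
    output_dir: str = "."

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


#: module-level default configuration used when none is passed explicitly
DEFAULT_CONFIG = RunConfig()
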