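"""Run configuration: YAML schema, validation and presets."""

from __future__ import annotations

import pathlib
from dataclasses import asdict, dataclass

import yaml

from .random_field import delta_sup

__all__ = ["RunConfig", "load_config", "PRESETS"]

_ALLOWED_SOLVERS = ("fixed_point", "genetic")


@dataclass
class RunConfig:
    """Validated configuration of an identification run.

    Lengths in meters, moduli in GPa, traction in N/m^2.  ``adm_*`` are the
    closed admissible intervals discretized into ``nv`` points.
    """

    dim: int = 2
    domain_size: float = 2e-3
    traction: float = 5e7
    ns: int = 50
    nv: int = 6
    tol: float = 1e-9
    solver: str = "fixed_point"
    rve_multiplier: float = 10.0
    rve_cells_per_ell: int = 4
    smoothing_sigma: float = 0.0
    seed: int = 0
    adm_delta: tuple = (0.25, 0.50)
    adm_ell: tuple = (75e-6, 200e-6)
    adm_kappa: tuple = (10.0, 16.25)
    adm_mu: tuple = (2.587, 5.087)
    ga_population: int = 40
    ga_generations: int = 15
    out_dir: str = "mesoid_run"

    def __post_init__(self) -> None:
        if self.solver not in _ALLOWED_SOLVERS:
            raise ValueError(f"solver must be one of {_ALLOWED_SOLVERS}")
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        lo, hi = self.adm_delta
        if not 0.0 <= lo < hi < delta_sup(6):
            raise ValueError(
                f"delta interval [{lo}, {hi}] must lie inside "
                f"[0, {delta_sup(6):.4f})")
        for name in ("adm_ell", "adm_kappa", "adm_mu"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"invalid interval for {name}")
        if self.ns < 1 or self.nv < 2:
            raise ValueError("ns >= 1 and nv >= 2 required")

    def asdict(self) -> dict:
        return asdict(self)


PRESETS: dict[str, dict] = {
    # 2D plane-stress validation at full scale
    "2d_validation": dict(
        dim=2, domain_size=1e-2, traction=5e7, ns=500, nv=10, tol=1e-9,
        rve_multiplier=20.0, adm_delta=(0.25, 0.50), adm_ell=(20e-6, 250e-6),
        adm_kappa=(8.5, 17.0), adm_mu=(2.15, 4.50)),
    # 3D validation
    "3d_validation": dict(
        dim=3, domain_size=2e-3, traction=5e8, ns=500, nv=10, tol=1e-9,
        rve_multiplier=20.0, adm_delta=(0.20, 0.45), adm_ell=(50e-6, 120e-6),
        adm_kappa=(87.5, 200.0), adm_mu=(40.5, 95.0)),
    # cortical-bone application (2D plane stress, smoothed DIC data)
    "bone_2d": dict(
        dim=2, domain_size=1e-2, traction=9e7, ns=500, nv=10, tol=1e-9,
        rve_multiplier=20.0, smoothing_sigma=3.5,
        adm_delta=(0.30, 0.65), adm_ell=(50e-6, 100e-6),
        adm_kappa=(9.5, 11.0), adm_mu=(3.5, 5.0)),
}


def load_config(path: "str | pathlib.Path | None" = None,
                preset: "str | None" = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or missing content) file yields the all-defaults reduced-scale
    demo configuration; unknown keys are rejected with a field-level
    message."""
    data: dict = {}
    if preset is not None:
        data.update(PRESETS[preset])
    if path is not None:
        text = pathlib.Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must contain a YAML mapping")
        data.update(loaded)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("adm_delta", "adm_ell", "adm_kappa", "adm_mu"):
        if key in data:
            data[key] = tuple(data[key])
    return RunConfig(**data)
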