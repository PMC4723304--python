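"""Model parameters, non-dimensionalisation, and configuration I/O.

The model works internally in non-dimensional units: lengths in cell
diameters (one lattice spacing), times in cell cycles, and oxygen as a
fraction of the arterial concentration.  Dimensional inputs use the units
conventional for this system: cm²/s for diffusion, mol/cell/s for uptake,
µm for the cell diameter, hours for the cell cycle, seconds for the oxygen
time step, and mol/cell for concentrations.

Given a cell cycle ``tau`` (converted to seconds) and a lattice spacing
``dx`` (converted to cm), the transforms are

    D_c   = D_c_dim * tau / dx**2          (cell-cycle⁻¹)
    r_c   = tau * r_c_dim / c_max_dim      (cell-cycle⁻¹)
    c_ap  = c_ap_dim / c_max_dim
    K_m   = K_m_dim / c_max_dim
    dt_nd = dt_oxygen / tau

so that the non-dimensional arterial oxygen concentration is 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = [
    "ConfigurationError",
    "ModelParameters",
    "nondimensionalise",
    "dimensionalise",
    "stability_factor",
    "default_parameters",
    "load_config",
    "save_config",
]

#: fields that must be strictly positive before non-dimensionalisation
_POSITIVE_DIMENSIONAL = (
    "D_c_dim",
    "r_c_dim",
    "r_p_factor",
    "dx",
    "dt_oxygen",
    "tau",
    "c_max_dim",
    "c_max_mmHg",
    "c_ap_dim",
    "c_p_over_c_ap",
    "K_m_dim",
    "mu_H",
    "mu_T_ratio",
    "K_OER",
    "alpha_max",
    "beta_max",
)

_OER_FORMS = ("saturating_decreasing", "saturating_increasing")


class ConfigurationError(ValueError):
    """Raised when a parameter value or configuration file is invalid."""


@dataclass
class ModelParameters:
    """All model constants, in dimensional and non-dimensional form.

    Dimensional fields carry a ``_dim`` suffix (or explicit unit names such
    as ``dx`` in µm, ``tau`` in hours).  Non-dimensional fields are filled
    by :func:`nondimensionalise`; constructing via :func:`default_parameters`
    returns a fully populated instance with the standard glioblastoma-derived
    estimates.
    """

    # --- dimensional constants -------------------------------------------
    D_c_dim: float = 1.0e-5          # oxygen diffusion coefficient, cm² s⁻¹
    r_c_dim: float = 4.6e-16         # maximal oxygen consumption, mol cell⁻¹ s⁻¹
    r_p_factor: float = 5.0          # proliferative consumption multiplier
    dx: float = 50.0                 # cell diameter / lattice spacing, µm
    dt_oxygen: float = 0.25          # oxygen update time step, s
    tau: float = 16.0                # cell cycle time, h
    c_max_dim: float = 5.14e-13      # arterial oxygen concentration, mol cell⁻¹
    c_max_mmHg: float = 80.0         # the same concentration as a partial pressure
    c_ap_dim: float = 5.14e-14       # hypoxic death threshold, mol cell⁻¹
    c_p_over_c_ap: float = 1.1       # quiescence threshold as a multiple of c_ap
    K_m_dim: float = 5.14e-15        # Michaelis-Menten constant, mol cell⁻¹
    mu_H: float = 1.0                # healthy metabolic constant
    mu_T_ratio: float = 2.0          # cancer/healthy metabolic ratio
    # --- per-cell-cycle fate probabilities (dimensionless) ---------------
    p_d: float = 0.25                # death probability when c < c_ap
    p_H: float = 0.005               # healthy division probability
    p_T: float = 0.01                # tumour division probability
    # --- radiation response ----------------------------------------------
    K_OER: float = 3.28              # OER half-saturation constant, mmHg
    rescale_K_OER_by_cmax: bool = True
    OER_alpha_min: float = 1.0
    OER_alpha_max: float = 1.75
    OER_beta_min: float = 1.0
    OER_beta_max: float = 3.25
    alpha_max: float = 0.3           # LQ alpha under full oxygenation, Gy⁻¹
    beta_max: float = 0.03           # LQ beta under full oxygenation, Gy⁻²
    oer_form: str = "saturating_decreasing"
    # --- numerics / bookkeeping ------------------------------------------
    c0: float = 1.0                  # initial uniform oxygen (non-dimensional)
    dc_bin: float = 0.01             # oxygen histogram bin width
    M_bins: int = 100                # oxygen histogram bin count
    # --- non-dimensional values (filled by nondimensionalise) ------------
    D_c: float | None = None         # diffusion, cell-cycle⁻¹
    r_c: float | None = None         # maximal uptake, cell-cycle⁻¹
    c_ap: float | None = None
    c_p: float | None = None
    K_m: float | None = None
    dt_oxygen_nd: float | None = None
    steps_per_cycle: int | None = None
    K_OER_nd: float | None = None

    # -- convenience ------------------------------------------------------
    @property
    def tau_s(self) -> float:
        """Cell cycle time in seconds."""
        return self.tau * 3600.0

    @property
    def dx_cm(self) -> float:
        """Lattice spacing in cm."""
        return self.dx * 1.0e-4

    @property
    def mu_T(self) -> float:
        """Tumour metabolic constant."""
        return self.mu_H * self.mu_T_ratio

    def validate_dimensional(self) -> None:
        for name in _POSITIVE_DIMENSIONAL:
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"missing dimensional parameter {name!r}")
            if not value > 0:
                raise ConfigurationError(
                    f"dimensional parameter {name!r} must be positive, got {value!r}"
                )
        if self.oer_form not in _OER_FORMS:
            raise ConfigurationError(
                f"oer_form must be one of {_OER_FORMS}, got {self.oer_form!r}"
            )

    def validate(self) -> None:
        """Check invariants on the fully populated parameter set."""
        self.validate_dimensional()
        if self.D_c is None:
            raise ConfigurationError("non-dimensional fields not populated; "
                                     "call nondimensionalise() first")
        if not (0 < self.c_ap < self.c_p <= 1):
            raise ConfigurationError(
                f"thresholds must satisfy 0 < c_ap < c_p <= 1, got "
                f"c_ap={self.c_ap}, c_p={self.c_p}"
            )
        if not (0 < self.K_m < 1):
            raise ConfigurationError(f"K_m must lie in (0, 1), got {self.K_m}")
        for name in ("p_d", "p_H", "p_T"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for ab in ("alpha", "beta"):
            lo = getattr(self, f"OER_{ab}_min")
            hi = getattr(self, f"OER_{ab}_max")
            if not (1 <= lo <= hi):
                raise ConfigurationError(
                    f"OER_{ab} constants must satisfy 1 <= min <= max, "
                    f"got min={lo}, max={hi}"
                )
        if not (0 <= self.c0 <= 1):
            raise ConfigurationError(f"c0 must lie in [0, 1], got {self.c0}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with ``changes`` applied and non-dimensional
        fields recomputed."""
        p = dataclasses.replace(self, **changes)
        return nondimensionalise(p)


def nondimensionalise(params: ModelParameters) -> ModelParameters:
    """Fill the non-dimensional fields from the dimensional ones.

    Returns a new :class:`ModelParameters`; the dimensional fields are
    retained so the transform can be inverted with :func:`dimensionalise`.
    """
    params.validate_dimensional()
    tau_s = params.tau_s
    c_ap = params.c_ap_dim / params.c_max_dim
    K_OER_nd = (
        params.K_OER / params.c_max_mmHg
        if params.rescale_K_OER_by_cmax
        else params.K_OER
    )
    out = dataclasses.replace(
        params,
        D_c=params.D_c_dim * tau_s / params.dx_cm**2,
        r_c=tau_s * params.r_c_dim / params.c_max_dim,
        c_ap=c_ap,
        c_p=params.c_p_over_c_ap * c_ap,
        K_m=params.K_m_dim / params.c_max_dim,
        dt_oxygen_nd=params.dt_oxygen / tau_s,
        steps_per_cycle=round(tau_s / params.dt_oxygen),
        K_OER_nd=K_OER_nd,
    )
    out.validate()
    return out


def dimensionalise(params: ModelParameters) -> ModelParameters:
    """Invert :func:`nondimensionalise`, recovering the dimensional fields
    from the non-dimensional ones (round-trip identity up to round-off)."""
    if params.D_c is None:
        raise ConfigurationError("non-dimensional fields not populated")
    tau_s = params.tau_s
    return dataclasses.replace(
        params,
        D_c_dim=params.D_c * params.dx_cm**2 / tau_s,
        r_c_dim=params.r_c * params.c_max_dim / tau_s,
        c_ap_dim=params.c_ap * params.c_max_dim,
        K_m_dim=params.K_m * params.c_max_dim,
        dt_oxygen=params.dt_oxygen_nd * tau_s,
    )


def stability_factor(params: ModelParameters) -> float:
    """Diffusion number D_c·Δt̃/Δx̃² of the explicit oxygen scheme (Δx̃ = 1).

    The two-dimensional five-point explicit scheme is stable for values
    up to 0.25; the default parameters give 0.1.
    """
    if params.D_c is None or params.dt_oxygen_nd is None:
        raise ConfigurationError("non-dimensional fields not populated")
    return params.D_c * params.dt_oxygen_nd


def default_parameters(**overrides) -> ModelParameters:
    """The standard parameter set, non-dimensionalised and validated."""
    return nondimensionalise(ModelParameters(**overrides))


# ---------------------------------------------------------------------------
# configuration file I/O
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = {
    f.name for f in dataclasses.fields(ModelParameters)
} - {
    # derived fields may not be set from a file
    "D_c", "r_c", "c_ap", "c_p", "K_m", "dt_oxygen_nd",
    "steps_per_cycle", "K_OER_nd",
}


def load_config(path) -> ModelParameters:
    """Read a flat key-value YAML parameter file.

    Every dimensional Table-style symbol is addressable by its field name;
    unknown keys are rejected with an error naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration file {path!s} is not a mapping")
    unknown = sorted(set(raw) - _CONFIG_FIELDS)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {unknown}")
    return default_parameters(**raw)


def save_config(params: ModelParameters, path) -> None:
    """Write the dimensional configuration (settable fields only) as YAML."""
    data = {k: getattr(params, k) for k in sorted(_CONFIG_FIELDS)}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
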