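"""Configuration for the neurovascular-unit (NVU) virtual phantom.

A single YAML document with sections ``geometry``, ``endfeet``,
``rheology``, ``isf``, ``transport``, ``kinetics``, ``scenario`` and
``numerics`` describes one simulation.  The packaged default file
(``nvusim/data/default_config.yaml``) carries the literature parameter
set for a cortical capillary (7 um lumen radius, 1 um endothelium,
100 nm basal lamina, 25 um of surrounding parenchyma) together with
Carreau blood rheology, interstitial Darcy properties, glucose
diffusion/consumption kinetics and GLUT1 carrier densities.

Everything is validated at load time and normalised to SI units;
concentrations are kept in mol/m^3 (numerically equal to mM).
Pressures may be given in mmHg with a ``_mmhg`` key suffix.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .constants import MMHG_TO_PA


class ConfigurationError(KeyError):
    """A mandatory configuration key is missing or unreadable."""


class ValidationError(ValueError):
    """A configuration value violates a physical or structural constraint."""


def _require(section: dict, key: str, section_name: str) -> Any:
    if key not in section:
        raise ConfigurationError(
            f"missing configuration key '{section_name}.{key}'")
    return section[key]


def _check(cond: bool, constraint: str) -> None:
    if not cond:
        raise ValidationError(f"configuration violates constraint: {constraint}")


@dataclass(frozen=True)
class GeometryConfig:
    """Axisymmetric phantom geometry (all lengths in metres)."""

    L_capillary: float
    R0: float
    h_end: float
    h_bl: float
    L_surround: float

    def __post_init__(self):
        for name in ("L_capillary", "R0", "h_end", "h_bl", "L_surround"):
            _check(getattr(self, name) > 0.0, f"geometry.{name} > 0")

    @property
    def r_endo_outer(self) -> float:
        return self.R0 + self.h_end

    @property
    def r_bl_outer(self) -> float:
        return self.R0 + self.h_end + self.h_bl

    @property
    def r_outer(self) -> float:
        return self.R0 + self.h_end + self.h_bl + self.L_surround


@dataclass(frozen=True)
class EndFeetLayout:
    """Axial striping of the basal-lamina outer surface.

    ``coverage_fraction`` is the requested fraction of that surface
    occupied by astrocyte end-feet (delta_end-feet / 100); the rest is
    free-diffusion cleft.  The surface is divided into ``n_bands``
    annular end-foot stripes, each centred in an equal axial segment.
    """

    coverage_fraction: float
    n_bands: int = 8

    def __post_init__(self):
        _check(0.0 <= self.coverage_fraction <= 1.0,
               "endfeet.coverage_fraction in [0, 1]")
        _check(self.n_bands >= 1, "endfeet.n_bands >= 1")


@dataclass(frozen=True)
class RheologyParams:
    """Carreau shear-thinning blood rheology."""

    rho_blood: float   # kg/m^3
    mu_0: float        # Pa s, zero-shear plateau
    mu_inf: float      # Pa s, infinite-shear plateau
    lambda_c: float    # s, Carreau time constant
    n_idx: float       # dimensionless Carreau index

    def __post_init__(self):
        _check(self.mu_inf > 0.0, "rheology.mu_inf > 0")
        _check(self.mu_0 > self.mu_inf, "rheology.mu_0 > mu_inf")
        _check(self.lambda_c >= 0.0, "rheology.lambda_c >= 0")
        _check(0.0 < self.n_idx <= 1.0, "rheology.n_idx in (0, 1]")
        _check(self.rho_blood > 0.0, "rheology.rho_blood > 0")


@dataclass(frozen=True)
class ISFParams:
    """Interstitial fluid and porous-medium properties of parenchyma."""

    rho_isf: float     # kg/m^3
    mu_isf: float      # kg/m/s
    kappa: float       # m^2, Darcy permeability
    alpha_icf: float   # porosity (ISF volume fraction)
    tau: float         # tortuosity

    def __post_init__(self):
        _check(self.kappa > 0.0, "isf.kappa > 0")
        _check(0.0 < self.alpha_icf < 1.0, "isf.alpha_icf in (0, 1)")
        _check(self.tau >= 1.0, "isf.tau >= 1")
        _check(self.mu_isf > 0.0, "isf.mu_isf > 0")


@dataclass(frozen=True)
class TransportParams:
    """Glucose diffusion, carrier and consumption parameters.

    Diffusion coefficients are free-medium values per region; the
    anisotropy factors ``sigma_long`` (axial) and ``sigma_trans``
    (radial) multiply them into a diagonal tensor.  Carrier surface
    densities are per m^2 of membrane; ``k_cat`` is the GLUT1 turnover
    number.  The hexokinase-phosphofructokinase sink is parameterised
    by first-order constants ``k_glc_*`` per region, the ATP level and
    its Hill-type inhibition, and a glucose affinity ``K_glc``.
    """

    D_lumen: float         # m^2/s
    D_bl: float            # m^2/s
    D_tissue: float        # m^2/s
    D_endothelium: float   # m^2/s
    sigma_long: float
    sigma_trans: float
    Km_glut: float         # mol/m^3
    N_glut_endo_inner: float   # 1/m^2
    N_glut_endo_outer: float   # 1/m^2
    N_glut_endfeet: float      # 1/m^2
    k_cat: float           # 1/s
    k_glc_E: float         # 1/s
    k_glc_II: float        # 1/s
    k_glc_I: float         # 1/s
    K_I_ATP: float         # mol/m^3
    n_H: float
    c_ATP: float           # mol/m^3
    K_glc: float           # mol/m^3

    def __post_init__(self):
        for name in ("D_lumen", "D_bl", "D_tissue", "D_endothelium"):
            _check(getattr(self, name) > 0.0, f"transport.{name} > 0")
        for name in ("N_glut_endo_inner", "N_glut_endo_outer", "N_glut_endfeet"):
            _check(getattr(self, name) >= 0.0, f"transport.{name} >= 0")
        for name in ("Km_glut", "K_glc", "K_I_ATP"):
            _check(getattr(self, name) > 0.0, f"kinetics.{name} > 0")
        _check(self.n_H >= 1.0, "kinetics.n_H >= 1")
        _check(self.sigma_long > 0.0 and self.sigma_trans > 0.0,
               "transport.sigma_long, sigma_trans > 0")
        _check(self.k_cat >= 0.0, "transport.k_cat >= 0")
        for name in ("k_glc_E", "k_glc_II", "k_glc_I"):
            _check(getattr(self, name) >= 0.0, f"kinetics.{name} >= 0")
        _check(self.c_ATP >= 0.0, "kinetics.c_ATP >= 0")

    def epsilon(self, region_rate_const: float) -> float:
        """Maximal consumption rate eps = k*c_ATP/(1+(c_ATP/K_I)^n_H)."""
        return (region_rate_const * self.c_ATP
                / (1.0 + (self.c_ATP / self.K_I_ATP) ** self.n_H))


_DIRECTIONS = ("baseline", "decrease", "increase")


@dataclass(frozen=True)
class ScenarioParams:
    """Pressure protocol, timing and concentration settings."""

    p0: float            # Pa, mid-capillary baseline pressure
    dp: float            # Pa, half inlet-to-mid pressure difference
    t0: float            # s, shift mid-point
    dt_smooth: float     # s, smoothing window width
    amplitude_a: float   # terminal |delta|
    direction: str       # baseline / decrease / increase
    t_end: float         # s
    c_inlet: float       # mol/m^3, feed concentration c~
    c_init_lumen: float  # mol/m^3
    c_init_tissue: float # mol/m^3
    c_init_endo: float   # mol/m^3
    c_init_bl: float     # mol/m^3
    dp_isf: float        # Pa, axial pressure difference driving ISF percolation

    def __post_init__(self):
        _check(self.direction in _DIRECTIONS,
               f"scenario.direction in {_DIRECTIONS}")
        if self.direction != "baseline":
            _check(0.5 <= self.amplitude_a < 1.0,
                   "scenario.amplitude_a in [0.5, 1)")
            _check(self.t0 + self.dt_smooth / 2.0 <= self.t_end,
                   "scenario.t0 + dt_smooth/2 <= t_end")
        _check(self.dt_smooth > 0.0, "scenario.dt_smooth > 0")
        _check(self.t_end > 0.0, "scenario.t_end > 0")
        for name in ("c_inlet", "c_init_lumen", "c_init_tissue",
                     "c_init_endo", "c_init_bl"):
            _check(getattr(self, name) >= 0.0, f"scenario.{name} >= 0")
        _check(self.dp >= 0.0, "scenario.dp >= 0")


@dataclass(frozen=True)
class NumericsParams:
    """Discretisation and coupling controls."""

    nr: int = 60
    nz: int = 120
    dt: float = 1e-3          # s, transport step
    record_every: float = 1e-2   # s, scalar diagnostics cadence
    snapshot_every: float = 0.25  # s, full-field cadence
    carrier_mode: str = "symmetric"   # or "one_sided"
    lumen_mode: str = "quasi_steady"  # or "transient"
    flow_resolve_threshold: float = 0.05
    fixed_endcap_concentration: float | None = None  # mol/m^3, optional variant
    venous_inflow: bool = False   # optional variant: feed at parenchyma caps
    fp_tol: float = 1e-8
    fp_max_iter: int = 200
    fp_relax: float = 0.7
    relinearize_every: int = 5

    # relinearize_every: steps between refreshes of the lagged
    # Michaelis-Menten linearisation (carrier + consumption); the cached
    # LU factorisation is reused in between.

    def __post_init__(self):
        _check(self.nr >= 16, "numerics.nr >= 16 (four cells per region)")
        _check(self.nz >= 4, "numerics.nz >= 4")
        _check(self.dt > 0.0, "numerics.dt > 0")
        _check(self.carrier_mode in ("symmetric", "one_sided"),
               "numerics.carrier_mode in {symmetric, one_sided}")
        _check(self.lumen_mode in ("quasi_steady", "transient"),
               "numerics.lumen_mode in {quasi_steady, transient}")
        _check(self.relinearize_every >= 1, "numerics.relinearize_every >= 1")


@dataclass(frozen=True)
class PhantomConfig:
    """Fully validated parameter set for one simulation."""

    geometry: GeometryConfig
    endfeet: EndFeetLayout
    rheology: RheologyParams
    isf: ISFParams
    transport: TransportParams
    scenario: ScenarioParams
    numerics: NumericsParams = field(default_factory=NumericsParams)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **section_updates) -> "PhantomConfig":
        """Return a copy with whole or partial sections replaced.

        ``section_updates`` maps section names to either a replacement
        dataclass instance or a dict of field updates.
        """
        parts = {s: getattr(self, s) for s in (
            "geometry", "endfeet", "rheology", "isf", "transport",
            "scenario", "numerics")}
        for name, upd in section_updates.items():
            if name not in parts:
                raise ConfigurationError(f"unknown config section '{name}'")
            if isinstance(upd, dict):
                d = asdict(parts[name])
                d.update(upd)
                parts[name] = type(parts[name])(**d)
            else:
                parts[name] = upd
        return PhantomConfig(**parts)


def _pressure(section: dict, key: str, section_name: str) -> float:
    """Read a pressure in Pa, accepting a ``<key>_mmhg`` alternative."""
    if key + "_mmhg" in section:
        return float(section[key + "_mmhg"]) * MMHG_TO_PA
    return float(_require(section, key, section_name))


def _parse(doc: dict) -> PhantomConfig:
    g = doc.get("geometry", {})
    geometry = GeometryConfig(
        L_capillary=float(_require(g, "L_capillary", "geometry")),
        R0=float(_require(g, "R0", "geometry")),
        h_end=float(_require(g, "h_end", "geometry")),
        h_bl=float(_require(g, "h_bl", "geometry")),
        L_surround=float(_require(g, "L_surround", "geometry")),
    )
    e = doc.get("endfeet", {})
    endfeet = EndFeetLayout(
        coverage_fraction=float(_require(e, "coverage_fraction", "endfeet")),
        n_bands=int(e.get("n_bands", 8)),
    )
    r = doc.get("rheology", {})
    rheology = RheologyParams(
        rho_blood=float(_require(r, "rho_blood", "rheology")),
        mu_0=float(_require(r, "mu_0", "rheology")),
        mu_inf=float(_require(r, "mu_inf", "rheology")),
        lambda_c=float(_require(r, "lambda_c", "rheology")),
        n_idx=float(_require(r, "n_idx", "rheology")),
    )
    i = doc.get("isf", {})
    isf = ISFParams(
        rho_isf=float(_require(i, "rho_isf", "isf")),
        mu_isf=float(_require(i, "mu_isf", "isf")),
        kappa=float(_require(i, "kappa", "isf")),
        alpha_icf=float(_require(i, "alpha_icf", "isf")),
        tau=float(_require(i, "tau", "isf")),
    )
    t = dict(doc.get("transport", {}))
    k = doc.get("kinetics", {})
    # The endothelium coefficient defaults to the cytosolic tissue value.
    t.setdefault("D_endothelium", _require(t, "D_tissue", "transport"))
    transport = TransportParams(
        D_lumen=float(_require(t, "D_lumen", "transport")),
        D_bl=float(_require(t, "D_bl", "transport")),
        D_tissue=float(_require(t, "D_tissue", "transport")),
        D_endothelium=float(t["D_endothelium"]),
        sigma_long=float(_require(t, "sigma_long", "transport")),
        sigma_trans=float(_require(t, "sigma_trans", "transport")),
        Km_glut=float(_require(t, "Km_glut", "transport")),
        N_glut_endo_inner=float(_require(t, "N_glut_endo_inner", "transport")),
        N_glut_endo_outer=float(_require(t, "N_glut_endo_outer", "transport")),
        N_glut_endfeet=float(_require(t, "N_glut_endfeet", "transport")),
        k_cat=float(_require(t, "k_cat", "transport")),
        k_glc_E=float(_require(k, "k_glc_E", "kinetics")),
        k_glc_II=float(_require(k, "k_glc_II", "kinetics")),
        k_glc_I=float(k.get("k_glc_I", 0.01 * float(_require(k, "k_glc_E", "kinetics")))),
        K_I_ATP=float(_require(k, "K_I_ATP", "kinetics")),
        n_H=float(_require(k, "n_H", "kinetics")),
        c_ATP=float(_require(k, "c_ATP", "kinetics")),
        K_glc=float(_require(k, "K_glc", "kinetics")),
    )
    s = doc.get("scenario", {})
    scenario = ScenarioParams(
        p0=_pressure(s, "p0", "scenario"),
        dp=_pressure(s, "dp", "scenario"),
        t0=float(_require(s, "t0", "scenario")),
        dt_smooth=float(_require(s, "dt_smooth", "scenario")),
        amplitude_a=float(_require(s, "amplitude_a", "scenario")),
        direction=str(_require(s, "direction", "scenario")),
        t_end=float(_require(s, "t_end", "scenario")),
        c_inlet=float(_require(s, "c_inlet", "scenario")),
        c_init_lumen=float(_require(s, "c_init_lumen", "scenario")),
        c_init_tissue=float(_require(s, "c_init_tissue", "scenario")),
        c_init_endo=float(s.get("c_init_endo", s.get("c_init_tissue"))),
        c_init_bl=float(s.get("c_init_bl", s.get("c_init_tissue"))),
        dp_isf=float(_require(s, "dp_isf", "scenario")),
    )
    n = doc.get("numerics", {})
    try:
        numerics = NumericsParams(**{key: val for key, val in n.items()})
    except TypeError as exc:
        raise ConfigurationError(f"unknown numerics key: {exc}") from exc
    return PhantomConfig(geometry=geometry, endfeet=endfeet, rheology=rheology,
                         isf=isf, transport=transport, scenario=scenario,
                         numerics=numerics)


def _default_doc() -> dict:
    res = importlib.resources.files("nvusim").joinpath("data/default_config.yaml")
    with res.open("r") as fh:
        return yaml.safe_load(fh)


def default_config() -> PhantomConfig:
    """The packaged default parameter set."""
    return _parse(_default_doc())


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> PhantomConfig:
    """Load a YAML configuration, filling omitted keys from the defaults.

    With ``path=None`` the packaged default configuration is returned.
    Raises :class:`ConfigurationError` for missing mandatory keys and
    :class:`ValidationError` for invariant violations.
    """
    doc = _default_doc()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"configuration file not found: {path}")
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"configuration file is not a mapping: {path}")
        # A user-supplied pressure in either unit overrides both spellings.
        for sec, key in (("scenario", "p0"), ("scenario", "dp")):
            u = user.get(sec, {})
            if key in u or key + "_mmhg" in u:
                doc.get(sec, {}).pop(key, None)
                doc.get(sec, {}).pop(key + "_mmhg", None)
        doc = _deep_merge(doc, user)
    return _parse(doc)


def save_config(config: PhantomConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through :func:`load_config`)."""
    doc = config.to_dict()
    doc["numerics"] = {k: v for k, v in doc["numerics"].items() if v is not None}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
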