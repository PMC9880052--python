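"""Model parameters: loading, validation, and unit conventions.

Every dynamic species in the well-stirred model is expressed as a volumetric
concentration (uM) referred to the outer-segment cytosolic volume ``V_cyt``.
Catalytic rates that are naturally quoted per molecule (um^3 s^-1) are
converted once, at load time, to uM^-1 s^-1 using the equivalence
1 um^3 s^-1 = 602.214 uM^-1 s^-1 (Avogadro's number at micromolar scale).

The packaged defaults describe a wild-type mouse rod.  Each value in the
parameter file carries a provenance comment: either a published mouse-rod
measurement or a value calibrated within published ranges so that the model
reproduces the measured saturation behaviour of wild-type and mutant rods.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "Params",
    "ParamSchemaError",
    "ParamValidationError",
    "load_params",
    "save_params",
    "default_params",
    "FARADAY",
    "UM3_PER_S_TO_PER_UM_PER_S",
]

#: Faraday constant, C mol^-1.
FARADAY = 96_500.0

#: 1 molecule um^-3 = 1/602.214 uM, hence 1 um^3 s^-1 = 602.214 uM^-1 s^-1.
UM3_PER_S_TO_PER_UM_PER_S = 602.214

SCHEMA_VERSION = 1


class ParamSchemaError(ValueError):
    """A parameter file is structurally invalid (missing/unknown keys)."""


class ParamValidationError(ValueError):
    """A parameter value violates a model constraint."""


@dataclass(frozen=True)
class Params:
    """Immutable bundle of every constant of the phototransduction model.

    Units are uM for concentrations, s^-1 for first-order rates,
    uM^-1 s^-1 for bimolecular rates, pA for currents, and um^3 for volume,
    unless noted otherwise in the field comments below.
    """

    # --- guanylate cyclase (two GCAP-regulated activities) ---
    alpha_min: float          # cGMP synthesis at saturating Ca2+, uM s^-1
    alpha_max: float          # cGMP synthesis at vanishing Ca2+, uM s^-1
    beta: float               # weight of the GCAP1-regulated component, [0, 1]
    K_cyc1: float             # Ca2+ K_1/2 of the GCAP1 component, uM
    K_cyc2: float             # Ca2+ K_1/2 of the GCAP2 component, uM
    m_cyc1: float             # Hill exponent, GCAP1 component
    m_cyc2: float             # Hill exponent, GCAP2 component

    # --- cGMP hydrolysis by PDE (volumetric rates, um^3 s^-1 in files) ---
    k_hyd_vol: float          # basal (dark) PDE subunit catalytic rate
    k_sigma_hyd_vol: float    # activated PDE subunit catalytic rate

    # --- CNG channel ---
    j_cg_max: float           # whole-cell current at saturating cGMP, pA
    K_cG_min: float           # channel cGMP K_1/2 at low Ca2+, uM
    K_cG_max: float           # channel cGMP K_1/2 at high Ca2+, uM
    m_cG: float               # channel Hill exponent for cGMP
    m_CaM: float              # Hill exponent for Ca2+/calmodulin modulation
    K_CaM: float              # Ca2+ K_1/2 of the calmodulin effect, uM
    f_Ca: float               # fraction of CNG current carried by Ca2+

    # --- Na+/Ca2+,K+ exchanger ---
    j_ex_sat: float           # saturated exchange current, pA
    K_ex: float               # Ca2+ K_1/2 of exchange current, uM

    # --- calcium bookkeeping ---
    B_Ca: float               # dimensionless cytosolic Ca2+ buffering power
    V_cyt: float              # outer-segment cytosolic volume, um^3

    # --- rhodopsin phosphorylation chain ---
    n_sites: int              # maximum number of phosphorylations (mouse: 6)
    lambda_max: tuple[float, ...]  # per-state max phosphorylation rates, s^-1,
                                   # length n_sites+1 with the final entry 0
    mu_max: float             # arrestin capture rate for states j >= 4, s^-1

    # --- recoverin / rhodopsin-kinase equilibrium ---
    K1: float                 # Ca2+ binding to recoverin, uM
    K2: float                 # membrane association constant, uM
    K3: float                 # Rec.Ca2 binding to RK (cytosolic), uM
    K4: float                 # Rec.Ca2 binding to RK (membrane), uM
    M_rec: float              # membrane site availability, uM
    RK_tot: float             # total rhodopsin kinase, uM
    Rec_tot: float            # total recoverin, uM (0 = recoverin knockout)

    # --- transducin / PDE / RGS9 front end ---
    nu_RT: float              # transducin activation rate per R*, s^-1
    nu: tuple[float, ...]     # per-state activation rates, length n_sites+1,
                              # final entry 0 (arrestin-quenched state)
    k_TE: float               # T* + E association, uM^-1 s^-1
    k_f: float                # RGS9 + T*--E association, uM^-1 s^-1
    k_b: float                # RGS9--T*--E dissociation, s^-1
    k_cat: float              # GTP hydrolysis in RGS9--T*--E, s^-1
    T0: float                 # total transducin, uM
    E0: float                 # total PDE catalytic subunits, uM
    RGS9_0: float             # total RGS9 complex, uM
    k_E: float                # first-order E* shutoff of the simplified
                              # front-end variant, s^-1

    # --- closed-form saturation theory ---
    nu_RE: float | None       # lumped R* -> E* gain, s^-1; None = derive
    epsilon: float            # criterion recovery fraction for T_sat

    # --- geometry ---
    collecting_area: float    # um^2, converts flash strength to Phi

    # --- mutant flags ---
    cam_null: bool = False    # True: K_cG pinned at K_cG_min (no CaM effect)
    alpha_freeze: float | None = None  # uM s^-1; Ca-independent cyclase rate
                                       # (GCAPs knockout), None = normal

    # ------------------------------------------------------------------
    @property
    def k_hyd(self) -> float:
        """Basal PDE rate in concentration units, uM^-1 s^-1."""
        return self.k_hyd_vol * UM3_PER_S_TO_PER_UM_PER_S

    @property
    def k_sigma_hyd(self) -> float:
        """Activated PDE rate in concentration units, uM^-1 s^-1."""
        return self.k_sigma_hyd_vol * UM3_PER_S_TO_PER_UM_PER_S

    @property
    def E_tot(self) -> float:
        """Total effector subunits; identical to the basal PDE pool E0."""
        return self.E0

    @property
    def eta(self) -> float:
        """Current-to-concentration conversion, uM s^-1 per pA."""
        return 1.0e9 / (FARADAY * self.B_Ca * self.V_cyt)

    @property
    def uM_per_molecule(self) -> float:
        """Concentration of a single molecule in V_cyt, uM."""
        return 1.0 / (UM3_PER_S_TO_PER_UM_PER_S * self.V_cyt)

    def mu_vector(self) -> tuple[float, ...]:
        """Arrestin capture rates per state: 0 below 4 phosphates, mu_max after.

        State j (1-based) carries j-1 phosphates; arrestin binds only states
        with at least 3 phosphates attached, i.e. j >= 4.
        """
        return tuple(
            self.mu_max if j >= 4 else 0.0 for j in range(1, self.n_sites + 2)
        )

    def replace(self, **changes: Any) -> "Params":
        """Return a copy with the given fields replaced (re-validated)."""
        p = dataclasses.replace(self, **changes)
        p.validate()
        return p

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ParamValidationError` on any constraint violation."""
        errs: list[str] = []

        def positive(name: str) -> None:
            v = getattr(self, name)
            if not (v > 0):
                errs.append(f"{name} must be strictly positive (got {v!r})")

        for name in (
            "alpha_min", "alpha_max", "K_cyc1", "K_cyc2", "m_cyc1", "m_cyc2",
            "k_hyd_vol", "k_sigma_hyd_vol", "j_cg_max", "K_cG_min", "K_cG_max",
            "m_cG", "m_CaM", "K_CaM", "j_ex_sat", "K_ex", "B_Ca", "V_cyt",
            "mu_max", "K1", "K2", "K3", "K4", "M_rec", "RK_tot",
            "nu_RT", "k_TE", "k_f", "k_b", "k_cat", "T0", "E0", "RGS9_0",
            "k_E", "collecting_area",
        ):
            positive(name)
        if self.f_Ca <= 0 or self.f_Ca >= 1:
            errs.append(f"f_Ca must lie in (0, 1) (got {self.f_Ca!r})")
        if not (0.0 <= self.beta <= 1.0):
            errs.append(f"beta must lie in [0, 1] (got {self.beta!r})")
        if not (self.alpha_min < self.alpha_max):
            errs.append("alpha_min must be < alpha_max")
        if not (self.K_cG_min < self.K_cG_max):
            errs.append("K_cG_min must be < K_cG_max")
        if self.n_sites < 1:
            errs.append(f"n_sites must be >= 1 (got {self.n_sites!r})")
        if self.Rec_tot < 0:
            errs.append("Rec_tot must be >= 0")
        if len(self.lambda_max) != self.n_sites + 1:
            errs.append(
                f"lambda_max must have length n_sites+1 = {self.n_sites + 1}"
            )
        elif self.lambda_max[-1] != 0.0:
            errs.append("lambda_max must end with 0 (arrestin-quenched state)")
        elif any(l <= 0 for l in self.lambda_max[:-1]):
            errs.append("lambda_max entries for states 1..n must be > 0")
        if len(self.nu) != self.n_sites + 1:
            errs.append(f"nu must have length n_sites+1 = {self.n_sites + 1}")
        elif self.nu[-1] != 0.0:
            errs.append("nu must end with 0 (arrestin-quenched state)")
        elif any(v < 0 for v in self.nu[:-1]):
            errs.append("nu entries must be >= 0")
        if not (0 < self.epsilon < 1):
            errs.append(f"epsilon must lie in (0, 1) (got {self.epsilon!r})")
        if self.nu_RE is not None and not (self.nu_RE > 0):
            errs.append("nu_RE must be > 0 or null")
        if self.alpha_freeze is not None and not (self.alpha_freeze > 0):
            errs.append("alpha_freeze must be > 0 or null")

        if errs:
            raise ParamValidationError("; ".join(errs))


# ----------------------------------------------------------------------
# file I/O

_VECTOR_FIELDS = {"lambda_max", "nu"}
_OPTIONAL_DEFAULTS: dict[str, Any] = {
    "nu": None,          # defaults to uniform nu_RT over states 1..n
    "nu_RE": None,
    "cam_null": False,
    "alpha_freeze": None,
}
_FIELD_NAMES = [f.name for f in dataclasses.fields(Params)]


def _params_from_mapping(doc: Mapping[str, Any], source: str) -> Params:
    if not isinstance(doc, Mapping):
        raise ParamSchemaError(f"{source}: expected a key/value mapping")
    doc = dict(doc)
    version = doc.pop("schema_version", None)
    if version is None:
        raise ParamSchemaError(f"{source}: missing required key 'schema_version'")
    if version != SCHEMA_VERSION:
        raise ParamSchemaError(
            f"{source}: unsupported schema_version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )

    unknown = sorted(set(doc) - set(_FIELD_NAMES))
    if unknown:
        raise ParamSchemaError(f"{source}: unknown keys {unknown}")
    missing = sorted(
        set(_FIELD_NAMES) - set(doc) - set(_OPTIONAL_DEFAULTS)
    )
    if missing:
        raise ParamSchemaError(f"{source}: missing required keys {missing}")

    kwargs: dict[str, Any] = {}
    for name in _FIELD_NAMES:
        if name in doc:
            kwargs[name] = doc[name]
        else:
            kwargs[name] = _OPTIONAL_DEFAULTS[name]

    n = int(kwargs["n_sites"])
    kwargs["n_sites"] = n
    # scalar lambda_max/nu mean "uniform over phosphorylation states"
    lam = kwargs["lambda_max"]
    if isinstance(lam, (int, float)):
        kwargs["lambda_max"] = tuple([float(lam)] * n + [0.0])
    else:
        kwargs["lambda_max"] = tuple(float(x) for x in lam)
    nu = kwargs["nu"]
    if nu is None:
        kwargs["nu"] = tuple([float(kwargs["nu_RT"])] * n + [0.0])
    elif isinstance(nu, (int, float)):
        kwargs["nu"] = tuple([float(nu)] * n + [0.0])
    else:
        kwargs["nu"] = tuple(float(x) for x in nu)

    for name in _FIELD_NAMES:
        if name in ("n_sites", "cam_null") or name in _VECTOR_FIELDS:
            continue
        v = kwargs[name]
        if v is not None:
            kwargs[name] = float(v)
    kwargs["cam_null"] = bool(kwargs["cam_null"])

    p = Params(**kwargs)
    p.validate()
    return p


def load_params(path: str) -> Params:
    """Load and validate a parameter file (YAML key/value text)."""
    with open(path, "r") as fh:
        doc = yaml.safe_load(fh)
    return _params_from_mapping(doc, source=str(path))


def save_params(p: Params, path: str) -> None:
    """Write a parameter set back to a YAML file (round-trips exactly)."""
    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
    for name in _FIELD_NAMES:
        v = getattr(p, name)
        if isinstance(v, tuple):
            v = list(v)
        doc[name] = v
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_params() -> Params:
    """The packaged wild-type mouse-rod parameter set."""
    ref = importlib.resources.files("rodcascade.data") / "default_params.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_params(str(path))
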