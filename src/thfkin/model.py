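"""Reaction-network types and the reference THF-biosynthesis model.

The reference network covers the last four steps of tetrahydrofolate (THF)
biosynthesis (FolK, FolP, FolC, FolA), the main CH2-THF synthesizing
reaction (GlyA, reversible and near equilibrium), a folate-cleaving side
reaction of PanB that returns the pterin and pABA moieties of CH2-THF to
the head of the pathway, constant-flux exchange reactions supplying
H2-HMPt and pABA, and two saturating drain reactions representing the
growth-associated dilution of THF and CH2-THF.

Units: concentrations are mmol.ml-1 cytoplasm (numerically equal to
mol.L-1), time is seconds, fluxes are mmol.ml-1.s-1.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "KineticLaw",
    "MassActionIrrev",
    "MassActionRev",
    "ConstantFlux",
    "SaturatingIrrev",
    "Species",
    "Reaction",
    "PathwayModel",
    "ModelConfig",
    "ValidationReport",
    "build_reference_model",
    "validate_model",
    "PTERIN_MOIETY",
]


class ConfigurationError(KeyError):
    """A required parameter or species is missing from the configuration."""


class ValidationError(ValueError):
    """A supplied value violates a model invariant (e.g. negative rate)."""


# --------------------------------------------------------------------------
# Kinetic laws
# --------------------------------------------------------------------------

class KineticLaw:
    """Base class for rate laws.

    Subclasses implement :meth:`rate`, receiving substrate and product
    ``(concentration, stoichiometry)`` pairs, and return a flux in
    mmol.ml-1.s-1.  Parameters are exposed through :meth:`parameters` /
    :meth:`set_parameter` so that calibration and scenario machinery can
    manipulate them generically.
    """

    form: str = "abstract"

    def rate(self, substrates, products) -> float:
        raise NotImplementedError

    def parameters(self) -> dict[str, float]:
        return {k: v for k, v in vars(self).items() if isinstance(v, (int, float))}

    def set_parameter(self, name: str, value: float) -> None:
        if name not in self.parameters():
            raise ConfigurationError(f"law {self.form!r} has no parameter {name!r}")
        if value < 0:
            raise ValidationError(f"parameter {name!r} must be >= 0, got {value}")
        setattr(self, name, float(value))

    def _check_nonnegative(self) -> None:
        for name, value in self.parameters().items():
            if value < 0:
                raise ValidationError(
                    f"parameter {name!r} of {self.form} law must be >= 0, got {value}"
                )


@dataclass
class MassActionIrrev(KineticLaw):
    """v = k * prod([S_i]^n_i) over all substrates (fixed species included)."""

    k: float
    form = "mass_action_irrev"

    def __post_init__(self):
        self._check_nonnegative()

    def rate(self, substrates, products):
        v = self.k
        for conc, stoich in substrates:
            v *= conc ** stoich
        return v


@dataclass
class MassActionRev(KineticLaw):
    """v = kf * prod(substrates) - kr * prod(products)."""

    kf: float
    kr: float
    form = "mass_action_rev"

    def __post_init__(self):
        self._check_nonnegative()

    def rate(self, substrates, products):
        fwd = self.kf
        for conc, stoich in substrates:
            fwd *= conc ** stoich
        rev = self.kr
        for conc, stoich in products:
            rev *= conc ** stoich
        return fwd - rev


@dataclass
class ConstantFlux(KineticLaw):
    """v = v0, independent of every concentration."""

    v0: float
    form = "constant_flux"

    def __post_init__(self):
        self._check_nonnegative()

    def rate(self, substrates, products):
        return self.v0


@dataclass
class SaturatingIrrev(KineticLaw):
    """Irreversible Michaelis-Menten form, v = vmax * [S] / (km + [S]).

    Bounded above by vmax and monotone nondecreasing in [S]; used for the
    growth-dilution drain reactions.  [S] is the first-listed substrate;
    any further substrates participate stoichiometrically but do not
    enter the rate (a co-reactant lumped into vmax).
    """

    vmax: float
    km: float
    form = "saturating_irrev"

    def __post_init__(self):
        self._check_nonnegative()

    def rate(self, substrates, products):
        if not substrates:
            raise ValidationError("saturating law requires a substrate")
        s = substrates[0][0]
        return self.vmax * s / (self.km + s)


# --------------------------------------------------------------------------
# Network types
# --------------------------------------------------------------------------

@dataclass
class Species:
    """A chemical species.

    ``fixed`` species are held at ``init_conc`` for the whole simulation and
    are excluded from the ODE state (boundary species in SBML terms).
    """

    id: str
    name: str
    init_conc: float
    fixed: bool = False

    def __post_init__(self):
        if self.init_conc < 0:
            raise ValidationError(
                f"species {self.id!r}: init_conc must be >= 0, got {self.init_conc}"
            )


@dataclass
class Reaction:
    id: str
    substrates: dict[str, int]
    products: dict[str, int]
    law: KineticLaw

    def __post_init__(self):
        for side in (self.substrates, self.products):
            for sid, n in side.items():
                if not (isinstance(n, int) and n > 0):
                    raise ValidationError(
                        f"reaction {self.id!r}: stoichiometry for {sid!r} must be a "
                        f"positive integer, got {n!r}"
                    )

    def flux(self, conc: Mapping[str, float]) -> float:
        subs = [(conc[s], n) for s, n in self.substrates.items()]
        prods = [(conc[s], n) for s, n in self.products.items()]
        return self.law.rate(subs, prods)


@dataclass
class PathwayModel:
    """An ordered collection of species and reactions with rate laws."""

    species: list[Species]
    reactions: list[Reaction]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        sids = [s.id for s in self.species]
        if len(set(sids)) != len(sids):
            raise ValidationError("species ids must be unique")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ValidationError("reaction ids must be unique")

    # -- lookups ----------------------------------------------------------
    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise ConfigurationError(f"no species {sid!r}")

    def reaction_by_id(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise ConfigurationError(f"no reaction {rid!r}")

    @property
    def dynamic_species(self) -> list[Species]:
        return [s for s in self.species if not s.fixed]

    @property
    def fixed_species(self) -> list[Species]:
        return [s for s in self.species if s.fixed]

    def get_param(self, rid: str, name: str) -> float:
        params = self.reaction_by_id(rid).law.parameters()
        if name not in params:
            raise ConfigurationError(f"reaction {rid!r} has no parameter {name!r}")
        return params[name]

    def set_param(self, rid: str, name: str, value: float) -> None:
        self.reaction_by_id(rid).law.set_parameter(name, value)

    # -- structure --------------------------------------------------------
    def stoichiometric_matrix(self):
        """S (n_dynamic x n_reactions): net stoichiometry of dynamic species."""
        import numpy as np

        dyn = {s.id: i for i, s in enumerate(self.dynamic_species)}
        S = np.zeros((len(dyn), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sid, n in r.substrates.items():
                if sid in dyn:
                    S[dyn[sid], j] -= n
            for sid, n in r.products.items():
                if sid in dyn:
                    S[dyn[sid], j] += n
        return S

    def initial_concentrations(self) -> dict[str, float]:
        return {s.id: s.init_conc for s in self.species}

    def copy(self) -> "PathwayModel":
        return copy.deepcopy(self)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

#: Pterin-moiety content of each species in the reference model.
PTERIN_MOIETY = {
    "H2HMPt": 1,
    "H2HMPtPP": 1,
    "H2pteroate": 1,
    "DHF": 1,
    "THF": 1,
    "CH2THF": 1,
}

#: Growth-dilution demand for THF compounds in exponentially growing
#: E. coli, mmol.ml-1 cytoplasm.s-1; also the rate of both precursor
#: exchange reactions.
V_NET = 1.66e-7

_DEFAULT_PARAMETERS: dict[tuple[str, str], float] = {
    ("SRC_HMPt", "v0"): V_NET,
    ("SRC_pABA", "v0"): V_NET,
    ("FolK", "k"): 207.5,        # M-1 s-1 (second order with ATP)
    ("FolP", "k"): 2.0e6,        # M-1 s-1
    ("FolC", "k"): 415.0,        # M-1 s-1 (second order with ATP)
    ("FolA", "k"): 4.0,          # s-1 (NADPH lumped into the constant)
    ("GlyA", "kf"): 2.72e5,      # M-1 s-1 (with serine)
    ("GlyA", "kr"): 1.0e4,       # M-1 s-1 (with glycine)
    ("PanB_side", "k"): 3.32e-3,  # s-1; scales with PanB enzyme level
    ("DRAIN_THF", "vmax"): 2.0e-7,
    ("DRAIN_THF", "km"): 1.0e-5,
    ("DRAIN_CH2THF", "vmax"): 3.65e-7,
    ("DRAIN_CH2THF", "km"): 1.0e-4,
}

# Fixed cofactor/cosubstrate pools, mol.L-1, standard E. coli metabolome
# values (implementation defaults; the steady state is insensitive to them).
_DEFAULT_FIXED = {
    "ATP": 9.6e-3,
    "ADP": 5.6e-4,
    "AMP": 2.8e-4,
    "Pi": 1.0e-2,
    "PPi": 5.0e-4,
    "Ser": 6.8e-5,
    "Gly": 3.7e-3,
}

_DEFAULT_INIT = {
    "H2HMPt": 1.0e-7,
    "H2HMPtPP": 1.0e-7,
    "H2pteroate": 5.0e-8,
    "DHF": 5.0e-8,
    "THF": 2.0e-5,
    "CH2THF": 1.0e-5,
    "pABA": 1.0e-6,
}

_SPECIES_NAMES = {
    "H2HMPt": "6-hydroxymethyl-7,8-dihydropterin",
    "H2HMPtPP": "6-hydroxymethyl-7,8-dihydropterin pyrophosphate",
    "H2pteroate": "7,8-dihydropteroate",
    "DHF": "dihydrofolate",
    "THF": "tetrahydrofolate",
    "CH2THF": "5,10-methylenetetrahydrofolate",
    "pABA": "p-aminobenzoate",
    "ATP": "ATP",
    "ADP": "ADP",
    "AMP": "AMP",
    "Pi": "phosphate",
    "PPi": "pyrophosphate",
    "Ser": "L-serine",
    "Gly": "glycine",
}


@dataclass
class ModelConfig:
    """Flat parameterization of the reference model.

    ``parameters`` keys are ``(reaction id, parameter name)``; fixed-pool
    and initial concentrations are keyed by species id.
    """

    parameters: dict[tuple[str, str], float] = field(default_factory=dict)
    fixed_conc: dict[str, float] = field(default_factory=dict)
    init_conc: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ModelConfig":
        return cls(
            parameters=dict(_DEFAULT_PARAMETERS),
            fixed_conc=dict(_DEFAULT_FIXED),
            init_conc=dict(_DEFAULT_INIT),
        )

    def updated(self, parameters=None, fixed_conc=None, init_conc=None) -> "ModelConfig":
        """Return a copy with selected entries overridden."""
        cfg = ModelConfig(
            parameters=dict(self.parameters),
            fixed_conc=dict(self.fixed_conc),
            init_conc=dict(self.init_conc),
        )
        cfg.parameters.update(parameters or {})
        cfg.fixed_conc.update(fixed_conc or {})
        cfg.init_conc.update(init_conc or {})
        return cfg

    # -- flat key-value file format ---------------------------------------
    def to_file(self, path) -> None:
        lines = ["# thfkin model configuration", ""]
        for (rid, pname), value in sorted(self.parameters.items()):
            lines.append(f"reaction.{rid}.{pname} = {value!r}")
        lines.append("")
        for sid, value in sorted(self.fixed_conc.items()):
            lines.append(f"species.{sid}.init = {value!r}")
            lines.append(f"species.{sid}.fixed = true")
        for sid, value in sorted(self.init_conc.items()):
            lines.append(f"species.{sid}.init = {value!r}")
            lines.append(f"species.{sid}.fixed = false")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "ModelConfig":
        parameters: dict[tuple[str, str], float] = {}
        init: dict[str, float] = {}
        fixed_flag: dict[str, bool] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = (t.strip() for t in line.partition("="))
                parts = key.split(".")
                try:
                    if parts[0] == "reaction" and len(parts) == 3:
                        parameters[(parts[1], parts[2])] = float(value)
                    elif parts[0] == "species" and len(parts) == 3 and parts[2] == "init":
                        init[parts[1]] = float(value)
                    elif parts[0] == "species" and len(parts) == 3 and parts[2] == "fixed":
                        fixed_flag[parts[1]] = value.lower() in ("true", "1", "yes")
                    else:
                        raise ConfigurationError(f"{path}:{lineno}: unrecognized key {key!r}")
                except ValueError as exc:
                    raise ConfigurationError(f"{path}:{lineno}: bad value {value!r}") from exc
        fixed_conc = {s: c for s, c in init.items() if fixed_flag.get(s, False)}
        init_conc = {s: c for s, c in init.items() if not fixed_flag.get(s, False)}
        return cls(parameters=parameters, fixed_conc=fixed_conc, init_conc=init_conc)


# --------------------------------------------------------------------------
# Reference model
# --------------------------------------------------------------------------

def _param(config: ModelConfig, rid: str, name: str) -> float:
    try:
        value = config.parameters[(rid, name)]
    except KeyError:
        raise ConfigurationError(f"missing parameter ({rid!r}, {name!r})") from None
    if value < 0:
        raise ValidationError(f"parameter ({rid}, {name}) must be >= 0, got {value}")
    return value


def build_reference_model(config: ModelConfig | None = None) -> PathwayModel:
    """Construct the 10-reaction reference network.

    Species: six pterin-containing intermediates plus pABA are dynamic;
    ATP, ADP, AMP, Pi, PPi, Ser, Gly are fixed pools.

    The PanB side reaction is written CH2-THF -> H2-HMPt + pABA: the
    cleavage releases pABA-Glu, whose hydrolysis back to pABA is treated
    as instantaneous (glutamate untracked).  Returning the pABA moiety is
    required for a steady state to exist at all when the cleavage flux is
    nonzero, because FolP consumes pABA at v_net + v_PanB while the
    exchange reaction supplies it at v_net.
    """
    cfg = config or ModelConfig.default()

    species = []
    for sid in _DEFAULT_INIT:
        if sid not in cfg.init_conc:
            raise ConfigurationError(f"missing initial concentration for species {sid!r}")
        species.append(Species(sid, _SPECIES_NAMES[sid], cfg.init_conc[sid], fixed=False))
    for sid in _DEFAULT_FIXED:
        if sid not in cfg.fixed_conc:
            raise ConfigurationError(f"missing fixed concentration for species {sid!r}")
        species.append(Species(sid, _SPECIES_NAMES[sid], cfg.fixed_conc[sid], fixed=True))

    p = lambda rid, name: _param(cfg, rid, name)
    reactions = [
        Reaction("SRC_HMPt", {}, {"H2HMPt": 1}, ConstantFlux(p("SRC_HMPt", "v0"))),
        Reaction("SRC_pABA", {}, {"pABA": 1}, ConstantFlux(p("SRC_pABA", "v0"))),
        Reaction(
            "FolK",
            {"H2HMPt": 1, "ATP": 1},
            {"H2HMPtPP": 1, "AMP": 1},
            MassActionIrrev(p("FolK", "k")),
        ),
        Reaction(
            "FolP",
            {"H2HMPtPP": 1, "pABA": 1},
            {"H2pteroate": 1, "PPi": 1},
            MassActionIrrev(p("FolP", "k")),
        ),
        Reaction(
            "FolC",
            {"H2pteroate": 1, "ATP": 1},
            {"DHF": 1, "ADP": 1, "Pi": 1},
            MassActionIrrev(p("FolC", "k")),
        ),
        Reaction("FolA", {"DHF": 1}, {"THF": 1}, MassActionIrrev(p("FolA", "k"))),
        Reaction(
            "GlyA",
            {"THF": 1, "Ser": 1},
            {"CH2THF": 1, "Gly": 1},
            MassActionRev(p("GlyA", "kf"), p("GlyA", "kr")),
        ),
        Reaction(
            "PanB_side",
            {"CH2THF": 1},
            {"H2HMPt": 1, "pABA": 1},
            MassActionIrrev(p("PanB_side", "k")),
        ),
        Reaction(
            "DRAIN_THF",
            {"THF": 1},
            {},
            SaturatingIrrev(p("DRAIN_THF", "vmax"), p("DRAIN_THF", "km")),
        ),
        Reaction(
            "DRAIN_CH2THF",
            {"CH2THF": 1},
            {},
            SaturatingIrrev(p("DRAIN_CH2THF", "vmax"), p("DRAIN_CH2THF", "km")),
        ),
    ]
    return PathwayModel(
        species=species,
        reactions=reactions,
        metadata={"name": "THF biosynthesis with PanB cleavage and FolK recycling"},
    )


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    infos: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_model(model: PathwayModel, moiety: Mapping[str, int] | None = None) -> ValidationReport:
    """Report structural problems without raising.

    Checks dangling species references, unused fixed species, zero-valued
    rate constants, per-reaction pterin-moiety balance (sources may create
    one pterin, drains destroy one, every other reaction must conserve the
    count), and whether the summed drain capacity can absorb the constant
    pterin influx.
    """
    rep = ValidationReport()
    moiety = dict(PTERIN_MOIETY if moiety is None else moiety)
    sids = {s.id for s in model.species}

    referenced: set[str] = set()
    for r in model.reactions:
        for sid in list(r.substrates) + list(r.products):
            referenced.add(sid)
            if sid not in sids:
                rep.errors.append(f"reaction {r.id!r} references unknown species {sid!r}")
        zero = [n for n, v in r.law.parameters().items() if v == 0]
        if zero:
            rep.warnings.append(f"reaction {r.id!r} has zero-valued parameter(s) {zero}")

    for s in model.fixed_species:
        if s.id not in referenced:
            rep.infos.append(f"fixed species {s.id!r} is not used by any reaction")

    # moiety balance per reaction
    influx = 0.0
    capacity = 0.0
    for r in model.reactions:
        n_in = sum(moiety.get(sid, 0) * n for sid, n in r.substrates.items() if sid in sids)
        n_out = sum(moiety.get(sid, 0) * n for sid, n in r.products.items() if sid in sids)
        delta = n_out - n_in
        if isinstance(r.law, ConstantFlux) and delta > 0:
            influx += delta * r.law.v0
        elif isinstance(r.law, SaturatingIrrev) and delta < 0:
            capacity += -delta * r.law.vmax
        elif delta != 0:
            rep.errors.append(
                f"reaction {r.id!r} does not conserve the pterin moiety (net {delta:+d})"
            )
    if influx > 0 and influx >= capacity:
        rep.warnings.append(
            "pterin moiety has a constant source flux "
            f"({influx:.3g}) at or above the summed drain capacity ({capacity:.3g}); "
            "no steady state is possible"
        )
    return rep
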