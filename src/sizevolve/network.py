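"""Gene networks as species + interactions, and their rate laws.

A network is a bipartite description: biochemical species (proteins, one
G1/S inhibitor ``I``, one binary cell-cycle switch) and interactions
between them (Hill-type transcriptional activation/repression and
mass-action complex formation).  Networks are the evolvable genotype; this
module turns them into deterministic rate functions and stochastic
(tau-leaping) increments for concentration dynamics in a growing cell.

Unit conventions: concentrations are in arbitrary units where one unit
corresponds to roughly ``omega0`` molecules in a cell of volume 1
(~100 fL); one time unit is roughly 30 min.  Protein production is
proportional to volume, so production in *concentration* units is volume
independent and the only deterministic volume effect on concentrations is
dilution at the growth rate.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

FORMAT_VERSION = 1

ROLE_PROTEIN = "protein"
ROLE_INHIBITOR = "inhibitor-I"
ROLE_SWITCH = "switch"
ROLES = (ROLE_PROTEIN, ROLE_INHIBITOR, ROLE_SWITCH)

KIND_ACTIVATION = "transcriptional-activation"
KIND_REPRESSION = "transcriptional-repression"
KIND_COMPLEX = "complex-formation"
KINDS = (KIND_ACTIVATION, KIND_REPRESSION, KIND_COMPLEX)

#: Parameter bounds used for validation of evolvable networks and for
#: mutation/addition sampling.  rho and K span six decades around unity,
#: degradation rates four; Hill exponents are capped at 10.
PARAM_BOUNDS = {
    "rho": (1e-3, 1e3),
    "rho0": (1e-3, 1e3),
    "K": (1e-3, 1e3),
    "hill_n": (1.0, 10.0),
    "delta": (1e-2, 1e2),
    "k_on": (1e-3, 1e3),
    "k_off": (1e-3, 1e3),
    "delta_complex": (1e-2, 1e2),
}


class NetworkError(ValueError):
    """Raised for invalid network specifications or documents."""


@dataclass
class SpeciesSpec:
    """One biochemical species.

    Parameters
    ----------
    id : str
        Short unique name (e.g. ``"I"``, ``"R"``).
    role : str
        ``"protein"``, ``"inhibitor-I"`` (the species gating the G1/S
        transition) or ``"switch"`` (the binary S/G2/M pseudo-species,
        0 in G1 and 1 in S/G2/M, with no dynamics of its own).
    delta : float
        Constant degradation rate (1/time).
    rho0 : float
        Basal production rate (concentration/time); 0 for genes produced
        only through regulation.
    init_conc : float
        Concentration at simulation start.
    """

    id: str
    role: str = ROLE_PROTEIN
    delta: float = 0.0
    rho0: float = 0.0
    init_conc: float = 0.0

    def validate(self) -> None:
        if not self.id or not isinstance(self.id, str):
            raise NetworkError("species id must be a non-empty string")
        if self.role not in ROLES:
            raise NetworkError(f"unknown species role {self.role!r} for {self.id!r}")
        for name in ("delta", "rho0", "init_conc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise NetworkError(f"species {self.id!r}: {name} must be >= 0, got {v}")
        if self.role == ROLE_SWITCH and (self.delta != 0 or self.rho0 != 0):
            raise NetworkError("the switch is a binary pseudo-species without dynamics")


@dataclass
class InteractionSpec:
    """One interaction.

    ``kind`` selects the parameter set:

    - transcriptional-activation: ``rho`` (strength, concentration/time),
      ``K`` (threshold), ``hill_n`` (>= 1); single source.
    - transcriptional-repression: ``K``, ``hill_n``; single source.
      Repressors act multiplicatively on the target's total production,
      so they carry no strength of their own.
    - complex-formation: ``k_on``, ``k_off``, ``delta_complex``; exactly
      two sources, creating an implicit inert complex species.
    """

    kind: str
    sources: tuple[str, ...]
    target: str
    rho: float | None = None
    K: float | None = None
    hill_n: float | None = None
    k_on: float | None = None
    k_off: float | None = None
    delta_complex: float | None = None
    mutable: bool = True

    def __post_init__(self) -> None:
        self.sources = tuple(self.sources)

    def _check_positive(self, name: str, bounds_key: str | None = None) -> None:
        v = getattr(self, name)
        if v is None or not np.isfinite(v) or v <= 0:
            raise NetworkError(f"{self.kind} {self.sources}->{self.target}: "
                               f"parameter {name} must be > 0, got {v}")

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise NetworkError(f"unknown interaction kind {self.kind!r}")
        if self.kind in (KIND_ACTIVATION, KIND_REPRESSION):
            if len(self.sources) != 1:
                raise NetworkError(f"{self.kind} takes exactly one source")
            if self.kind == KIND_ACTIVATION:
                self._check_positive("rho")
            self._check_positive("K")
            if self.hill_n is None or self.hill_n < 1:
                raise NetworkError(
                    f"{self.kind} {self.sources[0]}->{self.target}: "
                    f"hill_n must be >= 1, got {self.hill_n}")
            if self.hill_n > PARAM_BOUNDS["hill_n"][1]:
                raise NetworkError(f"hill_n {self.hill_n} above bound "
                                   f"{PARAM_BOUNDS['hill_n'][1]}")
        else:
            if len(self.sources) != 2:
                raise NetworkError("complex-formation takes exactly two sources")
            if self.sources[0] == self.sources[1]:
                raise NetworkError("complex-formation sources must be distinct")
            self._check_positive("k_on")
            self._check_positive("k_off")
            self._check_positive("delta_complex")

    @property
    def key(self) -> tuple:
        if self.kind == KIND_COMPLEX:
            return (self.kind, tuple(sorted(self.sources)))
        return (self.kind, self.sources, self.target)

    def params(self) -> dict[str, float]:
        """Mutable numeric parameters of this interaction, by name."""
        if self.kind == KIND_ACTIVATION:
            return {"rho": self.rho, "K": self.K, "hill_n": self.hill_n}
        if self.kind == KIND_REPRESSION:
            return {"K": self.K, "hill_n": self.hill_n}
        return {"k_on": self.k_on, "k_off": self.k_off,
                "delta_complex": self.delta_complex}


def complex_id(a: str, b: str) -> str:
    """Canonical id of the implicit inert complex of species ``a`` and ``b``."""
    lo, hi = sorted((a, b))
    return f"cplx_{lo}_{hi}"


@dataclass
class NetworkSpec:
    """Species + interactions; the evolvable genotype.

    Complexes created by complex-formation interactions are implicit: they
    are tracked in :meth:`complex_registry` and materialized as dynamic
    species when the network is compiled, but they do not appear in
    ``species`` and cannot be regulated or sensed.
    """

    species: list[SpeciesSpec] = field(default_factory=list)
    interactions: list[InteractionSpec] = field(default_factory=list)
    version: int = FORMAT_VERSION

    # -- introspection -------------------------------------------------
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == sid:
                return s
        raise NetworkError(f"unknown species {sid!r}")

    @property
    def inhibitor(self) -> SpeciesSpec:
        return next(s for s in self.species if s.role == ROLE_INHIBITOR)

    @property
    def switch(self) -> SpeciesSpec:
        return next(s for s in self.species if s.role == ROLE_SWITCH)

    def complex_registry(self) -> dict[str, InteractionSpec]:
        """Map implicit complex id -> the interaction creating it."""
        return {complex_id(*ix.sources): ix
                for ix in self.interactions if ix.kind == KIND_COMPLEX}

    # -- validation ----------------------------------------------------
    def validate(self) -> "NetworkSpec":
        if self.version > FORMAT_VERSION:
            raise NetworkError(
                f"network format version {self.version} is newer than the "
                f"supported version {FORMAT_VERSION}")
        ids = self.species_ids()
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate species ids")
        for s in self.species:
            s.validate()
        n_inh = sum(s.role == ROLE_INHIBITOR for s in self.species)
        n_sw = sum(s.role == ROLE_SWITCH for s in self.species)
        if n_inh != 1:
            raise NetworkError(f"exactly one inhibitor-I species required, got {n_inh}")
        if n_sw != 1:
            raise NetworkError(f"exactly one switch species required, got {n_sw}")
        seen: set[tuple] = set()
        sw = self.switch.id
        for ix in self.interactions:
            ix.validate()
            for sid in (*ix.sources, ix.target):
                if sid not in ids:
                    raise NetworkError(
                        f"interaction references unknown species {sid!r}")
            if ix.kind == KIND_COMPLEX and sw in ix.sources:
                raise NetworkError("the switch cannot form complexes")
            if ix.target == sw:
                raise NetworkError("the switch cannot be a regulation target")
            if ix.key in seen:
                raise NetworkError(f"duplicate interaction {ix.key}")
            seen.add(ix.key)
        return self

    def copy(self) -> "NetworkSpec":
        return copy.deepcopy(self)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        doc = {
            "version": self.version,
            "species": [
                {"id": s.id, "role": s.role, "delta": s.delta,
                 "rho0": s.rho0, "init_conc": s.init_conc}
                for s in self.species
            ],
            "interactions": [],
        }
        for ix in self.interactions:
            d = {"kind": ix.kind, "sources": list(ix.sources),
                 "target": ix.target, "mutable": ix.mutable}
            d.update({k: v for k, v in ix.params().items()})
            doc["interactions"].append(d)
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "NetworkSpec":
        if not isinstance(doc, Mapping):
            raise NetworkError("network document must be a mapping")
        for key in ("version", "species", "interactions"):
            if key not in doc:
                raise NetworkError(f"network document missing field {key!r}")
        species = []
        for sd in doc["species"]:
            unknown = set(sd) - {"id", "role", "delta", "rho0", "init_conc"}
            if unknown:
                raise NetworkError(f"unknown species fields {sorted(unknown)}")
            species.append(SpeciesSpec(**sd))
        interactions = []
        allowed = {"kind", "sources", "target", "mutable", "rho", "K",
                   "hill_n", "k_on", "k_off", "delta_complex"}
        for xd in doc["interactions"]:
            unknown = set(xd) - allowed
            if unknown:
                raise NetworkError(f"unknown interaction fields {sorted(unknown)}")
            if xd.get("kind") not in KINDS:
                raise NetworkError(
                    f"unknown interaction kind {xd.get('kind')!r} in document")
            xd = dict(xd)
            xd["sources"] = tuple(xd.get("sources", ()))
            interactions.append(InteractionSpec(**xd))
        net = cls(species=species, interactions=interactions,
                  version=int(doc["version"]))
        return net.validate()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkSpec):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def serialize_network(network: NetworkSpec) -> str:
    """Serialize a validated network to a versioned JSON document."""
    network.validate()
    return json.dumps(network.to_dict(), indent=2, sort_keys=True)


def deserialize_network(document: str | Mapping) -> NetworkSpec:
    """Parse and validate a network document (JSON text or mapping)."""
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"malformed network document: {exc}") from exc
    return NetworkSpec.from_dict(document)


# ---------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------

def hill_regulation(conc: float, K: float, n: float, kind: str) -> float:
    """Hill multiplier in [0, 1] for a transcriptional input.

    Activation returns ``conc**n / (K**n + conc**n)``; repression returns
    ``K**n / (K**n + conc**n)``.
    """
    if K <= 0:
        raise NetworkError(f"Hill threshold K must be > 0, got {K}")
    if n < 1:
        raise NetworkError(f"Hill exponent must be >= 1, got {n}")
    if conc < 0:
        raise NetworkError(f"concentration must be >= 0, got {conc}")
    cn = conc ** n
    kn = K ** n
    act = cn / (kn + cn)
    if kind in (KIND_ACTIVATION, "activation"):
        return act
    if kind in (KIND_REPRESSION, "repression"):
        return 1.0 - act
    raise NetworkError(f"unknown regulation kind {kind!r}")


@dataclass
class RateVector:
    """Per-species deterministic rates (concentration/time) at a state.

    ``production`` and ``degradation`` are the nonnegative propensities of
    the corresponding elementary reactions; ``dilution`` is the (also
    nonnegative) growth-dilution loss, which is not a chemical reaction
    and carries no molecular noise.  ``complex_on``/``complex_off`` are
    the mass-action fluxes of each complex-formation channel, indexed in
    the order of ``complex_triples`` (partner a, partner b, complex).
    """

    names: list[str]
    production: np.ndarray
    degradation: np.ndarray
    dilution: np.ndarray
    complex_on: np.ndarray
    complex_off: np.ndarray
    complex_triples: list[tuple[int, int, int]]

    def net(self) -> dict[str, float]:
        """Net deterministic d[X]/dt per species."""
        dx = self.production - self.degradation - self.dilution
        for j, (a, b, c) in enumerate(self.complex_triples):
            flux = self.complex_on[j] - self.complex_off[j]
            dx[a] -= flux
            dx[b] -= flux
            dx[c] += flux
        return dict(zip(self.names, dx))


def assemble_rates(network: NetworkSpec, conc: Mapping[str, float],
                   switch_value: float, volume: float,
                   growth_rate: float) -> RateVector:
    """Evaluate all deterministic rates for ``network`` at a state.

    ``conc`` maps species id -> concentration for every protein species
    and (optionally) implicit complexes; missing complexes default to 0.
    The switch enters transcription as an exact 0/1 factor.  Production of
    species X follows the combination rule

        (rho0_X + sum over activators rho_a * h_act) * prod over repressors h_rep

    and every species additionally loses ``delta_X*[X]`` to degradation and
    ``lambda*[X]`` to dilution.  Complexes obey
    ``k_on[A][B] - k_off[C] - delta_C[C] - lambda[C]``.
    """
    if volume <= 0:
        raise NetworkError(f"volume must be > 0, got {volume}")
    registry = network.complex_registry()
    names = [s.id for s in network.species if s.role != ROLE_SWITCH]
    names += list(registry)
    index = {nm: i for i, nm in enumerate(names)}
    sw_id = network.switch.id

    x = np.zeros(len(names))
    for nm in names:
        v = conc.get(nm, 0.0)
        if v < 0:
            raise NetworkError(f"negative concentration for {nm!r}")
        x[index[nm]] = v

    production = np.zeros(len(names))
    degradation = np.zeros(len(names))
    for s in network.species:
        if s.role == ROLE_SWITCH:
            continue
        production[index[s.id]] = s.rho0
        degradation[index[s.id]] = s.delta * x[index[s.id]]

    def _source_conc(sid: str) -> float:
        if sid == sw_id:
            return 1.0 if switch_value else 0.0
        if sid in index:
            return x[index[sid]]
        raise NetworkError(f"interaction references unknown species {sid!r}")

    for ix in network.interactions:
        if ix.kind == KIND_ACTIVATION:
            h = hill_regulation(_source_conc(ix.sources[0]), ix.K, ix.hill_n,
                                KIND_ACTIVATION)
            # the switch is a step input: contributes exactly 0 or 1
            if ix.sources[0] == sw_id:
                h = 1.0 if switch_value else 0.0
            production[index[ix.target]] += ix.rho * h
    for ix in network.interactions:
        if ix.kind == KIND_REPRESSION:
            if ix.sources[0] == sw_id:
                h = 0.0 if switch_value else 1.0
            else:
                h = hill_regulation(_source_conc(ix.sources[0]), ix.K,
                                    ix.hill_n, KIND_REPRESSION)
            production[index[ix.target]] *= h

    triples: list[tuple[int, int, int]] = []
    c_on, c_off = [], []
    for cid, ix in registry.items():
        a, b = ix.sources
        ia, ib, ic = index[a], index[b], index[cid]
        triples.append((ia, ib, ic))
        c_on.append(ix.k_on * x[ia] * x[ib])
        c_off.append(ix.k_off * x[ic])
        degradation[ic] = ix.delta_complex * x[ic]

    return RateVector(
        names=names,
        production=production,
        degradation=degradation,
        dilution=growth_rate * x,
        complex_on=np.asarray(c_on, dtype=float),
        complex_off=np.asarray(c_off, dtype=float),
        complex_triples=triples,
    )


def tau_leap_step(rates: RateVector, conc: Mapping[str, float], dt: float,
                  volume: float, noise_on: bool, omega0: float,
                  rng: np.random.Generator | None = None) -> dict[str, float]:
    """Advance concentrations by one (possibly stochastic) tau-leap of ``dt``.

    Each elementary reaction with concentration-rate k corresponds to a
    molecular rate ``k * omega0 * volume``; its tau-leaping increment is
    ``k_mol*dt + Normal(0, k_mol*dt)`` molecules, converted back to
    concentration units.  Equivalently, in concentration units the added
    Gaussian noise has variance ``k*dt / (omega0*volume)`` — the 1/V
    scaling that makes small cells noisy.  Dilution is deterministic.
    With ``noise_on`` false this reduces to a forward-Euler step.
    Concentrations are floored at 0.
    """
    if dt <= 0:
        raise NetworkError(f"dt must be > 0, got {dt}")
    if volume <= 0:
        raise NetworkError(f"volume must be > 0, got {volume}")
    n = len(rates.names)
    x = np.array([conc.get(nm, 0.0) for nm in rates.names], dtype=float)

    def channel(rate: float) -> float:
        if rate < 0:
            raise NetworkError(f"negative propensity {rate}")
        inc = rate * dt
        if noise_on and inc > 0:
            inc += math.sqrt(rate * dt / (omega0 * volume)) * rng.standard_normal()
        return inc

    dx = np.zeros(n)
    for i in range(n):
        dx[i] += channel(rates.production[i])
        dx[i] -= channel(rates.degradation[i])
        dx[i] -= rates.dilution[i] * dt
    for j, (a, b, c) in enumerate(rates.complex_triples):
        on = channel(rates.complex_on[j])
        off = channel(rates.complex_off[j])
        dx[a] += off - on
        dx[b] += off - on
        dx[c] += on - off
    x = np.maximum(x + dx, 0.0)
    return dict(zip(rates.names, x))
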