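"""Event-by-event Monte Carlo electron transport through a pyridine gas cell.

Each electron is followed collision by collision: an exponential free
path is drawn from the local mean free path, the interaction channel is
sampled from the relative integral cross sections, the scattering angle
from the channel's angular model and the energy loss from the channel's
loss distribution; the direction is updated by an explicit 3-D rotation
(polar scattering angle about the current direction, uniform azimuth).
Secondary electrons from ionization are transported with the same
physics.  Electrons falling below 0.1 eV are culled and their residual
energy tallied as locally deposited.

Two virtual experiments are built on the engine:

* the magnetically confined transmission measurement: a strong axial
  field freezes transverse motion (gyro-radius of microns), so
  scattering manifests purely as loss of axial kinetic energy
  ``E_par = E * d_z**2``; a retarding-potential analyzer then counts the
  electrons whose axial energy exceeds the barrier, producing a
  transmission curve;
* a linear attenuation measurement of an effective total cross section
  ``sigma_eff = ln(I0/I) / (n L)``, where the transmitted intensity I
  depends on the detector's ability to discriminate forward-scattered
  electrons — reproducing the "missing angle" systematics of real
  transmission experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .angular import (
    InelasticAngularParams,
    RotationalDCS,
    ScreenedRutherfordDCS,
)
from .eloss import (
    DEFAULT_BINDING_EV,
    EnergyLossModel,
    default_loss_models,
    elastic_recoil,
)
from .xsec import (
    CHANNEL_ORDER,
    Channel,
    CrossSectionSet,
    GasConditions,
    load_builtin,
    mean_free_path,
    pressure_to_density,
)

__all__ = [
    "CULL_ENERGY_EV",
    "ElectronState",
    "EventRecord",
    "SimConfig",
    "Physics",
    "RunResult",
    "TransmissionCurve",
    "run_beam",
    "axial_energy",
    "rpa_curve",
    "virtual_tcs",
]

#: electrons below this kinetic energy are culled from the simulation, eV.
CULL_ENERGY_EV = 0.1

_THETA_GRID = np.linspace(0.0, math.pi, 1024)
_SIN_GRID = np.sin(_THETA_GRID)


@dataclass
class ElectronState:
    """One electron's kinematic state."""

    position: np.ndarray  # m, (x, y, z)
    direction: np.ndarray  # unit 3-vector
    energy: float  # eV
    generation: int = 0
    alive: bool = True
    n_collisions: int = 0

    def copy(self) -> "ElectronState":
        return ElectronState(
            position=self.position.copy(),
            direction=self.direction.copy(),
            energy=self.energy,
            generation=self.generation,
            alive=self.alive,
            n_collisions=self.n_collisions,
        )


@dataclass(frozen=True)
class EventRecord:
    """Per-collision audit entry."""

    z: float  # m
    channel: Channel
    delta_e: float  # eV lost by the primary (deposited + secondary)
    theta: float  # rad (nan for attachment)
    secondary_spawned: bool
    generation: int


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one transport run."""

    gas: GasConditions
    beam_energy: float  # eV
    beam_fwhm: float = 0.45  # eV, Gaussian spread, truncated at the cull energy
    n_electrons: int = 1000
    seed: int = 0
    confinement: bool = True
    track_secondaries: bool = True
    max_generation: int = 3
    backscatter_policy: str = "lost"  # or "reflected"
    channels: tuple[Channel, ...] = CHANNEL_ORDER
    record_events: bool = True

    def __post_init__(self) -> None:
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")
        if self.beam_fwhm < 0:
            raise ValueError("beam_fwhm must be >= 0")
        if self.backscatter_policy not in ("lost", "reflected"):
            raise ValueError(f"unknown backscatter policy {self.backscatter_policy!r}")
        if not self.channels:
            raise ValueError("at least one channel must be active")
        object.__setattr__(
            self, "channels", tuple(Channel(c) for c in self.channels)
        )
        if self.beam_energy < CULL_ENERGY_EV:
            raise ValueError("beam energy below the cull threshold")


@dataclass
class Physics:
    """The cross-section set plus angular and energy-loss models."""

    dataset: CrossSectionSet
    elastic: object  # callable (E, theta) -> DCS
    rotational: RotationalDCS
    inelastic: InelasticAngularParams
    loss_models: dict[Channel, EnergyLossModel]
    _cdf_cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def default(
        cls,
        dataset: CrossSectionSet | None = None,
        variant: str = "recommended",
        eta0: float = 1.0,
        k: float = 1.3,
        formula: str = "eq2",
        binding_energy: float = DEFAULT_BINDING_EV,
    ) -> "Physics":
        """Default physics: screened-Rutherford elastic shape, dipole-Born
        rotational shape, the improved semi-empirical inelastic shape and
        the parametric energy-loss models."""
        if dataset is None:
            dataset = load_builtin(variant)
        return cls(
            dataset=dataset,
            elastic=ScreenedRutherfordDCS(
                ics=lambda e: dataset.sigma(Channel.ELASTIC, e), eta0=eta0
            ),
            rotational=RotationalDCS(
                ics=lambda e: dataset.sigma(Channel.ROTATIONAL, e)
            ),
            inelastic=InelasticAngularParams(k=k, formula=formula),
            loss_models=default_loss_models(binding_energy=binding_energy),
        )

    # -- angular sampling -------------------------------------------------

    def _cdf_for(self, channel: Channel, energy: float, exponent: float):
        # exact key: a hit must mean an identical CDF, so results never
        # depend on what an earlier run left in the cache
        key = (channel, energy, exponent)
        cached = self._cdf_cache.get(key)
        if cached is not None:
            return cached
        if channel is Channel.ROTATIONAL:
            pdf = self.rotational(energy, _THETA_GRID)
        else:
            pdf = np.asarray(self.elastic(energy, _THETA_GRID), dtype=float)
            if exponent != 1.0:
                pdf = pdf**exponent
        weights = pdf * _SIN_GRID
        cdf = integrate.cumulative_trapezoid(weights, _THETA_GRID, initial=0.0)
        total = cdf[-1]
        if total <= 0:
            raise ValueError(f"degenerate angular pdf for {channel} at {energy} eV")
        cdf = cdf / total
        if len(self._cdf_cache) > 8192:
            self._cdf_cache.clear()
        self._cdf_cache[key] = cdf
        return cdf

    def sample_angle(
        self, channel: Channel, energy: float, energy_loss: float, rng
    ) -> float:
        """Polar scattering angle for one collision (radians)."""
        if channel is Channel.ELASTIC:
            exponent = 1.0
        elif channel is Channel.ROTATIONAL:
            exponent = 1.0
        else:
            exponent = self.inelastic.exponent(energy, min(energy_loss, energy * 0.999))
        cdf = self._cdf_for(channel, energy, exponent)
        return float(np.interp(rng.random(), cdf, _THETA_GRID))


@dataclass(frozen=True)
class TransmissionCurve:
    """Electron intensity above a retarding-potential barrier."""

    potentials: np.ndarray  # V
    counts: np.ndarray  # per incident electron

    def __post_init__(self) -> None:
        object.__setattr__(self, "potentials", np.asarray(self.potentials, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        if np.any(np.diff(self.counts) > 1e-15):
            raise ValueError("transmission counts must be non-increasing")


@dataclass
class RunResult:
    """Exit states, event log and energy ledger of one run."""

    exits: list[ElectronState]
    backscattered: list[ElectronState]
    events: list[EventRecord]
    ledger: dict[str, float]
    n_incident: int
    config: SimConfig

    @property
    def transmitted_fraction(self) -> float:
        return sum(1 for s in self.exits if s.generation == 0) / self.n_incident

    @property
    def zero_collision_fraction(self) -> float:
        return (
            sum(1 for s in self.exits if s.generation == 0 and s.n_collisions == 0)
            / self.n_incident
        )


def _rotate(direction: np.ndarray, theta: float, phi: float) -> np.ndarray:
    """Rotate ``direction`` by polar angle ``theta`` about itself, azimuth ``phi``."""
    d = direction
    if abs(d[2]) < 0.9999:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    out = (
        math.cos(theta) * d
        + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2)
    )
    return out / np.linalg.norm(out)


def _initial_energy(config: SimConfig, rng) -> float:
    if config.beam_fwhm == 0.0:
        return config.beam_energy
    sigma = config.beam_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    while True:
        energy = rng.normal(config.beam_energy, sigma)
        if energy >= CULL_ENERGY_EV:
            return energy


def run_beam(config: SimConfig, physics: Physics | None = None) -> RunResult:
    """Transport ``config.n_electrons`` primaries through the gas cell.

    Fully reproducible for a fixed ``config.seed``: identical
    configurations give bit-identical event logs and ledgers.
    """
    if physics is None:
        physics = Physics.default()
    dataset = physics.dataset
    e_lo, e_hi = dataset.energy_range
    if config.beam_energy > e_hi:
        raise ValueError(
            f"beam energy {config.beam_energy} eV above the data set range"
        )
    for channel in config.channels:
        if channel is not Channel.ELASTIC and channel not in physics.loss_models:
            raise ValueError(f"no energy-loss model for {channel}")

    rng = np.random.default_rng(config.seed)
    gas = config.gas
    density = pressure_to_density(gas)
    length = gas.cell_length

    exits: list[ElectronState] = []
    backscattered: list[ElectronState] = []
    events: list[EventRecord] = []
    ledger = {
        "injected": 0.0,
        "exited_forward": 0.0,
        "exited_backward": 0.0,
        "deposited": 0.0,
        "culled": 0.0,
        "secondary_untracked": 0.0,
    }

    def sigmas_at(energy: float) -> dict[Channel, float]:
        # the cull threshold (0.1 eV) can sit just below the first tabulated
        # energy; clamp the lookup to the grid edge over that sliver
        energy = min(max(energy, e_lo), e_hi)
        return {c: dataset.sigma(c, energy) for c in config.channels}

    def transport(state: ElectronState) -> None:
        while state.alive:
            # lookup energy clamped to the tabulated grid over the sliver
            # between the cull threshold and the first tabulated energy
            e_query = min(max(state.energy, e_lo), e_hi)
            sigmas = sigmas_at(state.energy)
            sigma_tot = sum(sigmas.values())
            lam = mean_free_path(sigma_tot, density)
            if math.isinf(lam):
                step = math.inf
            else:
                step = rng.exponential(lam)
            dz = state.direction[2]
            z = state.position[2]
            if dz > 0 and (math.isinf(step) or z + step * dz >= length):
                state.position = state.position + state.direction * (
                    (length - z) / dz
                )
                exits.append(state)
                ledger["exited_forward"] += state.energy
                return
            if dz < 0 and (math.isinf(step) or z + step * dz <= 0.0):
                if config.backscatter_policy == "reflected":
                    # specular return at the source plane; the remaining
                    # flight is redrawn (memoryless free path)
                    state.position = state.position + state.direction * (-z / dz)
                    state.direction = state.direction.copy()
                    state.direction[2] = -state.direction[2]
                    continue
                state.position = state.position + state.direction * (-z / dz)
                backscattered.append(state)
                ledger["exited_backward"] += state.energy
                return
            if math.isinf(step):  # dz == 0 in vacuum: cannot exit axially
                backscattered.append(state)
                ledger["exited_backward"] += state.energy
                return
            # collision
            state.position = state.position + state.direction * step
            if config.confinement:
                state.position[0] = 0.0
                state.position[1] = 0.0
            state.n_collisions += 1
            u = rng.random() * sigma_tot
            acc = 0.0
            channel = config.channels[-1]
            for c in config.channels:
                acc += sigmas[c]
                if u <= acc:
                    channel = c
                    break

            if channel is Channel.ATTACHMENT:
                deposited, secondary, theta = state.energy, 0.0, math.nan
                state.alive = False
            else:
                if channel is Channel.ELASTIC:
                    theta = physics.sample_angle(channel, e_query, 0.0, rng)
                    deposited = elastic_recoil(
                        state.energy, theta, gas.molar_mass
                    )
                    secondary = 0.0
                else:
                    deposited, secondary = physics.loss_models[channel].sample(
                        state.energy, rng
                    )
                    theta = physics.sample_angle(
                        channel, e_query, deposited + secondary, rng
                    )
                phi = 2.0 * math.pi * rng.random()
                state.direction = _rotate(state.direction, theta, phi)

            ledger["deposited"] += deposited
            if config.record_events:
                events.append(
                    EventRecord(
                        z=float(state.position[2]),
                        channel=channel,
                        delta_e=deposited + secondary,
                        theta=theta,
                        secondary_spawned=secondary > 0.0,
                        generation=state.generation,
                    )
                )
            if secondary > 0.0:
                if (
                    config.track_secondaries
                    and state.generation < config.max_generation
                ):
                    if secondary < CULL_ENERGY_EV:
                        ledger["culled"] += secondary
                    else:
                        child = ElectronState(
                            position=state.position.copy(),
                            direction=_rotate(
                                np.array([0.0, 0.0, 1.0]),
                                math.acos(2.0 * rng.random() - 1.0),
                                2.0 * math.pi * rng.random(),
                            ),
                            energy=secondary,
                            generation=state.generation + 1,
                        )
                        pending.append(child)
                else:
                    ledger["secondary_untracked"] += secondary

            if state.alive:
                state.energy = state.energy - deposited - secondary
                if state.energy < CULL_ENERGY_EV:
                    ledger["culled"] += state.energy
                    state.alive = False

    for _ in range(config.n_electrons):
        energy0 = _initial_energy(config, rng)
        ledger["injected"] += energy0
        primary = ElectronState(
            position=np.zeros(3),
            direction=np.array([0.0, 0.0, 1.0]),
            energy=energy0,
        )
        pending: list[ElectronState] = [primary]
        while pending:
            transport(pending.pop())

    return RunResult(
        exits=exits,
        backscattered=backscattered,
        events=events,
        ledger=ledger,
        n_incident=config.n_electrons,
        config=config,
    )


def axial_energy(state: ElectronState) -> float:
    """Axial kinetic energy ``E * d_z**2``, eV.

    Under magnetic confinement the transverse energy stays locked in
    gyro-motion, so the retarding barrier probes only this component.
    """
    return state.energy * float(state.direction[2]) ** 2


def rpa_curve(
    result: RunResult,
    potentials: np.ndarray,
    include_secondaries: bool = False,
) -> TransmissionCurve:
    """Retarding-potential transmission curve of a confined run.

    ``counts(V)`` is the number of forward exits with axial kinetic
    energy of at least ``e*V``, per incident electron; it is
    non-increasing in V.  By default only primaries are counted so the
    per-incident normalization is bounded by 1.
    """
    potentials = np.asarray(potentials, dtype=float)
    states = [
        s for s in result.exits if include_secondaries or s.generation == 0
    ]
    if not states:
        import warnings

        warnings.warn("empty exit set: all-zero transmission curve")
        return TransmissionCurve(potentials, np.zeros_like(potentials))
    e_par = np.sort([axial_energy(s) for s in states])
    counts = (
        e_par.size - np.searchsorted(e_par, potentials, side="left")
    ) / result.n_incident
    return TransmissionCurve(potentials, counts)


def virtual_tcs(
    config: SimConfig,
    physics: Physics | None = None,
    acceptance: tuple[str, float] | None = None,
) -> float:
    """Effective total cross section from a virtual attenuation run, 1e-20 m^2.

    ``sigma_eff = ln(I0 / I) / (n L)`` where I counts the transmitted
    primaries under the chosen discrimination criterion:

    * ``None`` — perfect discrimination: only never-collided primaries
      count as transmitted, recovering the full total cross section;
    * ``("angle", theta_acc)`` — exits whose final polar angle lies
      within the acceptance cone also count (missing-angle deficit);
    * ``("axial", delta_e)`` — exits whose axial energy is within
      ``delta_e`` of the beam energy also count (confined apparatus).

    The thin-target regime (n sigma L < ~0.5) is recommended.
    """
    if physics is None:
        physics = Physics.default()
    result = run_beam(config, physics)
    primaries = [s for s in result.exits if s.generation == 0]
    if acceptance is None:
        transmitted = [s for s in primaries if s.n_collisions == 0]
    else:
        kind, value = acceptance
        if kind == "angle":
            transmitted = [
                s for s in primaries if math.acos(min(s.direction[2], 1.0)) <= value
            ]
        elif kind == "axial":
            transmitted = [
                s for s in primaries if axial_energy(s) >= config.beam_energy - value
            ]
        else:
            raise ValueError(f"unknown acceptance kind {kind!r}")
    intensity = len(transmitted)
    if intensity == 0:
        raise ValueError("opaque target: no transmitted electrons")
    density = pressure_to_density(config.gas)
    sigma_si = math.log(config.n_electrons / intensity) / (
        density * config.gas.cell_length
    )
    return sigma_si / 1e-20
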