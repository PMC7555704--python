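"""Integral cross-section tables for electron-pyridine scattering (0.1-100 eV).

This module is the machine-readable twin of the compiled recommended
cross-section set: one grid of integral cross sections per scattering
channel (elastic, rotational excitation, vibrational excitation,
electronic excitation, ionization, dissociative electron attachment),
each tabulated against incident electron energy in units of 1e-20 m^2.

Two elastic variants are shipped:

``recommended``
    R-matrix below 10 eV joined to IAM-SCAR above, the set recommended
    for transport modelling.
``smc``
    Schwinger-multichannel (pseudopotential, SEP level) elastic integral
    cross sections below 20 eV, joined to the recommended values above;
    used for sensitivity studies of the simulated transmission.

Interpolation between grid points is log-log linear by default (the
tabulated values span four orders of magnitude); inside the sharp
attachment resonance windows and across the verbatim-retained SMC spike
at 0.9 eV it is linear-linear so the densely tabulated peak shapes are
not distorted.  No extrapolation is performed outside the tabulated
energy range.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
from scipy import constants

__all__ = [
    "Channel",
    "ChannelGrid",
    "CrossSectionSet",
    "GasConditions",
    "load_builtin",
    "pressure_to_density",
    "mean_free_path",
]


class Channel(str, enum.Enum):
    """The six scattering channels of the compiled data set."""

    ELASTIC = "elastic"
    ROTATIONAL = "rotational"
    VIBRATIONAL = "vibrational"
    ELECTRONIC = "electronic"
    IONIZATION = "ionization"
    ATTACHMENT = "attachment"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: channels whose first tabulated energy is a physical onset; queries below
#: (or above the end of) their tabulated support return zero cross section.
THRESHOLD_CHANNELS = frozenset(
    {Channel.VIBRATIONAL, Channel.ELECTRONIC, Channel.IONIZATION, Channel.ATTACHMENT}
)

#: canonical ordering used for probability vectors and event sampling.
CHANNEL_ORDER = (
    Channel.ELASTIC,
    Channel.ROTATIONAL,
    Channel.VIBRATIONAL,
    Channel.ELECTRONIC,
    Channel.IONIZATION,
    Channel.ATTACHMENT,
)

#: upper-bound table cells ("<0.1") are decoded to the interval midpoint.
BOUND_SENTINEL = "<0.1"
BOUND_VALUE = 0.05

#: energy windows (eV) interpolated linear-linear instead of log-log.
ATTACHMENT_LINEAR_WINDOWS = ((0.71, 0.935), (1.01, 1.2))
SMC_LINEAR_WINDOWS = ((0.8, 1.0),)


class CrossSectionError(ValueError):
    """Raised for schema violations in cross-section tables and range errors."""


@dataclass(frozen=True)
class ChannelGrid:
    """One channel's integral cross section tabulated against energy.

    Parameters
    ----------
    channel
        Scattering channel the grid belongs to.
    energies
        Incident electron energies, eV, strictly ascending.
    values
        Integral cross sections, 1e-20 m^2, aligned with ``energies``.
    below_threshold_policy
        ``"zero"`` (threshold channels: queries outside the tabulated
        support return 0) or ``"error"``.
    source
        Free-text provenance tag.
    bound_flags
        True where the printed cell was an upper bound ("<0.1") decoded
        to the interval midpoint.
    linear_windows
        Energy windows within which interpolation is linear-linear.
    raw_values
        The printed cell strings, kept for lossless re-serialization.
    """

    channel: Channel
    energies: np.ndarray
    values: np.ndarray
    below_threshold_policy: str = "zero"
    source: str = ""
    bound_flags: np.ndarray | None = None
    linear_windows: tuple[tuple[float, float], ...] = ()
    raw_values: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        energies = np.asarray(self.energies, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "energies", energies)
        object.__setattr__(self, "values", values)
        if energies.ndim != 1 or energies.shape != values.shape:
            raise CrossSectionError(f"{self.channel}: energies/values shape mismatch")
        if energies.size == 0:
            raise CrossSectionError(f"{self.channel}: empty grid")
        if np.any(energies <= 0):
            row = int(np.argmax(energies <= 0))
            raise CrossSectionError(
                f"{self.channel}: non-positive energy at row {row} ({energies[row]})"
            )
        if np.any(np.diff(energies) <= 0):
            row = int(np.argmax(np.diff(energies) <= 0)) + 1
            raise CrossSectionError(
                f"{self.channel}: energies not strictly increasing at row {row} "
                f"({energies[row]})"
            )
        if np.any(values < 0):
            row = int(np.argmax(values < 0))
            raise CrossSectionError(
                f"{self.channel}: negative cross section at row {row} ({values[row]})"
            )
        if self.below_threshold_policy not in ("zero", "error"):
            raise CrossSectionError(
                f"{self.channel}: unknown policy {self.below_threshold_policy!r}"
            )

    @property
    def support(self) -> tuple[float, float]:
        """Tabulated energy support (eV)."""
        return float(self.energies[0]), float(self.energies[-1])

    def _in_linear_window(self, e_lo: float, e_hi: float) -> bool:
        return any(lo <= e_lo and e_hi <= hi for lo, hi in self.linear_windows)

    def __call__(self, energy: float) -> float:
        """Cross section at ``energy`` (eV), in 1e-20 m^2.

        Returns the stored value exactly at grid energies.  Between grid
        points the interpolation is log-log linear, or linear-linear
        inside a designated resonance window.  Outside the tabulated
        support the result is 0 under the ``zero`` policy and an error
        under ``error``.
        """
        e = float(energy)
        lo, hi = self.support
        if e < lo or e > hi:
            if self.below_threshold_policy == "zero":
                return 0.0
            raise CrossSectionError(
                f"{self.channel}: energy {e} eV outside tabulated range [{lo}, {hi}]"
            )
        idx = int(np.searchsorted(self.energies, e))
        if idx < self.energies.size and self.energies[idx] == e:
            return float(self.values[idx])
        e0, e1 = self.energies[idx - 1], self.energies[idx]
        v0, v1 = self.values[idx - 1], self.values[idx]
        if self._in_linear_window(float(e0), float(e1)) or v0 == 0.0 or v1 == 0.0:
            t = (e - e0) / (e1 - e0)
            return float(v0 + t * (v1 - v0))
        t = (math.log(e) - math.log(e0)) / (math.log(e1) - math.log(e0))
        return float(math.exp(math.log(v0) + t * (math.log(v1) - math.log(v0))))


@dataclass(frozen=True)
class GasConditions:
    """Gas-cell conditions of a transmission measurement.

    The effective gas temperature is the geometric mean of the chamber
    temperature (thermocouple) and the capacitance-gauge operating
    temperature, which accounts for thermal transpiration between the
    cell and the gauge head.
    """

    pressure_mtorr: float
    chamber_temperature: float = 300.0  # K
    gauge_temperature: float = 300.0  # K
    cell_length: float = 0.05  # m, linear-spectrometer cell
    molar_mass: float = 79.0  # amu, pyridine

    def __post_init__(self) -> None:
        if self.pressure_mtorr < 0:
            raise ValueError("pressure must be >= 0")
        if self.chamber_temperature <= 0 or self.gauge_temperature <= 0:
            raise ValueError("temperatures must be > 0")
        if self.cell_length <= 0:
            raise ValueError("cell length must be > 0")

    @property
    def effective_temperature(self) -> float:
        """T = sqrt(T_C * T_m), K."""
        return math.sqrt(self.chamber_temperature * self.gauge_temperature)


@dataclass(frozen=True)
class CrossSectionSet:
    """The full per-channel cross-section set with interpolation."""

    grids: dict[Channel, ChannelGrid]
    elastic_variant: str = "recommended"
    _raw_rows: tuple[tuple[str, ...], ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CHANNEL_ORDER if c not in self.grids]
        if missing:
            raise CrossSectionError(f"missing channel grids: {missing}")

    @property
    def energy_range(self) -> tuple[float, float]:
        """Queryable energy range, set by the resolved elastic grid."""
        return self.grids[Channel.ELASTIC].support

    def _check_range(self, energy: float) -> None:
        lo, hi = self.energy_range
        if not (lo <= energy <= hi):
            raise CrossSectionError(
                f"energy {energy} eV outside the set's range [{lo}, {hi}] "
                "(no extrapolation)"
            )

    def sigma(self, channel: Channel | str, energy: float) -> float:
        """Integral cross section of ``channel`` at ``energy`` eV, 1e-20 m^2."""
        self._check_range(float(energy))
        return self.grids[Channel(channel)](float(energy))

    def total_sigma(self, energy: float, include_rotational: bool = True) -> float:
        """Sum of the open channels' cross sections at ``energy`` eV.

        The rotational channel can be excluded to match the convention
        of transmission-measured total cross sections, which do not
        resolve rotational excitation.
        """
        channels: Iterable[Channel] = (
            CHANNEL_ORDER
            if include_rotational
            else [c for c in CHANNEL_ORDER if c is not Channel.ROTATIONAL]
        )
        return float(sum(self.sigma(c, energy) for c in channels))

    def channel_probabilities(
        self, energy: float, include_rotational: bool = True
    ) -> dict[Channel, float]:
        """Relative collision probability of each channel at ``energy`` eV."""
        sigmas = {
            c: self.sigma(c, energy)
            for c in CHANNEL_ORDER
            if include_rotational or c is not Channel.ROTATIONAL
        }
        total = sum(sigmas.values())
        if total <= 0:
            raise CrossSectionError(f"zero total cross section at {energy} eV")
        return {c: s / total for c, s in sigmas.items()}

    def serialize_table(self) -> str:
        """Re-emit the packaged table body, cell for cell as printed."""
        header = "E_eV," + ",".join(c.value for c in _TABLE1_COLUMNS)
        lines = [header]
        for row in self._raw_rows:
            lines.append(",".join(row))
        return "\n".join(lines) + "\n"


_TABLE1_COLUMNS = (
    Channel.ELASTIC,
    Channel.ATTACHMENT,
    Channel.ELECTRONIC,
    Channel.VIBRATIONAL,
    Channel.IONIZATION,
    Channel.ROTATIONAL,
)


def _parse_cell(cell: str) -> tuple[float | None, bool]:
    cell = cell.strip()
    if not cell:
        return None, False
    if cell == BOUND_SENTINEL:
        return BOUND_VALUE, True
    return float(cell), False


def _read_csv(name: str) -> list[list[str]]:
    text = resources.files("pyrscat.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split(","))
    return rows


def load_builtin(variant: str = "recommended") -> CrossSectionSet:
    """Load the packaged cross-section tables.

    Parameters
    ----------
    variant
        ``"recommended"`` for the R-matrix/IAM-SCAR elastic channel or
        ``"smc"`` for the Schwinger-multichannel elastic channel below
        20 eV (joined to the recommended values above 20 eV).
    """
    if variant not in ("recommended", "smc"):
        raise CrossSectionError(f"unknown elastic variant {variant!r}")

    rows = _read_csv("table1_recommended.csv")
    header, body = rows[0], rows[1:]
    expected = ["E_eV"] + [c.value for c in _TABLE1_COLUMNS]
    if header != expected:
        raise CrossSectionError(f"table1 header mismatch: {header}")

    per_channel: dict[Channel, list[tuple[float, float, bool, str]]] = {
        c: [] for c in _TABLE1_COLUMNS
    }
    raw_rows = []
    for i, row in enumerate(body):
        if len(row) != len(expected):
            raise CrossSectionError(f"table1 row {i}: expected {len(expected)} cells")
        try:
            energy = float(row[0])
        except ValueError as err:
            raise CrossSectionError(f"table1 row {i}: bad energy {row[0]!r}") from err
        for channel, cell in zip(_TABLE1_COLUMNS, row[1:]):
            try:
                value, is_bound = _parse_cell(cell)
            except ValueError as err:
                raise CrossSectionError(
                    f"table1 row {i} ({channel}): bad cell {cell!r}"
                ) from err
            if value is not None:
                per_channel[channel].append((energy, value, is_bound, cell))
        raw_rows.append(tuple(row))

    def make_grid(
        channel: Channel,
        points: list[tuple[float, float, bool, str]],
        policy: str,
        source: str,
        windows: tuple[tuple[float, float], ...] = (),
    ) -> ChannelGrid:
        energies = [p[0] for p in points]
        return ChannelGrid(
            channel=channel,
            energies=np.array(energies),
            values=np.array([p[1] for p in points]),
            below_threshold_policy=policy,
            source=source,
            bound_flags=np.array([p[2] for p in points]),
            linear_windows=windows,
            raw_values=tuple(p[3] for p in points),
        )

    grids: dict[Channel, ChannelGrid] = {}
    for channel in _TABLE1_COLUMNS:
        policy = "zero" if channel in THRESHOLD_CHANNELS else "error"
        windows = ATTACHMENT_LINEAR_WINDOWS if channel is Channel.ATTACHMENT else ()
        grids[channel] = make_grid(
            channel,
            per_channel[channel],
            policy,
            source="recommended compilation (table 1)",
            windows=windows,
        )

    if variant == "smc":
        smc_rows = _read_csv("table2_smc.csv")
        if smc_rows[0] != ["E_eV", "elastic"]:
            raise CrossSectionError(f"table2 header mismatch: {smc_rows[0]}")
        points = []
        for i, row in enumerate(smc_rows[1:]):
            try:
                points.append((float(row[0]), float(row[1]), False, row[1]))
            except (ValueError, IndexError) as err:
                raise CrossSectionError(f"table2 row {i}: bad cells {row}") from err
        smc_max = max(p[0] for p in points)
        points += [p for p in per_channel[Channel.ELASTIC] if p[0] > smc_max]
        grids[Channel.ELASTIC] = make_grid(
            Channel.ELASTIC,
            points,
            policy="error",
            source="SMC (table 2) below 20 eV, recommended above",
            windows=SMC_LINEAR_WINDOWS,
        )

    return CrossSectionSet(
        grids=grids, elastic_variant=variant, _raw_rows=tuple(raw_rows)
    )


def pressure_to_density(gas: GasConditions) -> float:
    """Gas number density n = P / (k_B * T_eff), m^-3.

    The pressure is converted from mTorr to Pa and the effective
    temperature is sqrt(T_C * T_m).
    """
    pressure_pa = gas.pressure_mtorr * 1e-3 * constants.torr
    return pressure_pa / (constants.k * gas.effective_temperature)


def mean_free_path(sigma_total: float, number_density: float) -> float:
    """Mean free path 1/(n*sigma), m, for sigma in 1e-20 m^2.

    Zero density or zero cross section gives an infinite path (collisionless
    medium sentinel, ``math.inf``).
    """
    if sigma_total < 0 or number_density < 0:
        raise ValueError("sigma and density must be non-negative")
    if sigma_total == 0 or number_density == 0:
        return math.inf
    return 1.0 / (number_density * sigma_total * 1e-20)
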