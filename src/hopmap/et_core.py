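"""Semiclassical (Marcus) electron-transfer rate law and redox thermochemistry.

The rate of nonadiabatic electron transfer between a donor and acceptor
separated by a distance ``r`` is modelled as

    k = k0 * exp(-beta * (r - r0)) * exp(-(dG + lambda)^2 / (4 * lambda * kB * T))

where ``lambda`` is the reorganization energy (eV), ``beta`` the exponential
distance-decay constant of the squared electronic coupling (1/Angstrom),
``k0`` the activationless rate at van der Waals contact ``r0``, and
``dG`` the standard free-energy change of the transfer (eV).  For
one-electron transfers dG (eV) equals minus the potential difference (V)
between acceptor and donor couples, so potentials and energies share the
same numeric scale here.

This module also carries descriptive operations on the measured peak
potentials (pH 5-9, Cu(II/I) and Tyr109 couples in three azurin variants)
and observed Cu(I)-oxidation rate constants that drive the hopping
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "PhysicalConstants",
    "ETParameters",
    "RedoxCouple",
    "PotentialTable",
    "RateTable",
    "driving_force",
    "franck_condon_factor",
    "coupling_decay",
    "marcus_rate",
    "reverse_rate",
    "max_potential_spread",
    "fold_change_for_potential_shift",
    "percent_rate_difference",
    "round_to_nearest_ten_percent",
]

#: Boltzmann constant in eV/K (CODATA).
BOLTZMANN_EV_PER_K = 8.617333e-5


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants used throughout the package."""

    boltzmann_ev_per_k: float = BOLTZMANN_EV_PER_K


@dataclass(frozen=True)
class ETParameters:
    """Parameters of the semiclassical ET rate law.

    Defaults are the hopping-map conventions for Ru-azurin: lambda = 0.8 eV,
    beta = 1.1 / Angstrom, T = 298 K, with an activationless contact rate
    k0 = 1e13 / s at a van der Waals contact distance r0 = 3 Angstrom.
    """

    lambda_reorg: float = 0.8  # eV
    beta: float = 1.1  # 1/Angstrom
    temperature: float = 298.0  # K
    k0: float = 1.0e13  # 1/s, activationless rate at contact
    r0: float = 3.0  # Angstrom, contact distance

    def __post_init__(self) -> None:
        if self.lambda_reorg <= 0:
            raise ConfigError(f"lambda_reorg must be > 0, got {self.lambda_reorg}")
        if self.beta <= 0:
            raise ConfigError(f"beta must be > 0, got {self.beta}")
        if self.temperature <= 0:
            raise ConfigError(f"temperature must be > 0, got {self.temperature}")
        if self.k0 <= 0:
            raise ConfigError(f"k0 must be > 0, got {self.k0}")
        if self.r0 < 0:
            raise ConfigError(f"r0 must be >= 0, got {self.r0}")

    @property
    def kbt(self) -> float:
        """Thermal energy kB*T in eV."""
        return BOLTZMANN_EV_PER_K * self.temperature


@dataclass(frozen=True)
class RedoxCouple:
    """A one-electron redox couple with a formal potential in V vs NHE."""

    name: str
    potential: float  # V vs NHE
    n_electrons: int = 1

    def __post_init__(self) -> None:
        if self.n_electrons != 1:
            raise ConfigError(
                f"only one-electron couples are modelled; "
                f"{self.name} has n_electrons={self.n_electrons}"
            )


class PotentialTable:
    """pH-indexed formal potentials for a set of redox species.

    Wraps a DataFrame with columns ``ph``, ``species``, ``potential_v_nhe``.
    Keys (ph, species) must be unique; potentials must lie in 0-2 V
    (values outside that window indicate mV input) and pH in 0-14.
    """

    COLUMNS = ("ph", "species", "potential_v_nhe")

    def __init__(self, rows: pd.DataFrame | Iterable[tuple[float, str, float]]):
        if isinstance(rows, pd.DataFrame):
            df = rows.loc[:, list(self.COLUMNS)].copy()
        else:
            df = pd.DataFrame(list(rows), columns=list(self.COLUMNS))
        if df.empty:
            raise DataError("potential table has no rows")
        if df.duplicated(subset=["ph", "species"]).any():
            dup = df[df.duplicated(subset=["ph", "species"], keep=False)]
            raise DataError(f"duplicate (pH, species) keys:\n{dup}")
        if ((df["potential_v_nhe"] < 0) | (df["potential_v_nhe"] > 2)).any():
            raise DataError("potentials outside 0-2 V; check that units are V, not mV")
        if ((df["ph"] < 0) | (df["ph"] > 14)).any():
            raise DataError("pH values outside 0-14")
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def species(self) -> list[str]:
        return sorted(self._df["species"].unique())

    def ph_values(self) -> list[float]:
        return sorted(self._df["ph"].unique())

    def potential(self, ph: float, species: str) -> float:
        """Formal potential (V vs NHE) of `species` at `ph`."""
        sel = self._df[(self._df["ph"] == ph) & (self._df["species"] == species)]
        if sel.empty:
            raise DataError(f"no potential for species={species!r} at pH={ph}")
        return float(sel["potential_v_nhe"].iloc[0])

    def couple(self, ph: float, species: str) -> RedoxCouple:
        return RedoxCouple(name=species, potential=self.potential(ph, species))


class RateTable:
    """Observed rate constants (k_obs, s^-1) indexed by pH and variant."""

    COLUMNS = ("ph", "variant", "k_obs_s", "k_err_s")

    def __init__(self, rows: pd.DataFrame | Iterable[tuple[float, str, float, float]]):
        if isinstance(rows, pd.DataFrame):
            df = rows.loc[:, list(self.COLUMNS)].copy()
        else:
            df = pd.DataFrame(list(rows), columns=list(self.COLUMNS))
        if df.empty:
            raise DataError("rate table has no rows")
        if df.duplicated(subset=["ph", "variant"]).any():
            raise DataError("duplicate (pH, variant) keys in rate table")
        if (df["k_obs_s"] <= 0).any():
            raise DataError("k_obs must be > 0")
        if (df["k_err_s"] < 0).any():
            raise DataError("k_err must be >= 0")
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    def k_obs(self, ph: float, variant: str) -> float:
        sel = self._df[(self._df["ph"] == ph) & (self._df["variant"] == variant)]
        if sel.empty:
            raise DataError(f"no rate for variant={variant!r} at pH={ph}")
        return float(sel["k_obs_s"].iloc[0])


def driving_force(donor: RedoxCouple, acceptor: RedoxCouple) -> float:
    """Standard free-energy change (eV) for one-electron transfer.

    The electron moves from the reduced donor to the oxidized acceptor;
    dG = -(E_acceptor - E_donor).  Negative means exergonic.
    """
    if donor.n_electrons != 1 or acceptor.n_electrons != 1:
        raise ConfigError("driving_force is defined for one-electron couples only")
    return -(acceptor.potential - donor.potential)


def franck_condon_factor(dg, params: ETParameters):
    """Marcus activation factor exp(-(dG + lambda)^2 / (4 lambda kB T)).

    Dimensionless, in (0, 1]; equals 1 exactly at the activationless point
    dG = -lambda and is symmetric about it.  Accepts scalars or arrays.
    """
    dg = np.asarray(dg, dtype=float)
    lam = params.lambda_reorg
    out = np.exp(-((dg + lam) ** 2) / (4.0 * lam * params.kbt))
    return out if out.ndim else float(out)


def coupling_decay(r, params: ETParameters):
    """Squared-coupling distance attenuation exp(-beta (r - r0)).

    Unity at contact (r = r0); r inside contact is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < params.r0):
        raise ConfigError(f"distance r={r} inside contact distance r0={params.r0}")
    out = np.exp(-params.beta * (r - params.r0))
    return out if out.ndim else float(out)


def marcus_rate(dg, r, params: ETParameters):
    """Semiclassical ET rate k0 * coupling_decay(r) * franck_condon_factor(dG)."""
    out = params.k0 * coupling_decay(r, params) * franck_condon_factor(dg, params)
    return out if np.ndim(out) else float(out)


def reverse_rate(k_forward, dg, params: ETParameters):
    """Reverse rate by detailed balance: k_r = k_f * exp(dG / kB T).

    Identical to evaluating the Marcus rate at -dG with the same distance,
    since the Marcus form satisfies detailed balance automatically.
    """
    k_forward = np.asarray(k_forward, dtype=float)
    if np.any(k_forward <= 0):
        raise ConfigError("k_forward must be > 0")
    out = k_forward * np.exp(np.asarray(dg, dtype=float) / params.kbt)
    return out if out.ndim else float(out)


def max_potential_spread(table: PotentialTable, species_group: Sequence[str]) -> float:
    """Largest pairwise potential difference (V) within a species group.

    Scans every pH at which at least two of the named species are tabulated,
    takes the largest absolute pairwise difference at each, and returns the
    maximum over pH, rounded to 0.01 V (the reporting precision of the
    measured potentials).  A single-species group returns 0.
    """
    group = list(species_group)
    if not group:
        raise DataError("species_group is empty")
    df = table.frame
    df = df[df["species"].isin(group)]
    if df.empty:
        raise DataError(f"none of {group} present in table")
    if len(group) == 1:
        return 0.0
    best = None
    for _, sub in df.groupby("ph"):
        if len(sub) < 2:
            continue
        pots = sub["potential_v_nhe"].to_numpy()
        spread = float(pots.max() - pots.min())
        best = spread if best is None else max(best, spread)
    if best is None:
        raise DataError(f"species {group} share no pH value in the table")
    return round(best, 2)


def fold_change_for_potential_shift(
    delta_e: float, dg_baseline: float, params: ETParameters
) -> float:
    """Rate ratio from making the reaction `delta_e` V more exergonic.

    Distance and coupling cancel, so the ratio is purely the ratio of
    Franck-Condon factors at dG = dg_baseline - delta_e vs dg_baseline.
    In the normal region (dG > -lambda) a positive shift accelerates ET.
    """
    return float(
        franck_condon_factor(dg_baseline - delta_e, params)
        / franck_condon_factor(dg_baseline, params)
    )


def percent_rate_difference(
    table: RateTable, variant_a: str, variant_b: str, ph: float
) -> float:
    """Percent difference 100 * (k_a - k_b) / k_b between two variants at a pH."""
    k_a = table.k_obs(ph, variant_a)
    k_b = table.k_obs(ph, variant_b)
    return 100.0 * (k_a - k_b) / k_b


def round_to_nearest_ten_percent(percent: float) -> float:
    """Round a percent difference to the nearest 10% (reporting convenience)."""
    return 10.0 * round(percent / 10.0)
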