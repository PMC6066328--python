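"""Bell-Evans bond kinetics and the two-state extended freely jointed chain.

The Bell-Evans picture treats a protein-protein bond as a single sharp
energy barrier a distance ``x_beta`` (nm) along the pulling coordinate.
A tensile force F tilts the landscape and accelerates dissociation:

    k(F) = k0_off * exp(F * x_beta / kBT)

Under a constant loading rate r_f (pN/s) the rupture-force density is the
first-passage density of this escape process and its mode -- the most
probable rupture force -- grows with the logarithm of the loading rate:

    F* = (kBT / x_beta) * ln(r_f * x_beta / (k0_off * kBT))

The tether connecting the molecule to the cantilever is poly(ethylene
glycol), modelled as an extended freely jointed chain whose monomers
interconvert between a short helical (ttg) and a longer planar (ttt)
conformer under load, in series with a per-monomer backbone elasticity
[two-state FJC of the PEG single-molecule stretching literature].  The
conformer populations follow a force-dependent Boltzmann weight with free
energy gap dG(F) = dG0*kBT - F*(l_planar - l_helical), so the planar
(long) conformer is populated at high force.

All forces are tensile and positive (pN); lengths in nm; energies pN*nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .exceptions import DomainError, RangeError

__all__ = [
    "KBT_ROOM",
    "KineticParams",
    "TetherModel",
    "LoadingRate",
    "bell_off_rate",
    "most_probable_force",
    "rupture_force_pdf",
    "sample_rupture_force",
    "fjc_extension",
    "fjc_force",
]

#: thermal energy at 25 C in pN*nm
KBT_ROOM = 4.114

#: default force ceiling for tether inversion (pN)
F_MAX_DEFAULT = 500.0


@dataclass(frozen=True)
class KineticParams:
    """Bell-Evans bond parameters.

    Parameters
    ----------
    k0_off : float
        Intrinsic off-rate at zero force, 1/s. ``1/k0_off`` is the
        intrinsic bond lifetime.
    x_beta : float
        Width of the transition energy barrier along the pulling
        coordinate, nm.
    kBT : float
        Thermal energy, pN*nm (default: 25 C).
    """

    k0_off: float
    x_beta: float
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        if not (self.k0_off > 0 and self.x_beta > 0 and self.kBT > 0):
            raise DomainError(
                "KineticParams requires k0_off > 0, x_beta > 0, kBT > 0; got "
                f"k0_off={self.k0_off}, x_beta={self.x_beta}, kBT={self.kBT}"
            )

    @property
    def force_scale(self) -> float:
        """kBT/x_beta, the natural force scale of the barrier (pN)."""
        return self.kBT / self.x_beta


@dataclass(frozen=True)
class TetherModel:
    """Two-state extended freely jointed chain for a PEG tether.

    The defaults describe two MW-5000 PEG linkers in series (one on the
    tip, one on the substrate; the molecular complex bridges them), about
    113 monomers each, with conformer lengths, Kuhn length and segment
    elasticity at literature-typical values for PEG in aqueous buffer.
    They are configuration defaults, not measured quantities.

    ``monomer_stiffness`` is the per-monomer backbone elasticity in
    pN/nm*monomer: a chain of n monomers has spring constant
    ``monomer_stiffness / n`` (springs in series), i.e. 150 pN/nm for a
    single 113-mer PEG.
    """

    n_monomers: float = 226.0
    l_planar: float = 0.358
    l_helical: float = 0.28
    delta_g0: float = 3.0  # units of kBT, favouring the helical conformer at F=0
    kuhn_length: float = 0.7
    monomer_stiffness: float = 16950.0
    kBT: float = KBT_ROOM

    def __post_init__(self) -> None:
        ok = (
            self.l_planar > self.l_helical > 0
            and self.n_monomers >= 1
            and self.kuhn_length > 0
            and self.monomer_stiffness > 0
            and self.kBT > 0
        )
        if not ok:
            raise DomainError(f"invalid TetherModel: {self}")

    @property
    def contour_length(self) -> float:
        """Maximum (all-planar) extension Lc = n_monomers * l_planar, nm."""
        return self.n_monomers * self.l_planar

    def with_contour_length(self, lc: float) -> "TetherModel":
        """Return a copy rescaled to contour length ``lc`` (nm)."""
        if lc <= 0:
            raise DomainError(f"contour length must be positive, got {lc}")
        return replace(self, n_monomers=lc / self.l_planar)

    @classmethod
    def peg_5k_pair(cls) -> "TetherModel":
        """Two MW-5000 PEG tethers in series (the default geometry)."""
        return cls()


@dataclass(frozen=True)
class LoadingRate:
    """Rate of force application on the bond, pN/s."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise DomainError(f"loading rate must be positive, got {self.value}")


def _rate_value(r_f) -> float:
    r = r_f.value if isinstance(r_f, LoadingRate) else float(r_f)
    if not r > 0:
        raise DomainError(f"loading rate must be positive, got {r}")
    return r


def bell_off_rate(force, kin: KineticParams):
    """Force-dependent off-rate k(F) = k0_off * exp(F*x_beta/kBT), 1/s.

    ``force`` may be a scalar or array of tensile forces (pN, >= 0).
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise DomainError("bell_off_rate requires force >= 0")
    out = kin.k0_off * np.exp(f * kin.x_beta / kin.kBT)
    return float(out) if np.isscalar(force) else out


def most_probable_force(r_f, kin: KineticParams) -> float:
    """Most probable rupture force F* at loading rate ``r_f`` (pN).

    F* = (kBT/x_beta) * ln(r_f*x_beta/(k0_off*kBT)), clamped at 0 for
    loading rates below k0_off*kBT/x_beta: there the bond predominantly
    dissociates thermally before force builds and the distribution's mode
    sits at zero force.
    """
    r = _rate_value(r_f)
    arg = r * kin.x_beta / (kin.k0_off * kin.kBT)
    if arg <= 1.0:
        return 0.0
    return kin.force_scale * math.log(arg)


def rupture_force_pdf(force, r_f, kin: KineticParams):
    """First-passage rupture-force density p(F) at constant loading rate.

    p(F) = (k(F)/r_f) * exp[(k0_off*kBT/(x_beta*r_f)) * (1 - e^{F x_beta/kBT})]

    Normalized over [0, inf); unimodal with mode at the unclamped F*.
    """
    r = _rate_value(r_f)
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise DomainError("rupture_force_pdf requires force >= 0")
    c = kin.k0_off * kin.kBT / (kin.x_beta * r)  # = exp(-F*/force_scale)
    expo = np.exp(np.minimum(f * kin.x_beta / kin.kBT, 700.0))
    out = (kin.k0_off / r) * expo * np.exp(c * (1.0 - expo))
    return float(out) if np.isscalar(force) else out


def sample_rupture_force(r_f, kin: KineticParams, u):
    """Inverse-CDF sample of the rupture force from a uniform variate.

    ``u`` in (0, 1] is interpreted as the survival probability:
    F = (kBT/x_beta) * ln(1 - (x_beta*r_f/(k0_off*kBT)) * ln u) >= 0.
    Vectorized over ``u``.
    """
    r = _rate_value(r_f)
    uu = np.asarray(u, dtype=float)
    if np.any((uu <= 0) | (uu > 1)):
        raise DomainError("u must lie in (0, 1]")
    out = kin.force_scale * np.log1p(-(kin.x_beta * r / (kin.k0_off * kin.kBT)) * np.log(uu))
    return float(out) if np.isscalar(u) else out


def _langevin_factor(alpha: np.ndarray) -> np.ndarray:
    """coth(a) - 1/a, with the small-argument series for numerical safety."""
    small = alpha < 1e-4
    safe = np.where(small, 1.0, alpha)
    full = 1.0 / np.tanh(safe) - 1.0 / safe
    series = alpha / 3.0 - alpha**3 / 45.0
    return np.where(small, series, full)


def fjc_extension(force, tether: TetherModel):
    """Equilibrium extension (nm) of the two-state extended FJC at force F.

    x(F) = n * [l_p/(e^{dG/kBT}+1) + l_h/(e^{-dG/kBT}+1)] * (coth a - 1/a)
           + n * F / monomer_stiffness,
    dG(F) = dG0*kBT - F*(l_p - l_h),  a = F * L_K / kBT.

    The planar (long) conformer carries the inverted Boltzmann weight so
    that it is depopulated at zero force and dominates at high force.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise DomainError("fjc_extension requires force >= 0")
    x = _fjc_extension_signed(f, tether)
    return float(x) if np.isscalar(force) else x


def _fjc_extension_signed(f: np.ndarray, tether: TetherModel) -> np.ndarray:
    """Odd extension of fjc_extension to negative force (x(-F) = -x(F)).

    Used by orthogonal-distance fitting, where the adjusted abscissae may
    transiently dip below zero.
    """
    sign = np.sign(f)
    fa = np.abs(f)
    dg = np.clip(tether.delta_g0 - fa * (tether.l_planar - tether.l_helical) / tether.kBT, -60.0, 60.0)
    l_conf = tether.l_planar / (np.exp(dg) + 1.0) + tether.l_helical / (np.exp(-dg) + 1.0)
    alpha = fa * tether.kuhn_length / tether.kBT
    conf = tether.n_monomers * l_conf * _langevin_factor(alpha)
    elastic = tether.n_monomers * fa / tether.monomer_stiffness
    return sign * (conf + elastic)


def fjc_force(extension: float, tether: TetherModel, f_max: float = F_MAX_DEFAULT) -> float:
    """Force (pN) at a given tether extension, by monotone root-find.

    ``extension`` must satisfy 0 <= extension <= fjc_extension(f_max).
    """
    if extension < 0:
        raise DomainError(f"extension must be non-negative, got {extension}")
    x_max = fjc_extension(f_max, tether)
    if extension > x_max:
        raise RangeError(
            f"extension {extension:.6g} nm exceeds the tether extension "
            f"{x_max:.6g} nm at the configured F_max = {f_max:.6g} pN"
        )
    if extension == 0.0:
        return 0.0
    return brentq(
        lambda f: fjc_extension(f, tether) - extension,
        0.0,
        f_max,
        xtol=1e-14,
        rtol=8.9e-16,
        maxiter=200,
    )
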