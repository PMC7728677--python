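"""Closed-form null probabilities for chromosomal fusion types.

Under the null hypothesis that every chromosome is equally likely to fuse
with any non-homologous chromosome, the chance that a random fusion joins a
sex chromosome and an autosome (an SA-fusion) is a simple function of the
karyotype: the diploid autosome count, the number and kind of sex
chromosomes, and the share of fusions arising in each sex.  This module
implements those closed forms for male-heterogametic (XO, XY, multi-XY),
female-heterogametic (ZO, ZW, multi-ZW) and UV (haploid-phase) systems.

Notation (male-heterogametic reading):

* ``Da`` -- diploid autosome count (autosomes come in pairs, so even);
* ``Xs`` -- number of X chromosomes in males; females carry ``2*Xs``;
* ``Y``  -- number of Y chromosomes in males;
* ``Ds = Da + Xs + Y`` -- male diploid number;
* ``Dd = Da + 2*Xs`` -- female diploid number;
* ``mu_d`` -- proportion of fusions originating in females (the dam).

The three fusion classes partition all possibilities, so

    P(SA) = 1 - P(AA) - P(SS).

P(SS) is ``mu_d * 4 Xs (Xs-1) / (Dd (Dd-2))`` for the female germ line plus
``(1-mu_d) * [Xs(Xs-1)/(Ds(Ds+Xs-1)) + Y(Y-1)/(Ds(Ds+Y-1))]`` for the male;
P(AA) is ``mu_d * Da(Da-2)/(Dd(Dd-2)) + (1-mu_d) * Da(Da-2)/(Ds(Ds-2))``.
Homologous fusions (X with Y, or a chromosome with its homolog) are excluded
throughout: they would produce unbalanced gametes.

A ZW system is the mirror image under exchange of the sexes, so the same
code serves with ``Xs`` read as the Z count in females, ``Y`` as the W
count, and ``mu_d`` as the proportion of fusions arising in males.  UV
systems (separate haploid sexes, as in bryophytes) have no diploid
homogametic individuals; they are handled by forcing ``mu_d = 0`` and
setting both sex-chromosome slots to the shared U/V count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = [
    "Karyotype",
    "SexBias",
    "FusionProbabilities",
    "KaryotypeError",
    "ConsistencyError",
    "p_ss",
    "p_aa",
    "p_sa",
    "probabilities",
    "probabilities_zw",
    "probabilities_uv",
    "sweep",
]

#: Relative rounding slack absorbed silently when clamping probabilities
#: into [0, 1].  Anything larger indicates a genuine inconsistency.
_CLAMP_RTOL = 4.0 * math.ulp(1.0)


class KaryotypeError(ValueError):
    """A karyotype or sex-bias parameter violates its constraints."""


class ConsistencyError(ArithmeticError):
    """A computed probability fell outside [0, 1] by more than rounding."""


@dataclass(frozen=True)
class Karyotype:
    """A sex-chromosome-system parameterization of a karyotype.

    For ``system="ZW-like"`` the slots are read with the sexes exchanged
    (``xs`` holds the Z count in females, ``y`` the W count); for
    ``system="UV"`` both slots hold the shared U/V count.
    """

    da: int
    xs: int
    y: int
    system: str = "XY-like"

    _SYSTEMS = ("XY-like", "ZW-like", "UV")

    def __post_init__(self) -> None:
        for name in ("da", "xs", "y"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise KaryotypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise KaryotypeError(f"{name} must be >= 0, got {v}")
        if self.da % 2 != 0:
            raise KaryotypeError(
                f"diploid autosome count must be even (autosomes come in "
                f"homologous pairs), got Da={self.da}"
            )
        if self.system not in self._SYSTEMS:
            raise KaryotypeError(
                f"unknown sex-chromosome system {self.system!r}; "
                f"expected one of {self._SYSTEMS}"
            )

    @property
    def ds(self) -> int:
        """Heterogametic-sex diploid number, Da + Xs + Y."""
        return self.da + self.xs + self.y

    @property
    def dd(self) -> int:
        """Homogametic-sex diploid number, Da + 2*Xs."""
        return self.da + 2 * self.xs

    def validate_for_probabilities(self) -> None:
        """Check the denominators of the fusion-probability formulas."""
        if self.ds <= 2:
            raise KaryotypeError(
                f"heterogametic diploid number Ds={self.ds} must exceed 2 "
                f"(denominator Ds*(Ds-2) must be positive)"
            )
        if self.dd <= 2:
            raise KaryotypeError(
                f"homogametic diploid number Dd={self.dd} must exceed 2 "
                f"(denominator Dd*(Dd-2) must be positive)"
            )


@dataclass(frozen=True)
class SexBias:
    """Proportion of fusions originating in the homogametic sex.

    ``mu_d`` is the dam (female) share for XY-like systems; for ZW-like
    systems the same slot carries the sire share.  Defaults to equal
    contributions from the two sexes.
    """

    mu_d: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_d <= 1.0):
            raise KaryotypeError(f"mu_d must lie in [0, 1], got {self.mu_d}")


@dataclass(frozen=True)
class FusionProbabilities:
    """The probability triple (P(SA), P(AA), P(SS)); sums to one."""

    p_sa: float
    p_aa: float
    p_ss: float

    def __iter__(self):
        yield from (self.p_sa, self.p_aa, self.p_ss)

    def as_dict(self) -> dict[str, float]:
        return {"p_sa": self.p_sa, "p_aa": self.p_aa, "p_ss": self.p_ss}


def _clamp_unit(x: float, what: str) -> float:
    """Clamp ``x`` into [0, 1], absorbing only rounding-level excursions."""
    if x < 0.0:
        if x < -_CLAMP_RTOL:
            raise ConsistencyError(f"{what} = {x} is negative beyond rounding")
        return 0.0
    if x > 1.0:
        if x > 1.0 + _CLAMP_RTOL:
            raise ConsistencyError(f"{what} = {x} exceeds 1 beyond rounding")
        return 1.0
    return x


def _coerce_bias(b: SexBias | float | None) -> SexBias:
    if b is None:
        return SexBias()
    if isinstance(b, SexBias):
        return b
    return SexBias(float(b))


def p_ss(k: Karyotype, b: SexBias | float | None = None) -> float:
    """Probability that a random fusion joins two sex chromosomes."""
    b = _coerce_bias(b)
    k.validate_for_probabilities()
    mu = b.mu_d
    xs, y, ds, dd = k.xs, k.y, k.ds, k.dd
    female = 4.0 * xs * (xs - 1) / (dd * (dd - 2))
    male = 0.0
    if xs > 1:
        male += xs * (xs - 1) / (ds * (ds + xs - 1))
    if y > 1:
        male += y * (y - 1) / (ds * (ds + y - 1))
    return _clamp_unit(mu * female + (1.0 - mu) * male, "P(SS)")


def p_aa(k: Karyotype, b: SexBias | float | None = None) -> float:
    """Probability that a random fusion joins two autosomes."""
    b = _coerce_bias(b)
    k.validate_for_probabilities()
    mu = b.mu_d
    da, ds, dd = k.da, k.ds, k.dd
    if da <= 2:
        return 0.0
    female = da * (da - 2) / (dd * (dd - 2))
    male = da * (da - 2) / (ds * (ds - 2))
    return _clamp_unit(mu * female + (1.0 - mu) * male, "P(AA)")


def p_sa(k: Karyotype, b: SexBias | float | None = None) -> float:
    """Probability that a random fusion joins a sex chromosome and an autosome.

    Computed as the complement ``1 - P(AA) - P(SS)``.
    """
    b = _coerce_bias(b)
    return _clamp_unit(1.0 - p_aa(k, b) - p_ss(k, b), "P(SA)")


def probabilities(k: Karyotype, b: SexBias | float | None = None) -> FusionProbabilities:
    """The full fusion-type triple; components sum to one by construction."""
    b = _coerce_bias(b)
    aa = p_aa(k, b)
    ss = p_ss(k, b)
    sa = _clamp_unit(1.0 - aa - ss, "P(SA)")
    return FusionProbabilities(p_sa=sa, p_aa=aa, p_ss=ss)


def probabilities_zw(k: Karyotype, b: SexBias | float | None = None) -> FusionProbabilities:
    """Fusion probabilities for a ZW-like system.

    The ZW case is the XY case with the sexes exchanged, so this is a pure
    relabelling: ``k.xs`` is the Z count in females, ``k.y`` the W count,
    and the bias slot carries the sire share mu_s.
    """
    if k.system != "ZW-like":
        raise KaryotypeError(
            f"probabilities_zw expects system='ZW-like', got {k.system!r}"
        )
    mirror = Karyotype(da=k.da, xs=k.xs, y=k.y, system="XY-like")
    return probabilities(mirror, b)


def probabilities_uv(da: int, v: int) -> FusionProbabilities:
    """Fusion probabilities for a UV system with equal U and V counts.

    There are no homogametic diploid individuals, so the homogametic-sex
    term is dropped (``mu_d = 0``) and both sex-chromosome slots carry the
    shared count ``v``.  Unequal U and V counts are not supported.
    """
    k = Karyotype(da=da, xs=v, y=v, system="UV")
    return probabilities(Karyotype(da=da, xs=v, y=v, system="XY-like"), SexBias(0.0))


def unequal_uv_unsupported(u: int, v: int) -> None:
    """Raise for unequal U/V counts, which the model does not cover."""
    if u != v:
        raise NotImplementedError(
            f"UV systems are only supported with equal U and V counts; "
            f"got U={u}, V={v}"
        )


def sweep(
    systems: Iterable[tuple[str, Karyotype]] | dict[str, Karyotype],
    da_range: Iterable[int],
    b: SexBias | float | None = None,
) -> pd.DataFrame:
    """Evaluate P(SA) over a grid of diploid autosome counts.

    ``systems`` maps a label to a template karyotype whose sex-chromosome
    slots are held fixed while ``da`` runs over ``da_range`` (even counts).
    Returns a tidy table with columns (system, da, p_sa, p_aa, p_ss).
    """
    b = _coerce_bias(b)
    if isinstance(systems, dict):
        items = list(systems.items())
    else:
        items = list(systems)
    rows = []
    for label, template in items:
        for da in da_range:
            k = Karyotype(da=int(da), xs=template.xs, y=template.y,
                          system=template.system)
            if k.system == "ZW-like":
                triple = probabilities_zw(k, b)
            else:
                triple = probabilities(k, b)
            rows.append(
                {"system": label, "da": int(da), "p_sa": triple.p_sa,
                 "p_aa": triple.p_aa, "p_ss": triple.p_ss}
            )
    return pd.DataFrame(rows, columns=["system", "da", "p_sa", "p_aa", "p_ss"])
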