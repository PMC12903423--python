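"""Domain types and stoichiometric arithmetic for well-plate RDRP planning.

The central object is a :class:`RecipeSpec`: one polymerization condition
expressed the way bench chemists write it — reagent molar ratios relative to
the initiator (initiator = 1), a target degree of polymerization (DP, the
monomer:initiator ratio), a final monomer concentration [M]_f, and a reaction
volume. Everything downstream (dilution selection, transfer volumes, screen
enumeration, classifier features) is derived from these ratios.

Unit conventions, applied throughout the package: concentrations are stored
in mM, volumes in uL, molar masses in g/mol. [M]_f is accepted in mol/L at
the I/O boundary (sheets, constructors) because that is how it is quoted in
the lab, and converted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "ValidationError",
    "Reagent",
    "MonomerComposition",
    "RecipeSpec",
    "ROLES",
    "load_reagent_table",
    "target_concentrations",
    "mean_monomer_mass",
    "theoretical_mn",
]

#: Recognized reagent roles. "cta" covers the chain-transfer agent slot used
#: by PET-RAFT planning; the remaining six are the photo-ATRP vocabulary.
ROLES = frozenset(
    {"monomer", "initiator", "metal", "ligand", "photocatalyst", "solvent", "cta"}
)

_FRACTION_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a domain object or operation input violates an invariant."""


@dataclass(frozen=True)
class Reagent:
    """A named chemical with a role and (except possibly solvents) a molar mass."""

    name: str
    role: str
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("reagent name must be non-empty")
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r} for reagent {self.name!r}; "
                f"expected one of {sorted(ROLES)}"
            )
        if self.molar_mass is None:
            if self.role != "solvent":
                raise ValidationError(
                    f"reagent {self.name!r} ({self.role}) requires a molar mass"
                )
        elif not self.molar_mass > 0:
            raise ValidationError(
                f"molar mass of {self.name!r} must be positive, got {self.molar_mass}"
            )


@dataclass(frozen=True)
class MonomerComposition:
    """Monomer blend as (reagent, mole fraction) entries; fractions sum to 1.

    A statistical copolymer row with unspecified fractions defaults to an
    equimolar blend (see :meth:`equimolar`).
    """

    entries: tuple[tuple[Reagent, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("monomer composition must contain at least one monomer")
        total = 0.0
        for reagent, fraction in self.entries:
            if reagent.role != "monomer":
                raise ValidationError(f"{reagent.name!r} is not a monomer")
            if not (0.0 < fraction <= 1.0):
                raise ValidationError(
                    f"mole fraction of {reagent.name!r} must be in (0, 1], got {fraction}"
                )
            total += fraction
        if abs(total - 1.0) > _FRACTION_TOL:
            raise ValidationError(f"mole fractions must sum to 1, got {total!r}")

    @classmethod
    def equimolar(cls, monomers: list[Reagent] | tuple[Reagent, ...]) -> "MonomerComposition":
        n = len(monomers)
        if n == 0:
            raise ValidationError("monomer composition must contain at least one monomer")
        return cls(tuple((m, 1.0 / n) for m in monomers))

    @property
    def monomer_names(self) -> tuple[str, ...]:
        return tuple(r.name for r, _ in self.entries)


@dataclass(frozen=True)
class RecipeSpec:
    """One polymerization condition.

    ``ratios`` maps reagent name -> molar ratio relative to the initiator
    (which is 1 by definition); the monomer does not appear in ``ratios``
    (its ratio is ``dp``). ``m_final`` is [M]_f in mol/L; ``v_total`` in uL.
    ``extras`` carries unrecognized sheet columns through read/write untouched.
    """

    composition: MonomerComposition
    initiator: Reagent
    ratios: Mapping[str, float]
    dp: float
    m_final: float
    v_total: float = 200.0
    label: str = "recipe"
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dp < 0:
            raise ValidationError(f"dp must be non-negative, got {self.dp}")
        if not self.m_final > 0:
            raise ValidationError(f"m_final must be positive, got {self.m_final}")
        if not self.v_total > 0:
            raise ValidationError(f"v_total must be positive, got {self.v_total}")
        if self.initiator.role not in {"initiator", "cta"}:
            raise ValidationError(f"{self.initiator.name!r} is not an initiator")
        for name, ratio in self.ratios.items():
            if ratio < 0:
                raise ValidationError(
                    f"ratio for {name!r} in recipe {self.label!r} is negative ({ratio})"
                )
        init_ratio = self.ratios.get(self.initiator.name)
        if init_ratio is not None and init_ratio != 1:
            raise ValidationError(
                f"initiator ratio must be 1 in recipe {self.label!r}, got {init_ratio}"
            )

    @property
    def c_initiator_mM(self) -> float:
        """Initiator concentration in mM: [M]_f / DP (with [M]_f in mM)."""
        if self.dp <= 0:
            raise ValidationError(f"dp must be positive to set concentrations, got {self.dp}")
        return self.m_final * 1000.0 / self.dp


def load_reagent_table(path: str | None = None) -> dict[str, Reagent]:
    """Load the packaged reagent table (or a user CSV with the same columns).

    Columns: ``name``, ``role``, ``molar_mass``. The packaged table holds the
    common photo-ATRP reagents (monomers HEA/MA/HPA/MMA, initiators MBiB/BPN,
    CuBr2, ligands Me6TREN/PMDETA, photocatalysts ZnTPP/EosinY, DMSO).
    """
    if path is None:
        with resources.files("plateplan.data").joinpath("reagents.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    table: dict[str, Reagent] = {}
    for _, row in frame.iterrows():
        mass = row.get("molar_mass")
        mass = None if pd.isna(mass) else float(mass)
        reagent = Reagent(str(row["name"]), str(row["role"]), mass)
        if reagent.name in table:
            raise ValidationError(f"duplicate reagent {reagent.name!r} in table")
        table[reagent.name] = reagent
    return table


def target_concentrations(recipe: RecipeSpec) -> dict[str, float]:
    """Per-reagent target concentrations (mM) in the final reaction well.

    The initiator sits at [M]_f / DP; every ratio-listed reagent scales from
    it; each monomer contributes its mole fraction of [M]_f.
    """
    c_init = recipe.c_initiator_mM
    out: dict[str, float] = {}
    for reagent, fraction in recipe.composition.entries:
        out[reagent.name] = recipe.m_final * 1000.0 * fraction
    out[recipe.initiator.name] = c_init
    for name, ratio in recipe.ratios.items():
        if name == recipe.initiator.name:
            continue
        out[name] = ratio * c_init
    return out


def mean_monomer_mass(composition: MonomerComposition) -> float:
    """Mole-fraction-weighted mean monomer molar mass (g/mol)."""
    total = 0.0
    for reagent, fraction in composition.entries:
        if reagent.molar_mass is None:
            raise ValidationError(f"monomer {reagent.name!r} has no molar mass")
        total += fraction * reagent.molar_mass
    return total


def theoretical_mn(recipe: RecipeSpec, conversion: float = 1.0) -> float:
    """Theoretical number-average molecular weight, in kDa.

    Mn,th = conversion x DP x mean monomer mass + initiator mass. The default
    ``conversion=1`` is the full-conversion convention under which polymers
    such as pHEA(200) from MBiB come out at 23.4 kDa.
    """
    if not 0.0 <= conversion <= 1.0:
        raise ValidationError(f"conversion must lie in [0, 1], got {conversion}")
    if recipe.initiator.molar_mass is None:
        raise ValidationError(f"initiator {recipe.initiator.name!r} has no molar mass")
    mean_mass = mean_monomer_mass(recipe.composition)
    return (conversion * recipe.dp * mean_mass + recipe.initiator.molar_mass) / 1000.0
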