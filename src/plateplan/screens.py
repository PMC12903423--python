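"""Screen generation and chain-extension arithmetic.

Two screen shapes cover the common optimization workflows:

* full factorial — every combination of ratio levels crossed with every
  ligand and initiator identity (e.g. 16 ratio tuples x 2 ligands x 2
  initiators = 64 conditions for a methacrylate ligand/initiator comparison);
* one-factor-at-a-time (OFAT) — one reagent's ratio swept per series while
  the others sit at the base recipe's values.

Chain extension follows the withdraw-then-add model: an equal volume is
removed from the reaction well and replaced with concentrated monomer stock,
keeping the total volume constant, so the transfer volume that reaches a
target second-block monomer concentration is v = m_target * v_well / c_stock.
"""

from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

from .chem import (
    Reagent,
    RecipeSpec,
    ValidationError,
    load_reagent_table,
)

__all__ = [
    "enumerate_factorial",
    "enumerate_ofat",
    "chain_extension_volume",
    "extension_block_ratio",
]

#: Levels may be given per-reagent (cross product) or as explicit ratio tuples.
Levels = Mapping[str, Sequence[float]] | Sequence[Mapping[str, float]]


def _replace_ratio_key(ratios: dict[str, float], old: str, new: str) -> dict[str, float]:
    return {new if k == old else k: v for k, v in ratios.items()}


def enumerate_factorial(
    base: RecipeSpec,
    levels: Levels,
    ligands: Sequence[Reagent] = (),
    initiators: Sequence[Reagent] = (),
    reagent_table: dict[str, Reagent] | None = None,
) -> list[RecipeSpec]:
    """Cross ratio levels with ligand and initiator identities.

    ``levels`` is either {reagent name: [ratios...]} (expanded as a cross
    product, in input order) or an explicit list of {reagent name: ratio}
    tuples. Output count = (number of ratio tuples) x len(ligands) x
    len(initiators); ordering is ligand-major, initiator-next, ratio tuples
    innermost; labels are unique.
    """
    if isinstance(levels, Mapping):
        if not levels or any(len(v) == 0 for v in levels.values()):
            raise ValidationError("every level list must be non-empty")
        names = list(levels)
        tuples: list[dict[str, float]] = [
            dict(zip(names, combo)) for combo in product(*(levels[n] for n in names))
        ]
    else:
        tuples = [dict(t) for t in levels]
        if not tuples:
            raise ValidationError("at least one ratio tuple is required")
    table = reagent_table if reagent_table is not None else load_reagent_table()
    ligands = list(ligands) or [None]  # type: ignore[list-item]
    initiators = list(initiators) or [base.initiator]

    # identify which base ratio key is the ligand slot (for identity swaps)
    base_ligand = next(
        (n for n in base.ratios if n in table and table[n].role == "ligand"), None
    )
    out: list[RecipeSpec] = []
    idx = 1
    for ligand in ligands:
        for initiator in initiators:
            for tup in tuples:
                ratios = dict(base.ratios)
                ratios.pop(base.initiator.name, None)
                lig_name = base_ligand
                if ligand is not None:
                    if base_ligand is None:
                        raise ValidationError(
                            "base recipe has no ligand ratio to vary across ligands"
                        )
                    if ligand.name != base_ligand:
                        ratios = _replace_ratio_key(ratios, base_ligand, ligand.name)
                    lig_name = ligand.name
                for name, value in tup.items():
                    # level keys use the base recipe's reagent names; the ligand
                    # key follows the identity swap
                    key = lig_name if (name == base_ligand and lig_name) else name
                    ratios[key] = value
                suffix = f"_{ligand.name}" if ligand is not None else ""
                suffix += f"_{initiator.name}" if len(initiators) > 1 or initiators[0] is not base.initiator else ""
                label = f"{base.label}_{idx:03d}{suffix}"
                out.append(
                    RecipeSpec(
                        composition=base.composition,
                        initiator=initiator,
                        ratios=ratios,
                        dp=base.dp,
                        m_final=base.m_final,
                        v_total=base.v_total,
                        label=label,
                    )
                )
                idx += 1
    return out


def enumerate_ofat(
    base: RecipeSpec, sweeps: Mapping[str, Sequence[float]]
) -> list[RecipeSpec]:
    """One-factor-at-a-time sweeps around a base recipe.

    The base recipe appears once; each swept level equal to the base value
    (and any duplicate level) is deduplicated, so with base levels included
    in the sweeps the count is 1 + sum(len(levels) - 1).
    """
    out = [base]
    for name, levels in sweeps.items():
        if name not in base.ratios:
            raise ValidationError(f"swept reagent {name!r} is not in the base recipe")
        seen: set[float] = {base.ratios[name]}
        for level in levels:
            if level in seen:
                continue
            seen.add(level)
            ratios = dict(base.ratios)
            ratios[name] = level
            out.append(
                RecipeSpec(
                    composition=base.composition,
                    initiator=base.initiator,
                    ratios=ratios,
                    dp=base.dp,
                    m_final=base.m_final,
                    v_total=base.v_total,
                    label=f"{base.label}_{name}_{level:g}",
                )
            )
    return out


def chain_extension_volume(v_well: float, c_stock: float, m_target: float) -> float:
    """Monomer-stock volume (uL) for an equal-volume withdraw-then-add extension.

    ``c_stock`` and ``m_target`` in mol/L; ``v_well`` in uL. Returns the
    unrounded volume (display convention is 0.1 uL). m_target = 0 gives 0.
    """
    if m_target < 0:
        raise ValidationError(f"target concentration must be non-negative, got {m_target}")
    if m_target == 0:
        return 0.0
    if c_stock < m_target:
        raise ValidationError(
            f"stock at {c_stock:g} M cannot reach target {m_target:g} M"
        )
    return m_target * v_well / c_stock


def extension_block_ratio(
    c_initiator_mM: float, v_well: float, v: float, c_stock: float
) -> float:
    """Second-block monomer:initiator ratio after a withdraw-then-add extension.

    Added monomer moles (c_stock [M] x v) over initiator moles remaining after
    the withdrawal (c_initiator x (v_well - v)). Unreacted first-block monomer
    is not counted (not quantifiable without conversion data).
    """
    if v == 0:
        return 0.0
    if not 0 < v < v_well:
        raise ValidationError(f"transfer volume must lie in (0, v_well), got {v}")
    if not c_initiator_mM > 0:
        raise ValidationError("initiator concentration must be positive")
    return (c_stock * v) / (c_initiator_mM / 1000.0 * (v_well - v))
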