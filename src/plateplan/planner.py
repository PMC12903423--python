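"""Dilution selection and worklist generation for well-plate polymerizations.

Given a batch of recipes and the stocks on deck, the planner has to decide,
per reagent, which concentrations to have available so that every recipe can
be pipetted within the liquid handler's physical limits (a smallest reliable
transfer ``v_min`` and a cap on how much of the well any single non-monomer
reagent may occupy), while preparing as few extra dilutions as possible.
Candidate dilution concentrations are user-listed per reagent (they need not
form a serial-dilution chain); the stock itself is always free. The cover is
found by exact enumeration of candidate subsets in increasing cardinality,
which guarantees the minimal-dilution objective for the short candidate lists
used in practice.

Volumes are quantized to a configurable quantum (default 0.01 uL) and each
well is topped to exactly ``v_total`` with solvent, which absorbs the rounding
residue — so volume conservation holds exactly, by construction. The planner
is fully deterministic: identical inputs yield byte-identical worklists.

Infeasible recipes (a target concentration no available source can deliver
within bounds, or non-solvent volumes exceeding the well) are reported in the
worklist diagnostics and skipped; the rest of the batch proceeds, mirroring
screening practice where not every requested ratio combination is makeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .chem import RecipeSpec, ValidationError, target_concentrations

__all__ = [
    "InfeasibleSourceError",
    "PlanningError",
    "Stock",
    "StockSet",
    "Constraints",
    "PlateGeometry",
    "Infeasibility",
    "ReagentPlan",
    "DilutionPlan",
    "TransferStep",
    "Worklist",
    "required_volume",
    "feasible_sources",
    "select_dilutions",
    "dilution_prep_steps",
    "plan_batch",
]

logger = logging.getLogger("plateplan")

WORKLIST_COLUMNS = [
    "step_type",
    "source_name",
    "source_conc_mM",
    "source_position",
    "dest",
    "volume_uL",
    "order_index",
]


class InfeasibleSourceError(ValidationError):
    """A source concentration cannot deliver the requested target."""


class PlanningError(ValidationError):
    """The batch as specified cannot be planned."""


@dataclass(frozen=True)
class Stock:
    """One reagent stock: concentration (mM), permissible dilutions, deck position."""

    name: str
    conc: float
    allowed_dilutions: tuple[float, ...] = ()
    position: str = ""

    def __post_init__(self) -> None:
        if not self.conc > 0:
            raise ValidationError(f"stock concentration of {self.name!r} must be > 0")
        for d in self.allowed_dilutions:
            if not 0 < d < self.conc:
                raise ValidationError(
                    f"allowed dilution {d} mM of {self.name!r} must lie in (0, stock)"
                )
        # normalize: unique, sorted descending
        object.__setattr__(
            self, "allowed_dilutions", tuple(sorted(set(self.allowed_dilutions), reverse=True))
        )

    @property
    def candidates(self) -> tuple[float, ...]:
        """Stock plus allowed dilutions, descending."""
        return (self.conc, *self.allowed_dilutions)


@dataclass
class StockSet:
    """The stocks available for a batch, plus the solvent source."""

    stocks: dict[str, Stock]
    solvent_name: str = "DMSO"
    solvent_position: str = "solvent"

    def __getitem__(self, name: str) -> Stock:
        return self.stocks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.stocks


@dataclass(frozen=True)
class Constraints:
    """Liquid-handler limits.

    v_min: smallest pipettable transfer (uL). v_max_frac: largest fraction of
    v_total a single non-monomer, non-solvent transfer may occupy. quantum:
    volume rounding quantum (uL).
    """

    v_min: float = 1.0
    v_max_frac: float = 0.25
    quantum: float = 0.01

    def __post_init__(self) -> None:
        if not self.v_min > 0:
            raise ValidationError("v_min must be positive")
        if not 0 < self.v_max_frac <= 1:
            raise ValidationError("v_max_frac must lie in (0, 1]")
        if not self.quantum > 0:
            raise ValidationError("rounding quantum must be positive")

    def quantize(self, volume: float) -> float:
        """Round a volume to the quantum (ties to even, like the hardware driver)."""
        return round(round(volume / self.quantum) * self.quantum, 10)


@dataclass(frozen=True)
class PlateGeometry:
    rows: int = 8
    cols: int = 12

    @property
    def capacity(self) -> int:
        return self.rows * self.cols

    def well_ids(self) -> list[str]:
        """Row-major A1-style ids: A1..A12, B1.."""
        if self.rows > 26:
            raise ValidationError("plates beyond 26 rows are not supported")
        return [
            f"{chr(ord('A') + r)}{c + 1}" for r in range(self.rows) for c in range(self.cols)
        ]


@dataclass(frozen=True)
class Infeasibility:
    label: str
    reagent: str
    target_mM: float
    reason: str


@dataclass
class ReagentPlan:
    prepared: tuple[float, ...]  # descending, includes stock when used
    assignment: dict[str, float]  # recipe label -> chosen source conc


@dataclass
class DilutionPlan:
    reagents: dict[str, ReagentPlan]
    infeasible: list[Infeasibility] = field(default_factory=list)

    @property
    def n_dilutions(self) -> int:
        """Number of additional (non-stock) dilutions to prepare, batch-wide."""
        return sum(len(rp.prepared) for rp in self.reagents.values())

    @property
    def infeasible_labels(self) -> set[str]:
        return {inf.label for inf in self.infeasible}


@dataclass(frozen=True)
class TransferStep:
    step_type: str  # dilution_prep | well_transfer | solvent_makeup
    source_name: str
    source_conc_mM: float
    source_position: str
    dest: str
    volume_uL: float
    order_index: int


@dataclass
class Worklist:
    dilution_prep_steps: list[TransferStep]
    well_steps: list[TransferStep]
    plate: dict[str, str]  # well id -> recipe label
    diagnostics: list[Infeasibility]
    v_total: dict[str, float] = field(default_factory=dict)  # well -> target volume

    @property
    def steps(self) -> list[TransferStep]:
        return [*self.dilution_prep_steps, *self.well_steps]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step_type": s.step_type,
                "source_name": s.source_name,
                "source_conc_mM": s.source_conc_mM,
                "source_position": s.source_position,
                "dest": s.dest,
                "volume_uL": s.volume_uL,
                "order_index": s.order_index,
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows, columns=WORKLIST_COLUMNS)

    def well_volumes(self) -> dict[str, float]:
        totals: dict[str, float] = {w: 0.0 for w in self.plate}
        for s in self.well_steps:
            totals[s.dest] = round(totals[s.dest] + s.volume_uL, 10)
        return totals

    def summary(self) -> str:
        lines = [
            f"planned wells: {len(self.plate)}",
            f"dilution preparations: {len(self.dilution_prep_steps)} steps",
            f"well transfer steps: {len(self.well_steps)}",
        ]
        if self.diagnostics:
            lines.append(f"infeasible recipes: {len(self.infeasible_labels())}")
            for inf in self.diagnostics:
                lines.append(
                    f"  - {inf.label}: {inf.reagent} at {inf.target_mM:g} mM ({inf.reason})"
                )
        else:
            lines.append("infeasible recipes: none")
        return "\n".join(lines)

    def infeasible_labels(self) -> set[str]:
        return {inf.label for inf in self.diagnostics}


def required_volume(c_target: float, c_source: float, v_total: float) -> float:
    """Unrounded transfer volume (uL) to reach c_target in v_total from c_source."""
    if not c_target > 0:
        raise ValidationError(f"target concentration must be positive, got {c_target}")
    if c_source < c_target:
        raise InfeasibleSourceError(
            f"source at {c_source:g} mM cannot reach target {c_target:g} mM"
        )
    return c_target * v_total / c_source


def feasible_sources(
    c_target: float,
    stock: Stock,
    v_total: float,
    constraints: Constraints,
    exempt_vmax: bool = False,
) -> list[float]:
    """Candidate source concentrations able to deliver c_target within bounds.

    A candidate is feasible when its required volume lies in
    [v_min, v_max_frac x v_total] (upper bound waived for monomers).
    Returned sorted descending (higher concentration = smaller transfer).
    """
    v_max = v_total if exempt_vmax else constraints.v_max_frac * v_total
    out = []
    for c in stock.candidates:
        if c < c_target:
            continue
        v = required_volume(c_target, c, v_total)
        if constraints.v_min <= v <= v_max:
            out.append(c)
    return out


def _reagent_targets(
    recipes: Sequence[RecipeSpec],
) -> tuple[dict[str, dict[str, float]], set[str]]:
    """Targets per reagent: {reagent: {label: c_target_mM}}, plus monomer names."""
    targets: dict[str, dict[str, float]] = {}
    monomers: set[str] = set()
    for recipe in recipes:
        monomers.update(recipe.composition.monomer_names)
        for name, c in target_concentrations(recipe).items():
            if c <= 0:
                continue  # a zero ratio means the reagent is simply absent
            targets.setdefault(name, {})[recipe.label] = c
    return targets, monomers


def select_dilutions(
    recipes: Sequence[RecipeSpec],
    stocks: StockSet,
    constraints: Constraints = Constraints(),
) -> DilutionPlan:
    """Choose, per reagent, a minimum-cardinality set of extra dilutions.

    The stock is always available at no cost; only listed dilutions count
    toward the objective. Among equal-cardinality covers the lexicographically
    highest concentration set is preferred (smaller transfer volumes), and
    each recipe is assigned the highest feasible prepared concentration.
    Recipes with no feasible source for some reagent are reported, not fatal.
    """
    if len({r.label for r in recipes}) != len(recipes):
        raise ValidationError("recipe labels must be unique within a batch")
    targets, monomer_names = _reagent_targets(recipes)
    plan = DilutionPlan(reagents={})
    for name, by_label in targets.items():
        if name not in stocks:
            for label, c in by_label.items():
                plan.infeasible.append(
                    Infeasibility(label, name, c, "no stock available for reagent")
                )
            continue
        stock = stocks[name]
        exempt = name in monomer_names
        by_v_total: dict[str, float] = {r.label: r.v_total for r in recipes}

        feas: dict[str, list[float]] = {}
        for label, c in by_label.items():
            sources = feasible_sources(c, stock, by_v_total[label], constraints, exempt)
            if not sources:
                vt = by_v_total[label]
                cap = vt if exempt else constraints.v_max_frac * vt
                if stock.conc < c:
                    reason = f"target exceeds stock concentration ({stock.conc:g} mM)"
                else:
                    vols = [required_volume(c, cand, vt) for cand in stock.candidates if cand >= c]
                    if vols and max(vols) < constraints.v_min:
                        reason = f"all candidate volumes below v_min ({constraints.v_min:g} uL)"
                    else:
                        reason = f"no candidate volume within [{constraints.v_min:g}, {cap:g}] uL"
                plan.infeasible.append(Infeasibility(label, name, c, reason))
            else:
                feas[label] = sources

        # Labels that stock alone serves are free; the rest need a dilution cover.
        need_cover = {lab: srcs for lab, srcs in feas.items() if stock.conc not in srcs}
        chosen: tuple[float, ...] = ()
        if need_cover:
            dilutions = stock.allowed_dilutions
            best: tuple[float, ...] | None = None
            for k in range(1, len(dilutions) + 1):
                covers = [
                    subset
                    for subset in combinations(dilutions, k)
                    if all(any(c in subset for c in srcs) for srcs in need_cover.values())
                ]
                if covers:
                    best = max(covers)  # lexicographically highest (tuples are desc-sorted)
                    break
            if best is None:  # cannot happen: each label in need_cover has >=1 source
                raise PlanningError(f"internal: no cover found for {name!r}")
            chosen = best
        assignment = {
            lab: max(c for c in (stock.conc, *chosen) if c in srcs)
            for lab, srcs in feas.items()
        }
        plan.reagents[name] = ReagentPlan(prepared=chosen, assignment=assignment)
    return plan


def dilution_prep_steps(
    plan: DilutionPlan,
    stocks: StockSet,
    demand: dict[tuple[str, float], float],
    constraints: Constraints = Constraints(),
    dead_volume: float = 50.0,
    start_index: int = 0,
    vessel_capacity: float = 1500.0,
) -> list[TransferStep]:
    """Transfer steps preparing each planned dilution from its stock.

    ``demand`` maps (reagent, prepared conc) -> summed downstream draw (uL);
    each preparation makes demand + dead_volume. Dilutions are made directly
    from the stock unless the stock transfer would fall below v_min, in which
    case a two-stage serial chain through the next-higher prepared
    concentration is emitted (processing low-to-high so upstream demand
    accumulates before its own preparation volume is fixed).
    """
    steps: list[TransferStep] = []
    order = start_index
    # accumulate chained demand bottom-up, then emit steps top-down
    prep: dict[str, list[tuple[float, float, float]]] = {}  # name -> (conc, src_conc, vol)
    extra_demand: dict[tuple[str, float], float] = dict(demand)
    for name, rplan in plan.reagents.items():
        stock = stocks[name]
        rows: list[tuple[float, float, float]] = []
        for conc in sorted(rplan.prepared):  # ascending: chains add demand upstream
            vol = extra_demand.get((name, conc), 0.0) + dead_volume
            if vol > vessel_capacity:
                raise PlanningError(
                    f"preparation of {name} at {conc:g} mM needs {vol:g} uL "
                    f"(> vessel capacity {vessel_capacity:g} uL)"
                )
            v_stock = required_volume(conc, stock.conc, vol)
            if v_stock >= constraints.v_min:
                rows.append((conc, stock.conc, vol))
            else:
                higher = [c for c in rplan.prepared if c > conc]
                src = min(higher) if higher else None
                if src is None or required_volume(conc, src, vol) < constraints.v_min:
                    raise PlanningError(
                        f"cannot prepare {name} at {conc:g} mM: stock transfer below "
                        f"v_min and no higher prepared concentration to chain through"
                    )
                extra_demand[(name, src)] = extra_demand.get((name, src), 0.0) + required_volume(
                    conc, src, vol
                )
                rows.append((conc, src, vol))
        prep[name] = rows
    for name, rows in prep.items():
        stock = stocks[name]
        for conc, src_conc, vol in sorted(rows, key=lambda r: -r[0]):  # high conc first
            v_src = constraints.quantize(required_volume(conc, src_conc, vol))
            v_solvent = constraints.quantize(vol - v_src)
            src_pos = (
                stock.position if src_conc == stock.conc else f"dilution:{name}@{src_conc:g}"
            )
            dest = f"dilution:{name}@{conc:g}"
            steps.append(
                TransferStep("dilution_prep", name, src_conc, src_pos, dest, v_src, order)
            )
            order += 1
            steps.append(
                TransferStep(
                    "dilution_prep",
                    stocks.solvent_name,
                    0.0,
                    stocks.solvent_position,
                    dest,
                    v_solvent,
                    order,
                )
            )
            order += 1
    return steps


def plan_batch(
    recipes: Sequence[RecipeSpec],
    stocks: StockSet,
    constraints: Constraints = Constraints(),
    plate: PlateGeometry = PlateGeometry(),
    dead_volume: float = 50.0,
) -> Worklist:
    """Plan a full batch: dilutions, per-well transfers, solvent makeup.

    Wells are assigned row-major to feasible recipes in input order. Within a
    well the order is monomer(s), initiator, remaining ratio reagents, solvent
    makeup; the solvent step absorbs the rounding residue so every well sums
    to exactly v_total.
    """
    if not recipes:
        return Worklist([], [], {}, [])
    if len(recipes) > plate.capacity:
        raise PlanningError(
            f"{len(recipes)} recipes exceed plate capacity {plate.capacity}"
        )
    plan = select_dilutions(recipes, stocks, constraints)
    bad = set(plan.infeasible_labels)
    diagnostics = list(plan.infeasible)

    wells = plate.well_ids()
    well_steps: list[TransferStep] = []
    plate_map: dict[str, str] = {}
    v_totals: dict[str, float] = {}
    demand: dict[tuple[str, float], float] = {}
    staged: list[list[TransferStep]] = []

    for recipe in recipes:
        if recipe.label in bad:
            continue
        targets = target_concentrations(recipe)
        ordered = list(recipe.composition.monomer_names)
        ordered.append(recipe.initiator.name)
        ordered.extend(
            n for n in recipe.ratios if n != recipe.initiator.name and targets.get(n, 0) > 0
        )
        q = constraints.quantize
        steps: list[tuple[str, str, float, str, float]] = []  # type, name, conc, pos, vol
        total_q = 0.0
        feasible = True
        for name in ordered:
            c_target = targets[name]
            if c_target <= 0:
                continue
            conc = plan.reagents[name].assignment[recipe.label]
            stock = stocks[name]
            pos = stock.position if conc == stock.conc else f"dilution:{name}@{conc:g}"
            vol = q(required_volume(c_target, conc, recipe.v_total))
            steps.append(("well_transfer", name, conc, pos, vol))
            total_q = round(total_q + vol, 10)
        solvent = round(recipe.v_total - total_q, 10)
        if solvent < 0:
            diagnostics.append(
                Infeasibility(
                    recipe.label,
                    stocks.solvent_name,
                    0.0,
                    f"non-solvent volumes sum to {total_q:g} uL > v_total {recipe.v_total:g} uL",
                )
            )
            feasible = False
        if not feasible:
            bad.add(recipe.label)
            continue
        if solvent > 0:
            steps.append(
                ("solvent_makeup", stocks.solvent_name, 0.0, stocks.solvent_position, solvent)
            )
        well = wells[len(plate_map)]
        plate_map[well] = recipe.label
        v_totals[well] = recipe.v_total
        group = [TransferStep(t, n, c, p, well, v, -1) for (t, n, c, p, v) in steps]
        staged.append(group)
        for s in group:
            if s.step_type == "well_transfer" and s.source_position.startswith("dilution:"):
                key = (s.source_name, s.source_conc_mM)
                demand[key] = demand.get(key, 0.0) + s.volume_uL

    prep_steps = dilution_prep_steps(
        plan, stocks, demand, constraints, dead_volume, start_index=0
    )
    order = len(prep_steps)
    for group in staged:
        for s in group:
            well_steps.append(
                TransferStep(
                    s.step_type,
                    s.source_name,
                    s.source_conc_mM,
                    s.source_position,
                    s.dest,
                    s.volume_uL,
                    order,
                )
            )
            order += 1

    worklist = Worklist(prep_steps, well_steps, plate_map, diagnostics, v_totals)
    logger.info("%s", worklist.summary())
    return worklist
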