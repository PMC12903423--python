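"""Spreadsheet I/O: ratio sheets, stock sheets, and worklist export.

The sheet dialect is this package's own (the upstream robot software's sheets
are lab-internal); column names mirror the bench vocabulary. CSV and XLSX are
both supported, chosen by file extension, and every reader/writer pair
round-trips exactly. Unknown extra columns on a ratio sheet are carried
through on each recipe and re-emitted on write, never dropped.

Ratio sheet columns (photo-ATRP dialect):
    label, monomer_1..monomer_4, frac_1..frac_4 (optional; blank = equimolar),
    initiator, dp, m_final_M, v_total_uL (optional, default 200),
    metal, ratio_metal, ligand, ratio_ligand, pc, ratio_pc

With ``chemistry="pet-raft"`` the optimizable columns are instead
    cta, ratio_cta, pc, ratio_pc
and the CTA takes the initiator slot (ratio 1 by definition).

Stock sheet columns:
    reagent, stock_conc_mM, allowed_dilutions_mM (";"-separated), position
A row with a blank stock_conc_mM declares the solvent source.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .chem import (
    MonomerComposition,
    Reagent,
    RecipeSpec,
    ValidationError,
    load_reagent_table,
)
from .planner import WORKLIST_COLUMNS, Stock, StockSet, Worklist

__all__ = [
    "SheetError",
    "CHEMISTRY_ROLES",
    "read_ratio_sheet",
    "write_ratio_sheet",
    "read_stock_sheet",
    "write_worklist",
    "read_worklist",
]

MAX_MONOMERS = 4

#: Optimizable-role columns per chemistry: column stem -> accepted reagent roles.
CHEMISTRY_ROLES: dict[str, dict[str, set[str]]] = {
    "atrp": {"metal": {"metal"}, "ligand": {"ligand"}, "pc": {"photocatalyst"}},
    "pet-raft": {"cta": {"cta", "initiator"}, "pc": {"photocatalyst"}},
}


class SheetError(ValidationError):
    """Raised for malformed input sheets, naming the offending row and column."""


def _read_any(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path)
    return pd.read_csv(path)


def _write_any(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def _num(row: pd.Series, col: str, label: str) -> float:
    value = row.get(col)
    if pd.isna(value):
        raise SheetError(f"row {label!r}: missing value in column {col!r}")
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SheetError(f"row {label!r}: non-numeric value {value!r} in column {col!r}")


def read_ratio_sheet(
    path: str | Path,
    reagent_table: dict[str, Reagent] | None = None,
    chemistry: str = "atrp",
) -> list[RecipeSpec]:
    """Parse a ratio sheet into validated recipes (up to four monomers per row)."""
    if chemistry not in CHEMISTRY_ROLES:
        raise SheetError(f"unknown chemistry {chemistry!r}")
    table = reagent_table if reagent_table is not None else load_reagent_table()
    frame = _read_any(path)
    if frame.empty:
        return []
    role_cols = CHEMISTRY_ROLES[chemistry]
    extra_monomers = [
        c for c in frame.columns if c.startswith("monomer_") and int(c.split("_")[1]) > MAX_MONOMERS
    ]
    if extra_monomers:
        raise SheetError(
            f"at most {MAX_MONOMERS} monomers are supported; found column(s) {extra_monomers}"
        )
    required = ["label", "monomer_1", "initiator", "dp", "m_final_M"]
    required += [stem for stem in role_cols] + [f"ratio_{stem}" for stem in role_cols]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SheetError(f"ratio sheet is missing required column(s): {missing}")

    known = set(required) | {"v_total_uL"}
    known |= {f"monomer_{i}" for i in range(1, MAX_MONOMERS + 1)}
    known |= {f"frac_{i}" for i in range(1, MAX_MONOMERS + 1)}
    extra_cols = [c for c in frame.columns if c not in known]

    def resolve(name: object, roles: set[str], label: str, col: str) -> Reagent:
        if pd.isna(name):
            raise SheetError(f"row {label!r}: missing reagent name in column {col!r}")
        reagent = table.get(str(name))
        if reagent is None:
            raise SheetError(f"row {label!r}: unknown reagent {name!r} in column {col!r}")
        if reagent.role not in roles:
            raise SheetError(
                f"row {label!r}: reagent {name!r} has role {reagent.role!r}, "
                f"expected one of {sorted(roles)} for column {col!r}"
            )
        return reagent

    recipes: list[RecipeSpec] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        label = str(row["label"])
        if label in seen:
            raise SheetError(f"duplicate recipe label {label!r}")
        seen.add(label)
        monomers: list[Reagent] = []
        fracs: list[float] = []
        for i in range(1, MAX_MONOMERS + 1):
            name = row.get(f"monomer_{i}")
            if pd.isna(name) if name is not None else True:
                continue
            monomers.append(resolve(name, {"monomer"}, label, f"monomer_{i}"))
            frac = row.get(f"frac_{i}")
            fracs.append(float("nan") if frac is None or pd.isna(frac) else float(frac))
        if not monomers:
            raise SheetError(f"row {label!r}: no monomer given")
        if all(pd.isna(f) for f in fracs):
            composition = MonomerComposition.equimolar(monomers)
        elif any(pd.isna(f) for f in fracs):
            raise SheetError(f"row {label!r}: mole fractions must be all blank or all given")
        else:
            composition = MonomerComposition(tuple(zip(monomers, fracs)))
        initiator = resolve(row["initiator"], {"initiator", "cta"}, label, "initiator")
        ratios: dict[str, float] = {}
        for stem, roles in role_cols.items():
            reagent = resolve(row[stem], roles, label, stem)
            ratios[reagent.name] = _num(row, f"ratio_{stem}", label)
        v_total = row.get("v_total_uL")
        v_total = 200.0 if v_total is None or pd.isna(v_total) else float(v_total)
        extras = {c: row[c] for c in extra_cols if not pd.isna(row[c])}
        recipes.append(
            RecipeSpec(
                composition=composition,
                initiator=initiator,
                ratios=ratios,
                dp=_num(row, "dp", label),
                m_final=_num(row, "m_final_M", label),
                v_total=v_total,
                label=label,
                extras=extras,
            )
        )
    return recipes


def write_ratio_sheet(
    recipes: list[RecipeSpec],
    path: str | Path,
    chemistry: str = "atrp",
) -> None:
    """Write recipes back to the ratio-sheet dialect (extras preserved)."""
    role_cols = CHEMISTRY_ROLES[chemistry]
    role_of = {  # invert: reagent role -> column stem
        role: stem for stem, roles in role_cols.items() for role in roles
    }
    table = load_reagent_table()
    rows = []
    for r in recipes:
        row: dict[str, object] = {"label": r.label}
        for i, (monomer, frac) in enumerate(r.composition.entries, start=1):
            row[f"monomer_{i}"] = monomer.name
            row[f"frac_{i}"] = frac
        row["initiator"] = r.initiator.name
        row["dp"] = r.dp
        row["m_final_M"] = r.m_final
        row["v_total_uL"] = r.v_total
        for name, ratio in r.ratios.items():
            if name == r.initiator.name:
                continue
            reagent = table.get(name)
            stem = role_of.get(reagent.role if reagent else "", None)
            if stem is None:
                raise SheetError(
                    f"recipe {r.label!r}: cannot place reagent {name!r} in the "
                    f"{chemistry} sheet dialect"
                )
            row[stem] = name
            row[f"ratio_{stem}"] = ratio
        row.update(r.extras)
        rows.append(row)
    _write_any(pd.DataFrame(rows), path)


def read_stock_sheet(path: str | Path) -> StockSet:
    """Parse a stock sheet into a StockSet (solvent row has blank stock_conc_mM)."""
    frame = _read_any(path)
    missing = [c for c in ("reagent", "stock_conc_mM") if c not in frame.columns]
    if missing:
        raise SheetError(f"stock sheet is missing required column(s): {missing}")
    stocks: dict[str, Stock] = {}
    solvent_name, solvent_position = "DMSO", "solvent"
    for _, row in frame.iterrows():
        name = str(row["reagent"])
        conc = row["stock_conc_mM"]
        position = "" if "position" not in frame.columns or pd.isna(row.get("position")) else str(row["position"])
        if pd.isna(conc):  # solvent source row
            solvent_name, solvent_position = name, position or "solvent"
            continue
        if name in stocks:
            raise SheetError(f"duplicate stock row for reagent {name!r}")
        dilutions: tuple[float, ...] = ()
        raw = row.get("allowed_dilutions_mM")
        if raw is not None and not pd.isna(raw) and str(raw).strip():
            try:
                dilutions = tuple(float(tok) for tok in str(raw).split(";") if tok.strip())
            except ValueError:
                raise SheetError(
                    f"row {name!r}: cannot parse allowed_dilutions_mM value {raw!r}"
                )
        try:
            stocks[name] = Stock(name, float(conc), dilutions, position)
        except ValidationError as exc:
            raise SheetError(f"row {name!r}: {exc}")
    return StockSet(stocks, solvent_name, solvent_position)


def write_worklist(worklist: Worklist | pd.DataFrame, path: str | Path) -> None:
    """Serialize a worklist to CSV or XLSX with the fixed column schema."""
    frame = worklist.to_frame() if isinstance(worklist, Worklist) else worklist
    if list(frame.columns) != WORKLIST_COLUMNS:
        raise SheetError(f"worklist frame must have columns {WORKLIST_COLUMNS}")
    _write_any(frame, path)


def read_worklist(path: str | Path) -> pd.DataFrame:
    """Read a worklist file back; column values round-trip bit-exactly."""
    frame = _read_any(path)
    missing = [c for c in WORKLIST_COLUMNS if c not in frame.columns]
    if missing:
        raise SheetError(f"worklist file is missing column(s): {missing}")
    frame = frame[WORKLIST_COLUMNS]
    return frame.astype(
        {
            "step_type": str,
            "source_name": str,
            "source_conc_mM": float,
            "source_position": str,
            "dest": str,
            "volume_uL": float,
            "order_index": int,
        }
    )
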