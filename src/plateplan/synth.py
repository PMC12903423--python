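"""Synthetic screening batches and fixture sheets.

Real initiation labels come from SEC/NMR on screened wells and are not part
of this package; this module emulates them so the planner and classifier are
testable end to end. A batch is a set of (ligand, metal, PC) molar-ratio
tuples sampled over the screened ranges (ligand 0.2-1, metal 0.08-0.4,
PC 0.001-0.1) by either a grid or Latin hypercube design; labels are drawn
Bernoulli(sigma(linear score)) from a ground truth acting on standardized
features, optionally with symmetric label noise.

The default ground truth (+2 ligand, -1.5 metal, +0.1 PC, intercept 0,
5% label noise) is a synthetic choice, not a fit to any measured data: the
signs and ordering encode the mechanistic picture that more ligand promotes
initiation, more metal (deactivator) suppresses it, and the photocatalyst
loading matters least over the screened range.

What this generator does NOT emulate: reaction kinetics or induction periods,
correlations between ratios and monomer identity, batch-to-batch drift in
labelling criteria, or any dependence of the outcome on [M]_f and light dose.
Passing tests on this data demonstrate that the pipeline recovers a planted
monotone ratio-outcome structure at realistic batch sizes — not that any
particular chemistry behaves this way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .chem import ValidationError
from .classifier import BATCH, FEATURES, LABEL, BatchDataset

__all__ = [
    "GroundTruth",
    "DEFAULT_RANGES",
    "simulate_batch",
    "simulate_campaign",
    "make_fixture_sheets",
]

#: Sampling ranges for the three optimizable molar ratios (low, high).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "ratio_ligand": (0.2, 1.0),
    "ratio_metal": (0.08, 0.4),
    "ratio_pc": (0.001, 0.1),
}

#: Batch sizes of a typical staged screening campaign (42 + 37 + 88 = 167 wells).
CAMPAIGN_SIZES = (42, 37, 88)


@dataclass(frozen=True)
class GroundTruth:
    """Linear label-generating process on standardized ratio features."""

    intercept: float = 0.0
    coef_ligand: float = 2.0
    coef_metal: float = -1.5
    coef_pc: float = 0.1
    noise: float = 0.05  # symmetric label-flip rate

    def __post_init__(self) -> None:
        coefs = (self.intercept, self.coef_ligand, self.coef_metal, self.coef_pc)
        if not all(np.isfinite(c) for c in coefs):
            raise ValidationError("ground-truth coefficients must be finite")
        if not 0.0 <= self.noise < 0.5:
            raise ValidationError(f"label-noise rate must lie in [0, 0.5), got {self.noise}")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.coef_ligand, self.coef_metal, self.coef_pc])


def _uniform_moments(ranges: dict[str, tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Population mean/sd of the uniform design distribution per feature."""
    lo = np.array([ranges[f][0] for f in FEATURES])
    hi = np.array([ranges[f][1] for f in FEATURES])
    return (lo + hi) / 2.0, (hi - lo) / np.sqrt(12.0)


def simulate_batch(
    n: int,
    truth: GroundTruth = GroundTruth(),
    seed: int | np.random.SeedSequence = 0,
    design: str = "latin_hypercube",
    ranges: dict[str, tuple[float, float]] | None = None,
    batch_id: int = 1,
) -> BatchDataset:
    """Sample one labelled batch of ratio tuples.

    ``design`` is "latin_hypercube" (space filling, the usual recommendation
    for small screening batches) or "grid" (near-cubic lattice truncated to
    n). Standardization inside the label model uses the fixed uniform-design
    moments of ``ranges``, so the ground truth is independent of the sample.
    """
    if n <= 0:
        raise ValidationError(f"batch size must be positive, got {n}")
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    for f in FEATURES:
        lo, hi = ranges[f]
        if not lo < hi:
            raise ValidationError(f"empty range for {f!r}: ({lo}, {hi})")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    lo = np.array([ranges[f][0] for f in FEATURES])
    hi = np.array([ranges[f][1] for f in FEATURES])
    if design == "latin_hypercube":
        sampler = qmc.LatinHypercube(d=len(FEATURES), rng=rng)
        X = qmc.scale(sampler.random(n), lo, hi)
    elif design == "grid":
        per_dim = int(np.ceil(n ** (1 / len(FEATURES))))
        axes = [np.linspace(l, h, per_dim) for l, h in zip(lo, hi)]
        mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(FEATURES))
        X = mesh[:n]
    else:
        raise ValidationError(f"unknown design {design!r}")
    mean, sd = _uniform_moments(ranges)
    Z = (X - mean) / sd
    p = 1.0 / (1.0 + np.exp(-(truth.intercept + Z @ truth.coefficients)))
    y = (rng.random(n) < p).astype(int)
    if truth.noise > 0:
        flips = rng.random(n) < truth.noise
        y = np.where(flips, 1 - y, y)
    return BatchDataset.from_arrays(X, y, batch_id=batch_id)


def simulate_campaign(
    sizes: tuple[int, ...] = CAMPAIGN_SIZES,
    truth: GroundTruth = GroundTruth(),
    seed: int = 0,
    design: str = "latin_hypercube",
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[BatchDataset]:
    """Simulate a staged campaign: one batch per size, batch_id 1..len(sizes)."""
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    return [
        simulate_batch(n, truth, seed=child, design=design, ranges=ranges, batch_id=i + 1)
        for i, (n, child) in enumerate(zip(sizes, children))
    ]


def make_fixture_sheets(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the example input sheets and synthetic labelled campaigns.

    Emits:
      stocks_example.csv  — bench stocks (CuBr2 22.5 mM; Me6TREN 200 mM with
                            50/25/11.5 mM dilutions; ZnTPP 4 mM with a 1 mM
                            dilution; EosinY 2 mM) plus monomer/initiator
                            stocks and the DMSO solvent row;
      ratios_example.csv  — the standard acrylate condition
                            (HEA/MBiB/CuBr2/Me6TREN/ZnTPP = 200/1/0.08/0.2/0.002
                            at 1 M) and the open-air condition
                            (200/1/0.05/0.3/0.005 with EosinY at 2 M);
      campaign_synthetic.csv — a 42/37/88-row synthetic labelled campaign;
      screen_synthetic.csv   — an alternate single-batch 167-row screen.
    The labelled files are synthetic (generated, seed-stamped), not
    measurements.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    stocks = pd.DataFrame(
        [
            # neat-monomer molarity for HEA from density ~1.011 g/mL
            {"reagent": "HEA", "stock_conc_mM": 8700.0, "allowed_dilutions_mM": "", "position": "monomers:1"},
            {"reagent": "MBiB", "stock_conc_mM": 100.0, "allowed_dilutions_mM": "", "position": "initiators:1"},
            {"reagent": "CuBr2", "stock_conc_mM": 22.5, "allowed_dilutions_mM": "", "position": "metals:1"},
            {"reagent": "Me6TREN", "stock_conc_mM": 200.0, "allowed_dilutions_mM": "50;25;11.5", "position": "ligands:1"},
            {"reagent": "ZnTPP", "stock_conc_mM": 4.0, "allowed_dilutions_mM": "1", "position": "pcs:1"},
            {"reagent": "EosinY", "stock_conc_mM": 2.0, "allowed_dilutions_mM": "", "position": "pcs:2"},
            {"reagent": "DMSO", "stock_conc_mM": None, "allowed_dilutions_mM": "", "position": "solvents:1"},
        ]
    )
    paths["stocks"] = outdir / "stocks_example.csv"
    stocks.to_csv(paths["stocks"], index=False)

    ratios = pd.DataFrame(
        [
            {
                "label": "acrylate_standard",
                "monomer_1": "HEA",
                "initiator": "MBiB",
                "dp": 200,
                "m_final_M": 1.0,
                "v_total_uL": 200.0,
                "metal": "CuBr2",
                "ratio_metal": 0.08,
                "ligand": "Me6TREN",
                "ratio_ligand": 0.2,
                "pc": "ZnTPP",
                "ratio_pc": 0.002,
            },
            {
                "label": "open_air",
                "monomer_1": "HEA",
                "initiator": "MBiB",
                "dp": 200,
                "m_final_M": 2.0,
                "v_total_uL": 200.0,
                "metal": "CuBr2",
                "ratio_metal": 0.05,
                "ligand": "Me6TREN",
                "ratio_ligand": 0.3,
                "pc": "EosinY",
                "ratio_pc": 0.005,
            },
        ]
    )
    paths["ratios"] = outdir / "ratios_example.csv"
    ratios.to_csv(paths["ratios"], index=False)

    # positives outnumber negatives roughly 2:1, as screening data tend to;
    # with score sd ~2.5 the marginal positive rate is roughly
    # sigmoid(intercept / sqrt(1 + (0.59 * 2.5)^2)), so intercept 1.4 -> ~2/3
    campaign_truth = GroundTruth(intercept=1.4)
    campaign = BatchDataset.concat(simulate_campaign(CAMPAIGN_SIZES, campaign_truth, seed=seed))
    paths["campaign"] = outdir / "campaign_synthetic.csv"
    campaign.to_csv(paths["campaign"])

    screen = simulate_batch(sum(CAMPAIGN_SIZES), campaign_truth, seed=seed + 1, batch_id=1)
    paths["screen"] = outdir / "screen_synthetic.csv"
    screen.to_csv(paths["screen"])
    return paths
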