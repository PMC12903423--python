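# plateplan

Experiment planning for high-throughput, oxygen-tolerant photo-ATRP (and
PET-RAFT) in 96-well plates.

Controlled radical polymerizations are specified at the bench as reagent molar
ratios relative to the alkyl-halide initiator — e.g.
HEA/MBiB/CuBr₂/Me₆TREN/ZnTPP = 200/1/0.08/0.2/0.002 at a final monomer
concentration [M]_f = 1 M in a 200 µL well — but a liquid handler (or a
careful human) needs explicit transfer volumes from stocks of fixed
concentration. plateplan does that translation for whole batches at once:

- **Stoichiometry** — per-well target concentrations
  (c_initiator = [M]_f/DP, c_x = r_x·c_initiator) and theoretical molecular
  weights Mn,th = DP·M̄_monomer + M_initiator;
- **Dilution planning** — given each reagent's stock and the dilution
  concentrations the user is willing to prepare, chooses the *minimum* number
  of extra dilutions so that every recipe can be pipetted within instrument
  limits (smallest transfer v_min, largest well fraction per transfer), by
  exact set-cover enumeration;
- **Worklists** — ordered transfer steps (dilution preps, well transfers,
  solvent makeup) with every well topped to exactly its target volume,
  exported to CSV/XLSX;
- **Screens** — full factorial (ratio levels × ligands × initiators) and
  one-factor-at-a-time designs, plus chain-extension arithmetic for block
  copolymers (equal-volume withdraw-then-add);
- **Initiation classification** — a seeded SGD linear classifier on
  (ligand, metal, PC) ratios with balanced-accuracy evaluation, a
  sequential-batch protocol (train on batch 1 → score batch 2; retrain on
  1∪2 → score batch 3), and exact closed-form feature attributions
  φᵢ(x) = wᵢ·(zᵢ − z̄ᵢ) for the linear model;
- **Synthetic lab** — a generator of labelled screening batches with a
  planted monotone ground truth, so the whole pipeline is testable without
  any instrument data.

## Worked example

Plan the standard acrylate condition against typical bench stocks
(CuBr₂ 22.5 mM; Me₆TREN 200 mM, dilutable to 50/25/11.5 mM; ZnTPP 4 mM,
dilutable to 1 mM):

```python
import plateplan as pp

t = pp.load_reagent_table()
recipe = pp.RecipeSpec(
    composition=pp.MonomerComposition.equimolar([t["HEA"]]),
    initiator=t["MBiB"],
    ratios={"CuBr2": 0.08, "Me6TREN": 0.2, "ZnTPP": 0.002},
    dp=200, m_final=1.0, v_total=200.0, label="acrylate_standard",
)
print(pp.target_concentrations(recipe))
print(round(pp.theoretical_mn(recipe), 1))

stocks = pp.StockSet({
    "HEA": pp.Stock("HEA", 8700.0, (), "monomers:1"),
    "MBiB": pp.Stock("MBiB", 100.0, (), "initiators:1"),
    "CuBr2": pp.Stock("CuBr2", 22.5, (), "metals:1"),
    "Me6TREN": pp.Stock("Me6TREN", 200.0, (50.0, 25.0, 11.5), "ligands:1"),
    "ZnTPP": pp.Stock("ZnTPP", 4.0, (1.0,), "pcs:1"),
})
worklist = pp.plan_batch([recipe], stocks)
print(worklist.to_frame().to_string(index=False))
```

prints

```
{'HEA': 1000.0, 'MBiB': 5.0, 'CuBr2': 0.4, 'Me6TREN': 1.0, 'ZnTPP': 0.01}
23.4
     step_type source_name  source_conc_mM  source_position             dest  volume_uL  order_index
 dilution_prep       ZnTPP             4.0            pcs:1 dilution:ZnTPP@1      13.00            0
 dilution_prep        DMSO             0.0          solvent dilution:ZnTPP@1      39.00            1
 well_transfer         HEA          8700.0       monomers:1               A1      22.99            2
 well_transfer        MBiB           100.0     initiators:1               A1      10.00            3
 well_transfer       CuBr2            22.5         metals:1               A1       3.56            4
 well_transfer     Me6TREN           200.0        ligands:1               A1       1.00            5
 well_transfer       ZnTPP             1.0 dilution:ZnTPP@1               A1       2.00            6
solvent_makeup        DMSO             0.0          solvent               A1     160.45            7
```

Reading the numbers: the initiator sits at [M]_f/DP = 5 mM, so CuBr₂ (ratio
0.08) needs 0.4 mM — 3.56 µL of the 22.5 mM stock. ZnTPP's 0.01 mM target
would need only 0.5 µL of the 4 mM stock, below the 1 µL pipetting floor, so
the planner first prepares a 1 mM dilution (13 µL stock + 39 µL solvent,
covering the 2 µL draw plus dead volume) and draws 2 µL from it. Solvent
makeup tops the well to exactly 200 µL, leaving 100 µL of oxygen headspace in
a 300 µL well. Mn,th for pHEA₂₀₀ from MBiB is 23.4 kDa.

The same flow works from files via the CLI:

```bash
plateplan fixtures demo/                 # example stock/ratio sheets + synthetic campaigns
plateplan plan demo/ratios_example.csv demo/stocks_example.csv -o worklist.csv
plateplan extend --c-stock 11.105 --m-target 2.0 --c-initiator 40
plateplan classify demo/campaign_synthetic.csv --seed 0
```

`extend` prints `transfer volume: 36.0 uL` — the equal-volume
withdraw-then-add transfer that brings a 200 µL macroinitiator well to a 2 M
second-block monomer concentration from an 11.105 M stock.

See `docs/methods.md` for the model conventions, the dilution set-cover
objective, classifier design choices, and what the synthetic generator does
and does not emulate.

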