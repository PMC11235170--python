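# tandemrrm

Analysis toolkit for probing **thermodynamic coupling between tandem RRM
domains** — the situation, typified by the N-terminal module (UP1) of the
RNA-binding protein hnRNP A1, where two RNA-recognition motifs of nearly
identical fold and sequence have very different intrinsic stabilities, and
the interface between them decides whether the weaker domain survives.

It is written for structural biologists and biophysicists who have (or want
to simulate) the four kinds of evidence such a study rests on, and packages
each stage as an independent library module with a thin CLI:

| stage | question | core quantity |
|---|---|---|
| `structcore` | are the domains structurally equivalent but differently packed? | per-residue ASA, lowest-ASA core sets, nearest side-chain packing distance, Cα RMSD, identity/positives |
| `gomodel` | does the packing difference translate into stability? | Cα Go-model folding scans, WHAM heat capacity, folding temperature T_f |
| `cpmg` | do the domains differ in μs–ms dynamics? | R2,eff(ν_CPMG), Rex significance at 1.65σ, two-state exchange fits (k_ex, Φ_ex) |
| `pressure` | how do they unfold under pressure? | per-peak attenuation, two-state fits ΔG_u0, ΔV_u, midpoint p_1/2, sensitive/resistant classes |
| `saxs` | does the whole molecule expand? | Guinier fits (Rg, I₀) with self-consistent q·Rg ≤ 1.3 windows, Rg vs pressure |

plus `synthetic_data`, seeded generators that produce every input kind with
known ground truth, so the entire pipeline is testable without any
instrument data.

## The models in brief

* **Packing** — the structural core of a domain is its 10 residues of
  lowest solvent-accessible surface area (Shrake-Rupley, probe 1.4 Å);
  packing density is the mean over core residues of the nearest
  side-chain-heavy-atom distance to the rest of the core.
* **Folding** — a Clementi-style Cα Go model (12-10 native contact wells,
  native-value bonded terms, truncated excluded volume) integrated by
  BAOAB Langevin dynamics; multi-temperature energy histograms are
  combined by WHAM and T_f is the heat-capacity maximum.
* **Exchange** — R2,eff = −ln(I/I₀)/T_rlx; residues with
  Rex > 1.65 σ_Rex are fitted with the Luz-Meiboom fast and
  Tollinger-Kay slow two-state forms (AICc-selected), validated against an
  in-package Bloch-McConnell propagator.
* **Unfolding** — ΔG_u(p) = ΔG_u0 + ΔV_u(p − p₀);
  f_folded = 1/(1 + e^(−ΔG_u/RT)); p_1/2 = p₀ − ΔG_u0/ΔV_u.
* **Size** — ln I(q) = ln I₀ − Rg²q²/3 on a window grown until
  q_max·Rg ≤ 1.3.

Full derivations, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a pressure series for an unstable isolated domain, then analyze it:

```bash
tandemrrm simulate pressure --preset rrm2_like --seed 2 --out demo
tandemrrm pressure fit demo/pressure.tsv --peak rrm2_like_001
```

```json
{
  "rrm2_like_001": {
    "dg0_kj_mol": 11.15,
    "dv_ml_mol": -77.05,
    "p_half_bar": 1447.95,
    ...
  }
}
```

The fitted unfolding free energy (11.2 kJ/mol at 1 bar) and volume change
(−77 mL/mol) put the unfolding midpoint near 1.45 kbar: at that pressure
folded and unfolded populations are equal, and by 2.5 kbar the native
crosspeak has essentially vanished. The same call on a `rrm1_like` cohort
returns `"insufficient transition"` flags — a domain losing only ~8 % of
its intensity by 2.5 kbar carries no fittable transition, which is itself
the scientifically meaningful readout for a pressure-resistant domain.

Python access is one import away:

```python
from tandemrrm import pressure, synthetic_data

series, truth = synthetic_data.gen_pressure("up1dm_like", seed=2)
table = pressure.attenuation_table([s for s in series if s.species == "native"])
labels = pressure.classify_peaks(table)
print(f"{table.mean:.1f}% mean attenuation, gap = {labels.bimodality_gap:.1f}")
# 52.7% mean attenuation, gap = 18.0
```

A bimodality gap that large is the signature of an interface-broken tandem
construct: one subset of peaks unfolds almost completely while the other
barely responds.

The five-stage pipeline on simulated inputs, end to end:

```bash
tandemrrm pipeline --seed 5 --out run1
```

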