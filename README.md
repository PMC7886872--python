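# hepasim

Reduced-order, desk-scale simulation of hepatic arterial microsphere
transport for radioembolization treatment planning, with a fully synthetic
input generator and agreement statistics against an "observed" activity
distribution.

The pipeline mirrors a personalized treatment-simulation workflow:

1. **`hepasim.vasculature`** — synthetic truncated arterial trees (binary
   branching, Murray's-law radii), 8-segment liver volume/perfusion
   phantoms, catheter placements, and a noisy synthetic observation standing
   in for post-treatment quantitative imaging.
2. **`hepasim.boundary`** — per-segment arterial flow
   `q_s = V0_s·k1_s + Σ Vc_i·k2_i` (ml/min), equal healthy-volume and
   proximity-weighted tumor-volume assignment to outlets, per-outlet flow
   boundary conditions, inlet flow as their sum.
3. **`hepasim.hemodynamics`** — pulsatile inlet waveform (truncated Fourier
   pulse with exact cycle mean), 0D prescribed-fraction branch flows,
   quasi-steady Poiseuille profiles, Carreau shear-thinning viscosity.
4. **`hepasim.transport`** — Lagrangian microsphere tracking (Stokes drag +
   gravity/buoyancy, semi-implicit integration, default dt = 2 ms over four
   1 s cardiac cycles, injection during the first cycle), flux-matched chord
   partition of the lumen at bifurcations, per-outlet exit tallies.
5. **`hepasim.activity`** — outlet tallies → per-segment activity percent,
   absolute Bq and mean Bq/ml; multi-infusion combination weighted by GBq.
6. **`hepasim.stats`** — percentage-point differences, Spearman rank
   correlation (mid-ranks), Bland–Altman limits of agreement with 95% CIs,
   optional agreement plot.
7. **`hepasim.pipeline` / `hepasim.cli`** — one-config orchestration with
   derived per-stage seeds; byte-identical artifacts for identical
   (config, seed).

## CLI

```bash
hepasim generate-phantom --seed 1 --tumors 2 --depth 4 --out phantom/
hepasim compute-bc --phantom phantom/ --out bc.csv
hepasim run-all --config src/hepasim/data/demo_config.json --out run/
hepasim validate --simulated run/activity.csv --observed run/observed.csv \
    --out report.json
```

`run-all`/`simulate` accept `--seed`, `--particles` and `--cycles`
overrides. A demo configuration ships in `src/hepasim/data/demo_config.json`
along with example patient volume/perfusion tables
(`patient_segments.csv`, `patient{1,2,3}_tumors.csv`).

## Scope notes

- Outlet flows are boundary conditions, so branch flows follow from the
  prescribed split (0D); no pressure–resistance network solve.
- One-way fluid→particle coupling; no embolization/stasis feedback, vessel
  compliance, or catheter-induced obstruction.
- Cross-sectional positions are redistributed flux-weighted on branch entry;
  eccentric-release effects act at the bifurcation nearest the catheter tip.
- Carreau parameters and microsphere size/density are generic literature
  blood/resin-sphere values, all configurable.
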