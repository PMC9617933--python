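# dbsteer

A toolkit for algorithm-guided programming of directional deep-brain-stimulation
(DBS) leads. It models an 8-electrode (1-3-3-1) directional lead, collapses
multi-symptom clinical assessments into a single total weighted score, and runs
a two-stage iterative optimization loop over the stimulation space — ring-mode
(vertical position × amplitude) first, then directional-mode (rotation angle ×
amplitude) at the best vertical position. A synthetic-patient simulator makes
the full loop testable without clinical data, and a similarity module compares
stimulation settings, activated volumes and score profiles.

## Modules

| Module | Purpose |
|---|---|
| `dbsteer.lead` | Lead geometry; continuous (position, angle, amplitude) coordinates ↔ integer-percent electrode fractionalizations; configuration-string dialect |
| `dbsteer.scoring` | Symptom weights from baselines (`w = Δ²/(4·off)`), top-4 selection, total weighted score |
| `dbsteer.score_map` | Inverse-distance-weighted score surrogate over each 2D stage space, with side-effect amplitude boundaries |
| `dbsteer.optimizer` | Predefined seed points, explore-then-exploit acquisition, distance-threshold convergence, two-stage session loop |
| `dbsteer.patient_sim` | Synthetic patients (Gaussian spatial kernel × amplitude sigmoid per symptom, side-effect threshold surface); brute-force grid oracle |
| `dbsteer.similarity` | Setting similarity (amplitude ratio × electrode-configuration distance), voxel activated-volume stand-in with Jaccard overlap, score similarity |
| `dbsteer.session_io` / `dbsteer.cli` | Config loading (YAML/JSON), versioned session JSON, settings-table CSV dialect, CLI |

The activated-volume model is a deliberately simple stand-in (current-scaled
spheres minus an encapsulation shell), not a finite-element model; its absolute
volumes and Jaccard values are only meaningful relative to each other.

## CLI

```sh
# generate a synthetic patient (presets: easy | clinical | adversarial)
dbsteer simulate --seed 7 --preset clinical --out patient.json

# run the two-stage optimization for one hemisphere (deterministic per seed)
dbsteer optimize --patient patient.json --out session.json
dbsteer optimize --seed 7 --out session.json          # ad-hoc patient

# burden summary and score-map export of a recorded session
dbsteer report session.json
dbsteer export session.json --out-dir maps/

# row-by-row similarity of two settings tables (CSV dialect below)
dbsteer compare soc.csv agp.csv --out report.jsonl
```

Settings tables are CSV with columns `subject, hemisphere, arm, amplitude_mA,
frequency_Hz, pulse_width_us, electrode_configuration, stimulation_mode`, where
the configuration column uses strings like `"E1: -70%, E2, E3, E4: -10%"`
(grouped labels share the trailing percent). A bundled example cohort is
available via `dbsteer.session_io.load_reference_settings()`.

Run configuration files are YAML/JSON; unknown keys are rejected. Defaults:
130 Hz, 60 µs pulse width, 30 s wash-in (logged, never optimized), 5.0 mA
amplitude limit, 31×26 score-map lattice.

## Synthetic patient presets

Per symptom the simulator draws a baseline (2–4), a maximum improvement, a
sweet spot `(p*, θ*)`, spatial scales (σ_p ∈ [0.6, 1.0] level units,
σ_θ ∈ [60, 110]°), and an amplitude sigmoid (midpoint 1.0–2.5 mA). `easy` is
noise-free with one shared sweet spot and no side effects; `clinical` adds
score noise (0.15 clinician / 0.05 sensor SD) and a side-effect sector;
`adversarial` forces conflicting sweet spots ≥ 1 level unit apart.

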