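# cadecea

A Markov cohort cost-effectiveness model of **AI-aided polyp detection
(CADe) versus conventional colonoscopy** in patients referred for
colonoscopy after a positive faecal immunochemical test (FIT), from a
Canadian provincial payer perspective (2022 CAD).

## Who this is for

Health-economics and gastroenterology researchers who want a tested,
scriptable implementation of the published two-stage decision model: to
reproduce its base case, probe its assumptions (deterministic tornado
analysis), quantify decision uncertainty (probabilistic sensitivity
analysis with a cost-effectiveness acceptability curve), or re-run the
analysis under their own parameters, life tables, costs or surveillance
policies.

## The model

A cohort enters at age 50 with the FIT-positive mix of health states
(40.43% healthy; 34%/10.64%/10.43% small/medium/large adenomas;
2.37%/0.90%/1.23% CRC stages I–III) and receives an index colonoscopy.
Colonoscopy sensitivity is one minus the size-specific adenoma miss rate
(AMR: 31%, 19%, 9%); the CRC I/II miss rate is the large-adenoma AMR
halved (4.5%). The CADe arm uses the published AI-aided miss rates
(17.26%, 8.28%, 7.60%), with the CADe effect on CRC derived from the
per-patient detection rate ratio (3.36). Detected adenomas are resected;
detected cancers are treated (surgery ± chemotherapy) with stage-specific
recurrence and mortality. Missed lesions progress along the
adenoma–carcinoma sequence at published annual probabilities, and
undetected cancers can present clinically between scheduled tests.
Guideline surveillance (10-year FIT after a negative colonoscopy, 5-/3-year
colonoscopy after low-/high-risk findings) is encoded as tunnel states —
an integer countdown clock expanding the Markov state space — so the
whole model remains a finite Markov chain advanced in 1-year cycles to
age 100.

Per arm the model accrues discounted (3.5%/year) life years, QALYs
(utilities: adenoma 0.91; CRC I/II 0.67; III 0.59; IV 0.25) and costs,
including a CADe device fee of $2,250/month amortised over 1,000
colonoscopies/year ($27 per procedure). Arms are compared by incremental
cost-effectiveness ratio (ICER) with dominance classification and net
monetary benefit at a willingness-to-pay of $50,000/QALY:

    NMB = WTP × ΔQALY − ΔCost,    ICER = ΔCost / ΔEffect.

## Worked example

```python
import cadecea as cc

cfg = cc.default_scenario()                    # the packaged base case
conv = cc.run_arm(cfg, cc.conventional_detection(cfg.detection))
cade = cc.run_arm(cfg, cc.cade_detection(cfg.detection))
ce = cc.compare(conv, cade, cfg.economics.wtp)
print(f"conventional: {conv.ly:.3f} LY, {conv.qaly:.3f} QALY, ${conv.cost:,.2f}")
print(f"CADe:         {cade.ly:.3f} LY, {cade.qaly:.3f} QALY, ${cade.cost:,.2f}")
print(f"increment: ΔC ${ce.delta_cost:,.2f}, ΔQALY {ce.delta_qaly:.4f},"
      f" ICER {ce.icer_per_qaly}, NMB ${ce.nmb:,.2f}")
```

prints

```
conventional: 19.128 LY, 17.084 QALY, $3,013.30
CADe:         19.147 LY, 17.103 QALY, $2,986.45
increment: ΔC $-26.86, ΔQALY 0.0188, ICER DOMINANT, NMB $968.99
```

CADe adds a device fee to every colonoscopy yet still lowers the
lifetime per-case cost (fewer downstream cancer treatments and
follow-ups) while gaining QALYs, so it *dominates* conventional
colonoscopy — no ratio is reported for a dominant strategy.

The same run from a shell, plus the sensitivity analyses:

```bash
cadecea base --out out/base
cadecea dsa  --out out/dsa                      # tornado.csv, sorted by NMB spread
cadecea psa  --out out/psa --n-draws 1000 --seed 1 --truncation full
cadecea psa  --out out/psa_pos --n-draws 1000 --seed 1 --truncation positive
```

The PSA samples every parameter with a published uncertainty range (Beta
for probabilities/utilities, Gamma for costs at ±15%, Lognormal for rate
ratios) and reports the fraction of 1,000 simulations in which CADe is
cost-effective at $50,000/QALY, either across the full IRR confidence
intervals or restricted to the detection-improving range (IRR ≥ 1).

Scenario files are plain YAML overriding any subset of the defaults
(`cadecea fixtures --name paper_base --out scenario.yaml` writes a full
template); a custom background life table can be supplied as a
two-column CSV (age, qx).

## Layout

- `src/cadecea/params.py` — parameter schema, packaged defaults, YAML I/O
- `src/cadecea/detection.py` — per-arm colonoscopy sensitivity
- `src/cadecea/states.py`, `natural_history.py` — tunnel-state space and the one-cycle transition operator
- `src/cadecea/cohort.py` — lifetime cohort runs and the microsimulation oracle
- `src/cadecea/economics.py` — ICER / dominance / NMB comparison
- `src/cadecea/sensitivity.py` — tornado DSA and Monte Carlo PSA + CEAC
- `src/cadecea/synthetic.py` — Gompertz–Makeham life table, fixtures, trajectory sampling
- `src/cadecea/cli.py` — `cadecea base | dsa | psa | validate | fixtures`

See `docs/methods.md` for the model's assumptions, calibrations and
limitations.
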