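"""Simulate a paired pre/post cohort and look at its ground truth.

The generator plants clonal expansion in responders' repertoires and a
matched activation program (pDC shift, interferon module, disturbance)
in their expression data, coupled through a per-patient strength.
"""

from pathlib import Path

import clonalshift as cs

cfg = cs.CohortConfig(seed=7)
records, truth = cs.simulate_cohort(cfg)

print(f"{cfg.n_patients} patients, "
      f"{sum(t.responder for t in truth.patients)} responders")
for t in truth.patients[:4]:
    print(f"  {t.patient_id}: responder={t.responder} "
          f"expansion x{t.realized_expansion:.2f} "
          f"pdc_shift={t.realized_pdc_shift:.2f}")

r = records[0]
print(f"\n{r.patient_id} pre repertoire: {len(r.repertoire_pre.clones)} clones, "
      f"{r.repertoire_pre.total_count} reads")
print(f"{r.patient_id} pre expression: {r.expression_pre.shape[0]} cells x "
      f"{r.expression_pre.shape[1]} genes")

# persist the cohort as AIRR TSVs + MTX for file-based workflows
out = Path("scratch_cohort")
cs.write_cohort(records, truth, cfg, out)
print(f"\nwrote cohort files under {out}/")
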