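"""Quantify clonal expansion from paired TCR repertoires.

A negative diversity-index log fold change (DI logFC) means the post
sample is more clonal than the pre sample; the top-N clone mass shows
how concentrated the expanded repertoire is.
"""

import clonalshift as cs

cfg = cs.CohortConfig(seed=7)
records, truth = cs.simulate_cohort(cfg)

print(f"{'patient':8} {'resp':5} {'DI pre':>8} {'DI post':>8} "
      f"{'DI logFC':>9} {'top200 mass':>12}")
for r, t in zip(records, truth.patients):
    rec = cs.di_logfc(r.repertoire_pre, r.repertoire_post)
    prof = cs.top_clone_mass(r.repertoire_pre, r.repertoire_post, n_top=200)
    print(f"{r.patient_id:8} {str(t.responder):5} {rec.di_pre:8.4f} "
          f"{rec.di_post:8.4f} {rec.di_logfc:9.4f} {prof.mass_post:12.3f}")

n_neg = sum(
    cs.di_logfc(r.repertoire_pre, r.repertoire_post).di_logfc < 0
    for r in records)
print(f"\n{n_neg}/{len(records)} patients show expansion (DI logFC < 0)")
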