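"""Torsades de pointes classification and the inducibility table.

Synthesizes pseudo-ECG episodes on both sides of the operational TdP
definition (polymorphic ventricular tachycardia of more than 3 beats), then
tabulates the packaged 10-heart x 4-condition inducibility fixture and runs
Cochran's Q across conditions.
"""

from camapper import (
    classify_episode,
    cochran_q,
    make_episode_pecg,
    make_inducibility_fixture,
)

for label, n_beats in [("tdp", 3), ("tdp", 4), ("monomorphic_vt", 10)]:
    trace, _ = make_episode_pecg(label, n_beats, intrinsic_cl_ms=800.0, seed=0)
    epi = classify_episode(trace, intrinsic_cl_ms=800.0)
    corr = min(epi.morphology_correlations) if epi.morphology_correlations else None
    print(f"{n_beats}-beat {label} episode -> {epi.label} "
          f"(n_beats={epi.n_beats}, min successive r={corr:.2f})")

table = make_inducibility_fixture()
print("\ncondition  n_inducible  percent")
for cond, cnt, pct in zip(table.conditions, table.counts, table.percentages):
    print(f"{cond:<10} {cnt:>11}  {pct:.1f}%")

q = cochran_q(table.inducible)
print(f"\nCochran's Q across conditions: Q={q.q_stat:.2f}, df={q.df}, p={q.p:.4f}")

# A 3-beat polymorphic run is not TdP (the definition requires more than 3
# beats); the fixture reproduces the 0%/70%/20%/0% inducibility pattern and
# Cochran's Q confirms the condition effect.
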