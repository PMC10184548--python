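"""Hearing-frequency inference from inner-ear and basicranial measurements.

The endosseous cochlear duct length (ECD), normalised by basicranial
length (BCL) and log-transformed, predicts best hearing range and mean
best frequency through two empirical linear relations.
"""

from paleoneuro import hearing_estimate, load_reference_table

specimens = [
    ("Baryonyx (NHMUK PV R9951)", 19.6, 104.5),
    ("Ceratosuchops (IWCMS 2014.95.3)", 17.7, 106.8),
]
for label, ecd, bcl in specimens:
    est = hearing_estimate(ecd, bcl)
    print(
        f"{label}: x = {est.x:+.4f}  "
        f"best range {est.best_range_hz:.0f} Hz, "
        f"mean best {est.mean_freq_hz:.0f} Hz"
    )

# Context: the packaged comparative table (15 saurischians)
print("\ncomparative span of best hearing range:")
rows = [
    (r.taxon, r.values["best_hz"])
    for r in load_reference_table("hearing")
]
lo = min(rows, key=lambda t: t[1])
hi = max(rows, key=lambda t: t[1])
print(f"  lowest : {lo[0]} at {lo[1]:.0f} Hz")
print(f"  highest: {hi[0]} at {hi[1]:.0f} Hz")
# Large-bodied theropods cluster at the low-frequency end; small
# paravians and troodontids at the high end.
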