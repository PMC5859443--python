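"""From McrBC-qPCR Ct pairs to per-plant methylation calls.

McrBC cleaves methylated templates, so the digested aliquot amplifies
later than the mock; each extra cycle of delay halves the surviving
unmethylated fraction (at perfect efficiency E = 2).
"""

from paraseg.mcrbc import McrBCMeasurement, call_plant, summarize_family

plants = {  # (Ct digested, Ct mock)
    "F2_01": (20.0, 20.0),  # no delay: unmethylated
    "F2_02": (21.0, 20.0),  # one cycle: half the molecules methylated
    "F2_03": (24.0, 20.0),  # four cycles: ~94% methylated
    "F2_04": (27.3, 20.0),
    "F2_05": (20.9, 20.0),
    "F2_06": (25.0, 20.0),
}
calls = [
    call_plant(McrBCMeasurement(sample, "Hyper1", ct_d, ct_m))
    for sample, (ct_d, ct_m) in plants.items()
]
for c in calls:
    print(f"{c.sample}: fraction methylated = {c.fraction_methylated:.3f} -> {c.level}")

pedigree = {s: ("F1_a" if i < 3 else "F1_b") for i, s in enumerate(plants)}
print("\nF2 classes split by F1 parent (low / intermediate / high):")
print(summarize_family(calls, pedigree))
# Low is <= 33%, intermediate <= 66%, high > 66% of molecules methylated.
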