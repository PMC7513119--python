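"""Absolute-tolerance sample and fuzzy entropy on a synthetic VF window.

Generates one VF-like record, cuts the 5 s pre-shock analysis window
(leaving the 1 s guard), runs the entropy pipeline (band-pass 0.5-30 Hz,
resample to 60 Hz), and shows how the same waveform scores at different
matching tolerances — and how doubling the amplitude changes the score,
because the tolerance r is in µV, not SD units.
"""

from vfshock import (
    EntropyParams,
    VfGenParams,
    extract_preshock_window,
    fuzzyen,
    generate_vf,
    prepare_series,
    sampen,
)

record = generate_vf(VfGenParams(seed=1, amplitude=250, irregularity=0.6))
shock = record.shocks[0]
window = extract_preshock_window(record, shock, wl=5.0)
x60 = prepare_series(window.samples, window.fs, fs_star=60.0)

print(f"record: {record.duration:.0f} s at {record.fs:.0f} Hz, "
      f"window of {window.samples.size} samples -> {x60.size} at 60 Hz\n")

print(" r (µV)   SampEn(m=1)   FuzzyEn(m=3)")
for r in (15.0, 50.0, 80.0):
    s = sampen(x60, EntropyParams(m=1, r=r))
    f = fuzzyen(x60, EntropyParams(m=3, r=r))
    print(f"{r:7.0f}   {s.value:11.3f}   {f.value:12.3f}")

params = EntropyParams(m=3, r=80.0)
base = fuzzyen(x60, params).value
doubled = fuzzyen(2.0 * x60, params).value
print(f"\nFuzzyEn(m=3, r=80 µV): {base:.3f} -> {doubled:.3f} after doubling "
      "the amplitude")
print("Entropy falls as r grows (fewer mismatches) and rises with VF "
      "amplitude at fixed r:\nthe statistic deliberately encodes amplitude "
      "and irregularity together.")
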