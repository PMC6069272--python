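"""Power-of-two IIR filtering: shift exponents, cutoffs, and fixed-point
step response.

Each first-order section costs one shift-and-add per sample; its only
coefficient is the shift exponent k, which maps to a cutoff frequency
Fc = 1 / ((2^k - 1) 2 pi Ts).  This script prints the full cutoff table at
10 kHz sampling and the exact integer step response of a k=3 section.
"""

from meaflow import FirstOrderLowpass, FilterUnit, cutoff_from_k, k_from_cutoff

TS = 1e-4  # 10 kHz sampling

print("shift exponent -> cutoff (10 kHz sampling)")
for k in range(1, 18):
    print(f"  k={k:2d}  Fc = {cutoff_from_k(k, TS):10.3f} Hz")

print("\nnearest exponents for standard bands:")
for fc, label in [(300.0, "spike high-pass"), (100.0, "LFP upper edge"),
                  (2.0, "slow-potential upper edge"), (0.2, "slow-potential lower edge")]:
    k = k_from_cutoff(fc, TS)
    print(f"  {label:26s} target {fc:7.1f} Hz -> k={k:2d} "
          f"(actual {cutoff_from_k(k, TS):8.3f} Hz)")

sec = FirstOrderLowpass(3)
resp = [sec.step(1024) for _ in range(8)]
print("\nstep response of k=3 section to x=1024 (exact integers):")
print(" ", resp)
print("  (geometric approach to 1024 with ratio 7/8: unit DC gain)")

# band-pass as the difference of two chain taps
bp = FilterUnit(k_list=[2, 4], lp_tap=1, hp_tap=2)
trace = [bp.step(1000)[2] for _ in range(200)]
print("\nband-pass (k=[2,4], ~106-530 Hz) response to a DC step,")
print("sampled every 10 ticks:")
print(" ", trace[::10])
print("  the step transient passes, then the output returns to zero:")
print("  the band-pass rejects DC offsets")
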