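"""Immunity of the adaptive threshold to stimulus-correlated global offsets.

A 'global effect' shifts every T-value by a constant; fixed thresholds
then cut the distribution at the wrong point, while the mixture model
re-estimates the noise mean and moves its threshold along.  Dice overlap
between the thresholded shifted and unshifted maps measures stability.
"""

from athresh import run_global_experiment, summarize_global

table = run_global_experiment(n_reps=15, signal_height=0.08, seed=5)
s = summarize_global(table, n_boot=500, seed=5)

print("mean Dice(shifted vs unshifted mask), 15 replicates at SNR 0.08:")
for meth in ("AT", "FT-p", "FT-FWE"):
    print(f"  {meth:7s} {table[f'dice_{meth}'].mean():.3f}")
print()
print(f"Dice improvement of AT over FT 0.001: "
      f"{s['dice_improvement_ft_p']:+.3f}")
print(f"Dice improvement of AT over FT FWE:   "
      f"{s['dice_improvement_ft_fwe']:+.3f}")
print(f"corr(applied shift, fitted noise mean): {s['r_shift_mu']:.3f}")
print(f"corr(|shift|, Dice gain over FT 0.001): "
      f"{s['r_absshift_dicediff_ft_p']:.3f}")
print()
print("The fitted Gaussian mean tracks the injected offset almost exactly,")
print("so the adaptive masks barely move while fixed-threshold masks grow")
print("or shrink with the shift.")
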