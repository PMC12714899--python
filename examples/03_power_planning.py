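"""Plan group sizes from an anticipated effect and within-group spread.

Cohen's d divides the detectable mean difference by the pooled residual SD
(sqrt of summed SS over summed df).  The per-group n then comes from the
two-sample normal approximation at alpha = 0.05 (two-sided) and 80% power.
"""

from thermopref import PowerSpec, cohens_d, sample_size_per_group

# sigma = 1.2 C expressed through its sum-of-squares decomposition
for label, delta in (("sex difference (~1.5 C)", 1.5), ("inflammation (>2 C)", 2.0)):
    effect = cohens_d(delta, ss_a=72.0, dfd_a=50, ss_b=72.0, dfd_b=50)
    n = sample_size_per_group(effect.d)
    n_exact = sample_size_per_group(effect.d, PowerSpec(method="noncentral_t"))
    print(f"{label}")
    print(f"  pooled sigma = {effect.pooled_sigma:.2f} C, d = {effect.d:.2f}")
    print(f"  n/group = {n} (normal approximation), {n_exact} (noncentral t)")

print()
print("d >= 0.8 is conventionally a large effect; the noncentral-t count is")
print("the exact requirement and is never smaller than the approximation.")
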