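"""GxL-aware power analysis for a two-group design.

With an interaction factor gamma > 0 the comparison's standard error floors
at sigma*sqrt(2)*gamma no matter how many animals are used, so power is
capped.  This example prints the power curve over n, the asymptotic ceiling,
and the sample size needed for 80% power when it is attainable.
"""

from gxl import PowerDesign, power_limit, power_of_design, required_n

effect, sigma = 1.0, 1.0
for gamma in (0.0, 0.3, 0.5):
    ceiling = power_limit(effect, sigma, gamma, n_labs=3, n_genotypes=6)
    curve = {n: power_of_design(PowerDesign(effect, sigma, gamma, n_per_group=n))
             for n in (5, 10, 20, 50, 1000)}
    pts = "  ".join(f"n={n}: {p:.3f}" for n, p in curve.items())
    print(f"gamma={gamma:.1f}  {pts}  ceiling: {ceiling:.3f}")

print()
for gamma in (0.0, 0.15, 0.5):
    res = required_n(effect, sigma, gamma, target_power=0.8)
    if res.attainable:
        print(f"gamma={gamma:.2f}: need n = {res.n} per group for 80% power")
    else:
        print(f"gamma={gamma:.2f}: 80% power unattainable "
              f"(ceiling {res.asymptotic_power:.3f}) - no sample size suffices")
print()
print("Adding animals cannot compensate for genotype-by-lab interaction:")
print("above the ceiling the only remedies are better phenotypes or more labs.")
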