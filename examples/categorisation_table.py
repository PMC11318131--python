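"""How much information does a coarse outcome scale retain?

Builds categorised versions of the 0-99 gold-standard scale and computes the
variance from outcome categorisation for a uniform population and a tight
normal one (SD = 5).
"""

from noisy_measures import (
    categorisation_variance,
    constrained_normal_distribution,
    make_scale,
    uniform_distribution,
)

uniform = uniform_distribution()
tight = constrained_normal_distribution(mu=49.5, sigma=5.0)

print("M   uniform sigma_c^2 (reduction)   normal SD=5 sigma_c^2 (reduction)")
for M in (1, 2, 3, 5, 10, 100):
    scale = make_scale(M)
    u = categorisation_variance(uniform, scale)
    n = categorisation_variance(tight, scale)
    print(
        f"{M:>3} {u.sigma_c_sq:>10.2f} ({u.pct_reduction:6.1f}%)"
        f"   {n.sigma_c_sq:>10.2f} ({n.pct_reduction:8.1f}%)"
    )

print(
    "\nA 5-category scale removes 96% of the variance of non-measurement for"
    "\na uniform outcome, but a dichotomy on a tight SD=5 population is far"
    "\nworse than not measuring at all (negative reduction): scales must be"
    "\ncalibrated to the population's spread."
)
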